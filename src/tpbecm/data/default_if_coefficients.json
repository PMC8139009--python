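{
  "PPC": {
    "kind": "PPC",
    "values": [0.00469, 0.00112, 0.0044],
    "units_note": "h1 in mm; permittivity log arguments relative (dimensionless); IF in geometric-factor units",
    "provenance": "published-default"
  },
  "SPC": {
    "kind": "SPC",
    "values": [2830.0, 1000.0, 1300.0],
    "units_note": "h1 in mm; permittivity log arguments relative (dimensionless); IF in geometric-factor units",
    "provenance": "published-default"
  }
}
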