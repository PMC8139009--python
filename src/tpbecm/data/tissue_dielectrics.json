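{
  "_provenance": "Approximate transcription of the standard parametric tissue dielectric database (Gabriel et al., Phys. Med. Biol. 41, 1996; 4-term Cole-Cole models). External literature values, shipped as a swappable starter pack; replace with subject-specific tables where available.",
  "materials": {
    "skin_dry": {
      "eps_inf": 4.0,
      "sigma_static": 0.0002,
      "valid_range": [1e-3, 1e7],
      "terms": [
        {"delta_eps": 32.0, "tau_s": 7.23e-12, "alpha": 0.0},
        {"delta_eps": 1100.0, "tau_s": 32.48e-9, "alpha": 0.2}
      ]
    },
    "fat": {
      "eps_inf": 2.5,
      "sigma_static": 0.035,
      "valid_range": [1e-3, 1e7],
      "terms": [
        {"delta_eps": 9.0, "tau_s": 7.96e-12, "alpha": 0.2},
        {"delta_eps": 35.0, "tau_s": 15.92e-9, "alpha": 0.1},
        {"delta_eps": 33000.0, "tau_s": 159.15e-6, "alpha": 0.05},
        {"delta_eps": 1e7, "tau_s": 15.915e-3, "alpha": 0.01}
      ]
    },
    "muscle": {
      "eps_inf": 4.0,
      "sigma_static": 0.2,
      "valid_range": [1e-3, 1e7],
      "terms": [
        {"delta_eps": 50.0, "tau_s": 7.23e-12, "alpha": 0.1},
        {"delta_eps": 7000.0, "tau_s": 353.68e-9, "alpha": 0.1},
        {"delta_eps": 1.2e6, "tau_s": 318.31e-6, "alpha": 0.1},
        {"delta_eps": 2.5e7, "tau_s": 2.274e-3, "alpha": 0.0}
      ]
    }
  }
}
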