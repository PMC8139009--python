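# Example layered-body description: human forearm under a surface electrode
# pair (1 cm x 1 cm electrodes, 1 cm apart) with conductive gel.
# Materials refer to the built-in tissue dielectric starter pack.
layers:
  - material: skin_dry
    thickness_mm: 1.5
  - material: fat
    thickness_mm: 2.5
  - material: muscle
    infinite: true
geometry:
  width_m: 0.01
  length_m: 0.01
  separation_m: 0.01
gel_ohms: 160.0
# null -> conformal-mapping half-space estimate from the geometry
g2_m: null
# unit-interpretation factor applied to every interdimensional factor;
# see docs/methods.md ("Calibrating the IF scale")
calibration_scale: 1.0
materials: builtin
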