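# Medium, probe and run-control block for `wmcfit simulate` / `wmcfit build-lut`.
# Lengths in mm, times in ps; budget = detection-record target per run.
medium:
  musp: 1.7        # reduced scattering coefficient, mm^-1 (mus = musp/(1-g))
  g: 0.9
  n: 1.4
probe:
  source_radius: 0.025
  source_half_angle: 11.5
  detector_radius: 0.025
  detector_na: 0.2
  separation: 1.25
  immersion_depth: 0.0   # > 0 for immersed (liquid-phantom) geometry
  n_outside: 1.0
sim:
  bin_width_ps: 0.3125
  t_max_ps: 300.0
  budget: 60000
  seed: 1
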