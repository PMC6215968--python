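# One bent strand at 2x coarser resolution: 1.5 mm muscle, 6 mm
# endocardial bath, interface curvature +pi/2 1/cm (theta = pi, c = +1).
# Units: cm, radians, ms, mS/cm.  Run with:  endocv run-config strand.yaml
strand:
  lm: 0.15
  lb_endo: 0.6
  theta: 3.141592653589793
  c: 1
  hX: 0.005
  hY: 0.01

conductivity:
  sigma_if: 4.5
  sigma_it: 0.45
  sigma_ef: 4.5
  sigma_et: 1.8
  sigma_b: 20.0
  C_m: 1.0
  chi: 1000.0

stimulus:
  amplitude: 1.0e+5  # uA/cm^3 (equal-and-opposite compartment pair)
  duration: 2.0      # ms

simulation:
  dt: 0.0625
  end_time: 80.0
  membrane: courtemanche
  record_electrograms: true
  stop_margin: 10.0
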