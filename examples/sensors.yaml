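# Example sensor registry — PLACEHOLDER parameters, user-supplied.
#
# Kd and Hill coefficients of real GECI/GEDI variants must be taken from the
# characterization literature for the constructs you actually use; the values
# below are round numbers chosen only to illustrate the file format and the
# qualitative affinity gap between an activity sensor and a death sensor.
sensors:
  gcamp-like:        # activity sensor: responds to physiological transients
    kd: 3.75e-7      # molar
    hill_n: 2.3
    f_min: 0.0
    f_max: 1.0
  rgedi-like:        # death sensor: responds only near organellar/extracellular Ca2+
    kd: 5.6e-4
    hill_n: 1.8
    f_min: 0.0
    f_max: 1.0
  gc150-like:        # intermediate-affinity death sensor
    kd: 1.5e-4
    hill_n: 1.6
    f_min: 0.0
    f_max: 1.0
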