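"""Post-death fluorescence decay: both channels fade at matching rates.

Generates exponential decay traces for the death-indicator and morphology
channels at their post-death half-lives, fits the log2-linear regression,
and compares the recovered slopes — if the two fluorophores decayed at
different rates, the death ratio would drift in debris and corrupt late
death calls.
"""

import numpy as np

from gedipipe import compare_group_statistic, fit_log_decay, generate_decay_trace

times = np.arange(0.0, 97.0, 3.0)  # hours, a 4-day imaging window

half_lives = {"death-indicator channel": 20.45, "morphology channel": 20.73}
slopes = {}
for name, t_half in half_lives.items():
    trace = generate_decay_trace(1000.0, t_half, times, noise_sd=20.0, seed=42)
    fit = fit_log_decay(trace)
    slopes[name] = fit.slope
    print(f"{name}: true t1/2 = {t_half} h, recovered = {fit.half_life:.2f} h "
          f"(slope {fit.slope:.5f} log2/h, R^2 = {fit.r_squared:.4f})")

# per-neuron slope populations under noise: are the two channels different?
rng = np.random.default_rng(7)
a = [fit_log_decay(generate_decay_trace(1000.0, 20.45, times, 20.0, rng)).slope for _ in range(60)]
b = [fit_log_decay(generate_decay_trace(1000.0, 20.73, times, 20.0, rng)).slope for _ in range(60)]
test = compare_group_statistic(a, b)
print(f"\nMann-Whitney on 60+60 per-trace slopes: p = {test['p_value']:.3f}")
print("A large p means the channels decay at statistically indistinguishable "
      "rates, so the post-death ratio is stable while debris persists.")
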