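"""Survival statistics on a simulated two-group cohort.

Simulates control and disease-model neurons with a known hazard ratio,
estimates Kaplan-Meier survival, cumulative risk-of-death curves, and the
Cox proportional-hazards contrast, and prints how well the known effect is
recovered.
"""

from gedipipe import cox_fit, cumulative_risk, generate_survival_cohort, km_estimator

TRUE_HR = 1.8

records = generate_survival_cohort(
    n_per_group={"control": 700, "disease": 700},
    baseline_rate=0.01,     # deaths per hour in the control group
    hazard_ratio=TRUE_HR,
    censor_time=168.0,      # one week of imaging
    seed=5,
)

curves = km_estimator(records)
print("Kaplan-Meier survival at selected times:")
for name, curve in curves.items():
    s = {t: round(float(curve.survival_at(t)), 3) for t in (24, 72, 168)}
    print(f"  {name:8s} S(24h)={s[24]:.3f}  S(72h)={s[72]:.3f}  S(168h)={s[168]:.3f}")

crd = cumulative_risk(curves["disease"])
print(f"\nDisease-group cumulative incidence at end of imaging: "
      f"{crd['cumulative_incidence'].iloc[-1]:.3f} "
      f"(Nelson-Aalen cumulative hazard {crd['cumulative_hazard'].iloc[-1]:.3f})")

result = cox_fit(records, reference_group="control")[0]
print(f"\nCox fit: HR = {result.hr:.3f} (95% CI {result.ci_low:.3f}-{result.ci_high:.3f}, "
      f"p = {result.p_value:.2e}); generator truth was {TRUE_HR}.")
print("The hazard ratio is the multiplicative effect of the disease group on "
      "the instantaneous death rate; the CI should cover the truth ~95% of the time.")
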