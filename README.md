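# gedipipe

Automated single-cell death detection from two-channel time-lapse
fluorescence microscopy, for labs running longitudinal survival experiments
on cultured neurons (and similar sparse, adherent cells).

Genetically encoded death indicators (GEDIs) are low-affinity calcium
biosensors: their fluorescence stays dark through physiological Ca²⁺
transients and rises only when cytosolic Ca²⁺ reaches the catastrophic,
organellar/extracellular levels that mark an irreversible commitment to
death. Co-expressed with a constitutive morphology fluorophore via a P2a
peptide, the readout per neuron is the **GEDI ratio**

    R = mean GEDI intensity / mean morphology intensity

over the segmented soma, on background-subtracted images. Live and dead
cells separate widely on R, so a single cutoff calibrated from a live and a
dead reference population suffices:

    threshold = mean(R_live) + 0.25 · ( mean(R_dead) − mean(R_live) )

A neuron is dead from the first timepoint its ratio strictly exceeds the
threshold, or from the first timepoint its tracked segmentation label goes
missing; otherwise it is censored at the end of imaging. Per-neuron
time-to-death feeds Kaplan–Meier estimation, cumulative risk-of-death
curves (1 − S(t) and the Nelson–Aalen cumulative hazard), and Cox
proportional-hazards regression, whose hazard ratio HR = exp(β) is the
headline between-group contrast.

The package contains:

- `sensors` — equilibrium Hill-model fluorescence of GECI/GEDI variants
  (`f = f_min + (f_max − f_min)·ca^n/(Kd^n + ca^n)`), ΔF/F₀ traces, and the
  stimulation:death response ratio that distinguishes activity sensors from
  death sensors;
- `simulate` — a synthetic-plate generator with known ground truth: Gaussian
  somata on noisy background, group-specific proportional-hazards death
  times, an irreversible ratio jump at death, matched exponential decay of
  both channels afterwards, and eventual object disappearance; plus survival
  cohorts and decay traces without images;
- `images` — median background subtraction, montage stitching, translation
  registration, soma segmentation with a 100 px minimum size, feature
  extraction, ROI ratios, and normalised binarised-area quantification;
- `tracking` — minimum-total-distance centroid linking with a distance gate,
  and flagging of ratio-reversal artifacts (a "resurrected" neuron is a
  segmentation/tracking error, and is excluded rather than re-classified);
- `deathcall` — ratio computation, threshold calibration, live/dead
  classification, death-time assignment, and concordance against manual
  curation;
- `survival` — Kaplan–Meier, Nelson–Aalen, an Efron-tie Cox
  partial-likelihood fit (authored here, cross-checked against lifelines in
  the test suite), log₂-linear decay regression (slope = −1/t½), and
  plateau + one-phase-association rise fits (time constant τ);
- `workflow` / `cli` — `simulate` → `process` → `survival` orchestration
  with manifests, structured drop logs, and byte-reproducible outputs.

## Worked example

`examples/full_pipeline.py` renders a two-well plate (40 control neurons at
0.010 deaths/h, 40 disease-model neurons at 0.025 deaths/h, imaged every
24 h for a week), runs the full pipeline, and scores it against the
generator's truth. It prints:

```
Survival summary (80 subjects, 71 events)
  disease vs control: HR = 1.676 (95% CI 1.047-2.681, p = 3.14e-02, n = 80, events = 71)

Against ground truth (80 neurons matched): sensitivity = 1.000, specificity = 1.000
```

Every one of the 80 neurons was recovered by segmentation + tracking and
called correctly (dead vs censored); the fitted hazard ratio 1.68 is the
between-group death-rate contrast recovered from images alone — attenuated
from the continuous-time generator ratio 2.5 by the 24 h sampling grid, as
any observer of the same imaging schedule would be (see
`docs/methods.md`). The other examples (`sensor_response_curves.py`,
`decay_kinetics.py`, `survival_cohort.py`) each exercise one module the same
way.

The same pipeline is available from the shell:

```sh
gedipipe all --output results --seed 1 --overwrite
```

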