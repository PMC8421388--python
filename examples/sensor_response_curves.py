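"""Hill-model response curves: why a death sensor ignores activity.

Loads the placeholder sensor registry, evaluates each sensor's equilibrium
fluorescence across the Ca2+ range from cytosolic rest to extracellular
levels, and computes the stimulation:death response ratio for the
activity-like and death-like sensors.
"""

from pathlib import Path

import numpy as np

from gedipipe import FluorescenceTrace, hill_fluorescence, response_curve, stim_death_ratio
from gedipipe.sensors import load_sensor_registry

registry = load_sensor_registry(Path(__file__).with_name("sensors.yaml"))
ca_grid = np.geomspace(1e-8, 1e-2, 7)  # molar: rest ... extracellular

print("Relative fluorescence across [Ca2+] (rows: sensors, cols: ~10nM..10mM):")
for name, spec in registry.items():
    vals = response_curve(spec, ca_grid)
    print(f"  {name:12s} " + " ".join(f"{v:5.2f}" for v in vals))

# a physiological transient (to ~1 uM) versus death (rise to ~2 mM)
t = np.arange(8.0)
basal, transient_peak, death_level = 5e-8, 1e-6, 2e-3
stim_ca = np.array([basal, basal, transient_peak, transient_peak, basal, basal, basal, basal])
death_ca = np.array([basal, basal, basal, basal, death_level, death_level, death_level, death_level])

print("\nStimulation:death response ratio (near 1 = activity sensor, near 0 = death sensor):")
for name in ("gcamp-like", "rgedi-like"):
    spec = registry[name]
    offset = 0.05  # basal fluorescence so F0 > 0
    stim = FluorescenceTrace(t, offset + hill_fluorescence(spec, stim_ca), (0, 2))
    death = FluorescenceTrace(t, offset + hill_fluorescence(spec, death_ca), (0, 2))
    print(f"  {name:12s} {stim_death_ratio(stim, death):6.3f}")
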