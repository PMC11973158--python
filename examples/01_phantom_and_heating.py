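"""Generate a complex gradient-echo phantom, heat it, and recover the temperature.

Builds a 64x64 synthetic phantom, injects a Gaussian hotspot ramping to
5 degC via the PRF phase relation at 1.5 T / TE = 19.1 ms, then maps the
temperature back from the complex frames.  The recovered peak should match
the injected peak to numerical precision (no noise here).
"""

import numpy as np

from fourierpd import (
    HeatingScenario,
    PhantomConfig,
    ThermoConstants,
    make_complex_phantom,
    simulate_heating_series,
    temperature_series,
)

phantom = make_complex_phantom(PhantomConfig(grid_size=64, seed=42))
constants = ThermoConstants()  # proton gamma, alpha = -0.01 ppm/degC, 1.5 T, 19.1 ms
scenario = HeatingScenario(
    hotspot_center=(36, 30), hotspot_sigma=5, n_timepoints=4, peak_delta_T=5.0
)

frames = simulate_heating_series(phantom, scenario, constants)
maps = temperature_series(frames, constants)

print(f"phase shift per degC: {constants.rad_per_degC:+.5f} rad")
for t, dmap in enumerate(maps, start=1):
    print(f"time point {t}: recovered peak dT = {dmap.max():.3f} degC")
print(f"injected final peak: {scenario.peaks[-1]:.3f} degC")
# The recovered peaks climb linearly to the injected 5 degC because the
# PRF phase-to-temperature relation is exactly inverted by the mapping.
assert abs(maps[-1].max() - 5.0) < 1e-6
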