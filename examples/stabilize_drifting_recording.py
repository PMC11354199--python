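"""Undo whole-field drift before spectral analysis.

The sample cluster drifts slowly across the field during acquisition — a
quasi-periodic nuisance motion that corrupts the per-pixel power spectra.
Translation-only stabilization (phase correlation against the first frame)
recovers the drift exactly for integer shifts and restores the spectral peak.
"""

import numpy as np

from ciliafreq import (
    Region,
    SimConfig,
    mean_psd_cbf,
    pixel_power_spectra,
    simulate_cilia_stack,
    stabilize,
    subtract_mean_image,
)

texture = np.random.default_rng(0).uniform(60, 160, (64, 64))  # static cell field
base = dict(
    fps=500.0, n_frames=500, height=64, width=64,
    regions=[Region(("rect", 16, 16, 32, 32), cbf_hz=10.0, amplitude=20.0)],
    background=texture, seed=1,
)

drifting, truth = simulate_cilia_stack(SimConfig(drift=(0.02, -0.015), **base))
stabilized, trace = stabilize(drifting)

raw_peak = mean_psd_cbf(pixel_power_spectra(subtract_mean_image(drifting)))
fixed_peak = mean_psd_cbf(pixel_power_spectra(subtract_mean_image(stabilized)))

print(f"true drift over the recording : {truth.shifts[-1]} px (dx, dy)")
print(f"estimated correction          : {trace.shifts[-1]} px")
print(f"exact shift recovery          : {bool(np.all(trace.shifts == -truth.shifts))}")
print(f"mean-PSD peak, drifting       : {raw_peak.value_hz:.2f} Hz")
print(f"mean-PSD peak, stabilized     : {fixed_peak.value_hz:.2f} Hz")
# Drift smears per-pixel intensity series across the textured background and
# can bury or shift the beat peak; after stabilization the peak sits back at
# the true 10 Hz line.
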