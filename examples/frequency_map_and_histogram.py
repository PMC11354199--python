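"""Map spatially heterogeneous beating and summarize it as a histogram.

Two patches beat at 8 and 12 Hz on the same field.  The per-pixel dominant
frequency map localizes each patch; the histogram reports what fraction of
the analyzed area beats in each frequency bin — the spatial spread itself is
diagnostically useful.
"""

import numpy as np

from ciliafreq import (
    Region,
    SimConfig,
    cbf_histogram,
    dominant_frequency_map,
    pixel_power_spectra,
    simulate_cilia_stack,
)

config = SimConfig(
    fps=500.0,
    n_frames=1000,
    height=40,
    width=40,
    regions=[
        Region(("rect", 0, 0, 24, 40), cbf_hz=8.0, amplitude=20.0),   # 60 % of area
        Region(("rect", 24, 0, 16, 40), cbf_hz=12.0, amplitude=20.0),  # 40 %
    ],
    noise_sigma=2.0,
    seed=11,
)
stack, truth = simulate_cilia_stack(config)

spec = pixel_power_spectra(stack)
fmap = dominant_frequency_map(spec)
dist, mode = cbf_histogram(fmap, bin_width=spec.df)

print(f"modal CBF      : {mode.value_hz:.1f} Hz")
print(f"pixel median   : {dist.median_hz:.1f} Hz")
print(f"weighted mean  : {dist.weighted_mean_hz:.2f} Hz")
print("occupied bins  :")
for center, count, pct in dist.to_table():
    if count:
        print(f"  {center:5.1f} Hz : {int(count):4d} px  ({pct:5.1f} %)")
print(f"map matches truth: {bool(np.array_equal(fmap == 8.0, truth.frequency_map == 8.0))}")
# The 8 Hz patch covers 60 % of the field, so it owns the modal bin; the
# 12 Hz patch shows up as the remaining 40 %.
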