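"""Map an 88-channel montage onto the common 134-channel mask and group
channels into the 14 bilateral regions of interest.

The Gaussian kernel K = exp(-sigma d^2), column-normalised per mask
channel, redistributes local signal while preserving amplitudes; the ROI
step averages mask channels sharing anatomy.
"""

import numpy as np

from dyadnirs import (
    HbSeries,
    assign_channels,
    build_kernel,
    colocalise,
    generate_geometry,
    load_roi_table,
    pairwise_distances,
    roi_average,
)

geom_uk = generate_geometry("UK", seed=0)
mask = generate_geometry("US", seed=1)  # the ideal whole-head montage

distances = pairwise_distances(geom_uk, mask)
kernel = build_kernel(distances, sigma=0.01)
print(f"kernel: {kernel.n_mask} mask x {kernel.n_input} input channels; "
      f"row sums all 1: {np.allclose(kernel.weights.sum(axis=1), 1.0)}")

rng = np.random.default_rng(0)
data = rng.standard_normal((geom_uk.n_channels, 200))
hb = HbSeries(hbo2=data, hhb=-data / 3, sampling_rate=8.13)
hb_mask = colocalise(hb, kernel)
print(f"co-localised: {hb.n_channels} -> {hb_mask.n_channels} channels")

table = load_roi_table()
assignment = assign_channels(mask, table)
roi_series, regions = roi_average(hb_mask.hhb, assignment, table.regions)
counts = {r: int((assignment == r).sum()) for r in regions}
print(f"{len(regions)} bilateral ROIs; channels per ROI: {counts}")
print(f"angular gyrus HHb series: {roi_series[regions.index('angular_gyrus')].shape}")
# each ROI series is the unweighted mean of its member mask channels
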