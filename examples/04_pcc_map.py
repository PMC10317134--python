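"""Pearson cross-correlation of all frame pairs and per-point slice maps.

Run:  python examples/04_pcc_map.py
"""

import numpy as np

import diffscan as dsn
from diffscan.features import pcc_matrix, pcc_slice

geom = dsn.DetectorGeometry(n_pixels=128, camera_length_m=0.225)
models = dsn.default_frame_models(scale=0.25)
grid = (16, 16)
ds = dsn.simulate_scan(dsn.demo_scene(grid), models, geom,
                       dsn.ScanGeometry(grid_shape=grid), seed=7,
                       drift_px=(0.0, 0.0), jitter_sd=0.0)

M = pcc_matrix(ds.flat_frames().astype(np.float32), valid_mask=~ds.invalid_mask)
print(f"PCC matrix: {M.shape[0]}×{M.shape[1]}, range [{np.nanmin(M):.3f}, {np.nanmax(M):.3f}]")

pos = (8, 5)  # a scan point inside the ice hole
sl = pcc_slice(M, pos, grid)
same = ds.labels == ds.labels[pos]
same[pos] = False
print(f"slice at {pos} (label {dsn.CLASS_NAMES[ds.labels[pos]]}):")
print(f"  mean correlation with same-class points  {np.nanmean(sl[same]):.3f}")
print(f"  mean correlation with other-class points {np.nanmean(sl[~same]):.3f}")
print()
print("Reshaping one matrix row onto the scan grid maps out the region the")
print("queried point belongs to: like scatters with like.")
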