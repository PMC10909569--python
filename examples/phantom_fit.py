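"""Round trip: synthetic phantom -> voxel-wise fit -> regional medians.

A two-region phantom with known exchange rates is synthesized at control
SNR 30, fitted voxel by voxel, and summarized per region — the same
pipeline an in-vivo data set would go through after registration.
"""

import numpy as np

from ceasl import (FitConfig, NoiseModel, PhantomSpec, PhysioParams,
                   fit_volume, make_phantom)

labels = np.zeros((10, 10, 4), dtype=int)
labels[:5] = 1   # "healthy" region, slow exchange
labels[5:] = 2   # "leaky" region, fast exchange
spec = PhantomSpec(labels=labels,
                   regions={1: PhysioParams(k_b=1.0),
                            2: PhysioParams(k_b=3.5)},
                   noise=NoiseModel(sigma=0.0017, n_reps=1),  # SNR 30
                   seed=0)
phantom = make_phantom(spec)

maps = fit_volume(phantom["difference"], phantom["m0"], phantom["t1e"],
                  phantom["blood_t1s"], labels > 0,
                  config=FitConfig(n_starts=50, seed=0),
                  times=phantom["times"], roi_labels=labels)

print(maps["roi_table"].to_string(index=False,
                                  float_format=lambda v: f"{v:.2f}"))
print("\nTruth: k_b = 1.00 (region 1) and 3.50 (region 2). Regional "
      "medians\nrecover the ordering and approximate values; single-voxel "
      "estimates\nare noisy, which is why regional summaries are the "
      "useful output.")
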