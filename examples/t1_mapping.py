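"""Supporting T1 measurements: VFA mapping and blood-ROI extraction.

The kinetic fit needs the blood T1 before and after contrast.  Both come
from variable-flip-angle SPGR maps; the blood value is read from a
venous-sinus ROI restricted to voxels whose T1 dropped by at least 20%
after injection (the high-blood-volume voxels).
"""

import numpy as np

from ceasl import SpgrAcquisition, estimate_blood_t1, fit_vfa_t1, spgr_signal

rng = np.random.default_rng(0)
angles = (2.0, 5.0, 15.0, 20.0)
tr = 0.00475

# synthetic sinus ROI: mostly blood voxels (T1 1.8 s pre, ~1.0 s post),
# some partial-volume voxels that barely enhance
n = 200
is_blood = rng.random(n) < 0.7
t1_pre = np.where(is_blood, rng.normal(1.8, 0.05, n), rng.normal(1.4, 0.1, n))
t1_post = np.where(is_blood, rng.normal(1.0, 0.05, n), t1_pre * 0.95)

sig_pre = spgr_signal(np.array(angles), t1_pre[:, None], 1.0, tr)
fit_pre, _ = fit_vfa_t1(SpgrAcquisition(signals=sig_pre, flip_angles=angles,
                                        TR=tr))
print(f"VFA fit sanity: median |T1 error| = "
      f"{np.median(np.abs(fit_pre - t1_pre)) * 1000:.2f} ms (noise-free)")

t1b_pre, t1b_post = estimate_blood_t1(t1_pre, t1_post,
                                      np.ones(n, dtype=bool))
print(f"blood T1 pre-contrast : {t1b_pre:.3f} s")
print(f"blood T1 post-contrast: {t1b_post:.3f} s")
print("\nThe 20%-reduction rule drops the partial-volume voxels, so the "
      "75th\npercentile reads the high-blood-volume population the "
      "kinetic model needs.")
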