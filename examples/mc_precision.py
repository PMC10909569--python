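"""Expected precision of exchange-rate estimates at clinical SNR.

Monte Carlo replicates of the 5+1-PLD protocol are synthesized at the
noise level of background-suppressed control data with SNR 30, fitted,
and summarized by the coefficient of variation (IQR / truth).  400
replicates keep this demo quick; the acceptance script runs the full
2500.
"""

from ceasl import NoiseModel, roi_size_study

noise = NoiseModel(sigma=0.0017, n_reps=400, seed=0)  # control SNR 30
report = roi_size_study(roi_sizes=(1, 500, 10000), noise=noise)

print(report[["roi_size", "rel_error_kb", "cov_kb", "cov_f",
              "cov_tA"]].to_string(index=False,
                                   float_format=lambda v: f"{v:.1f}"))
print("\nSingle voxels are hopeless for k_b (CoV near 190%: estimates "
      "smeared\nover the whole fit range), but averaging a ~500-voxel "
      "cortical region\nbrings the CoV to ~30%, and a lobe-sized region "
      "to ~7%. Flow and\ntransit time are well determined even per voxel.")
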