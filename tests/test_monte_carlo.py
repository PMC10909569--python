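"""Noise model bookkeeping and Monte Carlo summaries."""

import numpy as np
import pandas as pd
import pytest

from ceasl import (FitConfig, NoiseModel, roi_size_study, run_mc_study,
                   simulate_noisy_difference, summarize)
from ceasl.model import signal


class TestNoiseModel:
    @pytest.mark.parametrize("sigma,snr", [(0.0033, 15.15), (0.0017, 29.41),
                                           (0.0011, 45.45)])
    def test_control_snr_levels(self, sigma, snr):
        assert NoiseModel(sigma=sigma).control_snr == pytest.approx(snr,
                                                                    abs=0.5)

    def test_difference_signal_snr(self, phys, acq):
        # reference difference signal at the pre-contrast PLD = 1.5 s point
        dm = float(signal(3.5, phys.f, phys.t_A, phys.k_b, 1.65, phys.T1_e))
        snr_diff = dm / (0.0017 * np.sqrt(2))
        assert snr_diff == pytest.approx(3.6, rel=0.05)

    def test_vanishing_noise_reproduces_clean_curve(self, phys, acq):
        noise = NoiseModel(sigma=1e-15, n_reps=8, roi_size=1)
        design, diffs = simulate_noisy_difference(phys, acq, noise)
        clean = signal(design.times, phys.f, phys.t_A, phys.k_b, design.t1b,
                       phys.T1_e)
        np.testing.assert_allclose(diffs, np.tile(clean, (8, 1)), atol=1e-12)

    def test_roi_scaling_reduces_noise_sd(self, phys, acq):
        n1 = NoiseModel(sigma=0.0017, n_reps=4000, roi_size=1, seed=5)
        n100 = n1.with_(roi_size=100)
        _, d1 = simulate_noisy_difference(phys, acq, n1)
        _, d100 = simulate_noisy_difference(phys, acq, n100)
        sd1 = (d1 - d1.mean(0)).std()
        sd100 = (d100 - d100.mean(0)).std()
        assert sd1 / sd100 == pytest.approx(10.0, rel=0.1)
        assert sd1 == pytest.approx(0.0017 * np.sqrt(2), rel=0.05)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma=0.0)


class TestSummarize:
    def test_degenerate_replicates(self):
        cfg = FitConfig(kb_bounds=(0, 10))
        row = summarize(np.full(50, 2.65), 2.65, cfg)
        assert row["rel_error_kb"] == 0.0
        assert row["cov_kb"] == 0.0
        assert row["extreme_fraction"] == 0.0

    def test_known_list_arithmetic(self):
        cfg = FitConfig(kb_bounds=(0, 10))
        row = summarize(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 3.0, cfg)
        assert row["rel_error_kb"] == 0.0
        assert row["cov_kb"] == pytest.approx(100 * 2 / 3)

    def test_extreme_screen(self):
        cfg = FitConfig(kb_bounds=(0, 10))
        kb = np.array([0.1, 9.9] + [2.65] * 18)  # two extreme fits
        row = summarize(kb, 2.65, cfg)
        assert row["extreme_fraction"] == pytest.approx(0.1)
        assert row["cov_kb"] == 0.0  # survivors are all at truth
        no_screen = summarize(kb, 2.65, cfg, screen=False)
        assert no_screen["cov_kb"] == 0.0
        assert no_screen["n_kept"] == 20

    def test_too_few_survivors_flagged(self):
        cfg = FitConfig(kb_bounds=(0, 10))
        row = summarize(np.array([0.1] * 30 + [2.65] * 5), 2.65, cfg)
        assert row["flagged"]


@pytest.fixture(scope="module")
def quick_roi():
    return roi_size_study(roi_sizes=(500,),
                          noise=NoiseModel(sigma=0.0017, n_reps=250,
                                           seed=11))


class TestStudies:
    def test_cortical_roi_precision_ballpark(self, quick_roi):
        row = quick_roi.iloc[0]
        assert 20 < row["cov_kb"] < 45
        assert abs(row["rel_error_kb"]) < 6
        assert row["extreme_fraction"] < 0.06

    def test_report_is_deterministic(self):
        kw = dict(roi_sizes=(200,),
                  noise=NoiseModel(sigma=0.0017, n_reps=60, seed=2))
        pd.testing.assert_frame_equal(roi_size_study(**kw),
                                      roi_size_study(**kw))

    def test_cov_shrinks_with_roi_size(self):
        rep = roi_size_study(roi_sizes=(100, 10000),
                             noise=NoiseModel(sigma=0.0017, n_reps=250,
                                              seed=4))
        t = rep.set_index("roi_size")
        assert t.loc[100, "cov_kb"] > t.loc[10000, "cov_kb"]
        # f and t_A follow the 1/sqrt(N) law away from the bounds
        ratio = t.loc[100, "cov_f"] / t.loc[10000, "cov_f"]
        assert ratio == pytest.approx(10.0, rel=0.35)

    def test_kb_grid_iqr_widens_with_exchange_rate(self):
        rep = run_mc_study(kb_grid=[0.8, 3.6],
                           noise=NoiseModel(sigma=0.0017, n_reps=250,
                                            roi_size=500, seed=8))
        # precision degrades at faster exchange: the absolute IQR of the
        # k_b estimates widens with the underlying rate
        iqr = rep["cov_kb"] * rep["kb_truth"] / 100.0
        assert iqr.iloc[1] > iqr.iloc[0]
        assert np.all(rep["extreme_fraction"] < 0.06)
        assert np.all(np.abs(rep["rel_error_kb"]) < 8)
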