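"""Parameter estimation: recovery, determinism, bounds, batched engine."""

import numpy as np
import pytest

from ceasl import (FitConfig, PhysioParams, fit_many,
                   fit_signal, fit_volume, make_signal_table)
from ceasl.fit import ModelDesign, _profiled_objective, design_from_curves

T1B = {"pre": 1.65, "post1": 0.8}


def make_curves(phys=None, seed=0, noise=None):
    return make_signal_table(truth=phys or PhysioParams(), noise=noise,
                             seed=seed)[0]


class TestFitSignal:
    def test_zero_noise_recovery(self, phys):
        res = fit_signal(make_curves(phys), T1B, t1e=phys.T1_e)
        assert res.f_hat == pytest.approx(phys.f, rel=1e-3)
        assert res.tA_hat == pytest.approx(phys.t_A, rel=1e-3)
        assert res.kb_hat == pytest.approx(phys.k_b, rel=1e-3)
        assert not res.extreme

    def test_no_exchange_lands_at_lower_bound(self, phys):
        p0 = phys.with_(k_b=0.0)
        res = fit_signal(make_curves(p0), T1B, t1e=p0.T1_e)
        assert res.kb_hat <= 0.25
        assert res.extreme

    def test_deterministic_given_seed(self, phys):
        curves = make_curves(phys, noise=None)
        a = fit_signal(curves, T1B, t1e=1.5, config=FitConfig(seed=42))
        b = fit_signal(curves, T1B, t1e=1.5, config=FitConfig(seed=42))
        assert (a.f_hat, a.tA_hat, a.kb_hat) == (b.f_hat, b.tA_hat, b.kb_hat)

    def test_pld_permutation_invariance(self, phys, rng):
        design, y = design_from_curves(make_curves(phys), T1B, t1e=1.5)
        perm = rng.permutation(y.size)
        d2 = ModelDesign(times=design.times[perm], t1b=design.t1b[perm],
                         t1e=design.t1e, t_L=design.t_L, alpha=design.alpha,
                         M0=design.M0, lambda_=design.lambda_)
        a = fit_many(y[None, :], design, FitConfig(seed=1))
        b = fit_many(y[perm][None, :], d2, FitConfig(seed=1))
        for k in ("f", "tA", "kb"):
            assert a[k][0] == pytest.approx(b[k][0], rel=1e-6)

    def test_too_few_points_rejected(self, phys):
        from ceasl.params import SignalCurve

        c = SignalCurve(times=[3.0, 3.5, 4.0], values=[1e-3, 1e-3, 1e-3],
                        contrast_phase="pre")
        with pytest.raises(ValueError):
            fit_signal([c], T1B, t1e=1.5)

    def test_simplex_mode_recovers_truth(self, phys):
        res = fit_signal(make_curves(phys), T1B, t1e=phys.T1_e,
                         config=FitConfig(method="simplex", max_iter=600))
        assert res.f_hat == pytest.approx(phys.f, rel=1e-3)
        assert res.kb_hat == pytest.approx(phys.k_b, rel=1e-2)


class TestRecoveryProperty:
    def test_noise_free_recovery_across_parameter_space(self, rng):
        # random ground truths strictly inside bounds, transit guard so the
        # bolus reaches the first measurement
        n = 200
        truths = np.column_stack([
            rng.uniform(10, 150, n),     # f
            rng.uniform(0.1, 2.2, n),    # t_A
            rng.uniform(0.2, 4.5, n),    # k_b
        ])
        times = np.array([2.9, 3.2, 3.5, 3.8, 4.1, 3.5])
        t1b = np.array([1.65] * 5 + [0.8])
        from ceasl.model import signal

        y = signal(times, truths[:, 0:1], truths[:, 1:2], truths[:, 2:3],
                   t1b, 1.5)
        design = ModelDesign(times=times, t1b=t1b, t1e=1.5)
        out = fit_many(y, design, FitConfig(seed=3))
        for key, col in (("f", 0), ("tA", 1), ("kb", 2)):
            rel = np.abs(out[key] - truths[:, col]) / truths[:, col]
            assert np.max(rel) < 0.005

    def test_bound_honesty(self, rng):
        times = np.array([2.9, 3.2, 3.5, 3.8, 4.1, 3.5])
        t1b = np.array([1.65] * 5 + [0.8])
        y = rng.normal(0.0, 0.01, (50, 6))  # pure noise
        cfg = FitConfig(seed=0)
        out = fit_many(y, ModelDesign(times=times, t1b=t1b, t1e=1.5), cfg)
        assert np.all(out["f"] >= cfg.f_bounds[0])
        assert np.all(out["f"] <= cfg.f_bounds[1])
        assert np.all(out["tA"] >= cfg.tA_bounds[0])
        assert np.all(out["tA"] <= cfg.tA_bounds[1])
        assert np.all(out["kb"] >= cfg.kb_bounds[0])
        assert np.all(out["kb"] <= cfg.kb_bounds[1])


class TestCompiledObjective:
    def test_compiled_matches_numpy_path(self, rng):
        times = np.array([2.9, 3.2, 3.5, 3.8, 4.1, 3.5])
        t1b = np.array([1.65] * 5 + [0.8])
        design = ModelDesign(times=times, t1b=t1b,
                             t1e=rng.uniform(1.2, 1.6, 40),
                             M0=rng.uniform(0.8, 1.2, 40))
        y = rng.normal(0.005, 0.002, (40, 6))
        cfg = FitConfig(kb_bounds=(0, 10))
        fun_c, _ = _profiled_objective(design, y, cfg, use_compiled=True)
        fun_n, _ = _profiled_objective(design, y, cfg, use_compiled=False)
        x = np.stack([rng.uniform(-0.3, 2.8, (7, 40)),
                      rng.uniform(-1, 11, (7, 40))], axis=-1)
        np.testing.assert_allclose(fun_c(x), fun_n(x), rtol=1e-12, atol=1e-15)


@pytest.fixture(scope="module")
def phantom_fit():
    from ceasl import NoiseModel, PhantomSpec, make_phantom

    labels = np.zeros((4, 3, 2), dtype=int)
    labels[:2] = 1
    labels[2:] = 2
    spec = PhantomSpec(labels=labels,
                       regions={1: PhysioParams(k_b=1.2),
                                2: PhysioParams(k_b=3.2, f=45.0)},
                       noise=NoiseModel(sigma=1e-12, n_reps=1),
                       seed=0)
    phantom = make_phantom(spec)
    maps = fit_volume(phantom["difference"], phantom["m0"],
                      phantom["t1e"], phantom["blood_t1s"],
                      labels > 0, config=FitConfig(n_starts=30),
                      times=phantom["times"], roi_labels=labels)
    return phantom, maps


class TestFitVolume:
    def test_zero_noise_phantom_recovery(self, phantom_fit):
        phantom, maps = phantom_fit
        for key in ("f", "tA", "kb"):
            rel = np.abs(maps[key] - phantom["truth"][key]) / phantom["truth"][key]
            assert np.nanmax(rel) < 0.005

    def test_roi_medians(self, phantom_fit):
        _, maps = phantom_fit
        table = maps["roi_table"].set_index("roi")
        assert table.loc[1, "kb_median"] == pytest.approx(1.2, rel=1e-3)
        assert table.loc[2, "f_median"] == pytest.approx(45.0, rel=1e-3)

    def test_single_voxel_reduces_to_fit_signal(self, phantom_fit, phys):
        phantom, _ = phantom_fit
        one = np.zeros_like(phantom["labels"], dtype=bool)
        one[0, 0, 0] = True
        maps = fit_volume(phantom["difference"], phantom["m0"],
                          phantom["t1e"], phantom["blood_t1s"], one,
                          config=FitConfig(n_starts=30),
                          times=phantom["times"])
        curves = make_curves(PhysioParams(k_b=1.2))
        res = fit_signal(curves, T1B, t1e=1.5, config=FitConfig(n_starts=30))
        assert maps["kb"][0, 0, 0] == pytest.approx(res.kb_hat, rel=1e-4)

    def test_empty_mask_rejected(self, phantom_fit):
        phantom, _ = phantom_fit
        with pytest.raises(ValueError):
            fit_volume(phantom["difference"], phantom["m0"], phantom["t1e"],
                       phantom["blood_t1s"], np.zeros_like(phantom["labels"],
                                                           dtype=bool))

    def test_shape_mismatch_rejected(self, phantom_fit):
        phantom, _ = phantom_fit
        with pytest.raises(ValueError):
            fit_volume(phantom["difference"], phantom["m0"][:2],
                       phantom["t1e"], phantom["blood_t1s"],
                       phantom["labels"] > 0)
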