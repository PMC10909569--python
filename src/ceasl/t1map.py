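"""Supporting T1 estimation: variable-flip-angle SPGR fitting, the
blood-ROI T1 extraction rule, and the ROI SNR estimator.

The spoiled gradient-recalled echo (SPGR) signal at flip angle theta is

    S(theta) = M0 sin(theta) (1 - E) / (1 - E cos(theta)),  E = exp(-TR/T1),

fitted per voxel over the acquired flip angles.  The linearized DESPOT1
regression (S/sin vs S/tan) provides starting values and an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["SpgrAcquisition", "BloodRoiSpec", "spgr_signal", "despot1",
           "fit_vfa_t1", "estimate_blood_t1", "roi_snr"]


@dataclass(frozen=True)
class SpgrAcquisition:
    """Flip angles (degrees), TR (s) and per-voxel signals.

    ``signals`` has shape (..., n_angles): any leading voxel dimensions.
    """

    signals: np.ndarray
    flip_angles: tuple[float, ...] = (2.0, 5.0, 15.0, 20.0)
    TR: float = 0.00475

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals",
                           np.asarray(self.signals, dtype=float))
        if len(set(self.flip_angles)) < 2:
            raise ValueError("need at least 2 distinct flip angles")
        if self.TR <= 0:
            raise ValueError("TR must be > 0")
        if self.signals.shape[-1] != len(self.flip_angles):
            raise ValueError("signals last axis must match flip_angles")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


@dataclass(frozen=True)
class BloodRoiSpec:
    """Blood-ROI selection rule for venous-sinus T1 extraction."""

    reduction_threshold: float = 0.20
    percentile: float = 75.0

    def __post_init__(self) -> None:
        if not 0 < self.reduction_threshold < 1:
            raise ValueError("reduction_threshold must be in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


def spgr_signal(theta_deg, t1, m0, tr):
    """SPGR steady-state signal; ``theta_deg`` in degrees."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    e = np.exp(-tr / np.asarray(t1, dtype=float))
    return m0 * np.sin(th) * (1 - e) / (1 - e * np.cos(th))


def despot1(acq: SpgrAcquisition):
    """Linearized T1/M0 estimate by regression of S/sin on S/tan.

    The SPGR equation rearranges to ``S/sin = E * S/tan + M0 (1-E)``; the
    slope gives ``T1 = -TR / ln(slope)``.  Vectorized over voxels.
    """
    th = np.deg2rad(np.asarray(acq.flip_angles, dtype=float))
    s = acq.signals
    x = s / np.tan(th)
    y = s / np.sin(th)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    denom = ((x - xm) ** 2).sum(axis=-1)
    slope = np.divide(((x - xm) * (y - ym)).sum(axis=-1), denom,
                      out=np.full(denom.shape, np.nan), where=denom > 0)
    slope = np.where((slope > 0) & (slope < 1), slope, np.nan)
    t1 = -acq.TR / np.log(slope)
    m0 = (ym[..., 0] - slope * xm[..., 0]) / (1 - slope)
    return t1, m0


def fit_vfa_t1(acq: SpgrAcquisition):
    """Nonlinear least-squares T1/M0 maps from variable-flip-angle SPGR.

    Returns ``(t1, m0)`` arrays matching the voxel dimensions; degenerate
    voxels (all-equal or zero signal) come back NaN.
    """
    shape = acq.signals.shape[:-1]
    s_flat = acq.signals.reshape(-1, acq.signals.shape[-1])
    th = np.asarray(acq.flip_angles, dtype=float)
    t1_init, m0_init = despot1(SpgrAcquisition(signals=s_flat,
                                               flip_angles=acq.flip_angles,
                                               TR=acq.TR))
    t1_out = np.full(s_flat.shape[0], np.nan)
    m0_out = np.full(s_flat.shape[0], np.nan)
    for i in range(s_flat.shape[0]):
        s = s_flat[i]
        if not np.all(np.isfinite(s)) or np.ptp(s) == 0 or s.max() <= 0:
            continue
        x0 = [t1_init[i] if np.isfinite(t1_init[i]) and t1_init[i] > 0 else 1.0,
              m0_init[i] if np.isfinite(m0_init[i]) and m0_init[i] > 0
              else s.max()]

        def resid(p):
            return spgr_signal(th, p[0], p[1], acq.TR) - s

        try:
            res = least_squares(resid, x0, bounds=([1e-4, 0], [20.0, np.inf]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        t1_out[i], m0_out[i] = res.x
    return t1_out.reshape(shape), m0_out.reshape(shape)


def estimate_blood_t1(t1_pre_map, t1_post_map, sinus_seed_roi,
                      spec: BloodRoiSpec | None = None):
    """Blood T1 before and after contrast from a venous-sinus seed ROI.

    Voxels in the seed showing at least a 20% T1 reduction after contrast
    form the blood ROI (highest blood volume).  T1b_pre is the 75th
    percentile of the pre-contrast map within that ROI; T1b_post is
    obtained by subtracting the 75th percentile of the pre-post difference
    from T1b_pre (not by reading the post map directly).
    """
    spec = spec or BloodRoiSpec()
    pre = np.asarray(t1_pre_map, dtype=float)
    post = np.asarray(t1_post_map, dtype=float)
    seed = np.asarray(sinus_seed_roi, dtype=bool)
    if not seed.any():
        raise ValueError("seed ROI is empty")
    reduction = (pre - post) / pre
    mask = seed & (reduction >= spec.reduction_threshold)
    if not mask.any():
        raise ValueError("no seed voxels show the required T1 reduction; "
                         "consider relaxing reduction_threshold")
    t1b_pre = float(np.percentile(pre[mask], spec.percentile))
    diff_pct = float(np.percentile((pre - post)[mask], spec.percentile))
    return t1b_pre, t1b_pre - diff_pct


def roi_snr(difference_image, roi_mask=None, ddof: int = 1) -> float:
    """Mean/SD of the ASL difference values within an ROI.

    Returns ``inf`` when the SD is zero (flagged degenerate ROI).
    """
    vals = np.asarray(difference_image, dtype=float)
    if roi_mask is not None:
        vals = vals[np.asarray(roi_mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 voxels in the ROI")
    sd = vals.std(ddof=ddof)
    if sd == 0:
        return float("inf")
    return float(vals.mean() / sd)
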