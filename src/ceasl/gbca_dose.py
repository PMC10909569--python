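"""Gadolinium dose and timing planner.

An intravascular gadolinium-based contrast agent (GBCA) shortens the
blood T1 through the relaxivity relation

    R1_b_post(t) = R1_b_pre + r1 * c_b(t)

with ``c_b(t)`` the blood concentration (the vascular input function,
VIF) and ``r1`` the longitudinal relaxivity.  Given a measured or
parametric VIF, the planner converts concentration to post-contrast blood
T1, scales the curve to fractional doses (linear kinetics), and reports
the time after injection at which the recovering T1 crosses a target
value such as the optimal 0.8 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = ["RelaxivityParams", "VifCurve", "parker_vif", "t1b_post",
           "cb_for_t1", "scale_dose", "time_to_target"]


@dataclass(frozen=True)
class RelaxivityParams:
    """Blood relaxation constants: r1 in s^-1 mM^-1, R1b_pre in s^-1."""

    r1: float = 3.4
    R1b_pre: float = 0.61

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.R1b_pre <= 0:
            raise ValueError("relaxivity parameters must be > 0")


# Population parameters of the bi-Gaussian + exponential-sigmoid arterial
# input function (Parker et al. 2006), for a standard 0.1 mmol/kg dose.
# A in mmol.min, T and sigma in min, alpha in mM, beta and s in 1/min,
# tau in min.
PARKER_POPULATION = {
    "A1": 0.809, "T1": 0.17046, "sigma1": 0.0563,
    "A2": 0.330, "T2": 0.365, "sigma2": 0.132,
    "alpha": 1.050, "beta": 0.1685, "s": 38.078, "tau": 0.483,
}


@dataclass
class VifCurve:
    """Blood GBCA concentration versus time after injection.

    ``t`` in minutes, ``cb`` in mM; ``dose_fraction`` records the scale
    relative to a full dose.
    """

    t: np.ndarray
    cb: np.ndarray
    dose_fraction: float = 1.0
    source: str = "measured_table"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if self.t.shape != self.cb.shape or self.t.ndim != 1:
            raise ValueError("t and cb must be matching 1-D arrays")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("t must be non-decreasing")
        if np.any(self.cb < 0):
            raise ValueError("cb must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "VifCurve":
        df = pd.read_csv(path)
        return cls(t=df.iloc[:, 0].to_numpy(), cb=df.iloc[:, 1].to_numpy())


def parker_vif(t_minutes, dose_fraction: float = 1.0,
               params: dict | None = None) -> VifCurve:
    """Synthesize a population VIF on a time grid (minutes).

    Two Gaussian bolus passes plus an exponential washout modulated by a
    sigmoid; scaled linearly for fractional doses.
    """
    p = dict(PARKER_POPULATION, **(params or {}))
    t = np.asarray(t_minutes, dtype=float)
    cb = np.zeros_like(t)
    for a, mu, sig in ((p["A1"], p["T1"], p["sigma1"]),
                       (p["A2"], p["T2"], p["sigma2"])):
        cb = cb + a / (sig * np.sqrt(2 * np.pi)) * np.exp(
            -((t - mu) ** 2) / (2 * sig**2))
    cb = cb + p["alpha"] * np.exp(-p["beta"] * t) / (
        1 + np.exp(-p["s"] * (t - p["tau"])))
    return VifCurve(t=t, cb=np.maximum(cb, 0.0) * dose_fraction,
                    dose_fraction=dose_fraction, source="parametric")


def t1b_post(cb, relax: RelaxivityParams | None = None):
    """Post-contrast blood T1 (s) for concentration ``cb`` (mM)."""
    relax = relax or RelaxivityParams()
    cb = np.asarray(cb, dtype=float)
    if np.any(cb < 0):
        raise ValueError("cb must be >= 0")
    return 1.0 / (relax.R1b_pre + relax.r1 * cb)


def cb_for_t1(t1: float, relax: RelaxivityParams | None = None) -> float:
    """Concentration (mM) producing blood T1 ``t1`` (s); inverse of t1b_post."""
    relax = relax or RelaxivityParams()
    if not 0 < t1 <= 1.0 / relax.R1b_pre:
        raise ValueError("target T1 must lie between 0 and the pre-contrast T1")
    return (1.0 / t1 - relax.R1b_pre) / relax.r1


def scale_dose(vif: VifCurve, fraction: float) -> VifCurve:
    """Scale a VIF to a fractional dose (linear-kinetics assumption)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return VifCurve(t=vif.t.copy(), cb=vif.cb * fraction,
                    dose_fraction=vif.dose_fraction * fraction,
                    source=vif.source)


def _extrapolated_washout(vif: VifCurve, t_end: float):
    """Append a fitted exponential tail when the samples end early.

    The late VIF decays exponentially (the sigmoid term saturates), so a
    log-linear fit to the final quarter of the washout samples provides
    the extrapolation to ``t_end`` minutes.
    """
    t, cb = vif.t, vif.cb
    if t[-1] >= t_end:
        return t, cb
    i_peak = int(np.argmax(cb))
    tail = slice(max(i_peak + 1, int(0.75 * t.size)), t.size)
    tt, cc = t[tail], cb[tail]
    pos = cc > 0
    if pos.sum() >= 2:
        b, a = np.polyfit(tt[pos], np.log(cc[pos]), 1)
        b = min(b, -1e-6)  # enforce decay
        t_ext = np.linspace(t[-1], t_end, 200)[1:]
        cb_ext = np.exp(a + b * t_ext)
        return np.concatenate([t, t_ext]), np.concatenate([cb, cb_ext])
    return t, cb


def time_to_target(vif: VifCurve, relax: RelaxivityParams | None = None,
                   target_t1: float = 0.8, t_end: float = 250.0):
    """Time (minutes) at which blood T1 recovers through ``target_t1``.

    Reports the latest washout crossing of the (possibly extrapolated) T1
    recovery curve.  Returns NaN when the target is never reached within
    ``t_end`` (e.g. a target at or above the pre-contrast T1, which is
    only approached asymptotically).
    """
    relax = relax or RelaxivityParams()
    cb_target = (1.0 / target_t1 - relax.R1b_pre) / relax.r1
    if cb_target <= 0:
        return np.nan
    t, cb = _extrapolated_washout(vif, t_end)
    if cb.max() < cb_target:
        return np.nan  # T1 never dips below target: nothing to recover from
    i_peak = int(np.argmax(cb))
    tw, cw = t[i_peak:], cb[i_peak:]
    # last sample still above the target concentration
    above = np.nonzero(cw >= cb_target)[0]
    i_last = above[-1]
    if i_last == cw.size - 1:
        return np.nan  # still above target at the end of the record
    # keep strictly increasing time nodes for the interpolator
    keep = np.concatenate([[True], np.diff(tw) > 0])
    interp = PchipInterpolator(tw[keep], cw[keep] - cb_target)
    lo, hi = tw[i_last], tw[min(i_last + 1, tw.size - 1)]
    if interp(lo) * interp(hi) > 0:
        return float(hi)
    return float(brentq(interp, lo, hi))


def dose_plan(vif_full: VifCurve, fractions=(0.25, 0.5, 0.75, 1.0),
              relax: RelaxivityParams | None = None,
              target_t1: float = 0.8) -> pd.DataFrame:
    """Time-to-optimal-T1 table across fractional doses."""
    rows = []
    for frac in fractions:
        scaled = scale_dose(vif_full, frac)
        rows.append({"dose_fraction": frac,
                     "minutes_to_target": time_to_target(scaled, relax,
                                                         target_t1)})
    return pd.DataFrame(rows)
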