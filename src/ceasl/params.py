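"""Parameter containers shared across the package.

Conventions
-----------
Cerebral blood flow ``f`` is stored in the conventional reporting unit
mL blood/min/100 mL tissue at all API boundaries and converted to s^-1
(division by 6000) inside the kinetic equations.  All times are seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhysioParams",
    "AcquisitionParams",
    "SignalCurve",
    "F_UNIT_SCALE",
]

#: divide CBF in mL/min/100 mL by this to obtain s^-1
F_UNIT_SCALE = 6000.0


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class PhysioParams:
    """Biophysical state of a voxel or ROI.

    Parameters
    ----------
    f : float
        Cerebral blood flow, mL blood/min/100 mL tissue.
    t_A : float
        Arterial transit time, s.
    k_b : float
        Blood-to-tissue water exchange rate, s^-1 (``k_b = PS / v_bw``).
    T1_b : float
        Longitudinal relaxation time of blood, s.  Pre-contrast at 3 T this
        is ~1.65 s; an intravascular gadolinium agent shortens it.
    T1_e : float
        Longitudinal relaxation time of the extravascular space, s.
    lambda_ : float
        Brain:blood partition coefficient, mL/g.
    v_bw : float or None
        Blood water volume fraction; only needed to report ``PS = k_b * v_bw``.
    """

    f: float = 60.0
    t_A: float = 1.2
    k_b: float = 2.65
    T1_b: float = 1.65
    T1_e: float = 1.5
    lambda_: float = 0.9
    v_bw: float | None = None

    def __post_init__(self) -> None:
        for name in ("f", "t_A", "k_b", "T1_b", "T1_e", "lambda_"):
            _check_finite(name, getattr(self, name))
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.t_A < 0:
            raise ValueError("t_A must be >= 0")
        if self.k_b < 0:
            raise ValueError("k_b must be >= 0")
        if self.T1_b <= 0 or self.T1_e <= 0:
            raise ValueError("T1 values must be > 0")
        if not 0 < self.lambda_ <= 1.2:
            raise ValueError("lambda_ must be in (0, 1.2]")

    @property
    def ps(self) -> float:
        """Permeability-surface-area product ``k_b * v_bw`` (needs v_bw)."""
        if self.v_bw is None:
            raise ValueError("v_bw is required to compute PS")
        return self.k_b * self.v_bw

    def with_(self, **kwargs) -> "PhysioParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AcquisitionParams:
    """Labelling and readout settings.

    ``plds`` are post-labelling delays; the measurement time from the start
    of labelling is ``t = t_L + PLD``.
    """

    t_L: float = 2.0
    alpha: float = 0.85
    M0: float = 1.0
    plds: tuple[float, ...] = (0.9, 1.2, 1.5, 1.8, 2.1)

    def __post_init__(self) -> None:
        for name in ("t_L", "alpha", "M0"):
            _check_finite(name, getattr(self, name))
        if self.t_L <= 0:
            raise ValueError("t_L must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.M0 <= 0:
            raise ValueError("M0 must be > 0")
        plds = tuple(float(p) for p in self.plds)
        if any(p < 0 for p in plds):
            raise ValueError("plds must be >= 0")
        if any(b <= a for a, b in zip(plds, plds[1:])):
            raise ValueError("plds must be strictly increasing")
        object.__setattr__(self, "plds", plds)

    @property
    def times(self) -> np.ndarray:
        """Measurement times from labelling onset, ``t_L + PLD``."""
        return self.t_L + np.asarray(self.plds, dtype=float)

    def with_(self, **kwargs) -> "AcquisitionParams":
        return replace(self, **kwargs)


@dataclass
class SignalCurve:
    """ASL difference-signal samples on a time grid.

    ``contrast_phase`` records which blood T1 applies ('pre', 'post1' or
    'post2'); times are measured from the start of labelling.
    """

    times: np.ndarray
    values: np.ndarray
    contrast_phase: str = "pre"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.contrast_phase not in ("pre", "post1", "post2"):
            raise ValueError("contrast_phase must be 'pre', 'post1' or 'post2'")

    def __len__(self) -> int:
        return self.times.size
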