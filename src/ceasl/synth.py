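"""Synthetic phantoms and signal tables with known ground truth.

Every other module is testable against these generators without any
external data.  Voxel values follow the control/label decomposition

    control = 0.05 M0 + dM/2 + noise,  label = 0.05 M0 - dM/2 + noise,

so the pairwise difference has mean dM and noise variance 2 sigma^2,
matching the Monte Carlo noise model (independent Gaussian noise on
control and label, 95% background suppression).  The static 0.05 M0 /
symmetric-split construction is a bookkeeping choice; only the difference
enters any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import signal
from .monte_carlo import NoiseModel
from .params import AcquisitionParams, PhysioParams, SignalCurve

__all__ = ["PhantomSpec", "make_phantom", "make_signal_table",
           "save_phantom_nifti"]

#: default contrast phases: blood T1 per phase and the PLDs acquired in it
DEFAULT_PHASES = (("pre", 1.65, (0.9, 1.2, 1.5, 1.8, 2.1)),
                  ("post1", 0.8, (1.5,)))


@dataclass(frozen=True)
class PhantomSpec:
    """Labelled-region phantom specification.

    ``labels`` is a 3-D integer map (0 = background); ``regions`` assigns a
    ground-truth parameter set to every positive label.  ``phases`` lists
    (name, blood T1, PLDs) per contrast phase.
    """

    labels: np.ndarray
    regions: Mapping[int, PhysioParams]
    phases: tuple = DEFAULT_PHASES
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(n_reps=1))
    seed: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels[labels > 0]).tolist())
        if not present:
            raise ValueError("phantom has no foreground region")
        missing = present - set(self.regions)
        if missing:
            raise ValueError(f"no parameters for labels {sorted(missing)}")
        t_max = max(self.acq.t_L + max(p) for _, _, p in self.phases)
        for lab, phys in self.regions.items():
            if lab in present and phys.t_A >= t_max:
                raise ValueError(f"region {lab}: t_A beyond last measurement")


def _measurement_axes(spec: PhantomSpec):
    times, t1b, phase_names = [], [], []
    for name, t1b_phase, plds in spec.phases:
        for p in plds:
            times.append(spec.acq.t_L + p)
            t1b.append(t1b_phase)
            phase_names.append(name)
    return np.array(times), np.array(t1b), phase_names


def make_phantom(spec: PhantomSpec) -> dict:
    """Generate control/label/difference volumes plus truth maps.

    Returns a dict with 4-D ``control``, ``label``, ``difference`` arrays
    (x, y, z, n_meas), the ``m0``/``t1e`` maps, per-parameter ``truth``
    maps, the ROI ``labels`` map and the ``blood_t1s`` vector giving the
    blood T1 applying to each measurement.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    shape = labels.shape
    times, t1b, phase_names = _measurement_axes(spec)
    n_meas = times.size

    m0_map = np.zeros(shape)
    t1e_map = np.zeros(shape)
    truth = {k: np.full(shape, np.nan) for k in ("f", "tA", "kb")}
    clean = np.zeros(shape + (n_meas,))
    for lab, phys in spec.regions.items():
        sel = labels == lab
        if not sel.any():
            continue
        m0_map[sel] = spec.acq.M0
        t1e_map[sel] = phys.T1_e
        truth["f"][sel] = phys.f
        truth["tA"][sel] = phys.t_A
        truth["kb"][sel] = phys.k_b
        dm = signal(times, phys.f, phys.t_A, phys.k_b, t1b, phys.T1_e,
                    t_l=spec.acq.t_L, alpha=spec.acq.alpha, m0=spec.acq.M0,
                    lambda_=phys.lambda_)
        clean[sel] = dm

    sd = spec.noise.sigma / np.sqrt(spec.noise.roi_size)
    base = spec.noise.background_suppression_factor * m0_map[..., None]
    fg = (labels > 0)[..., None]
    control = base + clean / 2 + rng.normal(0.0, sd, clean.shape) * fg
    label_img = base - clean / 2 + rng.normal(0.0, sd, clean.shape) * fg
    return {
        "control": control, "label": label_img,
        "difference": control - label_img,
        "m0": m0_map, "t1e": t1e_map, "truth": truth, "labels": labels,
        "times": times, "blood_t1s": t1b, "phase_names": phase_names,
        "acq": spec.acq,
    }


def make_signal_table(truth: PhysioParams | None = None,
                      phases=DEFAULT_PHASES,
                      acq: AcquisitionParams | None = None,
                      noise: NoiseModel | None = None,
                      seed: int = 0):
    """Tabular twin of the phantom: per-phase curves plus a tidy table.

    With ``noise=None`` the curves are noise-free.  Returns
    ``(curves, table)`` where ``curves`` is a list of `SignalCurve` (one
    per phase) and ``table`` a DataFrame with one row per measurement.
    """
    truth = truth or PhysioParams()
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    curves, rows = [], []
    for name, t1b_phase, plds in phases:
        times = acq.t_L + np.asarray(plds, dtype=float)
        dm = signal(times, truth.f, truth.t_A, truth.k_b, t1b_phase,
                    truth.T1_e, t_l=acq.t_L, alpha=acq.alpha, m0=acq.M0,
                    lambda_=truth.lambda_)
        if noise is not None:
            sd = noise.sigma * np.sqrt(2.0) / np.sqrt(noise.roi_size)
            dm = dm + rng.normal(0.0, sd, dm.shape)
        curves.append(SignalCurve(times=times, values=dm,
                                  contrast_phase=name))
        for p, t, v in zip(plds, times, dm):
            rows.append({"phase": name, "pld": p, "time": t, "t1b": t1b_phase,
                         "delta_M": v})
    return curves, pd.DataFrame(rows)


def save_phantom_nifti(phantom: dict, out_dir) -> dict:
    """Write the phantom volumes as NIfTI-1 files; returns the paths."""
    import json
    from pathlib import Path

    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    affine = np.eye(4)
    for key in ("control", "label", "difference", "m0", "t1e"):
        img = nib.Nifti1Image(np.asarray(phantom[key], dtype=np.float64),
                              affine)
        paths[key] = str(out_dir / f"{key}.nii")
        nib.save(img, paths[key])
    labels = nib.Nifti1Image(phantom["labels"].astype(np.int16), affine)
    paths["labels"] = str(out_dir / "labels.nii")
    nib.save(labels, paths["labels"])
    for k, vol in phantom["truth"].items():
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine)
        paths[f"truth_{k}"] = str(out_dir / f"truth_{k}.nii")
        nib.save(img, paths[f"truth_{k}"])
    sidecar = {"times": phantom["times"].tolist(),
               "blood_t1s": phantom["blood_t1s"].tolist(),
               "phase_names": phantom["phase_names"]}
    paths["sidecar"] = str(out_dir / "phantom.json")
    Path(paths["sidecar"]).write_text(json.dumps(sidecar, indent=2))
    return paths
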