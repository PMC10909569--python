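"""Matplotlib helpers mirroring the standard diagnostic figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_sensitivity_surface(surface, ax=None):
    """Heatmap of normalized sensitivity over (blood T1) x PLD."""
    if ax is None:
        _, ax = plt.subplots()
    extent = [surface.pld_grid[0], surface.pld_grid[-1],
              surface.t1b_grid[0], surface.t1b_grid[-1]]
    im = ax.imshow(surface.values, origin="lower", aspect="auto",
                   extent=extent, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.plot(surface.argmax[1], surface.argmax[0], "kx", markersize=10)
    ax.set_xlabel("PLD (s)")
    ax.set_ylabel("blood $T_1$ (s)")
    plt.colorbar(im, ax=ax, label=r"normalized $\partial\Delta M/\partial k_b$")
    return ax


def plot_signal_curves(curves, ax=None):
    """Difference-signal curves, one line per contrast phase."""
    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.times, c.values, "o-", label=c.contrast_phase)
    ax.set_xlabel("time from labelling onset (s)")
    ax.set_ylabel(r"$\Delta M$ (a.u.)")
    ax.legend()
    return ax


def plot_error_propagation(table, parameter="kb", ax=None):
    """Relative error of a fitted parameter versus T1 perturbation."""
    if ax is None:
        _, ax = plt.subplots()
    for target, sub in table.groupby("target"):
        ax.plot(100 * sub["perturbation"], sub[f"eps_{parameter}"],
                label=target)
    ax.axhline(10, color="0.6", ls="--")
    ax.axhline(-10, color="0.6", ls="--")
    ax.set_xlabel("T1 perturbation (%)")
    ax.set_ylabel(f"relative error of {parameter} (%)")
    ax.legend()
    return ax


def plot_t1_recovery(vifs, relax=None, target_t1=0.8, ax=None):
    """Blood T1 recovery after injection for a set of dose-scaled VIFs."""
    from .gbca_dose import t1b_post

    if ax is None:
        _, ax = plt.subplots()
    for vif in vifs:
        ax.plot(vif.t, t1b_post(vif.cb, relax),
                label=f"{vif.dose_fraction:g} dose")
    ax.axhline(target_t1, color="k", ls=":")
    ax.set_xlabel("time after injection (min)")
    ax.set_ylabel("blood $T_1$ (s)")
    ax.legend()
    return ax
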