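"""Diagnostic figures: Piper, Gibbs, Wilcox, USSL and the HQ cumulative curve.

All functions take a matplotlib Axes (created if omitted) and return
it, so figures compose; nothing is shown interactively.
"""

from __future__ import annotations

import math
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chemistry import WaterSample
from .facies import GIBBS_REGIONS, piper_coordinates, ratio_diagnostics
from .quality import DEFAULT_WILCOX_POLYGONS, irrigation_indices
from .risk import MCResult

__all__ = ["plot_piper", "plot_gibbs", "plot_wilcox", "plot_ussl", "plot_hq_cumulative"]

_S = math.sqrt(3.0) / 2.0


def _triangle(ax, x0: float, labels: tuple[str, str, str]) -> None:
    ax.plot([x0, x0 + 1, x0 + 0.5, x0], [0, 0, _S, 0], color="k", lw=0.8)
    ax.text(x0, -0.05, labels[0], ha="center", va="top", fontsize=8)
    ax.text(x0 + 1, -0.05, labels[1], ha="center", va="top", fontsize=8)
    ax.text(x0 + 0.5, _S + 0.03, labels[2], ha="center", fontsize=8)


def plot_piper(samples: Sequence[WaterSample], ax=None):
    """Piper trilinear diagram (cation/anion triangles plus diamond)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    _triangle(ax, 0.0, ("Ca", "Na+K", "Mg"))
    _triangle(ax, 1.2, ("HCO3+CO3", "Cl", "SO4"))
    # diamond corners follow from projecting the triangle vertices
    ax.plot(
        [1.1, 0.6, 1.1, 1.6, 1.1],
        [0.2 * _S, 1.2 * _S, 2.2 * _S, 1.2 * _S, 0.2 * _S],
        color="k", lw=0.8,
    )
    for s in samples:
        pp = piper_coordinates(s)
        ax.plot(*pp.cation_xy, "o", ms=3, color="tab:blue")
        ax.plot(*pp.anion_xy, "o", ms=3, color="tab:red")
        ax.plot(*pp.diamond_xy, "D", ms=3, color="tab:purple")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("Piper diagram")
    return ax


def plot_gibbs(samples: Sequence[WaterSample], which: str = "cation", ax=None):
    """Gibbs plot: TDS (log) vs Na/(Na+Ca) or Cl/(Cl+HCO3)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    xs, ys = [], []
    for s in samples:
        d = ratio_diagnostics(s)
        xs.append(d.gibbs_cation if which == "cation" else d.gibbs_anion)
        ys.append(s.tds)
    ax.scatter(xs, ys, s=12)
    for name, (t_lo, t_hi, r_lo, r_hi) in GIBBS_REGIONS.items():
        t_hi = min(t_hi, 1e5)
        ax.add_patch(
            plt.Rectangle(
                (r_lo, max(t_lo, 1.0)), r_hi - r_lo, t_hi - max(t_lo, 1.0),
                fill=False, ls="--", lw=0.7, ec="grey",
            )
        )
        ax.text(0.5 * (r_lo + r_hi), math.sqrt(max(t_lo, 1.0) * t_hi),
                name.replace("_", " "), fontsize=7, ha="center", color="grey")
    ax.set_yscale("log")
    ax.set_xlim(0, 1)
    ax.set_xlabel("Na/(Na+Ca)" if which == "cation" else "Cl/(Cl+HCO3)")
    ax.set_ylabel("TDS (mg/L)")
    ax.set_title("Gibbs diagram")
    return ax


def plot_wilcox(samples: Sequence[WaterSample], ax=None):
    """Wilcox diagram: EC vs %Na with the class region boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for name, verts in DEFAULT_WILCOX_POLYGONS:
        xs = [v[0] for v in verts] + [verts[0][0]]
        ys = [v[1] for v in verts] + [verts[0][1]]
        ax.plot(xs, ys, lw=0.7, ls="--", color="grey")
        ax.annotate(name.replace("_", " "), verts[-1], fontsize=6, color="grey")
    for s in samples:
        irr = irrigation_indices(s)
        ec = s.ec if s.ec is not None else s.tds / 0.64
        ax.plot(ec, irr.percent_na, "o", ms=4, color="tab:blue")
    ax.set_xlabel("EC (uS/cm)")
    ax.set_ylabel("%Na")
    ax.set_xlim(0, 3600)
    ax.set_ylim(0, 100)
    ax.set_title("Wilcox diagram")
    return ax


def plot_ussl(samples: Sequence[WaterSample], ax=None):
    """USSL diagram: EC (log) vs SAR with C and S class gridlines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for edge in (250, 750, 2250):
        ax.axvline(edge, color="grey", ls="--", lw=0.7)
    for edge in (10, 18, 26):
        ax.axhline(edge, color="grey", ls="--", lw=0.7)
    for s in samples:
        irr = irrigation_indices(s)
        ec = s.ec if s.ec is not None else s.tds / 0.64
        ax.plot(max(ec, 10.0), irr.sar, "o", ms=4, color="tab:green")
    ax.set_xscale("log")
    ax.set_xlabel("EC (uS/cm)")
    ax.set_ylabel("SAR")
    ax.set_title("USSL diagram")
    return ax


def plot_hq_cumulative(results: dict[str, np.ndarray] | dict[str, MCResult], ax=None):
    """Cumulative probability curves of HQ per age group.

    Accepts either raw HQ draws per group or MCResult summaries (the
    latter plot the five summary percentiles).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for group, val in results.items():
        if isinstance(val, MCResult):
            qs = sorted(val.percentiles)
            ax.plot([val.percentiles[q] for q in qs], [q / 100 for q in qs],
                    marker="o", label=group)
        else:
            x = np.sort(np.asarray(val, dtype=float))
            ax.plot(x, np.arange(1, len(x) + 1) / len(x), label=group)
    ax.axvline(1.0, color="red", ls="--", lw=0.8)
    ax.set_xlabel("HQ")
    ax.set_ylabel("cumulative probability")
    ax.legend(fontsize=8)
    ax.set_title("HQ cumulative distribution")
    return ax
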