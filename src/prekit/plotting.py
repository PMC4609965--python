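"""Figure exports: contact heat maps, titration curves, 3D titration surface."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pre import ContactMap
from .titration import ResidueFit, TitrationSet, binding_model

__all__ = ["plot_contact_map", "plot_titration_curves", "plot_titration_surface"]


def plot_contact_map(cmap: ContactMap, path: str | Path, vmax: float = 12.0) -> None:
    """Strip heat map: one row per spin label, colour saturating above vmax."""
    m = np.clip(cmap.matrix(), 0.0, None)
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(cmap.strips) + 1.5))
    im = ax.imshow(
        np.ma.masked_invalid(m), aspect="auto", cmap="jet",
        vmin=0.0, vmax=vmax, interpolation="nearest",
        extent=(0.5, cmap.sequence_length + 0.5, len(cmap.strips) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(cmap.strips)), [str(s) for s in cmap.sites])
    ax.set_xlabel("residue (visible chain)")
    ax.set_ylabel("spin-label site")
    for name, (a, b) in cmap.regions.regions.items():
        ax.axvline(b + 0.5, color="w", lw=0.5)
        ax.text((a + b) / 2, -0.8, name, ha="center", fontsize=8)
    fig.colorbar(im, ax=ax, label=r"$\Gamma_2$ (s$^{-1}$)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_titration_curves(
    tset: TitrationSet,
    fits: Mapping[int, ResidueFit],
    residues: Iterable[int],
    path: str | Path,
) -> None:
    """Per-residue Gamma2 against titrant concentration with fitted curves."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    xs_uM = tset.x * 1e6
    dense = np.linspace(0, tset.x.max(), 200)
    for r in residues:
        if r not in tset.gamma2:
            continue
        x, y, e = tset.series(r)
        (line,) = ax.plot(xs_uM, y, "o", ms=4, label=f"{r}")
        ax.errorbar(xs_uM, y, yerr=e, fmt="none", ecolor=line.get_color(), alpha=0.5)
        fit = fits.get(r)
        if fit and fit.saturation and fit.classification == "specific":
            s = fit.saturation
            ax.plot(dense * 1e6, binding_model(dense, s.gamma2_free, s.gamma2_bound, s.kd),
                    "-", color=line.get_color(), lw=1)
        elif fit and fit.linear:
            ax.plot(dense * 1e6, fit.linear.intercept + fit.linear.slope * dense,
                    "--", color=line.get_color(), lw=1)
    ax.set_xlabel("spin-labelled chain concentration (uM)")
    ax.set_ylabel(r"$\Gamma_2$ (s$^{-1}$)")
    ax.legend(title="residue", fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_titration_surface(tset: TitrationSet, residues: Iterable[int], path: str | Path) -> None:
    """Residue x ratio x Gamma2 surface for a block of residues."""
    residues = [r for r in residues if r in tset.gamma2]
    z = np.array([tset.gamma2[r] for r in residues])
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    rr, tt = np.meshgrid(tset.ratios, residues)
    ax.plot_surface(tt, rr, z, cmap="rainbow", edgecolor="k", lw=0.2)
    ax.set_xlabel("residue")
    ax.set_ylabel("ratio")
    ax.set_zlabel(r"$\Gamma_2$ (s$^{-1}$)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
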