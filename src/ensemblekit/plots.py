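"""Matplotlib renderings of the standard analysis products."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .coil_scaling import SectionStats
from .domain_partition import DomainPartition, PAEMatrix
from .site_disorder import FlexibilityProfile, OrderProfile

#: residue-class plot colors (Gly red, Pro green, Thr blue, other black)
CLASS_COLORS = {"G": "tab:red", "P": "tab:green", "T": "tab:blue",
                "other": "black"}


def plot_similarity_matrix(s: np.ndarray, labels, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(s, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    fig.colorbar(im, ax=ax, label="similarity $s_{kl}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ree_scaling(stats: SectionStats, path) -> None:
    """Sections vs fit: gray min/max band, green mean, red scaling law."""
    n = stats.ree.shape[0]
    dn = np.arange(1, n)
    lo = np.array([np.diagonal(stats.ree, k).min() for k in dn])
    hi = np.array([np.diagonal(stats.ree, k).max() for k in dn])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(dn, lo, hi, color="0.8", label="section range")
    ax.plot(dn, stats.ree_mean_by_length, color="tab:green",
            label=r"$\bar r_{ee}(\Delta N)$")
    ax.plot(dn, stats.b0 * dn ** stats.nu, color="tab:red",
            label=rf"$b_0 \Delta N^\nu$ ($b_0$={stats.b0:.2f}, "
                  rf"$\nu$={stats.nu:.3f})")
    ax.set_xlabel(r"section length $\Delta N$")
    ax.set_ylabel(r"$r_{ee}$ ($\mathrm{\AA}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_deviation_matrix(mat: np.ndarray, path, label: str = "S (A)",
                          residue_numbers=None) -> None:
    """Diverging heat map, blue = compact, red = expanded."""
    lim = np.nanmax(np.abs(mat)) or 1.0
    extent = None
    if residue_numbers is not None:
        extent = [residue_numbers[0], residue_numbers[-1],
                  residue_numbers[-1], residue_numbers[0]]
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(mat, cmap="bwr", vmin=-lim, vmax=lim, extent=extent)
    ax.set_xlabel("residue j")
    ax.set_ylabel("residue i")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profiles(order: OrderProfile, flex: FlexibilityProfile, path,
                  residue_numbers=None) -> None:
    """Per-residue order (top) and class-colored flexibility (bottom)."""
    nv = len(order.o)
    nr = len(flex.f)
    x_o = (np.asarray(residue_numbers[:nv]) if residue_numbers is not None
           else np.arange(1, nv + 1))
    x_f = (np.asarray(residue_numbers[:nr]) if residue_numbers is not None
           else np.arange(1, nr + 1))
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.plot(x_o, order.o, "o", ms=3, color="tab:blue")
    if order.reference_band:
        ax1.axhspan(*order.reference_band, color="0.85", zorder=0,
                    label="random-coil band")
        ax1.legend()
    ax1.set_ylabel("order $o_i$")
    cls = np.asarray(flex.classes)
    for c, color in CLASS_COLORS.items():
        sel = cls == c
        if sel.any():
            ax2.plot(x_f[sel], flex.f[sel], "o", ms=3, color=color, label=c)
        if flex.reference and c in flex.reference:
            _, lo, hi = flex.reference[c]
            ax2.hlines([lo, hi], x_f[0], x_f[-1], color=color, lw=0.6,
                       alpha=0.6)
    ax2.set_ylabel("flexibility $f_i$")
    ax2.set_xlabel("residue")
    ax2.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pae_partition(pae: PAEMatrix, partition: DomainPartition,
                       path) -> None:
    """PAE matrix with detected domains overlaid as red squares."""
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(pae.values, cmap="Greens_r", vmin=0, vmax=pae.cap)
    for a, b in partition.domains:
        ax.add_patch(plt.Rectangle((a - 1.5, a - 1.5), b - a + 1, b - a + 1,
                                   fill=False, edgecolor="red", lw=1.5))
    ax.set_title(f"class {partition.protein_class}")
    ax.set_xlabel("residue j")
    ax.set_ylabel("residue i")
    fig.colorbar(im, ax=ax, label="PAE ($\\mathrm{\\AA}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
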