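"""Deviation of chain-section statistics from Flory random-coil scaling.

For every chain section between residues i and j (sequence length
dN = j - i) the ensemble root-mean-square end-to-end distance is

    r_ee,i,j = sqrt( sum_c w_c r_ij,c^2 ).

For a homogeneous random coil these follow the Flory scaling law
r_ee(dN) = b0 * dN^nu with Kuhn length b0 and scaling exponent nu
(1/3 poor solvent, 1/2 theta solvent, 0.588 good solvent).  Deviations are
resolved per section by

* the proximity matrix      P_ij = (r_ee,i,j - b0 dN^nu) / (b0 dN^nu),
* the compactness matrix    C_ij, same form built from section gyration
  radii with their own (b0g, nug) fit,
* the section length deviation matrix  S_ij = r_ee,i,j - rbar_ee(dN),

where rbar_ee(dN) is the arithmetic mean of r_ee over the N - dN sections
of equal sequence length.  S highlights heterogeneous local compaction
(S < 0) and expansion (S > 0) without reference to a fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

from .io import CATrace

__all__ = [
    "section_ree", "section_gyration", "fit_flory", "mean_ree_by_length",
    "deviation_matrices", "SectionStats", "section_stats",
]


def section_ree(trace: CATrace, weights=None) -> np.ndarray:
    """Ensemble RMS end-to-end distance of every chain section.

    Returns an (N, N) symmetric matrix; entry (i, j) is r_ee for the section
    between residues at positions i and j (0 on the diagonal).
    """
    coords = trace.coordinates
    w = np.asarray(weights if weights is not None else trace.weights)
    n = coords.shape[1]
    acc = np.zeros(n * (n - 1) // 2)
    for c in range(coords.shape[0]):
        acc += w[c] * pdist(coords[c]) ** 2
    return squareform(np.sqrt(acc))


def section_gyration(trace: CATrace, weights=None) -> np.ndarray:
    """Ensemble RMS gyration radius of every contiguous section (C-alpha,
    equal masses), combined over conformers as sqrt(sum_c w_c Rg_c^2)."""
    coords = trace.coordinates
    w = np.asarray(weights if weights is not None else trace.weights)
    c, n, _ = coords.shape
    acc = np.zeros((n, n))
    idx = np.arange(n)
    length = np.abs(idx[None, :] - idx[:, None]) + 1  # residues in section
    for k in range(c):
        x = coords[k]
        cs1 = np.vstack([np.zeros(3), np.cumsum(x, axis=0)])       # (n+1, 3)
        cs2 = np.concatenate([[0.0], np.cumsum(np.sum(x * x, 1))])  # (n+1,)
        lo = np.minimum(idx[:, None], idx[None, :])
        hi = np.maximum(idx[:, None], idx[None, :])
        s2 = cs2[hi + 1] - cs2[lo]
        s1 = cs1[hi + 1] - cs1[lo]
        rg2 = s2 / length - np.sum(s1 * s1, axis=2) / length ** 2
        acc += w[k] * np.maximum(rg2, 0.0)
    return np.sqrt(acc)


def _upper_pairs(mat: np.ndarray):
    n = mat.shape[0]
    i, j = np.triu_indices(n, k=1)
    return (j - i).astype(float), mat[i, j]


def fit_flory(ree: np.ndarray, min_sections: int = 10,
              nu_bounds: tuple[float, float] = (0.1, 1.0),
              p0: tuple[float, float] = (3.8, 0.5)) -> tuple[float, float]:
    """Least-squares fit of r_ee = b0 * dN^nu to all sections (linear space).

    Returns (b0, nu); nu is constrained to ``nu_bounds``.
    """
    dn, r = _upper_pairs(np.asarray(ree, dtype=float))
    if len(r) < min_sections:
        raise ValueError(f"need at least {min_sections} sections, got {len(r)}")

    def resid(p):
        return p[0] * dn ** p[1] - r

    sol = least_squares(resid, x0=list(p0),
                        bounds=([1e-6, nu_bounds[0]], [np.inf, nu_bounds[1]]))
    if not sol.success:
        raise RuntimeError(f"Flory fit did not converge: {sol.message} "
                           f"(cost {sol.cost:.3g}, x {sol.x})")
    return float(sol.x[0]), float(sol.x[1])


def mean_ree_by_length(ree: np.ndarray) -> np.ndarray:
    """rbar_ee(dN) for dN = 1 .. N-1 (mean over the N - dN equal-length
    sections).  Index 0 of the returned vector corresponds to dN = 1."""
    ree = np.asarray(ree, dtype=float)
    n = ree.shape[0]
    return np.array([np.diagonal(ree, offset=dn).mean()
                     for dn in range(1, n)])


@dataclass
class SectionStats:
    ree: np.ndarray
    ree_mean_by_length: np.ndarray
    b0: float
    nu: float
    P: np.ndarray
    Cmat: np.ndarray | None
    S: np.ndarray
    b0g: float | None = None
    nug: float | None = None


def deviation_matrices(ree: np.ndarray, b0: float, nu: float,
                       trace: CATrace | None = None) -> SectionStats:
    """Build the P, C and S deviation matrices from a fitted scaling law.

    The compactness matrix C requires the C-alpha trace (section gyration
    radii get their own scaling fit); pass ``trace=None`` to skip it.
    """
    ree = np.asarray(ree, dtype=float)
    n = ree.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dn = np.abs(j - i).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        model = b0 * dn ** nu
        P = np.where(dn > 0, (ree - model) / model, 0.0)
    rbar = mean_ree_by_length(ree)
    S = np.where(dn > 0, ree - np.concatenate([[0.0], rbar])[dn.astype(int)], 0.0)
    Cmat = b0g = nug = None
    if trace is not None:
        rg = section_gyration(trace)
        b0g, nug = fit_flory(rg, p0=(1.5, 0.5))
        with np.errstate(divide="ignore", invalid="ignore"):
            model_g = b0g * dn ** nug
            Cmat = np.where(dn > 0, (rg - model_g) / model_g, 0.0)
    return SectionStats(ree, rbar, b0, nu, P, Cmat, S, b0g, nug)


def section_stats(trace: CATrace, weights=None,
                  with_compactness: bool = True) -> SectionStats:
    """One-call pipeline: r_ee matrix, Flory fit, P/C/S matrices."""
    ree = section_ree(trace, weights)
    b0, nu = fit_flory(ree)
    return deviation_matrices(ree, b0, nu,
                              trace if with_compactness else None)
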