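"""Similarity of weighted conformer ensembles in abstract conformer space.

Two conformers are compared by the distance root-mean-square deviation
(DRMSD) of their internal C-alpha distances,

    D(a, b) = sqrt( (2 / (N (N-1))) * sum_{i<j} (r_ij,a - r_ij,b)^2 ),

which is invariant under rigid motion and reflection of either conformer and
is a metric: conformers are points in a Euclidean "conformer space" (each
conformer maps to its scaled vector of internal distances).  For two
ensembles k and l the weighted mean square distance over all conformer pairs,

    Delta_kl = sum_{c_k} sum_{c_l} w_k,c_k w_l,c_l D(c_k, c_l)^2,

measures how far apart the ensembles are; Delta_kk is the (squared) width of
ensemble k.  The dimensionless similarity

    s_kl = sqrt(Delta_kk * Delta_ll) / Delta_kl

is 1 for identical ensembles and 0 for two distinct single-conformer
ensembles, abstracting from ensemble width.

The Shannon entropy of the weight vector, -sum_c w_c log10 w_c, quantifies
how parsimonious an ensemble description is (log10 of the effective number
of conformers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import CATrace, Ensemble, ca_trace

__all__ = [
    "shannon_entropy", "drmsd", "internal_distance_vectors",
    "ConformerDistanceMatrix", "distance_matrix", "ensemble_msd",
    "similarity", "similarity_matrix", "SimilarityResult",
]


def shannon_entropy(weights) -> float:
    """Shannon entropy of a normalized weight vector, decadic logarithm."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be normalized and non-negative")
    nz = w[w > 0]
    return float(-np.sum(nz * np.log10(nz)))


def internal_distance_vectors(coords: np.ndarray) -> np.ndarray:
    """Scaled condensed distance vectors: one row per conformer.

    Rows are the N(N-1)/2 internal C-alpha distances divided by
    sqrt(N(N-1)/2), so Euclidean distance between rows equals DRMSD.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    c, n, _ = coords.shape
    if n < 2:
        raise ValueError("need at least 2 residues")
    npairs = n * (n - 1) // 2
    out = np.empty((c, npairs))
    for i in range(c):
        out[i] = pdist(coords[i])
    return out / np.sqrt(npairs)


def drmsd(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """DRMSD (Angstrom) between two N x 3 C-alpha traces."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace shapes differ: {a.shape} vs {b.shape}")
    va = internal_distance_vectors(a[None])[0]
    vb = internal_distance_vectors(b[None])[0]
    return float(np.linalg.norm(va - vb))


@dataclass
class ConformerDistanceMatrix:
    """Pooled DRMSD matrix over the conformers of one or more ensembles."""

    values: np.ndarray            # (M, M) symmetric, zero diagonal, Angstrom
    ensemble_of: np.ndarray       # (M,) ensemble id k per pooled row
    conformer_of: np.ndarray      # (M,) conformer index within ensemble k
    weights: list[np.ndarray]     # per-ensemble weight vectors
    labels: list[str]

    @property
    def n_ensembles(self) -> int:
        return len(self.weights)

    def block(self, k: int, l: int) -> np.ndarray:
        rows = self.ensemble_of == k
        cols = self.ensemble_of == l
        return self.values[np.ix_(rows, cols)]


def _traces(ensembles) -> list[CATrace]:
    out = []
    for e in ensembles:
        out.append(ca_trace(e) if isinstance(e, Ensemble) else e)
    return out


def distance_matrix(ensembles) -> ConformerDistanceMatrix:
    """Pooled pairwise DRMSD matrix for a list of ensembles (or CATraces)."""
    traces = _traces(ensembles)
    n = traces[0].n_residues
    for t in traces[1:]:
        if t.n_residues != n:
            raise ValueError(
                f"ensembles differ in residue count: {t.n_residues} vs {n}")
    vecs = np.vstack([internal_distance_vectors(t.coordinates) for t in traces])
    values = squareform(pdist(vecs))
    ensemble_of = np.concatenate(
        [np.full(t.n_conformers, k) for k, t in enumerate(traces)])
    conformer_of = np.concatenate(
        [np.arange(t.n_conformers) for t in traces])
    labels = [getattr(e, "label", "") or f"ensemble_{k}"
              for k, e in enumerate(ensembles)]
    return ConformerDistanceMatrix(values, ensemble_of, conformer_of,
                                   [t.weights for t in traces], labels)


def ensemble_msd(dmat: ConformerDistanceMatrix, k: int, l: int) -> float:
    """Weighted mean square conformer-space distance Delta_kl (Angstrom^2).

    Includes self-pairs for k == l, so Delta_kk = 0 iff all conformers of k
    are identical point sets (in particular for a single conformer).
    """
    wk = dmat.weights[k]
    wl = dmat.weights[l]
    block = dmat.block(k, l)
    return float(wk @ (block ** 2) @ wl)


@dataclass
class SimilarityResult:
    delta_kk: float
    delta_ll: float
    delta_kl: float
    s: float
    entropy_k: float
    entropy_l: float


def similarity(dmat: ConformerDistanceMatrix, k: int, l: int) -> SimilarityResult:
    """Single-valued similarity s_kl of ensembles k and l."""
    d_kk = ensemble_msd(dmat, k, k)
    d_ll = ensemble_msd(dmat, l, l)
    d_kl = ensemble_msd(dmat, k, l)
    if d_kl <= 1e-30:
        # identical weighted point sets; the metric forces d_kk = d_ll = 0
        assert d_kk <= 1e-12 and d_ll <= 1e-12
        s = 1.0
    else:
        s = float(np.sqrt(d_kk * d_ll) / d_kl)
    return SimilarityResult(
        d_kk, d_ll, d_kl, s,
        shannon_entropy(dmat.weights[k]), shannon_entropy(dmat.weights[l]))


def similarity_matrix(ensembles) -> tuple[np.ndarray, ConformerDistanceMatrix]:
    """Symmetric matrix of s_kl over all ensemble pairs (unit diagonal)."""
    if len(ensembles) < 2:
        raise ValueError("need at least 2 ensembles")
    dmat = distance_matrix(ensembles)
    m = dmat.n_ensembles
    s = np.eye(m)
    for k in range(m):
        for l in range(k + 1, m):
            s[k, l] = s[l, k] = similarity(dmat, k, l).s
    return s, dmat
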