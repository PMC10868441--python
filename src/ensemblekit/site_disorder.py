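"""Site-specific order and Ramachandran flexibility of ensembles.

Two complementary per-site disorder measures:

*Order parameter* ``o_i`` — long-range orientational order.  For the unit
vectors u_i between consecutive C-alpha atoms, the ensemble variance of
cos(theta_ij) (theta_ij the angle between vectors i and j) approaches 1/2
for uncorrelated vector pairs with theta uniform and 0 for a rigid ensemble.
The site-pair correlation K_ij = 1 - sqrt(2)*sigma_ij therefore spans 0 (no
correlation) to 1 (perfect correlation); o_i is the mean of K_ij over all j
(including j = i).  o_i abstracts from local flexibility and is sensitive to
weak long-range order.

*Flexibility parameter* ``f_i`` — local dihedral disorder.  With the
circular resultant length R(alpha) = |sum_c w_c exp(i alpha_c)| of the
phi and psi angles at residue i,

    f_i = 1 - R(phi_i)/2 - R(psi_i)/2

runs from 0 (identical dihedrals in all conformers) to 1 (uniform
dihedrals).  Random-coil reference bands for both measures are obtained
from an unrestrained Ramachandran-sampled ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CATrace, DihedralSet

__all__ = [
    "bond_vectors", "pair_correlation", "order_parameter", "OrderProfile",
    "circular_resultant", "flexibility", "FlexibilityProfile",
    "residue_class", "random_coil_reference", "RandomCoilReference",
]

#: residue classes with distinct backbone statistics
CLASSES = ("G", "P", "T", "other")


def residue_class(one_letter: str) -> str:
    return one_letter if one_letter in ("G", "P", "T") else "other"


def bond_vectors(trace: CATrace) -> np.ndarray:
    """Unit vectors between consecutive C-alpha atoms, shape (C, N-1, 3)."""
    coords = trace.coordinates
    if coords.shape[1] < 2:
        raise ValueError("need at least 2 residues")
    diff = coords[:, 1:] - coords[:, :-1]
    norms = np.linalg.norm(diff, axis=2, keepdims=True)
    if np.any(norms <= 1e-12):
        raise ValueError("zero-length C-alpha bond vector")
    return diff / norms


def pair_correlation(vectors: np.ndarray, weights) -> np.ndarray:
    """Site-pair correlation matrix K over bond vectors.

    K_ij = 1 - sqrt(2) * sigma_ij, clipped to [0, 1], where sigma_ij^2 is
    the weighted ensemble variance of cos(theta_ij).
    """
    v = np.asarray(vectors, dtype=float)
    w = np.asarray(weights, dtype=float)
    c, nv, _ = v.shape
    # accumulate weighted first and second moments of the cosine matrices
    m1 = np.zeros((nv, nv))
    m2 = np.zeros((nv, nv))
    for i in range(c):
        cos = v[i] @ v[i].T
        m1 += w[i] * cos
        m2 += w[i] * cos * cos
    var = np.maximum(m2 - m1 * m1, 0.0)
    return np.clip(1.0 - np.sqrt(2.0 * var), 0.0, 1.0)


@dataclass
class OrderProfile:
    o: np.ndarray                 # per bond vector, in [0, 1]
    K: np.ndarray                 # (N_v, N_v) site-pair correlations
    reference_band: tuple | None = None


def order_parameter(K: np.ndarray,
                    reference_band: tuple | None = None) -> OrderProfile:
    """Site-specific order o_i = mean_j K_ij (j runs over all bond vectors)."""
    K = np.asarray(K, dtype=float)
    o = K.mean(axis=1)
    return OrderProfile(o, K, reference_band)


def circular_resultant(angles, weights) -> float:
    """Resultant length R = |sum w exp(i alpha)| in [0, 1].

    NaN angles are excluded with weight renormalization; returns NaN if all
    angles are undefined.
    """
    a = np.asarray(angles, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(a)
    if not ok.any():
        return float("nan")
    w = w[ok] / w[ok].sum()
    a = a[ok]
    return float(np.hypot(np.sum(w * np.cos(a)), np.sum(w * np.sin(a))))


@dataclass
class FlexibilityProfile:
    f: np.ndarray                      # per residue, in [0, 1]
    resultant_phi: np.ndarray
    resultant_psi: np.ndarray
    classes: list[str] = field(default_factory=list)
    reference: dict | None = None      # class -> (mean, low, high)

    def class_means(self) -> dict[str, float]:
        cls = np.asarray(self.classes)
        out = {}
        for c in CLASSES:
            sel = (cls == c) & np.isfinite(self.f)
            if sel.any():
                out[c] = float(self.f[sel].mean())
        return out


def flexibility(dihedrals: DihedralSet, weights=None,
                sequence: str | None = None,
                reference: dict | None = None) -> FlexibilityProfile:
    """Per-residue flexibility f_i = 1 - R(phi_i)/2 - R(psi_i)/2.

    At residues where only one of the two dihedrals is defined (termini,
    chain breaks) f is computed from the defined one alone.
    """
    w = np.asarray(weights if weights is not None else dihedrals.weights,
                   dtype=float)
    c, n = dihedrals.phi.shape
    r_phi = np.array([circular_resultant(dihedrals.phi[:, j], w)
                      for j in range(n)])
    r_psi = np.array([circular_resultant(dihedrals.psi[:, j], w)
                      for j in range(n)])
    f = np.empty(n)
    for j in range(n):
        parts = [r for r in (r_phi[j], r_psi[j]) if np.isfinite(r)]
        f[j] = 1.0 - np.mean(parts) if parts else float("nan")
    classes = ([residue_class(s) for s in sequence] if sequence
               else ["other"] * n)
    return FlexibilityProfile(f, r_phi, r_psi, classes, reference)


@dataclass
class RandomCoilReference:
    """95% bands of o and per-class f from an unrestrained coil ensemble."""

    o_mean: float
    o_band: tuple[float, float]
    f_class: dict[str, tuple[float, float, float]]  # class -> (mean, lo, hi)
    n_conformers: int
    seed: int


def random_coil_reference(sequence_length: int = 267, library=None,
                          n_conformers: int = 1000, seed: int = 7,
                          sequence: str | None = None) -> RandomCoilReference:
    """Random-coil reference bands from an unrestrained generated ensemble.

    Bands are mean +/- 1.96 std over sites of o_i, and per residue class of
    f_i.  Regenerated (seeded) rather than hard-coded because they depend on
    the Ramachandran library in use.
    """
    import warnings

    from . import generator
    from .io import backbone_dihedrals, ca_trace

    if n_conformers < 100:
        warnings.warn("fewer than 100 conformers gives a noisy reference")
    if sequence is None:
        sequence = generator.idr_like_sequence(sequence_length, seed=seed)
    config = generator.GeneratorConfig(
        sequence=sequence, n_conformers=n_conformers, seed=seed,
        library=library)
    ensemble = generator.generate_ensemble(config)
    trace = ca_trace(ensemble)
    K = pair_correlation(bond_vectors(trace), ensemble.weights)
    o = order_parameter(K).o
    o_mean = float(o.mean())
    o_band = (o_mean - 1.96 * float(o.std()), o_mean + 1.96 * float(o.std()))
    prof = flexibility(backbone_dihedrals(ensemble), ensemble.weights,
                       sequence=sequence)
    cls = np.asarray(prof.classes)
    f_class = {}
    for c in CLASSES:
        sel = (cls == c) & np.isfinite(prof.f)
        if sel.any():
            mu = float(prof.f[sel].mean())
            sd = float(prof.f[sel].std())
            f_class[c] = (mu, mu - 1.96 * sd, mu + 1.96 * sd)
    return RandomCoilReference(o_mean, o_band, f_class, n_conformers, seed)
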