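"""Partition proteins into folded domains and IDRs and classify them.

Folded domains appear in an AlphaFold predicted-aligned-error (PAE) matrix
as square submatrices of low PAE.  The detection algorithm thresholds the
symmetrized matrix at ``t_domain`` (default 10.58 Angstrom, one third of the
31.75 Angstrom PAE cap), measures for every residue the longest run of
consecutive low-PAE partners, smooths these run lengths with a width-5
moving average, and then iteratively seeds a domain at the largest smoothed
run, refines its boundaries by mean-PAE accretion, and masks it out, as long
as runs of at least ``min_domain`` (default 25) residues remain.  Domains
separated by linkers shorter than 3 residues are merged.

Proteins are classified as F (fully folded), Sf (single folded domain with
at least one terminal IDR of >= 10 residues), Mf (multiple folded domains)
or D (no folded domain / IDP).  A one-dimensional per-residue disorder
track (eSpritz- or CheZOD-style) supports the same partitioning via ordered
runs, and the mean PAE over sequence-distant pairs serves as a single-valued
disorder score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PAE_CAP", "PAEMatrix", "load_pae", "mean_pae_disorder",
    "DomainPartition", "partition_pae", "classify",
    "partition_disorder_track", "sweep_threshold",
]

#: value at which AlphaFold caps the predicted aligned error (Angstrom)
PAE_CAP = 31.75
_MASK = 1.0e6


@dataclass
class PAEMatrix:
    """Symmetrized N x N predicted-aligned-error matrix (Angstrom)."""

    values: np.ndarray
    cap: float = PAE_CAP

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PAE matrix must be square, got {v.shape}")
        if np.any(v > self.cap):
            warnings.warn(f"PAE entries above the {self.cap} A cap; clipping")
            v = np.minimum(v, self.cap)
        self.values = 0.5 * (v + v.T)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def load_pae(path) -> PAEMatrix:
    """Load a PAE matrix from AlphaFold-DB JSON or a plain CSV matrix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip()[:1] in "[{":
        data = json.loads(text)
        if isinstance(data, list):
            data = data[0]
        if "predicted_aligned_error" in data:
            mat = data["predicted_aligned_error"]
        elif "pae" in data:
            mat = data["pae"]
        else:  # legacy flat dialect: residue1/residue2/distance triples
            n = max(data["residue1"])
            mat = np.zeros((n, n))
            mat[np.asarray(data["residue1"]) - 1,
                np.asarray(data["residue2"]) - 1] = data["distance"]
        return PAEMatrix(np.asarray(mat, dtype=float))
    return PAEMatrix(np.loadtxt(path, delimiter=","))


def mean_pae_disorder(pae: PAEMatrix, min_seqsep: int = 10) -> float:
    """Mean PAE over residue pairs with sequence distance >= min_seqsep.

    Near-diagonal pairs are excluded because PAE is low there even for
    IDPs; the result is a single-valued disorder parameter in
    [0, ``pae.cap``].
    """
    n = pae.n_residues
    if n <= min_seqsep:
        raise ValueError("matrix smaller than the sequence-separation cutoff")
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    sel = np.abs(i - j) >= min_seqsep
    return float(pae.values[sel].mean())


@dataclass
class DomainPartition:
    """Folded-domain intervals (1-based inclusive) plus derived segments."""

    domains: list[tuple[int, int]]
    n_residues: int
    linkers: list[tuple[int, int]] = field(default_factory=list)
    n_terminal_idr: tuple[int, int] | None = None
    c_terminal_idr: tuple[int, int] | None = None
    protein_class: str = ""
    t_domain: float | None = None
    min_domain: int = 25

    def __post_init__(self) -> None:
        self.domains = sorted((int(a), int(b)) for a, b in self.domains)
        for (a, b) in self.domains:
            if not (1 <= a <= b <= self.n_residues):
                raise ValueError(f"domain ({a}, {b}) outside chain")
        for (_, b1), (a2, _) in zip(self.domains, self.domains[1:]):
            if a2 <= b1:
                raise ValueError("overlapping domains")
        self._derive_segments()

    def _derive_segments(self) -> None:
        self.linkers = []
        self.n_terminal_idr = None
        self.c_terminal_idr = None
        if not self.domains:
            return
        first_a = self.domains[0][0]
        last_b = self.domains[-1][1]
        if first_a > 1:
            self.n_terminal_idr = (1, first_a - 1)
        if last_b < self.n_residues:
            self.c_terminal_idr = (last_b + 1, self.n_residues)
        for (_, b1), (a2, _) in zip(self.domains, self.domains[1:]):
            self.linkers.append((b1 + 1, a2 - 1))

    @property
    def domain_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.domains)

    def to_bed(self, name: str = "domain") -> str:
        """0-based half-open BED lines of the folded domains."""
        return "".join(f"chain\t{a - 1}\t{b}\t{name}_{k + 1}\n"
                       for k, (a, b) in enumerate(self.domains))


def classify(partition: DomainPartition, n_residues: int | None = None,
             idr_min: int = 10) -> str:
    """Assign class F / Sf / Mf / D from a domain partition."""
    n = n_residues or partition.n_residues
    if not partition.domains:
        return "D"
    if len(partition.domains) >= 2:
        return "Mf"
    a, b = partition.domains[0]
    if (a - 1) >= idr_min or (n - b) >= idr_min:
        return "Sf"
    return "F"


def _merge_close(intervals: list[tuple[int, int]],
                 merge_gap: int) -> list[tuple[int, int]]:
    """Merge intervals separated by linkers of fewer than merge_gap residues."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for a, b in intervals[1:]:
        pa, pb = out[-1]
        if a - pb - 1 < merge_gap:
            out[-1] = (pa, max(pb, b))
        else:
            out.append((a, b))
    return out


def _run_lengths(binary: np.ndarray) -> np.ndarray:
    """e_i: longest dN with B[i, i+1..i+dN] all one (truncated at chain end)."""
    n = binary.shape[0]
    e = np.zeros(n, dtype=int)
    for i in range(n):
        run = 0
        for j in range(i + 1, n):
            if binary[i, j]:
                run += 1
            else:
                break
        e[i] = run
    return e


def _smooth_round(e: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-shrunk window, rounded half away
    from zero."""
    n = len(e)
    half = window // 2
    out = np.empty(n, dtype=int)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = int(np.floor(np.mean(e[lo:hi]) + 0.5))
    return out


def partition_pae(pae: PAEMatrix, t_domain: float = 10.58,
                  min_domain: int = 25, merge_gap: int = 3,
                  window: int = 5, idr_min: int = 10) -> DomainPartition:
    """Iterative folded-domain detection on a PAE matrix.

    Seeds domains at maxima of the smoothed low-PAE run-length vector,
    refines boundaries outward by mean-PAE accretion (contiguous growth
    only), masks accepted domains and repeats while the largest remaining
    run is at least ``min_domain``.
    """
    n = pae.n_residues
    if n < min_domain:
        raise ValueError(f"chain shorter than the minimum domain size "
                         f"({n} < {min_domain})")
    m = pae.values.copy()
    e = _smooth_round(_run_lengths(m < t_domain), window)
    domains: list[tuple[int, int]] = []
    while True:
        e_max = int(e.max())
        if e_max < min_domain:
            break
        i_max = int(np.argmax(e))  # lowest index wins ties
        lo = i_max
        hi = min(i_max + e_max, n - 1)
        # refine: grow contiguously while the candidate residue's mean PAE
        # to the current members stays below t_domain
        grown = True
        while grown:
            grown = False
            members = np.arange(lo, hi + 1)
            if lo > 0 and m[lo - 1, members].mean() < t_domain:
                lo -= 1
                grown = True
                continue
            members = np.arange(lo, hi + 1)
            if hi < n - 1 and m[hi + 1, members].mean() < t_domain:
                hi += 1
                grown = True
        domains.append((lo + 1, hi + 1))  # to 1-based inclusive
        e[lo:hi + 1] = 0
        m[lo:hi + 1, :] = _MASK
        m[:, lo:hi + 1] = _MASK
    domains = _merge_close(domains, merge_gap)
    part = DomainPartition(domains, n, t_domain=t_domain,
                           min_domain=min_domain)
    part.protein_class = classify(part, idr_min=idr_min)
    return part


def partition_disorder_track(scores, threshold: float = 0.15,
                             ordered_when: str = "below",
                             min_domain: int = 25, merge_gap: int = 3,
                             idr_min: int = 10) -> DomainPartition:
    """Domain partition from a 1-D per-residue disorder track.

    ``ordered_when='below'`` suits eSpritz-style disorder probabilities
    (ordered if score < threshold, strict); ``'above'`` suits CheZOD-style
    order scores (ordered if score >= threshold).
    """
    s = np.asarray(scores, dtype=float)
    if ordered_when == "below":
        ordered = s < threshold
    elif ordered_when == "above":
        ordered = s >= threshold
    else:
        raise ValueError("ordered_when must be 'below' or 'above'")
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(np.append(ordered, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))  # 1-based inclusive
            start = None
    domains = _merge_close([r for r in runs if r[1] - r[0] + 1 >= min_domain],
                           merge_gap)
    part = DomainPartition(domains, len(s), min_domain=min_domain)
    part.protein_class = classify(part, idr_min=idr_min)
    return part


def sweep_threshold(data, values, **kwargs) -> dict:
    """Class label per threshold plus a fraction-per-class summary.

    ``data`` is a PAEMatrix (sweeps t_domain) or a 1-D track (sweeps the
    disorder threshold; pass ``ordered_when`` through ``kwargs``).
    """
    labels = {}
    for t in values:
        if isinstance(data, PAEMatrix):
            part = partition_pae(data, t_domain=float(t), **kwargs)
        else:
            part = partition_disorder_track(data, threshold=float(t), **kwargs)
        labels[float(t)] = part.protein_class
    counts = {c: sum(1 for v in labels.values() if v == c)
              for c in ("F", "Sf", "Mf", "D")}
    total = len(labels)
    fractions = {c: counts[c] / total for c in counts}
    return {
        "classes": labels,
        "fractions": fractions,
        "consensus": max(counts, key=counts.get),
        "stable": len(set(labels.values())) == 1,
    }
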