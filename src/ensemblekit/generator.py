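"""Monte Carlo backbone-ensemble generator for disordered chains.

Conformers are grown residue by residue with ideal peptide geometry
(trans omega) and backbone dihedrals drawn from residue-type-specific
Ramachandran distributions, represented as mixtures of wrapped-Gaussian
basins for four residue classes (Gly, Pro, Thr, general).  The basin
layout follows the well-established features of coil-region Ramachandran
statistics: a dominant beta/polyproline-II region and an alpha_R region
for general residues, a small alpha_L population, near-mirror-symmetric
basins for Gly, phi restricted near -65 degrees for Pro, and only the
second/third quadrants (phi < 0) populated for Thr.

Optional whole-conformer rejection enforces C-alpha excluded volume
(pairs |i - j| >= 3 closer than 4 Angstrom are rejected) and distance
restraints between residue pairs via von Neumann rejection sampling
against a target distance histogram with a configurable acceptance
fraction.

The module also plants synthetic PAE matrices with folded-domain blocks
for testing domain partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_partition import PAE_CAP, PAEMatrix
from .io import Conformer, Ensemble, atomic_mass

__all__ = [
    "RamachandranLibrary", "default_library", "sample_ramachandran",
    "build_backbone", "GeneratorConfig", "DistanceRestraint",
    "generate_ensemble", "synthetic_pae", "idr_like_sequence",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone geometry (Angstrom / degrees), trans peptide
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


@dataclass(frozen=True)
class Basin:
    weight: float
    phi: float      # degrees
    psi: float
    sigma_phi: float
    sigma_psi: float


@dataclass
class RamachandranLibrary:
    """Mixtures of wrapped-Gaussian (phi, psi) basins per residue class."""

    classes: dict[str, list[Basin]]

    def __post_init__(self) -> None:
        for name, basins in self.classes.items():
            total = sum(b.weight for b in basins)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"basin weights of class {name!r} sum to "
                                 f"{total}, not 1")

    def basins(self, residue_class: str) -> list[Basin]:
        import warnings
        if residue_class not in self.classes:
            warnings.warn(f"unknown residue class {residue_class!r}; "
                          f"falling back to 'general'")
            residue_class = "general"
        return self.classes[residue_class]


def default_library() -> RamachandranLibrary:
    return RamachandranLibrary({
        "general": [
            Basin(0.65, -110.0, 135.0, 20.0, 20.0),   # beta / PPII
            Basin(0.28, -63.0, -43.0, 15.0, 15.0),    # alpha_R
            Basin(0.07, 55.0, 45.0, 15.0, 15.0),      # alpha_L
        ],
        "G": [
            Basin(0.42, -90.0, 150.0, 25.0, 25.0),
            Basin(0.14, 90.0, -150.0, 25.0, 25.0),    # mirrored beta
            Basin(0.30, -70.0, -30.0, 20.0, 20.0),
            Basin(0.14, 70.0, 30.0, 20.0, 20.0),      # mirrored alpha
        ],
        "P": [
            Basin(0.78, -65.0, 145.0, 10.0, 15.0),    # PPII
            Basin(0.22, -65.0, -30.0, 10.0, 15.0),    # alpha-like
        ],
        "T": [
            Basin(0.72, -110.0, 140.0, 18.0, 18.0),   # quadrant II
            Basin(0.28, -65.0, -40.0, 15.0, 15.0),    # quadrant III
        ],
    })


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles (radians) into (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def residue_class_of(letter: str) -> str:
    return letter if letter in ("G", "P", "T") else "general"


def sample_ramachandran(residue_class: str, rng: np.random.Generator,
                        library: RamachandranLibrary | None = None,
                        size: int = 1) -> np.ndarray:
    """Draw (phi, psi) pairs in radians; shape (size, 2)."""
    library = library or default_library()
    basins = library.basins(residue_class)
    weights = np.array([b.weight for b in basins])
    idx = rng.choice(len(basins), size=size, p=weights)
    phi = np.empty(size)
    psi = np.empty(size)
    for k, b in enumerate(basins):
        sel = idx == k
        m = int(sel.sum())
        if m:
            phi[sel] = np.deg2rad(b.phi) + np.deg2rad(b.sigma_phi) * rng.standard_normal(m)
            psi[sel] = np.deg2rad(b.psi) + np.deg2rad(b.sigma_psi) * rng.standard_normal(m)
    return np.column_stack([_wrap(phi), _wrap(psi)])


# ---------------------------------------------------------------------------
# geometry


def _place(a, b, c, bond: float, angle_deg: float, torsion):
    """Next-atom placement (NeRF): position d with given internal
    coordinates relative to the three previous atoms.  Vectorized over the
    leading axis; ``torsion`` in radians (scalar or array)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    c = np.atleast_2d(c)
    t = np.asarray(torsion, dtype=float).reshape(-1, 1)
    theta = np.deg2rad(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    # minus sign on the n component gives the IUPAC torsion sign convention
    d = (-np.cos(theta) * bc
         + np.sin(theta) * (np.cos(t) * m - np.sin(t) * n))
    return c + bond * d


def _build_batch(phi: np.ndarray, psi: np.ndarray):
    """Backbone N/CA/C/O coordinates for a batch of conformers.

    phi, psi: (C, N) radians (phi[:, 0] and psi[:, -1] are ignored).
    Returns (C, N, 4, 3) with atoms ordered N, CA, C, O.
    """
    cnum, nres = phi.shape
    out = np.empty((cnum, nres, 4, 3))
    # first residue: N at origin, CA on x, C in the xy-plane
    out[:, 0, 0] = 0.0
    out[:, 0, 1] = [BOND_N_CA, 0.0, 0.0]
    th = np.deg2rad(180.0 - ANGLE_N_CA_C)
    out[:, 0, 2] = out[:, 0, 1] + BOND_CA_C * np.array(
        [np.cos(th), np.sin(th), 0.0])
    omega = np.deg2rad(OMEGA)
    for i in range(1, nres):
        prev_n, prev_ca, prev_c = (out[:, i - 1, 0], out[:, i - 1, 1],
                                   out[:, i - 1, 2])
        n_i = _place(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N,
                     psi[:, i - 1])
        ca_i = _place(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = _place(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[:, i])
        out[:, i, 0], out[:, i, 1], out[:, i, 2] = n_i, ca_i, c_i
        # carbonyl O of the previous residue, anti to the next N
        out[:, i - 1, 3] = _place(prev_n, prev_ca, prev_c, BOND_C_O,
                                  ANGLE_CA_C_O, psi[:, i - 1] + np.pi)
    # terminal O: trans to the N-CA bond
    out[:, -1, 3] = _place(out[:, -1, 0], out[:, -1, 1], out[:, -1, 2],
                           BOND_C_O, ANGLE_CA_C_O, np.full(cnum, np.pi))
    return out


def build_backbone(sequence: str, dihedrals) -> Conformer:
    """Build one conformer from a list of (phi, psi) pairs (radians)."""
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.shape != (len(sequence), 2):
        raise ValueError("need one (phi, psi) pair per residue")
    coords = _build_batch(dihedrals[None, :, 0], dihedrals[None, :, 1])[0]
    return _conformer_from_coords(sequence, coords)


def _conformer_from_coords(sequence: str, coords: np.ndarray,
                           first_residue: int = 1) -> Conformer:
    nres = len(sequence)
    res_idx = np.repeat(np.arange(first_residue, first_residue + nres), 4)
    res_name = [
        _ONE_TO_THREE.get(sequence[i], "UNK") for i in range(nres)
        for _ in range(4)]
    atom_name = ["N", "CA", "C", "O"] * nres
    element = ["N", "C", "C", "O"] * nres
    mass = np.array([atomic_mass(e) for e in element])
    return Conformer(res_idx, res_name, atom_name, element, mass,
                     coords.reshape(-1, 3))


# ---------------------------------------------------------------------------
# ensemble generation


@dataclass
class DistanceRestraint:
    """Target C-alpha distance histogram between two residues (1-based
    positions in the sequence).  ``acceptance_fraction`` rescales the
    von Neumann acceptance ratio (1.0 = plain rejection sampling)."""

    i: int
    j: int
    bin_centers: np.ndarray
    probabilities: np.ndarray
    acceptance_fraction: float = 1.0

    def acceptance(self, r: np.ndarray) -> np.ndarray:
        p = np.interp(r, self.bin_centers, self.probabilities,
                      left=0.0, right=0.0)
        return np.minimum(p / (self.probabilities.max()
                               * self.acceptance_fraction), 1.0)


@dataclass
class GeneratorConfig:
    sequence: str
    n_conformers: int = 100
    seed: int = 0
    clash_mode: str = "off"              # "off" | "ca_excluded_volume"
    ca_clash_distance: float = 4.0       # Angstrom, pairs |i-j| >= 3
    max_restarts_per_conformer: int = 200
    restraints: list[DistanceRestraint] = field(default_factory=list)
    first_residue: int = 1
    library: RamachandranLibrary | None = None

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.ca_clash_distance <= 0:
            raise ValueError("clash distance must be positive")
        if self.clash_mode not in ("off", "ca_excluded_volume"):
            raise ValueError(f"unknown clash_mode {self.clash_mode!r}")


def _has_clash(ca: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-conformer clash flag for C-alpha pairs with |i - j| >= 3."""
    c, n, _ = ca.shape
    flags = np.zeros(c, dtype=bool)
    for off in range(3, n):
        d2 = np.sum((ca[:, off:] - ca[:, :-off]) ** 2, axis=2)
        flags |= np.any(d2 < cutoff * cutoff, axis=1)
    return flags


def generate_ensemble(config: GeneratorConfig) -> Ensemble:
    """Sample an ensemble of backbone conformers with uniform weights."""
    rng = np.random.default_rng(config.seed)
    seq = config.sequence
    nres = len(seq)
    lib = config.library or default_library()
    classes = [residue_class_of(s) for s in seq]
    want = config.n_conformers
    kept: list[np.ndarray] = []
    attempts = 0
    max_attempts = config.max_restarts_per_conformer * want
    while len(kept) < want:
        batch = max(want - len(kept), 1)
        attempts += batch
        if attempts > max_attempts:
            rate = len(kept) / attempts
            raise RuntimeError(
                f"acceptance starvation: {len(kept)}/{want} conformers after "
                f"{attempts} attempts (acceptance rate {rate:.2%}); relax "
                f"clash distance or restraint acceptance fractions")
        phi = np.empty((batch, nres))
        psi = np.empty((batch, nres))
        for i, cls in enumerate(classes):
            draws = sample_ramachandran(cls, rng, lib, size=batch)
            phi[:, i] = draws[:, 0]
            psi[:, i] = draws[:, 1]
        coords = _build_batch(phi, psi)
        ca = coords[:, :, 1, :]
        keep = np.ones(batch, dtype=bool)
        if config.clash_mode == "ca_excluded_volume" and nres >= 4:
            keep &= ~_has_clash(ca, config.ca_clash_distance)
        for rest in config.restraints:
            r = np.linalg.norm(ca[:, rest.j - 1] - ca[:, rest.i - 1], axis=1)
            keep &= rng.random(batch) < rest.acceptance(r)
        for c in np.nonzero(keep)[0]:
            if len(kept) < want:
                kept.append(coords[c])
    conformers = [_conformer_from_coords(seq, xyz, config.first_residue)
                  for xyz in kept]
    weights = np.full(want, 1.0 / want)
    return Ensemble(conformers, weights, label=f"generated_seed{config.seed}")


# ---------------------------------------------------------------------------
# synthetic PAE matrices


def synthetic_pae(n_residues: int, domains, within: float = 4.0,
                  between: float = 22.0, band_halfwidth: int = 10,
                  noise_sd: float = 1.0, seed: int = 0) -> PAEMatrix:
    """Plant folded-domain blocks in a synthetic PAE matrix.

    ``domains`` is a list of 1-based inclusive (start, end) intervals.
    Within-domain pairs get low PAE (``within``), everything else high
    (``between``), with Gaussian noise; pairs closer than
    ``band_halfwidth`` along the diagonal ramp linearly toward zero, as in
    real PAE matrices (alignment error is small at short sequence
    separation even in IDPs).
    """
    intervals = sorted((int(a), int(b)) for a, b in domains)
    for a, b in intervals:
        if not (1 <= a <= b <= n_residues):
            raise ValueError(f"interval ({a}, {b}) outside [1, {n_residues}]")
    for (_, b1), (a2, _) in zip(intervals, intervals[1:]):
        if a2 <= b1:
            raise ValueError("overlapping domain intervals")
    rng = np.random.default_rng(seed)
    values = np.full((n_residues, n_residues), between)
    for a, b in intervals:
        values[a - 1:b, a - 1:b] = within
    values = values + noise_sd * rng.standard_normal(values.shape)
    i, j = np.meshgrid(np.arange(n_residues), np.arange(n_residues),
                       indexing="ij")
    sep = np.abs(i - j)
    ramp = np.minimum(sep / max(band_halfwidth, 1), 1.0)
    values = np.minimum(values, values * ramp + 0.0)
    np.fill_diagonal(values, 0.0)
    return PAEMatrix(np.clip(values, 0.0, PAE_CAP))


def idr_like_sequence(n_residues: int = 267, seed: int = 0) -> str:
    """Low-complexity IDR-like sequence (composition of a prion-like,
    QGSY-rich N-terminal domain: rich in Ser/Gly/Gln/Tyr, some Pro/Thr)."""
    composition = {"S": 0.28, "G": 0.22, "Q": 0.14, "Y": 0.12,
                   "T": 0.06, "P": 0.08, "A": 0.04, "N": 0.06}
    letters = list(composition)
    probs = np.array([composition[k] for k in letters])
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(letters, size=n_residues, p=probs / probs.sum()))
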