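"""Ensemble shape visualization: inertia-tensor superposition, pseudo
electron density, and Debye-screened electrostatic surface coloring.

For a fully disordered chain no coordinate-RMSD superposition is
meaningful.  Instead every conformer is transformed into the principal axes
system (PAS) of its mass-weighted inertia tensor (eigenvalues ordered
I_x <= I_y <= I_z), which superimposes conformers as compactly as possible.
A sign convention anchors the chain direction: if the first atom of the
N-terminal residue ends up at larger x or z than the last atom of the
C-terminal residue, a proper pi-rotation about a principal axis flips two
coordinate signs to bring the N-terminus to low x and z.

The superposed ensemble is rendered as a pseudo-electron density: per-atom
isotropic Gaussians with amplitude equal to the electron count are summed
per conformer and combined with the conformer weights on a regular grid.
The displayed isosurface encloses a prescribed fraction (default 99.9%) of
the total density.  An approximate electrostatic potential is mapped onto
the surface from fractional side-chain charges (Henderson-Hasselbalch at
the given pH) with Debye-Hueckel screening, q exp(-d/lambda_D)/d, where
lambda_D = 0.304/sqrt(I[M]) nm for ionic strength I (7.85 Angstrom at
150 mM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Conformer, Ensemble, electron_count

__all__ = [
    "inertia_tensor", "pas_transform", "PASTransform", "pas_ensemble",
    "ensemble_density", "DensityGrid", "debye_length",
    "surface_potential", "SurfacePotential", "assign_charges",
    "write_ccp4",
]

#: Gaussian widths of the pseudo-density kernels (Angstrom)
SIGMA_HEAVY = 1.0
SIGMA_H = 0.7

#: side-chain pKa values (standard solution values)
PKA = {"ASP": 3.65, "GLU": 4.25, "LYS": 10.53, "ARG": 12.48, "HIS": 6.08}

#: phosphorylated residues carrying a -2 phosphate charge
PHOSPHO = {"SEP", "TPO", "PTR"}


def inertia_tensor(conformer_or_coords, masses=None) -> np.ndarray:
    """Mass-weighted inertia tensor about the center of mass (Da Angstrom^2)."""
    if isinstance(conformer_or_coords, Conformer):
        coords = conformer_or_coords.positions
        masses = conformer_or_coords.mass
    else:
        coords = np.asarray(conformer_or_coords, dtype=float)
        masses = (np.ones(len(coords)) if masses is None
                  else np.asarray(masses, dtype=float))
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    r = coords - (masses[:, None] * coords).sum(0) / total
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = np.sum(masses * (y * y + z * z))
    iyy = np.sum(masses * (x * x + z * z))
    izz = np.sum(masses * (x * x + y * y))
    ixy = -np.sum(masses * x * y)
    ixz = -np.sum(masses * x * z)
    iyz = -np.sum(masses * y * z)
    return np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])


@dataclass
class PASTransform:
    rotation: np.ndarray     # proper rotation, det = +1
    translation: np.ndarray  # applied before rotation (minus center of mass)
    eigenvalues: np.ndarray  # I_x <= I_y <= I_z


# the three proper pi-rotations about the principal axes
_PI_ROTATIONS = (
    np.diag([1.0, -1.0, -1.0]),   # about x
    np.diag([-1.0, 1.0, -1.0]),   # about y (negates x and z)
    np.diag([-1.0, -1.0, 1.0]),   # about z
)


def pas_transform(conformer: Conformer) -> tuple[PASTransform, Conformer]:
    """Transform a conformer into the principal axes system of its inertia
    tensor, with the N-terminus oriented toward low x and z."""
    tensor = inertia_tensor(conformer)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    if evals[-1] > 0 and np.min(np.diff(evals)) < 1e-6 * evals[-1]:
        warnings.warn("near-degenerate inertia spectrum; PAS orientation "
                      "is numerically unstable")
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    masses = conformer.mass
    com = (masses[:, None] * conformer.positions).sum(0) / masses.sum()
    rot = evecs.T  # rows are principal axes; coords' = rot @ (coords - com)
    moved = conformer.transformed(rot, -rot @ com)

    # first/last atoms of the terminal residues in file order
    n_idx = int(np.nonzero(moved.residue_index
                           == moved.residue_index.min())[0][0])
    c_idx = int(np.nonzero(moved.residue_index
                           == moved.residue_index.max())[0][-1])
    xn, _, zn = moved.positions[n_idx]
    xc, _, zc = moved.positions[c_idx]
    if xn > xc or zn > zc:
        # choose among the proper pi-rotations the one minimizing x_N + z_N,
        # ties broken toward the rotation about y
        best = None
        for pref, flip in ((1, _PI_ROTATIONS[1]), (0, _PI_ROTATIONS[0]),
                           (2, _PI_ROTATIONS[2])):
            p = flip @ moved.positions[n_idx]
            score = p[0] + p[2]
            if best is None or score < best[0] - 1e-12:
                best = (score, flip)
        flip = best[1]
        rot = flip @ rot
        moved = moved.transformed(flip, np.zeros(3))
    return PASTransform(rot, -rot @ com, evals), moved


def pas_ensemble(ensemble: Ensemble) -> Ensemble:
    """PAS-transform every conformer (weights and labels preserved)."""
    moved = [pas_transform(c)[1] for c in ensemble.conformers]
    return Ensemble(moved, ensemble.weights.copy(), ensemble.sequence,
                    ensemble.label)


@dataclass
class DensityGrid:
    origin: np.ndarray
    spacing: float
    values: np.ndarray          # (nx, ny, nz), arbitrary density units
    isolevel: float = 0.0
    fraction: float = 0.999

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def enclosed_fraction(self, level: float | None = None) -> float:
        level = self.isolevel if level is None else level
        return float(self.values[self.values >= level].sum() / self.total)


def _isolevel_for_fraction(values: np.ndarray, fraction: float) -> float:
    flat = np.sort(values[values > 0].ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, fraction * flat.sum()))
    return float(flat[min(k, len(flat) - 1)])


def ensemble_density(ensemble: Ensemble, spacing: float = 1.0,
                     pad: float = 5.0, fraction: float = 0.999,
                     max_voxels: int = 200_000_000) -> DensityGrid:
    """Weighted pseudo-electron density of a PAS-superposed ensemble.

    Each atom contributes an isotropic Gaussian of amplitude equal to its
    electron count; voxel values integrate the kernel over the voxel volume,
    so the grid total approximates the ensemble's total electron count.
    """
    all_pos = np.vstack([c.positions for c in ensemble.conformers])
    lo = all_pos.min(0) - pad
    hi = all_pos.max(0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(
            f"grid of {np.prod(shape)} voxels exceeds the cap; increase "
            f"the spacing (currently {spacing} A)")
    values = np.zeros(tuple(shape))
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    cutoff = 4.0  # sigmas
    for conf, w in zip(ensemble.conformers, ensemble.weights):
        electrons = np.array([electron_count(e) for e in conf.element], float)
        sigmas = np.where([e.upper() == "H" for e in conf.element],
                          SIGMA_H, SIGMA_HEAVY)
        for pos, ne, sg in zip(conf.positions, electrons, sigmas):
            sl = []
            g1d = []
            for d in range(3):
                a = axes[d]
                i0 = int(np.searchsorted(a, pos[d] - cutoff * sg))
                i1 = int(np.searchsorted(a, pos[d] + cutoff * sg))
                sl.append(slice(i0, i1))
                x = a[i0:i1] - pos[d]
                g1d.append(np.exp(-0.5 * (x / sg) ** 2)
                           / (sg * np.sqrt(2 * np.pi)))
            kernel = (g1d[0][:, None, None] * g1d[1][None, :, None]
                      * g1d[2][None, None, :])
            values[sl[0], sl[1], sl[2]] += w * ne * kernel * spacing ** 3
    grid = DensityGrid(lo, spacing, values, fraction=fraction)
    grid.isolevel = _isolevel_for_fraction(values, fraction)
    return grid


def debye_length(ionic_strength_mM: float = 150.0) -> float:
    """Debye screening length in Angstrom (0.304/sqrt(I[M]) nm)."""
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive")
    return 10.0 * 0.304 / np.sqrt(ionic_strength_mM / 1000.0)


def _midpoint(conf: Conformer, sel: list[int]) -> np.ndarray:
    return conf.positions[sel].mean(axis=0)


def assign_charges(conf: Conformer, pH: float = 7.0,
                   include_termini: bool = False) -> list[tuple[np.ndarray, float]]:
    """Fractional side-chain point charges (position, charge in e).

    Asp/Glu carboxylates: -1/(1 + 10^(pKa - pH)) at the O-pair midpoint;
    Lys (NZ), Arg (NH1/NH2 midpoint), His (ND1/NE2 midpoint):
    +1/(1 + 10^(pH - pKa)); phosphorylated Ser/Thr/Tyr: -2 at the midpoint
    of the three terminal phosphate oxygens.  Charged residues with missing
    side-chain atoms are skipped with a warning.
    """
    sites = {
        "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
        "LYS": ("NZ",), "ARG": ("NH1", "NH2"), "HIS": ("ND1", "NE2"),
    }
    charges: list[tuple[np.ndarray, float]] = []
    numbers = conf.residue_numbers
    for num in numbers:
        mask = conf.residue_index == num
        resname = conf.residue_name[int(np.nonzero(mask)[0][0])].upper()
        names = {conf.atom_name[i]: i for i in np.nonzero(mask)[0]}
        if resname in PHOSPHO:
            oxy = [names[a] for a in ("O1P", "O2P", "O3P") if a in names]
            if len(oxy) < 3:
                oxy = [names[a] for a in ("OP1", "OP2", "OP3") if a in names]
            if len(oxy) == 3:
                charges.append((_midpoint(conf, oxy), -2.0))
            else:
                warnings.warn(f"residue {num} ({resname}): phosphate oxygens "
                              f"missing; charge skipped")
            continue
        if resname not in sites:
            continue
        atoms = sites[resname]
        if not all(a in names for a in atoms):
            warnings.warn(f"residue {num} ({resname}): side-chain atoms "
                          f"missing; charge skipped")
            continue
        pos = _midpoint(conf, [names[a] for a in atoms])
        pka = PKA[resname]
        if resname in ("ASP", "GLU"):
            q = -1.0 / (1.0 + 10.0 ** (pka - pH))
        else:
            q = 1.0 / (1.0 + 10.0 ** (pH - pka))
        charges.append((pos, q))
    return charges


@dataclass
class SurfacePotential:
    points: np.ndarray              # (V, 3) isosurface vertices
    potential: np.ndarray           # (V,) signed, arbitrary units
    charges: list = field(default_factory=list)


def _screened_potential(points: np.ndarray, charges, lam: float) -> np.ndarray:
    phi = np.zeros(len(points))
    for pos, q in charges:
        d = np.linalg.norm(points - pos, axis=1)
        d = np.maximum(d, 1e-6)
        phi += q * np.exp(-d / lam) / d
    return phi


def surface_potential(ensemble: Ensemble, grid: DensityGrid,
                      pH: float = 7.0, ionic_strength_mM: float = 150.0,
                      include_termini: bool = False) -> SurfacePotential:
    """Electrostatic potential on the density isosurface.

    Vertices come from marching cubes at the grid's isolevel; the
    Debye-Hueckel potential of each conformer's fractional charges is
    averaged with the conformer weights.
    """
    from skimage.measure import marching_cubes

    verts, _, _, _ = marching_cubes(grid.values, level=grid.isolevel)
    points = grid.origin + verts * grid.spacing
    lam = debye_length(ionic_strength_mM)
    phi = np.zeros(len(points))
    all_charges = []
    for conf, w in zip(ensemble.conformers, ensemble.weights):
        charges = assign_charges(conf, pH=pH, include_termini=include_termini)
        all_charges.append(charges)
        if charges:
            phi += w * _screened_potential(points, charges, lam)
    return SurfacePotential(points, phi, all_charges)


def write_ccp4(grid: DensityGrid, path) -> None:
    """Write the density as a CCP4/MRC map."""
    import gemmi

    ccp4 = gemmi.Ccp4Map()
    nx, ny, nz = grid.values.shape
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(
        grid.values, dtype=np.float32))
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * grid.spacing, ny * grid.spacing, nz * grid.spacing, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
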