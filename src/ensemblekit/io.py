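"""Reading, writing and reduction of weighted conformer ensembles.

An ensemble is a set of C atomistic conformers of one polypeptide together
with a normalized weight vector w (w_c >= 0, sum w_c = 1).  On disk this is a
multi-model PDB file (MODEL/ENDMDL records, as deposited e.g. in the Protein
Ensemble Database) plus an optional plain-text sidecar file with one weight
per model.  All analyses consume either the reduced C-alpha trace or the
backbone dihedral angles (phi, psi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: maximum C(i)-N(i+1) peptide-bond length; larger gaps are chain breaks
CHAIN_BREAK_CUTOFF = 2.5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common phosphorylated residues keep their parent letter
    "SEP": "S", "TPO": "T", "PTR": "Y",
}


def three_to_one(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), "X")


def atomic_mass(element: str) -> float:
    """Standard atomic mass (Da) of an element symbol."""
    el = gemmi.Element(element)
    if el.name == "X" or el.weight <= 0:
        raise ValueError(f"unknown element {element!r}")
    return el.weight


def electron_count(element: str) -> int:
    el = gemmi.Element(element)
    if el.name == "X":
        raise ValueError(f"unknown element {element!r}")
    return el.atomic_number


@dataclass
class AtomRecord:
    """One atom: residue bookkeeping, element, mass (Da) and position (Angstrom)."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    mass: float
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for atom {self.atom_name}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")


class Conformer:
    """One atomistic structure, stored as parallel per-atom arrays."""

    def __init__(self, residue_index, residue_name, atom_name, element,
                 mass, positions):
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.residue_name = list(residue_name)
        self.atom_name = list(atom_name)
        self.element = list(element)
        self.mass = np.asarray(mass, dtype=float)
        self.positions = np.asarray(positions, dtype=float)
        n = len(self.residue_index)
        if not (len(self.residue_name) == len(self.atom_name)
                == len(self.element) == len(self.mass)
                == self.positions.shape[0] == n):
            raise ValueError("inconsistent per-atom array lengths")

    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord]) -> "Conformer":
        return cls(
            [a.residue_index for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            [a.mass for a in atoms],
            np.array([a.position for a in atoms], dtype=float),
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(int(self.residue_index[i]), self.residue_name[i],
                       self.atom_name[i], self.element[i],
                       float(self.mass[i]), self.positions[i])
            for i in range(len(self.residue_index))
        ]

    @property
    def residue_numbers(self) -> np.ndarray:
        """Author residue numbers in chain order (unique, order preserved)."""
        _, idx = np.unique(self.residue_index, return_index=True)
        return self.residue_index[np.sort(idx)]

    @property
    def residue_count(self) -> int:
        return len(self.residue_numbers)

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        """Positional index of a named atom in a residue; -1 if absent."""
        hits = np.nonzero(self.residue_index == residue_number)[0]
        for i in hits:
            if self.atom_name[i] == atom_name:
                return int(i)
        return -1

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return Conformer(self.residue_index, self.residue_name, self.atom_name,
                         self.element, self.mass, pos)


@dataclass
class Ensemble:
    """C weighted conformers of one sequence."""

    conformers: list[Conformer]
    weights: np.ndarray
    sequence: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.conformers) < 1:
            raise ValueError("ensemble needs at least one conformer")
        if len(self.weights) != len(self.conformers):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.conformers)} conformers")
        if np.any(self.weights < 0):
            raise ValueError("negative conformer weight")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("conformer weights sum to zero")
        self.weights = self.weights / total
        if not self.sequence:
            first = self.conformers[0]
            seen: dict[int, str] = {}
            for num, name in zip(first.residue_index, first.residue_name):
                seen.setdefault(int(num), three_to_one(name))
            self.sequence = "".join(seen[k] for k in sorted(seen))

    @property
    def size(self) -> int:
        return len(self.conformers)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.conformers[0].residue_numbers

    @property
    def residue_count(self) -> int:
        return self.conformers[0].residue_count


@dataclass
class CATrace:
    """C-alpha coordinates of all conformers: (C, N, 3) array plus weights."""

    coordinates: np.ndarray
    weights: np.ndarray
    residue_numbers: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (C, N, 3)")
        if self.coordinates.shape[0] != len(self.weights):
            raise ValueError("weights inconsistent with coordinates")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, self.coordinates.shape[1] + 1)

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class DihedralSet:
    """Backbone dihedrals in radians, NaN where undefined (termini, breaks)."""

    phi: np.ndarray
    psi: np.ndarray
    weights: np.ndarray
    residue_numbers: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi shapes differ")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, self.phi.shape[1] + 1)


# ---------------------------------------------------------------------------
# PDB input / output


def read_weights(path) -> np.ndarray:
    """Whitespace-separated weights, '#' comments allowed."""
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            values.extend(float(tok) for tok in line.split())
    return np.asarray(values, dtype=float)


def write_weights(weights, path) -> None:
    Path(path).write_text(
        "# conformer weights, one per model\n"
        + "\n".join(f"{w:.12g}" for w in np.asarray(weights)) + "\n")


def _conformer_from_model(model, include_ligands: bool) -> Conformer:
    res_idx, res_name, at_name, element, mass, pos = [], [], [], [], [], []
    dropped_altloc = 0
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and not include_ligands:
                continue
            if residue.is_water():
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    dropped_altloc += 1
                    continue
                res_idx.append(residue.seqid.num)
                res_name.append(residue.name)
                at_name.append(atom.name)
                element.append(atom.element.name)
                mass.append(atomic_mass(atom.element.name))
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if dropped_altloc:
        warnings.warn(f"dropped {dropped_altloc} alternate-location atoms")
    if not res_idx:
        raise ValueError("model contains no usable atoms")
    return Conformer(res_idx, res_name, at_name, element, mass, np.array(pos))


def read_ensemble(path, weights_path=None, label: str = "",
                  include_ligands: bool = False) -> Ensemble:
    """Read a (multi-model) PDB or mmCIF file as a weighted ensemble.

    Weights come from the sidecar file (one non-negative number per model,
    normalized on load) or default to uniform 1/C.
    """
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")
    conformers = [_conformer_from_model(m, include_ligands) for m in structure]
    n0 = len(conformers[0].residue_index)
    for i, conf in enumerate(conformers[1:], start=2):
        if len(conf.residue_index) != n0:
            raise ValueError(
                f"{path}: model {i} has {len(conf.residue_index)} atoms, "
                f"model 1 has {n0}")
    if weights_path is not None:
        weights = read_weights(weights_path)
        if len(weights) != len(conformers):
            raise ValueError(
                f"{len(weights)} weights for {len(conformers)} models")
    else:
        weights = np.full(len(conformers), 1.0 / len(conformers))
    return Ensemble(conformers, weights, label=label or Path(path).stem)


def write_ensemble(ensemble: Ensemble, path, weights_path=None) -> None:
    """Write a multi-model PDB; optionally a weights sidecar next to it."""
    structure = gemmi.Structure()
    structure.name = ensemble.label or "ensemble"
    for conf in ensemble.conformers:
        model = gemmi.Model(len(structure) + 1)
        chain = gemmi.Chain("A")
        current_num = None
        residue = None
        for i in range(len(conf.residue_index)):
            num = int(conf.residue_index[i])
            if num != current_num:
                residue = gemmi.Residue()
                residue.name = conf.residue_name[i]
                residue.seqid = gemmi.SeqId(num, " ")
                chain.add_residue(residue)
                residue = chain[-1]
                current_num = num
            atom = gemmi.Atom()
            atom.name = conf.atom_name[i]
            atom.element = gemmi.Element(conf.element[i])
            x, y, z = conf.positions[i]
            atom.pos = gemmi.Position(x, y, z)
            residue.add_atom(atom)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
    if weights_path is not None:
        write_weights(ensemble.weights, weights_path)


# ---------------------------------------------------------------------------
# Reduced representations


def ca_trace(ensemble: Ensemble) -> CATrace:
    """Extract the (C, N, 3) C-alpha trace, preserving conformer weights."""
    numbers = ensemble.residue_numbers
    row_of = {int(n): j for j, n in enumerate(numbers)}
    coords = np.empty((ensemble.size, len(numbers), 3))
    for c, conf in enumerate(ensemble.conformers):
        is_ca = np.asarray(conf.atom_name) == "CA"
        filled = np.zeros(len(numbers), dtype=bool)
        for r, p in zip(conf.residue_index[is_ca], conf.positions[is_ca]):
            j = row_of[int(r)]
            coords[c, j] = p
            filled[j] = True
        if not filled.all():
            missing = numbers[~filled][0]
            raise ValueError(f"residue {missing} has no CA atom "
                             f"(conformer {c + 1})")
    return CATrace(coords, ensemble.weights.copy(), numbers.copy())


def _dihedral(p0, p1, p2, p3):
    """Signed torsion angle (IUPAC convention) of four points, radians."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def backbone_dihedrals(ensemble: Ensemble) -> DihedralSet:
    """Compute phi/psi for every conformer.

    phi_i = C(i-1)-N(i)-CA(i)-C(i); psi_i = N(i)-CA(i)-C(i)-N(i+1).
    Undefined entries (chain termini, peptide bonds longer than
    ``CHAIN_BREAK_CUTOFF``) are NaN.
    """
    numbers = ensemble.residue_numbers
    nres = len(numbers)
    C = ensemble.size
    phi = np.full((C, nres), np.nan)
    psi = np.full((C, nres), np.nan)
    n_breaks = 0
    sorter = np.argsort(numbers, kind="stable")
    for c, conf in enumerate(ensemble.conformers):
        bb = np.full((nres, 3, 3), np.nan)  # N, CA, C positions per residue
        names = np.asarray(conf.atom_name)
        for k, name in enumerate(("N", "CA", "C")):
            sel = names == name
            rows = sorter[np.searchsorted(numbers[sorter],
                                          conf.residue_index[sel])]
            bb[rows, k] = conf.positions[sel]
            if len(rows) < nres or np.isnan(bb[:, k, 0]).any():
                missing = numbers[np.isnan(bb[:, k, 0])][0]
                raise ValueError(
                    f"residue {missing} lacks backbone atom {name}")
        # peptide-bond continuity C(i) -> N(i+1)
        gaps = np.linalg.norm(bb[1:, 0] - bb[:-1, 2], axis=1)
        intact = gaps <= CHAIN_BREAK_CUTOFF
        n_breaks += int(np.sum(~intact))
        phi_c = _dihedral(bb[:-1, 2], bb[1:, 0], bb[1:, 1], bb[1:, 2])
        psi_c = _dihedral(bb[:-1, 0], bb[:-1, 1], bb[:-1, 2], bb[1:, 0])
        phi[c, 1:] = np.where(intact, phi_c, np.nan)
        psi[c, :-1] = np.where(intact, psi_c, np.nan)
    if n_breaks:
        logger.warning("%d chain break(s) detected; spanning dihedrals "
                       "flagged undefined", n_breaks)
    return DihedralSet(phi, psi, ensemble.weights.copy(), numbers.copy())
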