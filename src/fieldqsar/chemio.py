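"""Molecule and activity I/O, atomic parameters, and potency conversion.

Molecules are held in a light container (:class:`Molecule`) that keeps,
per atom, everything the downstream field calculations need: 3D
coordinates, a Gasteiger partial charge, a van-der-Waals radius and
Lennard-Jones well depth from a fixed element table, a Crippen-type
atomic hydrophobicity contribution, and hydrogen-bond donor/acceptor
flags.  RDKit does the heavy lifting for file parsing, charge
assignment, aromaticity perception and the Crippen contribution table;
the container itself is deliberately independent of RDKit so synthetic
molecules with hand-placed atoms can flow through the same pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = [
    "Atom",
    "Molecule",
    "MoleculeSet",
    "ActivityRecord",
    "VDW_TABLE",
    "read_molecules",
    "write_molecules",
    "read_activities",
    "write_activities",
    "assign_partial_charges",
    "assign_field_params",
    "compute_logp",
    "pic50_from_ic50",
    "from_rdkit",
    "to_rdkit",
]

# Van der Waals radius (Å, Bondi) and Lennard-Jones well depth
# (kcal/mol, OPLS/AMBER-like magnitudes).  Unknown elements are a hard
# error rather than a silent default.
VDW_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.030),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.344),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}

Endpoint = Literal["I", "II"]
SetLabel = Literal["train", "test"]


@dataclass
class Atom:
    """A single atom with the per-atom properties used by the lattice fields.

    ``hydrophobic_w`` is the atomic hydrophobicity contribution (Crippen
    atomic logP term); the donor/acceptor flags feed both the CoMSIA
    indicator fields and pharmacophore perception.
    """

    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    lj_epsilon: float = 0.0
    hydrophobic_w: float = 0.0
    is_hbd: bool = False
    is_hba: bool = False
    is_aromatic: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom coordinates must be a finite 3-vector, got {self.coords}")


@dataclass
class Molecule:
    """An identified molecule: atoms, bonds, optional extra conformers.

    ``bonds`` are (i, j, order) with order 1.5 marking aromatic bonds.
    ``conformers`` hold alternative coordinate sets (n_atoms, 3); the
    coordinates stored on the atoms themselves are the primary
    conformer.  ``properties`` carries SDF data fields (activities,
    ClogP, ...).
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    conformers: list[np.ndarray] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)
    rdkit_mol: Chem.Mol | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id}: bond index ({i},{j}) out of range")
        for k, conf in enumerate(self.conformers):
            conf = np.asarray(conf, dtype=float)
            if conf.shape != (n, 3):
                raise ValueError(f"molecule {self.id}: conformer {k} has shape {conf.shape}")
            self.conformers[k] = conf

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, xyz):
            a.coords = row.copy()

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[
                Atom(
                    a.element,
                    a.coords.copy(),
                    a.partial_charge,
                    a.vdw_radius,
                    a.lj_epsilon,
                    a.hydrophobic_w,
                    a.is_hbd,
                    a.is_hba,
                    a.is_aromatic,
                    a.formal_charge,
                )
                for a in self.atoms
            ],
            bonds=list(self.bonds),
            conformers=[c.copy() for c in self.conformers],
            properties=dict(self.properties),
            rdkit_mol=self.rdkit_mol,
        )

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out


class MoleculeSet:
    """An ordered collection of molecules with unique ids."""

    def __init__(self, molecules: Iterable[Molecule]):
        self.molecules: list[Molecule] = list(molecules)
        seen: set[str] = set()
        for m in self.molecules:
            if m.id in seen:
                raise ValueError(f"duplicate molecule id {m.id!r}")
            seen.add(m.id)
        self._by_id = {m.id: m for m in self.molecules}

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, key: int | str) -> Molecule:
        if isinstance(key, str):
            return self._by_id[key]
        return self.molecules[key]

    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._by_id


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    endpoint: Endpoint
    pic50: float
    set_label: SetLabel

    def __post_init__(self) -> None:
        if self.endpoint not in ("I", "II"):
            raise ValueError(f"endpoint must be 'I' or 'II', got {self.endpoint!r}")
        if self.set_label not in ("train", "test"):
            raise ValueError(f"set_label must be 'train' or 'test', got {self.set_label!r}")
        if not math.isfinite(self.pic50):
            raise ValueError(f"pic50 must be finite for compound {self.compound_id!r}")


# ---------------------------------------------------------------------------
# RDKit conversion


def from_rdkit(rdmol: Chem.Mol, mol_id: str | None = None) -> Molecule:
    """Convert an RDKit mol (with a 3D conformer) into a :class:`Molecule`."""
    if rdmol.GetNumConformers() == 0:
        raise ValueError("RDKit molecule has no conformer (3D coordinates required)")
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                is_aromatic=a.GetIsAromatic(),
                formal_charge=a.GetFormalCharge(),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = mol_id
    if name is None:
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    props = {k: rdmol.GetProp(k) for k in rdmol.GetPropNames()}
    return Molecule(id=name, atoms=atoms, bonds=bonds, properties=props, rdkit_mol=rdmol)


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Build a sanitized RDKit mol from a :class:`Molecule`.

    Used for writing SDF and for substructure queries when no source
    RDKit molecule is attached.
    """
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j, order in mol.bonds:
        if order == 1.5:
            bt = Chem.BondType.AROMATIC
        elif order == 2:
            bt = Chem.BondType.DOUBLE
        elif order == 3:
            bt = Chem.BondType.TRIPLE
        else:
            bt = Chem.BondType.SINGLE
        rw.AddBond(i, j, bt)
    m = rw.GetMol()
    conf = Chem.Conformer(mol.n_atoms)
    for idx, a in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, tuple(float(x) for x in a.coords))
    m.AddConformer(conf)
    Chem.SanitizeMol(m)
    m.SetProp("_Name", mol.id)
    for k, v in mol.properties.items():
        m.SetProp(k, str(v))
    return m


# ---------------------------------------------------------------------------
# File I/O


def read_molecules(path: str | Path, fmt: Literal["sdf", "mol2"] = "sdf") -> MoleculeSet:
    """Read an SDF (V2000) or MOL2 file into a :class:`MoleculeSet`.

    Hydrogens are kept as present in the file; the title line provides
    the compound id and SDF data fields are copied into ``properties``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mols: list[Molecule] = []
    if fmt == "sdf":
        if not path.read_text().strip():
            raise ValueError(f"empty SDF file: {path}")
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        any_record = False
        for idx, rdmol in enumerate(supplier):
            any_record = True
            if rdmol is None:
                raise ValueError(f"unparsable SDF record at index {idx} in {path}")
            mols.append(from_rdkit(rdmol))
        if not any_record:
            raise ValueError(f"empty SDF file: {path}")
    elif fmt == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
        if not blocks:
            raise ValueError(f"no TRIPOS MOLECULE records in {path}")
        for idx, block in enumerate(blocks):
            rdmol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if rdmol is None:
                raise ValueError(f"unparsable MOL2 record at index {idx} in {path}")
            mols.append(from_rdkit(rdmol))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for i, m in enumerate(mols):
        if not m.id:
            m.id = f"mol_{i}"
    return MoleculeSet(mols)


def write_molecules(mols: MoleculeSet | Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to a V2000 SDF with properties as data fields."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for m in mols:
            rdmol = m.rdkit_mol
            if rdmol is None or rdmol.GetNumAtoms() != m.n_atoms:
                rdmol = to_rdkit(m)
            else:
                rdmol = Chem.Mol(rdmol)
                conf = rdmol.GetConformer()
                for idx, a in enumerate(m.atoms):
                    conf.SetAtomPosition(idx, tuple(float(x) for x in a.coords))
                rdmol.SetProp("_Name", m.id)
                for k, v in m.properties.items():
                    rdmol.SetProp(k, str(v))
            writer.write(rdmol)
    finally:
        writer.close()


_ACTIVITY_COLUMNS = ["compound_id", "endpoint", "pic50", "set_label"]


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table (CSV: compound_id, endpoint, pic50, set_label)."""
    df = pd.read_csv(path, dtype={"compound_id": str, "endpoint": str, "set_label": str})
    missing = [c for c in _ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity CSV missing columns: {missing}")
    pic50 = pd.to_numeric(df["pic50"], errors="coerce")
    if pic50.isna().any():
        bad = df.loc[pic50.isna(), "compound_id"].tolist()
        raise ValueError(f"non-numeric pic50 for compounds: {bad}")
    records = [
        ActivityRecord(row.compound_id, row.endpoint, float(p), row.set_label)
        for row, p in zip(df.itertuples(index=False), pic50)
    ]
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.compound_id, r.endpoint)
        if key in seen:
            raise ValueError(f"duplicate activity record for {key}")
        seen.add(key)
    return records


def write_activities(records: Iterable[ActivityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.compound_id, r.endpoint, r.pic50, r.set_label) for r in records],
        columns=_ACTIVITY_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Atomic parameter assignment


def assign_partial_charges(mol: Molecule, method: Literal["gasteiger"] = "gasteiger") -> Molecule:
    """Assign iterative Gasteiger partial charges (in place; also returned).

    Requires explicit hydrogens so that the charge on each heavy atom is
    not folded into implicit neighbours.  The sum of partial charges
    equals the sum of formal charges to numerical precision.
    """
    if method != "gasteiger":
        raise ValueError(f"unsupported charge method {method!r}")
    rdmol = mol.rdkit_mol
    if rdmol is None:
        rdmol = to_rdkit(mol)
        mol.rdkit_mol = rdmol
    for a in rdmol.GetAtoms():
        if a.GetSymbol() not in VDW_TABLE:
            raise ValueError(f"element {a.GetSymbol()!r} not supported for charge assignment")
    AllChem.ComputeGasteigerCharges(rdmol)
    for atom, ratom in zip(mol.atoms, rdmol.GetAtoms()):
        q = float(ratom.GetProp("_GasteigerCharge"))
        if not math.isfinite(q):
            raise ValueError(f"non-finite Gasteiger charge in molecule {mol.id}")
        atom.partial_charge = q
        atom.is_aromatic = ratom.GetIsAromatic()
        atom.formal_charge = ratom.GetFormalCharge()
    return mol


def _bonded_h_count(mol: Molecule, idx: int) -> int:
    return sum(1 for j in mol.neighbors(idx) if mol.atoms[j].element == "H")


def assign_field_params(mol: Molecule) -> Molecule:
    """Assign vdW/LJ parameters, hydrophobic contributions, and HBD/HBA flags.

    Donor rule: N or O bearing at least one hydrogen.  Acceptor rule:
    N or O with non-positive formal charge (so quaternary/protonated
    nitrogens are excluded).
    """
    for atom in mol.atoms:
        if atom.element not in VDW_TABLE:
            raise ValueError(f"element {atom.element!r} has no vdW/LJ parameters")
    rdmol = mol.rdkit_mol
    if rdmol is None:
        rdmol = to_rdkit(mol)
        mol.rdkit_mol = rdmol
    contribs = rdMolDescriptors._CalcCrippenContribs(rdmol)
    for idx, atom in enumerate(mol.atoms):
        atom.vdw_radius, atom.lj_epsilon = VDW_TABLE[atom.element]
        atom.hydrophobic_w = float(contribs[idx][0])
        if atom.element in ("N", "O"):
            atom.is_hbd = _bonded_h_count(mol, idx) >= 1
            atom.is_hba = atom.formal_charge <= 0
        else:
            atom.is_hbd = False
            atom.is_hba = False
    return mol


def compute_logp(mol: Molecule) -> float:
    """Atomic-contribution (Crippen) logP estimate; stored as property 'ClogP'.

    Additive over atoms, so disconnected duplicates double the value.
    """
    if mol.n_atoms == 0:
        raise ValueError("cannot compute logP of an empty molecule")
    logp = float(sum(a.hydrophobic_w for a in mol.atoms))
    mol.properties["ClogP"] = repr(logp)
    return logp


def pic50_from_ic50(ic50: float) -> float:
    """Convert a molar IC50 to pIC50 = -log10(IC50)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50)
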