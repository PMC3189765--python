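"""Common-scaffold detection and rigid least-squares superposition.

Every molecule of a congeneric series is mapped onto a template through
a shared substructure (SMARTS query) and superposed by the closed-form
Kabsch solution (SVD with reflection correction), so that all compounds
live in one frame before lattice fields are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from fieldqsar.chemio import Molecule, MoleculeSet, to_rdkit

__all__ = ["ScaffoldMapping", "find_scaffold_mapping", "superpose", "align_series", "kabsch"]


@dataclass(frozen=True)
class ScaffoldMapping:
    """Paired atom indices (template vs molecule) plus the fitted RMSD."""

    template_atoms: tuple[int, ...]
    molecule_atoms: tuple[int, ...]
    rmsd: float

    def __post_init__(self) -> None:
        if len(self.template_atoms) != len(self.molecule_atoms):
            raise ValueError("mapping lists must have equal length")
        if len(self.template_atoms) < 3:
            raise ValueError("mapping must contain at least 3 atom pairs")
        if len(set(self.template_atoms)) != len(self.template_atoms):
            raise ValueError("duplicate template atom in mapping")
        if len(set(self.molecule_atoms)) != len(self.molecule_atoms):
            raise ValueError("duplicate molecule atom in mapping")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q (rotation + translation).

    Returns ``(R, t, rmsd)`` with ``P @ R.T + t ≈ Q`` and ``det(R) = +1``
    (proper rotation, no reflection).  Raises on fewer than 3 points or
    a degenerate (collinear) reference geometry.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise ValueError("degenerate geometry: mapped atoms are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def _query_from_pattern(pattern: str) -> Chem.Mol:
    q = Chem.MolFromSmarts(pattern)
    if q is None:
        raise ValueError(f"invalid substructure pattern {pattern!r}")
    return q


def _rdkit_of(mol: Molecule) -> Chem.Mol:
    if mol.rdkit_mol is not None and mol.rdkit_mol.GetNumAtoms() == mol.n_atoms:
        return mol.rdkit_mol
    return to_rdkit(mol)


def find_scaffold_mapping(mol: Molecule, template: Molecule, scaffold_pattern: str) -> ScaffoldMapping:
    """Locate the shared scaffold and pair template/molecule atoms.

    The pattern must match the template exactly once (up to atom
    permutation); among multiple matches in the molecule the one giving
    the lowest post-superposition RMSD wins, ties broken by the lowest
    lexicographic atom-index sequence.
    """
    query = _query_from_pattern(scaffold_pattern)
    t_matches = _rdkit_of(template).GetSubstructMatches(query, uniquify=True)
    if len(t_matches) == 0:
        raise ValueError("scaffold pattern does not match the template")
    if len(t_matches) > 1:
        raise ValueError("ambiguous scaffold match in template")
    t_idx = t_matches[0]
    m_matches = _rdkit_of(mol).GetSubstructMatches(query, uniquify=False, maxMatches=5000)
    if len(m_matches) == 0:
        raise ValueError(f"scaffold absent from molecule {mol.id!r}")
    t_coords = template.coords[list(t_idx)]
    best: tuple[float, tuple[int, ...]] | None = None
    for match in sorted(set(m_matches)):
        m_coords = mol.coords[list(match)]
        try:
            _, _, rmsd = kabsch(m_coords, t_coords)
        except ValueError:
            continue
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, match)
    if best is None:
        raise ValueError(f"no non-degenerate scaffold match in molecule {mol.id!r}")
    return ScaffoldMapping(template_atoms=tuple(t_idx), molecule_atoms=best[1], rmsd=best[0])


def superpose(
    mol: Molecule, template: Molecule, mapping: ScaffoldMapping
) -> tuple[Molecule, float]:
    """Rigidly transform all atoms of ``mol`` onto the template frame.

    The rotation/translation is fitted over the mapped atoms only; the
    returned RMSD is over those atoms.
    """
    for idx in mapping.molecule_atoms:
        if not 0 <= idx < mol.n_atoms:
            raise ValueError("mapping refers to an atom outside the molecule")
    for idx in mapping.template_atoms:
        if not 0 <= idx < template.n_atoms:
            raise ValueError("mapping refers to an atom outside the template")
    P = mol.coords[list(mapping.molecule_atoms)]
    Q = template.coords[list(mapping.template_atoms)]
    R, t, rmsd = kabsch(P, Q)
    aligned = mol.copy()
    aligned.set_coords(mol.coords @ R.T + t)
    aligned.conformers = [c @ R.T + t for c in mol.conformers]
    return aligned, rmsd


def align_series(
    mols: MoleculeSet, template_id: str, scaffold_pattern: str
) -> tuple[MoleculeSet, dict[str, float]]:
    """Superpose every molecule of the series onto the template.

    Returns the aligned set (template included, untouched) and a map of
    per-molecule scaffold RMSDs.
    """
    if template_id not in mols:
        raise ValueError(f"template {template_id!r} not in the molecule set")
    template = mols[template_id]
    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for m in mols:
        if m.id == template_id:
            aligned.append(m.copy())
            rmsds[m.id] = 0.0
            continue
        mapping = find_scaffold_mapping(m, template, scaffold_pattern)
        am, rmsd = superpose(m, template, mapping)
        aligned.append(am)
        rmsds[m.id] = rmsd
    return MoleculeSet(aligned), rmsds
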