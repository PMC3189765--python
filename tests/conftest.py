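"""Shared fixtures: small embedded molecules and matrix wrappers."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from fieldqsar.chemio import (
    Molecule,
    assign_field_params,
    assign_partial_charges,
    compute_logp,
    from_rdkit,
)
from fieldqsar.fields import FieldGrid
from fieldqsar.qsar_pls import DescriptorMatrix, assemble_descriptors
from fieldqsar.synthetic import SyntheticSpec, make_congeneric_series


def mol_from_smiles(smiles: str, mol_id: str = "mol", seed: int = 42) -> Molecule:
    """Embed a SMILES in 3D and convert, with charges and field params."""
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    m = Chem.AddHs(m)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(m, params) == 0, smiles
    mol = from_rdkit(m, mol_id=mol_id)
    assign_partial_charges(mol)
    assign_field_params(mol)
    compute_logp(mol)
    return mol


def dm_from_matrix(X: np.ndarray, sigma_min: float = 0.0) -> DescriptorMatrix:
    """Wrap a plain matrix as a one-field descriptor matrix (no filtering)."""
    X = np.asarray(X, dtype=float)
    grids = [
        FieldGrid(f"row_{i}", "comsia_steric", X[i]) for i in range(X.shape[0])
    ]
    return assemble_descriptors(grids, sigma_min=sigma_min)


@pytest.fixture(scope="session")
def small_series():
    """A 12-compound pre-aligned synthetic congeneric series."""
    return make_congeneric_series(SyntheticSpec(n_compounds=12, seed=5))


@pytest.fixture(scope="session")
def water():
    return mol_from_smiles("O", "water")


@pytest.fixture(scope="session")
def benzene():
    return mol_from_smiles("c1ccccc1", "benzene")
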