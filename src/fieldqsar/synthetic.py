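"""Synthetic congeneric series with planted structure-activity signal.

Because field-based 3D-QSAR needs a series sharing one rigid scaffold,
the generator builds carbazole-like tricycles decorated with 1-3 small
substituents at three ring positions, embeds each compound with seeded
distance geometry, and snaps every scaffold atom onto the template
coordinates so the series is pre-aligned by construction.

Activities are planted as a linear combination of the compounds' own
lattice-field values at a small set of high-variance cells, plus
Gaussian noise — so a PLS model fitted downstream has a known ground
truth to recover.  A second endpoint is derived from the first with an
analytically calibrated noise admixture reproducing a chosen expected
squared correlation between the two assays.

A separate helper plants rigid dummy molecules carrying an exact set of
pharmacophore features (with hand-assigned charges and donor/acceptor
flags) for testing the common-feature search.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from fieldqsar.alignment import find_scaffold_mapping, superpose
from fieldqsar.chemio import (
    ActivityRecord,
    Atom,
    Molecule,
    MoleculeSet,
    assign_field_params,
    assign_partial_charges,
    compute_logp,
    from_rdkit,
    write_activities,
    write_molecules,
)
from fieldqsar.fields import Lattice, ProbeSpec, build_lattice, comfa_fields
from fieldqsar.qsar_pls import split_train_test

__all__ = [
    "SCAFFOLD_TEMPLATE",
    "SCAFFOLD_QUERY",
    "DEFAULT_SUBSTITUENTS",
    "SyntheticSpec",
    "make_congeneric_series",
    "plant_activities",
    "plant_endpoint_pair",
    "generate_benchmark",
    "evaluate_recovery",
    "make_planted_pharmacophore_set",
]

# rigid fused tricycle with three substituent positions
SCAFFOLD_TEMPLATE = "c1cc({R1})c2c(c1)[nH]c1cc({R2})c({R3})cc21"
SCAFFOLD_QUERY = "c1ccc2c(c1)[nH]c1ccccc12"

DEFAULT_SUBSTITUENTS = (
    "F",
    "Cl",
    "Br",
    "C",
    "O",
    "OC",
    "C(F)(F)F",
    "C#N",
    "N",
    "C#C",
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic congeneric series.

    ``noise_sd`` is in pIC50 units; ``endpoint_r2`` is the expected
    squared correlation between the two endpoints (the dual-assay
    coupling observed for this antagonist class is about 0.39).
    ``planted_cells`` may pin the signal-carrying lattice cells as
    (field, flat index, weight) triples; by default they are drawn from
    the highest-variance cells.
    """

    n_compounds: int = 75
    substituent_library: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    planted_cells: tuple[tuple[str, int, float], ...] | None = None
    n_regions_per_field: int = 2
    noise_sd: float = 0.2
    endpoint_r2: float = 0.39
    seed: int = 0
    activity_mean: float = 7.0
    activity_sd: float = 1.0
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_compounds < 8:
            raise ValueError("n_compounds must be at least 8")
        if not 0.0 <= self.endpoint_r2 <= 1.0:
            raise ValueError("endpoint_r2 must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.substituent_library:
            raise ValueError("substituent library is empty")


def _embed(smiles: str, seed: int) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"invalid generated SMILES {smiles!r}")
    m = Chem.AddHs(m)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(m, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(m, params) != 0:
            raise ValueError(f"3D embedding failed for {smiles!r}")
    return m


def make_congeneric_series(spec: SyntheticSpec) -> MoleculeSet:
    """Generate the pre-aligned series with charges and field parameters.

    Every molecule carries the identical scaffold at identical
    coordinates; substituent positions and identities are drawn with a
    generator seeded from ``spec.seed``, so the output is a pure
    function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    # template: the bare scaffold, embedded deterministically
    template_seed = int(rng.integers(1, 2**31 - 1))
    tmpl_rd = _embed(SCAFFOLD_TEMPLATE.format(R1="[H]", R2="[H]", R3="[H]"), template_seed)
    template = from_rdkit(tmpl_rd, mol_id="template")
    assign_partial_charges(template)
    assign_field_params(template)
    scaffold_coords: np.ndarray | None = None

    mols: list[Molecule] = []
    width = len(str(spec.n_compounds))
    for k in range(spec.n_compounds):
        n_sub = int(rng.integers(1, 4))  # 1-3 substituted positions
        positions = rng.choice(3, size=n_sub, replace=False)
        subs = ["[H]", "[H]", "[H]"]
        for p in positions:
            subs[p] = str(spec.substituent_library[rng.integers(len(spec.substituent_library))])
        smiles = SCAFFOLD_TEMPLATE.format(R1=subs[0], R2=subs[1], R3=subs[2])
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol = from_rdkit(_embed(smiles, embed_seed), mol_id=f"cpd_{k + 1:0{width}d}")
        assign_partial_charges(mol)
        assign_field_params(mol)
        compute_logp(mol)
        mapping = find_scaffold_mapping(mol, template, SCAFFOLD_QUERY)
        aligned, _ = superpose(mol, template, mapping)
        # snap scaffold atoms exactly onto the template scaffold frame
        xyz = aligned.coords
        if scaffold_coords is None:
            scaffold_coords = template.coords[list(mapping.template_atoms)]
        xyz[list(mapping.molecule_atoms)] = scaffold_coords
        aligned.set_coords(xyz)
        mols.append(aligned)
    return MoleculeSet(mols)


def plant_endpoint_pair(
    y1: np.ndarray, endpoint_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """Second endpoint as y1 plus calibrated noise.

    With eta ~ N(0, 1) and s = sd(y1) * sqrt(1/r2 - 1), the expected
    squared correlation of (y1, y1 + s*eta) equals r2; the realized
    value fluctuates with sample size and is checked, not forced.
    """
    y1 = np.asarray(y1, dtype=float)
    if not 0.0 <= endpoint_r2 <= 1.0:
        raise ValueError("endpoint_r2 must lie in [0, 1]")
    sd1 = float(y1.std())
    if endpoint_r2 == 0.0:
        return float(y1.mean()) + sd1 * rng.standard_normal(y1.size)
    if endpoint_r2 == 1.0:
        return y1.copy()
    s = sd1 * np.sqrt(1.0 / endpoint_r2 - 1.0)
    return y1 + s * rng.standard_normal(y1.size)


def plant_activities(
    mols: MoleculeSet, lattice: Lattice, spec: SyntheticSpec
) -> tuple[list[ActivityRecord], dict]:
    """Plant two activity endpoints linear in local field values.

    Endpoint I is an affine function of the CoMFA field values at the
    planted cells plus N(0, noise_sd²) noise, rescaled to the requested
    activity mean/sd; endpoint II adds the calibrated correlation
    noise.  Returns the records (both endpoints, stratified train/test
    labels) and a truth dictionary with the planted weights on the
    rescaled activity scale, the noise draws and the lattice geometry.
    """
    rng = np.random.default_rng(spec.seed + 1)
    probe = ProbeSpec()
    steric_cols = []
    elec_cols = []
    clash_cols = []
    for m in mols:
        s, e = comfa_fields(m, lattice, probe)
        steric_cols.append(s.values)
        elec_cols.append(e.values)
        clash_cols.append(e.clash_mask)
    X = {"comfa_steric": np.vstack(steric_cols), "comfa_elec": np.vstack(elec_cols)}
    clash = np.vstack(clash_cols)
    # mean-fill clashed electrostatic cells so the planted signal is
    # reproducible from the descriptor matrix used downstream
    Xe = X["comfa_elec"]
    for j in range(Xe.shape[1]):
        bad = clash[:, j]
        if bad.any() and not bad.all():
            Xe[bad, j] = Xe[~bad, j].mean()

    if spec.planted_cells is not None:
        cells = list(spec.planted_cells)
        for fname, idx, _ in cells:
            if fname not in X:
                raise ValueError(f"unknown planted field {fname!r}")
            if not 0 <= idx < lattice.n_points:
                raise ValueError(f"planted cell {idx} outside the lattice")
    else:
        # the planted signal mimics a binding-pocket preference: a few
        # spatially coherent regions (a high-variance seed cell plus its
        # 26-neighbourhood) with one weight per region.  Cells must
        # comfortably survive the 1 kcal/mol column filter and not be
        # dominated by the truncation plateau (at most half the series
        # saturated), where the field degenerates into a clash flag.
        cells = []
        truncation = probe.truncation
        for fname in ("comfa_steric", "comfa_elec"):
            vals = X[fname]
            stds = vals.std(axis=0)
            sat_frac = (np.abs(vals) >= truncation - 1e-9).mean(axis=0)
            eligible = np.nonzero((stds >= 2.0) & (sat_frac <= 0.5))[0]
            if eligible.size == 0:
                raise ValueError(f"no eligible signal cells for field {fname!r}")
            ranked = eligible[np.argsort(stds[eligible])[::-1]]
            seeds: list[int] = []
            for cand in ranked:
                if len(seeds) >= spec.n_regions_per_field:
                    break
                cand_ijk = np.array(lattice.unravel(int(cand)))
                if any(
                    np.abs(cand_ijk - np.array(lattice.unravel(s))).max() <= 2
                    for s in seeds
                ):
                    continue  # keep regions disjoint
                seeds.append(int(cand))
            for s in seeds:
                w = float(rng.uniform(0.5, 1.5)) * (1.0 if rng.random() < 0.5 else -1.0)
                ix, iy, iz = lattice.unravel(s)
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            try:
                                nb = lattice.index_of(ix + dx, iy + dy, iz + dz)
                            except IndexError:
                                continue
                            if stds[nb] >= 2.0 and sat_frac[nb] <= 0.5:
                                cells.append((fname, int(nb), w))

    raw = np.zeros(len(mols))
    for fname, idx, w in cells:
        raw += w * X[fname][:, idx]
    if raw.std() == 0:
        raise ValueError("planted cells carry no variance across the series")
    scale = spec.activity_sd / raw.std()
    shift = spec.activity_mean - raw.mean() * scale
    signal = raw * scale + shift
    scaled_cells = [(f, i, w * scale) for f, i, w in cells]
    eps = spec.noise_sd * rng.standard_normal(len(mols))
    y1 = signal + eps
    y2 = plant_endpoint_pair(y1, spec.endpoint_r2, rng)

    n_test = max(2, int(round(spec.test_fraction * len(mols))))
    labels = split_train_test(y1, n_test, spec.seed + 2)
    records: list[ActivityRecord] = []
    for i, m in enumerate(mols):
        records.append(ActivityRecord(m.id, "I", float(y1[i]), str(labels[i])))
        records.append(ActivityRecord(m.id, "II", float(y2[i]), str(labels[i])))
    truth = {
        "cells": [
            {"field": f, "index": i, "weight": w, "grid_index": list(lattice.unravel(i))}
            for f, i, w in scaled_cells
        ],
        "intercept": shift,
        "noise_sd": spec.noise_sd,
        "endpoint_r2": spec.endpoint_r2,
        "signal": signal.tolist(),
        "eps": eps.tolist(),
        "lattice": {
            "origin": list(lattice.origin),
            "spacing": lattice.spacing,
            "dims": list(lattice.dims),
        },
    }
    return records, truth


def generate_benchmark(
    spec: SyntheticSpec, out_dir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write the benchmark bundle: SDF, activity CSV, truth JSON, config.

    Regeneration from the same spec is bit-identical.  Refuses to write
    into a non-empty directory unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    mols = make_congeneric_series(spec)
    lattice = build_lattice(mols)
    records, truth = plant_activities(mols, lattice, spec)
    paths = {
        "structures": out_dir / "series.sdf",
        "activities": out_dir / "activities.csv",
        "truth": out_dir / "truth.json",
        "config": out_dir / "config.json",
    }
    write_molecules(mols, paths["structures"])
    write_activities(records, paths["activities"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    cfg = asdict(spec)
    cfg["substituent_library"] = list(cfg["substituent_library"])
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths


def evaluate_recovery(spec: SyntheticSpec, c_max: int = 8, endpoint: str = "I") -> dict:
    """Fit the full QSAR pipeline on a generated benchmark and score recovery.

    Returns LOO ``q2`` at the optimal component count, external
    ``r2_pred``, and ``sign_agreement``: among the top-decile
    |stdev*coeff| lattice cells of the fitted model, the fraction of
    planted cells whose recovered sign matches the planted weight.
    """
    from fieldqsar.contour import stdev_coeff_grid
    from fieldqsar.qsar_pls import (
        assemble_descriptors,
        block_scale,
        loo_validate,
        nipals_pls,
        r2_pred,
        transform_like,
    )

    mols = make_congeneric_series(spec)
    lattice = build_lattice(mols)
    records, truth = plant_activities(mols, lattice, spec)
    grids = []
    for m in mols:
        grids.extend(comfa_fields(m, lattice))
    grids.sort(key=lambda g: g.field)
    clogp = {m.id: float(m.properties["ClogP"]) for m in mols}
    dm = block_scale(assemble_descriptors(grids, {"ClogP": clogp}), "comfa_std")
    by_id = {(r.compound_id, r.endpoint): r for r in records}
    y = np.array([by_id[(i, endpoint)].pic50 for i in dm.row_ids])
    labels = np.array([by_id[(i, endpoint)].set_label for i in dm.row_ids])
    train = np.nonzero(labels == "train")[0]
    test = np.nonzero(labels == "test")[0]
    dm_train = dm.subset(train)
    q2_by_c, _, opn = loo_validate(dm_train, y[train], c_max)
    model = nipals_pls(dm_train, y[train], opn)
    X_test = transform_like(dm_train, dm.raw[test], dm.clash[test])
    r2p = r2_pred(y[test], model.predict(X_test), float(y[train].mean()))
    planted = {(c["field"], c["index"]): c["weight"] for c in truth["cells"]}
    sgrids = {f: stdev_coeff_grid(model, dm_train, f) for f in ("comfa_steric", "comfa_elec")}
    ranked = sorted(
        ((abs(v), f, k, np.sign(v)) for f, g in sgrids.items() for k, v in enumerate(g) if v != 0),
        reverse=True,
    )
    top = ranked[: max(1, len(ranked) // 10)]
    matches = [
        float(np.sign(planted[(f, k)]) == s) for _, f, k, s in top if (f, k) in planted
    ]
    return {
        "q2": float(q2_by_c[opn - 1]),
        "opn": int(opn),
        "r2_pred": float(r2p),
        "sign_agreement": float(np.mean(matches)) if matches else float("nan"),
        "n_train": int(train.size),
        "n_test": int(test.size),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Planted pharmacophore fixtures


def _hexagon(radius: float) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _base_planted_molecule() -> tuple[Molecule, dict[str, list[int]]]:
    """A rigid synthetic dummy molecule with exactly six features.

    Hand-placed atoms with hand-assigned charges and flags (this is a
    synthetic stand-in, not real chemistry): an aromatic six-ring
    (AR + one HP at the same centroid), an ether-type oxygen acceptor
    (HA, no acceptor site since it is non-terminal), a three-carbon
    hydrophobic cluster (second HP) and an N-H donor (HD + DS).
    """
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, float]] = []
    ring = _hexagon(1.39)  # atoms 0-5, centroid at the origin
    for xyz in ring:
        atoms.append(Atom("C", xyz, partial_charge=0.0, is_aromatic=True, hydrophobic_w=0.15))
    for i in range(6):
        bonds.append((i, (i + 1) % 6, 1.5))
    o_idx = len(atoms)  # acceptor oxygen bridging ring and cluster
    atoms.append(Atom("O", np.array([2.75, 0.0, 0.0]), partial_charge=-0.35, is_hba=True))
    bonds.append((0, o_idx, 1.0))
    cluster_center = np.array([5.0, 0.0, 0.0])
    cluster_idx = []
    for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        xyz = cluster_center + 0.87 * np.array([np.cos(ang), np.sin(ang), 0.0])
        cluster_idx.append(len(atoms))
        atoms.append(Atom("C", xyz, partial_charge=0.0, hydrophobic_w=0.3))
    bonds.extend(
        [
            (cluster_idx[0], cluster_idx[1], 1.0),
            (cluster_idx[1], cluster_idx[2], 1.0),
            (cluster_idx[2], cluster_idx[0], 1.0),
        ]
    )
    bonds.append((o_idx, cluster_idx[1], 1.0))
    n_idx = len(atoms)  # donor nitrogen with one hydrogen
    atoms.append(Atom("N", np.array([-2.80, 0.0, 0.0]), partial_charge=-0.30, is_hbd=True))
    bonds.append((3, n_idx, 1.0))
    h_idx = len(atoms)
    atoms.append(Atom("H", np.array([-3.55, 0.65, 0.0]), partial_charge=0.15))
    bonds.append((n_idx, h_idx, 1.0))
    mol = Molecule(id="planted", atoms=atoms, bonds=bonds)
    groups = {
        "AR": list(range(6)),
        "HP1": list(range(6)),
        "HA": [o_idx],
        "HP2": cluster_idx,
        "HD": [n_idx, h_idx],
        "DS": [n_idx, h_idx],
    }
    return mol, groups


def _random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-5.0, 5.0, size=3)
    return R, t


def make_planted_pharmacophore_set(
    n_molecules: int = 5,
    displaced_feature: str | None = None,
    displacement: float = 1.0,
    seed: int = 0,
) -> MoleculeSet:
    """Rigid copies of the planted six-feature molecule, randomly reposed.

    Each copy receives a seeded random rigid transform (the search only
    uses internal distances, so the common model is unaffected).  When
    ``displaced_feature`` names a feature group ("HP2", "HA", ...), the
    parent atoms of that feature are shifted by ``displacement`` Å in
    the last copy, pushing it beyond any sub-Å tolerance.
    """
    if n_molecules < 2:
        raise ValueError("need at least 2 molecules for a common-feature search")
    base, groups = _base_planted_molecule()
    if displaced_feature is not None and displaced_feature not in groups:
        raise ValueError(f"unknown feature group {displaced_feature!r}")
    rng = np.random.default_rng(seed)
    mols = []
    for k in range(n_molecules):
        m = base.copy()
        m.id = f"planted_{k + 1}"
        xyz = m.coords
        if displaced_feature is not None and k == n_molecules - 1:
            # shift along x: radial to the rest of the molecule, so every
            # inter-feature distance involving the group changes by ~the
            # displacement rather than a second-order amount
            xyz[groups[displaced_feature]] += np.array([displacement, 0.0, 0.0])
        R, t = _random_rigid_transform(rng)
        m.set_coords(xyz @ R.T + t)
        mols.append(m)
    return MoleculeSet(mols)
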