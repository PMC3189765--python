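"""Common-feature pharmacophore perception and clique-based search.

Feature kinds follow the distance-comparison (DISCO) tradition:

* HD — hydrogen-bond donor heavy atom
* HA — hydrogen-bond acceptor heavy atom
* DS — donor site, projected 2.9 Å from the donor along each D-H bond
* AS — acceptor site, projected 2.9 Å along the lone-pair axis of a
  terminal acceptor (opposite its single heavy-atom bond)
* AR — aromatic ring centroid
* HP — centroid of a connected group of >= 3 low-polarity heavy atoms
  (carbon or halogen with |partial charge| < 0.2)
* PN — positively charged or basic (protonatable) nitrogen

The search pairs same-kind features between a reference molecule and
every other molecule, keeps pairs whose internal distances agree within
2x the tolerance, enumerates maximal cliques of the correspondence
graph (Bron-Kerbosch with pivoting), and intersects the clique feature
sets across molecules.  Surviving feature sets become pharmacophore
models reported with SIZE, HITS, SCORE, TOLERANCE and DMEAN, plus the
inter-feature distance table.  Because only internal distances enter,
the result is invariant under rigid motion of any input molecule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist, squareform

from fieldqsar.chemio import Molecule, MoleculeSet

__all__ = [
    "PharmFeature",
    "FeatureSet",
    "PharmSearchParams",
    "PharmacophoreModel",
    "perceive_features",
    "generate_conformers",
    "disco_search",
    "model_metrics",
    "distance_table",
]

FEATURE_KINDS = ("HD", "HA", "DS", "AS", "HP", "AR", "PN")
PROJECTION_DISTANCE = 2.9  # Å, idealized H-bond length for DS/AS sites
HP_CHARGE_CUTOFF = 0.2
HP_ELEMENTS = {"C", "F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class PharmFeature:
    kind: str
    location: tuple[float, float, float]
    parent_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.location, dtype=float)


FeatureSet = list[PharmFeature]


@dataclass(frozen=True)
class PharmSearchParams:
    tolerance: float = 0.25
    min_features: int = 4
    max_features: int = 16
    n_conformers_max: int = 50
    n_conformers_select: int = 7
    tanimoto_threshold: float = 0.6
    seed: int = 0
    node_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_features > self.max_features:
            raise ValueError("min_features must not exceed max_features")


@dataclass
class PharmacophoreModel:
    """A common-feature model in the reference-molecule frame."""

    features: FeatureSet
    hits: int
    score: float
    tolerance: float
    dmean: float
    distance_table: np.ndarray
    reference_id: str = ""
    matches: dict[str, tuple[int, ...]] = dc_field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.features)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.features)


# ---------------------------------------------------------------------------
# Feature perception


def _aromatic_rings(mol: Molecule) -> list[list[int]]:
    """Rings of the aromatic subgraph via a minimum cycle basis."""
    g = nx.Graph()
    arom = [i for i, a in enumerate(mol.atoms) if a.is_aromatic]
    g.add_nodes_from(arom)
    for i, j, order in mol.bonds:
        if mol.atoms[i].is_aromatic and mol.atoms[j].is_aromatic:
            g.add_edge(i, j)
    rings: list[list[int]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for cycle in nx.minimum_cycle_basis(sub):
            if len(cycle) >= 5:
                rings.append(sorted(cycle))
    return rings


def _is_basic_nitrogen(mol: Molecule, idx: int) -> bool:
    """Protonatable amine: sp3-like N, not aromatic, not amide-adjacent."""
    atom = mol.atoms[idx]
    if atom.element != "N" or atom.is_aromatic:
        return False
    if any(mol.atoms[nb].is_aromatic for nb in mol.neighbors(idx)):
        return False  # aniline-type nitrogen: conjugation removes basicity
    for i, j, order in mol.bonds:
        if idx in (i, j) and order > 1:
            return False  # sp2/sp nitrogen
    for nb in mol.neighbors(idx):
        if mol.atoms[nb].element == "C":
            for i, j, order in mol.bonds:
                if nb in (i, j) and order == 2:
                    other = j if i == nb else i
                    if mol.atoms[other].element in ("O", "S"):
                        return False  # amide/thioamide nitrogen
    return True


def perceive_features(mol: Molecule) -> FeatureSet:
    """Derive the typed feature points of one conformer.

    Requires donor/acceptor flags and partial charges to be present
    (``assign_partial_charges`` + ``assign_field_params``, or planted by
    a generator).
    """
    if all(a.partial_charge == 0.0 for a in mol.atoms) and not any(
        a.is_hbd or a.is_hba for a in mol.atoms
    ):
        raise ValueError(
            f"molecule {mol.id!r} has no charges or donor/acceptor flags; "
            "assign atomic parameters first"
        )
    feats: FeatureSet = []
    coords = mol.coords
    # donor/acceptor atoms and projected sites
    for idx, atom in enumerate(mol.atoms):
        if atom.is_hbd:
            feats.append(PharmFeature("HD", tuple(coords[idx]), (idx,)))
            for nb in mol.neighbors(idx):
                if mol.atoms[nb].element == "H":
                    v = coords[nb] - coords[idx]
                    norm = np.linalg.norm(v)
                    if norm > 0:
                        loc = coords[idx] + PROJECTION_DISTANCE * v / norm
                        feats.append(PharmFeature("DS", tuple(loc), (idx, nb)))
        if atom.is_hba:
            feats.append(PharmFeature("HA", tuple(coords[idx]), (idx,)))
            # acceptor sites only where the lone-pair axis is well defined:
            # terminal acceptors with exactly one heavy neighbour (C=O, C#N, ...)
            heavies = [nb for nb in mol.neighbors(idx) if mol.atoms[nb].element != "H"]
            if len(heavies) == 1:
                v = coords[heavies[0]] - coords[idx]
                norm = np.linalg.norm(v)
                if norm > 0:
                    loc = coords[idx] - PROJECTION_DISTANCE * v / norm
                    feats.append(PharmFeature("AS", tuple(loc), (idx,)))
        if atom.element == "N" and (
            atom.formal_charge > 0 or _is_basic_nitrogen(mol, idx)
        ):
            feats.append(PharmFeature("PN", tuple(coords[idx]), (idx,)))
    # aromatic ring centroids
    for ring in _aromatic_rings(mol):
        centroid = coords[ring].mean(axis=0)
        feats.append(PharmFeature("AR", tuple(centroid), tuple(ring)))
    # hydrophobic clusters
    hp_atoms = {
        i
        for i, a in enumerate(mol.atoms)
        if a.element in HP_ELEMENTS and abs(a.partial_charge) < HP_CHARGE_CUTOFF
    }
    g = nx.Graph()
    g.add_nodes_from(hp_atoms)
    for i, j, _ in mol.bonds:
        if i in hp_atoms and j in hp_atoms:
            g.add_edge(i, j)
    for comp in nx.connected_components(g):
        if len(comp) >= 3:
            members = sorted(comp)
            centroid = coords[members].mean(axis=0)
            feats.append(PharmFeature("HP", tuple(centroid), tuple(members)))
    return feats


# ---------------------------------------------------------------------------
# Conformers


def _n_rotatable(rdmol: Chem.Mol) -> int:
    from rdkit.Chem import rdMolDescriptors

    return int(rdMolDescriptors.CalcNumRotatableBonds(rdmol))


def generate_conformers(mol: Molecule, params: PharmSearchParams) -> list[np.ndarray]:
    """Seeded stochastic conformer pool, pruned to a diverse selection.

    Rigid molecules (no rotatable bonds, or no attached RDKit
    structure) keep their input conformer.  Otherwise up to
    ``n_conformers_max`` distance-geometry embeddings are generated,
    sorted by MMFF energy when available, pruned by a Tanimoto-style
    similarity of their sorted heavy-atom distance profiles, and the
    first ``n_conformers_select`` survivors kept.
    """
    rdmol = mol.rdkit_mol
    if rdmol is None or _n_rotatable(rdmol) == 0:
        return [mol.coords]
    work = Chem.Mol(rdmol)
    cids = AllChem.EmbedMultipleConfs(
        work,
        numConfs=params.n_conformers_max,
        randomSeed=int(params.seed % (2**31 - 1)) or 1,
        useRandomCoords=False,
    )
    if len(cids) == 0:
        raise ValueError(f"conformer embedding failed for molecule {mol.id!r}")
    energies: list[float] = []
    props = AllChem.MMFFGetMoleculeProperties(work)
    for cid in cids:
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(work, props, confId=cid)
            energies.append(float(ff.CalcEnergy()) if ff is not None else 0.0)
        else:
            energies.append(0.0)
    order = sorted(range(len(cids)), key=lambda k: (energies[k], k))
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    pools: list[np.ndarray] = []
    profiles: list[np.ndarray] = []
    for k in order:
        conf = work.GetConformer(cids[k])
        xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.n_atoms)])
        profile = np.sort(pdist(xyz[heavy]))
        keep = True
        for p in profiles:
            sim = float(np.minimum(profile, p).sum() / np.maximum(profile, p).sum())
            if sim >= params.tanimoto_threshold:
                keep = False
                break
        if keep:
            pools.append(xyz)
            profiles.append(profile)
        if len(pools) >= params.n_conformers_select:
            break
    if not pools:  # all near-duplicates: fall back to the lowest-energy one
        conf = work.GetConformer(cids[order[0]])
        pools = [np.array([list(conf.GetAtomPosition(i)) for i in range(mol.n_atoms)])]
    return pools


def _conformer_features(mol: Molecule, params: PharmSearchParams) -> list[FeatureSet]:
    sets = []
    for xyz in generate_conformers(mol, params):
        m = mol.copy()
        m.set_coords(xyz)
        sets.append(perceive_features(m))
    return sets


# ---------------------------------------------------------------------------
# Clique search


def _feature_distmat(feats: FeatureSet) -> np.ndarray:
    pts = np.array([f.xyz for f in feats])
    return squareform(pdist(pts)) if len(feats) > 1 else np.zeros((1, 1))


def _cliques_vs_reference(
    ref_feats: FeatureSet,
    ref_d: np.ndarray,
    mol_feats: FeatureSet,
    params: PharmSearchParams,
) -> list[dict[int, int]]:
    """Maximal consistent correspondences (ref feature -> mol feature)."""
    nodes = [
        (i, a)
        for i, rf in enumerate(ref_feats)
        for a, mf in enumerate(mol_feats)
        if rf.kind == mf.kind
    ]
    if len(nodes) > params.node_cap:
        raise ValueError(
            f"correspondence graph too large ({len(nodes)} nodes > cap {params.node_cap})"
        )
    mol_d = _feature_distmat(mol_feats)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    limit = 2.0 * params.tolerance
    for (i, a), (j, b) in itertools.combinations(nodes, 2):
        if i == j or a == b:
            continue
        if abs(ref_d[i, j] - mol_d[a, b]) <= limit:
            g.add_edge((i, a), (j, b))
    out: list[dict[int, int]] = []
    for clique in nx.find_cliques(g):
        out.append(dict(sorted(clique)))
    return out


def disco_search(
    mols: MoleculeSet,
    reference_id: str,
    params: PharmSearchParams = PharmSearchParams(),
) -> list[PharmacophoreModel]:
    """Find feature patterns common to every molecule of the set.

    For each reference conformer the clique feature sets against every
    other molecule (over all of its conformers) are intersected; the
    surviving reference-feature subsets within the size window become
    models ranked by score.  Returns an empty list when nothing of at
    least ``min_features`` features is shared.
    """
    if reference_id not in mols:
        raise ValueError(f"reference molecule {reference_id!r} not in the set")
    others = [m for m in mols if m.id != reference_id]
    ref = mols[reference_id]
    all_models: list[PharmacophoreModel] = []
    other_feature_sets = {m.id: _conformer_features(m, params) for m in others}
    for ref_feats in _conformer_features(ref, params):
        ref_d = _feature_distmat(ref_feats)
        candidate_sets: set[frozenset[int]] | None = None
        for m in others:
            mol_sets: set[frozenset[int]] = set()
            for mol_feats in other_feature_sets[m.id]:
                for cl in _cliques_vs_reference(ref_feats, ref_d, mol_feats, params):
                    mol_sets.add(frozenset(cl))
            if not mol_sets:
                candidate_sets = set()
                break
            if candidate_sets is None:
                candidate_sets = mol_sets
            else:
                candidate_sets = {
                    c & s for c in candidate_sets for s in mol_sets if len(c & s) > 0
                }
            # keep only maximal sets, capped deterministically by size
            candidate_sets = _prune_maximal(candidate_sets, cap=256)
            if not candidate_sets:
                break
        if not candidate_sets:
            continue
        for fs in sorted(candidate_sets, key=lambda s: (-len(s), sorted(s))):
            if not params.min_features <= len(fs) <= params.max_features:
                continue
            feat_idx = sorted(fs)
            features = [ref_feats[i] for i in feat_idx]
            model = _build_model(
                features, ref, others, other_feature_sets, params, reference_id
            )
            if model is not None:
                all_models.append(model)
    return _dedupe_and_rank(all_models, params)


def _prune_maximal(sets: set[frozenset[int]], cap: int) -> set[frozenset[int]]:
    ordered = sorted(sets, key=lambda s: (-len(s), sorted(s)))
    maximal: list[frozenset[int]] = []
    for s in ordered:
        if not any(s < m for m in maximal):
            maximal.append(s)
        if len(maximal) >= cap:
            break
    return set(maximal)


def _best_match(
    features: FeatureSet, mol_feats: FeatureSet, params: PharmSearchParams
) -> tuple[tuple[int, ...], float] | None:
    """Best assignment of model features onto one conformer's features.

    Returns the matched feature indices and the mean absolute pairwise
    distance discrepancy, or None when no consistent assignment exists.
    """
    ref_d = _feature_distmat(features)
    try:
        cliques = _cliques_vs_reference(features, ref_d, mol_feats, params)
    except ValueError:
        return None
    full = [cl for cl in cliques if len(cl) == len(features)]
    if not full:
        return None
    mol_d = _feature_distmat(mol_feats)
    best: tuple[float, tuple[int, ...]] | None = None
    for cl in full:
        pairs = sorted(cl.items())
        devs = [
            abs(ref_d[i, j] - mol_d[cl[i], cl[j]])
            for (i, _), (j, _) in itertools.combinations(pairs, 2)
        ]
        mean_dev = float(np.mean(devs)) if devs else 0.0
        assignment = tuple(cl[i] for i, _ in pairs)
        if best is None or mean_dev < best[0]:
            best = (mean_dev, assignment)
    return best[1], best[0]


def _build_model(
    features: FeatureSet,
    ref: Molecule,
    others: list[Molecule],
    other_feature_sets: dict[str, list[FeatureSet]],
    params: PharmSearchParams,
    reference_id: str,
) -> PharmacophoreModel | None:
    matches: dict[str, tuple[int, ...]] = {}
    deviations: list[float] = [0.0]  # reference matches itself exactly
    matches[reference_id] = tuple(range(len(features)))
    for m in others:
        best: tuple[tuple[int, ...], float] | None = None
        for mol_feats in other_feature_sets[m.id]:
            res = _best_match(features, mol_feats, params)
            if res is not None and (best is None or res[1] < best[1]):
                best = res
        if best is None:
            continue
        matches[m.id] = best[0]
        deviations.append(best[1])
    hits = len(matches)
    if hits < len(others) + 1:
        return None  # a common-feature model must cover every molecule
    d = _feature_distmat(features)
    iu = np.triu_indices(len(features), k=1)
    dmean = float(d[iu].mean()) if iu[0].size else 0.0
    mean_dev = float(np.mean(deviations))
    score = len(features) * (1.0 - mean_dev / params.tolerance)
    return PharmacophoreModel(
        features=features,
        hits=hits,
        score=score,
        tolerance=params.tolerance,
        dmean=dmean,
        distance_table=d,
        reference_id=reference_id,
        matches=matches,
    )


def _dedupe_and_rank(
    models: list[PharmacophoreModel], params: PharmSearchParams
) -> list[PharmacophoreModel]:
    unique: list[PharmacophoreModel] = []
    for m in sorted(models, key=lambda x: (-x.score, -x.size)):
        dup = False
        for u in unique:
            if m.kinds == u.kinds and m.size == u.size:
                if np.allclose(m.distance_table, u.distance_table, atol=params.tolerance):
                    dup = True
                    break
        if not dup:
            unique.append(m)
    return unique


def model_metrics(
    model: PharmacophoreModel, mols: MoleculeSet, params: PharmSearchParams
) -> tuple[float, int, float]:
    """Recompute (score, hits, dmean) of a model against a molecule set.

    ``hits`` counts molecules with at least one conformer matching every
    feature within the pairwise tolerance; ``score`` is
    size * (1 - mean_deviation / tolerance) with the mean distance
    discrepancy averaged over all matched molecules and feature pairs.
    """
    if model.size == 0:
        raise ValueError("empty pharmacophore model")
    hits = 0
    deviations: list[float] = []
    for m in mols:
        best: float | None = None
        for feats in _conformer_features(m, params):
            res = _best_match(model.features, feats, params)
            if res is not None and (best is None or res[1] < best):
                best = res[1]
        if best is not None:
            hits += 1
            deviations.append(best)
    d = model.distance_table
    iu = np.triu_indices(model.size, k=1)
    dmean = float(d[iu].mean()) if iu[0].size else 0.0
    mean_dev = float(np.mean(deviations)) if deviations else 0.0
    score = model.size * (1.0 - mean_dev / params.tolerance)
    return score, hits, dmean


def distance_table(model: PharmacophoreModel) -> tuple[np.ndarray, list[str]]:
    """Symmetric inter-feature distance matrix with kind-numbered labels."""
    if model.size == 0:
        raise ValueError("empty pharmacophore model")
    counts: dict[str, int] = {}
    labels = []
    for f in model.features:
        counts[f.kind] = counts.get(f.kind, 0) + 1
        labels.append(f"{f.kind}{counts[f.kind]}")
    return model.distance_table.copy(), labels
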