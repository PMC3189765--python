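"""End-to-end study orchestration and plain-text reporting.

``run_study`` drives the whole workflow from one configuration:
load (or simulate) the series, align on the common scaffold, evaluate
lattice fields, fit and validate the PLS model (LOO for the optimal
component count, external test set for r²pred), export stdev*coeff
contours, and search a common-feature pharmacophore over the most
active compounds.  The report is a plain JSON-serializable dictionary;
``report_table`` renders its PLS statistics in the conventional
Q²/R²ncv/SEE/F/R²pre/SEP/OPN layout with per-field contribution rows.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from fieldqsar.alignment import align_series
from fieldqsar.chemio import (
    ActivityRecord,
    MoleculeSet,
    assign_field_params,
    assign_partial_charges,
    compute_logp,
    read_activities,
    read_molecules,
    write_molecules,
)
from fieldqsar.contour import export_contours, extract_contours
from fieldqsar.fields import ProbeSpec, build_lattice, comfa_fields, comsia_fields
from fieldqsar.pharmacophore import PharmSearchParams, disco_search, distance_table
from fieldqsar.qsar_pls import (
    assemble_descriptors,
    block_scale,
    field_fractions,
    loo_validate,
    model_summary,
    nipals_pls,
    r2_pred,
    transform_like,
)
from fieldqsar.synthetic import SyntheticSpec, make_congeneric_series, plant_activities
from fieldqsar.synthetic import SCAFFOLD_QUERY

__all__ = ["StudyConfig", "run_study", "report_table", "parse_report_table"]

log = logging.getLogger("fieldqsar")


@dataclass
class StudyConfig:
    """Flat key/value configuration of one complete study.

    Defaults mirror the conventional settings of lattice-field QSAR:
    2 Å spacing, attenuation 0.3, 30 kcal/mol truncation, 1 kcal/mol
    minimum sigma, 0.25 Å pharmacophore tolerance, 4-16 features and a
    50-conformer pool pruned to 7.
    """

    structures: str | None = None  # SDF path; None -> simulate
    activities: str | None = None  # CSV path; None -> simulate
    scaffold_pattern: str = SCAFFOLD_QUERY
    template_id: str | None = None  # None -> most active training compound
    endpoint: str = "I"
    field_set: str = "comfa"  # comfa | comsia | both
    spacing: float = 2.0
    margin: float = 4.0
    attenuation_alpha: float = 0.3
    truncation: float = 30.0
    sigma_min: float = 1.0
    scheme: str = "comfa_std"
    c_max: int = 8
    favored_pct: float = 0.80
    disfavored_pct: float = 0.20
    pharmacophore: bool = True
    pharm_tolerance: float = 0.25
    pharm_min_features: int = 4
    pharm_max_features: int = 16
    pharm_n_conformers_max: int = 50
    pharm_n_conformers_select: int = 7
    pharm_tanimoto: float = 0.6
    pharm_n_actives: int = 10
    simulate_n_compounds: int = 75
    simulate_noise_sd: float = 0.2
    simulate_endpoint_r2: float = 0.39
    seed: int = 0
    out_dir: str = "study_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _load_inputs(cfg: StudyConfig) -> tuple[MoleculeSet, list[ActivityRecord]]:
    if cfg.structures is None or cfg.activities is None:
        log.info(
            "stage=simulate n=%d noise_sd=%.3g endpoint_r2=%.3g seed=%d",
            cfg.simulate_n_compounds,
            cfg.simulate_noise_sd,
            cfg.simulate_endpoint_r2,
            cfg.seed,
        )
        spec = SyntheticSpec(
            n_compounds=cfg.simulate_n_compounds,
            noise_sd=cfg.simulate_noise_sd,
            endpoint_r2=cfg.simulate_endpoint_r2,
            seed=cfg.seed,
        )
        mols = make_congeneric_series(spec)
        lattice = build_lattice(mols, cfg.spacing, cfg.margin)
        records, _ = plant_activities(mols, lattice, spec)
        return mols, records
    mols = read_molecules(cfg.structures)
    records = read_activities(cfg.activities)
    for m in mols:
        assign_partial_charges(m)
        assign_field_params(m)
        compute_logp(m)
    return mols, records


def run_study(cfg: StudyConfig) -> dict:
    """Execute every stage and write report + artifacts to ``cfg.out_dir``.

    Any stage failure aborts with a stage-named error after removing
    partial outputs.  The report is deterministic for a fixed config.
    """
    out_dir = Path(cfg.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_study_inner(cfg, out_dir)
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise type(exc)(f"{exc}") from exc


def _run_study_inner(cfg: StudyConfig, out_dir: Path) -> dict:
    stage = "load"
    try:
        mols, records = _load_inputs(cfg)
        recs = [r for r in records if r.endpoint == cfg.endpoint]
        by_id = {r.compound_id: r for r in recs}
        missing = [r.compound_id for r in recs if r.compound_id not in mols]
        if missing:
            raise ValueError(f"activity records without structures: {missing}")
        keep = [m.id for m in mols if m.id in by_id]
        if not keep:
            raise ValueError(f"no compound has activity for endpoint {cfg.endpoint}")
        mols = MoleculeSet([mols[i].copy() for i in keep])

        stage = "align"
        template_id = cfg.template_id
        if template_id is None:
            train = [r for r in recs if r.set_label == "train"]
            template_id = max(train, key=lambda r: r.pic50).compound_id
        log.info("stage=align template=%s pattern=%s", template_id, cfg.scaffold_pattern)
        aligned, rmsds = align_series(mols, template_id, cfg.scaffold_pattern)

        stage = "fields"
        probe = ProbeSpec(
            attenuation_alpha=cfg.attenuation_alpha, truncation=cfg.truncation
        )
        lattice = build_lattice(aligned, cfg.spacing, cfg.margin)
        log.info(
            "stage=fields set=%s spacing=%.2f dims=%s", cfg.field_set, cfg.spacing, lattice.dims
        )
        grids = []
        for m in aligned:
            if cfg.field_set in ("comfa", "both"):
                grids.extend(comfa_fields(m, lattice, probe))
            if cfg.field_set in ("comsia", "both"):
                grids.extend(comsia_fields(m, lattice, probe))
        grids.sort(key=lambda g: g.field)  # group grids by field, molecule order kept
        clogp = {m.id: float(m.properties.get("ClogP", 0.0)) for m in aligned}

        stage = "fit"
        dm_full = assemble_descriptors(grids, {"ClogP": clogp}, cfg.sigma_min)
        dm_full = block_scale(dm_full, cfg.scheme)
        y_all = np.array([by_id[i].pic50 for i in dm_full.row_ids])
        labels = np.array([by_id[i].set_label for i in dm_full.row_ids])
        train_rows = np.nonzero(labels == "train")[0]
        test_rows = np.nonzero(labels == "test")[0]
        dm_train = dm_full.subset(train_rows)
        y_train = y_all[train_rows]
        c_max = min(cfg.c_max, len(train_rows) - 2)
        log.info("stage=fit n_train=%d n_test=%d c_max=%d", len(train_rows), len(test_rows), c_max)
        q2_by_c, sep_by_c, opn = loo_validate(dm_train, y_train, c_max)
        model = nipals_pls(dm_train, y_train, opn)
        stats = model_summary(model, dm_train, y_train)
        fractions = field_fractions(model, dm_train)
        fitted_train = model.predict(dm_train.retained())

        stage = "predict"
        report_pred = {
            dm_train.row_ids[i]: {"observed": float(y_train[i]), "predicted": float(fitted_train[i]), "set": "train"}
            for i in range(len(train_rows))
        }
        r2p = None
        if len(test_rows) >= 2:
            X_test = transform_like(dm_train, dm_full.raw[test_rows], dm_full.clash[test_rows])
            pred_test = model.predict(X_test)
            y_test = y_all[test_rows]
            r2p = r2_pred(y_test, pred_test, float(y_train.mean()))
            for k, row in enumerate(test_rows):
                report_pred[dm_full.row_ids[row]] = {
                    "observed": float(y_test[k]),
                    "predicted": float(pred_test[k]),
                    "set": "test",
                }

        stage = "contour"
        contour_files = {}
        for fname in dict.fromkeys(b for b, _ in dm_train.column_meta if b != "extra"):
            try:
                cs = extract_contours(
                    model, dm_train, fname, lattice, cfg.favored_pct, cfg.disfavored_pct
                )
            except ValueError:
                continue  # field entirely filtered out
            path = out_dir / f"contour_{fname}.cube"
            export_contours(cs, path, "cube")
            contour_files[fname] = str(path)
        log.info("stage=contour files=%d", len(contour_files))

        stage = "pharmacophore"
        pharm_models = []
        if cfg.pharmacophore:
            params = PharmSearchParams(
                tolerance=cfg.pharm_tolerance,
                min_features=cfg.pharm_min_features,
                max_features=cfg.pharm_max_features,
                n_conformers_max=cfg.pharm_n_conformers_max,
                n_conformers_select=cfg.pharm_n_conformers_select,
                tanimoto_threshold=cfg.pharm_tanimoto,
                seed=cfg.seed,
            )
            n_act = min(cfg.pharm_n_actives, len(aligned))
            top = sorted(aligned, key=lambda m: -by_id[m.id].pic50)[:n_act]
            reference = top[0].id
            log.info("stage=pharmacophore n_actives=%d reference=%s", n_act, reference)
            models = disco_search(MoleculeSet([m.copy() for m in top]), reference, params)
            for pm in models[:10]:
                dmat, labels_ = distance_table(pm)
                pharm_models.append(
                    {
                        "size": pm.size,
                        "hits": pm.hits,
                        "score": round(pm.score, 4),
                        "tolerance": pm.tolerance,
                        "dmean": round(pm.dmean, 4),
                        "kinds": list(pm.kinds),
                        "labels": labels_,
                        "distance_table": np.round(dmat, 4).tolist(),
                        "reference": pm.reference_id,
                    }
                )

        stage = "report"
        report = {
            "config": asdict(cfg),
            "endpoint": cfg.endpoint,
            "n_train": int(len(train_rows)),
            "n_test": int(len(test_rows)),
            "template": template_id,
            "alignment_rmsd_max": float(max(rmsds.values())),
            "lattice": {"origin": list(lattice.origin), "spacing": lattice.spacing, "dims": list(lattice.dims)},
            "q2": float(q2_by_c[opn - 1]),
            "q2_by_components": [float(v) for v in q2_by_c],
            "sep": float(sep_by_c[opn - 1]),
            "opn": int(opn),
            "r2_ncv": float(stats.r2_ncv),
            "see": float(stats.see),
            "f_stat": float(stats.f_stat),
            "r2_pred": None if r2p is None else float(r2p),
            "field_fractions": {k: float(v) for k, v in fractions.items()},
            "predictions": report_pred,
            "contour_files": contour_files,
            "pharmacophore_models": pharm_models,
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "report.txt").write_text(report_table(report))
        write_molecules(aligned, out_dir / "aligned.sdf")
        return report
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc


_TABLE_ROWS = [
    ("Q2", "q2"),
    ("R2ncv", "r2_ncv"),
    ("SEE", "see"),
    ("F", "f_stat"),
    ("R2pre", "r2_pred"),
    ("SEP", "sep"),
    ("OPN", "opn"),
]

_FRACTION_ORDER = [
    ("Steric", ("comfa_steric", "comsia_steric")),
    ("Electrostatic", ("comfa_elec", "comsia_elec")),
    ("Hydrophobic", ("comsia_hydrophobic",)),
    ("H-donor", ("comsia_donor",)),
    ("H-acceptor", ("comsia_acceptor",)),
    ("Clogp", ("ClogP",)),
]


def report_table(report: dict) -> str:
    """Render the PLS statistics block as a plain-text summary table."""
    lines = ["PLS Statistics"]
    for label, key in _TABLE_ROWS:
        val = report.get(key)
        if val is None:
            continue
        if key == "opn":
            lines.append(f"{label:<16}{int(val)}")
        else:
            lines.append(f"{label:<16}{val:.3f}")
    fractions = report.get("field_fractions") or {}
    if fractions:
        lines.append("Contribution")
        for label, keys in _FRACTION_ORDER:
            total = sum(fractions[k] for k in keys if k in fractions)
            present = any(k in fractions for k in keys)
            if present:
                lines.append(f"{label:<16}{total:.3f}")
    return "\n".join(lines) + "\n"


def parse_report_table(text: str) -> dict:
    """Parse a ``report_table`` rendering back into numeric fields."""
    label_to_key = {label: key for label, key in _TABLE_ROWS}
    out: dict = {}
    fractions: dict[str, float] = {}
    in_fractions = False
    for line in text.splitlines():
        parts = line.split()
        if not parts or line.startswith("PLS"):
            continue
        if parts[0] == "Contribution":
            in_fractions = True
            continue
        label, value = parts[0], parts[-1]
        if in_fractions:
            fractions[label] = float(value)
        elif label in label_to_key:
            key = label_to_key[label]
            out[key] = int(value) if key == "opn" else float(value)
    if fractions:
        out["field_fractions"] = fractions
    return out
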