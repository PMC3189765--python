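"""Descriptor assembly, NIPALS PLS, and model validation statistics.

The descriptor matrix stacks, per compound, the lattice-field columns
(CoMFA and/or CoMSIA) followed by any extra whole-molecule descriptors
(e.g. ClogP).  Columns are preprocessed in three steps, all recomputed
inside every leave-one-out fold to avoid information leakage:

1. clash mean-filling — CoMFA electrostatic values at sterically
   excluded points are replaced by the training-column mean;
2. minimum-sigma column filtering — lattice columns whose standard
   deviation falls below ``sigma_min`` (default 1 kcal/mol) are dropped
   (extra descriptors are exempt);
3. block scaling — each field block is divided by its pooled standard
   deviation so blocks contribute comparable variance ("CoMFA-std");
   extras are scaled to unit variance.

PLS is fitted by NIPALS on centered data.  Reported statistics follow
the classical QSAR conventions: LOO Q² = 1 - PRESS/SS, SEP =
sqrt(PRESS/(n-c-1)), SEE = sqrt(RSS/(n-c-1)), F = [R²/(1-R²)]·(n-c-1)/c,
external r²pred = 1 - PRESS/SD with deviations about the training mean,
and per-field contribution fractions from |coefficient|·stdev sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Literal, Sequence

import numpy as np

from fieldqsar.fields import FieldGrid

__all__ = [
    "DescriptorMatrix",
    "PLSModel",
    "ValidationStats",
    "assemble_descriptors",
    "block_scale",
    "nipals_pls",
    "predict",
    "transform_like",
    "loo_validate",
    "model_summary",
    "f_statistic",
    "field_fractions",
    "q2_statistic",
    "r2_pred",
    "split_train_test",
    "endpoint_correlation",
]

Scheme = Literal["comfa_std", "none"]


@dataclass
class DescriptorMatrix:
    """Compounds × descriptor columns with per-column metadata.

    ``raw`` keeps the unprocessed values (plus the clash flags) so the
    preprocessing can be re-derived on any row subset; ``values`` holds
    the processed matrix for the full set.  ``column_meta`` entries are
    ``(block, key)`` where block is a field name or ``"extra"``.
    """

    row_ids: list[str]
    raw: np.ndarray
    clash: np.ndarray
    column_meta: list[tuple[str, int | str]]
    sigma_min: float
    values: np.ndarray
    retained_mask: np.ndarray
    scheme: Scheme = "none"
    block_weights: dict[str, float] = dc_field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.raw.shape[0]

    @property
    def n_columns(self) -> int:
        return self.raw.shape[1]

    def blocks(self) -> list[str]:
        """Distinct blocks in column order (extras keyed by name)."""
        out: list[str] = []
        for b, k in self.column_meta:
            name = str(k) if b == "extra" else b
            if name not in out:
                out.append(name)
        return out

    def column_blocks(self) -> np.ndarray:
        return np.array(
            [str(k) if b == "extra" else b for b, k in self.column_meta], dtype=object
        )

    def retained(self) -> np.ndarray:
        """Processed matrix restricted to retained columns."""
        return self.values[:, self.retained_mask]

    def subset(self, rows: Sequence[int]) -> "DescriptorMatrix":
        """Row subset with filling/filtering/scaling refitted on those rows."""
        rows = np.asarray(rows, dtype=int)
        raw = self.raw[rows]
        clash = self.clash[rows]
        prep = _make_prep(raw, clash, self.column_meta, np.arange(rows.size), self.sigma_min, self.scheme)
        values = prep.transform(raw, clash)
        blocks = [str(k) if b == "extra" else b for b, k in self.column_meta]
        weights = {name: float(prep.scale[blocks.index(name)]) for name in dict.fromkeys(blocks)}
        return DescriptorMatrix(
            row_ids=[self.row_ids[r] for r in rows],
            raw=raw,
            clash=clash,
            column_meta=self.column_meta,
            sigma_min=self.sigma_min,
            values=values,
            retained_mask=prep.retained,
            scheme=self.scheme,
            block_weights=weights,
        )


class _Preprocessor:
    """Fill/filter/scale state fitted on a training row subset.

    Built by :func:`_make_prep`; holds ``fill_means`` (clash filling),
    ``retained`` (minimum-sigma mask) and ``scale`` (per-column block
    scaling factors).
    """

    column_meta: list[tuple[str, int | str]]
    fill_means: np.ndarray
    retained: np.ndarray
    scale: np.ndarray
    _fillable: np.ndarray

    def _apply_fill(self, raw: np.ndarray, clash: np.ndarray) -> np.ndarray:
        out = raw.copy()
        mask = clash & self._fillable[None, :]
        if mask.any():
            ridx, cidx = np.nonzero(mask)
            out[ridx, cidx] = self.fill_means[cidx]
        return out

    def transform(self, raw: np.ndarray, clash: np.ndarray) -> np.ndarray:
        """Processed matrix (all columns); select with ``self.retained``."""
        filled = self._apply_fill(raw, clash)
        return filled * self.scale


def _make_prep(
    raw: np.ndarray,
    clash: np.ndarray,
    column_meta: list[tuple[str, int | str]],
    rows: np.ndarray,
    sigma_min: float,
    scheme: Scheme,
) -> _Preprocessor:
    # two-phase construction: filling depends on fill_means computed first
    prep = _Preprocessor.__new__(_Preprocessor)
    prep.column_meta = column_meta
    is_extra = np.array([b == "extra" for b, _ in column_meta])
    fillable = np.array([b == "comfa_elec" for b, _ in column_meta])
    prep._fillable = fillable
    sub_raw = raw[rows]
    sub_clash = clash[rows]
    ok = ~sub_clash
    counts = ok.sum(axis=0)
    sums = np.where(ok, sub_raw, 0.0).sum(axis=0)
    prep.fill_means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    filled = prep._apply_fill(sub_raw, sub_clash)
    stds = filled.std(axis=0)
    prep.retained = is_extra | (stds >= sigma_min)
    prep.scale = np.ones(raw.shape[1])
    if scheme == "comfa_std":
        blocks = np.array(
            [str(k) if b == "extra" else b for b, k in column_meta], dtype=object
        )
        var = filled.var(axis=0)
        for name in dict.fromkeys(blocks):
            sel = (blocks == name) & prep.retained
            if not sel.any():
                continue
            pooled = float(np.sqrt(var[sel].mean()))
            if pooled == 0.0:
                if is_extra[sel].all():
                    continue
                raise ValueError(f"zero-variance block {name!r} cannot be scaled")
            prep.scale[sel] = 1.0 / pooled
    return prep


def assemble_descriptors(
    grids: Sequence[FieldGrid],
    extras: dict[str, dict[str, float]] | None = None,
    sigma_min: float = 1.0,
) -> DescriptorMatrix:
    """Stack field grids (one per molecule per field) into a descriptor matrix.

    ``extras`` maps descriptor name → {compound id → value}; extra
    columns are appended last and never filtered.  Clash mean-filling is
    applied before the minimum-sigma filter.
    """
    if not grids:
        raise ValueError("no field grids supplied")
    by_field: dict[str, list[FieldGrid]] = {}
    for g in grids:
        by_field.setdefault(g.field, []).append(g)
    field_names = list(by_field)
    row_ids = [g.molecule_id for g in by_field[field_names[0]]]
    n = len(row_ids)
    n_points = by_field[field_names[0]][0].values.size
    cols_raw: list[np.ndarray] = []
    cols_clash: list[np.ndarray] = []
    meta: list[tuple[str, int | str]] = []
    for fname in field_names:
        fgrids = by_field[fname]
        ids = [g.molecule_id for g in fgrids]
        if ids != row_ids:
            raise ValueError(f"field {fname!r} has inconsistent molecule order or count")
        sizes = {g.values.size for g in fgrids}
        if sizes != {n_points}:
            raise ValueError("inconsistent lattice between field grids")
        cols_raw.append(np.vstack([g.values for g in fgrids]))
        cols_clash.append(np.vstack([g.clash_mask for g in fgrids]))
        meta.extend((fname, int(i)) for i in range(n_points))
    raw = np.hstack(cols_raw)
    clash = np.hstack(cols_clash)
    if extras:
        for name, table in extras.items():
            missing = [i for i in row_ids if i not in table]
            if missing:
                raise ValueError(f"extra descriptor {name!r} missing for {missing}")
            raw = np.hstack([raw, np.array([[table[i]] for i in row_ids])])
            clash = np.hstack([clash, np.zeros((n, 1), dtype=bool)])
            meta.append(("extra", name))
    prep = _make_prep(raw, clash, meta, np.arange(n), sigma_min, "none")
    values = prep.transform(raw, clash)
    return DescriptorMatrix(
        row_ids=row_ids,
        raw=raw,
        clash=clash,
        column_meta=meta,
        sigma_min=sigma_min,
        values=values,
        retained_mask=prep.retained,
        scheme="none",
    )


def block_scale(dm: DescriptorMatrix, scheme: Scheme = "comfa_std") -> DescriptorMatrix:
    """Apply block scaling ("comfa_std") or return the matrix unchanged."""
    if scheme == "none":
        return replace(dm)
    if scheme != "comfa_std":
        raise ValueError(f"unknown scaling scheme {scheme!r}")
    prep = _make_prep(
        dm.raw, dm.clash, dm.column_meta, np.arange(dm.n_rows), dm.sigma_min, scheme
    )
    values = prep.transform(dm.raw, dm.clash)
    weights: dict[str, float] = {}
    blocks = dm.column_blocks()
    for name in dict.fromkeys(blocks):
        sel = blocks == name
        weights[str(name)] = float(prep.scale[sel][0])
    return replace(
        dm,
        values=values,
        retained_mask=prep.retained,
        scheme=scheme,
        block_weights=weights,
    )


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model on the retained-column matrix."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, c)
    loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    scores: np.ndarray  # (n, c)
    coefficients: np.ndarray  # (p,), original (uncentered) column space
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept


def _nipals(
    X: np.ndarray, y: np.ndarray, c: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core NIPALS loop on centered data; returns (W, P, q, T)."""
    n, p = X.shape
    Xr = X.copy()
    yr = y.copy()
    W = np.zeros((p, c))
    P = np.zeros((p, c))
    q = np.zeros(c)
    T = np.zeros((n, c))
    for k in range(c):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # residual exhausted: freeze remaining components at zero
            W, P, q, T = W[:, : k or 1], P[:, : k or 1], q[: k or 1], T[:, : k or 1]
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q, T = W[:, : k or 1], P[:, : k or 1], q[: k or 1], T[:, : k or 1]
            break
        pvec = Xr.T @ t / tt
        qk = float(yr @ t) / tt
        Xr = Xr - np.outer(t, pvec)
        yr = yr - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pvec, qk, t
    return W, P, q, T


def nipals_pls(X: np.ndarray | DescriptorMatrix, y: Sequence[float], c: int) -> PLSModel:
    """Fit a PLS model with ``c`` latent variables by NIPALS.

    ``X`` may be a plain matrix or a (scaled) :class:`DescriptorMatrix`,
    in which case its retained columns are used.  Centering is internal;
    coefficients are returned in the (uncentered) input column space.
    """
    if isinstance(X, DescriptorMatrix):
        X = X.retained()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if c < 1:
        raise ValueError("at least one component is required")
    if c >= n:
        raise ValueError(f"components ({c}) must be fewer than rows ({n})")
    if np.ptp(y) == 0:
        raise ValueError("response y is constant")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T = _nipals(Xc, yc, c)
    c_eff = W.shape[1]
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=c_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coef,
        intercept=intercept,
    )


def predict(model: PLSModel, X: np.ndarray | DescriptorMatrix) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        X = X.retained()
    return model.predict(X)


def transform_like(
    dm: DescriptorMatrix, raw: np.ndarray, clash: np.ndarray | None = None
) -> np.ndarray:
    """Process new raw rows with the preprocessing fitted on ``dm``.

    Used to push external (test) compounds through a training-set
    descriptor matrix: clash cells are filled with training means and
    the training retained-mask and scale factors are applied.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if clash is None:
        clash = np.zeros(raw.shape, dtype=bool)
    prep = _make_prep(
        dm.raw, dm.clash, dm.column_meta, np.arange(dm.n_rows), dm.sigma_min, dm.scheme
    )
    return prep.transform(raw, np.atleast_2d(clash))[:, prep.retained]


def _coefs_per_component(Xc: np.ndarray, yc: np.ndarray, c_max: int) -> list[np.ndarray]:
    """Coefficient vectors (centered space) for c = 1..c_max from one fit."""
    W, P, q, _ = _nipals(Xc, yc, c_max)
    out = []
    for k in range(1, W.shape[1] + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        out.append(Wk @ np.linalg.solve(Pk.T @ Wk, qk))
    while len(out) < c_max:  # residual exhausted early: reuse last
        out.append(out[-1])
    return out


def loo_validate(
    dm: DescriptorMatrix,
    y: Sequence[float],
    c_max: int,
    scheme: Scheme | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Leave-one-out cross-validation over component counts 1..c_max.

    Filtering, clash filling and scaling are refitted inside every fold
    on the remaining rows.  Returns ``(q2_by_c, sep_by_c, opn)`` with
    Q² per the PRESS/SS convention about the full-set mean and
    SEP(c) = sqrt(PRESS/(n-c-1)); the optimal component count maximizes
    Q² with ties resolved toward fewer components.
    """
    y = np.asarray(y, dtype=float)
    n = dm.n_rows
    if n < 4:
        raise ValueError("LOO validation needs at least 4 rows")
    if c_max >= n - 1:
        raise ValueError(f"c_max ({c_max}) must be < n - 1 ({n - 1})")
    if scheme is None:
        scheme = dm.scheme
    press = np.zeros(c_max)
    for i in range(n):
        rows = np.array([r for r in range(n) if r != i])
        prep = _make_prep(dm.raw, dm.clash, dm.column_meta, rows, dm.sigma_min, scheme)
        Xtr = prep.transform(dm.raw[rows], dm.clash[rows])[:, prep.retained]
        Xte = prep.transform(dm.raw[i : i + 1], dm.clash[i : i + 1])[:, prep.retained]
        ytr = y[rows]
        x_mean = Xtr.mean(axis=0)
        y_mean = float(ytr.mean())
        coefs = _coefs_per_component(Xtr - x_mean, ytr - y_mean, c_max)
        for ci, coef in enumerate(coefs):
            pred = float(((Xte - x_mean) @ coef)[0]) + y_mean
            press[ci] += (pred - y[i]) ** 2
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    cs = np.arange(1, c_max + 1)
    sep = np.sqrt(press / (n - cs - 1))
    opn = int(np.argmax(q2)) + 1
    return q2, sep, opn


@dataclass
class ValidationStats:
    """The statistics conventionally reported for a lattice-field model."""

    q2: float | None = None
    sep: float | None = None
    r2_ncv: float | None = None
    see: float | None = None
    f_stat: float | None = None
    opn: int | None = None
    r2_pred: float | None = None
    press: float | None = None
    sd: float | None = None
    field_fractions: dict[str, float] | None = None


def model_summary(
    model: PLSModel, X: np.ndarray | DescriptorMatrix, y: Sequence[float]
) -> ValidationStats:
    """Non-cross-validated fit statistics: R²ncv, SEE, F.

    F uses the explained/unexplained variance ratio with the degrees of
    freedom that match the convention SEE = sqrt(RSS/(n-c-1)):
    F = [R²/(1-R²)] · (n-c-1)/c.  A perfect fit reports F = +inf.
    """
    if isinstance(X, DescriptorMatrix):
        X = X.retained()
    y = np.asarray(y, dtype=float)
    n = len(y)
    c = model.n_components
    if n <= c + 1:
        raise ValueError("too few rows for the fitted component count")
    fitted = model.predict(X)
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    see = float(np.sqrt(rss / (n - c - 1)))
    if rss == 0.0 or r2 >= 1.0:
        f = float("inf")
    else:
        f = (r2 / (1.0 - r2)) * (n - c - 1) / c
    return ValidationStats(r2_ncv=r2, see=see, f_stat=f, opn=c)


def f_statistic(r2: float, n: int, c: int) -> float:
    """F from (R², n rows, c components): [R²/(1-R²)]·(n-c-1)/c."""
    if not 0 <= r2 <= 1:
        raise ValueError("R² must lie in [0, 1]")
    if n <= c + 1:
        raise ValueError("need n > c + 1")
    if r2 == 1.0:
        return float("inf")
    return (r2 / (1.0 - r2)) * (n - c - 1) / c


def field_fractions(model: PLSModel, dm: DescriptorMatrix) -> dict[str, float]:
    """Per-block contribution fractions: sum |coeff|·std over each block.

    Computed on the matrix as fitted (i.e. after any block scaling), so
    the products are scale-invariant.
    """
    Xr = dm.retained()
    stds = Xr.std(axis=0)
    weights = np.abs(model.coefficients) * stds
    blocks = dm.column_blocks()[dm.retained_mask]
    total = float(weights.sum())
    if total == 0:
        raise ValueError("model has all-zero coefficients")
    out: dict[str, float] = {}
    for name in dict.fromkeys(dm.column_blocks()):
        sel = blocks == name
        out[str(name)] = float(weights[sel].sum()) / total
    return out


def q2_statistic(
    y_obs: Sequence[float], y_pred: Sequence[float], y_mean: float | None = None
) -> float:
    """Cross-validated Q² = 1 - Σ(pred-obs)² / Σ(obs-mean)²."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("y_obs and y_pred must be equal-length vectors of size >= 2")
    if np.ptp(y_obs) == 0:
        raise ValueError("observed activities are constant")
    if y_mean is None:
        y_mean = float(y_obs.mean())
    press = float(((y_pred - y_obs) ** 2).sum())
    ss = float(((y_obs - y_mean) ** 2).sum())
    return 1.0 - press / ss


def r2_pred(
    y_test_obs: Sequence[float], y_test_pred: Sequence[float], y_train_mean: float
) -> float:
    """External r²pred = 1 - PRESS/SD with SD about the training-set mean."""
    y_obs = np.asarray(y_test_obs, dtype=float)
    y_pred = np.asarray(y_test_pred, dtype=float)
    if y_obs.size < 2 or y_obs.shape != y_pred.shape:
        raise ValueError("test vectors must be equal-length with size >= 2")
    sd = float(((y_obs - y_train_mean) ** 2).sum())
    if sd == 0:
        raise ValueError("SD about the training mean is zero")
    press = float(((y_pred - y_obs) ** 2).sum())
    return 1.0 - press / sd


def split_train_test(
    activities: Sequence[float], n_test: int, seed: int
) -> np.ndarray:
    """Activity-stratified train/test labels (test uniform across quantile bins).

    Compounds are ordered by activity, cut into ``n_test`` near-equal
    bins, and one member per bin is drawn with a seeded generator.
    Deterministic for a given seed.
    """
    y = np.asarray(activities, dtype=float)
    n = y.size
    if n_test <= 0:
        raise ValueError("n_test must be positive")
    if n_test >= n:
        raise ValueError("n_test must be smaller than the number of compounds")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    bins = np.array_split(order, n_test)
    labels = np.array(["train"] * n, dtype=object)
    for b in bins:
        labels[rng.choice(b)] = "test"
    return labels


def endpoint_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Squared Pearson correlation between two activity endpoints."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (endpoint I, endpoint II) pairs")
    x, yv = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(yv) == 0:
        raise ValueError("an endpoint vector is constant")
    r = float(np.corrcoef(x, yv)[0, 1])
    return r * r
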