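"""Prediction of brain-wide cellular activity from subsampled predictors.

The central question: given a limited number of recording channels, are
single cells or coarse-grained macrovoxels more predictive of brain-wide
activity at cellular resolution?  Predictor sets are built from a
:class:`~obliquescale.core.CellTable` by random cell sampling, grid
voxelization (non-overlapping cubic bins, mean trace of member cells),
spatial shuffling (assemblies with randomized cell-to-coordinate
assignment) or principal components; targets are held-out cells.

Prediction is linear ridge regression with double cross-validation:
timepoints are split into train/validation/test (60/20/20%, block
structured: within every 5-minute block the first 3 min train, then 1 min
validation, 1 min test), the regularization α is chosen on the validation
set and performance is reported on the test set only.  The performance
measure is the variance-weighted average of per-cell R² = 1 − SS_res/SS_tot
over held-out timepoints.

Dimensionality is bounded with bi-cross-validated principal component
regression: components are computed on training cells and timepoints,
held-out cells are regressed on the component scores, and the held-out
(test-timepoint) R² as a function of component count gives the estimate —
the smallest count within 1% of the curve's maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellTable

__all__ = [
    "SplitScheme",
    "PredictorSet",
    "RegressionConfig",
    "split_timepoints",
    "voxelize_grid",
    "sample_predictors",
    "spatial_shuffle",
    "ridge_predict",
    "predict_brainwide",
    "pcr_dimensionality",
    "variance_weighted_r2",
]

BLOCK_S = 300.0
TRAIN_S = 180.0
VAL_S = 60.0


@dataclass(frozen=True)
class SplitScheme:
    """Disjoint train/validation/test timepoint index sets covering 0..T−1."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split sets overlap")

    @property
    def n_timepoints(self) -> int:
        return self.train.size + self.validation.size + self.test.size


@dataclass
class PredictorSet:
    """A trace matrix with provenance.

    ``provenance`` is one of 'cells', 'grid_voxels', 'shuffled_voxels',
    'principal_components'; ``member_ids`` lists the cells behind each
    predictor (disjoint for voxel provenance).
    """

    traces: np.ndarray  # (T, P)
    provenance: str
    member_ids: list[np.ndarray] = field(default_factory=list)
    voxel_size_um: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.traces.ndim != 2 or self.traces.shape[1] < 1:
            raise ValueError("traces must be (T, P) with P >= 1")

    @property
    def n_predictors(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class RegressionConfig:
    """Ridge / batching configuration.

    ``ridge_alpha_grid`` are multipliers of (mean predictor variance × T);
    the default is 7 log-spaced values spanning 1e−2…1e4.
    """

    ridge_alpha_grid: tuple[float, ...] = tuple(np.geomspace(1e-2, 1e4, 7))
    n_target_fraction: float = 0.10
    n_seeds: int = 10

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.ridge_alpha_grid):
            raise ValueError("ridge alphas must be positive")


def split_timepoints(T: int, rate: float = 1.0) -> SplitScheme:
    """Block-structured 60/20/20% train/validation/test split.

    Each 5-min block contributes its first 3 min to training, the next
    1 min to validation and the last 1 min to testing; a trailing partial
    block is divided in the same 60/20/20 proportions.
    """
    block = int(round(BLOCK_S * rate))
    if T < block:
        raise ValueError(f"need at least one {BLOCK_S:.0f}-s block ({block} samples), got {T}")
    tr, va, te = [], [], []
    for b0 in range(0, T, block):
        blk = np.arange(b0, min(b0 + block, T))
        L = blk.size
        n_tr = int(round(L * TRAIN_S / BLOCK_S))
        n_va = int(round(L * VAL_S / BLOCK_S))
        tr.append(blk[:n_tr])
        va.append(blk[n_tr : n_tr + n_va])
        te.append(blk[n_tr + n_va :])
    return SplitScheme(
        train=np.concatenate(tr), validation=np.concatenate(va), test=np.concatenate(te)
    )


def _table_dff(table: CellTable) -> tuple[np.ndarray, np.ndarray]:
    tab = table.passing()
    if tab.dff is None:
        raise ValueError("CellTable has no ΔF/F traces")
    dff = tab.dff
    if tab.valid_timepoints is not None:
        dff = dff[tab.valid_timepoints]
    return dff, tab.positions


def voxelize_grid(
    table: CellTable, size_um: float, cell_subset: np.ndarray | None = None
) -> PredictorSet:
    """Discretize the brain into non-overlapping cubic bins of side
    ``size_um`` anchored at the coordinate origin (half-open
    [k·size, (k+1)·size)); every non-empty bin becomes a predictor whose
    trace is the mean ΔF/F of its member cells."""
    if size_um <= 0:
        raise ValueError("voxel size must be positive")
    dff, pos = _table_dff(table)
    if cell_subset is not None:
        dff = dff[:, cell_subset]
        pos = pos[cell_subset]
    keys = np.floor(pos / size_um).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    P = uniq.shape[0]
    traces = np.zeros((dff.shape[0], P))
    counts = np.bincount(inverse, minlength=P)
    np.add.at(traces.T, inverse, dff.T)
    traces /= counts[None, :]
    members = [np.flatnonzero(inverse == p) for p in range(P)]
    if cell_subset is not None:
        members = [np.asarray(cell_subset)[m] for m in members]
    return PredictorSet(
        traces=traces, provenance="grid_voxels", member_ids=members, voxel_size_um=size_um
    )


def sample_predictors(
    source: PredictorSet | CellTable, count: int, seed: int
) -> PredictorSet:
    """Uniform sample of ``count`` predictors without replacement (cells of
    a table, or columns of a predictor set).  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    if isinstance(source, PredictorSet):
        P = source.n_predictors
        if count > P:
            raise ValueError(f"count {count} exceeds available predictors {P}")
        idx = rng.choice(P, size=count, replace=False)
        return PredictorSet(
            traces=source.traces[:, idx],
            provenance=source.provenance,
            member_ids=[source.member_ids[i] for i in idx] if source.member_ids else [],
            voxel_size_um=source.voxel_size_um,
            seed=seed,
        )
    dff, _ = _table_dff(source)
    if count > dff.shape[1]:
        raise ValueError(f"count {count} exceeds available cells {dff.shape[1]}")
    idx = rng.choice(dff.shape[1], size=count, replace=False)
    return PredictorSet(
        traces=dff[:, idx],
        provenance="cells",
        member_ids=[np.array([i]) for i in idx],
        seed=seed,
    )


def spatial_shuffle(table: CellTable, seed: int) -> CellTable:
    """Randomize the assignment between cell traces and cell coordinates
    (positions permuted relative to traces; both multisets unchanged)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_cells)
    return CellTable(
        positions=table.positions[perm],
        raw_traces=table.raw_traces,
        dff=table.dff,
        qc_snr=table.qc_snr,
        qc_pass=table.qc_pass,
        valid_timepoints=table.valid_timepoints,
        rate=table.rate,
    )


def variance_weighted_r2(r2: np.ndarray, variances: np.ndarray) -> float:
    """Average of per-cell R² weighted by each cell's (held-out) variance."""
    return float(np.average(np.asarray(r2, float), weights=np.asarray(variances, float)))


def _ridge_solve(XtX: np.ndarray, XtY: np.ndarray, alpha: float) -> np.ndarray:
    A = XtX + alpha * np.eye(XtX.shape[0])
    try:
        return np.linalg.solve(A, XtY)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular ridge system; use a positive regularization alpha"
        ) from err


def ridge_predict(
    predictors: PredictorSet | np.ndarray,
    targets: np.ndarray,
    split: SplitScheme,
    config: RegressionConfig = RegressionConfig(),
    raw_sd: float | None = None,
) -> dict:
    """Double-cross-validated ridge regression.

    The coefficient matrix is ``(XᵀX + αI)⁻¹ XᵀY`` on training timepoints;
    α is picked on the validation set (maximizing variance-weighted R²) and
    the reported per-target R² comes from the test set only.  Predictors
    and targets are centred with their *training* means; the predictor
    matrix is globally rescaled to the average standard deviation of the
    raw dataset (``raw_sd``, default: the targets' average training SD), so
    a single α grid serves all predictor types.

    Returns a dict with 'r2' (per-target, test), 'r2_weighted',
    'alpha', 'coef', and 'r2_validation'.
    """
    X = predictors.traces if isinstance(predictors, PredictorSet) else np.asarray(predictors)
    Y = np.asarray(targets, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("predictors and targets must share timepoints")
    tr, va, te = split.train, split.validation, split.test

    mu_x = X[tr].mean(axis=0, keepdims=True)
    mu_y = Y[tr].mean(axis=0, keepdims=True)
    Xc = X - mu_x
    Yc = Y - mu_y
    sd_x = Xc[tr].std(axis=0, ddof=0).mean()
    if raw_sd is None:
        raw_sd = Yc[tr].std(axis=0, ddof=0).mean()
    if sd_x > 0 and raw_sd > 0:
        Xc = Xc * (raw_sd / sd_x)

    Xtr = Xc[tr]
    XtX = Xtr.T @ Xtr
    XtY = Xtr.T @ Yc[tr]
    mean_var = np.trace(XtX) / XtX.shape[0] / max(len(tr), 1)
    alpha_scale = mean_var * len(tr)

    best = None
    for mult in config.ridge_alpha_grid:
        alpha = mult * alpha_scale
        W = _ridge_solve(XtX, XtY, alpha)
        pred_va = Xc[va] @ W
        resid = Yc[va] - pred_va
        ss_tot = ((Yc[va] - Yc[va].mean(axis=0)) ** 2).sum(axis=0)
        ss_res = (resid**2).sum(axis=0)
        ok = ss_tot > 0
        r2_va = np.where(ok, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 0.0)
        score = variance_weighted_r2(r2_va[ok], ss_tot[ok]) if ok.any() else -np.inf
        if best is None or score > best[0]:
            best = (score, alpha, W)

    score_va, alpha, W = best
    pred_te = Xc[te] @ W
    ss_tot = ((Yc[te] - Yc[te].mean(axis=0)) ** 2).sum(axis=0)
    ss_res = ((Yc[te] - pred_te) ** 2).sum(axis=0)
    ok = ss_tot > 0
    r2 = np.where(ok, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 0.0)
    return {
        "r2": r2,
        "r2_weighted": variance_weighted_r2(r2[ok], ss_tot[ok]),
        "alpha": alpha,
        "coef": W,
        "r2_validation": score_va,
    }


def _target_folds(n_cells: int, fraction: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of cells into ⌈1/fraction⌉ target folds."""
    n_folds = int(round(1.0 / fraction))
    perm = rng.permutation(n_cells)
    return [f for f in np.array_split(perm, n_folds) if f.size]


def predict_brainwide(
    table: CellTable,
    predictor_type: str = "cells",
    count: int | None = None,
    voxel_size_um: float | None = None,
    config: RegressionConfig = RegressionConfig(),
    split: SplitScheme | None = None,
    base_seed: int = 0,
    n_folds: int | None = None,
) -> pd.DataFrame:
    """Brain-wide prediction benchmark for one predictor specification.

    For each of ``config.n_seeds`` seeds, cells are partitioned into target
    folds (10% each by default); for every fold the remaining 90% of cells
    build the predictors (random cells, sampled grid voxels, or spatially
    shuffled voxels) and the fold's cells are predicted with
    :func:`ridge_predict`.  Returns one row per batch (seed × fold) with
    the variance-weighted test R².

    ``predictor_type``: 'cells' | 'voxels' | 'shuffled_voxels'.
    """
    dff, pos = _table_dff(table)
    T, N = dff.shape
    if split is None:
        split = split_timepoints(T, table.rate)
    raw_sd = (dff[split.train] - dff[split.train].mean(0)).std(axis=0).mean()
    rows = []
    for s in range(config.n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, s]))
        folds = _target_folds(N, config.n_target_fraction, rng)
        if n_folds is not None:
            folds = folds[:n_folds]
        for f, fold in enumerate(folds):
            others = np.setdiff1d(np.arange(N), fold)
            sub = CellTable(positions=pos[others], dff=dff[:, others], rate=table.rate)
            pred_seed = int(rng.integers(0, 2**31 - 1))
            if predictor_type == "cells":
                source: PredictorSet | CellTable = sub
            elif predictor_type == "voxels":
                if voxel_size_um is None:
                    raise ValueError("voxel_size_um required for voxel predictors")
                source = voxelize_grid(sub, voxel_size_um)
            elif predictor_type == "shuffled_voxels":
                if voxel_size_um is None:
                    raise ValueError("voxel_size_um required for shuffled voxels")
                source = voxelize_grid(spatial_shuffle(sub, pred_seed), voxel_size_um)
            else:
                raise ValueError(f"unknown predictor_type {predictor_type!r}")
            if count is not None:
                pset = sample_predictors(source, count, pred_seed)
            elif isinstance(source, PredictorSet):
                pset = source
            else:
                pset = sample_predictors(source, sub.n_cells, pred_seed)
            res = ridge_predict(pset, dff[:, fold], split, config, raw_sd=raw_sd)
            rows.append(
                {
                    "predictor_type": predictor_type,
                    "voxel_size_um": voxel_size_um,
                    "count": pset.n_predictors,
                    "seed": s,
                    "fold": f,
                    "r2_weighted": res["r2_weighted"],
                    "alpha": res["alpha"],
                }
            )
    return pd.DataFrame(rows)


def pcr_dimensionality(
    table: CellTable,
    split: SplitScheme | None = None,
    max_components: int = 600,
    target_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Bi-cross-validated principal component regression.

    Cells are split 90/10 into predictor and held-out sets; principal
    components are computed from the predictor cells on training
    timepoints; held-out cells are regressed on the leading component
    scores (ordinary least squares, scores are orthogonal on the training
    set) and evaluated on test timepoints.  Returns
    ``(dimensionality, r2_curve, r2_at_dim)`` where dimensionality is the
    smallest component count whose held-out variance-weighted R² is within
    1% of the curve's maximum.
    """
    dff, _ = _table_dff(table)
    T, N = dff.shape
    if split is None:
        split = split_timepoints(T, table.rate)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    n_targ = max(1, int(round(N * target_fraction)))
    targ, pred = perm[:n_targ], perm[n_targ:]
    M = int(min(max_components, len(split.train), pred.size))
    if M < 1:
        raise ValueError("max_components too small")

    Xp, Yt = dff[:, pred], dff[:, targ]
    mu_x = Xp[split.train].mean(axis=0, keepdims=True)
    mu_y = Yt[split.train].mean(axis=0, keepdims=True)
    Xtr = Xp[split.train] - mu_x
    Xte = Xp[split.test] - mu_x
    Ytr = Yt[split.train] - mu_y
    Yte = Yt[split.test] - mu_y

    U, S, Vt = np.linalg.svd(Xtr, full_matrices=False)
    S = S[:M]
    scores_tr = U[:, :M] * S
    scores_te = Xte @ Vt[:M].T
    beta = (scores_tr.T @ Ytr) / np.maximum(S**2, 1e-300)[:, None]

    pred_te = np.zeros_like(Yte)
    ss_tot = ((Yte - Yte.mean(axis=0)) ** 2).sum(axis=0)
    ok = ss_tot > 0
    curve = np.empty(M)
    for m in range(M):
        pred_te += np.outer(scores_te[:, m], beta[m])
        ss_res = ((Yte - pred_te) ** 2).sum(axis=0)
        r2 = 1.0 - ss_res[ok] / ss_tot[ok]
        curve[m] = variance_weighted_r2(r2, ss_tot[ok])
    r_max = curve.max()
    dim = int(np.argmax(curve >= 0.99 * r_max)) + 1
    return dim, curve, float(curve[dim - 1])
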