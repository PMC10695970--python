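"""Functional coupling across spatial scale.

Functional coupling (FC) between two cells is the Pearson correlation of
their ΔF/F traces.  This module characterises how FC depends on spatial
scale: the mean FC per Euclidean-distance bin and its power-law decay
exponent, per-cell neighbourhood FC maps, radius-voxelized traces (each
cell's trace replaced by the mean over all cells within a radius) and the
*secondary correlation* between cell-pair FC and the corresponding
radius-voxel-pair FC.

Distance bins are log-spaced (default 30 bins over 5–2000 μm) with explicit
underflow/overflow bins so every one of the n(n−1)/2 unique pairs is
counted; the power-law fit is a least-squares line on log(mean FC) vs
log(distance) over a fit range (default 20–1000 μm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .core import CellTable

__all__ = [
    "FCDistanceProfile",
    "correlation_vs_distance",
    "fit_power_law",
    "neighborhood_fc_map",
    "voxelize_by_radius",
    "fc_scale_comparison",
]

DEFAULT_BIN_RANGE_UM = (5.0, 2000.0)
DEFAULT_N_BINS = 30
DEFAULT_FIT_RANGE_UM = (20.0, 1000.0)


@dataclass
class FCDistanceProfile:
    """Mean pairwise correlation per distance bin, plus the power-law fit.

    ``bin_edges`` has length n_bins + 1 and includes an underflow bin
    starting at 0 and an overflow bin ending at infinity, so ``n_pairs``
    sums to n(n−1)/2.
    """

    bin_edges: np.ndarray  # μm
    mean_corr: np.ndarray  # per bin (NaN where empty)
    n_pairs: np.ndarray  # per bin
    exponent: float = np.nan
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE_UM

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        centers = np.sqrt(e[:-1] * e[1:])
        centers[0] = e[1] / 2 if not np.isfinite(centers[0]) or centers[0] == 0 else centers[0]
        if not np.isfinite(centers[-1]):
            centers[-1] = e[-2] * 1.5
        return centers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_lo_um": self.bin_edges[:-1],
                "d_hi_um": self.bin_edges[1:],
                "d_center_um": self.bin_centers,
                "mean_corr": self.mean_corr,
                "n_pairs": self.n_pairs,
            }
        )


def _dff_of(table: CellTable | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(table, CellTable):
        tab = table.passing()
        dff = tab.dff
        if dff is None:
            raise ValueError("CellTable has no ΔF/F traces")
        if tab.valid_timepoints is not None:
            dff = dff[tab.valid_timepoints]
        return dff, tab.positions
    return np.asarray(table, dtype=float), None


def _pairwise_corr(dff: np.ndarray) -> np.ndarray:
    """Full correlation matrix; zero-variance traces give 0 off-diagonal."""
    x = dff - dff.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    c = (x / sd_safe).T @ (x / sd_safe) / x.shape[0]
    bad = sd == 0
    if bad.any():
        c[bad, :] = 0.0
        c[:, bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def correlation_vs_distance(
    table: CellTable,
    bin_range_um: tuple[float, float] = DEFAULT_BIN_RANGE_UM,
    n_bins: int = DEFAULT_N_BINS,
    fit_range_um: tuple[float, float] = DEFAULT_FIT_RANGE_UM,
    max_pairs: int = 10_000_000,
    seed: int = 0,
) -> FCDistanceProfile:
    """Mean pairwise Pearson correlation per Euclidean-distance bin.

    All n(n−1)/2 unique non-identical pairs are used; above ``max_pairs``
    a seeded random subset of cells is taken so the pair count stays
    tractable (an unbiased estimator of the bin means).  The power-law
    exponent over ``fit_range_um`` is fitted and stored on the profile.
    """
    dff, pos = _dff_of(table)
    if pos is None or pos.shape[0] < 2:
        raise ValueError("need at least 2 QC-passing cells with positions")
    n = pos.shape[0]
    if n * (n - 1) // 2 > max_pairs:
        keep = int((1 + np.sqrt(1 + 8 * max_pairs)) / 2)
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=keep, replace=False)
        pos = pos[idx]
        dff = dff[:, idx]
        n = keep
    corr = _pairwise_corr(dff)
    iu = np.triu_indices(n, 1)
    c = corr[iu]
    d = pdist(pos)

    inner = np.geomspace(bin_range_um[0], bin_range_um[1], n_bins + 1)
    edges = np.concatenate([[0.0], inner, [np.inf]])
    which = np.digitize(d, edges) - 1  # 0..n_bins+1
    n_total = len(edges) - 1
    n_pairs = np.bincount(which, minlength=n_total)
    sums = np.bincount(which, weights=c, minlength=n_total)
    with np.errstate(invalid="ignore"):
        means = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    prof = FCDistanceProfile(
        bin_edges=edges, mean_corr=means, n_pairs=n_pairs, fit_range=fit_range_um
    )
    prof.exponent = fit_power_law(prof, fit_range_um)
    return prof


def fit_power_law(
    profile: FCDistanceProfile, fit_range_um: tuple[float, float] | None = None
) -> float:
    """Decay exponent of mean FC vs distance: the magnitude of the
    least-squares slope of log(mean corr) vs log(distance) over the fit
    range.  Bins with non-positive mean are dropped with a warning."""
    import warnings

    rng = fit_range_um or profile.fit_range
    centers = profile.bin_centers
    means = profile.mean_corr
    sel = (
        (centers >= rng[0])
        & (centers <= rng[1])
        & np.isfinite(means)
        & (profile.n_pairs > 0)
    )
    if np.any(sel & (means <= 0)):
        warnings.warn("dropping distance bins with non-positive mean correlation")
        sel &= means > 0
    if sel.sum() < 2:
        return float("nan")
    slope = np.polyfit(np.log(centers[sel]), np.log(means[sel]), 1)[0]
    return float(-slope)


def neighborhood_fc_map(
    table: CellTable, outer_um: float = 50.0, inner_um: float = 25.0
) -> np.ndarray:
    """Per-cell FC with its neighbourhood mean trace.

    For each cell: Pearson correlation between its trace and the mean trace
    of cells at distance within [inner, outer] μm (the inner exclusion
    guards against optical cross-talk).  Cells with an empty shell get NaN.
    """
    if not 0 < inner_um < outer_um:
        raise ValueError("need 0 < inner < outer radius")
    dff, pos = _dff_of(table)
    n = pos.shape[0]
    tree = cKDTree(pos)
    x = dff - dff.mean(axis=0, keepdims=True)
    out = np.full(n, np.nan)
    for i in range(n):
        nb = tree.query_ball_point(pos[i], outer_um)
        nb = [j for j in nb if j != i and np.linalg.norm(pos[j] - pos[i]) >= inner_um]
        if not nb:
            continue
        m = x[:, nb].mean(axis=1)
        denom = np.linalg.norm(x[:, i]) * np.linalg.norm(m)
        if denom > 0:
            out[i] = float(x[:, i] @ m / denom)
    return out


def voxelize_by_radius(table: CellTable, radius_um: float) -> np.ndarray:
    """Radius-voxelized traces: one trace per cell, the mean ΔF/F of all
    cells (including itself) within ``radius_um`` of its position.  With a
    radius below the minimum inter-cell spacing this returns the input
    traces."""
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    dff, pos = _dff_of(table)
    n = pos.shape[0]
    tree = cKDTree(pos)
    out = np.empty_like(dff)
    groups = tree.query_ball_point(pos, radius_um + 1e-12)
    for i in range(n):
        out[:, i] = dff[:, groups[i]].mean(axis=1)
    return out


def fc_scale_comparison(
    table: CellTable, radii_um: list[float], max_cells: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Secondary Pearson correlation between cell-pair FC values and the
    FC values of radius-voxel pairs centred on the same cells.

    Returns a DataFrame (radius_um, secondary_corr, n_pairs).  At radius
    ≈ 0 each voxel holds one cell, the two FC matrices coincide and the
    secondary correlation is 1; it decays as the radius grows.
    """
    dff, pos = _dff_of(table)
    n = pos.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    if n > max_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max_cells, replace=False)
        sub = CellTable(positions=pos[idx], dff=dff[:, idx], rate=getattr(table, "rate", 1.0))
        return fc_scale_comparison(sub, radii_um, max_cells=max_cells, seed=seed)
    cell_fc = _pairwise_corr(dff)
    iu = np.triu_indices(n, 1)
    cvals = cell_fc[iu]
    rows = []
    base = CellTable(positions=pos, dff=dff, rate=getattr(table, "rate", 1.0))
    for r in radii_um:
        vox = voxelize_by_radius(base, r)
        vvals = _pairwise_corr(vox)[iu]
        rows.append(
            {
                "radius_um": r,
                "secondary_corr": float(np.corrcoef(cvals, vvals)[0, 1]),
                "n_pairs": cvals.size,
            }
        )
    return pd.DataFrame(rows)
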