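"""Distortion and similarity of neuronal population geometry.

Any recording with fewer channels than neurons is a low-dimensional
embedding of the full population trajectory.  Two measures quantify how
subsampling or coarse-graining distorts that geometry:

* **Distortion stress** — pairwise Euclidean distances between all
  timepoints are computed in the reference space (``D``) and the reduced
  space (``D_red``); after the least-squares global rescaling
  ``k = ΣD·D_red / ΣD_red²`` the stress is ``Σ(D − k·D_red)² / ΣD²`` over
  unique off-diagonal pairs.  Zero iff the reduced distances match up to a
  global scale.
* **Representational similarity** — the Pearson correlation between the
  unique off-diagonal entries of the time-by-time correlation matrices of
  the two spaces.

The comparison protocol splits cells 50/50: the reference space is one
half; reduced spaces are subsampled cells or subsampled grid voxels built
from the held-out half, at matched predictor counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core import CellTable
from .prediction import sample_predictors, voxelize_grid

__all__ = [
    "distortion_stress",
    "representational_similarity",
    "geometry_scale_protocol",
    "cell_voxel_ratios",
]


def distortion_stress(reference: np.ndarray, reduced: np.ndarray) -> tuple[float, float]:
    """Distortion stress between timepoint geometries of two spaces.

    Both matrices are (T × n) trace matrices over the *same* timepoints
    (n may differ).  Returns ``(stress, k)``; stress is 0 and k = 1/c when
    ``reduced`` equals ``c · reference``.
    """
    ref = np.asarray(reference, dtype=float)
    red = np.asarray(reduced, dtype=float)
    if ref.shape[0] != red.shape[0]:
        raise ValueError("spaces must share the timepoint dimension")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    D = pdist(ref)
    Dr = pdist(red)
    denom = float(Dr @ Dr)
    k = float(D @ Dr) / denom if denom > 0 else 0.0
    ssd = float(D @ D)
    if ssd == 0:
        return 0.0, k
    stress = float(((D - k * Dr) ** 2).sum()) / ssd
    return stress, k


def _time_corr_offdiag(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique off-diagonal entries of the time-by-time correlation matrix;
    timepoints with constant population vectors are dropped with a warning.
    Returns (values, kept timepoint mask)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant-population timepoints")
    xk = x[keep]
    c = np.corrcoef(xk)
    iu = np.triu_indices(xk.shape[0], 1)
    return c[iu], keep


def representational_similarity(reference: np.ndarray, reduced: np.ndarray) -> float:
    """Pearson correlation between the off-diagonal time-by-time
    correlation structure of two spaces over the same timepoints."""
    ref = np.asarray(reference, dtype=float)
    red = np.asarray(reduced, dtype=float)
    if ref.shape[0] != red.shape[0]:
        raise ValueError("spaces must share the timepoint dimension")
    sd_a = ref.std(axis=1, ddof=0)
    sd_b = red.std(axis=1, ddof=0)
    keep = (sd_a > 0) & (sd_b > 0)
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant-population timepoints")
    ca = np.corrcoef(ref[keep])
    cb = np.corrcoef(red[keep])
    iu = np.triu_indices(int(keep.sum()), 1)
    return float(np.corrcoef(ca[iu], cb[iu])[0, 1])


def geometry_scale_protocol(
    table: CellTable,
    counts: list[int],
    voxel_sizes_um: list[float],
    seed: int = 0,
    n_seeds: int = 3,
    max_timepoints: int = 3000,
) -> pd.DataFrame:
    """Distortion and similarity of subsampled cells vs subsampled voxels.

    Per seed: cells are split 50/50; the reference space is one half; for
    every count K the reduced space is either K cells subsampled from the
    held-out half, or K grid voxels (per tested size) subsampled from the
    voxelization of the held-out half.  Returns a tidy DataFrame with one
    row per (seed, provenance, voxel size, count).  Above
    ``max_timepoints`` the timepoints are subsampled (seeded) to bound the
    T×T matrices.
    """
    from .prediction import _table_dff

    dff, pos = _table_dff(table)
    T, N = dff.shape
    rows = []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        if T > max_timepoints:
            t_idx = np.sort(rng.choice(T, size=max_timepoints, replace=False))
        else:
            t_idx = np.arange(T)
        perm = rng.permutation(N)
        ref_half, red_half = perm[: N // 2], perm[N // 2 :]
        reference = dff[np.ix_(t_idx, ref_half)]
        held = CellTable(positions=pos[red_half], dff=dff[:, red_half], rate=table.rate)

        for K in counts:
            if K > red_half.size:
                continue
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cells = sample_predictors(held, K, cell_seed).traces[t_idx]
            c_stress, _ = distortion_stress(reference, cells)
            c_sim = representational_similarity(reference, cells)
            rows.append(
                {
                    "seed": s,
                    "provenance": "cells",
                    "voxel_size_um": np.nan,
                    "count": K,
                    "distortion": c_stress,
                    "similarity": c_sim,
                }
            )
            for size in voxel_sizes_um:
                vox = voxelize_grid(held, size)
                if K > vox.n_predictors:
                    continue
                v = sample_predictors(vox, K, cell_seed).traces[t_idx]
                v_stress, _ = distortion_stress(reference, v)
                v_sim = representational_similarity(reference, v)
                rows.append(
                    {
                        "seed": s,
                        "provenance": "voxels",
                        "voxel_size_um": size,
                        "count": K,
                        "distortion": v_stress,
                        "similarity": v_sim,
                    }
                )
    return pd.DataFrame(rows)


def cell_voxel_ratios(report: pd.DataFrame) -> dict[str, float]:
    """Mean cell/voxel distortion and similarity ratios over matched
    (seed, count, voxel size) conditions of a geometry report."""
    cells = report[report.provenance == "cells"].set_index(["seed", "count"])
    vox = report[report.provenance == "voxels"]
    d_ratios, s_ratios = [], []
    for (s, size, K), grp in vox.groupby(["seed", "voxel_size_um", "count"]):
        if (s, K) not in cells.index:
            continue
        c = cells.loc[(s, K)]
        v = grp.iloc[0]
        if v.distortion > 0:
            d_ratios.append(c.distortion / v.distortion)
        if v.similarity != 0:
            s_ratios.append(c.similarity / v.similarity)
    return {
        "distortion_ratio": float(np.mean(d_ratios)) if d_ratios else float("nan"),
        "similarity_ratio": float(np.mean(s_ratios)) if s_ratios else float("nan"),
    }
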