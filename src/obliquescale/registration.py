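"""Volume-to-template motion correction.

The correction follows a coarse-to-fine locally-rigid scheme: volumes are
band-pass filtered with a difference of Gaussians (σ₀ = 2 px, σ₁ = 5 px) to
enhance high-frequency features and suppress residual faceplate grid
artefacts, chunked into non-overlapping blocks, and each block's 3D rigid
displacement is estimated by the peak of the normalized cross-correlation
with the template (sub-voxel via per-axis 3-point parabolic interpolation).
A global affine is least-squares fitted to the coarse displacement field;
after affine correction a finer block grid yields a dense non-rigid field by
trilinear interpolation of the block shifts.  The compound transform is
applied to the original volume with linear interpolation.  Timepoints where
registration failed are detected by thresholding the first difference of
the registration metric (global Pearson correlation to the template) at
1.5 standard deviations and are excluded from downstream trace analyses.

Default block sizes follow the acquisition-scale processing: coarse
[604, 192, 28] and fine [32, 32, 16] voxels (XYZ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DisplacementField",
    "bandpass_dog",
    "estimate_block_displacements",
    "fit_affine",
    "warp_volume",
    "register_volume",
    "register_series",
    "detect_failed_frames",
]

COARSE_BLOCK_XYZ = (604, 192, 28)
FINE_BLOCK_XYZ = (32, 32, 16)
MIN_BLOCK_PX = 8
MIN_PEAK_CORRELATION = 0.2


@dataclass
class DisplacementField:
    """Block-wise displacement estimates for one volume.

    ``block_centers`` and ``vectors`` are in voxel units, (z, y, x) order.
    ``affine`` is a 3×4 matrix mapping homogeneous voxel coordinates of the
    template to the moving volume.  ``metric`` is the global Pearson
    correlation between the (warped) volume and the template.
    """

    block_centers: np.ndarray  # (B, 3) voxels, z/y/x
    vectors: np.ndarray  # (B, 3) voxels, z/y/x
    peak_corr: np.ndarray  # (B,)
    affine: np.ndarray | None = None  # (3, 4)
    dense: np.ndarray | None = None  # (3, Nz, Ny, Nx)
    metric: float = np.nan

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        if self.affine is not None and abs(np.linalg.det(self.affine[:, :3])) <= 0:
            raise ValueError("affine must be non-singular")

    def valid(self) -> np.ndarray:
        """Blocks retained for fitting (peak correlation above threshold)."""
        return self.peak_corr >= MIN_PEAK_CORRELATION


def bandpass_dog(volume: np.ndarray, sigma0: float = 2.0, sigma1: float = 5.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass: G(σ0)∗v − G(σ1)∗v."""
    if not 0 < sigma0 < sigma1:
        raise ValueError("need sigma1 > sigma0 > 0")
    v = np.asarray(volume, dtype=float)
    return ndimage.gaussian_filter(v, sigma0) - ndimage.gaussian_filter(v, sigma1)


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom >= 0:  # not a maximum, or flat
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def _block_shift(
    block: np.ndarray, template: np.ndarray, max_shift: tuple[int, int, int] | None = None
) -> tuple[np.ndarray, float]:
    """Rigid 3D shift of `block` relative to `template`.

    Zero-padded FFT cross-correlation normalized per lag by the overlap
    volume (so the estimate is not biased toward zero lag); the peak is
    searched within ``max_shift`` (default: a quarter of the block per axis)
    and refined per axis with a 3-point parabola.  Returns (shift zyx,
    normalized peak correlation).
    """
    a = block - block.mean()
    b = template - template.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.zeros(3), 0.0
    shape = np.array(a.shape)
    if max_shift is None:
        max_shift = np.maximum(shape // 4, 1)
    else:
        max_shift = np.minimum(np.asarray(max_shift, int), shape - 1)
    pad = tuple(int(n + m) for n, m in zip(shape, max_shift))
    fa = np.fft.rfftn(a, s=pad, axes=range(a.ndim))
    fb = np.fft.rfftn(b, s=pad, axes=range(b.ndim))
    cc = np.fft.irfftn(fa * np.conj(fb), s=pad, axes=range(a.ndim))
    # reorder so axis lag runs -max_shift..max_shift at index 0..2*max_shift
    cc = np.concatenate([cc[-max_shift[0] :], cc[: max_shift[0] + 1]], axis=0)
    cc = np.concatenate([cc[:, -max_shift[1] :], cc[:, : max_shift[1] + 1]], axis=1)
    cc = np.concatenate([cc[:, :, -max_shift[2] :], cc[:, :, : max_shift[2] + 1]], axis=2)
    lags = [np.arange(-m, m + 1) for m in max_shift]
    overlap = (
        (shape[0] - np.abs(lags[0]))[:, None, None]
        * (shape[1] - np.abs(lags[1]))[None, :, None]
        * (shape[2] - np.abs(lags[2]))[None, None, :]
    ).astype(float)
    n_vox = float(shape.prod())
    ncc = cc * n_vox / (overlap * na * nb)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    shift = np.empty(3)
    for ax, p in enumerate(peak):
        if 0 < p < ncc.shape[ax] - 1:
            sl = list(peak)
            sl[ax] = p - 1
            ym = ncc[tuple(sl)]
            sl[ax] = p + 1
            yp = ncc[tuple(sl)]
            frac = _parabolic_offset(ym, ncc[peak], yp)
        else:
            frac = 0.0
        shift[ax] = lags[ax][p] + frac
    return shift, float(ncc[peak])


def estimate_block_displacements(
    volume: np.ndarray,
    template: np.ndarray,
    blocksize_xyz: tuple[int, int, int] = COARSE_BLOCK_XYZ,
) -> DisplacementField:
    """Per-block rigid displacements of ``volume`` relative to ``template``.

    Both inputs should already be band-passed and share a shape; blocks are
    non-overlapping, clipped to the volume, and blocks smaller than 8 px in
    any axis (after clipping the block grid) are rejected.
    """
    volume = np.asarray(volume, dtype=float)
    template = np.asarray(template, dtype=float)
    if volume.shape != template.shape:
        raise ValueError("volume and template shapes differ")
    bs = tuple(min(int(b), n) for b, n in zip(blocksize_xyz[::-1], volume.shape))
    if any(b < MIN_BLOCK_PX for b in bs):
        raise ValueError(f"block size {bs} (zyx) below {MIN_BLOCK_PX} px")
    centers, vectors, peaks = [], [], []
    nz, ny, nx = volume.shape
    for z0 in range(0, nz, bs[0]):
        for y0 in range(0, ny, bs[1]):
            for x0 in range(0, nx, bs[2]):
                sl = (
                    slice(z0, min(z0 + bs[0], nz)),
                    slice(y0, min(y0 + bs[1], ny)),
                    slice(x0, min(x0 + bs[2], nx)),
                )
                if any(s.stop - s.start < MIN_BLOCK_PX for s in sl):
                    continue
                shift, peak = _block_shift(volume[sl], template[sl])
                centers.append([(s.start + s.stop - 1) / 2.0 for s in sl])
                vectors.append(shift)
                peaks.append(peak)
    metric = _pearson(volume, template)
    return DisplacementField(
        block_centers=np.asarray(centers, dtype=float),
        vectors=np.asarray(vectors, dtype=float),
        peak_corr=np.asarray(peaks, dtype=float),
        metric=metric,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_affine(field: DisplacementField) -> np.ndarray:
    """Least-squares affine (3×4, zyx) mapping block centers to centers +
    displacement vectors.  Requires ≥ 4 non-collinear valid block centers."""
    keep = field.valid()
    centers = field.block_centers[keep]
    targets = centers + field.vectors[keep]
    if centers.shape[0] < 4:
        raise ValueError("need at least 4 valid blocks for an affine fit")
    X = np.hstack([centers, np.ones((centers.shape[0], 1))])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate block geometry: centers are coplanar/collinear")
    coef, *_ = np.linalg.lstsq(X, targets, rcond=None)
    return coef.T  # (3, 4)


def identity_affine() -> np.ndarray:
    return np.hstack([np.eye(3), np.zeros((3, 1))])


def dense_field_from_blocks(
    field: DisplacementField, shape: tuple[int, int, int]
) -> np.ndarray:
    """Dense per-voxel displacement by trilinear interpolation of fine block
    shifts on the block-center lattice, nearest-extrapolated at borders."""
    from scipy.interpolate import RegularGridInterpolator

    keep = field.valid()
    centers = field.block_centers
    # lattice coordinates per axis (blocks laid out on a regular grid)
    axes = [np.unique(centers[:, a]) for a in range(3)]
    grid_shape = tuple(len(a) for a in axes)
    vec = np.zeros(grid_shape + (3,))
    wsum = np.zeros(grid_shape)
    idx = [np.searchsorted(axes[a], centers[:, a]) for a in range(3)]
    for b in range(centers.shape[0]):
        if not keep[b]:
            continue
        vec[idx[0][b], idx[1][b], idx[2][b]] = field.vectors[b]
        wsum[idx[0][b], idx[1][b], idx[2][b]] = 1.0
    dense = np.zeros((3,) + shape)
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    # clamp to lattice bounds -> nearest extrapolation beyond border blocks
    pts = np.stack(
        [np.clip(coords[a], axes[a][0], axes[a][-1]) for a in range(3)], axis=-1
    )
    for a in range(3):
        interp = RegularGridInterpolator(axes, vec[..., a], method="linear")
        dense[a] = interp(pts)
    return dense


def warp_volume(
    volume: np.ndarray,
    affine: np.ndarray | None = None,
    fine_field: DisplacementField | None = None,
) -> np.ndarray:
    """Apply the compound transform (affine, then dense non-rigid) with
    trilinear interpolation; out-of-bounds voxels are filled with 0."""
    volume = np.asarray(volume, dtype=float)
    shape = volume.shape
    coords = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )
    pts = coords
    if affine is not None:
        flat = pts.reshape(3, -1)
        pts = (affine[:, :3] @ flat + affine[:, 3:4]).reshape((3,) + shape)
    if fine_field is not None:
        dense = fine_field.dense
        if dense is None:
            dense = dense_field_from_blocks(fine_field, shape)
        pts = pts + dense
    return ndimage.map_coordinates(volume, pts, order=1, mode="constant", cval=0.0)


def register_volume(
    volume: np.ndarray,
    template: np.ndarray,
    coarse_block_xyz: tuple[int, int, int] = COARSE_BLOCK_XYZ,
    fine_block_xyz: tuple[int, int, int] = FINE_BLOCK_XYZ,
    sigma0: float = 2.0,
    sigma1: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Full two-stage registration of one volume onto a template.

    Returns (warped volume, affine 3×4, fine displacement field with the
    post-warp Pearson metric)."""
    bp_t = bandpass_dog(template, sigma0, sigma1)
    bp_v = bandpass_dog(volume, sigma0, sigma1)

    coarse = estimate_block_displacements(bp_v, bp_t, coarse_block_xyz)
    try:
        affine = fit_affine(coarse)
    except ValueError:
        affine = identity_affine()
    after_affine = warp_volume(bp_v, affine=affine)

    fine = estimate_block_displacements(after_affine, bp_t, fine_block_xyz)
    fine.affine = affine
    warped = warp_volume(volume, affine=affine, fine_field=fine)
    fine.metric = _pearson(bandpass_dog(warped, sigma0, sigma1), bp_t)
    return warped, affine, fine


def register_series(
    movie: np.ndarray,
    template_index: int | None = None,
    **kwargs,
) -> tuple[np.ndarray, list[DisplacementField], np.ndarray]:
    """Register every timepoint of a (T, Z, Y, X) movie onto a template
    frame (default: the middle frame).  Returns the corrected movie, the
    per-timepoint fields and the per-timepoint metric series."""
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    if template_index is None:
        template_index = T // 2
    template = movie[template_index]
    out = np.empty_like(movie)
    fields: list[DisplacementField] = []
    metrics = np.empty(T)
    for t in range(T):
        warped, affine, fld = register_volume(movie[t], template, **kwargs)
        out[t] = warped
        fields.append(fld)
        metrics[t] = fld.metric
    return out, fields, metrics


def detect_failed_frames(metric_series: np.ndarray, n_std: float = 1.5) -> np.ndarray:
    """Flag timepoints where the registration metric jumps.

    A transition is above threshold when the absolute first difference of
    the metric exceeds ``n_std`` standard deviations of all first
    differences; the frame *after* each flagged transition is marked.
    Returns a boolean mask of length T (True = excluded).  Invariant to
    affine rescaling of the metric series.
    """
    m = np.asarray(metric_series, dtype=float)
    if m.size < 3:
        raise ValueError("need at least 3 timepoints")
    d = np.abs(np.diff(m))
    sd = d.std(ddof=0)
    mask = np.zeros(m.size, dtype=bool)
    if sd == 0:
        return mask
    mask[1:] = d > n_std * sd
    return mask
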