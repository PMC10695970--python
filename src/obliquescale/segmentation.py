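"""Nucleus segmentation and ΔF/F trace extraction.

Nuclei are detected on a *local correlation map* — the per-voxel mean
Pearson correlation of each voxel's time course with its 26-connected
neighbours — which highlights coherent blobs (cell nuclei) over shot noise.
The map is band-passed with a 3D difference of Gaussians (σ₀ = 1 px,
σ₁ = 4 px), local maxima are picked within spherical neighbourhoods of the
nucleus diameter (⌀ 5 μm) and thresholded globally.  Traces are the means
of Gaussian footprints (FWHM 5 μm) centred on the detected points.

ΔF/F uses a slow running baseline per trace: a median filter (7 s window),
then a minimum filter (101 s), then Gaussian smoothing (σ = 101 s); ΔF/F =
(F − baseline)/baseline in percent, mean-centred per cell.  Quality control
keeps cells whose spectral SNR — the ratio of average periodogram power
below 0.25 Hz to that at or above 0.25 Hz — is ≥ 1.3 and whose ΔF/F stays
within −100% … 2000%.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal
from scipy.cluster.hierarchy import leaves_list, ward
from scipy.spatial.distance import squareform
from skimage.feature import peak_local_max

from .core import CellTable, VolumeSeries

__all__ = [
    "running_baseline",
    "local_correlation_map",
    "detect_nuclei",
    "extract_traces",
    "compute_dff",
    "qc_filter",
    "order_traces",
    "segment_movie",
]

SNR_THRESHOLD = 1.3
DFF_RANGE_PCT = (-100.0, 2000.0)
SPLIT_FREQ_HZ = 0.25


def _as_movie_array(movie: VolumeSeries | np.ndarray) -> tuple[np.ndarray, tuple[float, float, float], float]:
    if isinstance(movie, VolumeSeries):
        return np.asarray(movie.data, dtype=float), movie.pitch, movie.rate
    arr = np.asarray(movie, dtype=float)
    return arr, (1.0, 1.0, 1.0), 1.0


def local_correlation_map(movie: VolumeSeries | np.ndarray) -> np.ndarray:
    """Mean Pearson correlation of each voxel with its 26 neighbours.

    Zero-variance voxels contribute correlation 0.  Border voxels average
    over their existing neighbours only.
    """
    data, _, _ = _as_movie_array(movie)
    if data.shape[0] < 10:
        raise ValueError("need at least 10 timepoints for a correlation map")
    T = data.shape[0]
    z = data - data.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, ddof=0)
    good = sd > 0
    z = np.where(good[None], z / np.where(good, sd, 1.0)[None], 0.0)

    acc = np.zeros(data.shape[1:])
    cnt = np.zeros(data.shape[1:])
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    # accumulate each unique offset once, crediting both voxels
    done = set()
    for off in offsets:
        if tuple(-o for o in off) in done:
            continue
        done.add(off)
        src = tuple(slice(max(0, -o), min(n, n - o)) for o, n in zip(off, data.shape[1:]))
        dst = tuple(slice(max(0, o), min(n, n + o)) for o, n in zip(off, data.shape[1:]))
        corr = np.einsum("t...,t...->...", z[(slice(None),) + src], z[(slice(None),) + dst]) / T
        acc[src] += corr
        acc[dst] += corr
        cnt[src] += 1
        cnt[dst] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / cnt, 0.0)
    return out


def detect_nuclei(
    corr_map: np.ndarray,
    pitch: tuple[float, float, float],
    sigma0: float = 1.0,
    sigma1: float = 4.0,
    radius_um: float = 2.5,
    threshold: float | None = None,
    threshold_percentile: float = 99.0,
) -> np.ndarray:
    """Detect nucleus centres on a (filtered) local-correlation map.

    The map is DoG-filtered (σ₀ = 1 px, σ₁ = 4 px), local maxima are found
    within spherical neighbourhoods of radius ``radius_um`` (⌀ 5 μm
    default — roughly one nucleus) and kept above a global threshold
    (absolute if given, else the ``threshold_percentile``-th percentile of
    the filtered map).  Returns positions in μm (x, y, z columns), at voxel
    centres.
    """
    m = np.asarray(corr_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("corr_map must be finite")
    filt = ndimage.gaussian_filter(m, sigma0) - ndimage.gaussian_filter(m, sigma1)
    px, py, pz = pitch
    # the spherical exclusion enforces one detection per nucleus: peaks
    # closer than the nucleus diameter (2 × radius) are duplicates
    sep = 2.0 * radius_um
    rz = max(1, int(round(sep / pz)))
    ry = max(1, int(round(sep / py)))
    rx = max(1, int(round(sep / px)))
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    footprint = ((zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2) <= 1.0
    thr = float(np.percentile(filt, threshold_percentile)) if threshold is None else threshold
    peaks = peak_local_max(
        filt, footprint=footprint, threshold_abs=thr, exclude_border=False
    )
    if peaks.size == 0:
        return np.zeros((0, 3))
    # sub-voxel refinement: intensity-weighted centroid of the positive DoG
    # response in a one-nucleus-radius neighbourhood around each peak
    refined = peaks.astype(float)
    for i, pk in enumerate(peaks):
        sl = tuple(
            slice(max(0, c - r), min(n, c + r + 1))
            for c, r, n in zip(pk, (rz, ry, rx), filt.shape)
        )
        w = np.clip(filt[sl], 0.0, None)
        tot = w.sum()
        if tot > 0:
            grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
            refined[i] = [float((g * w).sum() / tot) for g in grids]
    pos = (refined[:, ::-1] + 0.5) * np.array([px, py, pz])  # zyx -> xyz μm
    return pos


def extract_traces(
    movie: VolumeSeries | np.ndarray,
    positions_um: np.ndarray,
    footprint_fwhm_um: float = 5.0,
    pitch: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Weighted-mean time courses under Gaussian footprints (FWHM 5 μm).

    ``positions_um`` is (N, 3) x/y/z in μm; weights are normalized per cell.
    Positions outside the movie bounds raise, identifying the cell.
    """
    data, movie_pitch, _ = _as_movie_array(movie)
    if pitch is None:
        pitch = movie_pitch
    positions_um = np.atleast_2d(np.asarray(positions_um, dtype=float))
    T = data.shape[0]
    nz, ny, nx = data.shape[1:]
    px, py, pz = pitch
    bounds = np.array([nx * px, ny * py, nz * pz])
    sigma = footprint_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    traces = np.empty((T, positions_um.shape[0]))
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * py
    zs = (np.arange(nz) + 0.5) * pz
    flat = data.reshape(T, -1)
    for c, p in enumerate(positions_um):
        if np.any(p < 0) or np.any(p > bounds):
            raise ValueError(f"cell {c} at {p} μm lies outside the movie bounds {bounds}")
        wx = np.exp(-0.5 * ((xs - p[0]) / sigma) ** 2)
        wy = np.exp(-0.5 * ((ys - p[1]) / sigma) ** 2)
        wz = np.exp(-0.5 * ((zs - p[2]) / sigma) ** 2)
        w = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
        w = (w / w.sum()).ravel()
        traces[:, c] = flat @ w
    return traces


def running_baseline(
    raw: np.ndarray,
    rate: float,
    median_window_s: float = 7.0,
    minimum_window_s: float = 101.0,
    gaussian_sigma_s: float = 101.0,
) -> np.ndarray:
    """Slow fluorescence baseline: median (7 s) → minimum (101 s) →
    Gaussian (σ = 101 s) filtering along time, reflected boundaries."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    med_n = max(1, int(round(median_window_s * rate)))
    if med_n % 2 == 0:
        med_n += 1
    min_n = max(1, int(round(minimum_window_s * rate)))
    base = ndimage.median_filter(raw, size=(med_n, 1), mode="reflect")
    base = ndimage.minimum_filter(base, size=(min_n, 1), mode="reflect")
    return ndimage.gaussian_filter1d(base, sigma=gaussian_sigma_s * rate, axis=0, mode="reflect")


def compute_dff(
    raw: np.ndarray,
    rate: float,
    median_window_s: float = 7.0,
    minimum_window_s: float = 101.0,
    gaussian_sigma_s: float = 101.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent ΔF/F against a slow running baseline.

    The baseline of each trace is median (7 s) → minimum (101 s) →
    Gaussian (σ = 101 s) filtering, with reflected boundaries; ΔF/F =
    (F − baseline)/baseline × 100, then mean-centred per cell.  Windows are
    converted to samples at ``rate``; when timepoints have been excluded
    upstream the filters run on the gapped series with sample-index windows.

    Returns (dff, valid): cells whose baseline is not strictly positive
    anywhere are flagged invalid (their ΔF/F column is NaN).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    base = running_baseline(raw, rate, median_window_s, minimum_window_s, gaussian_sigma_s)
    valid = np.all(base > 0, axis=0)
    dff = np.full_like(raw, np.nan)
    if valid.any():
        b = base[:, valid]
        d = (raw[:, valid] - b) / b * 100.0
        dff[:, valid] = d - d.mean(axis=0, keepdims=True)
    return dff, valid


def spectral_snr(dff: np.ndarray, rate: float, split_hz: float = SPLIT_FREQ_HZ) -> np.ndarray:
    """Ratio of average periodogram power below ``split_hz`` to power at or
    above it, per trace (mean removed before the periodogram)."""
    if rate <= 2 * split_hz:
        raise ValueError(f"rate must exceed {2 * split_hz} Hz for a {split_hz} Hz split")
    x = np.asarray(dff, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    freqs, pxx = signal.periodogram(x - x.mean(axis=0), fs=rate, axis=0)
    lo = (freqs > 0) & (freqs < split_hz)
    hi = freqs >= split_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pxx[lo].mean(axis=0) / pxx[hi].mean(axis=0)
    return ratio


def qc_filter(
    dff: np.ndarray, rate: float, snr_threshold: float = SNR_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell QC: spectral SNR ≥ threshold AND ΔF/F within −100%…2000%.

    Returns (snr, passing) arrays.  NaN columns (invalid baselines) fail.
    """
    x = np.asarray(dff, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    finite = np.all(np.isfinite(x), axis=0)
    snr = np.full(x.shape[1], np.nan)
    if finite.any():
        snr[finite] = spectral_snr(x[:, finite], rate)
    in_range = finite & np.all(
        np.where(np.isfinite(x), (x >= DFF_RANGE_PCT[0]) & (x <= DFF_RANGE_PCT[1]), True),
        axis=0,
    )
    passing = finite & in_range & (snr >= snr_threshold)
    return snr, passing


def order_traces(dff: np.ndarray) -> np.ndarray:
    """1D display ordering of traces by Ward clustering on correlation
    distance (1 − r); returns the dendrogram leaf order."""
    x = np.asarray(dff, dtype=float)
    if x.ndim == 1 or x.shape[1] == 1:
        return np.array([0])
    n = x.shape[1]
    c = np.corrcoef(x.T)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    dist = squareform(1.0 - c, checks=False)
    link = ward(dist)
    return np.asarray(leaves_list(link))


def segment_movie(
    movie: VolumeSeries,
    threshold: float | None = None,
    threshold_percentile: float = 99.0,
    valid_timepoints: np.ndarray | None = None,
) -> CellTable:
    """Full segmentation of a movie into a :class:`CellTable`.

    Excluded (failed-registration) timepoints are dropped before trace
    baseline filtering, per ``valid_timepoints``.
    """
    data = np.asarray(movie.data, dtype=float)
    if valid_timepoints is not None:
        work = VolumeSeries(
            data=data[valid_timepoints],
            pitch=movie.pitch,
            sheared=movie.sheared,
            geometry=movie.geometry,
            rate=movie.rate,
        )
    else:
        work = movie
    cmap = local_correlation_map(work)
    pos = detect_nuclei(
        cmap, movie.pitch, threshold=threshold, threshold_percentile=threshold_percentile
    )
    if pos.shape[0] == 0:
        return CellTable(positions=np.zeros((0, 3)), rate=movie.rate)
    raw = extract_traces(work, pos)
    dff, valid_baseline = compute_dff(raw, movie.rate)
    snr, passing = qc_filter(dff, movie.rate)
    passing &= valid_baseline
    order = order_traces(np.nan_to_num(dff, nan=0.0))
    vt = None
    if valid_timepoints is not None:
        # re-embed the gapped traces at full length; excluded frames are NaN
        # ("white bands") and masked out again by downstream consumers
        vt = np.asarray(valid_timepoints, dtype=bool)
        T = vt.size
        raw_full = np.full((T, raw.shape[1]), np.nan)
        dff_full = np.full((T, dff.shape[1]), np.nan)
        raw_full[vt] = raw
        dff_full[vt] = dff
        raw, dff = raw_full, dff_full
    return CellTable(
        positions=pos,
        raw_traces=raw,
        dff=dff,
        qc_snr=snr,
        qc_pass=passing,
        order_1d=order,
        valid_timepoints=vt,
        rate=movie.rate,
    )
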