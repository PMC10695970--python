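"""Synthetic populations and movies with the statistical structure of
brain-wide calcium imaging.

The generator emulates the deposited recordings the analysis modules were
built for: tens of thousands of nuclear-GCaMP6s-labelled neurons recorded at
1 Hz for ~38 min, whose mean pairwise correlation decays with distance as a
power law (exponent ≈ 0.28 over 10–1000 μm) and whose shared activity spans
~400 latent dimensions.

Model
-----
Cell positions are sampled uniformly inside an ellipsoidal brain mask.
Activity is a linear latent-factor model: ``K`` temporally smooth latent
time series (white noise convolved with an exponential calcium kernel,
decay ``calcium_tau``) are mixed through spatial loading maps.  Each loading
map is a Gaussian random field of a given correlation length, realised with
random Fourier features; factors are distributed over log-spaced correlation
lengths whose amplitude weights are calibrated (once, by non-negative least
squares) so the expected pairwise correlation follows ``d^(−decay_exponent)``
over 10–1000 μm.  White Gaussian noise in ΔF/F units is added per cell.

Movies render each nucleus as a 3D Gaussian blob on the sheared acquisition
grid, modulated by its clean trace, with a multiplicative faceplate pattern,
additive camera background and Poisson + read noise (camera gain ≈ 5
e−/count), and optional rigid/affine motion with recorded ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import nnls
from scipy.signal import lfilter

from .core import CellTable, VolumeSeries
from .preprocess import ShearGeometry

__all__ = [
    "PopulationConfig",
    "GroundTruth",
    "MovieNoiseModel",
    "generate_cell_positions",
    "generate_population_activity",
    "generate_volume_movie",
]

# Mean per-cell standard deviation of the clean ΔF/F signal, in percent.
# Spontaneous nuclear GCaMP6s activity at 1 Hz typically shows tens of
# percent ΔF/F modulation; 25% is a representative value.
CLEAN_STD_PCT = 25.0

# Gaussian random field correlation lengths available to the loading maps
# (μm, log-spaced).  The span brackets the 10–1000 μm range over which the
# power-law decay is reproduced.
_GRF_LENGTHS_UM = np.geomspace(5.0, 5000.0, 16)

# Random Fourier features per latent factor; more features make each loading
# map closer to a Gaussian process draw of the target covariance.
_N_RFF = 8

# Minimum factor count per correlation length.  Long-length fields are
# nearly constant over the brain, so they offer few independent spatial
# degrees of freedom; allocating factors proportional to variance weight
# would waste latent dimensions on collinear fields, while allocating only
# dof-many makes the realised long-range correlation a high-variance draw.
# A floor of 8, combined with pinning each scale's realised variance (below),
# keeps the correlation decay reproducible while preserving ~n_latent
# effective predictive dimensions.
_MIN_FACTORS_PER_SCALE = 8


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of a synthetic cell population.

    Parameters
    ----------
    n_cells : int
        Number of cells (the recordings hold 17k–41k per animal; the
        desk-scale default is 3,000).
    duration : float
        Recording duration in seconds (default 2280 s = 38 min).
    rate : float
        Volume rate in Hz (default 1).
    n_latent : int
        Number of latent factors (default 400).
    decay_exponent : float
        Target power-law exponent of correlation-vs-distance decay
        (default 0.28).
    calcium_tau : float
        Calcium indicator decay time constant in seconds (default 4,
        GCaMP6s-like).
    noise_sd : float
        White noise standard deviation in percent ΔF/F (default 15).
    private_fraction : float
        Fraction of the clean signal variance that is cell-private
        (temporally smooth activity uncorrelated between cells, default
        0.2).  Shared (latent-factor) activity carries the remainder, so
        cross-validated analyses can explain at most roughly the shared
        fraction of the total variance — matching recordings where much of
        each cell's activity is not predictable from the rest of the
        population.
    brain_extent : tuple of float
        Bounding box of the ellipsoidal brain mask in μm
        (default 2200 × 1200 × 650).
    seed : int
        Seed for all randomness in the generator.
    """

    n_cells: int = 3000
    duration: float = 2280.0
    rate: float = 1.0
    n_latent: int = 400
    decay_exponent: float = 0.28
    calcium_tau: float = 4.0
    noise_sd: float = 15.0
    private_fraction: float = 0.2
    brain_extent: tuple[float, float, float] = (2200.0, 1200.0, 650.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if self.calcium_tau <= 0:
            raise ValueError("calcium_tau must be > 0")
        if self.rate <= 0 or self.duration < 0:
            raise ValueError("rate must be > 0 and duration >= 0")
        if not 0.0 <= self.private_fraction < 1.0:
            raise ValueError("private_fraction must lie in [0, 1)")
        nt = self.duration * self.rate
        if abs(nt - round(nt)) > 1e-9:
            raise ValueError(
                f"duration*rate must be an integer number of timepoints, got {nt}"
            )

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration * self.rate))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["brain_extent"] = list(self.brain_extent)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "brain_extent" in d:
            d["brain_extent"] = tuple(d["brain_extent"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Ground truth of a synthetic population."""

    positions: np.ndarray  # (N, 3) μm
    latent_factors: np.ndarray  # (T, K), unit variance, temporally smooth
    loadings: np.ndarray  # (K, N)
    clean_traces: np.ndarray  # (T, N), percent ΔF/F
    noisy_traces: np.ndarray  # (T, N), percent ΔF/F
    config: PopulationConfig

    def to_cell_table(self, noisy: bool = True) -> CellTable:
        traces = self.noisy_traces if noisy else self.clean_traces
        return CellTable(
            positions=self.positions,
            dff=traces - traces.mean(axis=0, keepdims=True),
            rate=self.config.rate,
        )

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("traces", data=self.noisy_traces)
            g = f.create_group("truth")
            g.create_dataset("latent_factors", data=self.latent_factors)
            g.create_dataset("loadings", data=self.loadings)
            g.create_dataset("clean_traces", data=self.clean_traces)
            f.attrs["config"] = yaml.safe_dump(
                {**asdict(self.config), "brain_extent": list(self.config.brain_extent)}
            )


def generate_cell_positions(config: PopulationConfig) -> np.ndarray:
    """Sample ``n_cells`` positions uniformly inside an ellipsoidal brain
    mask inscribed in ``brain_extent``.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    extent = np.asarray(config.brain_extent, dtype=float)
    if n == 0:
        return np.zeros((0, 3))
    semi = extent / 2.0
    out = np.zeros((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 16, 3))
        ok = (cand**2).sum(axis=1) <= 1.0
        cand = cand[ok]
        take = min(cand.shape[0], n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out * semi + semi  # into [0, extent]


def calibrate_scale_weights(
    decay_exponent: float,
    lengths_um: np.ndarray = _GRF_LENGTHS_UM,
    d_range: tuple[float, float] = (10.0, 1500.0),
) -> np.ndarray:
    """Per-correlation-length variance weights reproducing a power law.

    Solves the non-negative least-squares problem
    ``Σ_s w_s exp(−d²/(2ℓ_s²)) ≈ (d/10 μm)^(−exponent)`` on a log-spaced
    distance grid, so a mixture of Gaussian-covariance random fields at the
    stored correlation lengths yields the requested correlation decay.
    A zero exponent returns a single global (largest-length) component.
    """
    if decay_exponent == 0:
        w = np.zeros(len(lengths_um))
        w[-1] = 1.0
        return w
    d = np.geomspace(d_range[0], d_range[1], 80)
    A = np.exp(-(d[:, None] ** 2) / (2.0 * lengths_um[None, :] ** 2))
    target = (d / d_range[0]) ** (-decay_exponent)
    # weight the residuals evenly in log-distance (grid already log-spaced)
    w, _ = nnls(A, target)
    if w.sum() <= 0:
        raise RuntimeError("weight calibration failed")
    return w


def _spatial_dof(lengths_um: np.ndarray, extent: tuple[float, float, float]) -> np.ndarray:
    """Approximate spatial degrees of freedom of a Gaussian random field of
    each correlation length over the brain bounding box: Π_axis (1 + L/ℓ)."""
    ext = np.asarray(extent, dtype=float)
    dof = np.prod(1.0 + ext[:, None] / lengths_um[None, :], axis=0)
    return np.maximum(1, np.round(dof)).astype(int)


def _allocate_factors(
    weights: np.ndarray,
    lengths_um: np.ndarray,
    extent: tuple[float, float, float],
    n_latent: int,
) -> np.ndarray:
    """Integer factor counts per correlation length, summing to n_latent.

    Counts follow the variance weights (so individual factors carry
    comparable variance) but are capped at
    ``max(_MIN_FACTORS_PER_SCALE, spatial dof)``: beyond its spatial degrees
    of freedom a scale only produces collinear loading maps that add no
    effective dimensionality.  Freed capacity is redistributed to scales
    with room, by weight.
    """
    dof = _spatial_dof(lengths_um, extent)
    cap = np.maximum(_MIN_FACTORS_PER_SCALE, dof)
    counts = np.zeros(len(weights), dtype=int)
    # highest-averages apportionment: next factor goes to the scale with the
    # largest per-factor weight share, among scales with capacity left
    for _ in range(n_latent):
        share = np.where(counts < cap, weights / (counts + 1), -np.inf)
        if np.all(np.isinf(share) & (share < 0)):  # all capped: spill over
            share = weights / (counts + 1)
        counts[np.argmax(share)] += 1
    return counts


def _calcium_filter(x: np.ndarray, tau_samples: float) -> np.ndarray:
    """Causal exponential (AR(1)) calcium kernel along axis 0."""
    a = np.exp(-1.0 / tau_samples)
    return lfilter([1.0], [1.0, -a], x, axis=0)


def generate_population_activity(
    positions: np.ndarray, config: PopulationConfig
) -> GroundTruth:
    """Latent-factor activity for a set of cell positions.

    Returns a :class:`GroundTruth` whose noisy traces realise the configured
    correlation-distance decay, latent dimensionality and calcium kinetics.
    Reproducible given ``config.seed``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] == 0:
        raise ValueError("positions must be non-empty")
    T, K, N = config.n_timepoints, config.n_latent, positions.shape[0]
    if K > T:
        raise ValueError(f"n_latent ({K}) must not exceed n_timepoints ({T})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    weights = calibrate_scale_weights(config.decay_exponent)
    active = weights > 0
    lengths = _GRF_LENGTHS_UM[active]
    weights = weights[active]
    counts = _allocate_factors(weights, lengths, config.brain_extent, K)

    # loading maps: random-Fourier-feature Gaussian random fields.  Each
    # scale's block is rescaled so its realised total variance equals its
    # calibrated weight; for long correlation lengths (few spatial dof) this
    # pins the long-range correlation plateau that would otherwise be a
    # high-variance draw.
    loadings = np.zeros((K, N))
    row = 0
    for ell, w, m in zip(lengths, weights, counts):
        if m == 0:
            continue
        block = np.empty((m, N))
        for q in range(m):
            omega = rng.normal(0.0, 1.0 / ell, size=(3, _N_RFF))
            phase = rng.uniform(0.0, 2.0 * np.pi, size=_N_RFF)
            feats = np.cos(positions @ omega + phase)  # (N, _N_RFF)
            block[q] = feats @ np.full(_N_RFF, np.sqrt(2.0 / _N_RFF))
        mean_sq = (block**2).mean()
        block *= np.sqrt(w / (m * mean_sq))
        loadings[row : row + m] = block
        row += m

    # temporally smooth unit-variance latents: calcium-filtered white noise
    tau_samples = config.calcium_tau * config.rate
    latents = _calcium_filter(rng.normal(size=(T, K)), tau_samples)
    latents -= latents.mean(axis=0, keepdims=True)
    sd = latents.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    latents /= sd

    shared = latents @ loadings
    mean_var = (shared.var(axis=0, ddof=0)).mean()
    if mean_var > 0:
        shared *= CLEAN_STD_PCT * np.sqrt((1.0 - config.private_fraction) / mean_var)
    # cell-private smooth activity: calcium-filtered noise, uncorrelated
    # between cells; scales correlations down uniformly (the decay exponent
    # is untouched) and bounds the population-explainable variance
    if config.private_fraction > 0:
        priv = _calcium_filter(rng.normal(size=(T, N)), tau_samples)
        priv -= priv.mean(axis=0, keepdims=True)
        psd = priv.std(axis=0, ddof=0)
        psd[psd == 0] = 1.0
        priv *= CLEAN_STD_PCT * np.sqrt(config.private_fraction) / psd
        clean = shared + priv
    else:
        clean = shared
    noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
    return GroundTruth(
        positions=positions,
        latent_factors=latents,
        loadings=loadings,
        clean_traces=clean,
        noisy_traces=noisy,
        config=config,
    )


def gaussian_psf(
    pitch: tuple[float, float, float],
    fwhm_um: tuple[float, float, float] = (2.8, 2.4, 13.2),
    n_sigma: float = 3.0,
) -> np.ndarray:
    """Separable Gaussian PSF on a voxel grid, unit sum.

    Stands in for a bead-average PSF; default FWHMs follow the measured
    system resolution (x, y, z).
    """
    px, py, pz = pitch
    fx, fy, fz = fwhm_um
    k = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sig = np.array([fz / k / pz, fy / k / py, fx / k / px])  # voxels, zyx
    half = np.maximum(1, np.ceil(n_sigma * sig).astype(int))
    zz, yy, xx = np.meshgrid(
        *[np.arange(-h, h + 1, dtype=float) for h in half], indexing="ij"
    )
    psf = np.exp(-0.5 * ((zz / sig[0]) ** 2 + (yy / sig[1]) ** 2 + (xx / sig[2]) ** 2))
    return psf / psf.sum()


@dataclass(frozen=True)
class MovieNoiseModel:
    """Camera and faceplate noise model for rendered movies.

    ``gain`` is electrons per camera count (the acquisition LUT fixes it to
    ≈5 e−/count); Poisson noise acts on electrons, read noise on counts.
    The faceplate imprints a multiplicative quasi-periodic pattern at the
    fiber pitch onto every frame.
    """

    background: float = 10.0  # additive camera background, counts
    gain: float = 5.0  # e− per count
    read_noise: float = 1.5  # counts RMS
    pattern_amplitude: float = 0.08  # relative faceplate modulation
    pattern_period_px: float = 4.0  # fiber pitch on the camera, px


def _faceplate_pattern(ny: int, nx: int, noise: MovieNoiseModel, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    k = 2.0 * np.pi / noise.pattern_period_px
    phase_y, phase_x = rng.uniform(0, 2 * np.pi, 2)
    pat = 1.0 + noise.pattern_amplitude * 0.5 * (
        np.cos(k * yy + phase_y) + np.cos(k * xx + phase_x)
    )
    return pat


def generate_volume_movie(
    truth: GroundTruth,
    shear: ShearGeometry,
    noise_model: MovieNoiseModel | None = None,
    shape: tuple[int, int, int] = (16, 48, 64),
    blob_fwhm_lateral: float = 5.0,
    blob_fwhm_axial: float = 10.0,
    base_brightness: float = 50.0,
    motion_amplitude_um: float = 0.0,
    seed: int | None = None,
) -> VolumeSeries:
    """Render a population as a (sheared) volumetric movie.

    Nuclei are 3D Gaussian blobs (default lateral FWHM 5 μm) at the truth
    positions, with brightness ``base_brightness·(1 + clean ΔF/F)``.  The
    grid is the sheared acquisition grid of ``shear`` (plane k displaced by
    ``slope_s·k`` native y pixels); with ``slope_s == 0`` the grid is
    orthogonal.  Optional rigid motion is a smooth seeded random walk with
    the requested RMS amplitude, returned in ``VolumeSeries.motion``.

    ``shape`` is (Nz, Ny, Nx); a zero-cell truth yields background + noise
    only.
    """
    noise = noise_model or MovieNoiseModel()
    cfg = truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 2])
    )
    nz, ny, nx = shape
    px, py, pz = shear.native_pitch
    s = float(shear.slope_s)
    T = truth.clean_traces.shape[0] if truth.clean_traces.size else cfg.n_timepoints
    N = truth.positions.shape[0]

    sig_l = blob_fwhm_lateral / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_z = blob_fwhm_axial / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    if motion_amplitude_um > 0:
        steps = rng.normal(0.0, 1.0, size=(T, 3))
        walk = np.cumsum(steps, axis=0)
        walk -= walk.mean(axis=0, keepdims=True)
        rms = walk.std()
        motion = walk / (rms if rms > 0 else 1.0) * motion_amplitude_um
    else:
        motion = np.zeros((T, 3))

    pattern = _faceplate_pattern(ny, nx, noise, rng)
    brightness = base_brightness * np.clip(1.0 + truth.clean_traces / 100.0, 0.0, None)

    xs = (np.arange(nx) + 0.5) * px
    zs = (np.arange(nz) + 0.5) * pz
    data = np.empty((T, nz, ny, nx), dtype=np.float32)
    for t in range(T):
        vol = np.zeros((nz, ny, nx))
        pos_t = truth.positions + motion[t]
        for c in range(N):
            x0, y0, z0 = pos_t[c]
            ks = np.flatnonzero(np.abs(zs - z0) < 3.5 * sig_z)
            if ks.size == 0:
                continue
            ix = np.flatnonzero(np.abs(xs - x0) < 3.5 * sig_l)
            if ix.size == 0:
                continue
            gx = np.exp(-0.5 * ((xs[ix] - x0) / sig_l) ** 2)
            b = brightness[t, c]
            for k in ks:
                gz = np.exp(-0.5 * ((zs[k] - z0) / sig_z) ** 2)
                # sheared grid: row j of plane k sits at y = (j+0.5+s*k)*py
                ys = (np.arange(ny) + 0.5 + s * k) * py
                jy = np.flatnonzero(np.abs(ys - y0) < 3.5 * sig_l)
                if jy.size == 0:
                    continue
                gy = np.exp(-0.5 * ((ys[jy] - y0) / sig_l) ** 2)
                vol[k, jy[:, None], ix[None, :]] += b * gz * gy[:, None] * gx[None, :]
        frame = vol * pattern[None, :, :] + noise.background
        electrons = np.clip(frame, 0.0, None) * noise.gain
        noisy = rng.poisson(electrons) / noise.gain
        noisy = noisy + rng.normal(0.0, noise.read_noise, size=noisy.shape)
        data[t] = noisy.astype(np.float32)

    return VolumeSeries(
        data=data,
        pitch=shear.native_pitch,
        sheared=s != 0.0,
        geometry=shear,
        rate=cfg.rate,
        motion=motion if motion_amplitude_um > 0 else None,
    )
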