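"""Ground-truth generator: positions, activity statistics, movie rendering."""

import numpy as np
import pytest

from obliquescale.preprocess import ShearGeometry
from obliquescale.synthetic import (
    MovieNoiseModel,
    PopulationConfig,
    calibrate_scale_weights,
    gaussian_psf,
    generate_cell_positions,
    generate_population_activity,
    generate_volume_movie,
)


class TestPopulationConfig:
    def test_defaults_match_study_conditions(self):
        cfg = PopulationConfig()
        assert cfg.n_cells == 3000
        assert cfg.n_timepoints == 2280  # 38 min at 1 Hz
        assert cfg.n_latent == 400
        assert cfg.decay_exponent == 0.28
        assert cfg.calcium_tau == 4.0
        assert cfg.brain_extent == (2200.0, 1200.0, 650.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cells": -1},
            {"decay_exponent": -0.1},
            {"calcium_tau": 0.0},
            {"duration": 100.5, "rate": 1.0},
            {"private_fraction": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = PopulationConfig(n_cells=10, duration=50.0, seed=9)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert PopulationConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


class TestCellPositions:
    def test_zero_cells_empty(self):
        assert generate_cell_positions(PopulationConfig(n_cells=0)).shape == (0, 3)

    def test_points_inside_ellipsoid(self):
        cfg = PopulationConfig(n_cells=3000, seed=13)
        pos = generate_cell_positions(cfg)
        semi = np.array(cfg.brain_extent) / 2.0
        r2 = (((pos - semi) / semi) ** 2).sum(axis=1)
        assert pos.shape == (3000, 3)
        assert np.all(r2 <= 1.0 + 1e-12)

    def test_supports_study_scale_counts(self):
        cfg = PopulationConfig(n_cells=41_000, seed=1)
        pos = generate_cell_positions(cfg)
        assert pos.shape == (41_000, 3)

    def test_deterministic_given_seed(self):
        cfg = PopulationConfig(n_cells=100, seed=7)
        np.testing.assert_array_equal(
            generate_cell_positions(cfg), generate_cell_positions(cfg)
        )


class TestScaleWeights:
    def test_mixture_reproduces_power_law(self):
        from obliquescale.synthetic import _GRF_LENGTHS_UM

        w = calibrate_scale_weights(0.28)
        d = np.geomspace(20, 1000, 30)
        mix = (w[None, :] * np.exp(-(d[:, None] ** 2) / (2 * _GRF_LENGTHS_UM[None, :] ** 2))).sum(1)
        slope = np.polyfit(np.log(d), np.log(mix), 1)[0]
        assert -slope == pytest.approx(0.28, abs=0.02)

    def test_zero_exponent_single_global_scale(self):
        w = calibrate_scale_weights(0.0)
        assert np.count_nonzero(w) == 1


class TestPopulationActivity:
    def test_seed_reproducibility(self):
        cfg = PopulationConfig(n_cells=50, duration=100.0, n_latent=10, seed=3)
        pos = generate_cell_positions(cfg)
        a = generate_population_activity(pos, cfg)
        b = generate_population_activity(pos, cfg)
        np.testing.assert_array_equal(a.noisy_traces, b.noisy_traces)

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            generate_population_activity(np.zeros((0, 3)), PopulationConfig(n_cells=0))

    def test_more_latents_than_timepoints_rejected(self):
        cfg = PopulationConfig(n_cells=10, duration=50.0, n_latent=60, seed=0)
        pos = generate_cell_positions(cfg)
        with pytest.raises(ValueError):
            generate_population_activity(pos, cfg)

    def test_latent_rank_dominates_eigenspectrum(self):
        """n_latent=10, vanishing noise: ≈10 dominant covariance eigenvalues."""
        cfg = PopulationConfig(
            n_cells=120, duration=800.0, n_latent=10, noise_sd=1e-6,
            private_fraction=0.0, seed=8,
        )
        truth = generate_population_activity(generate_cell_positions(cfg), cfg)
        x = truth.noisy_traces - truth.noisy_traces.mean(axis=0)
        ev = np.linalg.svd(x, compute_uv=False) ** 2
        assert ev[9] / ev[10] > 100.0

    def test_autocorrelation_time_matches_calcium_tau(self):
        """Low-noise traces decorrelate on the calcium timescale (±20%)."""
        cfg = PopulationConfig(
            n_cells=60, duration=1800.0, n_latent=20, noise_sd=0.5,
            brain_extent=(500.0, 400.0, 300.0), seed=6,
        )
        truth = generate_population_activity(generate_cell_positions(cfg), cfg)
        x = truth.clean_traces - truth.clean_traces.mean(axis=0)
        taus = []
        for c in range(0, 60, 5):
            ac = [np.corrcoef(x[:-l, c], x[l:, c])[0, 1] for l in range(1, 7)]
            ac = np.abs(ac)
            taus.append(-1.0 / np.polyfit(np.arange(1, 7), np.log(ac), 1)[0])
        assert np.median(taus) == pytest.approx(cfg.calcium_tau, rel=0.2)

    def test_trace_shapes_and_units(self, default_population):
        truth, table = default_population
        cfg = truth.config
        assert truth.clean_traces.shape == (cfg.n_timepoints, cfg.n_cells)
        assert truth.loadings.shape == (cfg.n_latent, cfg.n_cells)
        # percent ΔF/F scale: average modulation of tens of percent
        assert 15.0 < truth.clean_traces.std(axis=0).mean() < 40.0


class TestVolumeMovie:
    GEOM = ShearGeometry(slope_s=0.0, native_pitch=(2.0, 2.0, 4.0), out_pitch=(2.0, 2.0, 4.0))

    def test_zero_cells_background_only(self):
        cfg = PopulationConfig(n_cells=0, duration=5.0, n_latent=2, seed=0)
        truth_like = type("T", (), {})()
        from obliquescale.synthetic import GroundTruth

        truth = GroundTruth(
            positions=np.zeros((0, 3)),
            latent_factors=np.zeros((5, 2)),
            loadings=np.zeros((2, 0)),
            clean_traces=np.zeros((5, 0)),
            noisy_traces=np.zeros((5, 0)),
            config=cfg,
        )
        noise = MovieNoiseModel(background=10.0)
        movie = generate_volume_movie(truth, self.GEOM, noise, shape=(4, 8, 8), seed=0)
        assert movie.data.mean() == pytest.approx(10.0, rel=0.1)

    def test_sheared_rendering_positions(self):
        """A blob rendered on a sheared grid appears displaced by s·k rows."""
        cfg = PopulationConfig(
            n_cells=1, duration=5.0, n_latent=1, noise_sd=0.0,
            brain_extent=(40.0, 40.0, 30.0), seed=0,
        )
        pos = np.array([[20.0, 30.0, 16.0]])
        truth = generate_population_activity(pos, cfg)
        quiet = MovieNoiseModel(background=0.0, pattern_amplitude=0.0, read_noise=0.0, gain=1e6)
        geom_flat = ShearGeometry(slope_s=0.0, native_pitch=(2.0, 2.0, 4.0), out_pitch=(2.0, 2.0, 4.0))
        geom_shear = ShearGeometry(slope_s=2.0, native_pitch=(2.0, 2.0, 4.0), out_pitch=(2.0, 2.0, 4.0))
        flat = generate_volume_movie(truth, geom_flat, quiet, shape=(8, 40, 20), seed=0)
        shear = generate_volume_movie(truth, geom_shear, quiet, shape=(8, 40, 20), seed=0)
        k = int(np.argmax(flat.data[0].sum(axis=(1, 2))))
        j_flat = np.argmax(flat.data[0, k].sum(axis=1))
        j_shear = np.argmax(shear.data[0, k].sum(axis=1))
        assert j_flat - j_shear == pytest.approx(2.0 * k, abs=1)

    def test_motion_recorded(self, nuclei_scene):
        truth, _ = nuclei_scene
        movie = generate_volume_movie(
            truth,
            ShearGeometry(slope_s=0.0, native_pitch=(1.5, 1.5, 3.0), out_pitch=(1.5, 1.5, 3.0)),
            shape=(18, 48, 64),
            motion_amplitude_um=2.0,
            seed=9,
        )
        assert movie.motion is not None
        assert movie.motion.std() == pytest.approx(2.0, rel=0.2)

    def test_faceplate_pattern_applied(self):
        cfg = PopulationConfig(n_cells=0, duration=3.0, n_latent=1, seed=0)
        from obliquescale.synthetic import GroundTruth

        truth = GroundTruth(
            positions=np.zeros((0, 3)),
            latent_factors=np.zeros((3, 1)),
            loadings=np.zeros((1, 0)),
            clean_traces=np.zeros((3, 0)),
            noisy_traces=np.zeros((3, 0)),
            config=cfg,
        )
        noise = MovieNoiseModel(pattern_amplitude=0.5)
        movie = generate_volume_movie(truth, self.GEOM, noise, shape=(2, 32, 32), seed=1)
        assert movie.data.shape == (3, 2, 32, 32)


class TestGaussianPsf:
    def test_normalized_and_peaked(self):
        psf = gaussian_psf((0.75, 1.0, 4.5))
        assert psf.sum() == pytest.approx(1.0)
        assert psf.max() == psf[tuple(s // 2 for s in psf.shape)]
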