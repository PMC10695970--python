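"""Local-correlation segmentation, trace extraction, ΔF/F and QC."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from obliquescale.core import VolumeSeries
from obliquescale.segmentation import (
    compute_dff,
    detect_nuclei,
    extract_traces,
    local_correlation_map,
    order_traces,
    qc_filter,
    segment_movie,
    spectral_snr,
)


def _movie(data, pitch=(1.0, 1.0, 1.0), rate=1.0):
    return VolumeSeries(data=data, pitch=pitch, rate=rate)


class TestLocalCorrelationMap:
    def test_iid_noise_near_zero(self, rng):
        m = local_correlation_map(_movie(rng.normal(size=(200, 6, 8, 8))))
        assert np.abs(m.mean()) < 0.05

    def test_shared_time_course_gives_one(self, rng):
        t = rng.normal(size=100)
        data = np.broadcast_to(t[:, None, None, None], (100, 5, 6, 6)).copy()
        m = local_correlation_map(_movie(data))
        np.testing.assert_allclose(m, 1.0, atol=1e-10)

    def test_matches_per_voxel_loop_oracle(self, rng):
        data = rng.normal(size=(40, 4, 5, 5))
        data[:, 1:3, 1:3, 1:3] += 3.0 * rng.normal(size=40)[:, None, None, None]
        m = local_correlation_map(_movie(data))

        T = data.shape[0]
        oracle = np.zeros(data.shape[1:])
        for z in range(4):
            for y in range(5):
                for x in range(5):
                    cors = []
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                if (dz, dy, dx) == (0, 0, 0):
                                    continue
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if not (0 <= zz < 4 and 0 <= yy < 5 and 0 <= xx < 5):
                                    continue
                                a, b = data[:, z, y, x], data[:, zz, yy, xx]
                                if a.std() == 0 or b.std() == 0:
                                    cors.append(0.0)
                                else:
                                    cors.append(float(np.corrcoef(a, b)[0, 1]))
                    oracle[z, y, x] = np.mean(cors)
        np.testing.assert_allclose(m, oracle, atol=1e-10)

    def test_zero_variance_voxel_contributes_zero(self, rng):
        data = rng.normal(size=(50, 3, 3, 3))
        data[:, 1, 1, 1] = 5.0  # constant voxel
        m = local_correlation_map(_movie(data))
        assert np.isfinite(m).all()

    def test_needs_ten_timepoints(self, rng):
        with pytest.raises(ValueError):
            local_correlation_map(_movie(rng.normal(size=(5, 3, 3, 3))))


class TestDetectNuclei:
    def test_noise_map_high_threshold_empty(self, rng):
        cmap = rng.normal(0, 0.01, (10, 20, 20))
        out = detect_nuclei(cmap, (1.5, 1.5, 3.0), threshold=5.0)
        assert out.shape == (0, 3)

    def test_ground_truth_recovery(self, nuclei_scene):
        """50 nuclei ≥ 8 μm apart: precision and recall ≥ 0.9 at 3 μm."""
        truth, movie = nuclei_scene
        cmap = local_correlation_map(movie)
        det = detect_nuclei(cmap, movie.pitch, threshold_percentile=98.0)
        d_det, _ = cKDTree(truth.positions).query(det)
        d_gt, _ = cKDTree(det).query(truth.positions)
        precision = (d_det <= 3.0).mean()
        recall = (d_gt <= 3.0).mean()
        assert precision >= 0.9
        assert recall >= 0.9

    def test_close_pair_suppressed(self):
        """Two maxima 4 μm apart: only the larger survives the 5 μm
        minimum-separation rule."""
        cmap = np.zeros((8, 24, 24))
        cmap[4, 12, 8] = 1.0
        cmap[4, 12, 12] = 0.7  # 4 μm away at 1 μm pitch
        cmap = ndimage.gaussian_filter(cmap, 1.0)
        det = detect_nuclei(cmap, (1.0, 1.0, 1.0), threshold=1e-4, sigma1=6.0)
        assert det.shape[0] == 1
        assert abs(det[0, 0] - 8.5) < 1.5  # the larger one

    def test_nonfinite_rejected(self):
        cmap = np.zeros((4, 4, 4))
        cmap[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            detect_nuclei(cmap, (1, 1, 1))


class TestExtractTraces:
    def test_uniform_movie_constant_traces(self):
        data = np.full((20, 6, 10, 10), 3.5)
        tr = extract_traces(_movie(data), np.array([[5.0, 5.0, 3.0]]))
        np.testing.assert_allclose(tr, 3.5)

    def test_rendered_nucleus_trace_recovered(self, nuclei_scene):
        truth, movie = nuclei_scene
        tr = extract_traces(movie, truth.positions)
        cors = [
            np.corrcoef(tr[:, i], truth.clean_traces[:, i])[0, 1]
            for i in range(truth.positions.shape[0])
        ]
        assert np.median(cors) >= 0.99

    def test_out_of_bounds_identifies_cell(self):
        data = np.zeros((12, 4, 4, 4))
        with pytest.raises(ValueError, match="cell 1"):
            extract_traces(_movie(data), np.array([[1.0, 1, 1], [99.0, 1, 1]]))


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        dff, valid = compute_dff(np.full((500, 1), 100.0), rate=1.0)
        assert valid[0]
        np.testing.assert_allclose(dff, 0.0, atol=1e-9)

    def test_baseline_recovered_on_drifting_trace(self, rng):
        """Sparse transients on a slow drift: baseline within 5% RMS."""
        t = np.arange(1500.0)
        baseline = 100.0 * (1.0 + 0.15 * np.sin(2 * np.pi * t / 1200.0))
        events = np.zeros_like(t)
        for onset in rng.choice(1400, 12, replace=False):
            events[int(onset) :] += 0.8 * np.exp(-(t[int(onset) :] - onset) / 4.0)
        raw = baseline * (1.0 + events)
        from obliquescale.segmentation import running_baseline

        est = running_baseline(raw[:, None], rate=1.0)[:, 0]
        rms = np.sqrt(np.mean((est - baseline) ** 2)) / baseline.mean()
        assert rms < 0.05

    def test_scale_invariance(self, rng):
        raw = 100.0 + 10.0 * rng.random((600, 3))
        dff1, _ = compute_dff(raw, 1.0)
        dff2, _ = compute_dff(7.3 * raw, 1.0)
        np.testing.assert_allclose(dff1, dff2, atol=1e-8)

    def test_nonpositive_baseline_flagged(self):
        raw = np.zeros((400, 1))
        dff, valid = compute_dff(raw, 1.0)
        assert not valid[0]
        assert np.isnan(dff).all()


class TestQcFilter:
    def test_white_noise_rejected(self, rng):
        dff = rng.normal(0, 10, (1024, 4))
        snr, passing = qc_filter(dff, rate=1.0)
        assert np.all(snr < 1.3)
        assert not passing.any()

    def test_slow_sinusoid_accepted(self, rng):
        t = np.arange(600.0)
        dff = (30.0 * np.sin(2 * np.pi * 0.05 * t))[:, None] + rng.normal(0, 1, (600, 1))
        snr, passing = qc_filter(dff, rate=1.0)
        assert snr[0] > 10.0
        assert passing[0]

    def test_slow_sinusoid_matches_periodogram_oracle(self, rng):
        from scipy.signal import periodogram

        t = np.arange(400.0)
        x = 5.0 * np.sin(2 * np.pi * 0.03 * t) + rng.normal(0, 1, 400)
        f, p = periodogram(x - x.mean(), fs=1.0)
        oracle = p[(f > 0) & (f < 0.25)].mean() / p[f >= 0.25].mean()
        assert spectral_snr(x, 1.0)[0] == pytest.approx(oracle, rel=1e-10)

    def test_range_violation_rejected(self, rng):
        t = np.arange(600.0)
        dff = (30.0 * np.sin(2 * np.pi * 0.05 * t))[:, None] + rng.normal(0, 1, (600, 1))
        dff[300, 0] = 2500.0  # out of the −100%…2000% window
        _, passing = qc_filter(dff, rate=1.0)
        assert not passing[0]

    def test_white_noise_ratio_tends_to_one(self, rng):
        dff = rng.normal(0, 1, (8192, 8))
        snr, _ = qc_filter(dff, rate=1.0)
        assert snr.mean() == pytest.approx(1.0, abs=0.1)


class TestOrderTraces:
    def test_single_trace(self):
        np.testing.assert_array_equal(order_traces(np.random.rand(50, 1)), [0])

    def test_anticorrelated_groups_contiguous(self, rng):
        t = rng.normal(size=200)
        traces = np.empty((200, 8))
        for i in range(4):
            traces[:, i] = t + 0.1 * rng.normal(size=200)
        for i in range(4, 8):
            traces[:, i] = -t + 0.1 * rng.normal(size=200)
        order = order_traces(traces)
        groups = [0 if i < 4 else 1 for i in order]
        # each group occupies a contiguous run of the ordering
        assert groups in ([0] * 4 + [1] * 4, [1] * 4 + [0] * 4)

    def test_is_permutation(self, rng):
        order = order_traces(rng.normal(size=(60, 17)))
        np.testing.assert_array_equal(np.sort(order), np.arange(17))


class TestSegmentMovie:
    def test_end_to_end_recovery(self, nuclei_scene):
        """≥ 90% of ground-truth cells recovered with trace correlation
        ≥ 0.9 on the default rendered scene."""
        truth, movie = nuclei_scene
        table = segment_movie(movie, threshold_percentile=98.0)
        assert table.n_cells > 0
        d_gt, idx = cKDTree(table.positions).query(truth.positions)
        matched = d_gt <= 3.0
        cors = np.array(
            [
                np.corrcoef(table.raw_traces[:, idx[i]], truth.clean_traces[:, i])[0, 1]
                for i in np.flatnonzero(matched)
            ]
        )
        recovered = matched.copy()
        recovered[matched] &= cors >= 0.9
        assert recovered.mean() >= 0.9
        assert table.order_1d is not None and len(table.order_1d) == table.n_cells
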