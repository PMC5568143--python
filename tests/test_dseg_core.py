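"""Normalisation, quartile-grid initialisation and k-medians clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pqdseg.dseg_core import (
    DsegModel,
    NormalisationParams,
    assign_segments,
    canonical_ordering,
    fit_normalisation,
    initialise_centroids,
    kmedians_fit,
    normalise_pq,
    subsample_stride,
)


def percentile_oracle(sorted_vals, pct):
    """Linear-interpolation percentile, written out from its definition."""
    n = len(sorted_vals)
    pos = (n - 1) * pct / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


class TestNormalisation:
    def test_percentiles_match_explicit_oracle(self):
        vals = np.arange(1.0, 10001.0)
        norm = fit_normalisation(vals, vals)
        assert norm.p_lo == pytest.approx(percentile_oracle(vals, 1.0), abs=1e-9)
        assert norm.p_lo == pytest.approx(100.99, abs=1e-9)
        assert norm.p_hi == pytest.approx(percentile_oracle(vals, 99.99), abs=1e-9)
        assert norm.p_hi == pytest.approx(9999.0, abs=1e-3)

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_normalisation(np.full(20000, 3.0), np.full(20000, 3.0))

    def test_small_sample_warns(self):
        vals = np.linspace(0, 1, 500)
        with pytest.warns(UserWarning, match="unstable"):
            fit_normalisation(vals, vals)

    def test_bounds_bracket_9998_percent(self, rng):
        vals = rng.normal(size=200_000)
        norm = fit_normalisation(vals, vals)
        inside = np.mean((vals >= norm.p_lo) & (vals <= norm.p_hi))
        assert inside >= 0.9898  # 1% clipped low, 0.01% high

    def test_normalise_endpoints_midpoint_and_clamping(self):
        norm = NormalisationParams(10.0, 20.0, 1.0, 3.0)
        p = np.array([10.0, 20.0, 15.0, 5.0, 25.0])
        q = np.array([1.0, 3.0, 2.0, 0.0, 9.0])
        xy = normalise_pq(p, q, norm)
        np.testing.assert_allclose(xy[:, 0], [0.0, 1.0, 0.5, 0.0, 1.0])
        np.testing.assert_allclose(xy[:, 1], [0.0, 1.0, 0.5, 0.0, 1.0])
        assert xy.shape[0] == p.size  # clipped voxels retained

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            NormalisationParams(1.0, 1.0, 0.0, 1.0)


class TestInitialisation:
    def test_uniform_samples_near_sixteenth_grid(self, rng):
        """Uniform density: cell medians sit at the 4x4 grid of odd eighths."""
        samples = rng.uniform(size=(40_000, 2))
        cents = initialise_centroids(samples)
        expected = np.array([[a, b] for a in (0.125, 0.375, 0.625, 0.875)
                             for b in (0.125, 0.375, 0.625, 0.875)])
        assert np.abs(cents - expected).max() < 0.02

    def test_separated_clouds_recover_their_medians(self, rng):
        centres = np.array([[a, b] for a in (0.1, 0.35, 0.65, 0.9)
                            for b in (0.1, 0.35, 0.65, 0.9)])
        pts = np.concatenate([c + rng.uniform(-0.02, 0.02, size=(200, 2))
                              for c in centres])
        cents = initialise_centroids(pts)
        # independent oracle: marginal medians per cloud
        expected = np.array([np.median(pts[i * 200:(i + 1) * 200], axis=0)
                             for i in range(16)])
        d = cdist(cents, expected)
        assert np.allclose(np.sort(d.min(axis=1)), 0.0, atol=1e-12)

    def test_identical_samples_exercise_empty_cell_reseed(self):
        samples = np.full((100, 2), 0.5)
        cents = initialise_centroids(samples)
        assert cents.shape == (16, 2)
        # one cell holds all the mass; the other 15 sit at geometric centres
        assert np.sum(np.all(cents == 0.5, axis=1)) >= 1
        assert np.all((cents >= 0) & (cents <= 1))

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            initialise_centroids(np.empty((0, 2)))


class TestKMedians:
    def test_two_blobs_toy_mode(self, rng):
        """k=2: centroids must be the component-wise medians of each blob."""
        a = rng.uniform(0.0, 0.2, size=(10, 2))
        b = rng.uniform(0.8, 1.0, size=(10, 2))
        samples = np.concatenate([a, b])
        model = kmedians_fit(samples, init=np.array([[0.1, 0.1], [0.9, 0.9]]))
        assert model.converged
        expected = np.array([np.median(a, axis=0), np.median(b, axis=0)])
        np.testing.assert_allclose(np.sort(model.centroids, axis=0),
                                   np.sort(expected, axis=0), atol=1e-12)

    def test_every_assignment_pass_matches_brute_force(self, rng):
        """On a <=20-point toy set the labels equal an exhaustive scan."""
        samples = rng.uniform(size=(20, 2))
        init = initialise_centroids(samples, k=4)
        model = kmedians_fit(samples, init)
        cano = model.canonical_centroids()
        brute = np.array([int(np.argmin([np.sum((s - c) ** 2) for c in cano])) + 1
                          for s in samples])
        got = assign_segments(samples[:, 0], samples[:, 1], model)
        np.testing.assert_array_equal(got, brute)

    def test_fixed_point_converges_in_one_iteration(self):
        pts = np.array([[i / 16 + 1 / 32, (i % 4) / 4 + 1 / 8] for i in range(16)])
        model = kmedians_fit(pts, init=pts.copy())
        assert model.converged and model.iterations_run == 1
        np.testing.assert_allclose(model.centroids, pts)

    def test_assignment_step_never_increases_objective(self, fitted_small):
        m = fitted_small.dseg_model
        post = np.array(m.objective_trace)
        pre = np.array(m.objective_pre_assign)
        assert np.all(post <= pre + 1e-9 * np.abs(pre))

    def test_convergence_is_a_fixed_point(self, fitted_small, small_cohort):
        """One more assignment pass after convergence changes no label."""
        m = fitted_small.dseg_model
        assert m.converged and m.iterations_run <= 250
        ph = small_cohort[0]
        seg1 = assign_segments(ph.p_map, ph.q_map, m, mask=ph.mask)
        seg2 = assign_segments(ph.p_map, ph.q_map, m, mask=ph.mask)
        np.testing.assert_array_equal(seg1, seg2)

    def test_empty_cluster_reseeded_to_farthest_sample(self, rng, caplog):
        samples = rng.uniform(0.0, 0.1, size=(30, 2))
        init = np.array([[0.05, 0.05], [0.9, 0.9]])  # second centroid never wins
        import logging
        with caplog.at_level(logging.WARNING, logger="pqdseg.dseg_core"):
            model = kmedians_fit(samples, init)
        assert "reseeded" in caplog.text
        assert model.converged

    def test_well_separated_16_cluster_recovery(self, rng):
        """Generator medians recovered within 0.02 with >=99% membership."""
        centres = np.array([[a, b] for a in (0.12, 0.37, 0.62, 0.87)
                            for b in (0.12, 0.37, 0.62, 0.87)])
        pts = np.concatenate([c + rng.normal(0, 0.015, size=(500, 2))
                              for c in centres])
        truth = np.repeat(np.arange(16), 500)
        model = kmedians_fit(np.clip(pts, 0, 1), initialise_centroids(np.clip(pts, 0, 1)))
        cano = model.canonical_centroids()
        labels = assign_segments(pts[:, 0], pts[:, 1], model)
        for g in range(16):
            sel = truth == g
            med = np.median(pts[sel], axis=0)
            j = int(np.argmin(np.linalg.norm(cano - med, axis=1)))
            assert np.linalg.norm(cano[j] - med) < 0.02
            # membership accuracy: the generator cluster maps to one segment
            assert np.mean(labels[sel] == j + 1) >= 0.99


class TestAssignAndOrdering:
    def _toy_model(self, centroids):
        return DsegModel(
            norm=NormalisationParams(0.0, 1.0, 0.0, 1.0),
            centroids=np.asarray(centroids, dtype=float),
            ordering=canonical_ordering(centroids),
            k=len(centroids),
            converged=True,
        )

    def test_voxel_on_centroid_gets_its_label(self):
        cents = np.column_stack([np.linspace(0.05, 0.95, 16), np.full(16, 0.5)])
        model = self._toy_model(cents)
        labels = assign_segments(cents[:, 0], cents[:, 1], model)
        np.testing.assert_array_equal(labels, np.arange(1, 17))

    def test_equidistant_tie_breaks_to_lowest_canonical_label(self):
        # canonical labels 3 and 7 are equidistant nearest to the query voxel
        cents = np.array([
            [0.10, 0.7], [0.20, 0.7], [0.40, 0.2], [0.45, 0.8],
            [0.50, 0.8], [0.55, 0.8], [0.60, 0.2], [0.65, 0.8],
            [0.70, 0.8], [0.75, 0.8], [0.80, 0.8], [0.85, 0.8],
            [0.90, 0.8], [0.92, 0.8], [0.95, 0.8], [0.97, 0.8],
        ])
        model = self._toy_model(cents)
        d = cdist(np.array([[0.5, 0.2]]), model.canonical_centroids()).ravel()
        assert d[2] == d[6] and np.all(d[[2, 6]] < np.delete(d, [2, 6]).min())
        label = assign_segments(np.array([0.5]), np.array([0.2]), model)[0]
        assert label == 3

    def test_full_map_matches_brute_force_scan(self, fitted_small, small_cohort):
        ph = small_cohort[1]
        m = fitted_small.dseg_model
        seg = assign_segments(ph.p_map, ph.q_map, m, mask=ph.mask)
        xy = normalise_pq(ph.p_map[ph.mask.data], ph.q_map[ph.mask.data], m.norm)
        cano = m.canonical_centroids()
        brute = np.argmin(cdist(xy, cano, "sqeuclidean"), axis=1) + 1
        np.testing.assert_array_equal(seg[ph.mask.data], brute)
        assert np.all(seg[~ph.mask.data] == 0)
        assert np.all((seg[ph.mask.data] >= 1) & (seg[ph.mask.data] <= 16))

    def test_ordering_identity_when_sorted(self):
        cents = np.column_stack([np.linspace(0, 1, 16), np.linspace(0, 1, 16)])
        np.testing.assert_array_equal(canonical_ordering(cents), np.arange(1, 17))

    def test_ordering_ties_by_q(self):
        cents = np.array([[0.5, 0.9], [0.5, 0.1], [0.2, 0.5]])
        np.testing.assert_array_equal(canonical_ordering(cents), [3, 2, 1])

    def test_ordering_is_permutation_and_idempotent(self, rng):
        cents = rng.uniform(size=(16, 2))
        ordering = canonical_ordering(cents)
        assert sorted(ordering) == list(range(1, 17))
        cano = np.empty_like(cents)
        cano[ordering - 1] = cents
        np.testing.assert_array_equal(canonical_ordering(cano), np.arange(1, 17))


class TestModelPersistence:
    def test_json_roundtrip_bit_exact(self, fitted_small, tmp_path):
        m = fitted_small.dseg_model
        path = tmp_path / "model.json"
        m.save(path)
        m2 = DsegModel.load(path)
        assert m.to_json() == m2.to_json()
        np.testing.assert_array_equal(m.centroids, m2.centroids)
        np.testing.assert_array_equal(m.ordering, m2.ordering)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            DsegModel(norm=NormalisationParams(0, 1, 0, 1),
                      centroids=np.zeros((16, 2)), ordering=np.ones(16, dtype=int))


class TestSubsampling:
    def test_below_cap_identity(self):
        idx, stride = subsample_stride(100, cap=1000)
        assert stride == 1 and len(idx) == 100

    def test_above_cap_deterministic_stride(self):
        idx, stride = subsample_stride(10_000, cap=1000, seed=5)
        assert stride == 10 and len(idx) == 1000
        idx2, _ = subsample_stride(10_000, cap=1000, seed=5)
        np.testing.assert_array_equal(idx, idx2)
        assert np.all(np.diff(idx) == stride)
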