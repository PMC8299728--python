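"""Density estimation, symmetric KL similarity, and the three builders."""

import numpy as np
import pytest

from mmconnect.netio import DataError, Modality, Parcellation
from mmconnect.networks import (
    DegenerateDistributionError,
    DensityEstimate,
    IncompatibleDensityError,
    build_functional_network,
    build_morphological_network,
    build_structural_network,
    estimate_density,
    symmetric_kl,
)
from mmconnect.synthetic import RegionSamples, RoiTimeSeries, TractographyCounts

# hand evaluation of the symmetric KL formula on a 2-point grid:
# P=(1/2,1/2), Q=(1/4,3/4):
#   P-part: .5 ln 2 + .5 ln(2/3) = 0.1438410...
#   Q-part: .25 ln(1/2) + .75 ln(3/2) = 0.1308122...
TWO_POINT_DKL = 0.2746532721
TWO_POINT_KLS = float(np.exp(-TWO_POINT_DKL))


def _density(mass):
    mass = np.asarray(mass, dtype=float)
    return DensityEstimate(grid=np.linspace(0, 1, len(mass)), mass=mass)


class TestEstimateDensity:
    def test_mass_normalised(self, rng):
        d = estimate_density(rng.normal(0.5, 0.1, 500), grid_lo=0, grid_hi=1)
        assert abs(d.mass.sum() - 1.0) < 1e-9
        assert (d.mass > 0).all()
        assert len(d.grid) == 128

    def test_mass_mean_tracks_sampling_distribution(self, rng):
        vals = rng.normal(0.5, 0.1, 10_000)
        d = estimate_density(vals, grid_lo=0.0, grid_hi=1.0)
        assert abs(float(d.grid @ d.mass) - 0.5) < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            estimate_density(np.full(50, 0.3))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(DataError):
            estimate_density(rng.normal(size=5))

    def test_small_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_density(rng.normal(size=50), n_points=4)


class TestSymmetricKL:
    def test_identity(self):
        p = _density([0.25, 0.25, 0.5])
        r = symmetric_kl(p, p)
        assert r.d_kl == 0.0 and r.kls == 1.0

    def test_two_point_hand_value(self):
        r = symmetric_kl(_density([0.5, 0.5]), _density([0.25, 0.75]))
        assert r.d_kl == pytest.approx(TWO_POINT_DKL, abs=1e-6)
        assert r.kls == pytest.approx(TWO_POINT_KLS, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.dirichlet(np.ones(16))
        b = rng.dirichlet(np.ones(16))
        assert symmetric_kl(_density(a), _density(b)).d_kl == pytest.approx(
            symmetric_kl(_density(b), _density(a)).d_kl, abs=1e-12
        )

    def test_grid_mismatch_rejected(self):
        p = _density([0.5, 0.5])
        q = DensityEstimate(grid=np.array([0.0, 2.0]), mass=np.array([0.25, 0.75]))
        with pytest.raises(IncompatibleDensityError):
            symmetric_kl(p, q)

    def test_kls_in_unit_interval(self, rng):
        for _ in range(20):
            a, b = rng.dirichlet(np.ones(32)), rng.dirichlet(np.ones(32))
            r = symmetric_kl(_density(a), _density(b))
            assert 0 < r.kls <= 1 and r.d_kl >= 0


def _region_samples(values_by_roi):
    return RegionSamples(
        samples={r: np.asarray(v, float) for r, v in values_by_roi.items()},
        subject_id="s",
        group="control",
    )


class TestMorphologicalNetwork:
    def test_identical_rois_edge_weight_one(self, rng):
        v = rng.uniform(0.2, 0.8, 200)
        other = rng.uniform(0.2, 0.8, 150)
        s = _region_samples({0: v, 1: v.copy(), 2: other})
        net = build_morphological_network(s, Parcellation.generic(3))
        assert net.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_separated_means_edge_near_zero(self, rng):
        s = _region_samples(
            {0: rng.normal(0.2, 0.05, 300).clip(1e-6, 1),
             1: rng.normal(0.8, 0.05, 300).clip(1e-6, 1)}
        )
        net = build_morphological_network(s, Parcellation.generic(2))
        assert net.values[0, 1] < 0.05

    def test_entries_in_unit_interval_and_symmetric(self, rng):
        s = _region_samples(
            {r: rng.uniform(0.1, 0.9, 120) for r in range(5)}
        )
        net = build_morphological_network(s, Parcellation.generic(5))
        assert (net.values >= 0).all() and (net.values <= 1).all()
        assert (np.diag(net.values) == 1).all()
        assert np.allclose(net.values, net.values.T)
        off = net.values[~np.eye(5, dtype=bool)]
        assert (off > 0).all()

    def test_permutation_equivariance(self, rng):
        vals = {r: rng.uniform(0.1, 0.9, 100) for r in range(4)}
        parc = Parcellation.generic(4)
        net = build_morphological_network(_region_samples(vals), parc)
        perm = [2, 0, 3, 1]
        net_p = build_morphological_network(
            _region_samples({k: vals[perm[k]] for k in range(4)}), parc
        )
        assert np.allclose(net_p.values, net.values[np.ix_(perm, perm)], atol=1e-12)

    def test_degenerate_roi_named_in_error(self, rng):
        s = _region_samples({0: rng.uniform(0.1, 0.9, 50), 1: np.full(50, 0.5)})
        with pytest.raises(DegenerateDistributionError, match="ROI 1"):
            build_morphological_network(s, Parcellation.generic(2))

    def test_gaussian_closed_form_limit(self, rng):
        # for N(mu1, s) vs N(mu2, s), symmetric KL = (mu1-mu2)^2 / s^2
        mu1, mu2, s = 0.45, 0.55, 0.05
        a = rng.normal(mu1, s, 100_000)
        b = rng.normal(mu2, s, 100_000)
        from mmconnect.networks import estimate_density, symmetric_kl

        lo, hi = 0.2, 0.8
        da = estimate_density(a, n_points=512, grid_lo=lo, grid_hi=hi)
        db = estimate_density(b, n_points=512, grid_lo=lo, grid_hi=hi)
        expected = (mu1 - mu2) ** 2 / s**2
        assert symmetric_kl(da, db).d_kl == pytest.approx(expected, rel=0.10)


class TestStructuralNetwork:
    def test_worked_probability_example(self):
        # seed i: 1,000 of 5,000x10 samples reach j -> p(i->j)=0.02
        # seed j: 3,000 of 5,000x20 samples reach i -> p(j->i)=0.03
        counts = np.array([[0, 1000], [3000, 0]])
        tc = TractographyCounts(
            counts=counts, voxel_counts=np.array([10, 20]), samples_per_voxel=5000
        )
        net = build_structural_network(tc, Parcellation.generic(2))
        assert net.values[0, 1] == pytest.approx(0.025, abs=1e-15)

    def test_zero_counts_zero_network(self):
        tc = TractographyCounts(
            counts=np.zeros((3, 3), int),
            voxel_counts=np.array([5, 5, 5]),
            samples_per_voxel=5000,
        )
        net = build_structural_network(tc, Parcellation.generic(3))
        assert np.all(net.values == 0)

    def test_asymmetric_counts_symmetric_network(self, rng):
        n = 5
        voxels = rng.integers(5, 20, n)
        totals = 5000 * voxels
        counts = rng.integers(0, 100, (n, n))
        np.fill_diagonal(counts, 0)
        tc = TractographyCounts(
            counts=counts, voxel_counts=voxels, samples_per_voxel=5000
        )
        net = build_structural_network(tc, Parcellation.generic(n))
        assert np.allclose(net.values, net.values.T)
        assert (net.values >= 0).all() and (net.values <= 1).all()
        assert np.all(np.diag(net.values) == 0)

    def test_determinism(self, rng):
        counts = rng.integers(0, 50, (4, 4))
        np.fill_diagonal(counts, 0)
        tc = TractographyCounts(
            counts=counts, voxel_counts=np.array([3, 4, 5, 6]), samples_per_voxel=5000
        )
        parc = Parcellation.generic(4)
        a = build_structural_network(tc, parc)
        b = build_structural_network(tc, parc)
        assert np.array_equal(a.values, b.values)


def _ts(values):
    return RoiTimeSeries(values=np.asarray(values, float), subject_id="s", group="c")


class TestFunctionalNetwork:
    def test_affine_dependence_gives_unit_correlation(self, rng):
        x = rng.standard_normal(100)
        ts = _ts(np.vstack([x, 2 * x + 3, -x]))
        net = build_functional_network(ts, Parcellation.generic(3))
        assert net.values[0, 1] == pytest.approx(1.0)
        assert net.values[0, 2] == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        ts = _ts(rng.standard_normal((2, 10_000)))
        net = build_functional_network(ts, Parcellation.generic(2))
        assert abs(net.values[0, 1]) < 0.05

    def test_constant_row_rejected(self, rng):
        vals = rng.standard_normal((3, 50))
        vals[1] = 0.7
        with pytest.raises(DataError):
            _ts(vals)

    def test_range_and_diagonal(self, rng):
        ts = _ts(rng.standard_normal((6, 80)))
        net = build_functional_network(ts, Parcellation.generic(6))
        assert (net.values >= -1).all() and (net.values <= 1).all()
        assert np.all(np.diag(net.values) == 1.0)
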