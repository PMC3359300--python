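"""Observable suite: MSD, loop distributions, density, shape, radial, MSMD,
correlations and lattice scaling — each checked against an independent
brute-force oracle or closed form where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dynloop.observables as obs
from dynloop.engine import Trajectory
from dynloop.expression import BinnedExpression, Region, RegionSet

from conftest import make_ensemble


def random_conformations(rng, n_conf, n_mono, scale=5.0):
    return [rng.normal(0, scale, (n_mono, 3)) for _ in range(n_conf)]


class TestMSD:
    def test_straight_rod_quadratic(self, straight_rod_ensemble):
        curve = obs.msd_total(straight_rod_ensemble)
        np.testing.assert_allclose(curve.msd, curve.separation.astype(float) ** 2)

    def test_zero_separation_zero(self, straight_rod_ensemble):
        assert obs.msd_total(straight_rod_ensemble).msd[0] == 0.0

    def test_matches_brute_force(self, rng):
        """Vectorized MSD equals an explicit double loop on random conformations."""
        confs = random_conformations(rng, 10, 20)
        ens = make_ensemble(confs)
        curve = obs.msd_total(ens)
        for n in (1, 3, 7, 19):
            acc = [
                np.sum((c[i + n] - c[i]) ** 2)
                for c in confs
                for i in range(20 - n)
            ]
            assert curve.msd[n] == pytest.approx(np.mean(acc))

    def test_invariant_under_rigid_motions(self, rng):
        confs = random_conformations(rng, 5, 15)
        moved = []
        for c in confs:
            q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved.append(c @ q.T + rng.normal(0, 50, 3))
        a = obs.msd_total(make_ensemble(confs)).msd
        b = obs.msd_total(make_ensemble(moved)).msd
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_loci_pairs(self, straight_rod_ensemble):
        vals = obs.msd_loci(straight_rod_ensemble, [(2, 2), (1, 4), (0, 10)])
        np.testing.assert_allclose(vals, [0.0, 9.0, 100.0])

    def test_loci_consistent_with_total(self, rng):
        confs = random_conformations(rng, 8, 12)
        ens = make_ensemble(confs)
        n = 4
        pairs = [(i, i + n) for i in range(12 - n)]
        per_pair = obs.msd_loci(ens, pairs)
        assert np.mean(per_pair) == pytest.approx(obs.msd_total(ens).msd[n])


class TestLoopDistribution:
    def test_single_snapshot_counts(self, rng):
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5)
        ens = make_ensemble([pos], bonds=[[(0, 2, 99), (1, 3, 99)]])
        dist = obs.loop_size_distribution(ens)
        assert dist.g.tolist() == [2]
        assert dist.p.tolist() == [1.0]

    def test_max_loops_combinatorics(self):
        # a chain of N=5 admits N-g=3 distinct loops of length g=2
        n, g = 5, 2
        placements = [(i, i + g) for i in range(n - g)]
        assert len(placements) == n - g == 3

    def test_uniform_bonds_recover_n_minus_g(self, rng):
        """Uniformly sampled bonds follow P(g) ~ (N-g)."""
        n = 40
        pairs = [(i, j) for i in range(n) for j in range(i + 2, n)]
        idx = rng.integers(len(pairs), size=100_000)
        log = np.array([[pairs[k][0], pairs[k][1], 0] for k in idx])
        dist = obs.loop_size_distribution(bond_log=log, n_monomers=n)
        expected = (n - dist.g) / np.sum(n - dist.g)
        chi2 = np.sum((dist.counts - expected * 100_000) ** 2 / (expected * 100_000))
        assert stats.chi2(df=dist.g.size - 1).sf(chi2) > 0.01

    def test_no_phantom_lengths(self, rng):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10)
        ens = make_ensemble([pos] * 3, bonds=[[(0, 2, 9)], [(0, 2, 9)], [(3, 5, 9)]])
        dist = obs.loop_size_distribution(ens)
        assert dist.g.tolist() == [2]


class TestLoopExponentFit:
    def make_dist(self, alpha, n=200):
        g = np.arange(2, 80)
        w = g.astype(float) ** alpha * (n - g)
        return obs.LoopDistribution(g=g, counts=w, p=w / w.sum(), n_monomers=n)

    def test_recovers_constructed_exponent(self):
        dist = self.make_dist(-1.5)
        assert obs.fit_loop_exponent(dist) == pytest.approx(-1.5, abs=0.02)

    def test_pure_combinatorial_gives_zero(self):
        dist = self.make_dist(0.0)
        assert obs.fit_loop_exponent(dist) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        g = np.array([2, 3])
        dist = obs.LoopDistribution(g=g, counts=g, p=g / g.sum(), n_monomers=50)
        with pytest.raises(ValueError, match=">= 4"):
            obs.fit_loop_exponent(dist)


class TestDensity:
    def test_cluster_denser_than_spread(self, rng):
        tight = rng.normal(0, 0.5, (20, 3))
        spread = rng.normal(0, 10.0, (20, 3))
        rho_t = obs.local_density_gkde(make_ensemble([tight])).rho
        rho_s = obs.local_density_gkde(make_ensemble([spread])).rho
        assert rho_t.mean() > rho_s.mean() * 10

    def test_two_equal_clusters_symmetric(self, rng):
        blob = rng.normal(0, 1.0, (15, 3))
        conf = np.vstack([blob, blob + [100.0, 0, 0]])
        rho = obs.local_density_gkde(make_ensemble([conf])).rho
        assert np.mean(rho[:15]) == pytest.approx(np.mean(rho[15:]), rel=0.01)

    def test_matches_direct_kernel_sum(self, rng):
        """KDE at the monomer positions equals the explicit Gaussian sum."""
        pts = rng.normal(0, 2.0, (10, 3))
        rho = obs.local_density_gkde(make_ensemble([pts])).rho
        # independent direct sum with Scott's bandwidth
        m = pts.shape[0]
        factor = m ** (-1.0 / 7.0)           # Scott, d=3
        cov = np.cov(pts.T, bias=False) * factor**2
        inv = np.linalg.inv(cov)
        norm = 1.0 / np.sqrt((2 * np.pi) ** 3 * np.linalg.det(cov))
        direct = np.zeros(m)
        for a in range(m):
            for b in range(m):
                d = pts[a] - pts[b]
                direct[a] += norm * np.exp(-0.5 * d @ inv @ d)
        direct /= m
        np.testing.assert_allclose(rho, direct, rtol=1e-8)


class TestVolumeRatio:
    regions = RegionSet(
        regions=(Region("high", 0, 5), Region("low", 5, 10)), n_monomers=10
    )

    def test_equal_densities_unity(self):
        field = obs.DensityField(rho=np.ones(10), bandwidth_factor=1.0)
        assert obs.volume_ratio(field, self.regions) == pytest.approx(1.0)

    def test_inverse_proportionality(self):
        rho = np.array([1.0] * 5 + [2.0] * 5)
        field = obs.DensityField(rho=rho, bandwidth_factor=1.0)
        assert obs.volume_ratio(field, self.regions) == pytest.approx(2.0)

    def test_swapped_regions_reciprocal(self, rng):
        rho = rng.uniform(0.5, 3.0, 10)
        field = obs.DensityField(rho=rho, bandwidth_factor=1.0)
        swapped = RegionSet(
            regions=(Region("low", 0, 5), Region("high", 5, 10)), n_monomers=10
        )
        assert obs.volume_ratio(field, self.regions) == pytest.approx(
            1.0 / obs.volume_ratio(field, swapped)
        )


class TestShape:
    def test_single_point_zero_tensor(self):
        np.testing.assert_allclose(obs.gyration_tensor(np.zeros((1, 3))), 0.0)

    def test_two_point_dumbbell(self):
        d = 4.0
        q = obs.gyration_tensor(np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]))
        expected = np.zeros((3, 3))
        expected[0, 0] = d * d / 4
        np.testing.assert_allclose(q, expected)

    def test_trace_equals_pairwise_identity(self, rng):
        """trace(Q) = (1/2M^2) sum_ij |r_i - r_j|^2 (Lagrange identity)."""
        for _ in range(10):
            pts = rng.normal(0, 3.0, (rng.integers(2, 40), 3))
            m = pts.shape[0]
            diff = pts[:, None, :] - pts[None, :, :]
            pairwise = np.sum(diff**2) / (2 * m * m)
            assert np.trace(obs.gyration_tensor(pts)) == pytest.approx(pairwise)

    @pytest.mark.parametrize(
        "eigs,expected",
        [((1.0, 1.0, 1.0), 0.0), ((1.0, 0.0, 0.0), 1.0), ((2.0, 1.0, 1.0), 0.0625)],
    )
    def test_asphericity_anchors(self, eigs, expected):
        assert obs.asphericity(np.array(eigs)) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lam=st.tuples(*[st.floats(1e-6, 1e3) for _ in range(3)]),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, lam, c):
        lam = np.array(lam)
        assert obs.asphericity(c * lam) == pytest.approx(obs.asphericity(lam), rel=1e-9)

    def test_shape_of_collinear_points(self):
        pts = np.zeros((9, 3))
        pts[:, 0] = np.arange(9)
        assert obs.shape_of(pts).asphericity == pytest.approx(1.0)


class TestRadialMetrics:
    def test_center_monomer_zero_distance(self):
        # symmetric cross: monomer 0 sits exactly at the center of mass
        pts = np.array(
            [[0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0],
             [0, 0, 2], [0, 0, -2]], dtype=float
        )
        rad = obs.radial_metrics(make_ensemble([pts]))
        assert rad.center_sq[0] == pytest.approx(0.0)

    def test_hull_vertex_zero_surface_distance(self):
        pts = np.array(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [1, 1, 1]], dtype=float
        )
        rad = obs.radial_metrics(make_ensemble([pts]))
        assert rad.surface_sq[0] == pytest.approx(0.0, abs=1e-12)

    def test_sphere_center_distance_is_radius(self, rng):
        """A point at the center of a dense spherical shell is ~R from the surface."""
        r = 8.0
        v = rng.normal(size=(400, 3))
        shell = r * v / np.linalg.norm(v, axis=1, keepdims=True)
        pts = np.vstack([[0.0, 0.0, 0.0], shell])
        rad = obs.radial_metrics(make_ensemble([pts]))
        assert np.sqrt(rad.surface_sq[0]) == pytest.approx(r, rel=0.05)


class TestMSMD:
    def make_traj(self, frames, interval=10):
        frames = np.asarray(frames, dtype=float)
        times = np.arange(1, frames.shape[0] + 1) * interval
        return Trajectory(times=times, positions=frames, frame_interval=interval)

    def test_frozen_conformation_zero(self, rng):
        conf = rng.normal(0, 3, (10, 3))
        curve = obs.msmd(self.make_traj([conf] * 8))
        for vals in curve.msmd.values():
            np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_rigid_translation_zero(self, rng):
        conf = rng.normal(0, 3, (10, 3))
        frames = [conf + [k * 5.0, 0, 0] for k in range(8)]
        curve = obs.msmd(self.make_traj(frames))
        np.testing.assert_allclose(curve.msmd["total"], 0.0, atol=1e-12)

    def test_free_random_walker_normal_diffusion(self, rng):
        """Unconfined random walk: MSMD(t)/t constant (center frame disabled)."""
        steps = rng.choice([-1, 1], size=(4000, 1, 3))
        frames = np.cumsum(steps, axis=0).astype(float)
        curve = obs.msmd(
            self.make_traj(frames, interval=1),
            edge_exclusion=0.0,
            max_lag_frames=20,
            relative_to_com=False,
        )
        diag = curve.diagnostic("total")
        assert np.all(np.abs(diag / diag[0] - 1) < 0.10)

    def test_region_curves_and_edge_exclusion(self, rng):
        frames = rng.normal(0, 1, (30, 40, 3))
        regions = RegionSet(
            regions=(Region("high", 0, 20), Region("low", 20, 40)), n_monomers=40
        )
        curve = obs.msmd(self.make_traj(frames), regions, edge_exclusion=0.05)
        assert set(curve.msmd) == {"total", "high", "low"}
        assert curve.lag_mcs[0] == 10


class TestCorrelations:
    def test_affine_metric_perfect_correlation(self):
        e = BinnedExpression(levels=np.array([1.0, 3.0, 2.0, 5.0, 4.0]))
        c = obs.correlate_with_expression(2 * e.levels + 1, e)
        assert c["pearson"] == pytest.approx(1.0)
        assert c["spearman"] == pytest.approx(1.0)

    def test_negated_metric_anticorrelated(self):
        e = BinnedExpression(levels=np.array([1.0, 3.0, 2.0, 5.0, 4.0]))
        c = obs.correlate_with_expression(-e.levels, e)
        assert c["pearson"] == pytest.approx(-1.0)
        assert c["spearman"] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self, rng):
        """Spearman equals the exhaustive rank-difference formula (no ties)."""
        x = rng.permutation(5).astype(float)
        y = rng.permutation(5).astype(float)
        c = obs.correlate_with_expression(x, np.asarray(y))
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        n = 5
        rho = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
        assert c["spearman"] == pytest.approx(rho)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            obs.correlate_with_expression(np.ones(5), np.arange(5.0))


class TestLatticeScaling:
    def sim_curve(self):
        sep = np.arange(50)
        return obs.MSDCurve(separation=sep, msd=(sep**1.2).astype(float))

    def test_quadruple_msd_gives_factor_two(self):
        sim = self.sim_curve()
        mb = sim.separation_mb()[5:40:5]
        exp = np.column_stack([mb, 4 * np.interp(mb, sim.separation_mb(), sim.msd)])
        assert obs.lattice_scaling(sim, exp) == pytest.approx(2.0)

    def test_identity_scaling(self):
        sim = self.sim_curve()
        mb = sim.separation_mb()[5:40:5]
        exp = np.column_stack([mb, np.interp(mb, sim.separation_mb(), sim.msd)])
        assert obs.lattice_scaling(sim, exp) == pytest.approx(1.0)

    def test_outside_support_rejected(self):
        sim = self.sim_curve()
        exp = np.array([[1000.0, 1.0]])
        with pytest.raises(ValueError, match="support"):
            obs.lattice_scaling(sim, exp)
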