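"""Storage-capacity theory: asymptotic formulas and finite Gaussian analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from plastinet.capacity import (
    CapacityQuery, memory_load, low_unit_error, predicted_output_noise,
    max_matrix_load, pattern_capacity, transinformation, weight_capacity,
    total_capacity, gaussian_moments, exact_potential_pmf,
    optimal_threshold_gaussian, pattern_capacity_finite, capacity_surface,
)
from plastinet.patterns import generate_memory_set
from plastinet.willshaw import store, random_mask


class TestMemoryLoad:
    def test_empty_and_saturated(self):
        assert memory_load(0, 8, 8, 64, 64) == 0.0
        assert memory_load(3, 64, 64, 64, 64) == 1.0

    def test_closed_form(self):
        assert memory_load(50, 8, 8, 64, 64) == pytest.approx(
            1 - (1 - 64 / 4096) ** 50)


class TestLowUnitError:
    def test_full_connectivity(self):
        assert low_unit_error(0.3, 10, 1.0, 1.0) == pytest.approx(0.3 ** 10)

    def test_saturated_load(self):
        assert low_unit_error(1.0, 10, 0.7, 0.4) == pytest.approx(1.0)

    def test_binomial_sum_equals_closed_form_on_grid(self):
        # the sum over connected-input counts collapses exactly
        for zk in (3, 10, 25):
            for P in (0.1, 0.5, 0.9):
                for p1 in (0.05, 0.3, 0.8):
                    c = np.arange(zk + 1)
                    total = float(stats.binom.pmf(c, zk, P) @ np.power(p1, c))
                    assert total == pytest.approx(
                        (1 - P + P * p1) ** zk, abs=1e-12)


class TestNoiseAndLoadInversion:
    def test_zero_error_rates(self):
        assert predicted_output_noise(0.0, 0.0, 10, 100) == 0.0

    def test_inversion(self):
        eps = 0.07
        p01 = eps * 10 / 90
        assert predicted_output_noise(p01, 0.0, 10, 100) == pytest.approx(eps)

    def test_max_matrix_load_closed_form(self):
        q = CapacityQuery(m=1000, n=1000, k=10, l=10, eps=0.01, P=1.0)
        assert max_matrix_load(q) == pytest.approx(
            (0.01 * 10 / 990) ** (1 / 10), abs=1e-10)

    def test_load_vanishes_with_noise_tolerance(self):
        loads = [max_matrix_load(CapacityQuery(m=1000, n=1000, k=10, l=10,
                                               eps=e, P=1.0))
                 for e in (1e-30, 1e-6, 1e-3, 0.01, 0.1)]
        assert loads == sorted(loads)
        assert loads[0] < 1e-2


class TestPatternAndWeightCapacity:
    def test_doubling_network_area_doubles_capacity(self):
        q1 = CapacityQuery(m=1000, n=1000, k=10, l=10, eps=0.01, P=1.0)
        q2 = CapacityQuery(m=2000, n=1000, k=10, l=10, eps=0.01, P=1.0)
        assert pattern_capacity(q2) == pytest.approx(2 * pattern_capacity(q1),
                                                     rel=2e-3)

    def test_transinformation_reduces_to_entropy(self):
        p = 0.05
        H = -p * math.log2(p) - (1 - p) * math.log2(1 - p)
        assert transinformation(p, 0.0, 0.0) == pytest.approx(H)

    def test_useless_channel_carries_nothing(self):
        assert transinformation(0.3, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_transinformation_matches_joint_enumeration(self):
        # direct double sum over the 2x2 joint distribution
        p, p01, p10 = 0.2, 0.08, 0.15
        joint = np.array([[(1 - p) * (1 - p01), (1 - p) * p01],
                          [p * p10, p * (1 - p10)]])
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        mask = joint > 0
        I = float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))
        assert transinformation(p, p01, p10) == pytest.approx(I, abs=1e-12)

    def test_total_capacity_exceeds_weight_capacity_below_saturation(self):
        q = CapacityQuery(m=1000, n=1000, k=10, l=10, eps=0.01, P=1.0)
        assert total_capacity(q, c_e=1.0) > weight_capacity(q)
        # normalization identity: dividing by consolidated instead of all synapses
        assert total_capacity(q, c_e=1.0) == pytest.approx(
            weight_capacity(q) / max_matrix_load(q))


class TestGaussianMoments:
    def test_empty_network(self):
        mom = gaussian_moments(0, 10, 10, 100, 100, lambda_=1.0, P=0.5)
        assert mom.mu_lo == 0 and mom.var_lo == 0
        assert mom.mu_hi == pytest.approx(10 * 0.5)
        assert mom.var_hi == pytest.approx(10 * 0.5 * 0.5)

    def test_noiseless_full_connectivity_high_units_are_deterministic(self):
        mom = gaussian_moments(50, 10, 10, 200, 200, lambda_=1.0, kappa=0.0, P=1.0)
        assert mom.mu_hi == 10 and mom.var_hi == 0

    def test_moments_match_simulation(self):
        # empirical dendritic-potential moments, clustering-robust bootstrap SE
        m = n = 300; k = l = 15; M = 150; P = 0.5
        mom = gaussian_moments(M, k, l, m, n, lambda_=1.0, kappa=0.0, P=P)
        rng = np.random.default_rng(0)
        per_trial = []
        for _ in range(60):
            mem = generate_memory_set(M, m, n, k, l, rng)
            A = (rng.random((m, n)) < P).astype(np.uint8)
            net = store(mem, A)
            x = mem.U[0] @ net.W
            lo = np.flatnonzero(mem.V[0] == 0)
            per_trial.append(x[rng.choice(lo, 40, replace=False)])
        samples = np.concatenate(per_trial)
        boot_mu, boot_var = [], []
        for _ in range(200):
            idx = rng.integers(0, 60, 60)
            s = np.concatenate([per_trial[i] for i in idx])
            boot_mu.append(s.mean()); boot_var.append(s.var())
        assert abs(samples.mean() - mom.mu_lo) <= 3 * np.std(boot_mu)
        assert abs(samples.var() - mom.var_lo) <= 3 * np.std(boot_var)


class TestExactPmf:
    def test_empty_network_point_mass(self):
        pmf = exact_potential_pmf(0, 4, 4, 16, 16, 4)
        assert pmf[0] == pytest.approx(1.0)

    def test_saturated_load_concentrates_at_top(self):
        pmf = exact_potential_pmf(2000, 4, 4, 16, 16, 4)
        assert pmf[-1] == pytest.approx(1.0, abs=1e-3)

    def test_matches_bruteforce_enumeration(self):
        # exhaustive enumeration over all assemblies, m=n=5, k=l=2, M=2
        import itertools
        m = n = 5
        subs = list(itertools.combinations(range(m), 2))
        counts = np.zeros(3)
        for u1 in subs:
            for v1 in subs:
                for u2 in subs:
                    for v2 in subs:
                        # potential of content unit 0 for query units {0, 1}
                        x = int((0 in u1 and 0 in v1) or (0 in u2 and 0 in v2)) + \
                            int((1 in u1 and 0 in v1) or (1 in u2 and 0 in v2))
                        counts[x] += 1
        brute = counts / counts.sum()
        pmf = exact_potential_pmf(2, 2, 2, 5, 5, 2)
        assert np.allclose(pmf, brute, atol=1e-12)

    def test_probabilities_sum_to_one_with_dilution(self):
        pmf = exact_potential_pmf(8, 4, 4, 16, 16, 4, P=0.5)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.all(pmf >= 0)


class TestThresholdAndFiniteCapacity:
    def test_separated_moments_pick_lowest_clean_threshold(self):
        from plastinet.capacity import PotentialMoments
        mom = PotentialMoments(mu_lo=1.0, var_lo=0.25, mu_hi=20.0, var_hi=0.25)
        res = optimal_threshold_gaussian(mom, l=10, n=100, theta_max=25)
        assert res.eps_hat < 1e-9
        assert 3 <= res.theta <= 18

    def test_degenerate_identical_distributions(self):
        from plastinet.capacity import PotentialMoments
        mom = PotentialMoments(mu_lo=5.0, var_lo=4.0, mu_hi=5.0, var_hi=4.0)
        res = optimal_threshold_gaussian(mom, l=10, n=100, theta_max=15)
        # direct scan oracle
        best = min(
            ((100 - 10) * stats.norm.sf(t - 0.5, 5, 2)
             + 10 * stats.norm.cdf(t - 0.5, 5, 2)) / 10
            for t in range(16))
        assert res.eps_hat == pytest.approx(best)

    def test_finite_capacity_matches_linear_scan(self):
        q = CapacityQuery(m=200, n=200, k=8, l=8, eps=0.05, P=0.8)
        r = pattern_capacity_finite(q)

        def eps_min(M):
            mom = gaussian_moments(M, q.k, q.l, q.m, q.n, q.lambda_, q.kappa, q.P)
            return optimal_threshold_gaussian(mom, q.l, q.n, theta_max=q.zk).eps_hat

        scan = max(M for M in range(0, 3 * r.M_eps + 2) if eps_min(M) <= q.eps)
        assert r.M_eps == scan

    def test_finite_capacity_monotone_in_noise_tolerance(self):
        Ms = [pattern_capacity_finite(
            CapacityQuery(m=300, n=300, k=10, l=10, eps=e, P=1.0)).M_eps
            for e in (0.01, 0.05, 0.2)]
        assert Ms == sorted(Ms)

    def test_huge_tolerance_hits_load_guard(self):
        q = CapacityQuery(m=100, n=100, k=5, l=5, eps=50.0, P=1.0)
        r = pattern_capacity_finite(q)
        assert memory_load(r.M_eps, 5, 5, 100, 100) > 0.999


class TestCapacitySurface:
    def test_cells_equal_single_queries_and_orderings(self):
        table = capacity_surface(400, k_grid=[8, 20], ce_grid=[0.4, 0.8], eps=0.05)
        for _, row in table.iterrows():
            r = pattern_capacity_finite(CapacityQuery(
                m=400, n=400, k=int(row.k), l=int(row.k), eps=0.05, P=row.c_e))
            assert r.M_eps == row.M_eps
        # more effectual connectivity -> more storable memories at fixed k
        for k in (8, 20):
            sub = table[table.k == k].sort_values("c_e")
            assert sub.M_eps.is_monotonic_increasing
        # sparser assemblies carry more bits per consolidated synapse
        hi = table[(table.c_e == 0.8)]
        assert hi[hi.k == 8].C_total.iloc[0] > hi[hi.k == 20].C_total.iloc[0]
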