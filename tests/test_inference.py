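import math

import numpy as np
import pytest

from dcabench.graph_ensemble import CouplingMatrix, GraphSpec, generate_er_couplings
from dcabench.inference import (
    DegenerateMarginalError,
    DegenerateMarginalWarning,
    SingularMomentsError,
    direct_pair_model,
    estimate_moments,
    exact_moments,
    global_scores,
    local_scores,
    mean_field_inversion,
)
from dcabench.spin_sampler import SampleSet, SpinModel, exact_distribution, sample_gibbs


def ising_samples(configs):
    return SampleSet(np.array(configs, dtype=np.int8), temperature=1.0, num_states=2)


class TestEstimateMoments:
    def test_constant_samples(self):
        s = ising_samples([[1, 1, 1]] * 10)
        mom = estimate_moments(s)
        assert np.allclose(mom.means, 1.0)
        assert np.allclose(mom.connected_correlations, 0.0)

    def test_perfect_anticorrelation(self):
        s = ising_samples([[1, -1], [-1, 1]] * 5)
        mom = estimate_moments(s)
        assert np.allclose(mom.means, 0.0)
        assert mom.connected_correlations[0, 1] == pytest.approx(-1.0)

    def test_matches_enumeration_on_chain(self, chain4_model, chain4_exact):
        K = 30_000
        samples = sample_gibbs(chain4_model, K, seed=11, burn_in=300, thinning=3)
        mom = estimate_moments(samples)
        exact_C = chain4_exact.connected_correlations()
        se = np.sqrt(1.0 / K)
        assert np.max(np.abs(mom.connected_correlations - exact_C)) < 6 * se

    def test_ising_diagonal_identity(self, chain4_model):
        samples = sample_gibbs(chain4_model, 500, seed=1, burn_in=50, thinning=1)
        mom = estimate_moments(samples)
        assert np.allclose(
            np.diag(mom.connected_correlations), 1 - mom.means**2, atol=1e-12
        )

    def test_potts_shapes(self):
        configs = np.array([[1, 2, 3], [3, 2, 1], [2, 2, 2], [1, 3, 1]], dtype=np.int8)
        s = SampleSet(configs, temperature=1.0, num_states=3)
        mom = estimate_moments(s)
        assert mom.state_frequencies.shape == (3, 3)
        assert mom.connected_correlations.shape == (6, 6)
        assert mom.full_covariance.shape == (9, 9)
        assert np.allclose(mom.state_frequencies.sum(axis=1), 1.0)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            estimate_moments(ising_samples([[1, 1]]))


class TestMeanFieldInversion:
    def test_identity_correlations_give_zero_couplings(self):
        mom = estimate_moments(ising_samples([[1, 1], [-1, 1], [1, -1], [-1, -1]]))
        # independent spins: C = I exactly
        assert np.allclose(mom.connected_correlations, np.eye(2))
        inv = mean_field_inversion(mom, temperature=1.0, ridge=0.0)
        assert inv.beta_couplings[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("beta_J", [0.1, 0.5, 1.2])
    def test_two_spin_closed_form(self, beta_J):
        # C = [[1, t], [t, 1]] inverts to beta_J_hat = t / (1 - t^2)
        t = math.tanh(beta_J)
        model = SpinModel(
            CouplingMatrix(np.array([[0, 1], [1, 0]], dtype=np.int8)),
            temperature=1.0 / beta_J,
        )
        mom = exact_moments(exact_distribution(model))
        inv = mean_field_inversion(mom, temperature=1.0 / beta_J, ridge=0.0)
        assert inv.beta_couplings[0, 1] == pytest.approx(t / (1 - t**2), abs=1e-10)

    def test_small_coupling_limit(self):
        t = math.tanh(0.1)
        assert t / (1 - t**2) == pytest.approx(0.1007, abs=1e-4)

    def test_chain_oracle_inverse(self, chain4_model, chain4_exact):
        # independent oracle: numpy.linalg.solve on the exact C
        mom = exact_moments(chain4_exact)
        C = mom.connected_correlations
        expected = -np.linalg.solve(C, np.eye(4))
        inv = mean_field_inversion(mom, temperature=1.0, ridge=0.0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(inv.beta_couplings[off], expected[off], atol=1e-10)

    def test_rank_deficiency_raises_without_ridge(self):
        s = ising_samples([[1, 1, 1, -1], [-1, 1, -1, -1]])  # K < n
        mom = estimate_moments(s)
        with pytest.raises(SingularMomentsError, match="rank deficient"):
            mean_field_inversion(mom, ridge=0.0)

    def test_default_ridge_handles_degenerate(self):
        s = ising_samples([[1, 1, 1, -1], [-1, 1, -1, -1]])
        inv = mean_field_inversion(estimate_moments(s))
        assert np.all(np.isfinite(inv.beta_couplings))
        assert inv.regularization_used > 0

    def test_dedimensionalization(self, chain4_exact):
        mom = exact_moments(chain4_exact)
        inv = mean_field_inversion(mom, temperature=2.5)
        assert np.allclose(inv.couplings, 2.5 * inv.beta_couplings)


class TestLocalScores:
    def test_chain_ordering_with_exact_moments(self, chain4_exact):
        mom = exact_moments(chain4_exact)
        scored = local_scores(mom)
        by_pair = dict(zip(map(tuple, scored.pairs), scored.scores))
        assert by_pair[(0, 1)] == pytest.approx(by_pair[(1, 2)], abs=1e-12)
        assert by_pair[(0, 1)] > by_pair[(0, 2)] > 0

    def test_all_equal_samples_complete_tie(self):
        mom = estimate_moments(ising_samples([[1, 1, 1]] * 8))
        scored = local_scores(mom)
        assert np.allclose(scored.scores, 1.0)

    def test_labels_from_truth(self, chain4_model, chain4_exact):
        scored = local_scores(exact_moments(chain4_exact), truth=chain4_model.couplings)
        by_pair = dict(zip(map(tuple, scored.pairs), scored.labels))
        assert by_pair[(0, 1)] and by_pair[(1, 2)] and by_pair[(2, 3)]
        assert not by_pair[(0, 2)] and not by_pair[(0, 3)]


class TestDirectPairModel:
    def test_zero_coupling_factorizes(self):
        dm = direct_pair_model(0.0, (0.3, -0.4))
        assert dm.direct_correlation == pytest.approx(0.3 * -0.4, abs=1e-12)
        assert dm.matching_fields[0] == pytest.approx(math.atanh(0.3), abs=1e-10)
        assert dm.matching_fields[1] == pytest.approx(math.atanh(-0.4), abs=1e-10)

    def test_zero_means_give_tanh(self):
        for a in (0.2, 1.0, -0.7):
            dm = direct_pair_model(a, (0.0, 0.0))
            assert dm.direct_correlation == pytest.approx(math.tanh(a), abs=1e-10)
            assert abs(dm.matching_fields[0]) < 1e-10

    def test_marginals_reproduced(self, rng):
        for _ in range(200):
            a = rng.normal(scale=2)
            m1, m2 = rng.uniform(-0.98, 0.98, size=2)
            dm = direct_pair_model(a, (m1, m2))
            h1, h2 = dm.matching_fields
            spins = np.array([(1, 1), (1, -1), (-1, 1), (-1, -1)], dtype=float)
            w = np.exp(a * spins[:, 0] * spins[:, 1] + h1 * spins[:, 0] + h2 * spins[:, 1])
            w /= w.sum()
            assert abs(w @ spins[:, 0] - m1) < 1e-8
            assert abs(w @ spins[:, 1] - m2) < 1e-8

    def test_boundary_marginal_raises(self):
        with pytest.raises(DegenerateMarginalError):
            direct_pair_model(0.5, (1.0, 0.0))


class TestGlobalScores:
    def test_zero_couplings_zero_means(self):
        mom = estimate_moments(ising_samples([[1, 1], [-1, 1], [1, -1], [-1, -1]]))
        inv = mean_field_inversion(mom, ridge=0.0)
        scored = global_scores(inv, mom)
        assert np.allclose(scored.scores, 0.0, atol=1e-10)

    def test_chain_indirect_pair_suppressed(self, chain4_exact):
        mom = exact_moments(chain4_exact)
        inv = mean_field_inversion(mom, temperature=1.0, ridge=0.0)
        glob = global_scores(inv, mom)
        loc = local_scores(mom)
        g = dict(zip(map(tuple, glob.pairs), glob.scores))
        l = dict(zip(map(tuple, loc.pairs), loc.scores))
        # direct score of the non-adjacent pair is nearer zero than its raw correlation
        assert abs(g[(0, 2)]) < abs(l[(0, 2)])
        assert abs(g[(0, 3)]) < abs(l[(0, 3)])

    def test_monotone_in_coupling_at_zero_means(self):
        scores = [
            direct_pair_model(a, (0.0, 0.0)).direct_correlation
            for a in np.linspace(-2, 2, 21)
        ]
        assert all(x < y for x, y in zip(scores, scores[1:]))

    def test_degenerate_marginals_warn_and_force(self):
        configs = np.array([[1, 1, -1], [1, -1, 1], [1, 1, 1], [1, -1, -1]], dtype=np.int8)
        mom = estimate_moments(SampleSet(configs, temperature=1.0, num_states=2))
        inv = mean_field_inversion(mom)
        with pytest.warns(DegenerateMarginalWarning):
            scored = global_scores(inv, mom)
        by_pair = dict(zip(map(tuple, scored.pairs), scored.scores))
        assert by_pair[(0, 1)] == pytest.approx(1.0 * mom.means[1])

    def test_global_spin_flip_invariance(self, chain4_model):
        samples = sample_gibbs(chain4_model, 2000, seed=3, burn_in=100, thinning=1)
        flipped = SampleSet(-samples.configurations, temperature=1.0, num_states=2)
        for s in (samples, flipped):
            pass
        mom_a = estimate_moments(samples)
        mom_b = estimate_moments(flipped)
        inv_a = mean_field_inversion(mom_a, ridge=1e-8)
        inv_b = mean_field_inversion(mom_b, ridge=1e-8)
        ga = global_scores(inv_a, mom_a)
        gb = global_scores(inv_b, mom_b)
        assert np.allclose(ga.scores, gb.scores, atol=1e-10)


@pytest.fixture(scope="module")
def potts_chain():
    entries = np.zeros((3, 3), dtype=np.int8)
    entries[0, 1] = entries[1, 0] = entries[1, 2] = entries[2, 1] = 1
    model = SpinModel(CouplingMatrix(entries), temperature=1.5, num_states=3)
    return model, exact_distribution(model)


class TestPottsInference:
    def test_gauge_invariance_of_scores(self, potts_chain):
        model, dist = potts_chain
        scores = []
        for ref in (0, 1, 2):
            mom = exact_moments(dist, num_states=3, reference_state=ref)
            inv = mean_field_inversion(mom, temperature=model.temperature, ridge=0.0)
            scores.append(global_scores(inv, mom).scores)
        assert np.allclose(scores[0], scores[1], atol=1e-8)
        assert np.allclose(scores[0], scores[2], atol=1e-8)

    def test_interacting_pairs_outscore_indirect(self, potts_chain):
        model, dist = potts_chain
        mom = exact_moments(dist, num_states=3)
        inv = mean_field_inversion(mom, temperature=model.temperature, ridge=0.0)
        for scored in (local_scores(mom), global_scores(inv, mom)):
            s = dict(zip(map(tuple, scored.pairs), scored.scores))
            assert s[(0, 1)] > s[(0, 2)]
            assert s[(1, 2)] > s[(0, 2)]

    def test_zero_sum_gauge_blocks(self, potts_chain):
        model, dist = potts_chain
        mom = exact_moments(dist, num_states=3)
        inv = mean_field_inversion(mom, temperature=model.temperature, ridge=0.0)
        block = inv.potts_blocks[0, 1]
        assert np.allclose(block.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(block.sum(axis=1), 0.0, atol=1e-10)


class TestHighTemperatureConsistency:
    def test_rank_correlation_with_truth(self):
        # naive inversion is first-order accurate when T >= 2 Tc and K is large;
        # Somers' D is the rank correlation appropriate against binary truth
        # (Spearman saturates below 1 because of the massive ties in J)
        from scipy.stats import somersd

        J = generate_er_couplings(GraphSpec(20, 6, seed=13))
        T = 2.0 * 6  # 2 Tc
        model = SpinModel(J, temperature=T)
        samples = sample_gibbs(model, 50_000, seed=21, burn_in=300, thinning=2)
        mom = estimate_moments(samples)
        inv = mean_field_inversion(mom, temperature=T)
        iu, ju = np.triu_indices(20, k=1)
        d = somersd(J.entries[iu, ju], inv.beta_couplings[iu, ju]).statistic
        assert d > 0.9
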