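"""The variational encoder: digamma expectations, inference, learning, free energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from meabayes import agent as ag
from meabayes import generative as g


def random_dirichlet(rng, low=0.5, high=20.0):
    return ag.DirichletLikelihood(
        counts=rng.uniform(low, high, (32, 2, 2, 2)), prior_counts=np.ones((32, 2, 2, 2))
    )


def true_lnA():
    with np.errstate(divide="ignore"):
        return np.log(g.true_likelihood().probs)


class TestExpectedLogLikelihood:
    def test_flat_counts_give_minus_one(self):
        """psi(1) - psi(2) = -1 for both outcomes under counts (1, 1)."""
        lnA = ag.expected_log_likelihood(ag.DirichletLikelihood.flat(1.0))
        assert np.allclose(lnA, -1.0, atol=1e-12)

    def test_large_count_limit(self):
        d = ag.DirichletLikelihood.flat(1.0)
        counts = d.counts.copy()
        counts[:, 1] = 75.0
        counts[:, 0] = 25.0
        d2 = ag.DirichletLikelihood(counts=counts, prior_counts=d.prior_counts)
        lnA = ag.expected_log_likelihood(d2)
        assert np.all(np.abs(lnA[:, 1] - np.log(0.75)) < 0.02)

    def test_jensen_gap(self, rng):
        """exp(E[ln A]) is sub-normalised: the geometric mean undershoots."""
        lnA = ag.expected_log_likelihood(random_dirichlet(rng))
        assert np.all(np.exp(lnA).sum(axis=1) <= 1.0 + 1e-12)

    def test_rejects_non_positive_counts(self):
        with pytest.raises(ValueError):
            ag.DirichletLikelihood(counts=np.zeros((32, 2, 2, 2)),
                                   prior_counts=np.ones((32, 2, 2, 2)))


class TestInference:
    def test_uniform_messages_give_uniform_posterior(self):
        lnA = np.full((32, 2, 2, 2), -0.7)
        post = ag.infer_states(lnA, np.zeros(32, dtype=int))
        assert np.allclose(post.joint, 0.25)

    def test_pool_pattern_under_true_likelihood(self):
        """Pool-1 stimulated, pool-2 silent: posterior concentrates on (1,0)
        with likelihood ratio 3^32 against (0,1); impossible states get 0."""
        o = np.concatenate([np.ones(16, int), np.zeros(16, int)])
        post = ag.infer_states(true_lnA(), o)
        assert post.joint[0] == 0.0 and post.joint[3] == 0.0
        assert post.joint[2] == pytest.approx(1 / (1 + 3.0**-32), abs=1e-15)

    def test_matches_enumeration_oracle(self, rng):
        """Softmax inference equals exhaustive 4-state Bayes normalisation."""
        prior = ag.StatePrior()
        for _ in range(100):
            lnA = ag.expected_log_likelihood(random_dirichlet(rng))
            o = rng.integers(0, 2, 32)
            post = ag.infer_states(lnA, o, prior)
            w = prior.log + ag.log_likelihood_messages(lnA, o)
            oracle = np.exp(w - logsumexp(w))
            assert np.max(np.abs(post.joint - oracle)) < 1e-12

    def test_wrong_outcome_length_rejected(self):
        with pytest.raises(ValueError):
            ag.infer_states(true_lnA(), np.zeros(31, dtype=int))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_posterior_is_simplex_with_consistent_marginals(self, seed):
        rng = np.random.default_rng(seed)
        lnA = ag.expected_log_likelihood(random_dirichlet(rng))
        post = ag.infer_states(lnA, rng.integers(0, 2, 32))
        assert post.joint.sum() == pytest.approx(1.0, abs=1e-10)
        m = post.marginals
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-10)
        assert m[0, 1] == pytest.approx(post.joint[2] + post.joint[3], abs=1e-12)


class TestRelaxation:
    def test_unit_step_is_exact(self, rng):
        lnA = ag.expected_log_likelihood(random_dirichlet(rng))
        o = rng.integers(0, 2, 32)
        post, trace = ag.relax_to_posterior(lnA, o, step=1.0, max_iter=2)
        assert np.allclose(post.joint, ag.infer_states(lnA, o).joint, atol=1e-12)
        assert post.n_iter <= 2

    def test_converges_to_closed_form(self, rng):
        for _ in range(50):
            lnA = ag.expected_log_likelihood(random_dirichlet(rng))
            o = rng.integers(0, 2, 32)
            post, _ = ag.relax_to_posterior(lnA, o, step=0.25, max_iter=400, tol=1e-9)
            assert post.converged
            assert np.max(np.abs(post.joint - ag.infer_states(lnA, o).joint)) < 1e-6

    def test_iterates_stay_on_simplex(self, rng):
        lnA = ag.expected_log_likelihood(random_dirichlet(rng))
        _, trace = ag.relax_to_posterior(lnA, rng.integers(0, 2, 32), max_iter=16)
        assert np.allclose(trace["s"].sum(axis=1), 1.0, atol=1e-10)
        assert (trace["s"] >= 0).all()

    def test_non_convergence_flagged_not_raised(self, rng):
        lnA = ag.expected_log_likelihood(random_dirichlet(rng))
        post, _ = ag.relax_to_posterior(lnA, rng.integers(0, 2, 32),
                                        step=0.01, max_iter=2, tol=1e-12)
        assert not post.converged

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            ag.relax_to_posterior(true_lnA(), np.zeros(32, int), step=1.5)


class TestLearning:
    def test_one_hot_update(self):
        a = ag.DirichletLikelihood.flat(1.0)
        s = ag.PosteriorState(joint=np.array([0.0, 0.0, 1.0, 0.0]),
                              v=np.array([-30.0, -30.0, 0.0, -30.0]))
        o = np.zeros(32, int)
        o[0] = 1
        a2 = ag.update_counts(a, o, s)
        assert a2.counts[0, 1, 1, 0] == 2.0
        delta = a2.counts - a.counts
        assert delta[0].sum() == pytest.approx(1.0)
        assert delta[0, 1, 1, 0] == 1.0 and np.count_nonzero(delta[0]) == 1

    def test_unit_mass_per_site_per_epoch(self, rng):
        a = ag.DirichletLikelihood.flat(1.0)
        joint = rng.dirichlet(np.ones(4))
        s = ag.PosteriorState(joint=joint, v=np.log(joint))
        a2 = ag.update_counts(a, rng.integers(0, 2, 32), s)
        assert np.allclose((a2.counts - a.counts).sum(axis=(1, 2, 3)), 1.0)

    def test_learning_decreases_state_free_energy(self):
        """Across seeds, the Eq.-1-form free energy (inaccuracy + state KL)
        falls from the first to the last 64 of 512 epochs."""
        wins = 0
        for seed in range(10):
            src = g.sample_sources(2, 256, seed=seed)
            stim = g.sample_stimuli(src, seed=seed)
            res = ag.run_training(stim, 512, ag.AgentConfig(seed=seed))
            fs = (res.free_energy.inaccuracy + res.free_energy.state_complexity).to_numpy()
            wins += fs[-64:].mean() < fs[:64].mean()
        assert wins >= 8

    def test_no_learning_control_has_no_trend(self, small_experiment):
        """With Dirichlet updates disabled the free energy is trendless."""
        from scipy import stats

        _, stim = small_experiment
        res = ag.run_training(stim, 512, ag.AgentConfig(seed=2, learn=False))
        fs = (res.free_energy.inaccuracy + res.free_energy.state_complexity).to_numpy()
        fit = stats.linregress(np.arange(len(fs)), fs)
        ci = 1.96 * fit.stderr
        assert abs(fit.slope) < ci + 1e-12

    def test_relabelling_equivariance(self, small_experiment):
        """Swapping the two 16-site pools in the stimuli (i.e. relabelling the
        sources) with correspondingly transformed initial counts yields the
        correspondingly transformed learned counts, exactly."""
        _, stim = small_experiment
        rng = np.random.default_rng(77)
        init = 1.0 + rng.uniform(0, 0.01, (32, 2, 2, 2))
        perm_e = np.concatenate([np.arange(16, 32), np.arange(16)])
        stim_swapped = g.StimulusTrain(outcomes=stim.outcomes[:, perm_e],
                                       site_map=stim.site_map)
        init_swapped = init[perm_e][:, :, :, :].transpose(0, 1, 3, 2)
        cfg = ag.AgentConfig(seed=0)
        r1 = ag.run_training(stim, 128, cfg, init_counts=init)
        r2 = ag.run_training(stim_swapped, 128, cfg, init_counts=init_swapped)
        transformed = r1.dirichlet.counts[perm_e].transpose(0, 1, 3, 2)
        assert np.allclose(r2.dirichlet.counts, transformed, atol=1e-10)


class TestFreeEnergy:
    def test_param_complexity_zero_at_prior(self):
        a = ag.DirichletLikelihood.flat(1.0)
        assert ag.dirichlet_param_complexity(a) == pytest.approx(0.0, abs=1e-12)

    def test_truncated_form_differs_by_prior_beta_constant(self, rng):
        """exact KL = truncated bookkeeping form + sum ln Beta(prior counts)."""
        from scipy.special import gammaln

        a = random_dirichlet(rng)
        a = ag.DirichletLikelihood(counts=a.counts, prior_counts=np.full(a.counts.shape, 2.0))
        exact = ag.dirichlet_param_complexity(a, exact=True)
        trunc = ag.dirichlet_param_complexity(a, exact=False)
        ln_beta0 = (gammaln(a.prior_counts).sum(axis=1)
                    - gammaln(a.prior_counts.sum(axis=1))).sum()
        assert exact == pytest.approx(trunc + ln_beta0, rel=1e-10)

    def test_uniform_posterior_has_zero_state_complexity(self):
        post = ag.PosteriorState(joint=np.full(4, 0.25), v=np.log(np.full(4, 0.25)))
        rec = ag.free_energy(np.zeros(32, int), post, true_lnA())
        assert rec.state_complexity == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_parts(self, rng):
        a = random_dirichlet(rng)
        lnA = ag.expected_log_likelihood(a)
        o = rng.integers(0, 2, 32)
        post = ag.infer_states(lnA, o)
        rec = ag.free_energy(o, post, lnA, a=a)
        assert rec.total == pytest.approx(
            rec.inaccuracy + rec.state_complexity + rec.param_complexity, abs=1e-10
        )
        assert rec.param_complexity >= 0

    def test_bound_with_known_likelihood(self, rng):
        """F >= -ln P(o) over vertex states, equality at the exact posterior."""
        lnA = true_lnA()
        A = g.true_likelihood().probs
        for trial in range(50):
            k, l = rng.integers(0, 2, 2)
            o = (rng.random(32) < A[:, 1, k, l]).astype(int)
            nle = ag.negative_log_evidence(lnA, o)
            post = ag.infer_states(lnA, o)
            assert ag.free_energy(o, post, lnA).total == pytest.approx(nle, abs=1e-10)
            msgs = ag.log_likelihood_messages(lnA, o)
            for v in range(4):
                if not np.isfinite(msgs[v]):
                    continue  # vertex with zero likelihood: F is +inf, bound trivial
                joint = np.zeros(4)
                joint[v] = 1.0
                vertex = ag.PosteriorState(joint=joint, v=np.where(joint > 0, 0.0, -1e9))
                assert ag.free_energy(o, vertex, lnA).total >= nle - 1e-10

    def test_bound_with_dirichlet_beliefs(self, rng):
        """State-terms F at the posterior bounds -ln E_Q(A)[P(o)] (Jensen)."""
        a = random_dirichlet(rng)
        lnA = ag.expected_log_likelihood(a)
        Abar = a.mean()
        for _ in range(20):
            o = rng.integers(0, 2, 32)
            post = ag.infer_states(lnA, o)
            F = ag.free_energy(o, post, lnA).total
            lik = Abar[np.arange(32), o].prod(axis=0).reshape(4)
            nle = -np.log(np.sum(0.25 * lik))
            assert F >= nle - 1e-10


class TestBlindRecovery:
    def test_recovers_generative_likelihood_up_to_relabelling(self, trained_512):
        """512 blind epochs recover the pool-level likelihood within 0.1."""
        _, err = ag.resolve_state_relabelling(
            trained_512.dirichlet.mean(), g.true_likelihood().probs
        )
        assert err < 0.1

    def test_alignment_fixes_labels(self, trained_512):
        aligned, perm = ag.align_to_reference(trained_512, g.true_likelihood().probs)
        _, err = ag.resolve_state_relabelling(
            aligned.dirichlet.mean(), g.true_likelihood().probs
        )
        identity_err = np.max(np.abs(
            ag.pool_average(aligned.dirichlet.mean())
            - ag.pool_average(g.true_likelihood().probs)
        ))
        assert identity_err == pytest.approx(err, abs=1e-12)
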