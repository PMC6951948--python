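"""Observation model and inference: emission densities, forward-backward,
Viterbi decoding and future prediction."""

import numpy as np
import numpy.testing as npt
import pytest
import scipy.stats

from cthmm import (
    Cohort,
    EmissionParams,
    PatientSeries,
    ScenarioConfig,
    TransitionCache,
    VisitModel,
    cohort_loglik,
    emission_loglik,
    forward_backward,
    predict_future,
    simulate_cohort,
    viterbi,
)

from conftest import enum_loglik, make_random_params, make_random_series


class TestEmissionLoglik:
    def test_density_one_at_mean_with_tuned_variance(self):
        """With sigma^2 = 1/(2 pi) the Gaussian density at the mean is 1."""
        em = EmissionParams(
            means=np.array([[2.0], [5.0]]),
            variances=np.full((2, 1), 1.0 / (2.0 * np.pi)),
        )
        ll = emission_loglik(np.array([2.0]), em)
        npt.assert_allclose(ll[0], 0.0, atol=1e-12)

    def test_identical_states_give_identical_entries(self):
        em = EmissionParams(means=np.ones((3, 2)), variances=np.ones((3, 2)))
        ll = emission_loglik(np.array([0.3, -1.2]), em)
        assert np.ptp(ll) == 0.0

    def test_matches_product_of_univariate_densities(self):
        rng = np.random.default_rng(0)
        em = EmissionParams(
            means=rng.normal(size=(4, 3)), variances=rng.uniform(0.5, 2, (4, 3))
        )
        z = rng.normal(size=3)
        expected = scipy.stats.norm.logpdf(
            z, em.means, np.sqrt(em.variances)
        ).sum(axis=1)
        npt.assert_allclose(emission_loglik(z, em), expected, atol=1e-12)

    def test_non_finite_observation_rejected(self):
        em = EmissionParams(means=np.zeros((2, 1)), variances=np.ones((2, 1)))
        with pytest.raises(ValueError, match="non-finite"):
            emission_loglik(np.array([np.nan]), em)


class TestForwardBackward:
    def test_single_visit_reduces_to_prior_mixture(self):
        params = make_random_params(3, 2, seed=1)
        p = make_random_series(params, 1, seed=2)
        post = forward_backward(params, p)
        dens = np.array(
            [
                scipy.stats.norm.logpdf(
                    p.observations[0],
                    params.emissions.means[s],
                    np.sqrt(params.emissions.variances[s]),
                ).sum()
                for s in range(3)
            ]
        )
        weights = params.pi * np.exp(dens)
        npt.assert_allclose(post.loglik, np.log(weights.sum()), rtol=1e-12)
        npt.assert_allclose(post.gamma[0], weights / weights.sum(), rtol=1e-10)
        assert post.xi.shape == (0, 3, 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_enumeration(self, seed):
        params = make_random_params(3, 2, seed=seed)
        p = make_random_series(params, 5, seed=seed + 100)
        post = forward_backward(params, p)
        npt.assert_allclose(post.loglik, enum_loglik(params, p), rtol=1e-10)

    def test_posterior_normalization_and_consistency(self):
        params = make_random_params(4, 2, seed=3, kind="forward_chain", order=2)
        p = make_random_series(params, 6, seed=4)
        post = forward_backward(params, p)
        npt.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)
        npt.assert_allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)
        # xi marginals reproduce gamma at both interval endpoints
        npt.assert_allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-8)
        npt.assert_allclose(post.xi.sum(axis=1), post.gamma[1:], atol=1e-8)

    def test_time_shift_invariance(self):
        params = make_random_params(3, 2, seed=5)
        p = make_random_series(params, 4, seed=6)
        shifted = PatientSeries(
            patient_id=p.patient_id,
            times=p.times + 37.25,
            observations=p.observations,
        )
        a = forward_backward(params, p)
        b = forward_backward(params, shifted)
        npt.assert_allclose(a.loglik, b.loglik, rtol=1e-12)
        npt.assert_allclose(a.gamma, b.gamma, atol=1e-12)
        assert np.array_equal(
            viterbi(params, p).states, viterbi(params, shifted).states
        )

    def test_no_underflow_on_long_series(self):
        """25 visits and 12 states stay finite under per-step scaling."""
        params = make_random_params(12, 3, seed=8)
        p = make_random_series(params, 25, seed=9)
        post = forward_backward(params, p)
        assert np.isfinite(post.loglik)
        assert np.isfinite(post.gamma).all()

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PatientSeries(
                patient_id="X",
                times=np.array([0.0, 1.0, 1.0]),
                observations=np.zeros((3, 1)),
            )


class TestCohortLoglik:
    def test_sums_over_patients_and_duplicates_double(self):
        params = make_random_params(3, 2, seed=10)
        p = make_random_series(params, 4, seed=11)
        single = Cohort(patients=(p,), feature_names=("f1", "f2"))
        ll1 = cohort_loglik(params, single)
        npt.assert_allclose(ll1, forward_backward(params, p).loglik, rtol=1e-12)
        p2 = PatientSeries(
            patient_id="P2", times=p.times, observations=p.observations
        )
        double = Cohort(patients=(p, p2), feature_names=("f1", "f2"))
        npt.assert_allclose(cohort_loglik(params, double), 2 * ll1, rtol=1e-12)

    def test_matches_enumeration_on_simulated_cohort(self):
        params = make_random_params(3, 2, seed=12, kind="forward_chain", order=2)
        config = ScenarioConfig(
            params=params,
            num_patients=20,
            visit_model=VisitModel(mean_visits=3.0, max_visits=5),
            entry_window=2.0,
            seed=13,
        )
        cohort, _ = simulate_cohort(config)
        expected = sum(enum_loglik(params, p) for p in cohort)
        npt.assert_allclose(cohort_loglik(params, cohort), expected, rtol=1e-10)

    def test_feature_mismatch_rejected(self):
        params = make_random_params(3, 2, seed=14)
        p = PatientSeries("P1", np.array([0.0]), np.zeros((1, 3)))
        bad = Cohort(patients=(p,), feature_names=("a", "b", "c"))
        with pytest.raises(ValueError, match="features"):
            cohort_loglik(params, bad)


class TestViterbi:
    def test_recovers_generating_sequence_with_separated_states(self):
        """With >= 10 sigma between state means, decoding should recover the
        simulated truth at nearly every visit."""
        params = make_random_params(
            3, 2, seed=15, kind="forward_chain", order=2, rate_scale=0.4
        )
        params = type(params)(
            Q=params.Q,
            pi=params.pi,
            emissions=EmissionParams(
                means=np.arange(3)[:, None] * np.full(2, 10.0),
                variances=np.ones((3, 2)),
            ),
            mask=params.mask,
        )
        config = ScenarioConfig(
            params=params,
            num_patients=100,
            visit_model=VisitModel(mean_visits=4.0),
            entry_window=2.0,
            seed=16,
        )
        cohort, truth = simulate_cohort(config)
        truth_by_id = {t.patient_id: t.states for t in truth}
        hits = total = 0
        for p in cohort:
            decoded = viterbi(params, p).states
            hits += int((decoded == truth_by_id[p.patient_id]).sum())
            total += p.num_visits
        assert hits / total >= 0.99

    def test_monotone_under_forward_chain_mask(self):
        params = make_random_params(5, 2, seed=17, kind="forward_chain", order=2)
        for seed in range(10):
            p = make_random_series(params, 8, seed=seed)
            states = viterbi(params, p).states
            assert (np.diff(states) >= 0).all()

    def test_single_state_chain_decodes_all_ones(self):
        # M=2 with no mass or reachability beyond state 1 behaves as M=1
        em = EmissionParams(means=np.zeros((2, 1)), variances=np.ones((2, 1)))
        mask = __import__("cthmm").build_structure_mask(
            2, "full", absorbing_last=False
        )
        params = type(make_random_params(2, 1, seed=0))(
            Q=np.zeros((2, 2)), pi=np.array([1.0, 0.0]), emissions=em, mask=mask
        )
        p = make_random_series(params, 4, seed=20)
        assert (viterbi(params, p).states == 1).all()

    def test_beats_random_sequences(self):
        """The decoded path's joint log-probability bounds 1000 random ones."""
        params = make_random_params(3, 2, seed=21)
        p = make_random_series(params, 6, seed=22)
        cache = TransitionCache(params.Q)

        def joint(seq):
            lp = np.log(params.pi[seq[0]])
            lp += scipy.stats.norm.logpdf(
                p.observations[0],
                params.emissions.means[seq[0]],
                np.sqrt(params.emissions.variances[seq[0]]),
            ).sum()
            for t in range(1, len(seq)):
                A = cache.transition(p.times[t] - p.times[t - 1])
                lp += np.log(A[seq[t - 1], seq[t]])
                lp += scipy.stats.norm.logpdf(
                    p.observations[t],
                    params.emissions.means[seq[t]],
                    np.sqrt(params.emissions.variances[seq[t]]),
                ).sum()
            return lp

        best = joint(viterbi(params, p).states - 1)
        rng = np.random.default_rng(23)
        for _ in range(1000):
            seq = rng.integers(0, 3, size=p.num_visits)
            assert best >= joint(seq) - 1e-10


class TestPredictFuture:
    def test_zero_horizon_returns_last_posterior(self):
        params = make_random_params(3, 2, seed=24)
        p = make_random_series(params, 4, seed=25)
        dist, _ = predict_future(params, p, 0.0)
        npt.assert_allclose(dist, forward_backward(params, p).gamma[-1], atol=1e-12)

    def test_absorbing_limit(self):
        params = make_random_params(
            3, 2, seed=26, kind="forward_chain", order=2, absorbing_last=True
        )
        p = make_random_series(params, 3, seed=27)
        dist, _ = predict_future(params, p, 1e6)
        assert dist[-1] >= 1 - 1e-6

    def test_expected_features_are_posterior_mixture(self):
        params = make_random_params(3, 2, seed=28)
        p = make_random_series(params, 4, seed=29)
        dist, feats = predict_future(params, p, 2.5)
        npt.assert_allclose(feats, dist @ params.emissions.means, atol=1e-12)

    def test_negative_horizon_rejected(self):
        params = make_random_params(2, 1, seed=30)
        p = make_random_series(params, 2, seed=31)
        with pytest.raises(ValueError, match="horizon"):
            predict_future(params, p, -1.0)
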