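"""EMHMM stack: forward likelihoods, VB fitting, clustering, scales, entropy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from gazehmm.emhmm import (
    HMMClusterer,
    VariationalGaussianHMM,
    ab_scale,
    fit_vbhmm,
    forward_loglik,
    overall_entropy,
    sample_hmm_sequences,
    vhem_cluster,
)
from gazehmm.gaze import GazeStrategy, ROI


def _random_hmm(K, d, rng, mean_scale=20.0):
    return dict(
        prior=rng.dirichlet(np.ones(K)),
        transition=rng.dirichlet(np.ones(K), size=K),
        means=rng.normal(0, mean_scale, (K, d)),
        covariances=np.array([np.diag(rng.uniform(1, 4, d)) for _ in range(K)]),
    )


def _enumerate_loglik(params, X):
    """Brute-force marginal likelihood: log-sum over all state paths."""
    from scipy.special import logsumexp

    means, covs = params["means"], params["covariances"]
    K, T = len(params["prior"]), X.shape[0]
    with np.errstate(divide="ignore"):
        logpi, logA = np.log(params["prior"]), np.log(params["transition"])
    path_logps = []
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]]
        for t in range(T):
            lp += multivariate_normal.logpdf(X[t], means[path[t]], covs[path[t]])
        path_logps.append(lp)
    return logsumexp(path_logps)


@pytest.mark.parametrize("K,T", [(1, 1), (1, 4), (2, 2), (2, 3), (3, 3), (3, 4)])
def test_forward_matches_exhaustive_enumeration(K, T):
    rng = np.random.default_rng(100 * K + T)
    params = _random_hmm(K, 2, rng)
    X = rng.normal(0, 20, (T, 2))
    got = forward_loglik(params, X)
    want = _enumerate_loglik(params, X)
    assert got == pytest.approx(want, rel=1e-10)


def test_single_state_forward_is_sum_of_gaussian_logpdfs():
    rng = np.random.default_rng(0)
    params = _random_hmm(1, 3, rng)
    X = rng.normal(0, 5, (4, 3))
    want = sum(
        multivariate_normal.logpdf(x, params["means"][0], params["covariances"][0]) for x in X
    )
    assert forward_loglik(params, X) == pytest.approx(want)


def test_forward_is_order_sensitive_under_asymmetric_transitions():
    params = dict(
        prior=np.array([0.9, 0.1]),
        transition=np.array([[0.1, 0.9], [0.9, 0.1]]),
        means=np.array([[0.0], [10.0]]),
        covariances=np.array([[[1.0]], [[1.0]]]),
    )
    X = np.array([[0.0], [10.0], [10.0]])
    assert forward_loglik(params, X) != pytest.approx(forward_loglik(params, X[::-1]), abs=1e-6)


def test_forward_rejects_dimension_mismatch():
    params = _random_hmm(2, 2, np.random.default_rng(0))
    with pytest.raises(ValueError):
        forward_loglik(params, np.zeros((3, 3)))


def test_forward_agrees_with_hmmlearn_reference():
    from hmmlearn.hmm import GaussianHMM

    rng = np.random.default_rng(5)
    params = _random_hmm(3, 2, rng)
    X = rng.normal(0, 20, (5, 2))
    ref = GaussianHMM(n_components=3, covariance_type="full", init_params="")
    ref.startprob_ = params["prior"]
    ref.transmat_ = params["transition"]
    ref.means_ = params["means"]
    ref.covars_ = params["covariances"]
    assert forward_loglik(params, X) == pytest.approx(ref.score(X), rel=1e-9)


# -- VB fitting --------------------------------------------------------------

def test_vbhmm_recovers_planted_two_state_model():
    truth = dict(
        prior=np.array([0.5, 0.5]),
        transition=np.array([[0.8, 0.2], [0.3, 0.7]]),
        means=np.array([[20.0, 20.0], [50.0, 40.0]]),
        covariances=np.array([np.eye(2) * 25.0] * 2),
    )
    seqs = sample_hmm_sequences(truth, 200, 3, np.random.default_rng(2))
    model = fit_vbhmm(list(seqs), k_range=(1, 4), restarts=10, rng_seed=0)
    assert model.n_states_ == 2
    order = np.argsort(model.means_[:, 0])
    err = np.linalg.norm(model.means_[order] - truth["means"], axis=1)
    assert np.all(err < 5.0)


def test_vbhmm_mean_error_shrinks_with_more_sequences():
    truth = dict(
        prior=np.array([0.6, 0.4]),
        transition=np.array([[0.7, 0.3], [0.4, 0.6]]),
        means=np.array([[10.0, 10.0], [40.0, 35.0]]),
        covariances=np.array([np.eye(2) * 16.0] * 2),
    )

    def mean_error(n):
        seqs = sample_hmm_sequences(truth, n, 3, np.random.default_rng(3))
        m = VariationalGaussianHMM(n_states=2, n_restarts=5, random_state=0).fit(list(seqs))
        order = np.argsort(m.means_[:, 0])
        return np.linalg.norm(m.means_[order] - truth["means"])

    assert mean_error(800) < mean_error(50)


def test_vbhmm_degenerate_data_yields_single_state_with_warning():
    X = np.full((20, 3, 2), 7.0) + np.random.default_rng(0).normal(0, 1e-12, (20, 3, 2))
    with pytest.warns(UserWarning):
        model = fit_vbhmm(list(X), k_range=(1, 3), restarts=3, rng_seed=0)
    assert model.n_states_ == 1


def test_more_restarts_never_decrease_selected_lower_bound():
    truth = dict(
        prior=np.array([0.5, 0.5]),
        transition=np.array([[0.6, 0.4], [0.4, 0.6]]),
        means=np.array([[0.0, 0.0], [15.0, 15.0]]),
        covariances=np.array([np.eye(2) * 9.0] * 2),
    )
    seqs = list(sample_hmm_sequences(truth, 60, 3, np.random.default_rng(4)))
    lb_few = fit_vbhmm(seqs, k_range=(1, 3), restarts=2, rng_seed=1).lower_bound_
    lb_many = fit_vbhmm(seqs, k_range=(1, 3), restarts=4, rng_seed=1).lower_bound_
    assert lb_many >= lb_few - 1e-9


def test_vbhmm_requires_at_least_two_sequences():
    with pytest.raises(ValueError):
        fit_vbhmm([np.zeros((3, 2))], restarts=1)


# -- clustering --------------------------------------------------------------

def _perturbed(template, rng, jitter=1.0):
    out = dict(template)
    out["means"] = template["means"] + rng.normal(0, jitter, template["means"].shape)
    return out


@pytest.fixture(scope="module")
def planted_cohort():
    rng = np.random.default_rng(0)
    temp_a = dict(
        prior=np.array([1.0, 0.0]),
        transition=np.array([[0.0, 1.0], [0.0, 1.0]]),
        means=np.array([[15.0, 15.0], [25.0, 15.0]]),  # "eyes": high on the face
        covariances=np.array([np.eye(2) * 4.0] * 2),
    )
    temp_b = dict(
        prior=np.array([1.0, 0.0]),
        transition=np.array([[0.0, 1.0], [0.0, 1.0]]),
        means=np.array([[32.0, 40.0], [32.0, 50.0]]),  # "nose/mouth": >5 SD away
        covariances=np.array([np.eye(2) * 4.0] * 2),
    )
    hmms = [_perturbed(temp_a, rng) for _ in range(10)] + [
        _perturbed(temp_b, rng) for _ in range(10)
    ]
    return hmms


def test_vhem_recovers_planted_groups_exactly(planted_cohort):
    result = vhem_cluster(planted_cohort, restarts=4, n_virtual_samples=40, rng_seed=0)
    labels = result.assignment
    assert len(set(labels[:10])) == 1
    assert len(set(labels[10:])) == 1
    assert labels[0] != labels[10]
    # each group's data is better explained by its own representative
    own = result.logliks[np.arange(20), labels]
    other = result.logliks[np.arange(20), 1 - labels]
    assert np.all(own > other)


def test_vhem_ab_scale_signs_follow_group_membership(planted_cohort):
    result = vhem_cluster(planted_cohort, restarts=4, n_virtual_samples=40, rng_seed=0)
    sgn = np.sign(result.ab_scale)
    assert len(set(sgn[:10])) == 1
    assert len(set(sgn[10:])) == 1
    assert sgn[0] != sgn[10]
    assert np.all(np.abs(result.ab_scale) <= 1.0)


def test_vhem_median_state_count_rule():
    rng = np.random.default_rng(1)
    hmms = [_random_hmm(K, 2, rng) for K in (2, 3, 3, 4)]
    clusterer = HMMClusterer(n_clusters=2, n_restarts=2, n_virtual_samples=20, random_state=0)
    clusterer.fit(hmms)
    assert clusterer.rep_states_ == 3
    hmms2 = [_random_hmm(K, 2, rng) for K in (2, 3)]
    clusterer2 = HMMClusterer(n_clusters=2, n_restarts=2, n_virtual_samples=20, random_state=0)
    clusterer2.fit(hmms2)
    assert clusterer2.rep_states_ == 3  # halves round up


def test_vhem_assignment_invariant_to_input_order(planted_cohort):
    base = vhem_cluster(planted_cohort, restarts=3, n_virtual_samples=30, rng_seed=0)
    perm = np.random.default_rng(2).permutation(len(planted_cohort))
    shuffled = [planted_cohort[i] for i in perm]
    again = vhem_cluster(shuffled, restarts=3, n_virtual_samples=30, rng_seed=0)
    a = base.assignment[perm]
    b = again.assignment
    assert np.array_equal(a, b) or np.array_equal(a, 1 - b)


def test_vhem_needs_enough_hmms(planted_cohort):
    with pytest.raises(ValueError):
        HMMClusterer(n_clusters=2).fit(planted_cohort[:1])


# -- AB scale ----------------------------------------------------------------

def test_ab_scale_examples():
    assert ab_scale(-5.0, -5.0) == 0.0
    assert ab_scale(-10.0, -30.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ab_scale(0.0, 0.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.floats(-1e6, 1e6, allow_nan=False),
    st.floats(-1e6, 1e6, allow_nan=False),
)
def test_ab_scale_bounded_for_any_signs(a, b):
    if abs(a) + abs(b) == 0:
        return
    assert -1.0 <= ab_scale(a, b) <= 1.0


# -- entropy -----------------------------------------------------------------

def _chain_strategy(sigma=10.0):
    rois = [
        ROI(np.array([x, y, 1.0]), np.diag([sigma**2, sigma**2, 1.0]))
        for x, y in ((20.0, 24.0), (44.0, 24.0), (32.0, 40.0))
    ]
    return GazeStrategy(rois=rois, saccade_noise_sd=0.0, image_size=64)


def test_entropy_of_deterministic_chain_matches_closed_form():
    rep = overall_entropy(_chain_strategy(10.0), T=3, include_scale=False)
    assert rep.discrete_component == pytest.approx(0.0)
    assert rep.total == pytest.approx(3 * np.log(2 * np.pi * np.e * 100.0), abs=1e-9)
    assert rep.normalized == pytest.approx(rep.total / 3)


def test_entropy_uniform_two_state_chain_discrete_component():
    params = dict(
        prior=np.array([0.5, 0.5]),
        transition=np.full((2, 2), 0.5),
        means=np.zeros((2, 2)),
        covariances=np.array([np.eye(2)] * 2),
    )
    rep = overall_entropy(params, T=3)
    assert rep.discrete_component == pytest.approx(3 * np.log(2))


def test_entropy_decreases_when_emissions_shrink():
    big = overall_entropy(_chain_strategy(10.0), T=3).total
    small = overall_entropy(_chain_strategy(5.0), T=3).total
    assert small < big


def test_entropy_invariant_under_state_relabelling():
    rng = np.random.default_rng(3)
    params = _random_hmm(3, 2, rng)
    perm = np.array([2, 0, 1])
    relabeled = dict(
        prior=params["prior"][perm],
        transition=params["transition"][np.ix_(perm, perm)],
        means=params["means"][perm],
        covariances=params["covariances"][perm],
    )
    assert overall_entropy(params, T=3).total == pytest.approx(
        overall_entropy(relabeled, T=3).total
    )


def test_entropy_rejects_singular_covariance():
    params = dict(
        prior=np.array([1.0]),
        transition=np.array([[1.0]]),
        means=np.zeros((1, 2)),
        covariances=np.zeros((1, 2, 2)),
    )
    with pytest.raises(np.linalg.LinAlgError):
        overall_entropy(params)


def test_entropy_components_sum_to_total():
    params = _random_hmm(2, 3, np.random.default_rng(9))
    rep = overall_entropy(params, T=3)
    assert rep.total == pytest.approx(rep.discrete_component + rep.differential_component)
    assert rep.discrete_component >= 0
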