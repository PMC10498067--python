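"""Graded-model estimation: recovery, EM monotonicity, EAP oracles, TCC."""

import warnings

import numpy as np
import pytest

from ordif.grm import GradedResponseModel, ItemParameters, eap_theta
from ordif.grm import test_characteristic_curve as characteristic_curve  # noqa: alias
# (aliased so pytest does not try to collect the library function)
from ordif.simulate import SyntheticSpec, generate


def test_parameter_recovery(recovery_data, recovery_fit):
    spec, _, _ = recovery_data
    est = recovery_fit.params_
    assert np.all(np.abs(est.discrimination - spec.discrimination) <= 0.25)
    assert np.all(np.abs(est.thresholds - spec.thresholds) <= 0.2)


def test_em_loglik_nondecreasing(recovery_fit):
    diffs = np.diff(recovery_fit.loglik_path_)
    assert np.all(diffs >= -1e-6)


def test_loglik_dominates_generating_parameters(recovery_data, recovery_fit):
    """ML estimates cannot fit the estimation sample worse than the truth."""
    spec, df, _ = recovery_data
    X = df.drop(columns="group")
    from ordif.grm import _category_logprobs, _person_node_loglik, quadrature_grid
    from scipy.special import logsumexp

    nodes, wq = quadrature_grid()
    Y = X.to_numpy().astype(int) - 1
    logP = _category_logprobs(spec.discrimination, spec.thresholds, nodes)
    ll_true = float(
        logsumexp(_person_node_loglik(logP, Y) + np.log(wq)[None, :], axis=1).sum()
    )
    n = len(df)
    assert recovery_fit.loglik_ >= ll_true - 1e-6 * n


def test_equal_discrimination_recovery():
    a = np.full(8, 1.3)
    rng_b = np.random.default_rng(4)
    b = np.sort(rng_b.uniform(-2, 2, (8, 4)), axis=1)
    b = np.maximum.accumulate(b + np.arange(4) * 0.05, axis=1)
    spec = SyntheticSpec(n_per_group=(1000, 1000), discrimination=a, thresholds=b)
    df, _ = generate(spec, seed=21)
    est = GradedResponseModel(variant="equal_discrimination").fit(df.drop(columns="group"))
    assert np.all(est.params_.discrimination == est.params_.discrimination[0])
    assert abs(est.params_.discrimination[0] - 1.3) <= 0.1


def test_eap_monotone_in_response_ordering(recovery_data):
    """EAP respects coordinatewise dominance of response patterns, and the
    average EAP rises strictly with the sum score."""
    spec, df, _ = recovery_data
    X = df.drop(columns="group").iloc[:400]
    est = GradedResponseModel(variant="equal_discrimination").fit(X)
    th = est.score_theta(X).theta
    sums = X.sum(axis=1).to_numpy()
    import pandas as pd

    from scipy.stats import spearmanr

    # the sum score is not sufficient under the graded model, so exact
    # monotonicity in the sum is not guaranteed — near-perfect rank
    # agreement is
    assert spearmanr(sums, th).statistic > 0.99
    # dominance chain: raising any single response raises the EAP
    chain = np.tile(np.array([2, 3, 2, 3, 2, 3, 2, 3, 2, 3]), (10, 1))
    for i in range(1, 10):
        chain[i:, i - 1] += 1
    th_chain = est.score_theta(
        pd.DataFrame(chain, columns=est.item_ids_)
    ).theta
    assert np.all(np.diff(th_chain) > 0)


def test_extreme_patterns_bound_eap(recovery_fit, recovery_data):
    _, df, _ = recovery_data
    X = df.drop(columns="group").copy()
    X.iloc[0] = 1  # all-lowest
    X.iloc[1] = 5  # all-highest
    th = recovery_fit.score_theta(X).theta
    assert th[0] == pytest.approx(th.min())
    assert th[1] == pytest.approx(th.max())


def test_eap_standardisation(recovery_fit, recovery_data):
    _, df, _ = recovery_data
    th = recovery_fit.score_theta(df.drop(columns="group"))
    assert th.theta.mean() == pytest.approx(0.0, abs=1e-8)
    assert th.theta.std() == pytest.approx(1.0, abs=1e-8)


def test_eap_matches_bruteforce_quadrature_oracle():
    """Posterior mean over the grid recomputed independently, to 1e-6."""
    params = ItemParameters(
        np.array([1.2, 0.8]), np.array([[-0.5, 0.7], [-1.0, 1.0]]), ["i1", "i2"]
    )
    pattern = np.array([[2, 3]])
    got = eap_theta(params, pattern, standardize=False)

    nodes = np.linspace(-4, 4, 49)
    w = np.exp(-0.5 * nodes**2)
    w /= w.sum()

    def cat_prob(theta, a, b, k):
        cum = 1.0 / (1.0 + np.exp(-a * (theta - np.asarray(b))))
        full = np.concatenate([[1.0], cum, [0.0]])
        return full[k - 1] - full[k]

    post = np.array(
        [
            w[q]
            * cat_prob(nodes[q], 1.2, [-0.5, 0.7], 2)
            * cat_prob(nodes[q], 0.8, [-1.0, 1.0], 3)
            for q in range(49)
        ]
    )
    oracle_mean = float((post * nodes).sum() / post.sum())
    assert got.theta[0] == pytest.approx(oracle_mean, abs=1e-6)


def test_empty_anchor_set_raises(recovery_fit, recovery_data):
    _, df, _ = recovery_data
    with pytest.raises(ValueError, match="purification"):
        recovery_fit.score_theta(df.drop(columns="group"), anchor_items=[])


def test_single_category_item_excluded():
    rng = np.random.default_rng(0)
    X = rng.integers(1, 6, size=(200, 3)).astype(float)
    X[:, 1] = 3.0
    with pytest.warns(UserWarning, match="single observed category"):
        est = GradedResponseModel(max_iter=5).fit(X)
    assert est.params_.n_items == 2


def test_tcc_identities_and_bounds():
    a = np.array([1.0, 1.5])
    b = np.array([[-1.0, 0.0, 1.0, 2.0], [-0.5, 0.3, 0.9, 1.8]])
    ref = ItemParameters(a, b, ["i1", "i2"])
    grid = np.linspace(-4, 4, 41)
    same = characteristic_curve({"m": ref, "f": ref}, ["i1", "i2"], grid)
    assert np.allclose(same["m"], same["f"], atol=1e-12)
    # uniform shift of focal thresholds orders the curves everywhere
    foc = ItemParameters(a, b + 0.5, ["i1", "i2"])
    shifted = characteristic_curve({"m": ref, "f": foc}, ["i1", "i2"], grid)
    assert np.all(shifted["f"].to_numpy() <= shifted["m"].to_numpy())
    # bounds and monotonicity
    assert np.all(same["m"] >= 2.0) and np.all(same["m"] <= 10.0)
    assert np.all(np.diff(same["m"]) >= 0)


def test_missing_responses_handled():
    spec = SyntheticSpec(
        n_per_group=(200, 200),
        discrimination=np.array([1.0, 1.2, 0.9, 1.4]),
        thresholds=np.tile(np.array([-1.0, 0.0, 1.0, 2.0]), (4, 1)),
    )
    df, _ = generate(spec, seed=3)
    X = df.drop(columns="group").astype(float)
    rng = np.random.default_rng(1)
    mask = rng.random(X.shape) < 0.05
    X = X.mask(mask)
    est = GradedResponseModel().fit(X)
    th = est.score_theta(X).theta
    assert np.all(np.isfinite(th))
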