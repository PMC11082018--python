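"""Estimation pipeline: Spearman, PD repair, glasso, EBIC selection."""

import numpy as np
import pytest
from scipy import optimize, stats

from promnet import (
    CorrelationMatrix,
    EstimatorConfig,
    ebic_score,
    ebicglasso,
    glasso_fit,
    lambda_path,
    nearest_pd_repair,
    precision_to_partial,
    spearman_correlation,
)
from promnet.synthetic import sample_observations

from conftest import make_truth_from_edges


# ---------------------------------------------------------------- Spearman

def test_spearman_monotone_and_reversed():
    X = np.column_stack([[1, 2, 3], [10, 20, 30]])
    assert spearman_correlation(X).values[0, 1] == pytest.approx(1.0)
    X = np.column_stack([[1, 2, 3], [3, 2, 1]])
    assert spearman_correlation(X).values[0, 1] == pytest.approx(-1.0)


def test_spearman_ties_match_rank_then_pearson_oracle():
    X = np.array([
        [1, 4, 2], [2, 4, 2], [2, 1, 3], [3, 1, 3], [3, 2, 5], [1, 2, 5],
    ], dtype=float)
    got = spearman_correlation(X).values
    ranks = np.column_stack([stats.rankdata(X[:, j]) for j in range(3)])
    expected = np.corrcoef(ranks, rowvar=False)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_spearman_pairwise_missing_records_n():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 3))
    X[:10, 0] = np.nan
    cm = spearman_correlation(X, missing_policy="pairwise")
    assert cm.pairwise_n[0, 1] == 30
    assert cm.pairwise_n[1, 2] == 40
    # oracle on the complete subset
    mask = ~np.isnan(X[:, 0])
    expected = stats.spearmanr(X[mask, 0], X[mask, 1]).statistic
    assert cm.values[0, 1] == pytest.approx(expected)


def test_spearman_too_few_complete_pairs_errors():
    X = np.full((5, 2), np.nan)
    X[:2] = [[1, 2], [3, 4]]
    with pytest.raises(ValueError, match="complete observations"):
        spearman_correlation(X, missing_policy="pairwise")


# ---------------------------------------------------------------- PD repair

def _cm(vals):
    p = vals.shape[0]
    return CorrelationMatrix(labels=[f"V{i}" for i in range(p)], values=vals,
                             pairwise_n=np.full((p, p), 100))


def test_pd_repair_leaves_pd_matrix_unchanged():
    vals = np.array([[1.0, 0.3], [0.3, 1.0]])
    out = nearest_pd_repair(_cm(vals))
    assert not out.pd_repaired
    np.testing.assert_array_equal(out.values, vals)
    ident = nearest_pd_repair(_cm(np.eye(4)))
    np.testing.assert_array_equal(ident.values, np.eye(4))


def test_pd_repair_indefinite_matrix():
    vals = np.array([
        [1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0],
    ])
    assert np.linalg.eigvalsh(vals)[0] < 0  # genuinely indefinite
    out = nearest_pd_repair(_cm(vals), floor=1e-3)
    assert out.pd_repaired
    assert np.linalg.eigvalsh(out.values)[0] >= 1e-3 - 1e-12
    np.testing.assert_allclose(np.diag(out.values), 1.0, atol=1e-12)
    # idempotent: repairing again changes nothing
    again = nearest_pd_repair(out, floor=1e-3)
    np.testing.assert_allclose(again.values, out.values, atol=1e-12)


# ------------------------------------------------------------- lambda path

def test_lambda_path_endpoints_and_log_spacing():
    vals = np.eye(3)
    vals[0, 1] = vals[1, 0] = 0.44
    vals[1, 2] = vals[2, 1] = 0.2
    path = lambda_path(_cm(vals), n_lambda=100, min_ratio=0.01)
    assert path[0] == pytest.approx(0.44)
    assert path[-1] == pytest.approx(0.0044)
    ratios = path[1:] / path[:-1]
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)


def test_lambda_path_degenerate_all_zero():
    with pytest.warns(UserWarning):
        path = lambda_path(_cm(np.eye(4)))
    np.testing.assert_array_equal(path, [0.0])


# ------------------------------------------------------------------ glasso

def test_glasso_above_lambda_max_gives_empty_network():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((100, 5))
    S = spearman_correlation(X)
    lam_max = lambda_path(S)[0]
    fit, _ = glasso_fit(S, lam_max * 1.01)
    assert fit.edge_count == 0


def test_glasso_unpenalized_is_inverse():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((500, 4))
    S = spearman_correlation(X)
    fit, _ = glasso_fit(S, 0.0, EstimatorConfig(conv_tol=1e-9))
    np.testing.assert_allclose(fit.precision, np.linalg.inv(S.values),
                               atol=1e-6)


def _penalized_objective(S, lam, eps=1e-14):
    """Smoothed penalized negative log-likelihood over symmetric Theta."""
    p = S.shape[0]
    iu = np.triu_indices(p)

    def unpack(x):
        T = np.zeros((p, p))
        T[iu] = x
        return T + np.triu(T, 1).T

    def f(x):
        T = unpack(x)
        w = np.linalg.eigvalsh(T)
        if w[0] <= 1e-10:
            return 1e8 - w[0]
        off = T[np.triu_indices(p, 1)]
        pen = lam * 2.0 * np.sum(np.sqrt(off**2 + eps))
        _, ld = np.linalg.slogdet(T)
        return -(ld - np.sum(S * T)) + pen

    return unpack, f, iu


@pytest.mark.parametrize("lam", [0.05, 0.1, 0.2])
def test_glasso_matches_brute_force_optimizer_p3(chain3_truth, lam):
    X = sample_observations(chain3_truth, 400, likert=False, seed=6)
    S = spearman_correlation(X.to_numpy())
    fit, _ = glasso_fit(S, lam, EstimatorConfig(conv_tol=1e-9))
    unpack, f, iu = _penalized_objective(S.values, lam)
    x0 = np.linalg.inv(S.values)[iu]
    res = optimize.minimize(f, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 40000, "maxfev": 40000})
    theta_oracle = unpack(res.x)
    assert np.abs(fit.precision - theta_oracle).max() < 1e-4


def test_glasso_matches_sklearn_reference():
    sklearn_cov = pytest.importorskip("sklearn.covariance")
    rng = np.random.default_rng(3)
    X = rng.standard_normal((300, 8))
    X[:, 1] += 0.7 * X[:, 0]
    S = spearman_correlation(X)
    for lam in (0.3, 0.1, 0.05):
        fit, _ = glasso_fit(S, lam, EstimatorConfig(conv_tol=1e-8))
        _, ref = sklearn_cov.graphical_lasso(S.values, alpha=lam,
                                             max_iter=2000, tol=1e-9)
        assert np.abs(fit.precision - ref).max() < 1e-3


# -------------------------------------------------------------------- EBIC

def test_ebic_direct_formula_identity_precision():
    fit, _ = glasso_fit(np.eye(3), 1.0)
    np.testing.assert_allclose(fit.precision, np.eye(3), atol=1e-12)
    # L = (100/2)(log det I - trace(I)) = -150; E = 0 -> EBIC = 300
    assert ebic_score(fit, np.eye(3), n=100, gamma=0.25) == pytest.approx(300.0)


def test_ebic_gamma_zero_is_bic():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((80, 4))
    S = spearman_correlation(X)
    fit, _ = glasso_fit(S, 0.1)
    L = 0.5 * 80 * (fit.logdet - np.sum(S.values * fit.precision))
    bic = -2 * L + fit.edge_count * np.log(80)
    assert ebic_score(fit, S, 80, gamma=0.0) == pytest.approx(bic)


def test_ebic_path_ranking_matches_reevaluation():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((50, 4))
    X[:, 2] += 0.6 * X[:, 1]
    S = nearest_pd_repair(spearman_correlation(X))
    path = lambda_path(S, n_lambda=25)
    fits = []
    state = None
    for lam in path:
        fit, state = glasso_fit(S, float(lam), state=state)
        fit.ebic = ebic_score(fit, S, 50, 0.25)
        fits.append(fit)
    # independent re-evaluation of the formula from the stored matrices
    def ref_ebic(fit):
        sgn, ld = np.linalg.slogdet(fit.precision)
        L = 0.5 * 50 * (ld - np.trace(S.values @ fit.precision))
        E = int((np.abs(fit.precision[np.triu_indices(4, 1)]) > 1e-8).sum())
        return -2 * L + E * np.log(50) + 4 * E * 0.25 * np.log(4)

    ref = [ref_ebic(f) for f in fits]
    np.testing.assert_allclose([f.ebic for f in fits], ref, rtol=1e-10)
    assert int(np.argmin([f.ebic for f in fits])) == int(np.argmin(ref))


# ------------------------------------------------------- partial correlation

def test_precision_to_partial_examples():
    np.testing.assert_array_equal(precision_to_partial(np.eye(4)),
                                  np.zeros((4, 4)))
    w = precision_to_partial(np.array([[1.0, -0.5], [-0.5, 1.0]]))
    assert w[0, 1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        precision_to_partial(np.array([[1.0, 0.0], [0.0, -2.0]]))


def test_precision_to_partial_roundtrip():
    rng = np.random.default_rng(6)
    A = rng.standard_normal((5, 5))
    theta = A @ A.T + 5 * np.eye(5)
    direct = precision_to_partial(theta)
    via_cov = precision_to_partial(np.linalg.inv(np.linalg.inv(theta)))
    np.testing.assert_allclose(direct, via_cov, atol=1e-10)


# -------------------------------------------------------------- ebicglasso

def test_selected_support_recovers_strong_edges():
    truth = make_truth_from_edges(
        6, [(0, 1, 0.3), (1, 2, 0.3), (2, 3, 0.3), (4, 5, 0.3)])
    X = sample_observations(truth, 2000, likert=False, seed=3)
    net = ebicglasso(X.to_numpy())
    est = np.abs(net.weights) > 0
    true = np.abs(truth.partials) > 1e-12
    np.testing.assert_array_equal(est, true)


def test_independent_columns_give_near_empty_network():
    counts = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((1000, 6))
        counts.append(ebicglasso(X).edge_count())
    assert np.median(counts) <= 1


def test_higher_gamma_never_adds_edges():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((200, 8))
    X[:, 1] += 0.5 * X[:, 0]
    e_low = ebicglasso(X, EstimatorConfig(gamma=0.25)).edge_count()
    e_high = ebicglasso(X, EstimatorConfig(gamma=0.75)).edge_count()
    assert e_high <= e_low


def test_edge_count_monotone_along_path():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((150, 7))
    X[:, 3] += 0.4 * X[:, 2]
    S = nearest_pd_repair(spearman_correlation(X))
    state = None
    counts = []
    for lam in lambda_path(S, n_lambda=40):
        fit, state = glasso_fit(S, float(lam), state=state)
        counts.append(fit.edge_count)
    assert all(a <= b for a, b in zip(counts[:-1], counts[1:]))


def test_edge_exclusion_consistency_and_provenance():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((300, 6))
    X[:, 1] += 0.6 * X[:, 0]
    net = ebicglasso(X)
    assert net.edge_count() == net.provenance["edge_count"]
    assert net.provenance["gamma"] == 0.25
    assert net.provenance["n"] == 300
    iu = np.triu_indices(6, 1)
    assert np.all(np.abs(net.weights[iu][net.weights[iu] != 0]) > 1e-8)
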