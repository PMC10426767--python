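import numpy as np
import pytest

from growl import (
    KernelSpec,
    Partition,
    SingularGramError,
    TrialDataset,
    build_simplex,
    fit_main_effect,
    predict,
    ramsvm_loss,
    solve_dual_kernel,
    solve_dual_linear,
    transform_residuals,
)
from growl.ramsvm import RecordSet, ramsvm_loss_matrix

from _qp_oracle import oracle_dual_optimum
from conftest import make_dataset


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------


def test_loss_at_zero_decision():
    """f = 0 gives (1-g)(K-1) + g(K-1) = K-1 for every label."""
    code = build_simplex(3)
    for lab in (1, 2, 3):
        assert ramsvm_loss(lab, np.zeros(2), 0.5, code) == pytest.approx(2.0)


def test_loss_vanishes_at_scaled_own_vertex():
    """f = (K-1) W_k puts every hinge at its kink: zero loss for label k."""
    for K in (2, 3, 5):
        code = build_simplex(K)
        for k in range(1, K + 1):
            f = (K - 1.0) * code.W[k - 1]
            assert ramsvm_loss(k, f, 0.5, code) == pytest.approx(0.0, abs=1e-12)


def test_loss_binary_hand_value():
    # K=2, label 1, f=-0.5: 0.5*(1+0.5) + 0.5*(1-(-0.5)) = 1.5
    code = build_simplex(2)
    assert ramsvm_loss(1, np.array([-0.5]), 0.5, code) == pytest.approx(1.5)


def test_loss_rejects_bad_gamma():
    with pytest.raises(ValueError):
        ramsvm_loss(1, np.zeros(1), 1.5, build_simplex(2))


def test_loss_matrix_matches_scalar(rng):
    code = build_simplex(4)
    F = rng.normal(size=(30, 3))
    labels = rng.integers(1, 5, size=30)
    vec = ramsvm_loss_matrix(labels, F, 0.3, code)
    ref = [ramsvm_loss(l, f, 0.3, code) for l, f in zip(labels, F)]
    np.testing.assert_allclose(vec, ref, atol=1e-12)


# --------------------------------------------------------------------------
# residual transform
# --------------------------------------------------------------------------


def _toy_dataset(R):
    n = len(R)
    X = np.linspace(-1, 1, n)[:, None]
    A = np.tile([1, 2, 3], n)[:n]
    prop = np.full((n, 3), 1 / 3)
    return TrialDataset(X=X, A=A, R=np.asarray(R, float), prop=prop)


def test_transform_positive_negative_zero_residuals():
    ds = _toy_dataset([2.0, -1.0, 0.0])
    part = Partition([1, 2, 3], 3)  # p(group|x) = 1/3 each
    rec = transform_residuals(ds, part, s=None, mode="expand")
    # subject 0: residual +2, weight 2/(1/3) = 6, label unchanged
    # subject 1: residual -1 -> 2 records, other groups, weight 1/(1/3) = 3
    # subject 2: residual 0 -> nothing
    assert len(rec) == 3
    r0 = [r for r in rec if r.index == 0]
    assert len(r0) == 1 and r0[0].group_label == part.labels[ds.A[0] - 1]
    assert r0[0].weight == pytest.approx(6.0)
    r1 = sorted((r.group_label for r in rec if r.index == 1))
    own1 = part.labels[ds.A[1] - 1]
    assert r1 == sorted(set(range(1, 4)) - {own1})
    assert all(r.weight == pytest.approx(3.0) for r in rec if r.index == 1)


def test_transform_sample_mode_weight_inflation():
    ds = _toy_dataset([-1.0])
    part = Partition([1, 2, 3], 3)
    rec = transform_residuals(ds, part, s=None, mode="sample", seed=0)
    assert len(rec) == 1
    own = part.labels[ds.A[0] - 1]
    assert rec[0].group_label != own
    assert rec[0].weight == pytest.approx((3 - 1) * 1.0 / (1 / 3))


def test_expand_equals_sample_in_expectation(rng):
    """At any fixed decision function the expand-mode weighted loss equals
    the mean over sampled switches, within 3 Monte-Carlo SEs."""
    ds = make_dataset(n=25, d=2, M=4, seed=3)
    part = Partition([1, 1, 2, 3], 3)
    s = fit_main_effect(ds)
    code = build_simplex(3)
    B = rng.normal(size=(2, 2))  # fixed arbitrary (K-1) x d decision function

    def weighted_loss(rec):
        f = rec.X @ B.T
        return float(rec.weights @ ramsvm_loss_matrix(rec.labels, f, 0.5, code))

    expand_val = weighted_loss(transform_residuals(ds, part, s, mode="expand"))
    draws = np.array([
        weighted_loss(transform_residuals(ds, part, s, mode="sample", seed=k))
        for k in range(400)
    ])
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - expand_val) < 3 * se + 1e-12


# --------------------------------------------------------------------------
# main effect
# --------------------------------------------------------------------------


def test_main_effect_constant_and_noiseless():
    ds = make_dataset(n=100, d=3, M=2, seed=1, R=np.full(100, 3.0))
    s = fit_main_effect(ds)
    np.testing.assert_allclose(s(ds.X), 3.0, atol=1e-10)

    ds2 = make_dataset(n=100, d=3, M=2, seed=2)
    R = 1.0 + 2.0 * ds2.X[:, 0]
    ds2 = TrialDataset(ds2.X, ds2.A, R, ds2.prop)
    s2 = fit_main_effect(ds2)
    np.testing.assert_allclose(s2.coef_, [1.0, 2.0, 0.0, 0.0], atol=1e-8)


def test_main_effect_rank_deficient_warns():
    X = np.ones((10, 2))  # duplicate constant columns
    ds = TrialDataset(X, np.tile([1, 2], 5), np.arange(10.0),
                      np.full((10, 2), 0.5))
    with pytest.warns(RuntimeWarning):
        fit_main_effect(ds)


# --------------------------------------------------------------------------
# dual solvers vs closed form and QP oracle
# --------------------------------------------------------------------------


def test_linear_dual_closed_form_single_record():
    """n=1, K=2, intercept-only: objective s^2/(2 lam) - s over s in [0,1],
    minimised at s = lam -> objective -lam/2, beta = 1."""
    rec = RecordSet(np.empty((1, 0)), np.array([1]), np.array([1.0]),
                    np.array([0]), 1)
    state, model = solve_dual_linear(rec, build_simplex(2), lam=0.25,
                                     gamma=0.5, tol=1e-12)
    assert state.objective == pytest.approx(-0.125, abs=1e-10)
    assert model.B[0, 0] == pytest.approx(1.0, abs=1e-8)


def test_all_zero_weights_give_zero_model():
    rec = RecordSet(np.ones((3, 2)), np.array([1, 2, 1]), np.zeros(3),
                    np.arange(3), 3)
    code = build_simplex(2)
    state, model = solve_dual_linear(rec, code, lam=1.0)
    assert np.all(state.alpha == 0) and np.all(model.B == 0)
    state, kmodel = solve_dual_kernel(rec, code, KernelSpec("rbf", 1.0), lam=1.0)
    assert np.all(kmodel.Theta == 0) and np.all(kmodel.intercepts == 0)


@pytest.mark.parametrize("seed,n,K,gamma", [(0, 8, 3, 0.5), (1, 10, 2, 0.5),
                                            (2, 6, 4, 0.25), (3, 12, 2, 0.4)])
def test_linear_dual_matches_qp_oracle(seed, n, K, gamma):
    rng = np.random.default_rng(seed)
    rec = RecordSet(rng.normal(size=(n, 2)), rng.integers(1, K + 1, n),
                    rng.uniform(0.2, 2.0, n), np.arange(n), n)
    code = build_simplex(K)
    lam = 0.5
    state, model = solve_dual_linear(rec, code, lam, gamma, tol=1e-10,
                                     max_sweeps=20000)
    Xa = np.column_stack([np.ones(n), rec.X])
    ref_obj, ref_alpha = oracle_dual_optimum(rec, code, gamma, Xa @ Xa.T, n, lam)
    assert state.objective == pytest.approx(ref_obj, abs=1e-6)
    # primal recovery consistent with the oracle's multipliers
    assert np.all(state.alpha >= -1e-12)
    assert np.all(state.alpha <= state.upper + 1e-12)


@pytest.mark.parametrize("seed,n,K,kernel", [
    (0, 6, 2, KernelSpec("rbf", 1.0)),
    (1, 7, 3, KernelSpec("rbf", 0.5)),
    (2, 6, 2, KernelSpec("linear")),
])
def test_kernel_dual_matches_qp_oracle(seed, n, K, kernel):
    rng = np.random.default_rng(seed)
    rec = RecordSet(rng.normal(size=(n, 2)), rng.integers(1, K + 1, n),
                    rng.uniform(0.2, 2.0, n), np.arange(n), n)
    code = build_simplex(K)
    lam = 0.5
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        state, model = solve_dual_kernel(rec, code, kernel, lam, 0.5,
                                         tol=1e-10, max_sweeps=20000)
    G = kernel.gram(rec.X)
    ref_obj, _ = oracle_dual_optimum(rec, code, 0.5, G + 1.0, n, lam)
    assert state.objective == pytest.approx(ref_obj, abs=1e-6)


def test_dual_objective_monotone_and_kkt(rng):
    rec = RecordSet(rng.normal(size=(20, 3)), rng.integers(1, 4, 20),
                    rng.uniform(0, 3, 20), np.arange(20), 20)
    code = build_simplex(3)
    state, _ = solve_dual_linear(rec, code, lam=0.1, tol=1e-8, max_sweeps=5000)
    assert np.all(np.diff(state.objective_trace) <= 1e-10)
    assert state.converged
    assert state.kkt_residual < 1e-6


def test_invalid_lambda_and_empty_records():
    rec = RecordSet(np.ones((2, 1)), np.array([1, 2]), np.ones(2),
                    np.arange(2), 2)
    with pytest.raises(ValueError):
        solve_dual_linear(rec, build_simplex(2), lam=0.0)
    empty = RecordSet(np.empty((0, 1)), np.empty(0, int), np.empty(0),
                      np.empty(0, int), 2)
    with pytest.raises(ValueError):
        solve_dual_linear(empty, build_simplex(2), lam=1.0)


def test_singular_gram_raises_without_jitter():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])  # duplicated row
    rec = RecordSet(X, np.array([1, 2, 1]), np.ones(3), np.arange(3), 3)
    with pytest.raises(SingularGramError):
        solve_dual_kernel(rec, build_simplex(2), KernelSpec("rbf", 1.0),
                          lam=1.0, jitter=False)
    with pytest.warns(RuntimeWarning):  # jitter path succeeds with warning
        solve_dual_kernel(rec, build_simplex(2), KernelSpec("rbf", 1.0),
                          lam=1.0, jitter=True)


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def test_zero_model_predicts_group_one():
    from growl.ramsvm import LinearDecisionModel

    model = LinearDecisionModel(B=np.zeros((2, 4)))
    f, groups = predict(model, np.random.default_rng(0).normal(size=(5, 3)),
                        build_simplex(3))
    assert np.all(f == 0) and np.all(groups == 1)


def test_prediction_invariant_to_positive_rescaling(rng):
    from growl.ramsvm import LinearDecisionModel

    B = rng.normal(size=(2, 4))
    X = rng.uniform(-1, 1, (40, 3))
    code = build_simplex(3)
    _, g1 = predict(LinearDecisionModel(B), X, code)
    _, g2 = predict(LinearDecisionModel(7.3 * B), X, code)
    assert np.array_equal(g1, g2)


def test_linear_and_linear_kernel_agree_on_most_points(rng):
    """Penalised-intercept linear dual vs free-intercept linear-kernel dual:
    same data, group predictions agree on >= 90% of a held-out grid."""
    import warnings

    n = 40
    X = rng.uniform(-1, 1, (n, 2))
    labels = (X[:, 0] > 0).astype(int) + 1
    rec = RecordSet(X, labels, rng.uniform(0.5, 1.5, n), np.arange(n), n)
    code = build_simplex(2)
    _, m_lin = solve_dual_linear(rec, code, lam=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, m_ker = solve_dual_kernel(rec, code, KernelSpec("linear"), lam=0.05)
    Xg = rng.uniform(-1, 1, (400, 2))
    _, g1 = predict(m_lin, Xg, code)
    _, g2 = predict(m_ker, Xg, code)
    assert np.mean(g1 == g2) >= 0.90


def test_predict_dimension_mismatch():
    from growl.ramsvm import LinearDecisionModel

    model = LinearDecisionModel(B=np.zeros((1, 3)))
    with pytest.raises(ValueError):
        predict(model, np.zeros((4, 5)), build_simplex(2))
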