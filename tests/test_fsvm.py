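"""Fuzzy SVM tests: membership rule, dual solver, oracle equivalence.

The independent oracle for the dual QP is a generic constrained optimiser
(scipy SLSQP) maximising the same objective under the same box and
equality constraints.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

import pbdkit as pk
from pbdkit import fsvm as fs
from pbdkit.exceptions import ValidationError


def _qp_oracle_objective(X, y, upper, kernel):
    """Brute-force dual maximum via a generic QP solver.

    SLSQP occasionally stalls from a given start, so several deterministic
    starting points are tried and the best successful solve is kept.
    """
    gamma = kernel.resolve_gamma(np.atleast_2d(np.asarray(X, float)))
    K = fs.kernel_matrix(kernel, X, X, gamma=gamma)
    Q = K * np.outer(y, y)
    starts = [np.zeros(len(y))]
    start_rng = np.random.default_rng(0)
    starts += [start_rng.uniform(0, 1, len(y)) * upper for _ in range(4)]
    best = None
    for x0 in starts:
        res = minimize(
            lambda a: 0.5 * a @ Q @ a - a.sum(),
            x0=x0,
            jac=lambda a: Q @ a - 1.0,
            bounds=[(0.0, u) for u in upper],
            constraints=[{"type": "eq", "fun": lambda a: a @ y,
                          "jac": lambda a: y}],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best):
            best = res.fun
    assert best is not None, "generic QP solver failed from every start"
    return -best


def _random_problem(seed, n=8, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.ones(n)
    y[: n // 2] = -1.0
    s = rng.uniform(0.05, 1.0, n)
    return X, y, s


def _assert_dual_feasible(model):
    assert np.all(model.alpha >= -1e-10)
    assert np.all(model.alpha <= model.memberships * model.C + 1e-10)
    assert abs(model.alpha @ model.y) < 1e-8


# ---------------------------------------------------------------- membership

def test_membership_model_centres_and_radii():
    X = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 5.0], [5.0, 6.0]])
    y = np.array([1, 1, -1, -1])
    mm = pk.fit_membership(X, y)
    assert np.allclose(mm.center_pos, [1.0, 0.0])
    assert mm.radius_pos == pytest.approx(1.0)
    assert mm.radius_neg == pytest.approx(0.5)
    s = pk.membership(mm, X, y)
    assert np.all((s > 0) & (s <= 1))
    # a point at its class mean has full membership
    assert pk.membership(mm, np.array([[1.0, 0.0]]), [1])[0] == pytest.approx(1.0)
    # a point at maximum radius keeps the small delta-floor membership
    at_edge = pk.membership(mm, np.array([[2.0, 0.0]]), [1])[0]
    assert at_edge == pytest.approx(mm.delta / (1.0 + mm.delta), rel=1e-6)


def test_singleton_and_duplicate_classes_get_full_membership():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    y = np.array([1, -1, -1])
    mm = pk.fit_membership(X, y)
    assert mm.radius_pos == 0.0 and mm.radius_neg == 0.0
    assert np.allclose(pk.membership(mm, X, y), 1.0)


def test_far_query_point_clamped_to_positive_floor():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    mm = pk.fit_membership(X, y)
    s = pk.membership(mm, np.array([[100.0, 100.0]]), [1])
    assert 0 < s[0] <= 1e-6


def test_single_class_membership_rejected():
    with pytest.raises(ValidationError):
        pk.fit_membership(np.ones((3, 2)), np.array([1, 1, 1]))


# ---------------------------------------------------------------- closed forms

def test_two_point_maximum_margin_closed_form():
    X = np.array([[0.0, 0.0], [2.0, 0.0]])
    y = np.array([-1.0, 1.0])
    model = pk.train_svm(X, y, C=100.0, kernel=pk.KernelSpec("linear"))
    # max margin between (0,0) and (2,0): w = (1/2)(x+ - x-), alpha = 1/2
    assert np.allclose(model.alpha, [0.5, 0.5], atol=1e-8)
    assert model.b == pytest.approx(-1.0, abs=1e-8)
    f = pk.decision_function(model, [[1.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
    assert f == pytest.approx([0.0, 1.0, -1.0], abs=1e-8)
    _assert_dual_feasible(model)


def test_separable_set_classified_exactly():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    model = pk.train_svm(X, y, C=10.0, kernel=pk.KernelSpec("linear"))
    labels, _ = pk.predict(model, X)
    assert np.array_equal(labels, y)


def test_boundary_tie_break_is_positive():
    X = np.array([[0.0, 0.0], [2.0, 0.0]])
    y = np.array([-1.0, 1.0])
    model = pk.train_svm(X, y, C=100.0, kernel=pk.KernelSpec("linear"))
    labels, f = pk.predict(model, [[1.0, 0.0]])
    assert f[0] == 0.0
    assert labels[0] == 1


def test_decision_values_invariant_to_query_order():
    X, y, _ = _random_problem(3, n=8)
    model = pk.train_svm(X, y, C=1.0)
    probe = np.random.default_rng(1).normal(size=(5, X.shape[1]))
    f = pk.decision_function(model, probe)
    assert np.allclose(pk.decision_function(model, probe[::-1]), f[::-1])


def test_dimension_mismatch_rejected():
    X, y, _ = _random_problem(0)
    model = pk.train_svm(X, y, C=1.0)
    with pytest.raises(ValidationError):
        pk.predict(model, np.ones((2, 5)))


# ---------------------------------------------------------------- oracle equivalence

@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("kernel", [pk.KernelSpec("linear"), pk.KernelSpec("rbf")])
def test_svm_dual_matches_generic_qp(seed, kernel):
    X, y, _ = _random_problem(seed)
    C = 1.0 + seed
    model = pk.train_svm(X, y, C=C, kernel=kernel)
    oracle = _qp_oracle_objective(X, y, np.full(len(y), C), kernel)
    assert fs.dual_objective(model) == pytest.approx(oracle, abs=1e-6)
    _assert_dual_feasible(model)


@pytest.mark.parametrize("seed", range(6))
def test_fsvm_dual_matches_generic_qp(seed):
    X, y, s = _random_problem(seed + 100)
    kernel = pk.KernelSpec("rbf")
    model = pk.train_fsvm(X, y, s=s, C=2.0, kernel=kernel)
    oracle = _qp_oracle_objective(X, y, s * 2.0, kernel)
    assert fs.dual_objective(model) == pytest.approx(oracle, abs=1e-6)
    _assert_dual_feasible(model)


@pytest.mark.parametrize("seed", range(4))
def test_unit_memberships_reduce_fsvm_to_svm(seed):
    X, y, _ = _random_problem(seed, n=10)
    svm = pk.train_svm(X, y, C=5.0)
    fsvm = pk.train_fsvm(X, y, s=np.ones(len(y)), C=5.0)
    assert np.abs(svm.alpha - fsvm.alpha).max() < 1e-6
    assert svm.b == pytest.approx(fsvm.b, abs=1e-6)
    probe = np.random.default_rng(seed).normal(size=(6, X.shape[1]))
    assert np.abs(pk.decision_function(svm, probe)
                  - pk.decision_function(fsvm, probe)).max() < 1e-6


def test_svm_agrees_with_sklearn_reference():
    from sklearn.svm import SVC

    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(1.5, 1, (15, 4))])
    y = np.hstack([-np.ones(15), np.ones(15)])
    kernel = pk.KernelSpec("rbf")
    model = pk.train_svm(X, y, C=2.0, kernel=kernel)
    ref = SVC(C=2.0, kernel="rbf", gamma=model.gamma, tol=1e-8).fit(X, y)
    probe = rng.normal(0.7, 1, (10, 4))
    assert np.abs(pk.decision_function(model, probe)
                  - ref.decision_function(probe)).max() < 1e-4


# ---------------------------------------------------------------- outlier handling

def _outlier_problem():
    """Six clean linearly separable points plus one mislabeled outlier.

    The outlier sits off-axis on the negative side, where the negative
    support vectors cannot redistribute multipliers to cancel its pull, so
    it genuinely drags the plain soft-margin boundary.
    """
    X_clean = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                        [2.0, 0.0], [2.0, 1.0], [2.0, -1.0]])
    y_clean = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
    outlier = np.array([[-1.0, 3.0]])  # negative region, labeled +1
    X = np.vstack([X_clean, outlier])
    y = np.append(y_clean, 1.0)
    return X_clean, y_clean, X, y


def test_low_membership_caps_outlier_and_restores_clean_boundary():
    X_clean, y_clean, X, y = _outlier_problem()
    kernel = pk.KernelSpec("linear")
    clean = pk.train_svm(X_clean, y_clean, C=10.0, kernel=kernel)
    plain = pk.train_svm(X, y, C=10.0, kernel=kernel)
    s = np.append(np.ones(6), 0.01)
    fuzzy = pk.train_fsvm(X, y, s=s, C=10.0, kernel=kernel)
    assert fuzzy.alpha[-1] <= 0.01 * 10.0 + 1e-10
    probe = np.array([[x1, x2] for x1 in (-1.0, 0.5, 1.0, 1.5, 3.0)
                      for x2 in (-1.0, 0.0, 1.0)])
    f_clean = pk.decision_function(clean, probe)
    d_fuzzy = np.abs(pk.decision_function(fuzzy, probe) - f_clean).max()
    d_plain = np.abs(pk.decision_function(plain, probe) - f_clean).max()
    assert d_plain > 0.5          # the outlier visibly drags the plain SVM
    assert d_fuzzy < 0.1          # the fuzzy machine ignores it
    assert d_fuzzy < d_plain


def test_boundary_converges_as_outlier_membership_shrinks():
    X_clean, y_clean, X, y = _outlier_problem()
    kernel = pk.KernelSpec("linear")
    clean = pk.train_svm(X_clean, y_clean, C=10.0, kernel=kernel)
    probe = np.array([[0.5, 0.0], [1.0, 0.5], [1.5, -0.5], [1.0, 0.0]])
    f_clean = pk.decision_function(clean, probe)
    distances = []
    for s_out in (1.0, 0.5, 0.1, 0.01):
        s = np.append(np.ones(6), s_out)
        model = pk.train_fsvm(X, y, s=s, C=10.0, kernel=kernel)
        distances.append(np.abs(pk.decision_function(model, probe) - f_clean).max())
    assert all(a >= b - 1e-9 for a, b in zip(distances, distances[1:]))
    assert distances[-1] < distances[0]


# ---------------------------------------------------------------- kernels

@pytest.mark.parametrize("kernel", [
    pk.KernelSpec("linear"),
    pk.KernelSpec("rbf", gamma=0.5),
    pk.KernelSpec("poly", gamma=0.1, degree=3, coef0=1.0),
])
def test_gram_matrices_symmetric_and_psd(kernel):
    X = np.random.default_rng(0).normal(size=(12, 4))
    K = fs.kernel_matrix(kernel, X, X,
                         gamma=kernel.resolve_gamma(X))
    assert np.allclose(K, K.T, atol=1e-12)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


def test_input_validation():
    X = np.ones((4, 2))
    with pytest.raises(ValidationError):
        pk.train_svm(X, np.array([1, 1, 1, 1]), C=1.0)       # one class
    with pytest.raises(ValidationError):
        pk.train_svm(X, np.array([1, 0, -1, 1]), C=1.0)      # bad labels
    with pytest.raises(ValidationError):
        pk.train_svm(X, np.array([1, -1, 1, -1]), C=-1.0)    # bad C
    with pytest.raises(ValidationError):
        pk.train_fsvm(X, np.array([1, -1, 1, -1]), s=np.array([0, 1, 1, 1]), C=1.0)
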