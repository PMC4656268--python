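"""Soft-margin SVM and fuzzy SVM via a membership-weighted dual QP.

The fuzzy SVM attaches a membership s_n in (0, 1] to each training sample,
scaling its slack penalty in the primal.  In the dual this changes exactly
one thing relative to the standard soft-margin SVM: the box constraint on
each multiplier becomes 0 <= alpha_n <= s_n * C, so low-membership points
(suspected noise or outliers) cannot exert full force on the separating
hyperplane.  With all memberships equal to one the two machines coincide.

Memberships come from a radius/centre rule: s_n = 1 - |x_c - x_n| / (r_c +
delta), where x_c is the sample's own class mean, r_c the maximum distance
of any class member to that mean and delta > 0 a small stabiliser keeping
memberships strictly positive.

The dual is solved by sequential minimal optimisation with maximal-violating
-pair working-set selection; the per-sample upper bounds enter only in the
clipping step of the two-variable update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ConvergenceError, ValidationError

_MEMBERSHIP_FLOOR = 1e-6


# --------------------------------------------------------------------------
# kernels

@dataclass(frozen=True)
class KernelSpec:
    """Kernel identifier and parameters.

    ``gamma="scale"`` resolves to 1 / (p * var(X)) on the training matrix,
    a standard heuristic that keeps the RBF width commensurate with the
    feature spread.
    """

    name: str = "rbf"
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf", "poly"):
            raise ConfigurationError(
                f"unknown kernel {self.name!r}; expected linear, rbf or poly"
            )

    def resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma == "scale":
            var = float(X.var())
            return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        return float(self.gamma)


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray,
                  gamma: float | None = None) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Y[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if spec.name == "linear":
        return X @ Y.T
    if spec.name == "poly":
        g = spec.resolve_gamma(X) if gamma is None else gamma
        return (g * (X @ Y.T) + spec.coef0) ** spec.degree
    g = spec.resolve_gamma(X) if gamma is None else gamma
    sq = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ Y.T
        + (Y**2).sum(axis=1)[None, :]
    )
    return np.exp(-g * np.maximum(sq, 0.0))


# --------------------------------------------------------------------------
# fuzzy membership

@dataclass
class MembershipModel:
    """Class centres and radii for the radius/centre membership rule."""

    center_pos: np.ndarray
    center_neg: np.ndarray
    radius_pos: float
    radius_neg: float
    delta: float

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError(f"delta must be > 0, got {self.delta}")


def fit_membership(X: np.ndarray, y: np.ndarray, delta: float | None = None,
                   rel_delta: float = 1e-3) -> MembershipModel:
    """Fit class means and radii on training data.

    The radius of a class is the maximum Euclidean distance of its members
    to the class mean (zero for singleton or duplicate-only classes).  When
    ``delta`` is not given it defaults to ``rel_delta * max(r+, r-)``, with
    an absolute floor so it stays positive even when both radii vanish.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present to fit memberships")
    c_pos, c_neg = pos.mean(axis=0), neg.mean(axis=0)
    r_pos = float(np.linalg.norm(pos - c_pos, axis=1).max())
    r_neg = float(np.linalg.norm(neg - c_neg, axis=1).max())
    if delta is None:
        delta = rel_delta * max(r_pos, r_neg)
        if delta == 0.0:
            delta = 1e-3
    return MembershipModel(c_pos, c_neg, r_pos, r_neg, float(delta))


def membership(model: MembershipModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Membership s = 1 - |x - x_c| / (r_c + delta) against the own-class centre.

    On the training set this is strictly positive by construction (no point
    lies beyond its class radius).  Points farther out — possible only for
    data not seen by :func:`fit_membership` — are clamped to a small
    positive floor rather than allowed to go nonpositive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    s = np.empty(len(X))
    for cls, center, radius in (
        (1, model.center_pos, model.radius_pos),
        (-1, model.center_neg, model.radius_neg),
    ):
        mask = y == cls
        if mask.any():
            dist = np.linalg.norm(X[mask] - center, axis=1)
            s[mask] = 1.0 - dist / (radius + model.delta)
    return np.clip(s, _MEMBERSHIP_FLOOR, 1.0)


# --------------------------------------------------------------------------
# dual solver

@dataclass
class FSVMModel:
    """Trained dual solution.

    ``alpha`` keeps one multiplier per training sample (including zeros) so
    dual feasibility — 0 <= alpha_n <= s_n C, sum alpha_n y_n = 0 — can be
    audited after the fact; prediction uses only the support vectors.
    """

    X: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    b: float
    C: float
    kernel: KernelSpec
    gamma: float
    memberships: np.ndarray
    n_iter: int = 0
    delta: float | None = None
    extraction: dict | None = None
    _sv_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self._sv_mask = self.alpha > 1e-12

    @property
    def support_vectors(self) -> np.ndarray:
        return self.X[self._sv_mask]

    @property
    def support_labels(self) -> np.ndarray:
        return self.y[self._sv_mask]

    @property
    def dual_coef(self) -> np.ndarray:
        """alpha_n * y_n over support vectors."""
        return (self.alpha * self.y)[self._sv_mask]


def _smo(Q: np.ndarray, y: np.ndarray, upper: np.ndarray, tol: float,
         max_iter: int) -> tuple[np.ndarray, float, int]:
    """SMO with second-order working-set selection on the dual

        min 1/2 a'Qa - e'a,   y'a = 0,   0 <= a <= upper.

    Returns (alpha, b, iterations).  Q already includes the label signs:
    Q[m, n] = y_m y_n k(x_m, x_n).  The first index of the working pair is
    the maximal KKT violator; the second maximises the guaranteed decrease
    of the dual objective.  The stopping test is on the KKT violation
    relative to the penalty scale, since the dual gradient grows linearly
    with the box bounds.
    """
    n = len(y)
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q @ alpha - e at alpha = 0
    tau = 1e-12
    diag = np.diag(Q)
    # KKT violation is measured relative to the dual gradient's natural
    # scale C_max * max K_nn; an absolute test below machine precision at
    # that scale can never be met.
    stop = tol * max(1.0, float(upper.max()) * float(diag.max()))
    it = 0
    while it < max_iter:
        it += 1
        neg_yg = -y * grad
        up = ((y == 1) & (alpha < upper - tau)) | ((y == -1) & (alpha > tau))
        low = ((y == -1) & (alpha < upper - tau)) | ((y == 1) & (alpha > tau))
        if not up.any() or not low.any():
            break
        i = np.flatnonzero(up)[np.argmax(neg_yg[up])]
        m_up = neg_yg[i]
        m_low = neg_yg[low].min()
        if m_up - m_low < stop:
            break
        # second-order choice of j among sufficiently violating candidates
        cand = low & (neg_yg < m_up - tau)
        if not cand.any():
            break
        idx = np.flatnonzero(cand)
        b_it = m_up - neg_yg[idx]
        a_it = diag[i] + diag[idx] - 2.0 * y[i] * y[idx] * Q[i, idx]
        a_it = np.where(a_it > 0, a_it, tau)
        j = idx[np.argmin(-(b_it**2) / a_it)]
        ai_old, aj_old = alpha[i], alpha[j]
        ci, cj = upper[i], upper[j]
        if y[i] != y[j]:
            quad = Q[i, i] + Q[j, j] + 2.0 * Q[i, j]
            if quad <= 0:
                quad = tau
            delta = (-grad[i] - grad[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > ci - cj:
                if alpha[i] > ci:
                    alpha[i] = ci
                    alpha[j] = ci - diff
            else:
                if alpha[j] > cj:
                    alpha[j] = cj
                    alpha[i] = cj + diff
        else:
            quad = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
            if quad <= 0:
                quad = tau
            delta = (grad[i] - grad[j]) / quad
            total = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if total > ci:
                if alpha[i] > ci:
                    alpha[i] = ci
                    alpha[j] = total - ci
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = total
            if total > cj:
                if alpha[j] > cj:
                    alpha[j] = cj
                    alpha[i] = total - cj
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = total
        grad += Q[:, i] * (alpha[i] - ai_old) + Q[:, j] * (alpha[j] - aj_old)
    else:
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations "
            f"(KKT violation {m_up - m_low:.3e}, tolerance {tol:.0e})"
        )

    # b: mean over free SVs of -y * grad; otherwise midpoint of the
    # KKT-feasible interval.
    free = (alpha > tau) & (alpha < upper - tau)
    neg_yg = -y * grad
    if free.any():
        b = float(neg_yg[free].mean())
    else:
        up = ((y == 1) & (alpha < upper - tau)) | ((y == -1) & (alpha > tau))
        low = ((y == -1) & (alpha < upper - tau)) | ((y == 1) & (alpha > tau))
        hi = neg_yg[up].max() if up.any() else 0.0
        lo = neg_yg[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b, it


def _validate_training(X, y, C):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValidationError(f"{len(X)} samples but {len(y)} labels")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be +1 or -1")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValidationError("both classes must be present")
    if C <= 0:
        raise ValidationError(f"C must be > 0, got {C}")
    return X, y


def train_fsvm(
    X: np.ndarray,
    y: np.ndarray,
    s: np.ndarray | None = None,
    C: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> FSVMModel:
    """Fit a fuzzy SVM by maximising the membership-bounded dual.

    ``s`` holds per-sample memberships in (0, 1]; ``None`` means all ones,
    which reduces the machine to the standard soft-margin SVM.  The dual

        max_a  sum a_n - 1/2 sum_mn a_m a_n y_m y_n k(x_m, x_n)
        s.t.   0 <= a_n <= s_n C,   sum a_n y_n = 0

    is solved to a KKT violation below ``tol``.
    """
    X, y = _validate_training(X, y, C)
    if s is None:
        s = np.ones(len(y))
    else:
        s = np.asarray(s, dtype=float).ravel()
        if len(s) != len(y):
            raise ValidationError("membership vector length mismatch")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValidationError("memberships must lie in (0, 1]")
    gamma = kernel.resolve_gamma(X)
    K = kernel_matrix(kernel, X, X, gamma=gamma)
    Q = K * np.outer(y, y)
    alpha, b, n_iter = _smo(Q, y, s * C, tol, max_iter)
    return FSVMModel(X=X.copy(), y=y.copy(), alpha=alpha, b=b, C=float(C),
                     kernel=kernel, gamma=gamma, memberships=s.copy(),
                     n_iter=n_iter)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> FSVMModel:
    """Standard soft-margin SVM: the fuzzy dual with unit memberships."""
    return train_fsvm(X, y, s=None, C=C, kernel=kernel, tol=tol, max_iter=max_iter)


def decision_function(model: FSVMModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_n alpha_n y_n k(x_n, x) + b over support vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.X.shape[1]:
        raise ValidationError(
            f"model expects {model.X.shape[1]} features, got {X.shape[1]}"
        )
    K = kernel_matrix(model.kernel, model.support_vectors, X, gamma=model.gamma)
    return model.dual_coef @ K + model.b


def predict(model: FSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and decision values; f(x) = 0 resolves to +1."""
    f = decision_function(model, X)
    labels = np.where(f >= 0.0, 1, -1)
    return labels, f


def dual_objective(model: FSVMModel) -> float:
    """Value of the maximised dual at the fitted multipliers."""
    K = kernel_matrix(model.kernel, model.X, model.X, gamma=model.gamma)
    ay = model.alpha * model.y
    return float(model.alpha.sum() - 0.5 * ay @ K @ ay)
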