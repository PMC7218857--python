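"""Regression-based joint-angle drift correction.

A fused-but-uncorrected joint angle carries a slowly varying bias (gyro drift,
calibration offset).  A per-joint regression model maps the estimated angle
plus its angular velocity to the reference angle, removing that bias while
remaining user- and speed-independent.  Three model families are supported:

* ``nn`` — a two-layer shallow network (5-20 tanh hidden units, one linear
  output) trained by damped least squares (Levenberg-Marquardt style) with
  four stopping rules: validation error rising for ``val_fail_limit``
  iterations, MSE reaching ``mse_goal``, gradient infinity-norm below
  ``grad_min``, or damping ``mu`` exceeding ``mu_max``.
* ``tree`` — binary regression tree, best split by MSE reduction, with the
  minimum leaf sizes {4, 12, 36, 50, 100} (fine/medium/coarse) and a
  200-observation branch minimum.
* ``svm`` — epsilon-insensitive support vector regression with linear,
  quadratic, cubic or Gaussian kernel.

Inputs and targets are min-max normalized into [-1, 1] before fitting and the
prediction is mapped back, so reported errors stay in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "NormalizationState",
    "minmax_fit_transform",
    "RegressionSpec",
    "DriftCorrector",
    "CvReport",
    "cross_validate",
    "train_regressor",
    "apply_correction",
]

TREE_LEAF_MENU = (4, 12, 36, 50, 100)
SVM_KERNEL_MENU = ("linear", "quadratic", "cubic", "gaussian")


# ---------------------------------------------------------------------------
# min-max normalization into [-1, 1]

@dataclass
class NormalizationState:
    """Per-variable min/max for the [-1, 1] min-max mapping."""

    data_min: np.ndarray
    data_max: np.ndarray

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return -1.0 + 2.0 * (X - self.data_min) / (self.data_max - self.data_min)

    def inverse(self, Xs) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        return self.data_min + (Xs + 1.0) * (self.data_max - self.data_min) / 2.0


def minmax_fit_transform(X) -> tuple[np.ndarray, NormalizationState]:
    """Affinely map each column so its observed min -> -1 and max -> +1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi <= lo):
        bad = np.nonzero(hi <= lo)[0]
        raise ValueError(f"constant variable(s) at column(s) {bad.tolist()}: "
                         "min-max normalization undefined")
    state = NormalizationState(data_min=lo, data_max=hi)
    return state.transform(X), state


# ---------------------------------------------------------------------------
# shallow network + damped least-squares trainer

def _net_unpack(w, d, h):
    i = 0
    W1 = w[i:i + h * d].reshape(h, d); i += h * d
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + h]; i += h
    b2 = w[i]
    return W1, b1, W2, b2


def _net_forward(w, X, h):
    W1, b1, W2, b2 = _net_unpack(w, X.shape[1], h)
    A = np.tanh(X @ W1.T + b1)          # (n, h)
    return A @ W2 + b2, A


def _net_jacobian(w, X, A):
    """d residual / d w for residual = y - net(X); shape (n, p)."""
    n, d = X.shape
    h = A.shape[1]
    W2 = _net_unpack(w, d, h)[2]
    dtanh = 1.0 - A ** 2                # (n, h)
    # columns ordered as the flattened parameter vector
    J_W1 = (dtanh * W2)[:, :, None] * X[:, None, :]   # (n, h, d)
    J_b1 = dtanh * W2                                  # (n, h)
    J_W2 = A                                           # (n, h)
    J_b2 = np.ones((n, 1))
    return -np.concatenate([J_W1.reshape(n, h * d), J_b1, J_W2, J_b2], axis=1)


def _train_shallow_nn(X, y, hidden, rng, max_iter=200, val_fraction=0.15,
                      val_fail_limit=10, mse_goal=0.0, grad_min=1e-7,
                      mu_max=1e10):
    """Damped least-squares fit of the shallow net.  Returns (w, info)."""
    n, d = X.shape
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n >= 10 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Xt, yt = X[tr_idx], y[tr_idx]
    Xv, yv = X[val_idx], y[val_idx]

    p = hidden * d + hidden + hidden + 1
    w = rng.uniform(-0.5, 0.5, p)
    mu = 1e-3
    out, A = _net_forward(w, Xt, hidden)
    r = yt - out
    sse = float(r @ r)
    best_w, best_val, val_fails = w.copy(), np.inf, 0
    reason = "max_iter"

    for _ in range(max_iter):
        if sse / len(yt) <= mse_goal:
            reason = "mse_goal"
            break
        J = _net_jacobian(w, Xt, A)
        grad = 2.0 * (J.T @ r) / len(yt)
        if np.max(np.abs(grad)) < grad_min:
            reason = "grad_min"
            break
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(p), Jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w - step
            out_new, A_new = _net_forward(w_new, Xt, hidden)
            r_new = yt - out_new
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                w, out, A, r, sse = w_new, out_new, A_new, r_new, sse_new
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            reason = "mu_max"
            break
        if n_val:
            rv = yv - _net_forward(w, Xv, hidden)[0]
            val_mse = float(rv @ rv) / len(yv)
            if val_mse < best_val:
                best_val, best_w, val_fails = val_mse, w.copy(), 0
            else:
                val_fails += 1
                if val_fails >= val_fail_limit:
                    reason = "val_fail"
                    break
    if n_val and np.isfinite(best_val):
        w = best_w
    return w, {"stop_reason": reason, "train_mse": sse / max(len(yt), 1)}


# ---------------------------------------------------------------------------
# estimator

@dataclass
class RegressionSpec:
    """Declarative model choice mirroring the tuning menus."""

    kind: str = "nn"
    nn_hidden: int = 5
    nn_stop: dict = field(default_factory=lambda: dict(
        val_fail_limit=10, mse_goal=0.0, grad_min=1e-7, mu_max=1e10))
    tree_min_leaf: int = 36
    tree_min_branch: int = 200
    svm_kernel: str = "gaussian"
    svm_C: float = 1.0
    svm_eps: float = 0.1
    svm_sigma: float = 1.35
    seed: int = 0


class DriftCorrector(BaseEstimator, RegressorMixin):
    """Joint-angle correction regressor (scikit-learn estimator).

    ``fit(X, y)`` expects X columns ``[joint angle deg, joint angular
    velocity deg/s]`` (a single angle column also works) and y the reference
    joint angle in degrees.  Normalization state is learned from the training
    data and stored on the fitted estimator.
    """

    def __init__(self, kind: str = "nn", hidden: int = 5,
                 tree_min_leaf: int = 36, tree_min_branch: int = 200,
                 svm_kernel: str = "gaussian", svm_C: float = 1.0,
                 svm_eps: float = 0.1, svm_sigma: float = 1.35,
                 max_iter: int = 200, val_fraction: float = 0.15,
                 val_fail_limit: int = 10, mse_goal: float = 0.0,
                 grad_min: float = 1e-7, mu_max: float = 1e10,
                 seed: int = 0):
        self.kind = kind
        self.hidden = hidden
        self.tree_min_leaf = tree_min_leaf
        self.tree_min_branch = tree_min_branch
        self.svm_kernel = svm_kernel
        self.svm_C = svm_C
        self.svm_eps = svm_eps
        self.svm_sigma = svm_sigma
        self.max_iter = max_iter
        self.val_fraction = val_fraction
        self.val_fail_limit = val_fail_limit
        self.mse_goal = mse_goal
        self.grad_min = grad_min
        self.mu_max = mu_max
        self.seed = seed

    def _validate_menu(self):
        if self.kind not in ("nn", "tree", "svm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "nn" and not (5 <= self.hidden <= 20):
            raise ValueError("nn hidden layer size must be within 5..20")
        if self.kind == "tree" and self.tree_min_leaf not in TREE_LEAF_MENU:
            raise ValueError(f"tree_min_leaf must be one of {TREE_LEAF_MENU}")
        if self.kind == "svm" and self.svm_kernel not in SVM_KERNEL_MENU:
            raise ValueError(f"svm_kernel must be one of {SVM_KERNEL_MENU}")

    def fit(self, X, y):
        self._validate_menu()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 2:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[0] == 0:
            raise ValueError("empty training data")
        Xs, self.x_norm_ = minmax_fit_transform(X)
        ys2, self.y_norm_ = minmax_fit_transform(y.reshape(-1, 1))
        ys = ys2.ravel()
        rng = np.random.default_rng(self.seed)
        if self.kind == "nn":
            self.weights_, info = _train_shallow_nn(
                Xs, ys, self.hidden, rng, max_iter=self.max_iter,
                val_fraction=self.val_fraction,
                val_fail_limit=self.val_fail_limit, mse_goal=self.mse_goal,
                grad_min=self.grad_min, mu_max=self.mu_max)
            self.stop_reason_ = info["stop_reason"]
            self.model_ = None
        elif self.kind == "tree":
            self.model_ = DecisionTreeRegressor(
                criterion="squared_error",
                min_samples_leaf=self.tree_min_leaf,
                min_samples_split=self.tree_min_branch,
                random_state=self.seed).fit(Xs, ys)
        else:
            kernel_map = {"linear": dict(kernel="linear"),
                          "quadratic": dict(kernel="poly", degree=2),
                          "cubic": dict(kernel="poly", degree=3),
                          "gaussian": dict(kernel="rbf",
                                           gamma=1.0 / (2.0 * self.svm_sigma ** 2))}
            self.model_ = SVR(C=self.svm_C, epsilon=self.svm_eps,
                              **kernel_map[self.svm_kernel]).fit(Xs, ys)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "x_norm_"):
            raise ValueError("DriftCorrector is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} input columns, got {X.shape[1]}")
        Xs = self.x_norm_.transform(X)
        if self.kind == "nn":
            ys = _net_forward(self.weights_, Xs, self.hidden)[0]
        else:
            ys = self.model_.predict(Xs)
        return self.y_norm_.inverse(ys.reshape(-1, 1)).ravel()


def train_regressor(spec: RegressionSpec, X, y) -> DriftCorrector:
    """Fit a :class:`DriftCorrector` from a declarative spec."""
    est = DriftCorrector(
        kind=spec.kind, hidden=spec.nn_hidden,
        tree_min_leaf=spec.tree_min_leaf, tree_min_branch=spec.tree_min_branch,
        svm_kernel=spec.svm_kernel, svm_C=spec.svm_C, svm_eps=spec.svm_eps,
        svm_sigma=spec.svm_sigma, seed=spec.seed, **spec.nn_stop)
    return est.fit(X, y)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CvReport:
    """Per-fold and mean NRMSE / R-squared of a k-fold evaluation."""

    fold_nrmse: list
    fold_r2: list
    folds: int = 5

    @property
    def mean_nrmse(self) -> float:
        return float(np.mean(self.fold_nrmse))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))


def cross_validate(estimator, X, y, folds: int = 5, groups=None,
                   seed: int = 0) -> CvReport:
    """k-fold CV reporting NRMSE (range-normalized) and R-squared.

    With ``groups`` (e.g. subject labels) folds are grouped so the model is
    always evaluated on unseen subjects (user independence); otherwise folds
    are random at the given seed.
    """
    from .metrics import nrmse

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < folds:
        raise ValueError(f"need at least {folds} observations")
    if groups is not None:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    fold_nrmse, fold_r2 = [], []
    for tr, te in split:
        model = clone(estimator).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        fold_nrmse.append(nrmse(pred, y[te]))
        fold_r2.append(r2_score(y[te], pred))
    return CvReport(fold_nrmse=fold_nrmse, fold_r2=fold_r2, folds=folds)


def apply_correction(models, joints, joint_names=("hip", "knee", "ankle")):
    """Apply fitted per-joint correctors to a :class:`JointAngleSeries`.

    ``models`` is a fitted :class:`DriftCorrector` (applied to every joint in
    ``joint_names``) or a mapping joint name -> fitted corrector.  Joints
    without a model pass through unchanged.  Empty series pass through.
    """
    from .kinematics import JointAngleSeries

    if len(joints) == 0:
        return joints
    if not isinstance(models, dict):
        models = {j: models for j in joint_names}
    corrected = {}
    for joint in ("hip", "knee", "ankle"):
        angle = getattr(joints, joint)
        model = models.get(joint)
        if model is None:
            corrected[joint] = angle.copy()
            continue
        if getattr(model, "n_features_in_", 2) == 2:
            X = np.column_stack([angle, joints.angular_velocity(joint)])
        else:
            X = angle.reshape(-1, 1)
        corrected[joint] = model.predict(X)
    return JointAngleSeries(hip=corrected["hip"], knee=corrected["knee"],
                            ankle=corrected["ankle"], fs=joints.fs,
                            side=joints.side)
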