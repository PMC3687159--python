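"""Structurally constrained feed-forward regression model.

One input node per upper-layer TF, one hidden (logistic) node per
middle-layer TF, a single linear output.  The input->hidden weight matrix
is masked by the cascade's edges: a weight without a corresponding edge is
pinned to exactly zero and is not a trainable parameter.  Training is
damped Gauss-Newton (Levenberg-Marquardt) on the sum of squared residuals
with an analytic Jacobian and validation-based early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .cascade_builder import Cascade
from .errors import ValidationError


def logsig(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic sigmoid 1 / (1 + exp(-z))."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class TrainParams:
    max_epochs: int = 100
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    val_patience: int = 6
    goal_mse: float = 0.0
    lambda_max: float = 1e10
    max_retries_per_epoch: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if not (self.lambda_up > 1 > self.lambda_down > 0):
            raise ValidationError("need lambda_up > 1 > lambda_down > 0")


@dataclass
class CascadeANN:
    """Parameter set mirroring a :class:`Cascade`.

    ``W_in`` is (n_upper, n_middle) with boolean ``mask``; entries where the
    mask is False are exactly 0 before, during and after training.
    """

    cascade: Cascade
    W_in: np.ndarray
    b_mid: np.ndarray
    w_out: np.ndarray
    b_out: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        nu, nm = len(self.cascade.upper_tfs), len(self.cascade.middle_tfs)
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b_mid = np.asarray(self.b_mid, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.W_in.shape != (nu, nm) or self.mask.shape != (nu, nm):
            raise ValidationError("W_in/mask shape must be (n_upper, n_middle)")
        if self.b_mid.shape != (nm,) or self.w_out.shape != (nm,):
            raise ValidationError("b_mid/w_out must have one entry per middle TF")
        if np.any(self.W_in[~self.mask] != 0.0):
            raise ValidationError("masked weights must be exactly zero")

    # -- free-parameter packing -------------------------------------------

    @property
    def n_free_parameters(self) -> int:
        return int(self.mask.sum()) + 2 * len(self.cascade.middle_tfs) + 1

    def pack(self) -> np.ndarray:
        return np.concatenate([
            self.W_in[self.mask], self.b_mid, self.w_out, [self.b_out]])

    def unpack(self, theta: np.ndarray) -> "CascadeANN":
        nm = len(self.cascade.middle_tfs)
        ne = int(self.mask.sum())
        W = np.zeros_like(self.W_in)
        W[self.mask] = theta[:ne]
        return CascadeANN(
            cascade=self.cascade,
            W_in=W,
            b_mid=theta[ne:ne + nm].copy(),
            w_out=theta[ne + nm:ne + 2 * nm].copy(),
            b_out=float(theta[-1]),
            mask=self.mask.copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_record(self) -> dict:
        return {
            "cascade": self.cascade.to_record(),
            "mask": self.mask.astype(int).tolist(),
            "theta": self.pack().tolist(),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "CascadeANN":
        cascade = Cascade.from_record(rec["cascade"])
        mask = np.asarray(rec["mask"], dtype=bool)
        nu, nm = len(cascade.upper_tfs), len(cascade.middle_tfs)
        shell = cls(cascade=cascade, W_in=np.zeros((nu, nm)), b_mid=np.zeros(nm),
                    w_out=np.zeros(nm), b_out=0.0, mask=mask)
        return shell.unpack(np.asarray(rec["theta"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CascadeANN":
        return cls.from_record(json.loads(Path(path).read_text(encoding="utf-8")))


def mask_from_cascade(cascade: Cascade) -> np.ndarray:
    nu, nm = len(cascade.upper_tfs), len(cascade.middle_tfs)
    mask = np.zeros((nu, nm), dtype=bool)
    ui = {t: i for i, t in enumerate(cascade.upper_tfs)}
    mi = {t: j for j, t in enumerate(cascade.middle_tfs)}
    for u, m in cascade.input_edges:
        mask[ui[u], mi[m]] = True
    return mask


def init_ann(cascade: Cascade, seed) -> CascadeANN:
    """Free parameters i.i.d. uniform on [-0.5, 0.5]; masked entries zero."""
    rng = np.random.default_rng(seed)
    mask = mask_from_cascade(cascade)
    nm = len(cascade.middle_tfs)
    n_free = int(mask.sum()) + 2 * nm + 1
    theta = rng.uniform(-0.5, 0.5, size=n_free)
    nu = len(cascade.upper_tfs)
    shell = CascadeANN(cascade=cascade, W_in=np.zeros((nu, nm)),
                       b_mid=np.zeros(nm), w_out=np.zeros(nm), b_out=0.0,
                       mask=mask)
    return shell.unpack(theta)


def forward(ann: CascadeANN, X: np.ndarray) -> np.ndarray:
    """y = logsig(X W_in + b_mid) . w_out + b_out for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(ann.cascade.upper_tfs):
        raise ValidationError(
            f"X has {X.shape[1]} columns, expected {len(ann.cascade.upper_tfs)}")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValidationError(f"non-finite input at sample(s) {np.where(bad)[0].tolist()}")
    h = logsig(X @ ann.W_in + ann.b_mid)
    return h @ ann.w_out + ann.b_out


def _residuals_and_jacobian(
    ann: CascadeANN, theta: np.ndarray, X: np.ndarray, y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals r = pred - y and the analytic Jacobian dr/dtheta.

    Parameter layout matches :meth:`CascadeANN.pack`:
    [W_in[mask], b_mid, w_out, b_out].
    """
    net = ann.unpack(theta)
    z = X @ net.W_in + net.b_mid        # (n, nm)
    h = logsig(z)
    pred = h @ net.w_out + net.b_out
    r = pred - y

    n, nm = h.shape
    dh = h * (1.0 - h)                  # logsig'
    # d pred / d W_in[i,j] = w_out[j] * dh[:,j] * X[:,i]
    g = dh * net.w_out                  # (n, nm), per-hidden chain factor
    rows, cols = np.where(ann.mask)
    J_w = X[:, rows] * g[:, cols]       # (n, n_edges)
    J_bmid = g                          # (n, nm)
    J_wout = h                          # (n, nm)
    J_bout = np.ones((n, 1))
    J = np.concatenate([J_w, J_bmid, J_wout, J_bout], axis=1)
    return r, J


@dataclass
class TrainingTrace:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1


def _mse(ann: CascadeANN, theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    pred = forward(ann.unpack(theta), X)
    return float(np.mean((pred - y) ** 2))


def train_lm(
    ann: CascadeANN,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    params: TrainParams = TrainParams(),
) -> tuple[CascadeANN, TrainingTrace]:
    """Levenberg-Marquardt over the free parameters only.

    Each epoch solves (J'J + lam I) delta = J'r and accepts the step iff the
    training MSE decreases (lam shrinks); otherwise lam grows and the step
    is retried.  Stops on max_epochs, goal_mse, lam overflow, or
    ``val_patience`` epochs without validation improvement.  Returns the
    parameters with the best validation MSE seen (best training MSE when no
    validation set is given).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    if X_train.shape[0] < 1:
        raise ValidationError("need at least one training sample")
    has_val = X_val is not None and len(np.atleast_1d(y_val)) > 0
    if has_val:
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        y_val = np.asarray(y_val, dtype=float).ravel()

    theta = ann.pack()
    lam = params.lambda0
    trace = TrainingTrace()

    def val_score(th: np.ndarray) -> float:
        if has_val:
            return _mse(ann, th, X_val, y_val)
        return _mse(ann, th, X_train, y_train)

    best_theta = theta.copy()
    best_val = val_score(theta)
    trace.best_epoch = 0
    bad_epochs = 0

    mse = _mse(ann, theta, X_train, y_train)
    for epoch in range(params.max_epochs):
        if mse <= params.goal_mse:
            trace.stop_reason = "goal_mse"
            break
        r, J = _residuals_and_jacobian(ann, theta, X_train, y_train)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _ in range(params.max_retries_per_epoch):
            try:
                delta = scipy.linalg.solve(
                    JtJ + lam * np.eye(JtJ.shape[0]), Jtr, assume_a="pos")
            except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
                lam *= params.lambda_up
                if lam > params.lambda_max:
                    break
                continue
            cand = theta - delta
            cand_mse = _mse(ann, cand, X_train, y_train)
            if np.isfinite(cand_mse) and cand_mse < mse:
                theta, mse = cand, cand_mse
                lam = max(lam * params.lambda_down, 1e-20)
                accepted = True
                break
            lam *= params.lambda_up
            if lam > params.lambda_max:
                break
        trace.train_mse.append(mse)
        trace.lambdas.append(lam)

        v = val_score(theta)
        trace.val_mse.append(v)
        if accepted and v < best_val:
            best_val = v
            best_theta = theta.copy()
            trace.best_epoch = epoch + 1
            bad_epochs = 0
        else:
            bad_epochs += 1

        if not accepted:
            trace.stop_reason = "lambda_overflow" if lam > params.lambda_max \
                else "no_decrease"
            break
        if bad_epochs >= params.val_patience:
            trace.stop_reason = "val_patience"
            break
    else:
        trace.stop_reason = "max_epochs"
    if not trace.stop_reason:
        trace.stop_reason = trace.stop_reason or "stopped"

    return ann.unpack(best_theta), trace
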