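"""Three-layer sigmoid MLP with Levenberg-Marquardt training.

The torque-angle field is learned by a small feedforward network: two
inputs (plane of elevation, elevation), one sigmoid hidden layer of H
units, three sigmoid outputs (the world-axis passive torque components).
Inputs and targets are min-max normalized to (0.05, 0.95) — strictly
inside the sigmoid's open range so every target is attainable.  Training
is full-batch Levenberg-Marquardt on the residual vector: the residual
Jacobian is assembled by backpropagation, each step solves
``(J^T J + mu I) delta = J^T r``, and the damping ``mu`` is decreased on
accepted steps and increased on rejected ones.  Performance is the mean
squared error of the normalized network output; training stops at the MSE
goal, the epoch cap, or when ``mu`` exceeds its ceiling.

:class:`LMMLPRegressor` follows the scikit-learn estimator contract
(``get_params``/``set_params``, ``fit``/``predict``, trailing-underscore
fitted attributes) and composes with sklearn model selection.  The
module-level :func:`train_lm`, :func:`predict_torque`,
:func:`fit_normalizer` and :func:`hidden_unit_sweep` are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MinMaxNormalizer",
    "fit_normalizer",
    "TrainingHistory",
    "TrainingDivergenceError",
    "LMMLPRegressor",
    "train_lm",
    "predict_torque",
    "hidden_unit_sweep",
]


class TrainingDivergenceError(RuntimeError):
    """Training loss became non-finite; the partial history is attached."""

    def __init__(self, message: str, history: "TrainingHistory | None" = None):
        super().__init__(message)
        self.history = history


class MinMaxNormalizer:
    """Per-dimension affine map sending the observed [min, max] to [lo, hi].

    A constant dimension maps to the midpoint (lo + hi) / 2 and its inverse
    is pinned to the constant, so degenerate columns never divide by zero.
    """

    def __init__(self, lo: float = 0.05, hi: float = 0.95):
        if not hi > lo:
            raise ValueError("hi must exceed lo")
        self.lo = float(lo)
        self.hi = float(hi)

    def fit(self, data) -> "MinMaxNormalizer":
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("need at least one sample")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        span = self.data_max_ - self.data_min_
        self.constant_ = span == 0
        safe = np.where(self.constant_, 1.0, span)
        self.scale_ = np.where(self.constant_, 0.0, (self.hi - self.lo) / safe)
        self.offset_ = np.where(
            self.constant_, 0.5 * (self.lo + self.hi),
            self.lo - self.data_min_ * self.scale_,
        )
        return self

    def transform(self, data) -> np.ndarray:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        return X * self.scale_ + self.offset_

    def inverse_transform(self, data) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(data, dtype=float))
        inv_scale = np.where(self.constant_, 0.0, 1.0 / np.where(self.scale_ == 0, 1.0, self.scale_))
        out = (Y - self.offset_) * inv_scale
        return np.where(self.constant_, self.data_min_, out)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo,
            "hi": self.hi,
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        norm = cls(lo=d["lo"], hi=d["hi"])
        span = np.asarray(d["data_max"], float) - np.asarray(d["data_min"], float)
        probe = np.vstack([np.asarray(d["data_min"], float), np.asarray(d["data_max"], float)])
        norm.fit(probe)
        # exact round trip even if min == max in some dimension
        assert np.all((span == 0) == norm.constant_)
        return norm


def fit_normalizer(data, lo: float = 0.05, hi: float = 0.95) -> MinMaxNormalizer:
    """Fit a :class:`MinMaxNormalizer` mapping each dimension's [min, max]
    onto [lo, hi]."""
    return MinMaxNormalizer(lo=lo, hi=hi).fit(data)


@dataclass
class TrainingHistory:
    """Per-epoch normalized MSE of accepted steps (index 0 is the initial
    loss before any step)."""

    mse: list = field(default_factory=list)
    epochs_run: int = 0
    goal_met: bool = False
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self.mse)), "mse": self.mse})


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LMMLPRegressor(BaseEstimator, RegressorMixin):
    """Sigmoid MLP regressor trained by Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int, default 9
        Hidden units H, 1 <= H <= 100.
    max_epochs : int, default 1000
        Cap on accepted LM steps.
    goal : float, default 1e-3
        Normalized-MSE stopping goal.
    learning_rate : float, default 0.01
        Recorded for config fidelity; inert, since LM has no learning-rate
        parameter.
    mu0, mu_inc, mu_dec, mu_max : float
        LM damping schedule: initial mu, factor on rejection, factor on
        acceptance, ceiling that terminates training.
    norm_lo, norm_hi : float
        Min-max normalization range for inputs and targets.
    random_state : int or None
        Seed for the Nguyen-Widrow initialization; a given (seed, data,
        config) triple reproduces the trained model bit-for-bit.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : ndarray
        Layer weights/biases (H x I, H, O x H, O).
    input_norm_, output_norm_ : MinMaxNormalizer
    history_ : TrainingHistory
    n_iter_ : int
    goal_met_ : bool
    """

    def __init__(self, n_hidden: int = 9, max_epochs: int = 1000, goal: float = 1e-3,
                 learning_rate: float = 0.01, mu0: float = 1e-3, mu_inc: float = 10.0,
                 mu_dec: float = 0.1, mu_max: float = 1e10,
                 norm_lo: float = 0.05, norm_hi: float = 0.95,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.goal = goal
        self.learning_rate = learning_rate
        self.mu0 = mu0
        self.mu_inc = mu_inc
        self.mu_dec = mu_dec
        self.mu_max = mu_max
        self.norm_lo = norm_lo
        self.norm_hi = norm_hi
        self.random_state = random_state

    # ---------------------------------------------------------------- init

    def _init_weights(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        """Nguyen-Widrow-style initialization: hidden-row directions random,
        magnitudes set to tile the normalized input box, biases spread
        across the active region; output layer small uniform."""
        H = self.n_hidden
        beta = 0.7 * H ** (1.0 / n_in)
        W = rng.uniform(-1.0, 1.0, size=(H, n_in))
        W *= beta / np.linalg.norm(W, axis=1, keepdims=True)
        b = beta * np.linspace(-1.0, 1.0, H) * np.sign(W[:, 0])
        # Nguyen-Widrow assumes inputs in [-1, 1]; fold in the affine map
        # from the actual normalized range [lo, hi].
        half = 0.5 * (self.norm_hi - self.norm_lo)
        mid = 0.5 * (self.norm_hi + self.norm_lo)
        self.W1_ = W / half
        self.b1_ = b - (self.W1_ @ np.full(n_in, mid))
        self.W2_ = rng.uniform(-0.5, 0.5, size=(n_out, H))
        self.b2_ = rng.uniform(-0.5, 0.5, size=n_out)

    # ------------------------------------------------------------- forward

    def _forward(self, Xn: np.ndarray):
        A = _sigmoid(Xn @ self.W1_.T + self.b1_)
        Yn = _sigmoid(A @ self.W2_.T + self.b2_)
        return A, Yn

    def _pack(self) -> np.ndarray:
        return np.concatenate([self.W1_.ravel(), self.b1_, self.W2_.ravel(), self.b2_])

    def _unpack(self, w: np.ndarray, n_in: int, n_out: int) -> None:
        H = self.n_hidden
        i = 0
        self.W1_ = w[i:i + H * n_in].reshape(H, n_in); i += H * n_in
        self.b1_ = w[i:i + H].copy(); i += H
        self.W2_ = w[i:i + n_out * H].reshape(n_out, H); i += n_out * H
        self.b2_ = w[i:i + n_out].copy()

    def _residual_jacobian(self, Xn: np.ndarray):
        """Residual vector r = yhat - t (flattened N*O) and its Jacobian
        (N*O x P) with respect to the packed weights, by backpropagation."""
        N, n_in = Xn.shape
        H = self.n_hidden
        A, Yn = self._forward(Xn)
        n_out = Yn.shape[1]
        dy = Yn * (1.0 - Yn)                      # N x O
        da = A * (1.0 - A)                        # N x H
        # sensitivity of output k to hidden activation j, per sample
        G = dy[:, :, None] * self.W2_[None, :, :] * da[:, None, :]   # N x O x H
        P = H * n_in + H + n_out * H + n_out
        J = np.zeros((N, n_out, P))
        i = 0
        J[:, :, i:i + H * n_in] = (G[:, :, :, None] * Xn[:, None, None, :]).reshape(N, n_out, H * n_in)
        i += H * n_in
        J[:, :, i:i + H] = G
        i += H
        blk = dy[:, :, None] * A[:, None, :]      # N x O x H, dy_k/dW2[k, j]
        for k in range(n_out):
            J[:, k, i + k * H:i + (k + 1) * H] = blk[:, k, :]
        i += n_out * H
        for k in range(n_out):
            J[:, k, i + k] = dy[:, k]
        return Yn, J.reshape(N * n_out, P)

    # ----------------------------------------------------------------- fit

    def fit(self, X, y) -> "LMMLPRegressor":
        """Train on raw (unnormalized) inputs X (n, d_in) and targets
        y (n, d_out) or (n,)."""
        if not 1 <= self.n_hidden <= 100:
            raise ValueError("n_hidden must lie in [1, 100]")
        if self.goal <= 0 or self.max_epochs < 1 or self.mu0 <= 0:
            raise ValueError("invalid training configuration")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self._y_1d_ = y.ndim == 1
        if self._y_1d_:
            y = y[:, None]
        if X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise ValueError("X and y must be nonempty and of equal length")
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]

        self.input_norm_ = fit_normalizer(X, self.norm_lo, self.norm_hi)
        self.output_norm_ = fit_normalizer(y, self.norm_lo, self.norm_hi)
        Xn = self.input_norm_.transform(X)
        Tn = self.output_norm_.transform(y)

        rng = np.random.default_rng(self.random_state)
        self._init_weights(self.n_features_in_, self.n_outputs_, rng)

        history = TrainingHistory()
        n_in, n_out = self.n_features_in_, self.n_outputs_
        N = Xn.shape[0]
        mu = float(self.mu0)
        _, Yn = self._forward(Xn)
        mse = float(np.mean((Yn - Tn) ** 2))
        history.mse.append(mse)
        if not np.isfinite(mse):
            raise TrainingDivergenceError("initial loss is non-finite", history)

        stop = "max_epochs"
        if mse <= self.goal:
            stop = "goal"
        else:
            for _ in range(self.max_epochs):
                Yn, J = self._residual_jacobian(Xn)
                r = (Yn - Tn).ravel()
                g = J.T @ r
                JtJ = J.T @ J
                w = self._pack()
                accepted = False
                while mu <= self.mu_max:
                    try:
                        delta = np.linalg.solve(JtJ + mu * np.eye(len(w)), g)
                    except np.linalg.LinAlgError:
                        mu *= self.mu_inc
                        continue
                    self._unpack(w - delta, n_in, n_out)
                    _, Y_try = self._forward(Xn)
                    mse_try = float(np.mean((Y_try - Tn) ** 2))
                    if not np.isfinite(mse_try):
                        self._unpack(w, n_in, n_out)
                        raise TrainingDivergenceError("loss became non-finite", history)
                    if mse_try < mse:
                        mse = mse_try
                        mu = max(mu * self.mu_dec, np.finfo(float).tiny)
                        accepted = True
                        break
                    self._unpack(w, n_in, n_out)
                    mu *= self.mu_inc
                if not accepted:
                    stop = "mu_max"
                    break
                history.mse.append(mse)
                history.epochs_run += 1
                if mse <= self.goal:
                    stop = "goal"
                    break

        history.goal_met = mse <= self.goal
        history.stop_reason = stop
        self.history_ = history
        self.n_iter_ = history.epochs_run
        self.goal_met_ = history.goal_met
        self.final_mse_ = mse
        return self

    # ------------------------------------------------------------- predict

    def _predict_normalized(self, X) -> np.ndarray:
        """Raw sigmoid outputs on the normalized scale, strictly in (0, 1)."""
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xn = self.input_norm_.transform(X)
        _, Yn = self._forward(Xn)
        return Yn

    def predict(self, X) -> np.ndarray:
        """Normalize, forward-pass, denormalize.  Outputs are bounded by
        the output normalizer's inverse image of (0, 1)."""
        Yn = self._predict_normalized(X)
        out = self.output_norm_.inverse_transform(Yn)
        return out.ravel() if self._y_1d_ else out

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        check_is_fitted(self, "W1_")
        return {
            "params": self.get_params(),
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_.tolist(),
            "activation": "sigmoid",
            "input_norm": self.input_norm_.to_dict(),
            "output_norm": self.output_norm_.to_dict(),
            "n_features_in": int(self.n_features_in_),
            "n_outputs": int(self.n_outputs_),
            "y_1d": bool(self._y_1d_),
            "history": {"mse": [float(m) for m in self.history_.mse],
                        "epochs_run": self.history_.epochs_run,
                        "goal_met": self.history_.goal_met,
                        "stop_reason": self.history_.stop_reason},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "LMMLPRegressor":
        model = cls(**d["params"])
        model.W1_ = np.asarray(d["W1"], float)
        model.b1_ = np.asarray(d["b1"], float)
        model.W2_ = np.asarray(d["W2"], float)
        model.b2_ = np.asarray(d["b2"], float)
        model.input_norm_ = MinMaxNormalizer.from_dict(d["input_norm"])
        model.output_norm_ = MinMaxNormalizer.from_dict(d["output_norm"])
        model.n_features_in_ = d["n_features_in"]
        model.n_outputs_ = d["n_outputs"]
        model._y_1d_ = d["y_1d"]
        h = d["history"]
        model.history_ = TrainingHistory(mse=list(h["mse"]), epochs_run=h["epochs_run"],
                                         goal_met=h["goal_met"], stop_reason=h["stop_reason"])
        model.n_iter_ = model.history_.epochs_run
        model.goal_met_ = model.history_.goal_met
        model.final_mse_ = model.history_.mse[-1] if model.history_.mse else np.nan
        return model

    @classmethod
    def load(cls, path) -> "LMMLPRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_mlp(n_hidden: int, seed: int | None = None, n_in: int = 2, n_out: int = 3) -> LMMLPRegressor:
    """Seeded, initialized (untrained) network with the pipeline's 2-in /
    3-out topology by default."""
    model = LMMLPRegressor(n_hidden=n_hidden, random_state=seed)
    if not 1 <= n_hidden <= 100:
        raise ValueError("n_hidden must lie in [1, 100]")
    model.n_features_in_ = n_in
    model.n_outputs_ = n_out
    model._init_weights(n_in, n_out, np.random.default_rng(seed))
    return model


def n_parameters(n_hidden: int, n_in: int = 2, n_out: int = 3) -> int:
    """Trainable parameter count: (n_in + 1) H + (H + 1) n_out."""
    return (n_in + 1) * n_hidden + (n_hidden + 1) * n_out


def train_lm(X, y, **params) -> LMMLPRegressor:
    """Fit an :class:`LMMLPRegressor` with the given constructor params."""
    return LMMLPRegressor(**params).fit(X, y)


def predict_torque(model: LMMLPRegressor, posture) -> np.ndarray:
    """Predict the torque vector(s) for posture angle pair(s)
    (plane of elevation, elevation), radians."""
    return model.predict(np.atleast_2d(np.asarray(posture, dtype=float)))


def hidden_unit_sweep(X, y, h_values, seed: int | None = None, **params) -> pd.DataFrame:
    """One seeded training run per hidden-layer size.

    Returns a DataFrame with one row per requested H, sorted by H, with
    columns ``n_hidden, epochs_run, goal_met, final_mse``.
    """
    rows = []
    for h in sorted(h_values):
        model = LMMLPRegressor(n_hidden=int(h), random_state=seed, **params).fit(X, y)
        rows.append({
            "n_hidden": int(h),
            "epochs_run": model.n_iter_,
            "goal_met": model.goal_met_,
            "final_mse": model.final_mse_,
        })
    return pd.DataFrame(rows)
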