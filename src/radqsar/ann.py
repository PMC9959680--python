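"""3-3-1 multilayer perceptron trained by Levenberg-Marquardt with Bayesian
regularization.

The network maps three molecular descriptors through one hidden layer of
three tanh units to a single linear output. Inputs and the target are
affinely scaled to [-1, 1] before training (the scaling is stored and
inverted on prediction). Training minimizes the regularized objective

    F(w) = beta * E_D + alpha * E_W,
    E_D = 1/2 * sum(residual^2),   E_W = 1/2 * sum(w^2),

with Levenberg-Marquardt steps

    dw = -(beta J'J + (mu + alpha) I)^-1 (beta J'r + alpha w),

where J is the analytic Jacobian of the residuals. After each accepted step
the evidence-framework (MacKay) hyperparameter updates are applied:

    gamma = N_w - alpha * tr(H^-1),  H = beta J'J + alpha I,
    alpha = gamma / (2 E_W),         beta = (n - gamma) / (2 E_D),

so the effective number of parameters gamma adapts to how much structure the
data actually supports -- the mechanism that lets a 16-weight network train
on a dozen compounds without overfitting.

Three stabilizations for the n < N_w regime (12 training compounds, 16
weights): gamma is clamped to [0, min(N_w, n - 1)], since no more effective
parameters than observations can be constrained (an unclamped gamma > n
would drive beta negative); the evidence updates start only after a short
warm-up of weight-decayed LM epochs (initial alpha = 0.1) so the error fit
takes shape before the hyperparameters adapt; and training is restarted
from several seeded initializations, keeping the solution with the highest
log model evidence

    log E = -alpha E_W - beta E_D - 1/2 log det H
            + N_w/2 log alpha + n/2 log beta  (+ const),

which is the evidence framework's own criterion for choosing among
self-consistent (alpha, beta, w) fixed points. gamma is recomputed from the
converged state before reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DataSet
from .errors import AlignmentError, RadqsarError, TrainingError
from .stats import RegressionStats, regression_report

__all__ = ["AnnArchitecture", "AnnTrainConfig", "TrainedAnn",
           "BayesianRegularizedMLP", "forward", "jacobian", "lm_step",
           "bayesian_update", "train_ann", "ann_report"]


@dataclass(frozen=True)
class AnnArchitecture:
    """Layer sizes; the canonical QSAR setup is 3-3-1 (16 weights)."""

    n_input: int = 3
    n_hidden: int = 3
    n_output: int = 1

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise RadqsarError("layer sizes must be positive")
        if self.n_output != 1:
            raise RadqsarError("only single-output networks are supported")

    @property
    def n_weights(self) -> int:
        return (self.n_input + 1) * self.n_hidden + (self.n_hidden + 1)


@dataclass(frozen=True)
class AnnTrainConfig:
    """Levenberg-Marquardt and regularization controls."""

    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    gradient_tolerance: float = 1e-7
    alpha_init: float = 0.1
    beta_init: float = 1.0
    warmup_epochs: int = 10
    n_restarts: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu_init, self.mu_increase, self.mu_max) <= 0:
            raise RadqsarError("damping controls must be positive")
        if not (self.mu_increase > 1.0 > self.mu_decrease > 0.0):
            raise RadqsarError("need mu_increase > 1 > mu_decrease > 0")


@dataclass
class _AffineMap:
    """x_scaled = (x - lo) / span * 2 - 1, per variable; degenerate spans map
    to 0."""

    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "_AffineMap":
        values = np.atleast_2d(values)
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        span = np.where(span == 0, 1.0, span)
        return cls(lo=lo, span=span)

    def forward(self, values: np.ndarray) -> np.ndarray:
        return (values - self.lo) / self.span * 2.0 - 1.0

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return (scaled + 1.0) / 2.0 * self.span + self.lo


@dataclass
class TrainedAnn:
    """A trained network: weights, scalings and regularization state."""

    architecture: AnnArchitecture
    weights: np.ndarray
    descriptor_ids: tuple[str, ...]
    input_scaling: _AffineMap
    output_scaling: _AffineMap
    alpha: float
    beta: float
    gamma: float
    epochs_run: int
    objective_history: list[float] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return forward(self, X)


def _unpack(arch: AnnArchitecture, w: np.ndarray):
    h, d = arch.n_hidden, arch.n_input
    W1 = w[: h * d].reshape(h, d)
    b1 = w[h * d: h * d + h]
    w2 = w[h * d + h: h * d + 2 * h]
    b2 = w[-1]
    return W1, b1, w2, b2


def _forward_scaled(arch: AnnArchitecture, w: np.ndarray, Xs: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    W1, b1, w2, b2 = _unpack(arch, w)
    H = np.tanh(Xs @ W1.T + b1)
    return H @ w2 + b2, H


def _resolve_inputs(net: TrainedAnn, X) -> np.ndarray:
    import pandas as pd

    if hasattr(X, "columns") and callable(getattr(X, "columns", None)):
        return X.columns(list(net.descriptor_ids))  # DescriptorTable
    if isinstance(X, pd.DataFrame):
        missing = [c for c in net.descriptor_ids if c not in X.columns]
        if missing:
            raise AlignmentError(
                "missing descriptor column(s): " + ", ".join(missing))
        return X[list(net.descriptor_ids)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != net.architecture.n_input:
        raise AlignmentError(
            f"network expects {net.architecture.n_input} input columns, "
            f"got {X.shape[1]}")
    return X


def forward(net: TrainedAnn, X) -> np.ndarray:
    """Predict activities: scale inputs, run tanh-hidden/linear-output
    network, unscale the output. Vectorized over rows."""
    Xs = net.input_scaling.forward(_resolve_inputs(net, X))
    out, _ = _forward_scaled(net.architecture, net.weights, Xs)
    return net.output_scaling.inverse(out)


def jacobian(arch: AnnArchitecture, w: np.ndarray, Xs: np.ndarray
             ) -> np.ndarray:
    """Analytic n x N_w Jacobian of the scaled-space residuals r = yhat - y
    with respect to the weights (backpropagated; independent of y since
    dr/dw = dyhat/dw)."""
    n = Xs.shape[0]
    h, d = arch.n_hidden, arch.n_input
    W1, b1, w2, _ = _unpack(arch, w)
    A = np.tanh(Xs @ W1.T + b1)          # n x h
    dA = (1.0 - A ** 2) * w2             # n x h, dyhat/d(preactivation_j)
    J = np.empty((n, arch.n_weights))
    J[:, : h * d] = (dA[:, :, None] * Xs[:, None, :]).reshape(n, h * d)
    J[:, h * d: h * d + h] = dA
    J[:, h * d + h: h * d + 2 * h] = A
    J[:, -1] = 1.0
    return J


def lm_step(weights: np.ndarray, J: np.ndarray, residuals: np.ndarray,
            mu: float, alpha: float = 0.0, beta: float = 1.0) -> np.ndarray:
    """One Levenberg-Marquardt proposal for the regularized objective.

    Returns the candidate weight vector; the caller accepts it only if the
    objective decreases, otherwise raises mu and retries. As mu -> inf the
    step shrinks to zero; with alpha = 0 and a linear residual, a single
    undamped step lands on the least-squares optimum."""
    gradient = beta * (J.T @ residuals) + alpha * weights
    A = beta * (J.T @ J) + (mu + alpha) * np.eye(weights.size)
    return weights - np.linalg.solve(A, gradient)


def _effective_parameters(alpha: float, beta: float, JtJ: np.ndarray,
                          n_obs: int, n_weights: int) -> float:
    """gamma = N_w - alpha tr(H^-1), H = beta J'J + alpha I, clamped to
    [0, min(N_w, n - 1)]. At alpha = 0 the trace term vanishes exactly."""
    cap = float(min(n_weights, n_obs - 1))
    if alpha == 0.0:
        return cap
    H = beta * JtJ + alpha * np.eye(n_weights)
    try:
        tr_Hinv = float(np.trace(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian in evidence update; using "
                      "ridge-stabilized inverse", UserWarning, stacklevel=2)
        ridge = 1e-8 * max(1.0, float(np.trace(H)) / n_weights)
        tr_Hinv = float(np.trace(np.linalg.inv(H + ridge * np.eye(n_weights))))
    return float(np.clip(n_weights - alpha * tr_Hinv, 0.0, cap))


def bayesian_update(alpha: float, beta: float, E_W: float, E_D: float,
                    n_obs: int, n_weights: int, JtJ: np.ndarray
                    ) -> tuple[float, float, float]:
    """Evidence-framework hyperparameter update.

    gamma = N_w - alpha tr(H^-1) with H = beta J'J + alpha I, clamped to
    [0, min(N_w, n - 1)] (see module docstring); then
    alpha = gamma / (2 E_W), beta = (n - gamma) / (2 E_D). A singular
    Hessian falls back to a ridge-stabilized inverse with a warning."""
    if E_W <= 0 or E_D <= 0:
        raise RadqsarError("bayesian_update requires E_W > 0 and E_D > 0")
    gamma = _effective_parameters(alpha, beta, JtJ, n_obs, n_weights)
    # cap to keep beta*J'J representable when E_D collapses to ~0
    new_alpha = min(gamma / (2.0 * E_W), 1e12)
    new_beta = min((n_obs - gamma) / (2.0 * E_D), 1e12)
    return new_alpha, new_beta, gamma


class BayesianRegularizedMLP(BaseEstimator, RegressorMixin):
    """scikit-learn-style regressor around the LM + Bayesian-regularization
    trainer.

    Parameters mirror :class:`AnnTrainConfig` plus ``n_hidden`` and
    ``bayesian`` (set False for plain unregularized Levenberg-Marquardt,
    used when quantifying how much the regularization suppresses
    overfitting). After :meth:`fit`: ``net_`` (:class:`TrainedAnn`),
    ``alpha_``, ``beta_``, ``gamma_``, ``epochs_run_``,
    ``objective_history_``.
    """

    def __init__(self, n_hidden: int = 3, max_epochs: int = 1000,
                 mu_init: float = 1e-3, mu_increase: float = 10.0,
                 mu_decrease: float = 0.1, mu_max: float = 1e10,
                 gradient_tolerance: float = 1e-7, alpha_init: float = 0.0,
                 beta_init: float = 1.0, warmup_epochs: int = 10,
                 bayesian: bool = True, rng_seed: int = 0):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.mu_init = mu_init
        self.mu_increase = mu_increase
        self.mu_decrease = mu_decrease
        self.mu_max = mu_max
        self.gradient_tolerance = gradient_tolerance
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.warmup_epochs = warmup_epochs
        self.bayesian = bayesian
        self.rng_seed = rng_seed

    def fit(self, X, y, feature_names: tuple[str, ...] | None = None
            ) -> "BayesianRegularizedMLP":
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            feature_names = tuple(str(c) for c in X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if y.shape[0] != n:
            raise AlignmentError(f"X has {n} rows but y has {y.shape[0]}")
        if n < 6:
            raise RadqsarError(f"need at least 6 training rows, got {n}")
        if feature_names is None:
            feature_names = tuple(f"x{j}" for j in range(d))

        arch = AnnArchitecture(n_input=d, n_hidden=self.n_hidden)
        cfg = AnnTrainConfig(
            max_epochs=self.max_epochs, mu_init=self.mu_init,
            mu_increase=self.mu_increase, mu_decrease=self.mu_decrease,
            mu_max=self.mu_max, gradient_tolerance=self.gradient_tolerance,
            alpha_init=self.alpha_init, beta_init=self.beta_init,
            warmup_epochs=self.warmup_epochs, rng_seed=self.rng_seed)
        self.net_ = _train(arch, X, y, feature_names, cfg,
                           bayesian=self.bayesian)
        self.alpha_, self.beta_ = self.net_.alpha, self.net_.beta
        self.gamma_ = self.net_.gamma
        self.epochs_run_ = self.net_.epochs_run
        self.objective_history_ = self.net_.objective_history
        return self

    def predict(self, X) -> np.ndarray:
        return forward(self.net_, X)


def _log_evidence(arch: AnnArchitecture, w: np.ndarray, Xs: np.ndarray,
                  ys: np.ndarray, alpha: float, beta: float) -> float:
    """Log model evidence (up to an additive constant) at a converged
    (w, alpha, beta) point, under the Gauss-Newton Hessian approximation."""
    out, _ = _forward_scaled(arch, w, Xs)
    r = out - ys
    E_D = 0.5 * float(r @ r)
    E_W = 0.5 * float(w @ w)
    a, b = max(alpha, 1e-12), max(beta, 1e-12)
    J = jacobian(arch, w, Xs)
    H = b * (J.T @ J) + a * np.eye(arch.n_weights)
    _, logdet = np.linalg.slogdet(H)
    return float(-a * E_W - b * E_D - 0.5 * logdet
                 + arch.n_weights / 2.0 * np.log(a)
                 + ys.size / 2.0 * np.log(b))


def _train(arch: AnnArchitecture, X: np.ndarray, y: np.ndarray,
           feature_names: tuple[str, ...], cfg: AnnTrainConfig,
           bayesian: bool = True) -> TrainedAnn:
    """Run ``cfg.n_restarts`` seeded trainings and keep the solution with the
    highest log evidence (lowest data error when bayesian=False).

    One extra conservative run starts the evidence updates immediately
    (warmup_epochs=1); it reliably finds the heavily regularized
    fixed point, so on structureless targets the evidence can prefer it over
    aggressively fitted restarts."""
    import dataclasses

    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(cfg.n_restarts)
    runs = [(cfg, int(s) % (2**31)) for s in seeds]
    if bayesian and cfg.warmup_epochs > 1:
        conservative = dataclasses.replace(cfg, warmup_epochs=1)
        runs.append((conservative, int(seeds[0]) % (2**31)))
    best: TrainedAnn | None = None
    best_score = -np.inf
    for run_cfg, s in runs:
        net = _train_once(arch, X, y, feature_names, run_cfg, s, bayesian)
        Xs = net.input_scaling.forward(X)
        ys = net.output_scaling.forward(y[:, None]).ravel()
        if bayesian:
            score = _log_evidence(arch, net.weights, Xs, ys, net.alpha,
                                  net.beta)
        else:
            out, _ = _forward_scaled(arch, net.weights, Xs)
            score = -float(np.sum((out - ys) ** 2))
        if score > best_score:
            best, best_score = net, score
    return best


def _train_once(arch: AnnArchitecture, X: np.ndarray, y: np.ndarray,
                feature_names: tuple[str, ...], cfg: AnnTrainConfig,
                weight_seed: int, bayesian: bool = True) -> TrainedAnn:
    rng = np.random.default_rng(weight_seed)
    in_map = _AffineMap.fit(X)
    out_map = _AffineMap.fit(y[:, None])
    Xs = in_map.forward(X)
    ys = out_map.forward(y[:, None]).ravel()
    n = Xs.shape[0]

    w = rng.uniform(-0.5, 0.5, size=arch.n_weights)
    alpha, beta, mu = cfg.alpha_init, cfg.beta_init, cfg.mu_init
    gamma = float(arch.n_weights)

    def objective(weights: np.ndarray, a: float, b: float) -> tuple[float, np.ndarray]:
        out, _ = _forward_scaled(arch, weights, Xs)
        r = out - ys
        return b * 0.5 * float(r @ r) + a * 0.5 * float(weights @ weights), r

    obj, r = objective(w, alpha, beta)
    history = [obj]
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        J = jacobian(arch, w, Xs)
        gradient = beta * (J.T @ r) + alpha * w
        if np.abs(gradient).max() < cfg.gradient_tolerance:
            break
        accepted = False
        while mu <= cfg.mu_max:
            try:
                w_new = lm_step(w, J, r, mu, alpha, beta)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_increase  # singular system: damp harder
                continue
            obj_new, r_new = objective(w_new, alpha, beta)
            if not np.isfinite(obj_new):
                raise TrainingError(
                    f"non-finite objective at epoch {epoch}; history: "
                    f"{history[-5:]}")
            if obj_new < obj:
                w, r = w_new, r_new
                mu = max(mu * cfg.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_increase
        if not accepted:
            break  # mu exceeded mu_max: converged as far as LM can go

        if bayesian and epoch >= cfg.warmup_epochs:
            E_W = 0.5 * float(w @ w)
            E_D = 0.5 * float(r @ r)
            if E_W > 0 and E_D > 0:
                alpha, beta, gamma = bayesian_update(
                    alpha, beta, E_W, E_D, n, arch.n_weights, J.T @ J)
        obj, _ = objective(w, alpha, beta)
        history.append(obj)

    if bayesian and alpha > 0:
        J = jacobian(arch, w, Xs)
        gamma = _effective_parameters(alpha, beta, J.T @ J, n, arch.n_weights)
    return TrainedAnn(architecture=arch, weights=w,
                      descriptor_ids=tuple(feature_names),
                      input_scaling=in_map, output_scaling=out_map,
                      alpha=alpha, beta=beta, gamma=gamma, epochs_run=epoch,
                      objective_history=history)


def train_ann(ds_train: DataSet, response_id: str,
              descriptor_ids: tuple[str, ...],
              cfg: AnnTrainConfig | None = None) -> TrainedAnn:
    """Train a 3-3-1 network for one activity on the named descriptors
    (conventionally the three selected by the GA-MLR equation for that
    activity)."""
    cfg = cfg or AnnTrainConfig()
    if len(descriptor_ids) != 3:
        raise RadqsarError("the 3-3-1 architecture takes exactly 3 descriptors")
    X = ds_train.descriptors.columns(list(descriptor_ids))
    y = ds_train.activities.response(response_id)
    return _train(AnnArchitecture(), X, y, tuple(descriptor_ids), cfg)


def ann_report(net: TrainedAnn, ds_train: DataSet, ds_test: DataSet | None,
               response_id: str) -> tuple[RegressionStats, RegressionStats | None]:
    """Evaluate a trained network with the standard regression diagnostics
    (R^2 = ESS/TSS, RMSE) on the training and optional test sets."""
    p = net.architecture.n_weights
    train_stats = regression_report(
        ds_train.activities.response(response_id),
        forward(net, ds_train.descriptors), p=p, with_f=False)
    test_stats = None
    if ds_test is not None:
        test_stats = regression_report(
            ds_test.activities.response(response_id),
            forward(net, ds_test.descriptors), p=p, with_f=False)
    return train_stats, test_stats
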