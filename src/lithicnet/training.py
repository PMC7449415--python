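"""Levenberg–Marquardt training with Bayesian-regularization updates.

One network is fit by damped least squares on the sum of squared errors
between output probabilities and one-hot targets, with a quadratic weight
penalty whose strength is re-estimated from the data by the evidence
framework (MacKay / Foresee–Hagan style):

    F = beta * E_D + alpha * E_W,
    E_D = sum of squared residuals,  E_W = sum of squared penalized parameters.

After each accepted step the effective number of parameters
``gamma = N − 2·alpha·tr(Hᶠ⁻¹)`` — with Hᶠ the full Hessian of F,
``2·beta·JᵀJ + 2·alpha·I``, so equivalently ``N − alpha·tr((beta·JᵀJ +
alpha·I)⁻¹)``; for a single parameter this is MacKay's ``λ/(λ+alpha)`` —
re-estimates ``alpha = gamma / (2 E_W)`` and ``beta = (N_resid −
gamma) / (2 E_D)``. This built-in shrinkage is why no separate validation set
is held out: the regularizer itself controls over-fitting on the small
assemblage sample.

The numerical kernels (:func:`lm_update`, :func:`evidence_quantities`)
operate on raw residual/Jacobian arrays so they can be exercised on scalar
surrogate problems; :func:`train_network` wires them to the perceptron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .assemblages import ClassScheme, TechnologyMatrix
from .mlp import (
    NetworkParameters,
    class_probabilities,
    forward,
    init_network,
    jacobian,
    rescale_inputs,
)

_TINY = 1e-300


@dataclass
class TrainingConfig:
    """Damping schedule, stopping rules and regularization starts.

    Defaults follow standard damped-LM practice on small networks: start
    nearly Gauss–Newton (small ``mu_init``), decade up/down damping, stop on
    a vanishing gradient, a stalled objective, the damping ceiling, or the
    epoch budget. ``alpha_init = 0`` lets the first evidence update set the
    penalty scale from the data.

    ``evidence_damping`` relaxes (alpha, beta) toward their evidence targets
    by that fraction per epoch instead of replacing them outright. With a
    network holding more parameters than training residuals the two point
    estimates have no joint fixed point away from degeneracy (gamma can reach
    N_resid, zeroing the implied beta), and undamped updates oscillate
    between all-data and all-penalty regimes; relaxation settles them on an
    interior balance.
    """

    max_epochs: int = 1000
    mu_init: float = 5e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    objective_tol: float = 1e-5
    alpha_init: float = 0.0
    beta_init: float = 1.0
    alpha_max: float = 1e10
    beta_max: float = 1e10
    evidence_damping: float = 0.5
    include_biases_in_penalty: bool = True

    def __post_init__(self) -> None:
        if self.mu_increase <= 1:
            raise ValueError("mu_increase must exceed 1")
        if not 0 < self.mu_decrease < 1:
            raise ValueError("mu_decrease must lie in (0, 1)")
        if self.grad_tol <= 0 or self.objective_tol <= 0:
            raise ValueError("tolerances must be positive")

    # ------------------------------------------------------------- round-trip
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_yaml(source) -> "TrainingConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yml", ".yaml", ".json")):
                with open(text, "r", encoding="utf-8") as fh:
                    text = fh.read()
            doc = yaml.safe_load(text)
        return TrainingConfig(**doc)


@dataclass
class TrainedNetwork:
    """One fitted network plus its partition, errors and diagnostics.

    ``accuracy_all`` — the proportion of *all* assemblages (training and test
    pooled) the network classifies correctly — is the weight the ensemble
    later attributes to this network.
    """

    params: NetworkParameters
    partition: "object"
    train_sse: float
    test_sse: float
    accuracy_all: float
    br_state: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return self.params.to_json(
            train_sse=self.train_sse,
            test_sse=self.test_sse,
            accuracy_all=self.accuracy_all,
            br_state={k: (float(v) if np.isscalar(v) else v) for k, v in self.br_state.items()},
        )


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def data_error(params: NetworkParameters, X: np.ndarray, T: np.ndarray) -> float:
    """E_D: sum of squared residuals of output probabilities vs targets."""
    Y = np.atleast_2d(forward(params, X))
    T = np.atleast_2d(T)
    return float(((Y - T) ** 2).sum())


def weight_error(params: NetworkParameters, include_biases: bool = True) -> float:
    """E_W: sum of squared penalized parameters."""
    theta = params.flatten()
    if not include_biases:
        theta = theta[~params.bias_mask()]
    return float((theta ** 2).sum())


def objective(
    params: NetworkParameters,
    data: tuple[np.ndarray, np.ndarray],
    alpha: float,
    beta: float,
    include_biases: bool = True,
) -> float:
    """The regularized objective F = beta·E_D + alpha·E_W."""
    X, T = data
    return beta * data_error(params, X, T) + alpha * weight_error(params, include_biases)


# --------------------------------------------------------------------------
# numerical kernels (array-level; usable on surrogate problems)
# --------------------------------------------------------------------------

def lm_update(
    J: np.ndarray,
    r: np.ndarray,
    theta: np.ndarray,
    mu: float,
    alpha: float,
    beta: float,
    pen_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the damped, regularized normal equations for the LM step.

        (beta·JᵀJ + alpha·P + mu·I) δ = −(beta·Jᵀr + alpha·P·theta)

    where P selects the penalized parameters. Returns the step δ.
    """
    n_p = theta.size
    if pen_mask is None:
        pen = np.ones(n_p)
    else:
        pen = pen_mask.astype(float)
    A = beta * (J.T @ J)
    A[np.diag_indices_from(A)] += alpha * pen + mu
    g = beta * (J.T @ r) + alpha * pen * theta
    try:
        return np.linalg.solve(A, -g)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, -g, rcond=None)[0]


def evidence_quantities(
    J: np.ndarray,
    e_d: float,
    e_w: float,
    alpha: float,
    beta: float,
    alpha_max: float = 1e10,
    beta_max: float = 1e10,
) -> tuple[float, float, float]:
    """Evidence-framework re-estimation of (alpha, beta) and gamma.

    The effective number of parameters is gamma = Σ λᵢ/(λᵢ+alpha) over the
    eigenvalues λᵢ of the Gauss–Newton matrix beta·JᵀJ — the eigen form of
    N_param − 2·alpha·tr(Hᶠ⁻¹) with Hᶠ = 2·beta·JᵀJ + 2·alpha·I the full
    Hessian of F, and the numerically robust one when JᵀJ is rank-deficient
    (gamma then tends to rank(J), not N_param, as alpha → 0). Then
    alpha' = gamma / (2 E_W) and beta' = (N_resid − gamma) / (2 E_D), both
    clamped to (0, cap].
    """
    n_resid, n_p = J.shape
    lam = np.linalg.eigvalsh(beta * (J.T @ J))
    lam = np.clip(lam, 0.0, None)
    if alpha > 0:
        gamma = float((lam / (lam + alpha)).sum())
    else:
        tol = lam.max() * n_p * np.finfo(float).eps if lam.size and lam.max() > 0 else 0.0
        gamma = float((lam > tol).sum())
    gamma = float(np.clip(gamma, 0.0, n_p))
    alpha_new = gamma / (2.0 * e_w) if e_w > _TINY else alpha_max
    beta_new = (n_resid - gamma) / (2.0 * e_d) if e_d > _TINY else beta_max
    alpha_new = float(np.clip(alpha_new, 0.0, alpha_max))
    beta_new = float(np.clip(beta_new, _TINY, beta_max))
    return alpha_new, beta_new, gamma


# --------------------------------------------------------------------------
# network-level wrappers
# --------------------------------------------------------------------------

def _residuals(params: NetworkParameters, X: np.ndarray, T: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(forward(params, X))
    return (Y - np.atleast_2d(T)).ravel()


def lm_step(
    params: NetworkParameters,
    data: tuple[np.ndarray, np.ndarray],
    mu: float,
    alpha: float,
    beta: float,
    config: TrainingConfig | None = None,
) -> tuple[NetworkParameters, bool, float]:
    """Attempt one Levenberg–Marquardt step.

    Returns ``(candidate, accepted, mu')``: on acceptance (F strictly
    decreased) the candidate parameters and ``mu·mu_decrease``; on rejection
    the *unchanged* parameters and ``mu·mu_increase``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    cfg = config or TrainingConfig()
    X, T = data
    pen = _pen_mask(params, cfg)
    theta = params.flatten()
    J = jacobian(params, X)
    r = _residuals(params, X, T)
    F0 = objective(params, data, alpha, beta, cfg.include_biases_in_penalty)
    delta = lm_update(J, r, theta, mu, alpha, beta, pen)
    candidate = params.with_flat(theta + delta)
    F1 = objective(candidate, data, alpha, beta, cfg.include_biases_in_penalty)
    if np.isfinite(F1) and F1 < F0:
        return candidate, True, mu * cfg.mu_decrease
    return params, False, mu * cfg.mu_increase


def evidence_update(
    params: NetworkParameters,
    data: tuple[np.ndarray, np.ndarray],
    alpha: float,
    beta: float,
    config: TrainingConfig | None = None,
) -> tuple[float, float, float]:
    """Re-estimate (alpha, beta, gamma) at the current parameters."""
    cfg = config or TrainingConfig()
    X, T = data
    J = jacobian(params, X)
    pen = _pen_mask(params, cfg)
    if pen is not None:
        J_pen = J[:, pen]
        # gamma/alpha refer to penalized parameters only in that case
        e_w = weight_error(params, include_biases=False)
        a, b, g = evidence_quantities(
            J_pen, data_error(params, X, T), e_w, alpha, beta,
            cfg.alpha_max, cfg.beta_max,
        )
        return a, b, g
    return evidence_quantities(
        J, data_error(params, X, T), weight_error(params, True),
        alpha, beta, cfg.alpha_max, cfg.beta_max,
    )


def _pen_mask(params: NetworkParameters, cfg: TrainingConfig):
    if cfg.include_biases_in_penalty:
        return None
    return ~params.bias_mask()


def one_hot_targets(labels: Sequence[str], scheme: ClassScheme) -> np.ndarray:
    """Targets for training: one-hot rows (three-way) or a {0,1} column
    with 1 = LSA (two-way sigmoid head)."""
    idx = np.array([scheme.class_index(lab) for lab in labels])
    if scheme.mode == "two_way":
        return (idx == 0).astype(float)[:, None]
    T = np.zeros((len(idx), scheme.n_classes))
    T[np.arange(len(idx)), idx] = 1.0
    return T


def train_network(
    matrix: TechnologyMatrix,
    scheme: ClassScheme,
    partition,
    config: TrainingConfig | None = None,
    rng: np.random.Generator | None = None,
    n_hidden: int = 10,
    params: NetworkParameters | None = None,
    log: list | None = None,
) -> TrainedNetwork:
    """Fit one network on the partition's training subset.

    Iterates LM steps with evidence re-estimation after every accepted step,
    until the epoch budget, a vanishing gradient, a stalled objective, or the
    damping ceiling. Records train/test SSE and the all-assemblage accuracy
    used later as the ensemble weight. Fully reproducible given ``rng``.
    """
    cfg = config or TrainingConfig()
    rng = rng or np.random.default_rng(0)
    labels = scheme.labels_for(matrix.labels3)
    X_all = rescale_inputs(matrix.presence)
    T_all = one_hot_targets(labels, scheme)
    tr = np.asarray(partition.train_indices)
    te = np.asarray(partition.test_indices)
    X, T = X_all[tr], T_all[tr]

    head = "sigmoid" if scheme.mode == "two_way" else "softmax"
    if params is None:
        params = init_network(matrix.n_technologies, n_hidden, head, rng,
                              n_out=1 if head == "sigmoid" else scheme.n_classes)
    pen = _pen_mask(params, cfg)
    include_b = cfg.include_biases_in_penalty

    alpha, beta = cfg.alpha_init, cfg.beta_init
    mu = cfg.mu_init
    gamma = float(params.n_params if include_b else (~params.bias_mask()).sum())
    F = objective(params, (X, T), alpha, beta, include_b)
    if not np.isfinite(F):
        raise FloatingPointError("non-finite objective at initialization")
    epochs = 0
    J = jacobian(params, X)  # reused across the epoch and refreshed on acceptance
    for epoch in range(cfg.max_epochs):
        theta = params.flatten()
        r = _residuals(params, X, T)
        pen_vec = np.ones(params.n_params) if pen is None else pen.astype(float)
        grad = 2.0 * (beta * (J.T @ r) + alpha * pen_vec * theta)
        if np.abs(grad).max() <= cfg.grad_tol:
            break
        accepted = False
        while mu <= cfg.mu_max:
            delta = lm_update(J, r, theta, mu, alpha, beta, pen)
            candidate = params.with_flat(theta + delta)
            F_new = objective(candidate, (X, T), alpha, beta, include_b)
            if np.isfinite(F_new) and F_new < F:
                params = candidate
                mu = max(mu * cfg.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_increase
        epochs = epoch + 1
        if not accepted:
            break  # damping ceiling: converged as far as LM can go
        # evidence re-estimation at the accepted parameters; this Jacobian
        # also serves the next epoch's step
        J = jacobian(params, X)
        e_d = data_error(params, X, T)
        e_w = weight_error(params, include_b)
        J_e = J if pen is None else J[:, pen]
        a_target, b_target, gamma = evidence_quantities(
            J_e, e_d, e_w, alpha, beta, cfg.alpha_max, cfg.beta_max
        )
        rho = cfg.evidence_damping
        alpha = (1.0 - rho) * alpha + rho * a_target
        beta = (1.0 - rho) * beta + rho * b_target
        F_prev, F = F, objective(params, (X, T), alpha, beta, include_b)
        if not np.isfinite(F):
            raise FloatingPointError("non-finite objective during training")
        if log is not None:
            log.append(
                {"epoch": epochs, "F": F, "E_D": e_d, "E_W": e_w,
                 "alpha": alpha, "beta": beta, "gamma": gamma, "mu": mu,
                 "accepted": accepted}
            )
        if abs(F_prev - F_new) <= cfg.objective_tol * max(1.0, abs(F_prev)):
            break

    probs = class_probabilities(params, X_all)
    predicted = probs.argmax(axis=1)
    truth = np.array([scheme.class_index(lab) for lab in labels])
    return TrainedNetwork(
        params=params,
        partition=partition,
        train_sse=data_error(params, X, T),
        test_sse=data_error(params, X_all[te], T_all[te]) if te.size else 0.0,
        accuracy_all=float((predicted == truth).mean()),
        br_state={"alpha": alpha, "beta": beta, "gamma": gamma, "epochs_run": epochs},
    )
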