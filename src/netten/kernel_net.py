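"""Stage 1: per-sample network inference by kernel-weighted penalized regression.

For every target gene l and every sample alpha, the varying coefficient
beta_jl(m_alpha) is estimated by minimizing

    1/2 sum_i w_i(alpha) * (y_il - beta_0 - sum_j beta_jl x_ij)^2 + P(beta),

where the weights come from a Gaussian kernel on the scalar modulator,

    w_i(alpha) = exp{ -(m_i - m_alpha)^2 / b },

so that only samples whose modulator is close to the target sample's inform
the fit. P is a recursive (adaptive) elastic net: the first round applies a
standard elastic-net penalty lambda * (alpha*|beta|_1 + (1-alpha)/2*|beta|_2^2)
and each subsequent round re-fits with per-coefficient weights
1/(|beta_prev| + delta), which de-biases large coefficients while keeping
noise coefficients at exactly zero. Stacking the fits over targets and
samples yields the NetworkTensor consumed by stage 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet

from .datasets import ExpressionDataset, NetworkTensor
from .exceptions import DegenerateFitError, InvalidArgumentError


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian kernel on the modulator; ``bandwidth`` is the denominator b."""

    bandwidth: float = 0.2
    bandwidth_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise InvalidArgumentError("bandwidth must be positive")


@dataclass(frozen=True)
class PenaltySpec:
    """Recursive elastic-net penalty configuration.

    ``lam`` is the overall strength on the weighted-least-squares scale; the
    string ``"auto"`` resolves per fit to ``lam_ratio`` times the smallest
    penalty that zeroes every coefficient. ``alpha`` is the L1/L2 mixing
    (1 = lasso). ``recursion_steps`` counts adaptive re-weighting rounds
    (1 = plain elastic net); ``weight_floor`` guards the adaptive division.
    """

    lam: float | str = "auto"
    alpha: float = 0.9
    recursion_steps: int = 2
    weight_floor: float = 1e-4
    lam_ratio: float = 0.05

    def __post_init__(self):
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise InvalidArgumentError("lam must be a number or 'auto'")
        elif self.lam < 0:
            raise InvalidArgumentError("lam must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgumentError("alpha must lie in [0, 1]")
        if self.recursion_steps < 1:
            raise InvalidArgumentError("recursion_steps must be >= 1")
        if self.weight_floor <= 0:
            raise InvalidArgumentError("weight_floor must be positive")


def gaussian_kernel_weights(m: np.ndarray, m_alpha: float, b: float) -> np.ndarray:
    """Kernel weights w_i = exp{-(m_i - m_alpha)^2 / b} grouping similar samples."""
    if b <= 0:
        raise InvalidArgumentError("bandwidth must be positive")
    m = np.asarray(m, dtype=float)
    return np.exp(-((m - m_alpha) ** 2) / b)


def _weighted_standardize(y, X, w):
    """Weighted centering of y and weighted center+unit-scale of X columns.

    Returns sqrt-weighted design/response so an unweighted solver minimizes
    the weighted objective, plus the statistics needed to map back.
    """
    sw = w.sum()
    xm = (w @ X) / sw
    ym = float(w @ y) / sw
    Xc = X - xm
    xs = np.sqrt((w @ (Xc**2)) / sw)
    xs[xs == 0] = 1.0  # constant columns get scale 1 -> coefficient stays 0
    root = np.sqrt(w)
    Xt = root[:, None] * (Xc / xs)
    yt = root * (y - ym)
    return yt, Xt, ym, xm, xs


def max_penalty(y: np.ndarray, X: np.ndarray, w: np.ndarray, alpha: float = 0.9) -> float:
    """Smallest lambda at which the weighted elastic net zeroes all coefficients."""
    yt, Xt, *_ = _weighted_standardize(np.asarray(y, float), np.asarray(X, float),
                                       np.asarray(w, float))
    corr = np.abs(Xt.T @ yt)
    return float(corr.max() / max(alpha, 1e-12))


def _resolve_lambda(yt, Xt, penalty: PenaltySpec) -> float:
    if penalty.lam != "auto":
        return float(penalty.lam)
    corr = np.abs(Xt.T @ yt)
    lam_max = float(corr.max()) / max(penalty.alpha, 1e-12)
    return penalty.lam_ratio * lam_max


def _enet(yt, Xt, lam, alpha, n):
    # sklearn's objective is 1/(2n)*||y-Xb||^2 + a*(rho*|b|_1 + (1-rho)/2*|b|_2^2),
    # so a = lam/n reproduces 1/2*||.||^2 + lam*P exactly.
    if lam == 0:
        coef, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        return coef
    model = ElasticNet(
        alpha=lam / n,
        l1_ratio=alpha,
        fit_intercept=False,
        max_iter=10_000,
        tol=1e-8,
        copy_X=False,
    )
    model.fit(Xt, yt)
    return model.coef_


def fit_target_sample(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, penalty: PenaltySpec = PenaltySpec()
) -> tuple[np.ndarray, float]:
    """Kernel-weighted recursive elastic-net fit for one (target, sample) pair.

    Returns ``(coefficients, intercept)`` on the original expression scale.
    Coefficients excluded by the penalty are exactly zero; the intercept is
    unpenalized.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.shape[0] != y.shape[0] or w.shape[0] != y.shape[0]:
        raise InvalidArgumentError("y, X and w disagree on sample count")
    if np.any(w < 0):
        raise InvalidArgumentError("weights must be nonnegative")
    if not np.any(w > 0):
        raise DegenerateFitError("all kernel weights are zero")

    n = y.shape[0]
    yt, Xt, ym, xm, xs = _weighted_standardize(y, X, w)
    lam = _resolve_lambda(yt, Xt, penalty)

    coef_std = _enet(yt, Xt, lam, penalty.alpha, n)
    for _ in range(penalty.recursion_steps - 1):
        if lam == 0:
            break
        u = np.abs(coef_std) + penalty.weight_floor
        coef_std = _enet(yt, Xt * u, lam, penalty.alpha, n) * u

    coef = coef_std / xs
    intercept = ym - float(xm @ coef)
    return coef, intercept


def select_hyperparameters(
    y: np.ndarray,
    X: np.ndarray,
    m: np.ndarray,
    m_alpha: float,
    bandwidth_grid,
    lambda_grid,
    alpha_grid=(0.9,),
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (bandwidth, lambda, alpha) by kernel-weighted K-fold cross-validation.

    The CV error of a grid point is the kernel-weighted squared prediction
    error summed over held-out folds; ties keep the first grid point in
    iteration order (bandwidth-major). Fold assignment is a seeded shuffle.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    m = np.asarray(m, float)
    n = y.shape[0]
    if not len(bandwidth_grid) or not len(lambda_grid) or not len(alpha_grid):
        raise InvalidArgumentError("hyperparameter grids must be nonempty")
    if n < n_folds:
        raise InvalidArgumentError(f"need at least {n_folds} samples for {n_folds}-fold CV")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[k::n_folds] for k in range(n_folds)]

    best = None
    best_err = np.inf
    seen = set()
    for b, lam, a in itertools.product(bandwidth_grid, lambda_grid, alpha_grid):
        if (b, lam, a) in seen:  # duplicate grid entries: keep first occurrence
            continue
        seen.add((b, lam, a))
        w = gaussian_kernel_weights(m, m_alpha, b)
        err = 0.0
        spec = PenaltySpec(lam=lam, alpha=a)
        for test_idx in folds:
            train = np.setdiff1d(np.arange(n), test_idx)
            if not np.any(w[train] > 0):
                err = np.inf
                break
            coef, b0 = fit_target_sample(y[train], X[train], w[train], spec)
            resid = y[test_idx] - b0 - X[test_idx] @ coef
            err += float(w[test_idx] @ resid**2)
        if err < best_err:
            best_err = err
            best = (float(b), float(lam), float(a))
    return best


def build_network_tensor(
    data: ExpressionDataset,
    kernel: KernelConfig = KernelConfig(),
    penalty: PenaltySpec = PenaltySpec(),
) -> NetworkTensor:
    """Fit every (target, sample) regression and stack into a NetworkTensor.

    A gene appearing on both axes never regresses on itself: its self-edge is
    structurally zero. Errors in individual fits propagate (fail-fast).
    """
    regulators = data.regulator_ids
    targets = data.target_ids
    m = data.modulator
    n = data.n_samples
    Xall = data.regulator_matrix()  # n x q
    Yall = data.target_matrix()  # n x p

    q, p = len(regulators), len(targets)
    coeffs = np.zeros((p, q, n))
    intercepts = np.zeros((p, n))
    reg_pos = {g: j for j, g in enumerate(regulators)}

    # kernel weights depend only on the sample, not the target: compute once
    weights = [gaussian_kernel_weights(m, m[a], kernel.bandwidth) for a in range(n)]

    for l, tgt in enumerate(targets):
        self_j = reg_pos.get(tgt)
        if self_j is None:
            cols = np.arange(q)
            Xl = Xall
        else:
            cols = np.array([j for j in range(q) if j != self_j])
            Xl = Xall[:, cols]
        y = Yall[:, l]
        for a in range(n):
            coef, b0 = fit_target_sample(y, Xl, weights[a], penalty)
            coeffs[l, cols, a] = coef
            intercepts[l, a] = b0

    return NetworkTensor(
        coefficients=coeffs,
        intercepts=intercepts,
        target_ids=list(targets),
        regulator_ids=list(regulators),
        sample_ids=data.sample_ids,
        modulator=m.copy(),
    )
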