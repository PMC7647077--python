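"""Stage 2: supervised orthonormal tensor subspace learning.

Each sample's network is a second-order tensor X_i (targets x regulators).
The learner estimates mode-wise projection matrices C^(1) (I1 x J1) and
C^(2) (I2 x J2) with orthonormal columns, projecting every network onto a
low-dimensional subspace

    Xbar_i = C^(1)T X_i C^(2),

while simultaneously predicting a per-sample response y_i from the projected
network through a small head f(Xbar_i, theta). The joint objective balances
prediction against reconstruction fidelity,

    O = (1/n) sum_i { L(y_i, yhat_i) + gamma * ||X_i - C^(1) Xbar_i C^(2)T||_F^2 },
    subject to C^(k)T C^(k) = I,

so the subspace retains as much network variance as possible while remaining
predictive. Orthonormality is enforced through the polar factor of a latent
matrix Z^(k): with thin SVD Z = P S Q^T, the projection is C = P Q^T, the
closest orthonormal matrix to Z in Frobenius norm. The optimizer alternates
head updates with line-searched gradient steps on Z^(k), re-orthonormalizing
after every step, which keeps the objective history non-increasing.

Interpretation attaches a multi-linear surrogate yhat'_i = <g1 o g2, Xbar_i> + b
fitted to the head's own predictions; contracting each sample's network with
the surrogate factor of the other mode yields per-sample score vectors
u_i^(k) whose principal components are the "crucial components" — the axes of
network variation that matter for the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    InvalidStateError,
    OptimizationFailureError,
)

_ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# prediction heads
# ---------------------------------------------------------------------------


class LinearHead:
    """yhat = w . vec(Xbar) + b."""

    def __init__(self, dim: int):
        self.dim = dim
        self.w = np.zeros(dim)
        self.b = 0.0

    def forward(self, F: np.ndarray) -> np.ndarray:
        return F @ self.w + self.b

    def grad_input(self, F: np.ndarray) -> np.ndarray:
        """d yhat_i / d x_i for each row of F; shape (n, dim)."""
        return np.broadcast_to(self.w, F.shape)

    def exact_update(self, F: np.ndarray, y: np.ndarray) -> None:
        """Closed-form least-squares update (gradient set to zero)."""
        design = np.column_stack([F, np.ones(len(F))])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.w = sol[:-1]
        self.b = float(sol[-1])

    def get_params(self):
        return np.concatenate([self.w, [self.b]])

    def set_params(self, theta):
        self.w = theta[:-1].copy()
        self.b = float(theta[-1])

    def grad_params(self, F: np.ndarray, dLdf: np.ndarray) -> np.ndarray:
        return np.concatenate([F.T @ dLdf, [dLdf.sum()]])


class MLPHead:
    """One-hidden-layer tanh network: yhat = w2 . tanh(W1 x + b1) + b2."""

    def __init__(self, dim: int, width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.width = width
        scale = 1.0 / np.sqrt(max(dim, 1))
        self.W1 = rng.normal(0.0, scale, size=(width, dim))
        self.b1 = np.zeros(width)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(width), size=width)
        self.b2 = 0.0

    def _hidden(self, F):
        return np.tanh(F @ self.W1.T + self.b1)

    def forward(self, F: np.ndarray) -> np.ndarray:
        return self._hidden(F) @ self.w2 + self.b2

    def grad_input(self, F: np.ndarray) -> np.ndarray:
        H = self._hidden(F)
        return ((1.0 - H**2) * self.w2) @ self.W1

    def get_params(self):
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    def set_params(self, theta):
        k = self.width * self.dim
        self.W1 = theta[:k].reshape(self.width, self.dim).copy()
        self.b1 = theta[k : k + self.width].copy()
        self.w2 = theta[k + self.width : k + 2 * self.width].copy()
        self.b2 = float(theta[-1])

    def grad_params(self, F: np.ndarray, dLdf: np.ndarray) -> np.ndarray:
        H = self._hidden(F)
        dH = dLdf[:, None] * self.w2
        dZ = dH * (1.0 - H**2)
        gW1 = dZ.T @ F
        gb1 = dZ.sum(axis=0)
        gw2 = H.T @ dLdf
        gb2 = dLdf.sum()
        return np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])


def _loss_value(kind: str, y: np.ndarray, f: np.ndarray) -> np.ndarray:
    if kind == "squared":
        return (y - f) ** 2
    # logistic: y in {0,1}, f is the raw score
    return np.logaddexp(0.0, f) - y * f


def _loss_grad(kind: str, y: np.ndarray, f: np.ndarray) -> np.ndarray:
    if kind == "squared":
        return -2.0 * (y - f)
    return expit(f) - y


# ---------------------------------------------------------------------------
# core tensor-subspace operations
# ---------------------------------------------------------------------------


def project(X: np.ndarray, C_list) -> np.ndarray:
    """Mode-wise projection Xbar = C1^T X C2 of a single sample network."""
    C1, C2 = C_list
    X = np.asarray(X, dtype=float)
    if X.shape != (C1.shape[0], C2.shape[0]):
        raise InvalidArgumentError(
            f"sample shape {X.shape} incompatible with projections "
            f"({C1.shape[0]}, {C2.shape[0]})"
        )
    return C1.T @ X @ C2


def reconstruction_error(X: np.ndarray, C_list) -> float:
    """Squared Frobenius distance ||X - C1 (C1^T X C2) C2^T||_F^2."""
    C1, C2 = C_list
    Xbar = project(X, C_list)
    R = X - C1 @ Xbar @ C2.T
    return float(np.sum(R * R))


def orthonormalize(Z: np.ndarray) -> np.ndarray:
    """Closest orthonormal matrix to Z (polar factor): SVD Z = P S Q^T, C = P Q^T."""
    Z = np.asarray(Z, dtype=float)
    P, s, Qt = np.linalg.svd(Z, full_matrices=False)
    if s[0] == 0 or s[-1] < 1e-12 * s[0]:
        collapsed = int(np.sum(s < 1e-12 * max(s[0], 1e-300)))
        raise DegenerateInputError(
            f"latent matrix is rank-deficient: {collapsed} of {Z.shape[1]} "
            "columns collapse"
        )
    return P @ Qt


def _check_orthonormal(C_list):
    for k, C in enumerate(C_list, start=1):
        gap = np.abs(C.T @ C - np.eye(C.shape[1])).max()
        if gap > 1e-6:
            raise InvalidStateError(
                f"projection C^({k}) is not orthonormal (max deviation {gap:.2e})"
            )


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class SubspaceModel:
    """Fitted projections, latents and prediction head, with the fit history."""

    projections: list  # [C1, C2]
    latents: list  # [Z1, Z2]
    head: object
    gamma: float
    loss_kind: str = "squared"
    history: list = field(default_factory=list)
    fitted: bool = False

    @property
    def J(self) -> tuple[int, int]:
        return tuple(C.shape[1] for C in self.projections)

    def features(self, tensors: np.ndarray) -> np.ndarray:
        """Flattened projected networks, one row per sample."""
        C1, C2 = self.projections
        Xbar = np.einsum("ab,nac,cd->nbd", C1, tensors, C2)
        return Xbar.reshape(len(tensors), -1)


@dataclass
class SurrogateModel:
    """Rank-one multi-linear read-out mimicking the head's predictions."""

    factors: list  # [g1, g2]
    bias: float
    fit_gap: float


@dataclass
class ComponentScores:
    """Per-sample projected score vectors and their principal components."""

    vectors: np.ndarray  # n x J_k raw u_i
    matrix: np.ndarray  # J_k x n, unit-norm columns (zero vectors kept zero)
    pc_scores: np.ndarray  # n x r
    loadings: np.ndarray  # r x J_k
    variance_explained: np.ndarray  # r, non-increasing, sums to 1


# ---------------------------------------------------------------------------
# prediction / objective
# ---------------------------------------------------------------------------


def predict(X: np.ndarray, model: SubspaceModel) -> float | np.ndarray:
    """Head output for one sample network (or a stack of them)."""
    if not model.fitted:
        raise InvalidStateError("model is not fitted")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    tensors = X[None] if single else X
    f = model.head.forward(model.features(tensors))
    if model.loss_kind == "logistic":
        f = expit(f)
    return float(f[0]) if single else f


def objective(tensors: np.ndarray, y: np.ndarray, model: SubspaceModel) -> float:
    """Mean prediction loss plus gamma times mean reconstruction error."""
    _check_orthonormal(model.projections)
    tensors = np.asarray(tensors, dtype=float)
    y = np.asarray(y, dtype=float)
    C1, C2 = model.projections
    Xbar = np.einsum("ab,nac,cd->nbd", C1, tensors, C2)
    f = model.head.forward(Xbar.reshape(len(tensors), -1))
    loss = _loss_value(model.loss_kind, y, f).sum()
    recon = np.einsum("nij,nij->", tensors, tensors) - np.einsum(
        "nij,nij->", Xbar, Xbar
    )
    # the Frobenius shortcut above is exact because the projections are
    # orthonormal (checked on entry)
    return float((loss + model.gamma * recon) / len(tensors))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _hosvd_init(tensors: np.ndarray, J: tuple[int, int]) -> list[np.ndarray]:
    """Leading mode-wise singular vectors of the mean-centered stack."""
    Xc = tensors - tensors.mean(axis=0)
    n, I1, I2 = Xc.shape
    M1 = np.moveaxis(Xc, 1, 0).reshape(I1, -1)
    M2 = np.moveaxis(Xc, 2, 0).reshape(I2, -1)
    U1, _, _ = np.linalg.svd(M1, full_matrices=False)
    U2, _, _ = np.linalg.svd(M2, full_matrices=False)
    return [np.ascontiguousarray(U1[:, : J[0]]), np.ascontiguousarray(U2[:, : J[1]])]


def _objective_given(tensors, y, C1, C2, head, gamma, loss_kind):
    Xbar = np.einsum("ab,nac,cd->nbd", C1, tensors, C2)
    f = head.forward(Xbar.reshape(len(tensors), -1))
    loss = _loss_value(loss_kind, y, f).sum()
    recon = float(
        np.einsum("nij,nij->", tensors, tensors) - np.einsum("nij,nij->", Xbar, Xbar)
    )
    return (loss + gamma * recon) / len(tensors)


def fit(
    tensors: np.ndarray,
    y: np.ndarray,
    J: tuple[int, int],
    gamma: float = 1.0,
    loss_kind: str = "squared",
    head: str = "mlp",
    head_width: int = 16,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    patience: int = 10,
    lr: float = 0.5,
    head_steps: int = 5,
    callback=None,
) -> SubspaceModel:
    """Jointly learn orthonormal projections and the prediction head.

    Alternates (a) a head update — exact least squares for the linear head
    with squared loss, line-searched gradient steps otherwise — with (b) a
    line-searched gradient step on each latent Z^(k), re-orthonormalized via
    its SVD polar factor after every step. Stops when the relative objective
    change drops below ``tol`` or ``max_iter`` is reached. ``callback`` is
    invoked as ``callback(iteration, model)`` after each iteration.
    """
    tensors = np.ascontiguousarray(tensors, dtype=float)
    y = np.asarray(y, dtype=float)
    n, I1, I2 = tensors.shape
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples")
    if not (1 <= J[0] <= I1 and 1 <= J[1] <= I2):
        raise InvalidArgumentError(f"J={J} incompatible with tensor modes ({I1}, {I2})")
    if gamma < 0:
        raise InvalidArgumentError("gamma must be nonnegative")
    if gamma == 0:
        warnings.warn("gamma=0 drops the reconstruction term; the subspace is "
                      "determined by prediction alone", stacklevel=2)

    Z = _hosvd_init(tensors, J)
    C = [orthonormalize(Zk) for Zk in Z]
    dim = J[0] * J[1]
    head_obj = (
        LinearHead(dim) if head == "linear" else MLPHead(dim, width=head_width, seed=seed)
    )
    if head not in ("linear", "mlp"):
        raise InvalidArgumentError(f"unknown head {head!r}")

    model = SubspaceModel(
        projections=C, latents=Z, head=head_obj, gamma=gamma, loss_kind=loss_kind
    )

    def obj():
        return _objective_given(tensors, y, C[0], C[1], head_obj, gamma, loss_kind)

    def head_update(current):
        if isinstance(head_obj, LinearHead) and loss_kind == "squared":
            F = model.features(tensors)
            old = head_obj.get_params()
            head_obj.exact_update(F, y)
            new_obj = obj()
            if new_obj > current + 1e-12:  # cannot happen for exact LS; guard anyway
                head_obj.set_params(old)
                return current
            return new_obj
        # generic: line-searched full-batch gradient descent on theta
        F = model.features(tensors)
        cur = current
        step = 0.1
        for _ in range(head_steps):
            f = head_obj.forward(F)
            dLdf = _loss_grad(loss_kind, y, f) / n
            g = head_obj.grad_params(F, dLdf)
            theta = head_obj.get_params()
            improved = False
            for _ in range(20):
                head_obj.set_params(theta - step * g)
                new_obj = obj()
                if new_obj <= cur + 1e-15:
                    cur = new_obj
                    step *= 1.5
                    improved = True
                    break
                step *= 0.5
            if not improved:
                head_obj.set_params(theta)
                break
        return cur

    def grad_wrt_C(k):
        """Ambient gradient of the objective with respect to C^(k)."""
        C1, C2 = C
        Xbar = np.einsum("ab,nac,cd->nbd", C1, tensors, C2)
        F = Xbar.reshape(n, -1)
        f = head_obj.forward(F)
        dLdf = _loss_grad(loss_kind, y, f)
        E = (head_obj.grad_input(F) * dLdf[:, None]).reshape(n, J[0], J[1])
        M = E - 2.0 * gamma * Xbar
        if k == 0:
            G = np.einsum("nac,cd,nbd->ab", tensors, C2, M)
        else:
            G = np.einsum("nac,ab,nbd->cd", tensors, C1, M)
        return G / n

    lrs = [lr, lr]
    current = obj()
    model.history.append(current)
    increases = 0
    for it in range(max_iter):
        prev = current
        current = head_update(current)
        for k in (0, 1):
            G = grad_wrt_C(k)
            gnorm = np.linalg.norm(G)
            if gnorm == 0:
                continue
            accepted = False
            for _ in range(30):
                Z_new = C[k] - lrs[k] * G
                try:
                    C_new = orthonormalize(Z_new)
                except DegenerateInputError:
                    lrs[k] *= 0.5
                    continue
                old_C = C[k]
                C[k] = C_new
                new_obj = obj()
                if new_obj <= current + 1e-15:
                    Z[k] = Z_new
                    current = new_obj
                    lrs[k] = min(lrs[k] * 1.3, 1e3)
                    accepted = True
                    break
                C[k] = old_C
                lrs[k] *= 0.5
            if not accepted:
                lrs[k] = max(lrs[k], 1e-8)
        model.history.append(current)
        if callback is not None:
            callback(it, model)
        if current > prev + 1e-9 * max(abs(prev), 1.0):
            increases += 1
            if increases >= patience:
                raise OptimizationFailureError(
                    f"objective increased for {patience} consecutive iterations "
                    f"(last value {current:.6g})",
                    history=model.history,
                )
        else:
            increases = 0
        if abs(prev - current) < tol * max(abs(prev), 1e-12):
            break

    model.fitted = True
    return model


# ---------------------------------------------------------------------------
# surrogate and component extraction
# ---------------------------------------------------------------------------


def fit_surrogate(model: SubspaceModel, tensors: np.ndarray, max_iter: int = 200,
                  tol: float = 1e-12) -> SurrogateModel:
    """Rank-one multi-linear approximation of the head, by alternating LS.

    Minimizes sum_i (yhat_i - (g1^T Xbar_i g2 + b))^2 over g1, g2, b; each
    sub-problem is an ordinary least squares. Initialization is the
    deterministic uniform vector on mode 2.
    """
    if not model.fitted:
        raise InvalidStateError("model is not fitted")
    tensors = np.asarray(tensors, dtype=float)
    C1, C2 = model.projections
    Xbar = np.einsum("ab,nac,cd->nbd", C1, tensors, C2)
    n = len(tensors)
    yhat = model.head.forward(Xbar.reshape(n, -1))
    if model.loss_kind == "logistic":
        yhat = expit(yhat)

    J1, J2 = model.J
    g2 = np.ones(J2) / np.sqrt(J2)
    g1 = np.zeros(J1)
    b = float(np.mean(yhat))
    prev_gap = np.inf
    for _ in range(max_iter):
        Zf = Xbar @ g2  # n x J1
        sol, *_ = np.linalg.lstsq(np.column_stack([Zf, np.ones(n)]), yhat, rcond=None)
        g1, b = sol[:-1], float(sol[-1])
        Vf = np.einsum("nij,i->nj", Xbar, g1)  # n x J2
        sol, *_ = np.linalg.lstsq(np.column_stack([Vf, np.ones(n)]), yhat, rcond=None)
        g2, b = sol[:-1], float(sol[-1])
        pred = np.einsum("i,nij,j->n", g1, Xbar, g2) + b
        gap = float(np.sum((yhat - pred) ** 2))
        if prev_gap - gap < tol * max(prev_gap, 1e-300):
            prev_gap = gap
            break
        prev_gap = gap
    return SurrogateModel(factors=[g1, g2], bias=b, fit_gap=prev_gap)


def component_scores(
    tensors: np.ndarray, model: SubspaceModel, surrogate: SurrogateModel, k: int
) -> ComponentScores:
    """Crucial-component extraction for mode ``k`` (1 or 2).

    Each sample network is contracted with the projection and surrogate
    factor of the *other* mode, then projected onto mode k's subspace:
    for k=2, u_i = C2^T X_i^T C1 g1. The unit-normalized u_i form the columns
    of U^(k); a PCA across samples of these vectors yields the component
    scores, ordered by decreasing variance with the sign fixed so each
    component's largest-magnitude loading is positive.
    """
    if not model.fitted:
        raise InvalidStateError("model is not fitted")
    if k not in (1, 2):
        raise InvalidArgumentError("mode index k must be 1 or 2")
    tensors = np.asarray(tensors, dtype=float)
    C1, C2 = model.projections
    g1, g2 = surrogate.factors
    if k == 2:
        # u_i = C2^T (X_i^T C1 g1)
        U_raw = np.einsum("nij,i->nj", tensors, C1 @ g1) @ C2
    else:
        # u_i = C1^T (X_i C2 g2)
        U_raw = np.einsum("nij,j->ni", tensors, C2 @ g2) @ C1

    norms = np.linalg.norm(U_raw, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = (U_raw / safe[:, None]).T  # J_k x n, zero columns stay zero

    D = U.T  # samples as observations
    Dc = D - D.mean(axis=0)
    Us, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        var = np.zeros(len(s))
        var[0] = 1.0  # degenerate: all mass formally on the first component
        scores = np.zeros_like(Us)
        loadings = Vt
    else:
        var = s**2 / total
        scores = Us * s
        loadings = Vt.copy()
        for r in range(loadings.shape[0]):
            jmax = int(np.argmax(np.abs(loadings[r])))
            if loadings[r, jmax] < 0:
                loadings[r] *= -1
                scores[:, r] *= -1
    return ComponentScores(
        vectors=U_raw,
        matrix=U,
        pc_scores=scores,
        loadings=loadings,
        variance_explained=var,
    )
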