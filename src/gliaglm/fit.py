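"""MAP estimation of the per-cell model parameters.

Every receiver cell is fitted independently: the log posterior decomposes
additively over cells, so the full-network MAP estimate is the collection of
per-cell optima.

* neurons: penalized logistic regression, maximized with L-BFGS-B (the
  problem is strictly concave once any quadratic penalty is present, so the
  optimum is unique);
* glial cells: penalized least squares with a closed-form normal-equation
  solution; the noise variance is the mean squared training residual (its
  MLE under the flat prior);
* positivity-constrained glial fits: the same quadratic objective under
  w_ng >= 0, solved exactly with a primal active-set loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.optimize
import scipy.sparse

from .model import (
    GliaParams,
    HistoryWindows,
    NetworkStructure,
    NeuronParams,
    ObservationSeries,
    PriorConfig,
    penalty_matrix,
)

__all__ = ["DesignMatrix", "FitResult", "build_design", "fit_neuron",
           "fit_glia", "fit_glia_positive"]

GRAD_TOL = 1e-6
MAX_ITER = 500


@dataclass
class DesignMatrix:
    """Materialised lagged-feature matrix for one receiver cell.

    ``X`` has one row per usable bin (t >= burn-in) and columns
    ``[intercept | permitted lagged features]``; ``column_map`` names every
    column as (sender, block, lag), with the intercept mapped to
    (-1, "bias", 0).  Feature order is: block (NN then GN for neurons,
    NG then GG for glia), sender ascending, lag ascending.
    """

    X: np.ndarray
    y: np.ndarray
    column_map: list[tuple[int, str, int]]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class FitResult:
    params: Union[NeuronParams, GliaParams]
    converged: bool
    final_grad_norm: float
    objective: float


def _lagged(x: np.ndarray, window: int, burn_in: int) -> np.ndarray:
    """(T-burn_in, n*window) matrix; column (sender, lag) = x[t-lag, sender]."""
    T, n = x.shape
    out = np.empty((T - burn_in, n * window), dtype=float)
    for tau in range(1, window + 1):
        out[:, tau - 1 :: window] = x[burn_in - tau : T - tau]
    return out


def build_design(
    obs: ObservationSeries,
    receiver: tuple[str, int],
    windows: HistoryWindows,
    structure: NetworkStructure,
) -> DesignMatrix:
    """Build the design matrix for one receiver under a network structure.

    ``receiver`` is ("neuron", i) or ("glia", j).  Only structure-permitted
    senders contribute columns.
    """
    kind, idx = receiver
    burn = windows.burn_in
    if obs.T <= burn + 1:
        raise ValueError(
            f"series of {obs.T} bins is too short for a burn-in of {burn}"
        )
    spk = obs.spikes.astype(float)
    if kind == "neuron":
        blocks = [("NN", spk, windows.t_nn, structure.mask_nn[idx]),
                  ("GN", obs.glia, windows.t_gn, structure.mask_gn[idx])]
        y = spk[burn:, idx]
    elif kind == "glia":
        blocks = [("NG", spk, windows.t_ng, structure.mask_ng[idx]),
                  ("GG", obs.glia, windows.t_gg, structure.mask_gg[idx])]
        y = obs.glia[burn:, idx]
    else:
        raise ValueError(f"receiver kind must be 'neuron' or 'glia', got {kind!r}")

    cols = [np.ones((obs.T - burn, 1))]
    cmap: list[tuple[int, str, int]] = [(-1, "bias", 0)]
    for block, data, window, mask_row in blocks:
        lagged = _lagged(data, window, burn)
        for sender in np.flatnonzero(mask_row):
            cols.append(lagged[:, sender * window : (sender + 1) * window])
            cmap.extend((int(sender), block, tau) for tau in range(1, window + 1))
    return DesignMatrix(np.hstack(cols), y, cmap)


def _penalty_block_diag(
    column_map: Sequence[tuple[int, str, int]], prior: PriorConfig
) -> np.ndarray:
    """Block-diagonal penalty over design columns (intercept unpenalized)."""
    p = len(column_map)
    P = np.zeros((p, p))
    start = 0
    while start < p:
        sender, block, _ = column_map[start]
        if block == "bias":
            start += 1
            continue
        end = start
        while end < p and column_map[end][:2] == (sender, block):
            end += 1
        lam, eta = prior.of_block(block)
        P[start:end, start:end] = penalty_matrix(end - start, lam, eta)
        start = end
    return P


# ---------------------------------------------------------------------------
# neurons: penalized logistic regression
# ---------------------------------------------------------------------------

class HybridDesign:
    """Column-partitioned design: [dense columns | sparse columns].

    Spike-history columns are extremely sparse at sub-hertz firing rates,
    so keeping them in CSR while the intercept and glial columns stay dense
    makes the logistic fits an order of magnitude cheaper.
    """

    def __init__(self, dense: np.ndarray, sparse: "scipy.sparse.spmatrix") -> None:
        self.dense = np.ascontiguousarray(dense)
        self.sparse = scipy.sparse.csr_matrix(sparse)
        if self.dense.shape[0] != self.sparse.shape[0]:
            raise ValueError("dense and sparse parts must share rows")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.dense.shape[0], self.dense.shape[1] + self.sparse.shape[1])

    @property
    def n_dense(self) -> int:
        return self.dense.shape[1]

    def matvec(self, beta: np.ndarray) -> np.ndarray:
        d = self.n_dense
        return self.dense @ beta[:d] + self.sparse @ beta[d:]

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        return np.concatenate([self.dense.T @ v, self.sparse.T @ v])

    def hessian_weighted(self, w: np.ndarray) -> np.ndarray:
        """Dense X' diag(w) X."""
        d, s = self.n_dense, self.sparse.shape[1]
        Dw = self.dense * w[:, None]
        H = np.empty((d + s, d + s))
        H[:d, :d] = Dw.T @ self.dense
        Sw = self.sparse.multiply(w[:, None]).tocsr()
        H[:d, d:] = self.dense.T @ Sw
        H[d:, :d] = H[:d, d:].T
        H[d:, d:] = (self.sparse.T @ Sw).toarray()
        return H

    def take_rows(self, keep: list[tuple[int, int]]) -> "HybridDesign":
        """Row restriction to a union of contiguous [start, stop) ranges."""
        dense = np.vstack([self.dense[a:b] for a, b in keep])
        sparse = scipy.sparse.vstack([self.sparse[a:b] for a, b in keep],
                                     format="csr")
        return HybridDesign(dense, sparse)


def _as_ops(X):
    if isinstance(X, HybridDesign):
        return X.matvec, X.rmatvec, X.hessian_weighted
    Xa = np.asarray(X, dtype=float)
    return (
        lambda beta: Xa @ beta,
        lambda v: Xa.T @ v,
        lambda w: (Xa * w[:, None]).T @ Xa,
    )


def fit_logistic_map(
    X,
    y: np.ndarray,
    P: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
    method: str = "newton",
) -> tuple[np.ndarray, bool, float, float]:
    """Maximize sum(y*a - log(1+e^a)) - beta'P beta with a = X @ beta.

    ``X`` is a dense matrix or a :class:`HybridDesign`.  The default backend
    is damped Newton (IRLS with an Armijo backtracking line search), which
    converges quadratically on this strictly concave problem; ``method=
    "lbfgs"`` runs scipy's L-BFGS-B on the identical objective and serves as
    an independent optimizer route.  The convergence certificate is the
    max-norm of the gradient below a threshold that scales with the number
    of rows (gradient entries are sums over observations).  Returns
    (beta, converged, grad_norm, objective).
    """
    matvec, rmatvec, hessw = _as_ops(X)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    tol_scaled = tol * (1.0 + 1e-3 * n)

    def negobj_grad(b: np.ndarray) -> tuple[float, np.ndarray]:
        a = matvec(b)
        ll = float(np.sum(y * a - np.logaddexp(0.0, a)))
        pen = float(b @ P @ b)
        mu = 0.5 * (1.0 + np.tanh(0.5 * a))
        grad = rmatvec(y - mu) - 2.0 * (P @ b)
        return -(ll - pen), -grad

    if method == "lbfgs":
        res = scipy.optimize.minimize(
            negobj_grad, beta, jac=True, method="L-BFGS-B",
            options={"gtol": tol_scaled / 100.0, "ftol": 1e-15,
                     "maxiter": max_iter, "maxcor": 20},
        )
        beta = res.x
        f, g = negobj_grad(beta)
    elif method == "newton":
        f, g = negobj_grad(beta)
        for _ in range(max_iter):
            gnorm = float(np.max(np.abs(g)))
            if gnorm < tol_scaled / 100.0:
                break
            a = matvec(beta)
            mu = 0.5 * (1.0 + np.tanh(0.5 * a))
            H = hessw(np.maximum(mu * (1.0 - mu), 1e-12)) + 2.0 * P
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = np.linalg.solve(H, -g)
            scale, improved = 1.0, False
            while scale > 1e-4:
                f_new, g_new = negobj_grad(beta + scale * step)
                # Armijo (g @ step < 0 for a PD Hessian); near the optimum
                # the decrease sits inside fp noise of f, so a full step
                # that halves the gradient norm is also accepted
                if (f_new <= f + 1e-4 * scale * float(g @ step)
                        or f_new < f
                        or (scale == 1.0
                            and float(np.max(np.abs(g_new))) < 0.5 * gnorm)):
                    beta = beta + scale * step
                    f, g, improved = f_new, g_new, True
                    break
                scale *= 0.5
            if not improved:
                break  # no descent within fp precision: numerical optimum
    else:
        raise ValueError(f"unknown optimizer backend {method!r}")
    grad_norm = float(np.max(np.abs(g)))
    return beta, grad_norm < tol_scaled, grad_norm, -f


def _unpack_neuron(
    beta: np.ndarray,
    column_map: Sequence[tuple[int, str, int]],
    windows: HistoryWindows,
    structure: NetworkStructure,
    i: int,
) -> NeuronParams:
    w_nn = np.zeros((structure.mask_nn.shape[1], windows.t_nn))
    w_gn = np.zeros((structure.mask_gn.shape[1], windows.t_gn))
    bias = 0.0
    for val, (sender, block, lag) in zip(beta, column_map):
        if block == "bias":
            bias = float(val)
        elif block == "NN":
            w_nn[sender, lag - 1] = val
        elif block == "GN":
            w_gn[sender, lag - 1] = val
    return NeuronParams(bias=bias, w_nn=w_nn, w_gn=w_gn)


def fit_neuron(
    obs: ObservationSeries,
    i: int,
    windows: HistoryWindows,
    structure: NetworkStructure,
    prior: PriorConfig,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
    rows: Optional[np.ndarray] = None,
) -> FitResult:
    """MAP fit of neuron ``i``; ``rows`` optionally restricts training bins."""
    design = build_design(obs, ("neuron", i), windows, structure)
    X, y = design.X, design.y
    if rows is not None:
        X, y = X[rows], y[rows]
    P = _penalty_block_diag(design.column_map, prior)
    beta, conv, gnorm, obj = fit_logistic_map(X, y, P, tol=tol, max_iter=max_iter)
    params = _unpack_neuron(beta, design.column_map, windows, structure, i)
    return FitResult(params, conv, gnorm, obj)


# ---------------------------------------------------------------------------
# glia: penalized least squares (closed form)
# ---------------------------------------------------------------------------

def solve_ridge(
    XtX: np.ndarray, Xty: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """Solve (X'X + 2P) theta = X'y.

    This is the unique minimizer of the glial quadratic cost
    0.5*||y - X theta||^2 + theta' P theta (the penalty weights squared
    residuals directly; glial traces are z-scored, so the residual scale is
    O(1) -- see docs/methods.md for the convention).
    """
    A = XtX + 2.0 * P
    try:
        return np.linalg.solve(A, Xty)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - λ>0 prevents this
        raise np.linalg.LinAlgError(
            "singular normal equations; use a positive sparseness penalty"
        ) from exc


def _unpack_glia(
    theta: np.ndarray,
    column_map: Sequence[tuple[int, str, int]],
    windows: HistoryWindows,
    structure: NetworkStructure,
    noise_var: float,
) -> GliaParams:
    w_ng = np.zeros((structure.mask_ng.shape[1], windows.t_ng))
    w_gg = np.zeros((structure.mask_gg.shape[1], windows.t_gg))
    bias = 0.0
    for val, (sender, block, lag) in zip(theta, column_map):
        if block == "bias":
            bias = float(val)
        elif block == "NG":
            w_ng[sender, lag - 1] = val
        elif block == "GG":
            w_gg[sender, lag - 1] = val
    return GliaParams(bias=bias, noise_var=noise_var, w_ng=w_ng, w_gg=w_gg)


def _glia_objective(
    X: np.ndarray, y: np.ndarray, P: np.ndarray, theta: np.ndarray
) -> float:
    """Negated glial quadratic cost (larger is better, 0 at a perfect fit)."""
    r = y - X @ theta
    return -(0.5 * float(r @ r) + float(theta @ P @ theta))


def fit_glia(
    obs: ObservationSeries,
    j: int,
    windows: HistoryWindows,
    structure: NetworkStructure,
    prior: PriorConfig,
    rows: Optional[np.ndarray] = None,
) -> FitResult:
    """Closed-form MAP fit of glial cell ``j`` (penalized least squares)."""
    design = build_design(obs, ("glia", j), windows, structure)
    X, y = design.X, design.y
    if rows is not None:
        X, y = X[rows], y[rows]
    P = _penalty_block_diag(design.column_map, prior)
    theta = solve_ridge(X.T @ X, X.T @ y, P)
    r = y - X @ theta
    noise_var = float(np.mean(r * r))
    params = _unpack_glia(theta, design.column_map, windows, structure, noise_var)
    grad = -(X.T @ r) + 2.0 * (P @ theta)
    return FitResult(params, True, float(np.max(np.abs(grad))),
                     _glia_objective(X, y, P, theta))


# ---------------------------------------------------------------------------
# glia with positivity constraints on neuron -> glia weights
# ---------------------------------------------------------------------------

def solve_bound_qp(
    A: np.ndarray,
    b: np.ndarray,
    nonneg: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Minimize 0.5 x'Ax - b'x subject to x[nonneg] >= 0 (A positive definite).

    Primal active-set method: finitely convergent for a strictly convex QP
    with simple bounds.
    """
    n = len(b)
    nonneg = np.asarray(nonneg, bool)
    active = np.zeros(n, bool)
    for _ in range(max_iter):
        free = ~active
        x = np.zeros(n)
        x[free] = np.linalg.solve(A[np.ix_(free, free)], b[free])
        violated = nonneg & free & (x < -tol)
        if violated.any():
            # clamp the worst violator and re-solve
            worst = np.argmin(np.where(violated, x, np.inf))
            active[worst] = True
            continue
        x[nonneg & (x < 0)] = 0.0
        grad = A @ x - b
        # a clamped coordinate with negative gradient wants to leave the bound
        release = active & (grad < -tol)
        if release.any():
            active[np.argmin(np.where(release, grad, np.inf))] = False
            continue
        return x
    raise RuntimeError("active-set QP did not converge")


def kkt_residual(A: np.ndarray, b: np.ndarray, nonneg: np.ndarray,
                 x: np.ndarray) -> float:
    """Max norm of the projected gradient of 0.5x'Ax - b'x under x[nonneg]>=0."""
    grad = A @ x - b
    proj = grad.copy()
    at_bound = nonneg & (x <= 1e-12)
    proj[at_bound] = np.minimum(grad[at_bound], 0.0)
    return float(np.max(np.abs(proj))) if len(proj) else 0.0


def fit_glia_positive(
    obs: ObservationSeries,
    j: int,
    windows: HistoryWindows,
    structure: NetworkStructure,
    prior: PriorConfig,
    rows: Optional[np.ndarray] = None,
) -> FitResult:
    """MAP fit of glial cell ``j`` with w_ng(tau) >= 0 for every neuron sender.

    The glial objective is quadratic, so the constrained optimum solves a
    bound-constrained QP; w_gg and the bias stay unconstrained.
    """
    design = build_design(obs, ("glia", j), windows, structure)
    X, y = design.X, design.y
    if rows is not None:
        X, y = X[rows], y[rows]
    P = _penalty_block_diag(design.column_map, prior)
    A = X.T @ X + 2.0 * P
    b = X.T @ y
    nonneg = np.array([blk == "NG" for (_, blk, _) in design.column_map])
    theta = solve_bound_qp(A, b, nonneg)
    resid = kkt_residual(A, b, nonneg, theta)
    r = y - X @ theta
    noise_var = float(np.mean(r * r))
    params = _unpack_glia(theta, design.column_map, windows, structure, noise_var)
    return FitResult(params, resid < 1e-6, resid,
                     _glia_objective(X, y, P, theta))
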