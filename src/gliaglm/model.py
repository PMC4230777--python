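"""Hybrid generative model of a neuron-glia network.

Neurons are modelled as conditionally independent Bernoulli point processes
whose per-bin spike probability is a logistic function of the recent spiking
history of all neurons and the recent activity of all glial cells.  Glial
cells are modelled as a vector autoregression (VAR) driven by lagged spikes
and lagged glial activity plus white Gaussian observation noise.  A directed
"response function" -- a weight vector over delay lags -- quantifies every
permitted sender -> receiver influence.

The log posterior is the sum of the data log-likelihood and a quadratic
log-prior that penalises the squared magnitude (L2-sparseness) and squared
first differences (smoothness) of each response function.  It decomposes
additively over receiver cells, which is what makes per-cell MAP fitting
possible.

Conventions
-----------
* time bins are 0-indexed; the bin width defaults to 10 ms;
* lags run from 1 to the block's history window; lag 0 is excluded
  (activities in the same bin are conditionally independent);
* the first ``max(windows)`` bins are burn-in and enter no likelihood;
* glial traces are z-scored per cell (mean 0, variance 1);
* connection blocks are named NN (neuron->neuron), GN (glia->neuron),
  NG (neuron->glia) and GG (glia->glia); matrices over pairs are always
  (receiver, sender).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BLOCKS = ("NN", "GN", "NG", "GG")

__all__ = [
    "BLOCKS",
    "ObservationSeries",
    "HistoryWindows",
    "ResponseFunction",
    "NeuronParams",
    "GliaParams",
    "PriorConfig",
    "NetworkStructure",
    "penalty_matrix",
    "neuron_spike_probability",
    "glia_conditional_mean",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _zscore_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("glial trace with zero variance cannot be z-scored")
    return (x - x.mean(axis=0)) / sd


@dataclass
class ObservationSeries:
    """Aligned binary spike trains and z-scored glial traces on one time grid.

    Parameters
    ----------
    spikes : (T, N) array of {0, 1}
        Binary spike indicator per bin and neuron.
    glia : (T, G) array of float
        Continuous glial activity, z-scored per column on construction when
        ``normalize=True`` (the default).
    bin_width : float
        Bin width in seconds (default 0.010 = 10 ms).
    coords : (N+G, 2) array, optional
        Cell centres in micrometers, neurons first then glia.
    """

    spikes: np.ndarray
    glia: np.ndarray
    bin_width: float = 0.010
    coords: Optional[np.ndarray] = None
    normalize: bool = True

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.glia = np.asarray(self.glia, dtype=float)
        if self.spikes.ndim != 2 or self.glia.ndim != 2:
            raise ValueError("spikes and glia must be 2D (time x cells)")
        if self.spikes.shape[0] != self.glia.shape[0]:
            raise ValueError(
                f"spikes ({self.spikes.shape[0]} bins) and glia "
                f"({self.glia.shape[0]} bins) must share the time axis"
            )
        if not np.isin(self.spikes, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.spikes, (0, 1)))[0]
            raise ValueError(
                f"non-binary spike entry at bin {bad[0]}, neuron {bad[1]}"
            )
        self.spikes = self.spikes.astype(np.uint8)
        if not np.isfinite(self.glia).all():
            raise ValueError("glial traces must be finite")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.normalize and self.glia.shape[1] > 0:
            self.glia = _zscore_columns(self.glia)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_cells, 2):
                raise ValueError(
                    f"coords must be ({self.n_cells}, 2), got {self.coords.shape}"
                )

    @property
    def T(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_glia(self) -> int:
        return self.glia.shape[1]

    @property
    def n_cells(self) -> int:
        return self.n_neurons + self.n_glia


@dataclass(frozen=True)
class HistoryWindows:
    """Maximum time lags (in bins) for the four connection blocks."""

    t_nn: int = 10
    t_gn: int = 10
    t_ng: int = 10
    t_gg: int = 10

    def __post_init__(self) -> None:
        for name in ("t_nn", "t_gn", "t_ng", "t_gg"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def burn_in(self) -> int:
        return max(self.t_nn, self.t_gn, self.t_ng, self.t_gg)

    def of_block(self, block: str) -> int:
        return {"NN": self.t_nn, "GN": self.t_gn,
                "NG": self.t_ng, "GG": self.t_gg}[block]


@dataclass
class ResponseFunction:
    """Directed sender -> receiver weight vector over delay lags 1..window."""

    sender: int
    receiver: int
    block: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or not np.isfinite(self.weights).all():
            raise ValueError("weights must be a finite 1D vector")


@dataclass
class NeuronParams:
    """Parameters of one neuron: bias plus incoming NN and GN kernels.

    ``w_nn`` is (n_neurons, t_nn); ``w_gn`` is (n_glia, t_gn); row = sender.
    """

    bias: float
    w_nn: np.ndarray
    w_gn: np.ndarray

    def __post_init__(self) -> None:
        self.w_nn = np.atleast_2d(np.asarray(self.w_nn, dtype=float))
        self.w_gn = np.atleast_2d(np.asarray(self.w_gn, dtype=float))


@dataclass
class GliaParams:
    """Parameters of one glial cell: bias, noise variance, NG and GG kernels."""

    bias: float
    noise_var: float
    w_ng: np.ndarray
    w_gg: np.ndarray

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        self.w_ng = np.atleast_2d(np.asarray(self.w_ng, dtype=float))
        self.w_gg = np.atleast_2d(np.asarray(self.w_gg, dtype=float))


@dataclass(frozen=True)
class PriorConfig:
    """L2-sparseness (lambda) and smoothness (eta) weights per block.

    Each response function w contributes
    ``-lam * sum(w**2) - eta * sum(diff(w)**2)`` to the log prior; biases and
    the glial noise variance carry flat (noninformative) priors.
    """

    lam_nn: float = 1.0
    lam_gn: float = 1.0
    lam_ng: float = 1.0
    lam_gg: float = 1.0
    eta_nn: float = 10.0
    eta_gn: float = 10.0
    eta_ng: float = 10.0
    eta_gg: float = 10.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def of_block(self, block: str) -> tuple[float, float]:
        return (getattr(self, f"lam_{block.lower()}"),
                getattr(self, f"eta_{block.lower()}"))


@dataclass
class NetworkStructure:
    """Boolean (receiver, sender) masks over the four connection blocks."""

    mask_nn: np.ndarray
    mask_gn: np.ndarray
    mask_ng: np.ndarray
    mask_gg: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mask_nn", "mask_gn", "mask_ng", "mask_gg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        n_nn, n_gn = self.mask_nn.shape, self.mask_gn.shape
        g_ng, g_gg = self.mask_ng.shape, self.mask_gg.shape
        if n_nn[0] != n_nn[1] or g_gg[0] != g_gg[1]:
            raise ValueError("mask_nn and mask_gg must be square")
        if n_gn[0] != n_nn[0] or g_ng[0] != g_gg[0]:
            raise ValueError("receiver dimensions of block masks disagree")
        if n_gn[1] != g_gg[1] or g_ng[1] != n_nn[1]:
            raise ValueError("sender dimensions of block masks disagree")

    @property
    def n_neurons(self) -> int:
        return self.mask_nn.shape[0]

    @property
    def n_glia(self) -> int:
        return self.mask_gg.shape[0]

    @classmethod
    def full(cls, n_neurons: int, n_glia: int) -> "NetworkStructure":
        """All connections permitted."""
        return cls(
            np.ones((n_neurons, n_neurons), bool),
            np.ones((n_neurons, n_glia), bool),
            np.ones((n_glia, n_neurons), bool),
            np.ones((n_glia, n_glia), bool),
        )

    @classmethod
    def within_blocks_only(cls, n_neurons: int, n_glia: int) -> "NetworkStructure":
        """Full NN and GG blocks, empty cross blocks (two independent nets)."""
        return cls(
            np.ones((n_neurons, n_neurons), bool),
            np.zeros((n_neurons, n_glia), bool),
            np.zeros((n_glia, n_neurons), bool),
            np.ones((n_glia, n_glia), bool),
        )

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(
            self.mask_nn.copy(), self.mask_gn.copy(),
            self.mask_ng.copy(), self.mask_gg.copy(),
        )

    def mask_of(self, block: str) -> np.ndarray:
        return {"NN": self.mask_nn, "GN": self.mask_gn,
                "NG": self.mask_ng, "GG": self.mask_gg}[block]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return all(
            np.array_equal(self.mask_of(b), other.mask_of(b)) for b in BLOCKS
        )


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def penalty_matrix(window: int, lam: float, eta: float) -> np.ndarray:
    """Quadratic-form matrix P with w @ P @ w = lam*sum(w^2) + eta*sum(dw^2).

    D is the (window-1, window) first-difference operator; P = lam*I + eta*D'D.
    """
    P = lam * np.eye(window)
    if window > 1 and eta > 0:
        D = np.diff(np.eye(window), axis=0)
        P = P + eta * (D.T @ D)
    return P


def _kernel_penalty(w: np.ndarray, lam: float, eta: float) -> float:
    w = np.asarray(w, dtype=float)
    pen = lam * float(np.sum(w * w))
    if w.size > 1:
        dw = np.diff(w)
        pen += eta * float(np.sum(dw * dw))
    return pen


def log_prior(
    neuron_params: list[NeuronParams],
    glia_params: list[GliaParams],
    prior: PriorConfig,
) -> float:
    """Log prior density (up to a constant): minus the quadratic penalties.

    Always <= 0, with equality iff every response function is zero.
    """
    total = 0.0
    for p in neuron_params:
        for row in p.w_nn:
            total -= _kernel_penalty(row, prior.lam_nn, prior.eta_nn)
        for row in p.w_gn:
            total -= _kernel_penalty(row, prior.lam_gn, prior.eta_gn)
    for p in glia_params:
        for row in p.w_ng:
            total -= _kernel_penalty(row, prior.lam_ng, prior.eta_ng)
        for row in p.w_gg:
            total -= _kernel_penalty(row, prior.lam_gg, prior.eta_gg)
    return total


# ---------------------------------------------------------------------------
# conditional distributions
# ---------------------------------------------------------------------------

def _logistic(x: float | np.ndarray) -> float | np.ndarray:
    # numerically safe sigmoid
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x)))


def _check_time(t: int, windows: HistoryWindows) -> None:
    if t < windows.burn_in:
        raise ValueError(
            f"bin {t} lies inside the burn-in window ({windows.burn_in} bins)"
        )


def _masked(weights: np.ndarray, mask_row: np.ndarray) -> np.ndarray:
    out = weights.copy()
    out[~mask_row, :] = 0.0
    return out


def neuron_spike_probability(
    obs: ObservationSeries,
    t: int,
    i: int,
    params: NeuronParams,
    windows: HistoryWindows,
    structure: NetworkStructure,
) -> float:
    """Per-bin spike probability of neuron ``i`` at bin ``t``.

    logistic( bias + sum_{i',tau} w_nn[i',tau] n_{i'}(t-tau)
                   + sum_{j,tau}  w_gn[j,tau]  g_j(t-tau) )
    """
    _check_time(t, windows)
    w_nn = _masked(params.w_nn, structure.mask_nn[i])
    w_gn = _masked(params.w_gn, structure.mask_gn[i])
    # history slices, lag tau=1..window -> reversed time order
    hist_n = obs.spikes[t - windows.t_nn : t][::-1].T  # (N, t_nn)
    hist_g = obs.glia[t - windows.t_gn : t][::-1].T    # (G, t_gn)
    drive = params.bias + float(np.sum(w_nn * hist_n)) + float(np.sum(w_gn * hist_g))
    return float(np.clip(_logistic(drive), np.nextafter(0, 1), np.nextafter(1, 0)))


def glia_conditional_mean(
    obs: ObservationSeries,
    t: int,
    j: int,
    params: GliaParams,
    windows: HistoryWindows,
    structure: NetworkStructure,
) -> float:
    """Conditional mean of glial cell ``j`` at bin ``t`` under the VAR model."""
    _check_time(t, windows)
    w_ng = _masked(params.w_ng, structure.mask_ng[j])
    w_gg = _masked(params.w_gg, structure.mask_gg[j])
    hist_n = obs.spikes[t - windows.t_ng : t][::-1].T
    hist_g = obs.glia[t - windows.t_gg : t][::-1].T
    return params.bias + float(np.sum(w_ng * hist_n)) + float(np.sum(w_gg * hist_g))


# ---------------------------------------------------------------------------
# likelihood / posterior
# ---------------------------------------------------------------------------

def _lagged_design(x: np.ndarray, window: int, burn_in: int) -> np.ndarray:
    """Columns (sender, lag) of ``x`` lagged 1..window over rows t >= burn_in.

    Column ordering: sender ascending (outer), lag ascending (inner).
    """
    T, n = x.shape
    cols = np.empty((T - burn_in, n * window), dtype=float)
    for tau in range(1, window + 1):
        cols[:, tau - 1 :: window] = x[burn_in - tau : T - tau]
    return cols


def neuron_loglik(
    obs: ObservationSeries,
    i: int,
    params: NeuronParams,
    windows: HistoryWindows,
    structure: NetworkStructure,
    rows: Optional[np.ndarray] = None,
) -> float:
    """Bernoulli log-likelihood of neuron ``i`` over post-burn-in bins."""
    burn = windows.burn_in
    Xn = _lagged_design(obs.spikes.astype(float), windows.t_nn, burn)
    Xg = _lagged_design(obs.glia, windows.t_gn, burn)
    w_nn = _masked(params.w_nn, structure.mask_nn[i]).ravel()
    w_gn = _masked(params.w_gn, structure.mask_gn[i]).ravel()
    a = params.bias + Xn @ w_nn + Xg @ w_gn
    y = obs.spikes[burn:, i].astype(float)
    if rows is not None:
        a, y = a[rows], y[rows]
    # log p = y*a - log(1+e^a), stable via logaddexp
    return float(np.sum(y * a - np.logaddexp(0.0, a)))


def glia_loglik(
    obs: ObservationSeries,
    j: int,
    params: GliaParams,
    windows: HistoryWindows,
    structure: NetworkStructure,
    rows: Optional[np.ndarray] = None,
) -> float:
    """Gaussian log-likelihood of glial cell ``j`` over post-burn-in bins."""
    burn = windows.burn_in
    Xn = _lagged_design(obs.spikes.astype(float), windows.t_ng, burn)
    Xg = _lagged_design(obs.glia, windows.t_gg, burn)
    w_ng = _masked(params.w_ng, structure.mask_ng[j]).ravel()
    w_gg = _masked(params.w_gg, structure.mask_gg[j]).ravel()
    mu = params.bias + Xn @ w_ng + Xg @ w_gg
    y = obs.glia[burn:, j]
    if rows is not None:
        mu, y = mu[rows], y[rows]
    r = y - mu
    s2 = params.noise_var
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * s2) - r * r / (2.0 * s2)))


def log_likelihood(
    obs: ObservationSeries,
    neuron_params: list[NeuronParams],
    glia_params: list[GliaParams],
    windows: HistoryWindows,
    structure: NetworkStructure,
) -> float:
    """Total data log-likelihood; sums per-cell terms (additive by design)."""
    total = 0.0
    for i, p in enumerate(neuron_params):
        total += neuron_loglik(obs, i, p, windows, structure)
    for j, p in enumerate(glia_params):
        total += glia_loglik(obs, j, p, windows, structure)
    return total


def log_posterior(
    obs: ObservationSeries,
    neuron_params: list[NeuronParams],
    glia_params: list[GliaParams],
    windows: HistoryWindows,
    structure: NetworkStructure,
    prior: PriorConfig,
) -> float:
    """Unnormalised log posterior = log likelihood + log prior."""
    return (
        log_likelihood(obs, neuron_params, glia_params, windows, structure)
        + log_prior(neuron_params, glia_params, prior)
    )
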