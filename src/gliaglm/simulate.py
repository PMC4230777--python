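"""Forward simulation of the neuron-glia generative model.

Ground-truth scenario builder and sampler used as the test bed for the
identification pipeline: neurons spike as Bernoulli draws from the logistic
conditional intensity, glial cells follow the VAR conditional mean plus
white Gaussian noise.  Scenario defaults emulate the target recordings:
10 ms bins, spontaneous firing rates inside the 0.03-1 Hz band, a few glial
cells with slow self-persistent continuous activity, inhibitory neuronal
self-feedback (refractoriness) and excitatory glial self-feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.special

from .model import (
    GliaParams,
    HistoryWindows,
    NetworkStructure,
    NeuronParams,
    ObservationSeries,
    PriorConfig,
)

__all__ = [
    "Scenario",
    "ReconstructionScore",
    "alpha_kernel",
    "build_scenario",
    "simulate",
    "score_reconstruction",
    "validation_experiment",
]

RATE_BAND_HZ = (0.01, 2.0)  # sanity band around the observed 0.03-1 Hz


def alpha_kernel(window: int, peak: float, tau_peak: Optional[float] = None) -> np.ndarray:
    """Smooth bump over lags 1..window: w(tau) = peak*(tau/tp)*exp(1 - tau/tp).

    ``tau_peak`` defaults to the mid-window, where the kernel attains
    ``peak`` exactly.
    """
    tp = window / 2.0 if tau_peak is None else tau_peak
    tau = np.arange(1, window + 1, dtype=float)
    return peak * (tau / tp) * np.exp(1.0 - tau / tp)


@dataclass
class Scenario:
    """A fully specified ground-truth network plus sampling configuration."""

    n_neurons: int
    n_glia: int
    T: int
    bin_width: float
    windows: HistoryWindows
    true_structure: NetworkStructure
    neuron_params: list[NeuronParams]
    glia_params: list[GliaParams]
    coords: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        lo, hi = RATE_BAND_HZ
        for i, p in enumerate(self.neuron_params):
            rate = scipy.special.expit(p.bias) / self.bin_width
            if not (lo <= rate <= hi):
                raise ValueError(
                    f"neuron {i}: baseline rate {rate:.3g} Hz outside the "
                    f"{lo}-{hi} Hz sanity band"
                )
        rho = self.glia_spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"glial VAR is non-stationary (spectral radius {rho:.3f} >= 1)"
            )

    def glia_spectral_radius(self) -> float:
        """Spectral radius of the companion form of the glial VAR block."""
        G, L = self.n_glia, self.windows.t_gg
        if G == 0:
            return 0.0
        A = np.zeros((G * L, G * L))
        for j, p in enumerate(self.glia_params):
            w = np.where(self.true_structure.mask_gg[j][:, None], p.w_gg, 0.0)
            for tau in range(1, L + 1):
                A[j, (tau - 1) * G : tau * G] = w[:, tau - 1]
        if L > 1:
            A[G:, :-G] = np.eye(G * (L - 1))
        return float(np.max(np.abs(np.linalg.eigvals(A))))


def rate_to_bias(rate_hz: float, bin_width: float) -> float:
    """Intercept giving a baseline firing rate (closed form: logit(p))."""
    p = rate_hz * bin_width
    if not 0.0 < p < 1.0:
        raise ValueError(f"rate {rate_hz} Hz infeasible at {bin_width}s bins")
    return float(scipy.special.logit(p))


def build_scenario(
    n_neurons: int = 8,
    n_glia: int = 2,
    density_gn: float = 0.25,
    density_ng: float = 0.25,
    kernel_shape: str = "alpha",
    T: int = 128_000,
    seed: int = 0,
    bin_width: float = 0.010,
    window: int = 8,
    rate_range_hz: tuple[float, float] = (0.2, 0.8),
    gn_peak: float = 0.15,
    ng_peak: float = 1.2,
    gn_sign: float = 1.0,
    ng_sign: float = -1.0,
    self_nn_peak: float = -2.0,
    self_gg_peak: float = 0.1,
    noise_var: float = 1.0,
    field_um: tuple[float, float] = (184.0, 94.0),
) -> Scenario:
    """Sample a ground-truth scenario with the given cross-block densities.

    Response kernels are alpha-function bumps; glia-to-neuron and
    neuron-to-glia kernel peaks default to values strong enough to dominate
    the glial noise floor, with neuronal self-feedback inhibitory and glial
    self-feedback excitatory.  Neuron biases are drawn so baseline rates fall
    inside ``rate_range_hz`` (which must sit inside the 0.01-2 Hz band).
    """
    if not (0.0 <= density_gn <= 1.0 and 0.0 <= density_ng <= 1.0):
        raise ValueError("densities must lie in [0, 1]")
    if kernel_shape != "alpha":
        raise ValueError(f"unknown kernel shape {kernel_shape!r}")
    rng = np.random.default_rng(seed)
    windows = HistoryWindows(window, window, window, window)

    structure = NetworkStructure.within_blocks_only(n_neurons, n_glia)
    structure.mask_gn = rng.random((n_neurons, n_glia)) < density_gn
    structure.mask_ng = rng.random((n_glia, n_neurons)) < density_ng

    log_lo, log_hi = np.log(rate_range_hz[0]), np.log(rate_range_hz[1])
    rates = np.exp(rng.uniform(log_lo, log_hi, size=n_neurons))

    neuron_params = []
    for i in range(n_neurons):
        w_nn = np.zeros((n_neurons, window))
        w_nn[i] = alpha_kernel(window, self_nn_peak)
        w_gn = np.zeros((n_glia, window))
        for j in np.flatnonzero(structure.mask_gn[i]):
            w_gn[j] = alpha_kernel(window, gn_sign * gn_peak)
        neuron_params.append(NeuronParams(rate_to_bias(rates[i], bin_width),
                                          w_nn, w_gn))

    glia_params = []
    for j in range(n_glia):
        w_gg = np.zeros((n_glia, window))
        w_gg[j] = alpha_kernel(window, self_gg_peak)
        w_ng = np.zeros((n_neurons, window))
        for i in np.flatnonzero(structure.mask_ng[j]):
            w_ng[i] = alpha_kernel(window, ng_sign * ng_peak)
        glia_params.append(GliaParams(0.0, noise_var, w_ng, w_gg))

    coords = rng.uniform((0.0, 0.0), field_um, size=(n_neurons + n_glia, 2))
    return Scenario(n_neurons, n_glia, T, bin_width, windows, structure,
                    neuron_params, glia_params, coords, seed)


def simulate(scenario: Scenario) -> ObservationSeries:
    """Sample an ObservationSeries from a scenario (reproducible by seed).

    Sequential sampling bin by bin; a burn-in of max(windows) bins is
    simulated and discarded; glial columns are z-scored afterwards.  One
    root seed spawns an independent child stream per cell, so adding a cell
    leaves the other cells' draws unchanged.
    """
    N, G = scenario.n_neurons, scenario.n_glia
    w = scenario.windows
    burn = w.burn_in
    T_total = scenario.T + burn

    ss = np.random.SeedSequence(scenario.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(N + G)]
    uniforms = np.column_stack([streams[i].random(T_total) for i in range(N)]) \
        if N else np.empty((T_total, 0))
    noises = np.column_stack([
        streams[N + j].normal(0.0, np.sqrt(scenario.glia_params[j].noise_var),
                              T_total)
        for j in range(G)
    ]) if G else np.empty((T_total, 0))

    # flattened (receiver, sender*lag) weight matrices, masked by structure
    def flat(params_w, mask, window):
        out = np.stack([
            np.where(mask[r][:, None], params_w[r], 0.0).ravel()
            for r in range(mask.shape[0])
        ])
        return out

    Wnn = flat([p.w_nn for p in scenario.neuron_params],
               scenario.true_structure.mask_nn, w.t_nn) if N else None
    Wgn = flat([p.w_gn for p in scenario.neuron_params],
               scenario.true_structure.mask_gn, w.t_gn) if N else None
    Wng = flat([p.w_ng for p in scenario.glia_params],
               scenario.true_structure.mask_ng, w.t_ng) if G else None
    Wgg = flat([p.w_gg for p in scenario.glia_params],
               scenario.true_structure.mask_gg, w.t_gg) if G else None
    bias_n = np.array([p.bias for p in scenario.neuron_params])
    bias_g = np.array([p.bias for p in scenario.glia_params])

    spikes = np.zeros((T_total, N), dtype=np.uint8)
    glia = np.zeros((T_total, G), dtype=float)

    for t in range(burn, T_total):
        hist_nn = spikes[t - w.t_nn : t][::-1].T.ravel().astype(float)
        hist_gn = glia[t - w.t_gn : t][::-1].T.ravel()
        if N:
            drive = bias_n + Wnn @ hist_nn + Wgn @ hist_gn
            p = 0.5 * (1.0 + np.tanh(0.5 * drive))
            spikes[t] = uniforms[t] < p
        if G:
            hist_ng = spikes[t - w.t_ng : t][::-1].T.ravel().astype(float)
            hist_gg = glia[t - w.t_gg : t][::-1].T.ravel()
            mu = bias_g + Wng @ hist_ng + Wgg @ hist_gg
            glia[t] = mu + noises[t]
            if np.any(np.abs(glia[t]) > 1e6):
                raise RuntimeError(
                    "glial trajectory exploded; check the VAR spectral radius "
                    f"({scenario.glia_spectral_radius():.3f})"
                )

    return ObservationSeries(
        spikes[burn:], glia[burn:], bin_width=scenario.bin_width,
        coords=scenario.coords, normalize=G > 0,
    )


@dataclass
class ReconstructionScore:
    """Confusion summary of an estimated cross-block mask vs ground truth."""

    block: str
    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int

    @property
    def accuracy(self) -> float:
        total = (self.true_positives + self.false_positives
                 + self.true_negatives + self.false_negatives)
        return (self.true_positives + self.true_negatives) / total


def score_reconstruction(
    true_structure: NetworkStructure,
    estimated_structure: NetworkStructure,
    block: str,
) -> ReconstructionScore:
    """Elementwise confusion over one cross-block mask ("GN" or "NG")."""
    if block not in ("GN", "NG"):
        raise ValueError("reconstruction is scored on the GN or NG block")
    truth = true_structure.mask_of(block)
    est = estimated_structure.mask_of(block)
    if truth.shape != est.shape:
        raise ValueError(
            f"shape mismatch: true {truth.shape} vs estimated {est.shape}"
        )
    return ReconstructionScore(
        block,
        int(np.sum(truth & est)),
        int(np.sum(~truth & est)),
        int(np.sum(~truth & ~est)),
        int(np.sum(truth & ~est)),
    )


def validation_experiment(
    scenario_config: Optional[dict] = None,
    n_trials: int = 10,
    seed: int = 0,
    T_grid: Sequence[int] = (64_000, 128_000),
    prior: Optional[PriorConfig] = None,
    alpha: float = 0.05,
    K: int = 10,
) -> pd.DataFrame:
    """Reconstruction accuracy of the full pipeline as a function of T.

    For each series length, ``n_trials`` scenarios are drawn, simulated,
    passed through the structure search, and scored against the planted
    cross-block structure.  Returns a table with per-length mean accuracy
    and 2.5/97.5 percentile bands for both cross blocks.
    """
    from .selection import CVEngine, search_structure  # deferred: cycle-free

    cfg = dict(scenario_config or {})
    prior = prior or PriorConfig()
    root = np.random.SeedSequence(seed)
    trial_seeds = root.generate_state(n_trials * len(T_grid)) % (2**31)
    records = []
    k = 0
    for T in T_grid:
        acc = {"GN": [], "NG": []}
        for _ in range(n_trials):
            scen = build_scenario(T=int(T), seed=int(trial_seeds[k]), **cfg)
            k += 1
            obs = simulate(scen)
            engine = CVEngine(obs, scen.windows, prior, K=K)
            result = search_structure(obs, scen.windows, prior, alpha=alpha,
                                      engine=engine)
            for block in ("GN", "NG"):
                acc[block].append(
                    score_reconstruction(scen.true_structure,
                                         result.structure, block).accuracy
                )
        for block in ("GN", "NG"):
            a = np.asarray(acc[block])
            records.append({
                "T": int(T), "block": block, "n_trials": n_trials,
                "mean_accuracy": float(a.mean()),
                "ci_low": float(np.percentile(a, 2.5)),
                "ci_high": float(np.percentile(a, 97.5)),
            })
    return pd.DataFrame.from_records(records)
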