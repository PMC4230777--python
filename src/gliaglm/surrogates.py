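"""Surrogate-data null tests for the bulk number of detected connections.

Glial traces are surrogated with the Iterated Amplitude Adjusted Fourier
Transform (IAAFT), which preserves the amplitude distribution exactly (the
surrogate is a permutation of the original values) and the power spectrum
approximately, while destroying cross-correlations with every other cell.
Spike trains are surrogated by a circular shift, which preserves the spike
count, the circular inter-spike-interval multiset and the autocorrelation
exactly.

The bulk-count test replaces the target cell's series with surrogates,
reruns the connection identification restricted to that cell, and compares
the observed number of detected connections with the surrogate null
distribution (add-one p-value convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import HistoryWindows, ObservationSeries, PriorConfig
from .selection import ALPHA, CVEngine, test_gn_connection, test_ng_connection

__all__ = [
    "SurrogateNull",
    "iaaft_surrogate",
    "circular_shift_surrogate",
    "bulk_count_test",
]


@dataclass
class SurrogateNull:
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    target_cell: int
    direction: str


def iaaft_surrogate(
    trace: np.ndarray,
    max_iter: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """IAAFT surrogate of a continuous series (Schreiber-Schmitz iteration).

    Alternates a spectrum-adjustment step (impose the original Fourier
    amplitudes) with a rank-ordering step (impose the original value
    multiset) until the rank ordering stabilises or ``max_iter`` is reached.
    The returned series is always an exact permutation of the input values.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("trace must be 1D with at least 4 samples")
    if not np.isfinite(x).all():
        raise ValueError("trace must be finite")
    if np.ptp(x) == 0.0:
        warnings.warn("constant series has no phase content; returned unchanged")
        return x.copy()
    rng = np.random.default_rng(seed) if rng is None else rng
    sorted_vals = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    r = rng.permutation(x)
    prev_ranks: Optional[np.ndarray] = None
    for _ in range(max_iter):
        # impose the original power spectrum, keep the current phases
        spec = np.fft.rfft(r)
        phases = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phases), n=len(x))
        # impose the original amplitude distribution by rank remapping
        ranks = np.argsort(np.argsort(s))
        r = sorted_vals[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return r


def circular_shift_surrogate(
    spikes: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    offset: Optional[int] = None,
) -> np.ndarray:
    """Rotate a spike train by a uniform random offset in [1, T-1]."""
    x = np.asarray(spikes)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("spike train must be 1D with at least 2 bins")
    if offset is None:
        rng = np.random.default_rng(seed) if rng is None else rng
        offset = int(rng.integers(1, len(x)))
    if not 1 <= offset <= len(x) - 1:
        raise ValueError(f"offset must lie in [1, {len(x) - 1}]")
    return np.roll(x, offset)


def _count_gn(engine: CVEngine, obs: ObservationSeries, j: int,
              windows: HistoryWindows, prior: PriorConfig, alpha: float) -> int:
    return sum(
        test_gn_connection(obs, j, i, windows, prior, alpha=alpha,
                           engine=engine).accepted
        for i in range(obs.n_neurons)
    )


def _count_ng(engine: CVEngine, obs: ObservationSeries, j: int,
              windows: HistoryWindows, prior: PriorConfig, alpha: float) -> int:
    return sum(
        test_ng_connection(obs, i, j, windows, prior, alpha=alpha,
                           engine=engine).accepted
        for i in range(obs.n_neurons)
    )


def bulk_count_test(
    obs: ObservationSeries,
    target_cell: int,
    direction: str,
    n_surrogates: int,
    windows: HistoryWindows,
    prior: PriorConfig,
    K: int = 10,
    alpha: float = ALPHA,
    seed: Optional[int] = None,
) -> SurrogateNull:
    """Surrogate null test of the number of connections involving one glia.

    direction "glia_to_neuron": the target glial cell's trace is replaced by
    IAAFT surrogates and the per-pair glia->neuron tests are rerun; counts
    the detected connections from that cell.  direction "neuron_to_glia":
    every neuronal spike train is independently circularly shifted (one
    offset per neuron per replicate) and the per-pair neuron->glia removal
    tests for the target receiver are rerun.

    p = (1 + #{null >= observed}) / (1 + n_surrogates), in (0, 1].
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate replicate")
    if direction not in ("glia_to_neuron", "neuron_to_glia"):
        raise ValueError(f"unknown direction {direction!r}")
    j = target_cell
    rng = np.random.default_rng(seed)

    engine = CVEngine(obs, windows, prior, K=K)
    if direction == "glia_to_neuron":
        observed = _count_gn(engine, obs, j, windows, prior, alpha)
    else:
        observed = _count_ng(engine, obs, j, windows, prior, alpha)

    # cache entries that do not involve the surrogated series stay valid
    # across replicates (e.g. the M0 fits, which exclude all glia)
    if direction == "glia_to_neuron":
        reusable = {k: v for k, v in engine._cache.items()
                    if k[0] == "n" and not np.frombuffer(k[3], bool)[j]}
    else:
        reusable = {}

    null_counts = np.empty(n_surrogates, dtype=int)
    for s in range(n_surrogates):
        if direction == "glia_to_neuron":
            glia = obs.glia.copy()
            glia[:, j] = iaaft_surrogate(obs.glia[:, j], rng=rng)
            surro = ObservationSeries(obs.spikes, glia, obs.bin_width,
                                      obs.coords, normalize=True)
            eng = CVEngine(surro, windows, prior, K=K)
            eng._cache.update(reusable)
            null_counts[s] = _count_gn(eng, surro, j, windows, prior, alpha)
        else:
            spikes = np.column_stack([
                circular_shift_surrogate(obs.spikes[:, i], rng=rng)
                for i in range(obs.n_neurons)
            ])
            surro = ObservationSeries(spikes, obs.glia, obs.bin_width,
                                      obs.coords, normalize=False)
            eng = CVEngine(surro, windows, prior, K=K)
            null_counts[s] = _count_ng(eng, surro, j, windows, prior, alpha)

    p = (1 + int(np.sum(null_counts >= observed))) / (1 + n_surrogates)
    return SurrogateNull(observed, null_counts, p, target_cell, direction)
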