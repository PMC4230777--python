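"""Post-identification summaries of a fitted neuron-glia network.

Connectivity strength (per-block normalized RMS of response functions),
excitatory/inhibitory classification by the sign of the temporal average,
average response functions with pointwise confidence bands, and a
resampling test of whether identified glia-to-neuron connections are
spatially local (their median distance smaller than random pairings).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .model import BLOCKS, GliaParams, NetworkStructure, NeuronParams

__all__ = [
    "StrengthMatrix",
    "DistanceTestResult",
    "strength_matrix",
    "classify_sign",
    "average_response",
    "median_distance_test",
]


def _kernel(neuron_params: Sequence[NeuronParams],
            glia_params: Sequence[GliaParams],
            block: str, receiver: int, sender: int) -> np.ndarray:
    if block == "NN":
        return neuron_params[receiver].w_nn[sender]
    if block == "GN":
        return neuron_params[receiver].w_gn[sender]
    if block == "NG":
        return glia_params[receiver].w_ng[sender]
    if block == "GG":
        return glia_params[receiver].w_gg[sender]
    raise ValueError(f"unknown block {block!r}")


@dataclass
class StrengthMatrix:
    """(N+G) x (N+G) matrix of normalized response-function magnitudes.

    Rows are receivers, columns senders, neurons first then glia; each of
    the four blocks is normalized independently to [0, 1].
    """

    values: np.ndarray
    n_neurons: int
    n_glia: int
    method: str


def strength_matrix(
    neuron_params: Sequence[NeuronParams],
    glia_params: Sequence[GliaParams],
    structure: NetworkStructure,
    method: str = "minmax",
) -> StrengthMatrix:
    """Per-connection RMS kernel magnitude, normalized within each block.

    entry (receiver, sender) = sqrt(mean_tau w(tau)^2) for permitted
    connections, 0 otherwise; ``method`` is "minmax" (default) or "maxabs"
    scaling within the block.
    """
    N, G = structure.n_neurons, structure.n_glia
    out = np.zeros((N + G, N + G))
    spans = {"NN": (slice(0, N), slice(0, N)),
             "GN": (slice(0, N), slice(N, N + G)),
             "NG": (slice(N, N + G), slice(0, N)),
             "GG": (slice(N, N + G), slice(N, N + G))}
    for block in BLOCKS:
        mask = structure.mask_of(block)
        rms = np.zeros(mask.shape)
        for r, s in np.argwhere(mask):
            w = _kernel(neuron_params, glia_params, block, r, s)
            rms[r, s] = np.sqrt(np.mean(w**2))
        if rms.max() > 0:
            if method == "minmax":
                rms = (rms - rms.min()) / (rms.max() - rms.min())
            elif method == "maxabs":
                rms = rms / rms.max()
            else:
                raise ValueError(f"unknown normalization {method!r}")
        out[spans[block]] = rms
    return StrengthMatrix(out, N, G, method)


def classify_sign(
    neuron_params: Sequence[NeuronParams],
    glia_params: Sequence[GliaParams],
    structure: NetworkStructure,
    epsilon: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Excitatory/inhibitory label per permitted connection.

    A connection is excitatory when the temporal average of its response
    function exceeds ``epsilon``, inhibitory when below ``-epsilon``, and
    "null" otherwise (exactly-zero averages fall here and are excluded from
    the positive fractions).  Returns the per-connection table and the
    percentage of positive (excitatory) connections per block.
    """
    rows = []
    for block in BLOCKS:
        for r, s in np.argwhere(structure.mask_of(block)):
            avg = float(np.mean(_kernel(neuron_params, glia_params, block, r, s)))
            if avg > epsilon:
                label = "excitatory"
            elif avg < -epsilon:
                label = "inhibitory"
            else:
                label = "null"
            rows.append({"block": block, "receiver": int(r), "sender": int(s),
                         "temporal_average": avg, "label": label})
    table = pd.DataFrame(rows, columns=["block", "receiver", "sender",
                                        "temporal_average", "label"])
    fractions = {}
    for block in BLOCKS:
        sub = table[(table.block == block) & (table.label != "null")]
        fractions[block] = (
            100.0 * float((sub.label == "excitatory").mean()) if len(sub)
            else float("nan")
        )
    return table, fractions


@dataclass
class AverageResponse:
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    t_statistic: float
    p_value: float


def average_response(
    neuron_params: Sequence[NeuronParams],
    glia_params: Sequence[GliaParams],
    accepted_connections: Sequence[tuple[int, int]],
    block: str,
) -> AverageResponse:
    """Mean kernel over accepted (sender, receiver) pairs with 95% t-CI.

    Also runs a two-sided one-sample t-test on the distribution of the
    kernels' temporal averages (is the block's mean effect signed?).
    """
    if len(accepted_connections) < 2:
        raise ValueError("need at least 2 accepted connections to average")
    kernels = np.vstack([
        _kernel(neuron_params, glia_params, block, receiver, sender)
        for sender, receiver in accepted_connections
    ])
    n = kernels.shape[0]
    mean = kernels.mean(axis=0)
    sem = kernels.std(axis=0, ddof=1) / np.sqrt(n)
    half = scipy.stats.t.ppf(0.975, df=n - 1) * sem
    averages = kernels.mean(axis=1)
    if np.var(averages, ddof=1) > 0:
        t, p = scipy.stats.ttest_1samp(averages, 0.0)
    else:
        t, p = float("nan"), float("nan")
    return AverageResponse(mean, mean - half, mean + half, n, float(t), float(p))


@dataclass
class DistanceTestResult:
    observed_median: float
    null_medians: np.ndarray
    p_value: float


def median_distance_test(
    accepted: Sequence[tuple[int, int]],
    neuron_coords: np.ndarray,
    glia_coords: np.ndarray,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> DistanceTestResult:
    """Are accepted glia->neuron connections spatially local?

    ``accepted`` lists (glia, neuron) pairs.  The observed statistic is the
    median Euclidean distance over accepted pairs.  Each null replicate
    redraws, for every glial cell k with n_k accepted connections, n_k
    neurons uniformly without replacement, pools the distances and takes the
    median.  One-sided: p = (1 + #{null <= observed}) / (1 + n_resamples),
    small when the accepted connections are closer than chance.
    """
    accepted = list(accepted)
    if not accepted:
        raise ValueError("no accepted connections to test")
    neuron_coords = np.asarray(neuron_coords, float)
    glia_coords = np.asarray(glia_coords, float)
    rng = np.random.default_rng(seed)

    dists = [
        float(np.linalg.norm(glia_coords[j] - neuron_coords[i]))
        for j, i in accepted
    ]
    observed = float(np.median(dists))

    counts: dict[int, int] = {}
    for j, _ in accepted:
        counts[j] = counts.get(j, 0) + 1
    n_neurons = len(neuron_coords)
    all_d = {
        j: np.linalg.norm(neuron_coords - glia_coords[j], axis=1)
        for j in counts
    }
    null = np.empty(n_resamples)
    for r in range(n_resamples):
        pool = np.concatenate([
            all_d[j][rng.choice(n_neurons, size=nk, replace=False)]
            for j, nk in counts.items()
        ])
        null[r] = np.median(pool)
    p = (1 + int(np.sum(null <= observed))) / (1 + n_resamples)
    return DistanceTestResult(observed, null, p)
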