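"""Connection identification by cross-validated likelihood.

The time series (after burn-in) is split into K contiguous folds.  For a
candidate network structure, every cell is re-fitted on K-1 folds and scored
by its mean per-bin held-out log-likelihood on the remaining fold.  A
candidate connection is judged by a paired t-statistic over the K per-fold
held-out log-likelihood differences between a structure with and a structure
without the connection:

    t = mean(d) / sqrt(var_unbiased(d) / K),   df = K - 1, one-sided.

Glia-to-neuron connections are grown additively from an empty block (a
connection is added when it yields a significant held-out gain); neuron-to-
glia connections are pruned subtractively from the full block (a connection
is kept only when its removal causes a significant held-out loss).  The
within-block N->N and G->G connections stay full and are not tested.

Histories cross fold boundaries: the folds partition the evaluated/trained
bins, not the lagged features, so a bin near a fold start may draw its
history from the preceding fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

import scipy.sparse

from .fit import HybridDesign, fit_logistic_map, solve_bound_qp
from .model import (
    HistoryWindows,
    NetworkStructure,
    ObservationSeries,
    PriorConfig,
    penalty_matrix,
)

__all__ = [
    "FoldPlan",
    "CVReport",
    "ConnectionTest",
    "make_folds",
    "CVEngine",
    "cv_likelihood",
    "t_statistic",
    "test_gn_connection",
    "test_ng_connection",
    "search_structure",
    "tune_hyperparameters",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """K contiguous, disjoint bin ranges covering all usable bins."""

    K: int
    fold_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = 0
        for start, stop in self.fold_bounds:
            if start != prev or stop <= start:
                raise ValueError("folds must be contiguous, ordered, non-empty")
            prev = stop

    @property
    def n_usable(self) -> int:
        return self.fold_bounds[-1][1]


def make_folds(T_usable: int, K: int = 10) -> FoldPlan:
    """Partition ``T_usable`` bins into K contiguous blocks of near-equal size."""
    if K < 1 or T_usable < K:
        raise ValueError(f"{T_usable} usable bins cannot support {K} folds")
    base, extra = divmod(T_usable, K)
    bounds = []
    start = 0
    for k in range(K):
        size = base + (1 if k < extra else 0)
        bounds.append((start, start + size))
        start += size
    return FoldPlan(K, tuple(bounds))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Held-out mean per-bin log-likelihoods, cells x folds (neurons first)."""

    per_cell_per_fold: np.ndarray
    structure: NetworkStructure
    prior: PriorConfig
    windows: HistoryWindows

    @property
    def neuron_wise(self) -> np.ndarray:
        """L_i(M): per-neuron mean over folds."""
        n = self.structure.n_neurons
        return self.per_cell_per_fold[:n].mean(axis=1)

    @property
    def glia_wise(self) -> np.ndarray:
        n = self.structure.n_neurons
        return self.per_cell_per_fold[n:].mean(axis=1)

    @property
    def L_N(self) -> float:
        """Cross-validated likelihood of the neuron side (mean over neurons)."""
        return float(self.neuron_wise.mean())

    @property
    def L_G(self) -> float:
        return float(self.glia_wise.mean())


@dataclass
class ConnectionTest:
    sender: int
    receiver: int
    block: str
    delta_per_fold: np.ndarray
    t_value: float
    p_value: float
    accepted: bool
    degenerate: bool = False


def t_statistic(deltas: np.ndarray) -> tuple[float, float, bool]:
    """Paired t over folds: (t, one-sided p, degenerate?); df = K - 1."""
    d = np.asarray(deltas, dtype=float)
    K = len(d)
    s2 = d.var(ddof=1) if K > 1 else 0.0
    if s2 == 0.0:
        return float("nan"), float("nan"), True
    t = float(d.mean() / np.sqrt(s2 / K))
    p = float(scipy.stats.t.sf(t, df=K - 1))
    return t, p, False


def _make_test(sender: int, receiver: int, block: str,
               deltas: np.ndarray, alpha: float) -> ConnectionTest:
    t, p, degenerate = t_statistic(deltas)
    if degenerate:
        accepted = bool(np.mean(deltas) > 0)
    else:
        accepted = p < alpha
    return ConnectionTest(sender, receiver, block, np.asarray(deltas, float),
                          t, p, accepted, degenerate)


# ---------------------------------------------------------------------------
# the CV engine (shared lag features, per-fold Gram matrices, result cache)
# ---------------------------------------------------------------------------

def _lagged(x: np.ndarray, window: int, burn_in: int) -> np.ndarray:
    T, n = x.shape
    out = np.empty((T - burn_in, n * window), dtype=float)
    for tau in range(1, window + 1):
        out[:, tau - 1 :: window] = x[burn_in - tau : T - tau]
    return out


class CVEngine:
    """Cross-validated likelihood evaluator with shared precomputation.

    Builds the full lagged feature matrices once, caches per-fold Gram
    matrices for the (quadratic) glial fits, and memoises per-cell CV
    vectors keyed by the cell's permitted-sender mask rows, so repeated
    structure comparisons (per-pair tests, the structure search, surrogate
    re-runs) never refit an already-evaluated sub-model.
    """

    def __init__(
        self,
        obs: ObservationSeries,
        windows: HistoryWindows,
        prior: PriorConfig,
        folds: Optional[FoldPlan] = None,
        K: int = 10,
        positive_ng: bool = False,
    ) -> None:
        self.obs = obs
        self.windows = windows
        self.prior = prior
        self.positive_ng = positive_ng
        burn = windows.burn_in
        T_eff = obs.T - burn
        self.folds = folds if folds is not None else make_folds(T_eff, K)
        if self.folds.n_usable != T_eff:
            raise ValueError(
                f"fold plan covers {self.folds.n_usable} bins but the series"
                f" has {T_eff} usable bins"
            )
        spk = obs.spikes.astype(float)
        ones = np.ones((T_eff, 1))
        # neuron-side lagged features; spike-history columns are kept sparse
        # (sub-hertz firing makes them ~99% zeros)
        self._spk_lag_n = scipy.sparse.csc_matrix(_lagged(spk, windows.t_nn, burn))
        self._glia_lag_n = _lagged(obs.glia, windows.t_gn, burn)
        self.y_spk = spk[burn:]
        # glia-side design
        self.Xg = np.hstack([ones, _lagged(spk, windows.t_ng, burn),
                             _lagged(obs.glia, windows.t_gg, burn)])
        self.y_glia = obs.glia[burn:]
        # per-fold sufficient statistics for the quadratic glial fits
        self._gram_full = self.Xg.T @ self.Xg
        self._xty_full = self.Xg.T @ self.y_glia
        self._yty_full = np.einsum("ij,ij->j", self.y_glia, self.y_glia)
        self._gram_fold, self._xty_fold, self._yty_fold = [], [], []
        for start, stop in self.folds.fold_bounds:
            Xf = self.Xg[start:stop]
            yf = self.y_glia[start:stop]
            self._gram_fold.append(Xf.T @ Xf)
            self._xty_fold.append(Xf.T @ yf)
            self._yty_fold.append(np.einsum("ij,ij->j", yf, yf))
        self._cache: dict = {}

    # -- column bookkeeping -------------------------------------------------

    @staticmethod
    def _sender_cols(senders: np.ndarray, window: int) -> np.ndarray:
        return np.concatenate([
            np.arange(s * window, (s + 1) * window) for s in senders
        ]) if len(senders) else np.empty(0, dtype=int)

    def _glia_cols(self, ng_row: np.ndarray, gg_row: np.ndarray) -> np.ndarray:
        w = self.windows
        N = self.obs.n_neurons
        idx = [0]
        for s in np.flatnonzero(ng_row):
            idx.extend(range(1 + s * w.t_ng, 1 + (s + 1) * w.t_ng))
        off = 1 + N * w.t_ng
        for s in np.flatnonzero(gg_row):
            idx.extend(range(off + s * w.t_gg, off + (s + 1) * w.t_gg))
        return np.asarray(idx)

    def _penalty(self, specs: list[tuple[int, int, float, float]]) -> np.ndarray:
        """Block-diagonal penalty: intercept, then (count, window, lam, eta)."""
        size = 1 + sum(c * t for c, t, _, _ in specs)
        P = np.zeros((size, size))
        pos = 1
        for count, t, lam, eta in specs:
            blk = penalty_matrix(t, lam, eta)
            for _ in range(count):
                P[pos : pos + t, pos : pos + t] = blk
                pos += t
        return P

    # -- per-cell cross-validated likelihood --------------------------------

    def neuron_cv(self, i: int, nn_row: np.ndarray, gn_row: np.ndarray) -> np.ndarray:
        """Per-fold held-out mean log-likelihood of neuron ``i``."""
        nn_row = np.asarray(nn_row, bool)
        gn_row = np.asarray(gn_row, bool)
        key = ("n", i, nn_row.tobytes(), gn_row.tobytes())
        if key in self._cache:
            return self._cache[key]
        w = self.windows
        # hybrid column order: [intercept | permitted glia lags | spike lags]
        dense = np.hstack([
            np.ones((self.folds.n_usable, 1)),
            self._glia_lag_n[:, self._sender_cols(np.flatnonzero(gn_row), w.t_gn)],
        ])
        sparse = self._spk_lag_n[:, self._sender_cols(np.flatnonzero(nn_row),
                                                      w.t_nn)]
        X = HybridDesign(dense, sparse)
        y = self.y_spk[:, i]
        P = self._penalty([
            (int(gn_row.sum()), w.t_gn, *self.prior.of_block("GN")),
            (int(nn_row.sum()), w.t_nn, *self.prior.of_block("NN")),
        ])
        beta_warm, *_ = fit_logistic_map(X, y, P)
        out = np.empty(self.folds.K)
        for k, (start, stop) in enumerate(self.folds.fold_bounds):
            Xtr = X.take_rows([(0, start), (stop, self.folds.n_usable)])
            ytr = np.concatenate([y[:start], y[stop:]])
            beta, converged, gnorm, _ = fit_logistic_map(
                Xtr, y=ytr, P=P, beta0=beta_warm
            )
            if not converged:
                raise RuntimeError(
                    f"neuron {i}, fold {k}: logistic MAP fit did not converge"
                    f" (grad norm {gnorm:.2e})"
                )
            a = X.take_rows([(start, stop)]).matvec(beta)
            out[k] = float(np.mean(y[start:stop] * a - np.logaddexp(0.0, a)))
        self._cache[key] = out
        return out

    def glia_cv(self, j: int, ng_row: np.ndarray, gg_row: np.ndarray) -> np.ndarray:
        """Per-fold held-out mean log-likelihood of glial cell ``j``."""
        ng_row = np.asarray(ng_row, bool)
        gg_row = np.asarray(gg_row, bool)
        key = ("g", j, ng_row.tobytes(), gg_row.tobytes(), self.positive_ng)
        if key in self._cache:
            return self._cache[key]
        idx = self._glia_cols(ng_row, gg_row)
        w = self.windows
        P = self._penalty([
            (int(ng_row.sum()), w.t_ng, *self.prior.of_block("NG")),
            (int(gg_row.sum()), w.t_gg, *self.prior.of_block("GG")),
        ])
        t_ng = self.windows.t_ng
        n_ng = int(ng_row.sum())
        nonneg = np.zeros(len(idx), bool)
        nonneg[1 : 1 + n_ng * t_ng] = True  # NG columns follow the intercept
        out = np.empty(self.folds.K)
        for k, (start, stop) in enumerate(self.folds.fold_bounds):
            gram = (self._gram_full - self._gram_fold[k])[np.ix_(idx, idx)]
            xty = (self._xty_full - self._xty_fold[k])[idx, j]
            yty = float(self._yty_full[j] - self._yty_fold[k][j])
            n_train = self.folds.n_usable - (stop - start)
            A = gram + 2.0 * P
            if self.positive_ng and n_ng:
                theta = solve_bound_qp(A, xty, nonneg)
            else:
                theta = np.linalg.solve(A, xty)
            rss = yty - 2.0 * theta @ xty + theta @ gram @ theta
            s2 = max(rss / n_train, 1e-300)
            mu = self.Xg[start:stop][:, idx] @ theta
            r = self.y_glia[start:stop, j] - mu
            out[k] = float(
                np.mean(-0.5 * np.log(2.0 * np.pi * s2) - r * r / (2.0 * s2))
            )
        self._cache[key] = out
        return out

    def structure_cv(self, structure: NetworkStructure) -> np.ndarray:
        """Cells x folds held-out log-likelihood matrix under ``structure``."""
        rows = [
            self.neuron_cv(i, structure.mask_nn[i], structure.mask_gn[i])
            for i in range(self.obs.n_neurons)
        ]
        rows += [
            self.glia_cv(j, structure.mask_ng[j], structure.mask_gg[j])
            for j in range(self.obs.n_glia)
        ]
        return np.vstack(rows)


def cv_likelihood(
    obs: ObservationSeries,
    structure: NetworkStructure,
    windows: HistoryWindows,
    prior: PriorConfig,
    folds: Optional[FoldPlan] = None,
    engine: Optional[CVEngine] = None,
) -> CVReport:
    """K-fold cross-validated likelihood of every cell under a structure."""
    if engine is None:
        engine = CVEngine(obs, windows, prior, folds)
    return CVReport(engine.structure_cv(structure), structure, prior, windows)


# ---------------------------------------------------------------------------
# per-connection tests
# ---------------------------------------------------------------------------

def test_gn_connection(
    obs: ObservationSeries,
    j: int,
    i: int,
    windows: HistoryWindows,
    prior: PriorConfig,
    folds: Optional[FoldPlan] = None,
    alpha: float = ALPHA,
    engine: Optional[CVEngine] = None,
) -> ConnectionTest:
    """Test the glia ``j`` -> neuron ``i`` connection.

    Compares M0 (no glia-to-neuron connections at all) against Mj (only glia
    ``j``'s connections to neurons present) on neuron ``i``'s per-fold
    held-out log-likelihood; one-sided for a positive gain.
    """
    if engine is None:
        engine = CVEngine(obs, windows, prior, folds)
    nn_full = np.ones(obs.n_neurons, bool)
    gn_none = np.zeros(obs.n_glia, bool)
    gn_j = gn_none.copy()
    gn_j[j] = True
    deltas = engine.neuron_cv(i, nn_full, gn_j) - engine.neuron_cv(i, nn_full, gn_none)
    return _make_test(j, i, "GN", deltas, alpha)


def test_ng_connection(
    obs: ObservationSeries,
    i: int,
    j: int,
    windows: HistoryWindows,
    prior: PriorConfig,
    folds: Optional[FoldPlan] = None,
    alpha: float = ALPHA,
    engine: Optional[CVEngine] = None,
) -> ConnectionTest:
    """Test the neuron ``i`` -> glia ``j`` connection by single-pair removal.

    Compares the full structure against the full structure minus this one
    connection on glia ``j``'s held-out log-likelihood; one-sided for a
    positive loss caused by the removal.
    """
    if engine is None:
        engine = CVEngine(obs, windows, prior, folds)
    ng_full = np.ones(obs.n_neurons, bool)
    gg_full = np.ones(obs.n_glia, bool)
    ng_minus = ng_full.copy()
    ng_minus[i] = False
    deltas = engine.glia_cv(j, ng_full, gg_full) - engine.glia_cv(j, ng_minus, gg_full)
    return _make_test(i, j, "NG", deltas, alpha)


def test_ng_block(
    obs: ObservationSeries,
    j: int,
    windows: HistoryWindows,
    prior: PriorConfig,
    folds: Optional[FoldPlan] = None,
    alpha: float = ALPHA,
    engine: Optional[CVEngine] = None,
) -> ConnectionTest:
    """Diagnostic block-level test: all neuron inputs to glia ``j`` vs none."""
    if engine is None:
        engine = CVEngine(obs, windows, prior, folds)
    ng_full = np.ones(obs.n_neurons, bool)
    ng_none = np.zeros(obs.n_neurons, bool)
    gg_full = np.ones(obs.n_glia, bool)
    deltas = engine.glia_cv(j, ng_full, gg_full) - engine.glia_cv(j, ng_none, gg_full)
    return _make_test(-1, j, "NG", deltas, alpha)


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    structure: NetworkStructure
    tests: list[ConnectionTest]
    trace: list[tuple[str, float]] = field(default_factory=list)


def _test_gn_removal(engine: CVEngine, obs: ObservationSeries, j: int, i: int,
                     alpha: float) -> ConnectionTest:
    """Subtractive G->N variant: full GN block vs full minus one pair."""
    nn_full = np.ones(obs.n_neurons, bool)
    gn_full = np.ones(obs.n_glia, bool)
    gn_minus = gn_full.copy()
    gn_minus[j] = False
    deltas = engine.neuron_cv(i, nn_full, gn_full) \
        - engine.neuron_cv(i, nn_full, gn_minus)
    return _make_test(j, i, "GN", deltas, alpha)


def _test_ng_addition(engine: CVEngine, obs: ObservationSeries, i: int, j: int,
                      alpha: float) -> ConnectionTest:
    """Additive N->G variant: empty NG block vs empty plus one pair."""
    gg_full = np.ones(obs.n_glia, bool)
    ng_none = np.zeros(obs.n_neurons, bool)
    ng_i = ng_none.copy()
    ng_i[i] = True
    deltas = engine.glia_cv(j, ng_i, gg_full) \
        - engine.glia_cv(j, ng_none, gg_full)
    return _make_test(i, j, "NG", deltas, alpha)


def search_structure(
    obs: ObservationSeries,
    windows: HistoryWindows,
    prior: PriorConfig,
    folds: Optional[FoldPlan] = None,
    alpha: float = ALPHA,
    engine: Optional[CVEngine] = None,
    gn_strategy: str = "additive",
    ng_strategy: str = "subtractive",
) -> SearchResult:
    """Incremental search for the cross-block connection structure.

    The within-block N->N and G->G connections stay full.  With the default
    strategies the G->N block is grown additively from empty: every (glia j,
    neuron i) pair is tested with the Mj-vs-M0 t-statistic, and significant
    pairs are added greedily (in decreasing t order) provided each addition
    also improves the receiving neuron's cross-validated likelihood under
    the structure grown so far, so the likelihood trace of accepted
    additions is non-decreasing.  The N->G block is pruned subtractively
    from full: a connection is kept only when its single-pair removal causes
    a significant held-out loss.  The opposite direction is available per
    block (``gn_strategy="subtractive"`` prunes G->N from full;
    ``ng_strategy="additive"`` grows N->G from empty) for experimentation.
    """
    if gn_strategy not in ("additive", "subtractive"):
        raise ValueError(f"unknown gn_strategy {gn_strategy!r}")
    if ng_strategy not in ("additive", "subtractive"):
        raise ValueError(f"unknown ng_strategy {ng_strategy!r}")
    if engine is None:
        engine = CVEngine(obs, windows, prior, folds)
    N, G = obs.n_neurons, obs.n_glia
    structure = NetworkStructure.within_blocks_only(N, G)
    structure.mask_ng[:] = True
    tests: list[ConnectionTest] = []
    trace: list[tuple[str, float]] = []
    nn_full = np.ones(N, bool)

    # --- glia -> neuron -----------------------------------------------------
    if gn_strategy == "additive":
        gn_tests = [
            test_gn_connection(obs, j, i, windows, prior, alpha=alpha,
                               engine=engine)
            for j in range(G)
            for i in range(N)
        ]
        tests.extend(gn_tests)
        candidates = sorted(
            (t for t in gn_tests if t.accepted and not t.degenerate),
            key=lambda t: -t.t_value,
        )
        cv_neuron = {
            i: float(np.mean(engine.neuron_cv(i, nn_full, np.zeros(G, bool))))
            for i in range(N)
        }
        trace.append(("start", float(np.mean(list(cv_neuron.values())))))
        for cand in candidates:
            j, i = cand.sender, cand.receiver
            row = structure.mask_gn[i].copy()
            row[j] = True
            new_cv = float(np.mean(engine.neuron_cv(i, nn_full, row)))
            if new_cv >= cv_neuron[i]:
                structure.mask_gn[i, j] = True
                cv_neuron[i] = new_cv
                trace.append((f"add GN {j}->{i}",
                              float(np.mean(list(cv_neuron.values())))))
    else:
        structure.mask_gn[:] = True
        for j in range(G):
            for i in range(N):
                t = _test_gn_removal(engine, obs, j, i, alpha)
                tests.append(t)
                if not t.accepted:
                    structure.mask_gn[i, j] = False

    # --- neuron -> glia -----------------------------------------------------
    if ng_strategy == "subtractive":
        for j in range(G):
            for i in range(N):
                t = test_ng_connection(obs, i, j, windows, prior, alpha=alpha,
                                       engine=engine)
                tests.append(t)
                if not t.accepted:
                    structure.mask_ng[j, i] = False
    else:
        structure.mask_ng[:] = False
        for j in range(G):
            for i in range(N):
                t = _test_ng_addition(engine, obs, i, j, alpha)
                tests.append(t)
                if t.accepted:
                    structure.mask_ng[j, i] = True
    return SearchResult(structure, tests, trace)


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

def tune_hyperparameters(
    obs: ObservationSeries,
    candidate_grids: Optional[dict] = None,
    tie_constraints: str = "paired",
    folds_K: int = 10,
) -> tuple[HistoryWindows, PriorConfig, pd.DataFrame]:
    """Exhaustive grid search for the tied tuning parameters.

    Under the default ("paired") tie constraints the neuron-side parameters
    (t_nn = t_gn, lam_nn = lam_gn, eta_nn = eta_gn) are chosen to maximize
    the neuron-wise cross-validated likelihood L^N of the full structure and
    the glia-side parameters (t_ng = t_gg, ...) to maximize L^G; the two
    sides decouple because each side's likelihood depends only on its own
    receivers' features.  Returns the argmax plus the full score table.
    """
    grids = {"window": [10, 30, 50], "lam": [0.1, 1.0, 10.0],
             "eta": [1.0, 10.0, 100.0]}
    if candidate_grids:
        grids.update(candidate_grids)
    for key in ("window", "lam", "eta"):
        if len(grids[key]) == 0:
            raise ValueError(f"empty candidate grid for {key!r}")
    if tie_constraints != "paired":
        raise NotImplementedError("only the paired tie constraints are built in")

    structure = NetworkStructure.full(obs.n_neurons, obs.n_glia)
    records = []
    best = {"neuron": (-np.inf, None), "glia": (-np.inf, None)}
    for window, lam, eta in itertools.product(
        grids["window"], grids["lam"], grids["eta"]
    ):
        windows = HistoryWindows(window, window, window, window)
        prior = PriorConfig(lam, lam, lam, lam, eta, eta, eta, eta)
        engine = CVEngine(obs, windows, prior, K=folds_K)
        L_N = float(np.mean([
            np.mean(engine.neuron_cv(i, structure.mask_nn[i], structure.mask_gn[i]))
            for i in range(obs.n_neurons)
        ]))
        L_G = float(np.mean([
            np.mean(engine.glia_cv(j, structure.mask_ng[j], structure.mask_gg[j]))
            for j in range(obs.n_glia)
        ])) if obs.n_glia else -np.inf
        records.append({"window": window, "lam": lam, "eta": eta,
                        "L_N": L_N, "L_G": L_G})
        if L_N > best["neuron"][0]:
            best["neuron"] = (L_N, (window, lam, eta))
        if L_G > best["glia"][0]:
            best["glia"] = (L_G, (window, lam, eta))

    wn, ln, en = best["neuron"][1]
    if obs.n_glia:
        wg, lg, eg = best["glia"][1]
    else:
        wg, lg, eg = wn, ln, en
    windows = HistoryWindows(t_nn=wn, t_gn=wn, t_ng=wg, t_gg=wg)
    prior = PriorConfig(lam_nn=ln, lam_gn=ln, lam_ng=lg, lam_gg=lg,
                        eta_nn=en, eta_gn=en, eta_ng=eg, eta_gg=eg)
    return windows, prior, pd.DataFrame.from_records(records)
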