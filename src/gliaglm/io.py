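"""Readers, writers, run configuration and the end-to-end pipeline.

Observation series round-trip through HDF5 (datasets ``spikes`` [T x N,
uint8] and ``glia`` [T x G, float]; attributes ``bin_ms`` and ``coords``)
and CSV (one column per cell, header "<kind>:<index>"; bin width in a
``# bin_ms=...`` comment line).  Parameter bundles serialize to HDF5
(``/neurons/{i}/...``, ``/glia/{j}/...``) and to a flat long-format CSV.
Time bins are 0-indexed everywhere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import selection, summarize, surrogates
from . import simulate as sim  # noqa: F401 -- the submodule, not the function

if not hasattr(sim, "build_scenario"):  # package re-exports shadow the module
    import importlib

    sim = importlib.import_module("gliaglm.simulate")
from .fit import fit_glia, fit_glia_positive, fit_neuron
from .model import (
    GliaParams,
    HistoryWindows,
    NetworkStructure,
    NeuronParams,
    ObservationSeries,
    PriorConfig,
)

logger = logging.getLogger("gliaglm")

__all__ = [
    "RunConfig",
    "read_observation",
    "write_observation",
    "read_params",
    "write_params",
    "params_to_frame",
    "tests_to_frame",
    "structure_to_frame",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# observation series
# ---------------------------------------------------------------------------

def write_observation(obs: ObservationSeries, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=obs.spikes, dtype="uint8")
            f.create_dataset("glia", data=obs.glia)
            f.attrs["bin_ms"] = obs.bin_width * 1000.0
            if obs.coords is not None:
                f.attrs["coords"] = obs.coords
    elif path.suffix == ".csv":
        cols = {f"neuron:{i}": obs.spikes[:, i] for i in range(obs.n_neurons)}
        cols.update({f"glia:{j}": obs.glia[:, j] for j in range(obs.n_glia)})
        with open(path, "w") as fh:
            fh.write(f"# bin_ms={obs.bin_width * 1000.0}\n")
            pd.DataFrame(cols).to_csv(fh, index=False)
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")


def read_observation(path: str | Path) -> ObservationSeries:
    """Load an ObservationSeries, validating binarity and metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("spikes", "glia"):
                if name not in f:
                    raise ValueError(f"{path}: missing dataset {name!r}")
            spikes = f["spikes"][()]
            glia = f["glia"][()]
            if "bin_ms" not in f.attrs:
                raise ValueError(f"{path}: missing attribute 'bin_ms'")
            bin_width = float(f.attrs["bin_ms"]) / 1000.0
            coords = np.asarray(f.attrs["coords"]) if "coords" in f.attrs else None
    elif path.suffix == ".csv":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# bin_ms="):
                raise ValueError(f"{path}: missing '# bin_ms=' header line")
            bin_width = float(first.split("=", 1)[1]) / 1000.0
            table = pd.read_csv(fh)
        n_cols = [c for c in table.columns if c.startswith("neuron:")]
        g_cols = [c for c in table.columns if c.startswith("glia:")]
        unknown = set(table.columns) - set(n_cols) - set(g_cols)
        if unknown:
            raise ValueError(f"{path}: unrecognised columns {sorted(unknown)}")
        n_cols.sort(key=lambda c: int(c.split(":")[1]))
        g_cols.sort(key=lambda c: int(c.split(":")[1]))
        spikes = table[n_cols].to_numpy()
        glia = table[g_cols].to_numpy(dtype=float)
        coords = None
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")
    bad = ~np.isin(spikes, (0, 1))
    if bad.any():
        t, i = map(int, np.argwhere(bad)[0])
        raise ValueError(f"{path}: non-binary spike value at bin {t}, neuron {i}")
    return ObservationSeries(spikes, glia, bin_width=bin_width, coords=coords)


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

def write_params(
    neuron_params: Sequence[NeuronParams],
    glia_params: Sequence[GliaParams],
    path: str | Path,
) -> None:
    with h5py.File(path, "w") as f:
        for i, p in enumerate(neuron_params):
            grp = f.create_group(f"neurons/{i}")
            grp.create_dataset("bias", data=p.bias)
            grp.create_dataset("w_nn", data=p.w_nn)
            grp.create_dataset("w_gn", data=p.w_gn)
        for j, p in enumerate(glia_params):
            grp = f.create_group(f"glia/{j}")
            grp.create_dataset("bias", data=p.bias)
            grp.create_dataset("noise_var", data=p.noise_var)
            grp.create_dataset("w_ng", data=p.w_ng)
            grp.create_dataset("w_gg", data=p.w_gg)


def read_params(path: str | Path) -> tuple[list[NeuronParams], list[GliaParams]]:
    neuron_params, glia_params = [], []
    with h5py.File(path, "r") as f:
        if "neurons" in f:
            for i in sorted(f["neurons"], key=int):
                g = f[f"neurons/{i}"]
                neuron_params.append(NeuronParams(
                    float(g["bias"][()]), g["w_nn"][()], g["w_gn"][()]))
        if "glia" in f:
            for j in sorted(f["glia"], key=int):
                g = f[f"glia/{j}"]
                glia_params.append(GliaParams(
                    float(g["bias"][()]), float(g["noise_var"][()]),
                    g["w_ng"][()], g["w_gg"][()]))
    return neuron_params, glia_params


def params_to_frame(
    neuron_params: Sequence[NeuronParams],
    glia_params: Sequence[GliaParams],
) -> pd.DataFrame:
    """Flat long format: receiver, sender, block, lag, weight."""
    rows = []
    for i, p in enumerate(neuron_params):
        rows.append({"receiver": i, "sender": -1, "block": "bias", "lag": 0,
                     "weight": p.bias})
        for block, w in (("NN", p.w_nn), ("GN", p.w_gn)):
            for s, kernel in enumerate(w):
                for lag, val in enumerate(kernel, start=1):
                    rows.append({"receiver": i, "sender": s, "block": block,
                                 "lag": lag, "weight": float(val)})
    for j, p in enumerate(glia_params):
        rows.append({"receiver": j, "sender": -1, "block": "bias_glia",
                     "lag": 0, "weight": p.bias})
        rows.append({"receiver": j, "sender": -1, "block": "noise_var",
                     "lag": 0, "weight": p.noise_var})
        for block, w in (("NG", p.w_ng), ("GG", p.w_gg)):
            for s, kernel in enumerate(w):
                for lag, val in enumerate(kernel, start=1):
                    rows.append({"receiver": j, "sender": s, "block": block,
                                 "lag": lag, "weight": float(val)})
    return pd.DataFrame(rows, columns=["receiver", "sender", "block", "lag",
                                       "weight"])


def tests_to_frame(tests: Sequence[selection.ConnectionTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sender": t.sender, "receiver": t.receiver, "block": t.block,
          "mean_delta": float(np.mean(t.delta_per_fold)), "t": t.t_value,
          "p": t.p_value, "accepted": t.accepted, "degenerate": t.degenerate}
         for t in tests],
        columns=["sender", "receiver", "block", "mean_delta", "t", "p",
                 "accepted", "degenerate"],
    )


def structure_to_frame(structure: NetworkStructure) -> pd.DataFrame:
    rows = []
    for block in ("NN", "GN", "NG", "GG"):
        mask = structure.mask_of(block)
        for r in range(mask.shape[0]):
            for s in range(mask.shape[1]):
                rows.append({"block": block, "receiver": r, "sender": s,
                             "present": bool(mask[r, s])})
    return pd.DataFrame(rows, columns=["block", "receiver", "sender", "present"])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to/from YAML.

    ``traces`` points at an existing trace file; when omitted, a scenario is
    simulated from ``scenario`` (build_scenario keyword arguments).  Unknown
    keys in a config file are rejected.
    """

    out_dir: str = "gliaglm_run"
    traces: Optional[str] = None
    scenario: dict = field(default_factory=dict)
    windows: dict = field(default_factory=lambda: dict(
        t_nn=10, t_gn=10, t_ng=10, t_gg=10))
    prior: dict = field(default_factory=lambda: dict(
        lam_nn=1.0, lam_gn=1.0, lam_ng=1.0, lam_gg=1.0,
        eta_nn=10.0, eta_gn=10.0, eta_ng=10.0, eta_gg=10.0))
    K: int = 10
    alpha: float = 0.05
    tune: bool = False
    tune_grids: dict = field(default_factory=dict)
    n_surrogates: int = 0
    positive_ng: bool = False
    threshold_sd: float = 3.0
    smooth_bins: float = 5.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def history_windows(self) -> HistoryWindows:
        return HistoryWindows(**self.windows)

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.prior)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Full identification run: load/simulate -> (tune) -> search -> reports.

    Writes every artifact plus the resolved configuration and a log under
    ``config.out_dir``; reruns with the same config and seeds reproduce all
    outputs.  Returns the in-memory result bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    bundle: dict = {}
    try:
        config.to_yaml(out / "config.yml")

        stage = "load"
        scenario = None
        if config.traces is not None:
            obs = read_observation(config.traces)
            logger.info("loaded %s: %d bins, %d neurons, %d glia",
                        config.traces, obs.T, obs.n_neurons, obs.n_glia)
        else:
            stage = "simulate"
            scenario = sim.build_scenario(seed=config.seed, **config.scenario)
            obs = sim.simulate(scenario)
            write_observation(obs, out / "traces.h5")
            logger.info("simulated scenario: %d bins, %d neurons, %d glia "
                        "(seed %d)", obs.T, obs.n_neurons, obs.n_glia,
                        config.seed)
        bundle["obs"], bundle["scenario"] = obs, scenario

        windows, prior = config.history_windows(), config.prior_config()
        if config.tune:
            stage = "tune"
            windows, prior, table = selection.tune_hyperparameters(
                obs, config.tune_grids, folds_K=config.K)
            table.to_csv(out / "tuning.csv", index=False)
            logger.info("tuned windows=%s prior=%s", windows, prior)
        bundle["windows"], bundle["prior"] = windows, prior

        stage = "identify"
        engine = selection.CVEngine(obs, windows, prior, K=config.K,
                                    positive_ng=config.positive_ng)
        result = selection.search_structure(obs, windows, prior,
                                            alpha=config.alpha, engine=engine)
        bundle["structure"], bundle["tests"] = result.structure, result.tests
        tests_to_frame(result.tests).to_csv(out / "connections.csv", index=False)
        structure_to_frame(result.structure).to_csv(out / "structure.csv",
                                                    index=False)
        report = selection.cv_likelihood(obs, result.structure, windows, prior,
                                         engine=engine)
        pd.DataFrame(report.per_cell_per_fold).to_csv(out / "cv_report.csv",
                                                      index=False)
        bundle["cv_report"] = report
        logger.info("identify: %d GN and %d NG connections accepted",
                    int(result.structure.mask_gn.sum()),
                    int(result.structure.mask_ng.sum()))

        stage = "fit"
        glia_fitter = fit_glia_positive if config.positive_ng else fit_glia
        neuron_params = [
            fit_neuron(obs, i, windows, result.structure, prior).params
            for i in range(obs.n_neurons)
        ]
        glia_params = [
            glia_fitter(obs, j, windows, result.structure, prior).params
            for j in range(obs.n_glia)
        ]
        bundle["neuron_params"], bundle["glia_params"] = neuron_params, glia_params
        write_params(neuron_params, glia_params, out / "params.h5")
        params_to_frame(neuron_params, glia_params).to_csv(
            out / "params.csv", index=False)

        if config.n_surrogates > 0:
            stage = "surrogate"
            rows = []
            for j in range(obs.n_glia):
                for direction in ("glia_to_neuron", "neuron_to_glia"):
                    null = surrogates.bulk_count_test(
                        obs, j, direction, config.n_surrogates, windows, prior,
                        K=config.K, alpha=config.alpha,
                        seed=config.seed + 1000 + j)
                    rows.append({"glia": j, "direction": direction,
                                 "observed": null.observed_count,
                                 "p": null.p_value,
                                 "null_mean": float(null.null_counts.mean())})
                    logger.info("surrogate %s glia %d: observed=%d p=%.3f",
                                direction, j, null.observed_count, null.p_value)
            bundle["surrogate"] = pd.DataFrame(rows)
            bundle["surrogate"].to_csv(out / "surrogate.csv", index=False)

        stage = "summarize"
        sm = summarize.strength_matrix(neuron_params, glia_params,
                                       result.structure)
        pd.DataFrame(sm.values).to_csv(out / "strength_matrix.csv", index=False)
        sign_table, fractions = summarize.classify_sign(
            neuron_params, glia_params, result.structure)
        sign_table.to_csv(out / "sign_table.csv", index=False)
        bundle["strength"], bundle["sign_fractions"] = sm, fractions
        for block, mask in (("GN", result.structure.mask_gn),
                            ("NG", result.structure.mask_ng)):
            pairs = [(int(s), int(r)) for r, s in np.argwhere(mask)]
            if len(pairs) >= 2:
                avg = summarize.average_response(neuron_params, glia_params,
                                                 pairs, block)
                pd.DataFrame({"lag": np.arange(1, len(avg.mean) + 1),
                              "mean": avg.mean, "ci_low": avg.ci_low,
                              "ci_high": avg.ci_high}).to_csv(
                    out / f"average_response_{block.lower()}.csv", index=False)
                bundle[f"average_response_{block}"] = avg
        # mask_gn is (receiver neuron, sender glia); the test wants (glia, neuron)
        accepted_gn = [(int(j), int(i))
                       for i, j in np.argwhere(result.structure.mask_gn)]
        if obs.coords is not None and accepted_gn:
            dt = summarize.median_distance_test(
                accepted_gn,
                obs.coords[: obs.n_neurons], obs.coords[obs.n_neurons:],
                seed=config.seed + 2000)
            bundle["distance_test"] = dt
            with open(out / "distance_test.json", "w") as fh:
                json.dump({"observed_median": dt.observed_median,
                           "p_value": dt.p_value}, fh, indent=2)
        logger.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception as exc:
        logger.exception("pipeline failed during stage %r", stage)
        raise RuntimeError(f"pipeline failed during stage {stage!r}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return bundle
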