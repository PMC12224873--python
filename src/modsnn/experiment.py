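"""Experiment orchestration: the generate -> settle -> damage -> metrics
(-> reservoir) pipeline, replicate management, artifact writing, and small
deterministic fixtures for testing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as burst_mod
from . import effective as eff_mod
from .config import (CutSpec, ExperimentConfig, GrowthConfig, config_hash,
                     config_to_dict, stage_seed)
from .damage import ProtocolResult, run_protocol
from .dynamics import SpikeRaster, save_raster_hdf5
from .network import (AxonPath, NeuronPopulation, StructuralNetwork,
                      generate_network, save_network)
from .plasticity import settle

__all__ = ["RunManifest", "run_experiment", "run_replicate",
           "scenario_cuts", "make_fixture", "replicate_metrics"]

logger = logging.getLogger("modsnn")

SCENARIOS = ("intra_half", "intra_full", "inter_half", "inter_full",
             "nomod_half", "nomod_full")


def scenario_cuts(diameter: float) -> dict:
    """The six standard damage scenarios: intra-/inter-modular x half/full
    cuts on patterned networks, plus half/full cuts on unpatterned ones."""
    half = diameter / 2.0
    return {
        "intra_half": (True, CutSpec("perpendicular_to_tracks", "half",
                                     half_length=half)),
        "intra_full": (True, CutSpec("perpendicular_to_tracks", "full")),
        "inter_half": (True, CutSpec("parallel_to_tracks", "half",
                                     half_length=half)),
        "inter_full": (True, CutSpec("parallel_to_tracks", "full")),
        "nomod_half": (False, CutSpec("perpendicular_to_tracks", "half",
                                      half_length=half)),
        "nomod_full": (False, CutSpec("perpendicular_to_tracks", "full")),
    }


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    replicate_seeds: list
    outputs: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def replicate_metrics(result: ProtocolResult,
                      burst_config=None) -> pd.DataFrame:
    """Per-timepoint metrics for one damage sequence.

    Burst ratios are reported both vs the pre-damage epoch (baseline mode)
    and vs the matched undamaged control (control mode); weighted global
    efficiency is computed on the E->E plastic submatrix.
    """
    pre = result.snapshots[0]
    rows = []
    n_alive_pre = int(pre.alive.sum())
    for snap in result.snapshots:
        n_alive = int(snap.alive.sum())
        n_bursts = len(burst_mod.detect_bursts(snap.raster, burst_config,
                                               n_units=n_alive))
        row = {"timepoint": snap.label, "time_s": snap.time_s,
               "n_alive": n_alive, "n_bursts": n_bursts,
               "mean_rate_hz": snap.raster.mean_rate_hz(snap.alive)}
        if snap is not pre:
            with np.errstate(all="ignore"):
                row["burst_ratio_baseline"] = burst_mod.burst_ratio(
                    snap.raster, pre.raster, burst_config,
                    n_units_test=n_alive, n_units_reference=n_alive_pre)
            if snap.control_raster is not None:
                row["burst_ratio_control"] = burst_mod.burst_ratio(
                    snap.raster, snap.control_raster, burst_config,
                    n_units_test=n_alive, n_units_reference=n_alive_pre)
        # efficiency on the plastic weight matrix at this timepoint
        w = np.zeros((result.network.n_neurons, result.network.n_neurons))
        m = result.network.plastic
        w[result.network.pre[m], result.network.post[m]] = snap.weights[m]
        row["e_glob_w"] = eff_mod.global_efficiency(
            w, mode="synaptic", w_max=None, alive=snap.alive)
        rows.append(row)
    return pd.DataFrame(rows)


def run_replicate(cfg: ExperimentConfig, replicate: int,
                  scenario: str | None = None,
                  out_dir: Path | None = None) -> dict:
    """One full damage sequence for one replicate seed.

    ``scenario`` overrides cfg.cut/cfg.growth.patterned with one of the six
    standard scenarios; None uses the config as given.
    """
    seed = stage_seed(cfg.master_seed, "replicate", replicate)
    growth = cfg.growth
    cut = cfg.cut
    if scenario is not None:
        patterned, cut = scenario_cuts(growth.culture_diameter)[scenario]
        growth = GrowthConfig(**{**config_to_dict(growth),
                                 "patterned": patterned})
    growth = GrowthConfig(**{**config_to_dict(growth),
                             "seed": stage_seed(seed, "growth")})
    t0 = time.time()
    net = generate_network(growth)
    logger.info("replicate %d%s: generated %d neurons / %d edges (%.1fs)",
                replicate, f" [{scenario}]" if scenario else "",
                net.n_neurons, net.n_edges, time.time() - t0)

    net, (ts, ws) = settle(net, cfg.settle_s, noise=cfg.noise,
                           stdp=cfg.stdp, dynamics=cfg.dynamics,
                           seed=stage_seed(seed, "settle"), in_place=True)
    logger.info("replicate %d: settled %.0fs sim, mean w %.3f",
                replicate, cfg.settle_s, net.mean_ee_weight())

    result = run_protocol(net, cut, cfg.protocol, noise=cfg.noise,
                          stdp=cfg.stdp, dynamics=cfg.dynamics, seed=seed)
    metrics = replicate_metrics(result)
    metrics.insert(0, "replicate", replicate)
    if scenario is not None:
        metrics.insert(0, "scenario", scenario)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = f"{scenario or 'custom'}_rep{replicate}"
        h5 = out_dir / f"{tag}.h5"
        save_network(result.network, h5)
        import h5py
        for snap in result.snapshots:
            save_raster_hdf5(snap.raster, h5, group=f"rasters/{snap.label}")
            with h5py.File(h5, "a") as fh:
                g = fh.require_group(f"snapshots/{snap.label}")
                for name, data in (("W_edges", snap.weights),
                                   ("alive", snap.alive)):
                    if name in g:
                        del g[name]
                    g.create_dataset(name, data=data)
                g.attrs["time_s"] = snap.time_s
        metrics.to_csv(out_dir / f"{tag}_metrics.csv", index=False)
        pd.DataFrame({"time_s": ts, "mean_ee_weight": ws}).to_csv(
            out_dir / f"{tag}_settle_weights.csv", index=False)
    return {"network": result.network, "result": result, "metrics": metrics,
            "settle_trajectory": (ts, ws)}


def run_experiment(cfg: ExperimentConfig, out_dir,
                   scenarios=None) -> RunManifest:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    ``scenarios`` defaults to the six standard damage conditions; pass a
    subset (or [None] for the single configured cut) to restrict the batch.
    Partial results are preserved on stage failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenarios is None:
        scenarios = list(SCENARIOS)
    reps = range(cfg.protocol.n_replicates)
    manifest = RunManifest(
        config=config_to_dict(cfg), config_hash=config_hash(cfg),
        replicate_seeds=[stage_seed(cfg.master_seed, "replicate", r)
                         for r in reps],
        started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    tables = []
    for scenario in scenarios:
        for r in reps:
            key = f"{scenario or 'custom'}_rep{r}"
            try:
                out = run_replicate(cfg, r, scenario=scenario,
                                    out_dir=out_dir)
                tables.append(out["metrics"])
                manifest.outputs[key] = f"{key}_metrics.csv"
            except Exception as exc:  # preserve partial results
                logger.exception("stage failure in %s", key)
                manifest.errors[key] = repr(exc)
    if tables:
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out_dir / "burst_ratio_table.csv", index=False)
        manifest.outputs["summary"] = "burst_ratio_table.csv"
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(kind: str, seed: int = 0):
    """Small deterministic artifacts used throughout the test suite."""
    rng = np.random.default_rng(seed)
    if kind == "toy_network":
        # five neurons on a 3 mm dish with hand-placed straight axons
        positions = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0],
                              [0.0, 0.6], [0.0, -0.6]])
        is_exc = np.array([True, True, True, True, False])
        paths = [
            AxonPath(0, np.array([[-1.0, 0.0], [-0.1, 0.0]]), 0.9),
            AxonPath(1, np.array([[0.0, 0.0], [0.9, 0.0]]), 0.9),
            AxonPath(2, np.array([[1.0, 0.0], [1.2, 0.0]]), 0.2),
            AxonPath(3, np.array([[0.0, 0.6], [0.0, 0.1]]), 0.5),
            AxonPath(4, np.array([[0.0, -0.6], [0.0, -0.1]]), 0.5),
        ]
        pre = np.array([0, 1, 3, 4])
        post = np.array([1, 2, 1, 1])
        weight = np.array([3.0, 3.0, 3.0, -3.0])
        delay = np.array([2.0, 3.0, 1.0, 1.0])
        return StructuralNetwork(
            population=NeuronPopulation(positions, is_exc),
            axon_paths=paths, pre=pre, post=post, weight=weight,
            delay_ms=delay, config=GrowthConfig(culture_diameter=3.0))
    if kind == "scripted_raster":
        # 100 units, 10 s: three 30%-participation bursts and one 10% blip
        n, T = 100, 10_000.0
        lists = [[] for _ in range(n)]
        for onset, frac in [(1000, 0.3), (4000, 0.3), (7000, 0.3),
                            (8500, 0.1)]:
            units = rng.choice(n, size=int(frac * n), replace=False)
            for u in units:
                lists[u].append(onset + float(rng.integers(0, 150)))
        for u in range(n):
            lists[u] = sorted(lists[u])
        return SpikeRaster.from_lists(lists, duration_ms=T)
    if kind == "planted_partition":
        # 40 nodes, 4 blocks, p_in = 0.9, p_out = 0.05
        n, blocks = 40, 4
        labels = np.repeat(np.arange(blocks), n // blocks)
        p = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
        m = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(m, 0.0)
        return m, labels
    if kind == "cochleagram_set":
        from .config import ReservoirConfig
        from .reservoir import make_trial_set
        cfg = ReservoirConfig(n_samples_per_class=3,
                              trial_period_ms=2000.0,
                              target_duration_ms=500.0)
        return make_trial_set(cfg, rng)
    raise ValueError(f"unknown fixture kind {kind!r}")
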