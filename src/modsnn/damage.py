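"""Geometric lesions and the timed damage-recovery protocol.

A lesion is a straight cut segment: every neuron whose axon path intersects
the cut is considered dead (axonal transection), is excluded from all
further updates, and its connections are removed.  The protocol then
continues plasticity-on simulation, recording an evaluation raster and a
weight snapshot at each post-injury timepoint, alongside a matched
undamaged control evolved with the identical seeded noise stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (ConfigurationError, CutSpec, DamageProtocol,
                     DynamicsConfig, NoiseConfig, StdpParams, stage_seed)
from .dynamics import Simulator, SpikeRaster
from .network import StructuralNetwork

__all__ = ["sever", "severed_neurons", "random_edge_lesion",
           "TimepointSnapshot", "ProtocolResult", "run_protocol"]


def _segments_intersect(p0, p1, q0, q1) -> np.ndarray:
    """Vectorized proper/improper segment intersection test.

    p0, p1: (M, 2) segment endpoints; q0, q1: (2,) the cut endpoints.
    """
    def cross(o, a, b):
        return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
                - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))

    q0 = np.broadcast_to(q0, p0.shape)
    q1 = np.broadcast_to(q1, p0.shape)
    d1 = cross(q0, q1, p0)
    d2 = cross(q0, q1, p1)
    d3 = cross(p0, p1, q0)
    d4 = cross(p0, p1, q1)
    proper = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0)) \
        & (d1 != 0) & (d2 != 0) & (d3 != 0) & (d4 != 0)

    def on_seg(o, a, b):
        # b collinear with o-a and within its bounding box
        in_x = (np.minimum(o[..., 0], a[..., 0]) <= b[..., 0]) \
            & (b[..., 0] <= np.maximum(o[..., 0], a[..., 0]))
        in_y = (np.minimum(o[..., 1], a[..., 1]) <= b[..., 1]) \
            & (b[..., 1] <= np.maximum(o[..., 1], a[..., 1]))
        return in_x & in_y

    collinear = ((d1 == 0) & on_seg(q0, q1, p0)) \
        | ((d2 == 0) & on_seg(q0, q1, p1)) \
        | ((d3 == 0) & on_seg(p0, p1, q0)) \
        | ((d4 == 0) & on_seg(p0, p1, q1))
    return proper | collinear


def severed_neurons(network: StructuralNetwork, cut: CutSpec) -> np.ndarray:
    """Ids of neurons whose axon path intersects the cut segment."""
    diameter = (network.config.culture_diameter if network.config is not None
                else 2.0 * np.max(np.hypot(
                    *network.population.positions.T), initial=1.0))
    q0, q1 = cut.segment(diameter)
    for q in (q0, q1):
        if np.hypot(*q) > diameter / 2.0 + 1e-9:
            raise ConfigurationError("cut extends outside the culture")
    dead = []
    for path in network.axon_paths:
        v = path.vertices
        if len(v) < 2:
            continue
        if _segments_intersect(v[:-1], v[1:], q0, q1).any():
            dead.append(path.origin)
    return np.array(sorted(dead), dtype=np.int64)


def sever(network: StructuralNetwork, cut: CutSpec,
          in_place: bool = False) -> tuple:
    """Apply the lesion; returns ``(lesioned_network, dead_ids)``.

    Dead neurons keep their row/column (indices stay stable) but are marked
    not-alive and their edge weights zeroed.  Idempotent.
    """
    dead = severed_neurons(network, cut)
    net = network if in_place else network.copy()
    if dead.size:
        net.alive[dead] = False
        gone = ~net.alive[net.pre] | ~net.alive[net.post]
        net.weight[gone] = 0.0
    return net, dead


def random_edge_lesion(network: StructuralNetwork, n_edges: int,
                       rng: np.random.Generator,
                       in_place: bool = False) -> tuple:
    """Control lesion: delete ``n_edges`` random alive edges (no neuron
    death), matching the connection count removed by a geometric cut."""
    net = network if in_place else network.copy()
    candidates = np.nonzero(net.edge_alive & (net.weight != 0.0))[0]
    n_edges = min(n_edges, candidates.size)
    chosen = rng.choice(candidates, size=n_edges, replace=False)
    net.weight[chosen] = 0.0
    return net, chosen


# ---------------------------------------------------------------------------
# protocol

@dataclass
class TimepointSnapshot:
    label: str
    time_s: float                 # simulated seconds post-injury (pre: < 0)
    raster: SpikeRaster
    weights: np.ndarray           # full edge-weight vector at epoch end
    alive: np.ndarray
    control_raster: SpikeRaster | None = None


@dataclass
class ProtocolResult:
    snapshots: list               # [pre, t0, ...] in time order
    dead: np.ndarray
    network: StructuralNetwork    # damaged network at the final state
    control: StructuralNetwork    # matched control at the final state

    def snapshot(self, label: str) -> TimepointSnapshot:
        for s in self.snapshots:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list:
        return [s.label for s in self.snapshots]


def _timepoint_label(t_s: float) -> str:
    if t_s < 60:
        return f"t{t_s:g}s" if t_s > 0 else "t0"
    if t_s < 3600:
        return f"t{t_s / 60:g}m"
    return f"t{t_s / 3600:g}h"


def run_protocol(network: StructuralNetwork, cut: CutSpec | None,
                 protocol: DamageProtocol,
                 noise: NoiseConfig | None = None,
                 stdp: StdpParams | None = None,
                 dynamics: DynamicsConfig | None = None,
                 seed: int = 0,
                 with_control: bool = True) -> ProtocolResult:
    """Run the timed damage-recovery sequence on a settled network.

    Records a pre-damage epoch, applies the cut, then simulates continuously
    (STDP on unless the protocol disables it), capturing an evaluation
    raster + weight snapshot at each protocol timepoint.  A deep copy of the
    settled network is evolved undamaged under the matched noise stream and
    sampled at the same timepoints (ratio-to-control metrics).
    ``cut=None`` runs the undamaged schedule only (both copies undamaged).
    """
    noise = noise if noise is not None else NoiseConfig()
    epoch_ms = protocol.epoch_s * 1000.0
    plast = protocol.stdp_during_recovery

    damaged = network.copy()
    sim = Simulator(damaged, noise=noise, stdp=stdp, dynamics=dynamics,
                    plasticity=plast, seed=stage_seed(seed, "damage"))
    csim = None
    control = network.copy()
    if with_control:
        # same seed as the damaged run: identical pre-damage history, and
        # (because dead neurons still consume their noise draws) the control
        # sees the exact drive the damaged network would have received
        csim = Simulator(control, noise=noise, stdp=stdp, dynamics=dynamics,
                         plasticity=plast, seed=stage_seed(seed, "damage"))

    snapshots: list[TimepointSnapshot] = []

    # pre-damage epoch (shared history contract: both copies start from the
    # same settled network)
    pre_raster = sim.run(epoch_ms)
    sim.write_back_weights()
    pre_ctrl = csim.run(epoch_ms) if csim is not None else None
    if csim is not None:
        csim.write_back_weights()
    snapshots.append(TimepointSnapshot(
        "pre", -protocol.epoch_s, pre_raster, damaged.weight.copy(),
        damaged.alive.copy(), pre_ctrl))

    # lesion
    if cut is not None:
        _, dead = sever(damaged, cut, in_place=True)
        sim.refresh_after_lesion()
    else:
        dead = np.empty(0, dtype=np.int64)

    prev = 0.0
    for t_s in protocol.timepoints_s:
        gap_ms = (t_s - prev) * 1000.0
        if gap_ms > 0:
            sim.run(gap_ms)
            if csim is not None:
                csim.run(gap_ms)
        raster = sim.run(epoch_ms)
        sim.write_back_weights()
        ctrl = None
        if csim is not None:
            ctrl = csim.run(epoch_ms)
            csim.write_back_weights()
        snapshots.append(TimepointSnapshot(
            _timepoint_label(t_s), t_s, raster, damaged.weight.copy(),
            damaged.alive.copy(), ctrl))
        prev = t_s + protocol.epoch_s

    return ProtocolResult(snapshots=snapshots, dead=dead,
                          network=damaged, control=control)
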