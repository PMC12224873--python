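"""Nearest-neighbour STDP with soft weight bounds.

The weight update for an E->E synapse i -> j with conduction delay d_ij uses
the delivery-corrected timing difference dt = t_j - t_i - d_ij:

    dt > 0  (causal):      dw = eta_plus  * (1 - w/w_max) * exp(-dt/tau)
    dt <= 0 (anti-causal): dw = eta_minus * (w/w_max)     * exp( dt/tau)

Only nearest-neighbour spike pairs contribute: each postsynaptic spike pairs
with the most recent presynaptic delivery, and each presynaptic delivery
pairs with the most recent postsynaptic spike.  With these soft bounds the
stationary mean weight is w_max * eta_plus / (eta_plus - eta_minus), which
also sets the magnitude of the fixed E->I, I->E and I->I weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, DynamicsConfig, NoiseConfig, StdpParams
from .network import StructuralNetwork

__all__ = ["stdp_delta", "PairingState", "apply_stdp",
           "equilibrium_mean_weight", "settle"]


def stdp_delta(w: float, delta_t: float, params: StdpParams) -> float:
    """Weight change for one spike pairing; the implied new weight
    ``w + dw`` is clamped to [0, w_max]."""
    if not 0.0 <= w <= params.w_max:
        raise ValueError(f"weight {w} outside [0, {params.w_max}]")
    if delta_t > 0:
        dw = params.eta_plus * (1.0 - w / params.w_max) \
            * np.exp(-delta_t / params.tau)
    else:
        dw = params.eta_minus * (w / params.w_max) \
            * np.exp(delta_t / params.tau)
    return float(np.clip(w + dw, 0.0, params.w_max) - w)


def equilibrium_mean_weight(params: StdpParams) -> float:
    """Stationary mean E->E weight, w_max * eta+ / (eta+ - eta-)."""
    denom = params.eta_plus - params.eta_minus
    if denom == 0:
        raise ConfigurationError("eta_plus - eta_minus must be nonzero")
    return params.w_max * params.eta_plus / denom


@dataclass
class PairingState:
    """Nearest-neighbour pairing memory for the plastic (E->E) synapses:
    the last presynaptic delivery time and last postsynaptic spike time."""

    last_pre_delivery: np.ndarray   # (E_plastic,) ms, -inf if none yet
    last_post: np.ndarray           # (N,) ms, -inf if none yet

    @classmethod
    def fresh(cls, n_plastic: int, n_neurons: int) -> "PairingState":
        return cls(np.full(n_plastic, -np.inf), np.full(n_neurons, -np.inf))


def apply_stdp(spike_lists, network: StructuralNetwork,
               pairing: PairingState | None, params: StdpParams,
               delay_ms: np.ndarray | None = None,
               t_max: float | None = None) -> np.ndarray:
    """Apply nearest-neighbour STDP for the spikes of one epoch.

    ``spike_lists`` holds per-neuron, strictly increasing spike times.  For
    every plastic synapse the presynaptic train is shifted by its delay
    (delivery times); deliveries and postsynaptic spikes are then processed
    in time order (deliveries first on ties).  A postsynaptic spike pairs
    with the most recent delivery; a delivery pairs with the most recent
    postsynaptic spike (anti-causal by construction).  Deliveries at or
    after ``t_max`` (e.g. past the epoch end) are ignored.  Returns the full
    edge weight vector with plastic entries updated; non-E->E weights untouched.
    """
    plastic = np.nonzero(network.plastic)[0]
    weights = network.weight.copy()
    if pairing is None:
        pairing = PairingState.fresh(len(plastic), network.n_neurons)
    delays = network.delay_ms if delay_ms is None else delay_ms

    for k, s in enumerate(plastic):
        i, j = network.pre[s], network.post[s]
        d = delays[s]
        deliveries = np.asarray(spike_lists[i], dtype=float) + d
        if t_max is not None:
            deliveries = deliveries[deliveries < t_max]
        posts = np.asarray(spike_lists[j], dtype=float)
        w = weights[s]
        last_p = pairing.last_pre_delivery[k]
        last_q = pairing.last_post[j]
        a = b = 0
        while a < len(deliveries) or b < len(posts):
            take_delivery = (b >= len(posts) or
                             (a < len(deliveries)
                              and deliveries[a] <= posts[b]))
            if take_delivery:
                t = deliveries[a]
                if np.isfinite(last_q):
                    w += stdp_delta(w, last_q - t, params)
                last_p = t
                a += 1
            else:
                t = posts[b]
                if np.isfinite(last_p):
                    w += stdp_delta(w, t - last_p, params)
                last_q = t
                b += 1
        weights[s] = w
        pairing.last_pre_delivery[k] = last_p
    for j in range(network.n_neurons):
        if len(spike_lists[j]):
            pairing.last_post[j] = max(pairing.last_post[j],
                                       spike_lists[j][-1])
    return weights


def settle(network: StructuralNetwork, duration_s: float,
           noise: NoiseConfig | None = None,
           stdp: StdpParams | None = None,
           dynamics: DynamicsConfig | None = None,
           seed: int | None = None,
           record_every_s: float = 10.0,
           in_place: bool = False):
    """Run plasticity-on dynamics until the weight distribution settles.

    Returns ``(network, trajectory)`` where ``trajectory`` is a
    (time_s, mean_ee_weight) record sampled every ``record_every_s``
    simulated seconds.  Zero duration returns the network unchanged.
    """
    from .dynamics import Simulator

    net = network if in_place else network.copy()
    times = [0.0]
    means = [net.mean_ee_weight()]
    if duration_s <= 0:
        return net, (np.array(times), np.array(means))

    sim = Simulator(net, noise=noise, stdp=stdp, dynamics=dynamics,
                    plasticity=True, seed=seed)
    remaining = duration_s
    elapsed = 0.0
    chunk = max(min(record_every_s, duration_s), 1e-3)
    while remaining > 1e-9:
        step_s = min(chunk, remaining)
        sim.run(step_s * 1000.0)
        elapsed += step_s
        remaining -= step_s
        sim.write_back_weights()
        times.append(elapsed)
        means.append(net.mean_ee_weight())
    return net, (np.array(times), np.array(means))
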