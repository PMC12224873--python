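"""Spiking dynamics: Izhikevich neurons, exponential synaptic currents with
conduction delays, Poisson background drive, and online nearest-neighbour
STDP on E->E synapses.

The membrane potential obeys

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_E + I_I + I_in
    du/dt = a (b v - u),        v >= 30 mV  =>  v <- c, u <- u + d

integrated with a fixed 1 ms step (two 0.5 ms substeps for v, as in the
standard polychronization-network scheme).  Each presynaptic spike at t adds
its weight to the target's current at t + d_ij (delays grid-rounded by
floor, minimum one step); currents decay exponentially (tau_E = 5 ms,
tau_I = 20 ms) between events, and independent Poisson events add the noise amplitude xi to the
excitatory current of each neuron.  Dead (lesioned) neurons are never
updated and never emit spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import DynamicsConfig, NeuronParams, NoiseConfig, StdpParams
from .network import StructuralNetwork

__all__ = ["SpikeRaster", "Simulator", "run_epoch",
           "NumericalInstabilityError",
           "save_raster_text", "load_raster_text",
           "save_raster_hdf5", "load_raster_hdf5"]

_NEVER = -1.0e18  # sentinel: no spike seen yet


def _mix_seed(seed: int, chunk: int) -> int:
    """Derive a 31-bit chunk seed from (seed, chunk) by integer mixing."""
    x = (seed * 0x9E3779B97F4A7C15 + chunk * 0xBF58476D1CE4E5B9 + 1) \
        % (1 << 64)
    x ^= x >> 30
    x = (x * 0xD6E8FEB86659FD93) % (1 << 64)
    x ^= x >> 27
    return int(x % (1 << 31))


class NumericalInstabilityError(RuntimeError):
    def __init__(self, neuron: int, time_ms: float):
        self.neuron = neuron
        self.time_ms = time_ms
        super().__init__(
            f"non-finite membrane potential in neuron {neuron} "
            f"at t = {time_ms:.3f} ms")


@dataclass
class SpikeRaster:
    """Spike raster over one epoch: parallel (unit, time) arrays sorted by
    time, with the unit count and epoch extent."""

    units: np.ndarray        # (S,) int
    times: np.ndarray        # (S,) ms, non-decreasing
    n_units: int
    duration_ms: float
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def to_lists(self) -> list:
        """Per-unit strictly increasing spike-time arrays."""
        out = [[] for _ in range(self.n_units)]
        for u, t in zip(self.units, self.times):
            out[u].append(t)
        return [np.array(x) for x in out]

    def counts(self) -> np.ndarray:
        return np.bincount(self.units, minlength=self.n_units)

    def mean_rate_hz(self, alive: np.ndarray | None = None) -> float:
        n = self.n_units if alive is None else int(np.sum(alive))
        if n == 0 or self.duration_ms == 0:
            return 0.0
        s = (self.n_spikes if alive is None
             else int(np.sum(alive[self.units])))
        return 1000.0 * s / (n * self.duration_ms)

    @classmethod
    def from_lists(cls, spike_lists, duration_ms: float,
                   dt: float = 1.0) -> "SpikeRaster":
        units, times = [], []
        for u, ts in enumerate(spike_lists):
            units.extend([u] * len(ts))
            times.extend(ts)
        units = np.array(units, dtype=np.int64)
        times = np.array(times, dtype=float)
        order = np.argsort(times, kind="stable")
        return cls(units[order], times[order], len(spike_lists),
                   duration_ms, dt)


# ---------------------------------------------------------------------------
# raster I/O

def save_raster_text(raster: SpikeRaster, path) -> None:
    """Two-column plain text: neuron_id time_ms."""
    with open(path, "w") as fh:
        fh.write(f"# n_units={raster.n_units} duration_ms={raster.duration_ms}"
                 f" dt={raster.dt}\n")
        for u, t in zip(raster.units, raster.times):
            fh.write(f"{u} {t:.6f}\n")


def load_raster_text(path, n_units: int | None = None,
                     duration_ms: float | None = None) -> SpikeRaster:
    units, times = [], []
    header = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=")
                        header[k] = float(v)
                continue
            u, t = line.split()[:2]
            units.append(int(u))
            times.append(float(t))
    units = np.array(units, dtype=np.int64)
    times = np.array(times, dtype=float)
    if n_units is None:
        n_units = int(header.get("n_units",
                                 units.max() + 1 if len(units) else 0))
    if duration_ms is None:
        duration_ms = float(header.get(
            "duration_ms", times.max() if len(times) else 0.0))
    order = np.argsort(times, kind="stable")
    return SpikeRaster(units[order], times[order], n_units, duration_ms,
                       header.get("dt", 1.0))


def save_raster_hdf5(raster: SpikeRaster, path, group: str = "raster") -> None:
    import h5py
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("units", data=raster.units)
        g.create_dataset("times", data=raster.times)
        g.attrs["n_units"] = raster.n_units
        g.attrs["duration_ms"] = raster.duration_ms
        g.attrs["dt"] = raster.dt


def load_raster_hdf5(path, group: str = "raster") -> SpikeRaster:
    import h5py
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return SpikeRaster(g["units"][...], g["times"][...],
                           int(g.attrs["n_units"]),
                           float(g.attrs["duration_ms"]),
                           float(g.attrs["dt"]))


# ---------------------------------------------------------------------------
# jitted core

@njit(cache=True)
def _core(n_steps, t0_step, dt, seed,
                          alive, edge_exc,
                          csr_ptr, edge_post, edge_w, edge_delay_steps,
                          edge_plastic,
                          csc_ptr, csc_syn,
                          par_a, par_b, par_c, par_d, v_peak,
                          v, u, i_exc, i_inh,
                          decay_e, decay_i,
                          noise_p, xi,
                          iin_units, iin_series,
                          plasticity_on, eta_p, eta_m, tau, w_max,
                          last_pre, last_post,
                          ring_syn, ring_count,
                          out_units, out_times, err_info):
    """One contiguous run of the simulation.  Returns the number of spikes
    emitted, -1 on raster-buffer overflow, -2 on numerical instability
    (details in err_info).  I_in is a dense series for a subset of units
    and enters the voltage equation directly."""
    if seed >= 0:
        np.random.seed(seed)
    n = v.shape[0]
    ring_size = ring_syn.shape[0]
    cap = out_units.shape[0]
    n_spk = 0
    n_iin_steps = iin_series.shape[0]
    n_iin = iin_units.shape[0]
    iin_now = np.zeros(n)

    for step in range(n_steps):
        t_abs = t0_step + step
        t_now = t_abs * dt

        for j in range(n):
            i_exc[j] *= decay_e
            i_inh[j] *= decay_i

        slot = t_abs % ring_size
        for q in range(ring_count[slot]):
            s = ring_syn[slot, q]
            j = edge_post[s]
            if not alive[j]:
                continue
            w = edge_w[s]
            if edge_exc[s]:
                i_exc[j] += w
            else:
                i_inh[j] += w
            if plasticity_on and edge_plastic[s]:
                if last_post[j] > _NEVER:
                    dtp = last_post[j] - t_now
                    dw = eta_m * (w / w_max) * np.exp(dtp / tau)
                    w = w + dw
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    edge_w[s] = w
                last_pre[s] = t_now
        ring_count[slot] = 0

        if noise_p > 0.0:
            # one draw per neuron regardless of alive state, so a lesioned
            # network consumes the identical stream as its matched control
            for j in range(n):
                if np.random.random() < noise_p and alive[j]:
                    i_exc[j] += xi

        if n_iin > 0:
            for q in range(n_iin):
                iin_now[iin_units[q]] = (iin_series[step, q]
                                         if step < n_iin_steps else 0.0)

        for j in range(n):
            if not alive[j]:
                continue
            i_tot = i_exc[j] + i_inh[j] + iin_now[j]
            vj = v[j]
            uj = u[j]
            for _ in range(2):
                vj += 0.5 * dt * (0.04 * vj * vj + 5.0 * vj + 140.0
                                  - uj + i_tot)
            uj += dt * par_a[j] * (par_b[j] * vj - uj)
            if not (np.isfinite(vj) and np.isfinite(uj)):
                err_info[0] = j
                err_info[1] = t_abs
                return -2
            v[j] = vj
            u[j] = uj

        for j in range(n):
            if not alive[j] or v[j] < v_peak:
                continue
            if n_spk >= cap:
                return -1
            out_units[n_spk] = j
            out_times[n_spk] = t_now
            n_spk += 1
            v[j] = par_c[j]
            u[j] += par_d[j]
            if plasticity_on:
                last_post[j] = t_now
                for p in range(csc_ptr[j], csc_ptr[j + 1]):
                    s = csc_syn[p]
                    if last_pre[s] > _NEVER:
                        dtp = t_now - last_pre[s]
                        w = edge_w[s]
                        if dtp > 0.0:
                            dw = eta_p * (1.0 - w / w_max) * np.exp(-dtp / tau)
                        else:
                            dw = eta_m * (w / w_max) * np.exp(dtp / tau)
                        w = w + dw
                        if w < 0.0:
                            w = 0.0
                        elif w > w_max:
                            w = w_max
                        edge_w[s] = w
            for p in range(csr_ptr[j], csr_ptr[j + 1]):
                ds = edge_delay_steps[p]
                tgt = (t_abs + ds) % ring_size
                ring_syn[tgt, ring_count[tgt]] = p
                ring_count[tgt] += 1
    return n_spk


# ---------------------------------------------------------------------------
# python-facing simulator

class Simulator:
    """Stateful wrapper around the jitted core.

    Holds membrane state, synaptic currents, pending deliveries and the
    nearest-neighbour pairing state, so that simulation can proceed in
    chunks (including single steps).  The Poisson stream is reseeded
    deterministically per chunk, so a fixed seed and chunk schedule give
    bit-identical results; different chunkings of the same interval are
    different (equally valid) noise realizations.
    """

    def __init__(self, network: StructuralNetwork,
                 noise: NoiseConfig | None = None,
                 dynamics: DynamicsConfig | None = None,
                 stdp: StdpParams | None = None,
                 plasticity: bool = True,
                 seed: int | None = None,
                 exc_params: NeuronParams | None = None,
                 inh_params: NeuronParams | None = None):
        self.network = network
        self.noise = noise if noise is not None else NoiseConfig()
        self.dyn = dynamics if dynamics is not None else DynamicsConfig()
        self.stdp = stdp if stdp is not None else StdpParams()
        self.plasticity = bool(plasticity)
        self._seed = int(seed if seed is not None else self.noise.seed)
        self._chunk = 0

        n = network.n_neurons
        exc = network.population.is_excitatory
        ep = exc_params if exc_params is not None else NeuronParams.excitatory()
        ip = inh_params if inh_params is not None else NeuronParams.inhibitory()
        self.par_a = np.where(exc, ep.a, ip.a)
        self.par_b = np.where(exc, ep.b, ip.b)
        self.par_c = np.where(exc, ep.c, ip.c)
        self.par_d = np.where(exc, ep.d, ip.d)
        self.v_peak = float(ep.v_peak)

        # edges sorted by presynaptic neuron (CSR)
        order = np.argsort(network.pre, kind="stable")
        self._perm = order
        self.edge_post = network.post[order].astype(np.int64)
        self.edge_w = network.weight[order].astype(np.float64).copy()
        dt = self.dyn.dt
        # delays are grid-rounded by floor with a minimum of one step: a
        # spike can never influence the very step in which it occurs, and
        # every delivery passes through the same (canonical) delivery phase
        self.edge_delay_steps = np.maximum(
            np.floor(network.delay_ms[order] / dt), 1).astype(np.int64)
        self.edge_exc = exc[network.pre[order]].astype(np.bool_)
        self.edge_plastic = network.plastic[order].astype(np.bool_)
        counts = np.bincount(network.pre[order], minlength=n)
        self.csr_ptr = np.concatenate(
            [[0], np.cumsum(counts)]).astype(np.int64)

        # plastic synapses grouped by postsynaptic neuron (CSC over synapse
        # indices in the CSR ordering)
        plast_idx = np.nonzero(self.edge_plastic)[0]
        if plast_idx.size:
            post_of = self.edge_post[plast_idx]
            o2 = np.argsort(post_of, kind="stable")
            self.csc_syn = plast_idx[o2].astype(np.int64)
            c2 = np.bincount(post_of, minlength=n)
            self.csc_ptr = np.concatenate(
                [[0], np.cumsum(c2)]).astype(np.int64)
        else:
            self.csc_syn = np.empty(0, dtype=np.int64)
            self.csc_ptr = np.zeros(n + 1, dtype=np.int64)

        # state
        self.v = self.par_c.copy()
        self.u = self.par_b * self.v
        self.i_exc = np.zeros(n)
        self.i_inh = np.zeros(n)
        self.last_pre = np.full(len(self.edge_post), _NEVER)
        self.last_post = np.full(n, _NEVER)
        max_ds = int(max(1, np.floor(self.dyn.max_delay / dt)))
        if self.edge_delay_steps.size:
            max_ds = max(max_ds, int(self.edge_delay_steps.max()))
        self.ring_size = max_ds + 1
        self.ring_syn = np.zeros(
            (self.ring_size, max(1, len(self.edge_post))), dtype=np.int64)
        self.ring_count = np.zeros(self.ring_size, dtype=np.int64)
        self.t_step = 0

        self.decay_e = float(np.exp(-dt / self.dyn.tau_exc))
        self.decay_i = float(np.exp(-dt / self.dyn.tau_inh))
        self.noise_p = self.noise.rate * dt / 1000.0

    @property
    def time_ms(self) -> float:
        return self.t_step * self.dyn.dt

    def run(self, duration_ms: float,
            iin_units: np.ndarray | None = None,
            iin_series: np.ndarray | None = None) -> SpikeRaster:
        """Advance the simulation by ``duration_ms`` and return the raster of
        that chunk (times are absolute simulation times)."""
        dt = self.dyn.dt
        n_steps = int(round(duration_ms / dt))
        if n_steps <= 0:
            return SpikeRaster(np.empty(0, dtype=np.int64), np.empty(0),
                               self.network.n_neurons, 0.0, dt)
        if iin_units is None:
            iin_units = np.empty(0, dtype=np.int64)
            iin_series = np.empty((0, 0))
        else:
            iin_units = np.asarray(iin_units, dtype=np.int64)
            iin_series = np.ascontiguousarray(iin_series, dtype=np.float64)
            if iin_series.ndim != 2 or iin_series.shape[1] != len(iin_units):
                raise ValueError("iin_series must be (n_steps, n_units)")

        cap = max(100_000,
                  int(self.network.n_neurons * n_steps * 0.02) + 1000)
        t0_abs_ms = self.time_ms
        while True:
            out_units = np.empty(cap, dtype=np.int64)
            out_times = np.empty(cap, dtype=np.float64)
            err = np.zeros(2, dtype=np.int64)
            # numba's RNG state is process-global: reseed deterministically at
            # every chunk so interleaved simulators cannot perturb each other
            # and results are independent of chunking
            seed = _mix_seed(self._seed, self._chunk)
            snapshot = self._snapshot()
            res = _core(
                n_steps, self.t_step, dt, seed,
                self.network.alive, self.edge_exc,
                self.csr_ptr, self.edge_post, self.edge_w,
                self.edge_delay_steps, self.edge_plastic,
                self.csc_ptr, self.csc_syn,
                self.par_a, self.par_b, self.par_c, self.par_d, self.v_peak,
                self.v, self.u, self.i_exc, self.i_inh,
                self.decay_e, self.decay_i,
                self.noise_p, self.noise.xi,
                iin_units, iin_series,
                self.plasticity, self.stdp.eta_plus, self.stdp.eta_minus,
                self.stdp.tau, self.stdp.w_max,
                self.last_pre, self.last_post,
                self.ring_syn, self.ring_count, out_units, out_times, err)
            if res == -1:
                self._restore(snapshot)
                cap *= 4
                continue
            if res == -2:
                raise NumericalInstabilityError(int(err[0]),
                                                float(err[1]) * dt)
            break
        self._chunk += 1
        self.t_step += n_steps
        raster = SpikeRaster(out_units[:res].copy(), out_times[:res].copy(),
                             self.network.n_neurons, n_steps * dt, dt)
        # report times relative to the chunk start
        raster.times -= t0_abs_ms
        return raster

    def step(self, iin: np.ndarray | None = None) -> np.ndarray:
        """Advance exactly one dt; return the ids of neurons that spiked."""
        if iin is not None:
            units = np.nonzero(iin)[0].astype(np.int64)
            series = np.asarray(iin, dtype=float)[units][None, :]
            r = self.run(self.dyn.dt, units, series)
        else:
            r = self.run(self.dyn.dt)
        return r.units

    def weights_in_network_order(self) -> np.ndarray:
        w = np.empty_like(self.edge_w)
        w[self._perm] = self.edge_w
        return w

    def write_back_weights(self) -> None:
        """Copy the (possibly plasticity-updated) weights into the network."""
        self.network.weight[:] = self.weights_in_network_order()

    def refresh_after_lesion(self) -> None:
        """Re-sync a running simulation after the network was lesioned:
        pull the (zeroed) weights and invalidate the pairing memory of
        synapses touching dead neurons, so stale pre-lesion spikes can
        never drive further plasticity on them."""
        net = self.network
        self.edge_w[:] = net.weight[self._perm]
        dead_edge = (~net.alive[net.pre] | ~net.alive[net.post])[self._perm]
        self.last_pre[dead_edge] = _NEVER
        self.last_post[~net.alive] = _NEVER

    def _snapshot(self):
        return (self.v.copy(), self.u.copy(), self.i_exc.copy(),
                self.i_inh.copy(), self.edge_w.copy(), self.last_pre.copy(),
                self.last_post.copy(), self.ring_syn.copy(),
                self.ring_count.copy())

    def _restore(self, snap) -> None:
        (self.v, self.u, self.i_exc, self.i_inh, self.edge_w,
         self.last_pre, self.last_post, self.ring_syn,
         self.ring_count) = [x.copy() for x in snap]


def run_epoch(network: StructuralNetwork, duration_ms: float,
              noise: NoiseConfig | None = None,
              stdp: StdpParams | None = None,
              plasticity: bool = False,
              dynamics: DynamicsConfig | None = None,
              seed: int | None = None,
              iin_units: np.ndarray | None = None,
              iin_series: np.ndarray | None = None,
              in_place: bool = False) -> tuple:
    """Simulate one epoch from the resting state.

    Returns ``(raster, network)``; with plasticity on, the returned network
    carries the updated weights (the input network itself is only modified
    when ``in_place`` is set).
    """
    net = network if in_place else network.copy()
    sim = Simulator(net, noise=noise, dynamics=dynamics, stdp=stdp,
                    plasticity=plasticity, seed=seed)
    raster = sim.run(duration_ms, iin_units=iin_units, iin_series=iin_series)
    if plasticity:
        sim.write_back_weights()
    return raster, net
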