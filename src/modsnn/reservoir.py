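"""Reservoir-computing harness on the spiking network.

A synthetic 78-channel cochleagram generator provides class-distinct,
trial-jittered stimuli (formant-like band trajectories with class-specific
sweeps).  A random 5% subset of neurons receives input current: for each
input unit the sum of two randomly chosen channels, scaled by the network's
mean E->E weight, is added to I_in.  A disjoint 5% subset provides the
reservoir state via leaky spike integration

    dx_i/dt = -x_i / tau_x + x_step * sum_k delta(t - t_i^k),

and a ridge-regression readout W_out = Y X^T (X X^T + lambda I)^{-1} is
trained on targets that are 1 for the correct class during a fixed window
after each stimulus onset.  Predicted label per trial: argmax of the
integrated outputs over that window.  Plasticity is frozen during the task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DynamicsConfig, NoiseConfig, ReservoirConfig, stage_seed
from .dynamics import Simulator, SpikeRaster
from .network import StructuralNetwork

__all__ = ["Cochleagram", "ReservoirWiring", "TrialSet", "synth_cochleagram",
           "make_trial_set", "make_wiring", "drive_network", "run_session",
           "reservoir_state", "train_readout", "classify",
           "evaluate_snapshot", "accuracy_timecourse",
           "save_cochleagram_csv", "load_cochleagram_csv",
           "save_trial_manifest"]


@dataclass
class Cochleagram:
    values: np.ndarray    # (n_channels, T_ms), max-normalized to 1
    label: int

    @property
    def duration_ms(self) -> int:
        return self.values.shape[1]


@dataclass
class ReservoirWiring:
    input_units: np.ndarray     # (n_in,)
    readout_units: np.ndarray   # (n_out,) disjoint from input_units
    channel_pairs: np.ndarray   # (n_in, 2) source channels per input unit


@dataclass
class TrialSet:
    cochleagrams: list          # ordered trials
    labels: np.ndarray
    onsets_ms: np.ndarray       # onset of each trial in session time
    trial_period_ms: float

    def __len__(self) -> int:
        return len(self.cochleagrams)


# ---------------------------------------------------------------------------
# synthetic stimuli

# per-class formant-like templates: (start_channel, end_channel, relative
# onset, relative offset) for each band; classes differ in band placement
# and sweep direction.  A broadband utterance envelope (class-specific bump
# timing) carries most of the energy, as speech cochleagrams do.
_CLASS_BANDS = {
    0: [(12.0, 24.0, 0.00, 0.55), (50.0, 36.0, 0.25, 0.95)],
    1: [(58.0, 70.0, 0.00, 0.60), (30.0, 10.0, 0.30, 1.00)],
    2: [(40.0, 42.0, 0.00, 0.45), (14.0, 56.0, 0.40, 0.90)],
}
_CLASS_BUMPS = {
    0: [(0.22, 0.12), (0.70, 0.14)],
    1: [(0.35, 0.20)],
    2: [(0.18, 0.08), (0.52, 0.10), (0.85, 0.08)],
}


def synth_cochleagram(class_id: int, rng: np.random.Generator,
                      config: ReservoirConfig | None = None) -> Cochleagram:
    """Generate one synthetic cochleagram for ``class_id``.

    Within-class variants share the class template (formant-like band
    trajectories riding on a broadband loudness envelope with
    class-specific bump timing) but differ in timing stretch, channel
    offset, amplitude and additive noise; the global maximum is normalized
    to exactly 1.
    """
    config = config if config is not None else ReservoirConfig()
    if class_id not in config.classes:
        raise ValueError(f"class {class_id} not in {config.classes}")
    n_ch = config.n_channels
    T = int(config.stimulus_duration_ms)
    vals = np.zeros((n_ch, T))
    t = np.arange(T) / T
    ch = np.arange(n_ch)[:, None]
    stretch = rng.uniform(0.9, 1.1)
    ch_shift = rng.uniform(-2.0, 2.0)

    # broadband loudness envelope: class-timed bumps across all channels,
    # stronger toward low channels as in auditory-filterbank outputs
    env = np.zeros(T)
    for (center_t, width_t) in _CLASS_BUMPS[class_id % 3]:
        amp = rng.uniform(0.8, 1.0)
        env += amp * np.exp(-0.5 * ((t - center_t * stretch) / width_t) ** 2)
    tilt = 1.0 - 0.15 * (np.arange(n_ch) / n_ch)
    vals += tilt[:, None] * env[None, :]

    for (c0, c1, t0, t1) in _CLASS_BANDS[class_id % 3]:
        t0s, t1s = np.clip([t0 * stretch, t1 * stretch], 0.0, 1.0)
        if t1s <= t0s:
            continue
        active = (t >= t0s) & (t < t1s)
        frac = (t - t0s) / (t1s - t0s)
        center = c0 + (c1 - c0) * frac + ch_shift
        width = rng.uniform(6.0, 9.0)
        amp = rng.uniform(0.35, 0.5)
        band_env = np.sin(np.pi * np.clip(frac, 0.0, 1.0)) ** 0.5
        vals += (amp * np.exp(-0.5 * ((ch - center) / width) ** 2)
                 * band_env * active)
    vals += rng.normal(0.0, 0.01, vals.shape)
    vals = np.clip(vals, 0.0, None)
    peak = vals.max()
    if peak > 0:
        vals /= peak
    return Cochleagram(values=vals, label=int(class_id))


def make_trial_set(config: ReservoirConfig,
                   rng: np.random.Generator) -> TrialSet:
    """Sample n_samples_per_class stimuli per class, shuffled, with onsets
    every trial_period_ms."""
    cochs, labels = [], []
    for cls in config.classes:
        for _ in range(config.n_samples_per_class):
            cochs.append(synth_cochleagram(cls, rng, config))
            labels.append(cls)
    order = rng.permutation(len(cochs))
    cochs = [cochs[i] for i in order]
    labels = np.array(labels)[order]
    onsets = np.arange(len(cochs)) * config.trial_period_ms
    return TrialSet(cochs, labels, onsets, config.trial_period_ms)


# ---------------------------------------------------------------------------
# wiring and simulation

def make_wiring(network: StructuralNetwork, config: ReservoirConfig,
                rng: np.random.Generator) -> ReservoirWiring:
    """Sample disjoint input and readout unit subsets and the two source
    channels feeding each input unit."""
    alive = np.nonzero(network.alive)[0]
    n_in = max(1, int(round(config.frac_input * network.n_neurons)))
    n_out = max(1, int(round(config.frac_readout * network.n_neurons)))
    chosen = rng.choice(alive, size=n_in + n_out, replace=False)
    pairs = rng.integers(0, config.n_channels, size=(n_in, 2))
    return ReservoirWiring(input_units=np.sort(chosen[:n_in]),
                           readout_units=np.sort(chosen[n_in:]),
                           channel_pairs=pairs)


def _input_series(wiring: ReservoirWiring, coch: Cochleagram,
                  gain: float) -> np.ndarray:
    """(T, n_in) external current: gain * (channel_a + channel_b)."""
    summed = (coch.values[wiring.channel_pairs[:, 0]]
              + coch.values[wiring.channel_pairs[:, 1]])  # (n_in, T)
    return gain * summed.T


def drive_network(network: StructuralNetwork, wiring: ReservoirWiring,
                  coch: Cochleagram,
                  duration_ms: float | None = None,
                  noise: NoiseConfig | None = None,
                  dynamics: DynamicsConfig | None = None,
                  seed: int = 0,
                  gain: float | None = None) -> SpikeRaster:
    """Present one stimulus to the network (plasticity frozen) and return
    the evoked raster over ``duration_ms`` (default: stimulus length)."""
    if not network.alive[wiring.input_units].any():
        warnings.warn("all input units are dead; stimulus has no effect")
    if gain is None:
        gain = network.mean_ee_weight()
    sim = Simulator(network.copy(), noise=noise, dynamics=dynamics,
                    plasticity=False, seed=seed)
    if duration_ms is None:
        duration_ms = float(coch.duration_ms)
    series = _input_series(wiring, coch, gain)
    return sim.run(duration_ms, iin_units=wiring.input_units,
                   iin_series=series[:int(duration_ms)])


def run_session(network: StructuralNetwork, wiring: ReservoirWiring,
                trials: TrialSet,
                noise: NoiseConfig | None = None,
                dynamics: DynamicsConfig | None = None,
                seed: int = 0,
                gain: float | None = None) -> SpikeRaster:
    """Present all trials back to back in one continuous simulation
    (reservoir state carries across trials; reset only between sessions).
    Weight updates are stopped for the whole session."""
    if gain is None:
        gain = network.mean_ee_weight()
    period = int(round(trials.trial_period_ms))
    T = period * len(trials)
    n_in = len(wiring.input_units)
    series = np.zeros((T, n_in))
    for coch, onset in zip(trials.cochleagrams, trials.onsets_ms):
        o = int(round(onset))
        d = min(coch.duration_ms, T - o)
        series[o:o + d] = _input_series(wiring, coch, gain)[:d]
    sim = Simulator(network.copy(), noise=noise, dynamics=dynamics,
                    plasticity=False, seed=seed)
    return sim.run(float(T), iin_units=wiring.input_units, iin_series=series)


# ---------------------------------------------------------------------------
# state, readout, classification

def reservoir_state(raster: SpikeRaster, readout_units: np.ndarray,
                    tau_x: float = 1000.0, x_step: float = 0.1,
                    dt: float = 1.0) -> np.ndarray:
    """Leaky spike integration sampled on the simulation grid.

    Returns X with shape (n_readout, T): exponential decay with time
    constant ``tau_x`` plus a jump of ``x_step`` at each spike of the unit.
    """
    readout_units = np.asarray(readout_units)
    T = int(round(raster.duration_ms / dt))
    n = len(readout_units)
    jumps = np.zeros((n, T))
    unit_row = -np.ones(raster.n_units, dtype=np.int64)
    unit_row[readout_units] = np.arange(n)
    rows = unit_row[raster.units]
    m = rows >= 0
    cols = np.minimum((raster.times[m] / dt).astype(np.int64), T - 1)
    np.add.at(jumps, (rows[m], cols), x_step)
    decay = np.exp(-dt / tau_x)
    x = np.zeros((n, T))
    prev = np.zeros(n)
    for t in range(T):
        prev = prev * decay + jumps[:, t]
        x[:, t] = prev
    return x


def target_matrix(trials: TrialSet, classes, target_duration_ms: float,
                  T: int, dt: float = 1.0) -> np.ndarray:
    """One-hot targets: row of the true class is 1 for the target window
    after each onset, 0 otherwise."""
    classes = list(classes)
    Y = np.zeros((len(classes), T))
    w = int(round(target_duration_ms / dt))
    for label, onset in zip(trials.labels, trials.onsets_ms):
        o = int(round(onset / dt))
        Y[classes.index(int(label)), o:min(o + w, T)] = 1.0
    return Y


def train_readout(X: np.ndarray, Y: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """Ridge solution W_out = Y X^T (X X^T + lambda I)^{-1}."""
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of columns")
    if lam <= 0:
        raise ValueError("regularization coefficient must be positive")
    n = X.shape[0]
    gram = X @ X.T + lam * np.eye(n)
    return np.linalg.solve(gram, X @ Y.T).T


def classify(y: np.ndarray, onsets_ms: np.ndarray,
             target_duration_ms: float, classes,
             dt: float = 1.0) -> np.ndarray:
    """Per-trial label: argmax over classes of the output integrated over
    [onset, onset + target window); ties resolve to the lowest label."""
    classes = np.asarray(list(classes))
    w = int(round(target_duration_ms / dt))
    preds = []
    for onset in onsets_ms:
        o = int(round(onset / dt))
        scores = y[:, o:o + w].sum(axis=1)
        preds.append(classes[int(np.argmax(scores))])  # argmax: first max
    return np.array(preds)


def evaluate_snapshot(network: StructuralNetwork, wiring: ReservoirWiring,
                      trials: TrialSet, config: ReservoirConfig,
                      noise: NoiseConfig | None = None,
                      dynamics: DynamicsConfig | None = None,
                      seed: int = 0,
                      w_out: np.ndarray | None = None) -> dict:
    """Drive the network with the trial set and classify.

    Trains the readout on this very session when ``w_out`` is None
    (training and test sets are identical by design); otherwise reuses the
    given (frozen) readout.  Returns accuracy, predictions, W_out, X, Y.
    """
    raster = run_session(network, wiring, trials, noise=noise,
                         dynamics=dynamics, seed=seed)
    X = reservoir_state(raster, wiring.readout_units,
                        tau_x=config.tau_x, x_step=config.x_step)
    Y = target_matrix(trials, config.classes, config.target_duration_ms,
                      X.shape[1])
    if w_out is None:
        w_out = train_readout(X, Y, config.ridge_lambda)
    y = w_out @ X
    preds = classify(y, trials.onsets_ms, config.target_duration_ms,
                     config.classes)
    acc = float(np.mean(preds == trials.labels))
    return {"accuracy": acc, "predictions": preds, "w_out": w_out,
            "X": X, "Y": Y, "raster": raster}


def accuracy_timecourse(snapshots, wiring: ReservoirWiring, trials: TrialSet,
                        config: ReservoirConfig, mode: str = "retrain",
                        noise: NoiseConfig | None = None,
                        dynamics: DynamicsConfig | None = None,
                        seed: int = 0) -> dict:
    """Classification accuracy across damage-protocol snapshots.

    ``snapshots`` is a list of (label, network) pairs in time order (e.g.
    reconstructed from a ProtocolResult).  mode='retrain' refits W_out on
    each snapshot's own session; mode='frozen' trains on the first snapshot
    and reuses that readout throughout.
    """
    if mode not in ("retrain", "frozen"):
        raise ValueError(f"unknown mode {mode!r}")
    labels, accs = [], []
    frozen_w = None
    for k, (label, net) in enumerate(snapshots):
        w_in = None
        if mode == "frozen" and k > 0:
            w_in = frozen_w
        res = evaluate_snapshot(net, wiring, trials, config, noise=noise,
                                dynamics=dynamics,
                                seed=stage_seed(seed, "reservoir", k),
                                w_out=w_in)
        if k == 0:
            frozen_w = res["w_out"]
        labels.append(label)
        accs.append(res["accuracy"])
    return {"labels": labels, "accuracy": np.array(accs)}


# ---------------------------------------------------------------------------
# plain-text exports

def save_cochleagram_csv(coch: Cochleagram, path) -> None:
    """channels x time CSV; the label rides in a header comment."""
    np.savetxt(path, coch.values, delimiter=",",
               header=f"label={coch.label}", fmt="%.6g")


def load_cochleagram_csv(path) -> Cochleagram:
    label = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "label=" in first:
            label = int(first.split("label=")[1])
    return Cochleagram(values=np.loadtxt(path, delimiter=",",
                                         comments="#"), label=label)


def save_trial_manifest(trials: TrialSet, out_dir, manifest_path) -> None:
    """Write each trial's cochleagram as CSV plus a (file, onset, label)
    manifest."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "w") as fh:
        fh.write("file,onset_ms,label\n")
        for k, (coch, onset, label) in enumerate(
                zip(trials.cochleagrams, trials.onsets_ms, trials.labels)):
            name = f"trial_{k:03d}.csv"
            save_cochleagram_csv(coch, out_dir / name)
            fh.write(f"{name},{onset:g},{int(label)}\n")
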