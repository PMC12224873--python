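"""Configuration objects for every stage of the pipeline.

All quantities are in the units used throughout the package: lengths in mm,
times in ms unless a field name says otherwise, rates in Hz, weights in the
dimensionless units of the synaptic model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class GrowthConfig:
    """Parameters of the culture geometry and the stochastic axon growth.

    The culture is a disk seeded uniformly with neurons (80% excitatory by
    default).  Each axon grows as a chain of short segments whose heading
    performs a Gaussian random walk; on track-patterned substrates the
    alternating crevice/valley bands act as obstacles that axons cross
    downwards with probability ``p_down`` and upwards with ``p_up``,
    otherwise deflecting to grow parallel to the band boundary.
    """

    culture_diameter: float = 3.0      # mm
    density: float = 400.0             # neurons / mm^2
    frac_excitatory: float = 0.8
    dendrite_radius: float = 0.150     # mm
    axon_mean_length: float = 1.1      # mm, mean of the Rayleigh length law
    segment_length: float = 0.1        # mm
    sigma_theta: float = 0.1           # rad, per-segment heading jitter
    p_up: float = 0.05
    p_down: float = 0.50
    crevice_width: float = 0.2         # mm
    valley_width: float = 0.3          # mm
    connect_prob: float = 0.2          # axon-dendrite contact retention
    patterned: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_up", "p_down", "connect_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in ("culture_diameter", "density", "dendrite_radius",
                     "axon_mean_length", "segment_length", "crevice_width",
                     "valley_width"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigurationError(f"{name}={v} must be positive")
        if not 0.0 < self.frac_excitatory < 1.0:
            raise ConfigurationError(
                f"frac_excitatory={self.frac_excitatory} outside (0, 1)")
        if self.sigma_theta < 0:
            raise ConfigurationError("sigma_theta must be >= 0")

    @property
    def radius(self) -> float:
        return self.culture_diameter / 2.0

    def expected_neuron_count(self) -> int:
        return int(round(self.density * np.pi * self.radius ** 2))


@dataclass
class NeuronParams:
    """Izhikevich model constants for one cell class."""

    a: float
    b: float
    c: float
    d: float
    v_peak: float = 30.0  # mV

    @classmethod
    def excitatory(cls) -> "NeuronParams":
        # regular-spiking cortical cell
        return cls(a=0.02, b=0.2, c=-65.0, d=8.0)

    @classmethod
    def inhibitory(cls) -> "NeuronParams":
        # fast-spiking interneuron
        return cls(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass
class NoiseConfig:
    """Poisson background drive: each neuron receives independent events at
    ``rate`` Hz, each event adding ``xi`` to its excitatory current.

    The default amplitude was calibrated once so that a settled, undamaged
    desk-scale network sustains spontaneous network bursting at the default
    1 Hz event rate.
    """

    rate: float = 1.0   # Hz per neuron
    xi: float = 6.1     # current increment per event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("noise rate must be >= 0")
        if self.xi < 0:
            raise ConfigurationError("noise amplitude xi must be >= 0")


@dataclass
class StdpParams:
    """Soft-bounded, nearest-neighbour STDP on excitatory-to-excitatory
    synapses: potentiation gain scales with (1 - w/w_max), depression with
    w/w_max, both windows exponential with time constant ``tau``."""

    eta_plus: float = 0.1
    eta_minus: float = -0.12
    tau: float = 20.0     # ms
    w_max: float = 6.8

    def __post_init__(self) -> None:
        if self.eta_plus <= 0:
            raise ConfigurationError("eta_plus must be > 0")
        if self.eta_minus >= 0:
            raise ConfigurationError("eta_minus must be < 0")
        if self.tau <= 0 or self.w_max <= 0:
            raise ConfigurationError("tau and w_max must be > 0")


@dataclass
class DynamicsConfig:
    """Integration settings for the spiking simulation."""

    dt: float = 1.0            # ms; v integrated in two dt/2 substeps
    tau_exc: float = 5.0       # ms, excitatory current decay
    tau_inh: float = 20.0      # ms, inhibitory current decay
    max_delay: float = 5.0     # ms, upper bound of excitatory delays
    inhibitory_delay: float = 1.0  # ms, fixed

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")


@dataclass
class BurstConfig:
    """Network-burst criterion: a burst occurs when more than
    ``participation_threshold`` of the alive units fire within ``window`` ms."""

    window: float = 200.0
    participation_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigurationError("burst window must be > 0")
        if not 0.0 < self.participation_threshold <= 1.0:
            raise ConfigurationError(
                "participation_threshold must be in (0, 1]")


@dataclass
class TeConfig:
    """Transfer-entropy estimation settings (binary 20 ms bins, Markov
    order 2, z-score threshold 2 for the binary effective network)."""

    bin_ms: float = 20.0
    markov_order: int = 2
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ConfigurationError("TE bin must be > 0")
        if self.markov_order < 1:
            raise ConfigurationError("Markov order must be >= 1")


@dataclass
class CutSpec:
    """Geometry of a straight-line lesion.

    ``orientation`` is relative to the track bands (which run horizontally):
    ``perpendicular_to_tracks`` severs intra-modular (along-track) links,
    ``parallel_to_tracks`` severs inter-modular links.  ``extent`` 'half'
    uses ``half_length`` (default half the culture diameter), 'full' spans
    the whole culture.
    """

    orientation: str = "perpendicular_to_tracks"
    extent: str = "half"
    center: tuple[float, float] = (0.0, 0.0)
    half_length: float = 1.5  # mm, used when extent == 'half'

    def __post_init__(self) -> None:
        if self.orientation not in (
                "perpendicular_to_tracks", "parallel_to_tracks"):
            raise ConfigurationError(
                f"unknown cut orientation {self.orientation!r}")
        if self.extent not in ("half", "full"):
            raise ConfigurationError(f"unknown cut extent {self.extent!r}")
        if self.half_length <= 0:
            raise ConfigurationError("cut length must be > 0")

    def segment(self, culture_diameter: float) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the cut segment in culture coordinates (mm)."""
        length = (culture_diameter if self.extent == "full"
                  else self.half_length)
        if length > culture_diameter:
            raise ConfigurationError("cut longer than culture diameter")
        cx, cy = self.center
        half = length / 2.0
        if self.orientation == "parallel_to_tracks":
            p0 = np.array([cx - half, cy])
            p1 = np.array([cx + half, cy])
        else:
            p0 = np.array([cx, cy - half])
            p1 = np.array([cx, cy + half])
        return p0, p1


@dataclass
class DamageProtocol:
    """Timed damage-recovery evaluation schedule.

    ``timepoints_s`` are the post-injury evaluation times (seconds of
    simulated time; the in-vitro schedule is 0 s, 15 min, 2 h, 6 h, 24 h).
    At each timepoint an epoch of ``epoch_s`` seconds is recorded.
    """

    timepoints_s: tuple[float, ...] = (0.0, 900.0, 7200.0, 21600.0, 86400.0)
    epoch_s: float = 60.0
    n_replicates: int = 15
    stdp_during_recovery: bool = True

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints_s)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.epoch_s <= 0:
            raise ConfigurationError("epoch length must be > 0")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate")


@dataclass
class ReservoirConfig:
    """Reservoir-computing harness settings."""

    n_channels: int = 78
    frac_input: float = 0.05       # fraction of neurons receiving input
    frac_readout: float = 0.05     # disjoint fraction used as reservoir state
    tau_x: float = 1000.0          # ms, leaky state time constant
    x_step: float = 0.1            # state increment per spike
    ridge_lambda: float = 1.0
    target_duration_ms: float = 2500.0   # 1-target window after each onset
    trial_period_ms: float = 10000.0     # output period per trial
    n_samples_per_class: int = 10
    classes: tuple[int, ...] = (0, 1, 2)
    stimulus_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.ridge_lambda <= 0:
            raise ConfigurationError("ridge_lambda must be > 0")
        if not 0 < self.frac_input < 0.5 or not 0 < self.frac_readout < 0.5:
            raise ConfigurationError("input/readout fractions unreasonable")
        if self.target_duration_ms > self.trial_period_ms:
            raise ConfigurationError(
                "target window cannot exceed the trial period")


@dataclass
class ExperimentConfig:
    """Top-level experiment description tying all stages together."""

    growth: GrowthConfig = field(default_factory=GrowthConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    stdp: StdpParams = field(default_factory=StdpParams)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cut: CutSpec = field(default_factory=CutSpec)
    protocol: DamageProtocol = field(default_factory=DamageProtocol)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    settle_s: float = 72.0 * 3600.0   # simulated seconds of STDP settling
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.settle_s < 0:
            raise ConfigurationError("settle duration must be >= 0")


def desk_preset(master_seed: int = 0, patterned: bool = True) -> ExperimentConfig:
    """Desk-scale preset: a 1.5 mm culture (~700 neurons), minutes-scale
    settling and compressed recovery timepoints, sized so a full damage
    sequence runs on one CPU in minutes instead of cluster-hours."""
    cfg = ExperimentConfig(
        growth=GrowthConfig(culture_diameter=1.5, patterned=patterned,
                            seed=master_seed),
        protocol=DamageProtocol(
            timepoints_s=(0.0, 60.0, 180.0, 360.0),
            epoch_s=60.0, n_replicates=5),
        settle_s=120.0,
        master_seed=master_seed,
    )
    cfg.cut = CutSpec(half_length=cfg.growth.culture_diameter / 2.0)
    return cfg


# ---------------------------------------------------------------------------
# seed fan-out

_STAGE_TAGS = ("growth", "settle", "damage", "control", "reservoir",
               "noise", "stimuli", "louvain")


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> int:
    """Derive an independent per-stage, per-replicate seed from the master
    seed via SHA-256 so no stage consumes another stage's random stream.
    The result fits in 31 bits."""
    h = hashlib.sha256(f"{master_seed}:{stage}:{replicate}".encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# (de)serialization

def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return experiment_config_from_dict(raw)


def experiment_config_from_dict(raw: dict) -> ExperimentConfig:
    def _tupled(d: dict, *keys) -> dict:
        out = dict(d)
        for k in keys:
            if k in out and isinstance(out[k], list):
                out[k] = tuple(out[k])
        return out

    return ExperimentConfig(
        growth=GrowthConfig(**raw.get("growth", {})),
        dynamics=DynamicsConfig(**raw.get("dynamics", {})),
        stdp=StdpParams(**raw.get("stdp", {})),
        noise=NoiseConfig(**raw.get("noise", {})),
        cut=CutSpec(**_tupled(raw.get("cut", {}), "center")),
        protocol=DamageProtocol(**_tupled(raw.get("protocol", {}),
                                          "timepoints_s")),
        reservoir=ReservoirConfig(**_tupled(raw.get("reservoir", {}),
                                            "classes")),
        settle_s=raw.get("settle_s", 72.0 * 3600.0),
        master_seed=raw.get("master_seed", 0),
    )
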