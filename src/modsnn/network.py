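"""Structural network generation by stochastic axon growth.

Neurons are scattered uniformly over a circular culture; each axon grows as a
chain of 0.1 mm segments whose heading performs a Gaussian random walk, with
total length drawn from a Rayleigh distribution.  On track-patterned
substrates, horizontal crevice/valley bands act as obstacles: an axon crosses
a band boundary downwards with probability ``p_down`` and upwards with
``p_up``, otherwise it is deflected to grow parallel to the boundary.  A
directed connection i -> j is created (with a fixed retention probability)
whenever the axon of i passes through the dendritic disk of j.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import ConfigurationError, GrowthConfig

__all__ = [
    "NeuronPopulation", "AxonPath", "StructuralNetwork",
    "place_neurons", "grow_axon", "grow_all_axons", "build_connectome",
    "generate_network", "connection_angle_distribution",
    "save_network", "load_network", "export_edge_list",
]


class StructureError(ValueError):
    """Inconsistent structural inputs (e.g. mismatched array sizes)."""


@dataclass
class NeuronPopulation:
    positions: np.ndarray          # (N, 2) mm
    is_excitatory: np.ndarray      # (N,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.is_excitatory = np.asarray(self.is_excitatory, dtype=bool)
        if len(self.positions) != len(self.is_excitatory):
            raise StructureError("positions / is_excitatory length mismatch")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class AxonPath:
    origin: int                    # neuron id
    vertices: np.ndarray           # (n_seg + 1, 2) mm, vertices[0] = soma
    max_length: float              # sampled Rayleigh cap (mm)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)

    @property
    def length(self) -> float:
        if len(self.vertices) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


@dataclass
class StructuralNetwork:
    """Directed structural connectome.

    Edges are stored as parallel arrays (pre, post, weight, delay).  The
    dense views ``A`` and ``W`` only include edges between alive neurons.
    """

    population: NeuronPopulation
    axon_paths: list            # list[AxonPath], index-aligned with neurons
    pre: np.ndarray             # (E,) presynaptic neuron index
    post: np.ndarray            # (E,) postsynaptic neuron index
    weight: np.ndarray          # (E,) signed weight
    delay_ms: np.ndarray        # (E,)
    alive: np.ndarray = None    # (N,) bool
    config: GrowthConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.population)
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        self.delay_ms = np.asarray(self.delay_ms, dtype=float)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        self.alive = np.asarray(self.alive, dtype=bool)
        if not (len(self.pre) == len(self.post) == len(self.weight)
                == len(self.delay_ms)):
            raise StructureError("edge arrays have mismatched lengths")
        if len(self.pre) and (self.pre.max() >= n or self.post.max() >= n):
            raise StructureError("edge index out of range")
        if np.any(self.pre == self.post):
            raise StructureError("self-connections are not allowed")

    # -- convenience views ---------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.population)

    @property
    def n_edges(self) -> int:
        return int(self.edge_alive.sum())

    @property
    def edge_alive(self) -> np.ndarray:
        """Edges whose both endpoints are alive."""
        return self.alive[self.pre] & self.alive[self.post]

    @property
    def plastic(self) -> np.ndarray:
        """E->E edges: the only ones modified by plasticity."""
        exc = self.population.is_excitatory
        return exc[self.pre] & exc[self.post]

    @property
    def A(self) -> np.ndarray:
        a = np.zeros((self.n_neurons, self.n_neurons), dtype=np.int8)
        m = self.edge_alive
        a[self.pre[m], self.post[m]] = 1
        return a

    @property
    def W(self) -> np.ndarray:
        w = np.zeros((self.n_neurons, self.n_neurons), dtype=float)
        m = self.edge_alive
        w[self.pre[m], self.post[m]] = self.weight[m]
        return w

    def ee_weight_matrix(self) -> np.ndarray:
        """Dense W restricted to plastic (E->E) alive edges, zero elsewhere."""
        w = np.zeros((self.n_neurons, self.n_neurons), dtype=float)
        m = self.edge_alive & self.plastic
        w[self.pre[m], self.post[m]] = self.weight[m]
        return w

    def mean_ee_weight(self) -> float:
        m = self.edge_alive & self.plastic
        if not m.any():
            return float("nan")
        return float(self.weight[m].mean())

    def copy(self) -> "StructuralNetwork":
        return StructuralNetwork(
            population=NeuronPopulation(self.population.positions.copy(),
                                        self.population.is_excitatory.copy()),
            axon_paths=[AxonPath(p.origin, p.vertices.copy(), p.max_length)
                        for p in self.axon_paths],
            pre=self.pre.copy(), post=self.post.copy(),
            weight=self.weight.copy(), delay_ms=self.delay_ms.copy(),
            alive=self.alive.copy(), config=self.config)


# ---------------------------------------------------------------------------
# placement

def place_neurons(config: GrowthConfig,
                  rng: np.random.Generator | None = None) -> NeuronPopulation:
    """Scatter neurons uniformly over the culture disk.

    The count is Poisson-distributed around density * area (spatial Poisson
    process); excitatory/inhibitory labels are independent Bernoulli draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.density * np.pi * config.radius ** 2
    n = int(rng.poisson(lam))
    r = config.radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    is_exc = rng.random(n) < config.frac_excitatory
    return NeuronPopulation(positions, is_exc)


# ---------------------------------------------------------------------------
# band geometry (track pattern)

def _band_boundaries_in(lo: float, hi: float, config: GrowthConfig) -> np.ndarray:
    """All crevice/valley boundary y-values within (lo, hi).

    Bands are infinite horizontal stripes with period crevice+valley; a
    crevice starts at y = 0 (phase anchored at the culture center).
    """
    period = config.crevice_width + config.valley_width
    k0 = int(np.floor(lo / period)) - 1
    k1 = int(np.ceil(hi / period)) + 1
    ks = np.arange(k0, k1 + 1, dtype=float)
    bounds = np.concatenate([ks * period, ks * period + config.crevice_width])
    return bounds[(bounds > lo) & (bounds < hi)]


def _first_boundary_crossed(y0: float, y1: float,
                            config: GrowthConfig) -> float | None:
    """First band boundary strictly between y0 and y1, in travel order."""
    lo, hi = (y0, y1) if y0 < y1 else (y1, y0)
    bounds = _band_boundaries_in(lo, hi, config)
    if bounds.size == 0:
        return None
    return float(bounds.min() if y1 > y0 else bounds.max())


# ---------------------------------------------------------------------------
# axon growth

def grow_axon(origin: np.ndarray, config: GrowthConfig,
              rng: np.random.Generator, origin_id: int = 0,
              initial_heading: float | None = None) -> AxonPath:
    """Grow one axon from ``origin`` by concatenating fixed-length segments.

    The total length is Rayleigh-distributed with mean ``axon_mean_length``
    (scale = mean * sqrt(2/pi)); the final segment is truncated so the path
    reaches exactly that length.  Growth stops early at the culture wall.
    ``initial_heading`` overrides the uniform-random initial direction
    (diagnostics and tests).
    """
    origin = np.asarray(origin, dtype=float)
    R = config.radius
    if np.hypot(*origin) > R + 1e-9:
        raise ConfigurationError("axon origin outside the culture")

    scale = config.axon_mean_length * np.sqrt(2.0 / np.pi)
    ell = float(rng.rayleigh(scale))
    heading = (float(rng.uniform(0.0, 2.0 * np.pi))
               if initial_heading is None else float(initial_heading))

    vertices = [origin]
    pos = origin.copy()
    grown = 0.0
    while grown < ell - 1e-12:
        step_len = min(config.segment_length, ell - grown)
        if config.sigma_theta > 0:
            heading += float(rng.normal(0.0, config.sigma_theta))
        else:
            heading += 0.0
        direction = np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + step_len * direction

        if config.patterned:
            b = _first_boundary_crossed(pos[1], nxt[1], config)
            if b is not None:
                going_down = nxt[1] < pos[1]
                p_cross = config.p_down if going_down else config.p_up
                if rng.random() >= p_cross:
                    # deflect: grow parallel to the boundary, preserving the
                    # sign of the tangential (x) component; perpendicular
                    # incidence broken by rng
                    tx = direction[0]
                    if tx == 0.0:
                        tx = 1.0 if rng.random() < 0.5 else -1.0
                    heading = 0.0 if tx > 0 else np.pi
                    direction = np.array([np.cos(heading), np.sin(heading)])
                    nxt = pos + step_len * direction

        if np.hypot(*nxt) > R:
            # truncate at the dish wall and stop growing
            nxt = _clip_to_disk(pos, nxt, R)
            seg = float(np.hypot(*(nxt - pos)))
            if seg > 1e-12:
                vertices.append(nxt)
                grown += seg
            break

        vertices.append(nxt)
        pos = nxt
        grown += step_len

    return AxonPath(origin=origin_id, vertices=np.array(vertices),
                    max_length=ell)


def _clip_to_disk(p0: np.ndarray, p1: np.ndarray, R: float) -> np.ndarray:
    """Intersection of segment p0->p1 with the circle of radius R (p0 inside)."""
    d = p1 - p0
    a = d @ d
    if a == 0.0:
        return p0
    b = 2.0 * (p0 @ d)
    c = p0 @ p0 - R * R
    disc = max(b * b - 4 * a * c, 0.0)
    t = (-b + np.sqrt(disc)) / (2 * a)
    t = min(max(t, 0.0), 1.0)
    return p0 + t * d


def grow_all_axons(population: NeuronPopulation, config: GrowthConfig,
                   rng: np.random.Generator) -> list:
    return [grow_axon(population.positions[i], config, rng, origin_id=i)
            for i in range(len(population))]


# ---------------------------------------------------------------------------
# connectome assembly

def _segment_point_dist(p0: np.ndarray, p1: np.ndarray,
                        q: np.ndarray) -> np.ndarray:
    """Distances from points q (M,2) to segment p0-p1 (analytic projection)."""
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0.0:
        return np.hypot(*(q - p0).T)
    t = np.clip(((q - p0) @ d) / dd, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.hypot(*(q - proj).T)


def _candidate_targets(path: AxonPath, tree: cKDTree,
                       positions: np.ndarray,
                       radius: float) -> np.ndarray:
    """Neurons whose dendritic disk the axon path intersects."""
    v = path.vertices
    if len(v) < 2:
        return np.empty(0, dtype=np.int64)
    mids = 0.5 * (v[:-1] + v[1:])
    half_len = 0.5 * np.hypot(*(v[1:] - v[:-1]).T).max()
    found: set[int] = set()
    # ball query around each segment midpoint with a safe radius, then an
    # exact segment-to-point distance test
    lists = tree.query_ball_point(mids, radius + half_len + 1e-9)
    for k, cand in enumerate(lists):
        cand = [c for c in cand if c not in found]
        if not cand:
            continue
        idx = np.array(cand, dtype=np.int64)
        dist = _segment_point_dist(v[k], v[k + 1], positions[idx])
        found.update(idx[dist <= radius].tolist())
    return np.array(sorted(found), dtype=np.int64)


def build_connectome(population: NeuronPopulation, axon_paths: list,
                     config: GrowthConfig, rng: np.random.Generator,
                     initial_ee_weight: float | None = None,
                     fixed_weight: float | None = None,
                     max_delay_ms: float = 5.0,
                     inhibitory_delay_ms: float = 1.0,
                     random_initial_weights: bool = False,
                     w_max: float | None = None) -> StructuralNetwork:
    """Assemble the directed connectome from grown axons.

    A candidate edge i -> j exists when any axon segment of i passes within
    ``dendrite_radius`` of soma j; each candidate pair is retained
    independently with ``connect_prob``.  E->E weights start at
    ``initial_ee_weight`` (or uniform in [0, w_max] with
    ``random_initial_weights``); all other connections get the fixed
    magnitude ``fixed_weight`` with the sign of the presynaptic class.
    Excitatory delays are uniform in [0, max_delay_ms]; inhibitory delays
    are fixed.
    """
    if len(axon_paths) != len(population):
        raise StructureError("one axon path required per neuron")
    if initial_ee_weight is None or fixed_weight is None:
        from .plasticity import equilibrium_mean_weight
        from .config import StdpParams
        wbar = equilibrium_mean_weight(StdpParams())
        initial_ee_weight = wbar if initial_ee_weight is None else initial_ee_weight
        fixed_weight = wbar if fixed_weight is None else fixed_weight

    positions = population.positions
    n = len(population)
    pre_list, post_list = [], []
    if n > 0:
        tree = cKDTree(positions)
        for i in range(n):
            targets = _candidate_targets(axon_paths[i], tree, positions,
                                         config.dendrite_radius)
            targets = targets[targets != i]
            if targets.size == 0:
                continue
            keep = rng.random(targets.size) < config.connect_prob
            kept = targets[keep]
            pre_list.append(np.full(kept.size, i, dtype=np.int64))
            post_list.append(kept)

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
    else:
        pre = np.empty(0, dtype=np.int64)
        post = np.empty(0, dtype=np.int64)

    exc = population.is_excitatory
    plastic = exc[pre] & exc[post] if pre.size else np.empty(0, dtype=bool)
    weight = np.empty(pre.size, dtype=float)
    if random_initial_weights:
        wm = w_max if w_max is not None else 2.0 * initial_ee_weight
        weight[plastic] = rng.uniform(0.0, wm, int(plastic.sum()))
    else:
        weight[plastic] = initial_ee_weight
    # fixed-weight classes: E->I positive, I->* negative
    fixed = ~plastic
    weight[fixed] = np.where(exc[pre[fixed]], fixed_weight, -fixed_weight)

    delay = np.empty(pre.size, dtype=float)
    is_exc_edge = exc[pre]
    delay[is_exc_edge] = rng.uniform(0.0, max_delay_ms, int(is_exc_edge.sum()))
    delay[~is_exc_edge] = inhibitory_delay_ms

    return StructuralNetwork(population=population, axon_paths=axon_paths,
                             pre=pre, post=post, weight=weight,
                             delay_ms=delay, config=config)


def generate_network(config: GrowthConfig, **kwargs) -> StructuralNetwork:
    """Place neurons, grow axons and build the connectome with one seed."""
    rng = np.random.default_rng(config.seed)
    pop = place_neurons(config, rng)
    paths = grow_all_axons(pop, config, rng)
    return build_connectome(pop, paths, config, rng, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics

def connection_angle_distribution(network: StructuralNetwork,
                                  n_bins: int = 18
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of soma-to-soma edge angles folded to [0, 180) degrees.

    Track-patterned networks show an excess near 0 degrees (edges aligned
    with the bands); unpatterned networks are isotropic.
    """
    edges = network.edge_alive
    bin_edges = np.linspace(0.0, 180.0, n_bins + 1)
    if not edges.any():
        return np.zeros(n_bins, dtype=int), bin_edges
    p = network.population.positions
    vec = p[network.post[edges]] - p[network.pre[edges]]
    ang = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 180.0
    hist, _ = np.histogram(ang, bins=bin_edges)
    return hist, bin_edges


# ---------------------------------------------------------------------------
# serialization

def save_network(network: StructuralNetwork, path) -> None:
    """Write the network to HDF5 (positions, labels, edges, paths, config)."""
    import h5py

    flat = (np.concatenate([p.vertices for p in network.axon_paths])
            if network.axon_paths else np.empty((0, 2)))
    counts = np.array([len(p.vertices) for p in network.axon_paths],
                      dtype=np.int64)
    ells = np.array([p.max_length for p in network.axon_paths], dtype=float)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=network.population.positions)
        fh.create_dataset("is_excitatory",
                          data=network.population.is_excitatory)
        fh.create_dataset("edges/pre", data=network.pre)
        fh.create_dataset("edges/post", data=network.post)
        fh.create_dataset("edges/weight", data=network.weight)
        fh.create_dataset("edges/delay_ms", data=network.delay_ms)
        fh.create_dataset("alive", data=network.alive)
        fh.create_dataset("axons/vertices", data=flat)
        fh.create_dataset("axons/vertex_counts", data=counts)
        fh.create_dataset("axons/max_length", data=ells)
        if network.config is not None:
            from .config import config_to_dict
            fh.attrs["config"] = json.dumps(config_to_dict(network.config))


def load_network(path) -> StructuralNetwork:
    import h5py

    with h5py.File(path, "r") as fh:
        pop = NeuronPopulation(fh["positions"][...], fh["is_excitatory"][...])
        flat = fh["axons/vertices"][...]
        counts = fh["axons/vertex_counts"][...]
        ells = fh["axons/max_length"][...]
        offs = np.concatenate([[0], np.cumsum(counts)])
        paths = [AxonPath(i, flat[offs[i]:offs[i + 1]], float(ells[i]))
                 for i in range(len(counts))]
        cfg = None
        if "config" in fh.attrs:
            raw = json.loads(fh.attrs["config"])
            raw.pop("radius", None)
            cfg = GrowthConfig(**raw)
        return StructuralNetwork(
            population=pop, axon_paths=paths,
            pre=fh["edges/pre"][...], post=fh["edges/post"][...],
            weight=fh["edges/weight"][...], delay_ms=fh["edges/delay_ms"][...],
            alive=fh["alive"][...], config=cfg)


def export_edge_list(network: StructuralNetwork, path) -> None:
    """Plain CSV edge list: i, j, w, d (alive edges only)."""
    m = network.edge_alive
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "w", "d_ms"])
        for i, j, w, d in zip(network.pre[m], network.post[m],
                              network.weight[m], network.delay_ms[m]):
            writer.writerow([int(i), int(j), f"{w:.8g}", f"{d:.8g}"])
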