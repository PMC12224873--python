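"""Effective connectivity and graph-level summaries.

Transfer entropy (TE) between binarized spike trains quantifies directed
information flow: with binary symbols x_m (1 if the unit spiked in the
20 ms bin m) and Markov order k,

    TE_{Y->X} = sum p(x_{m+1}, x_m^(k), y_m^(k))
                log2 [ p(x_{m+1} | x_m^(k), y_m^(k)) / p(x_{m+1} | x_m^(k)) ]

estimated by plug-in joint histograms (zero-count states skipped).  TE
values are z-scored over all ordered pairs and thresholded at z >= z_th to
yield the binary directed effective network Z.

Weighted global efficiency converts weights to lengths (stronger = shorter,
L_ij = w_max / w_ij, or TE_max / TE_ij for effective networks), runs
Dijkstra, and averages inverse shortest-path distances over ordered pairs;
unreachable pairs contribute zero.

Community structure uses the Louvain algorithm on the symmetrized matrix;
partitions are compared with normalized mutual information
NMI = 2 I(C, C') / (H(C) + H(C')), which is 1 iff the partitions are
identical up to relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .config import TeConfig
from .dynamics import SpikeRaster

__all__ = ["EffectiveNetwork", "binarize_raster", "transfer_entropy",
           "nonburst_transition_mask",
           "threshold_z", "global_efficiency", "louvain_partition", "nmi",
           "save_partition_csv", "load_partition_csv"]


@dataclass
class EffectiveNetwork:
    te: np.ndarray       # directed TE matrix, bits
    z: np.ndarray        # z-scored TE (diagonal NaN)
    Z: np.ndarray        # binary directed adjacency (z >= z_th)
    z_threshold: float


# ---------------------------------------------------------------------------
# transfer entropy

def binarize_raster(raster: SpikeRaster, bin_ms: float) -> np.ndarray:
    """(n_units, n_bins) binary array: 1 if the unit spiked in the bin."""
    n_bins = int(np.floor(raster.duration_ms / bin_ms))
    out = np.zeros((raster.n_units, max(n_bins, 0)), dtype=np.int8)
    if n_bins <= 0:
        return out
    b = (raster.times / bin_ms).astype(np.int64)
    m = b < n_bins
    out[raster.units[m], b[m]] = 1
    return out


def _past_codes(x: np.ndarray, k: int) -> np.ndarray:
    """Encode the k-bin past (x_m, ..., x_{m-k+1}) at each usable m."""
    T = x.shape[-1]
    code = np.zeros(T - k + 1, dtype=np.int64)
    for j in range(k):
        code = code * 2 + x[k - 1 - j: T - j]
    return code


def nonburst_transition_mask(binary: np.ndarray, k: int,
                             max_active_fraction: float = 0.2) -> np.ndarray:
    """Mask of transitions whose target bin is outside network-wide bursts
    (active-unit fraction at or below ``max_active_fraction``); used for
    burst-conditioned ("generalized") TE estimation."""
    frac = binary.mean(axis=0)
    return frac[k:] <= max_active_fraction


def transfer_entropy(raster: SpikeRaster, config: TeConfig | None = None,
                     binary: np.ndarray | None = None,
                     transition_mask: np.ndarray | None = None) -> np.ndarray:
    """Plug-in TE estimate (bits) for all ordered unit pairs.

    Streams that are all-zero or all-one carry no uncertainty; TE involving
    them is 0 by convention.  The diagonal is 0.  ``transition_mask``
    restricts estimation to a subset of transitions (e.g. the out-of-burst
    bins from :func:`nonburst_transition_mask`); off by default.
    """
    config = config if config is not None else TeConfig()
    k = config.markov_order
    x = binary if binary is not None else binarize_raster(raster,
                                                          config.bin_ms)
    n, T = x.shape
    te = np.zeros((n, n), dtype=float)
    if T < k + 1:
        return te
    # per-unit codes: next symbol and k-bin past
    past = np.stack([_past_codes(x[i], k)[:-1] for i in range(n)])   # (n, n_sym)
    nxt = x[:, k:].astype(np.int64)                                   # (n, n_sym)
    if transition_mask is not None:
        transition_mask = np.asarray(transition_mask, dtype=bool)
        if transition_mask.shape != (T - k,):
            raise ValueError("transition_mask must cover the T - k "
                             "transitions")
        past = past[:, transition_mask]
        nxt = nxt[:, transition_mask]
    n_sym = past.shape[1]
    if n_sym == 0:
        return te
    n_past = 2 ** k
    xcode = nxt + 2 * past  # (n, n_sym): x_{m+1} with own past, 2^(k+1) states
    n_x = 2 ** (k + 1)

    varying = (x.min(axis=1) != x.max(axis=1))
    for xi in range(n):
        if not varying[xi]:
            continue
        for yi in range(n):
            if yi == xi or not varying[yi]:
                continue
            joint = np.bincount(xcode[xi] + n_x * past[yi],
                                minlength=n_x * n_past).astype(float)
            te[yi, xi] = _te_from_counts(joint, n_x, n_past, n_sym)
    return te


def _te_from_counts(joint: np.ndarray, n_x: int, n_past: int,
                    n_sym: int) -> float:
    """TE from the joint histogram of (x_{m+1} + 2*xpast) x ypast."""
    j = joint.reshape(n_past, n_x)          # [ypast, (nxt + 2*xpast)]
    j3 = j.reshape(n_past, n_x // 2, 2)     # [ypast, xpast, nxt]
    p_joint = j3 / n_sym
    # p(x_{m+1} | xpast, ypast)
    denom_xy = j3.sum(axis=2, keepdims=True)
    # p(x_{m+1} | xpast)
    j_x = j3.sum(axis=0)                    # [xpast, nxt]
    denom_x = j_x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_xy = j3 / denom_xy
        cond_x = j_x / denom_x
        ratio = cond_xy / cond_x[None, :, :]
        logterm = np.log2(ratio)
    mask = p_joint > 0
    return float(np.sum(p_joint[mask] * logterm[mask]))


def threshold_z(te: np.ndarray,
                config: TeConfig | None = None) -> EffectiveNetwork:
    """z-score the off-diagonal TE values and binarize at z_th."""
    config = config if config is not None else TeConfig()
    te = np.asarray(te, dtype=float)
    n = te.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = te[off]
    if vals.size < 2:
        raise ValueError("need at least two off-diagonal TE values")
    mu = float(vals.mean())
    sigma = float(vals.std())
    z = np.full_like(te, np.nan)
    Z = np.zeros_like(te, dtype=np.int8)
    if sigma <= 1e-12 * max(abs(mu), 1.0):
        warnings.warn("constant TE matrix: sigma = 0, empty effective network")
        return EffectiveNetwork(te, z, Z, config.z_threshold)
    z[off] = (te[off] - mu) / sigma
    Z[off] = (z[off] >= config.z_threshold).astype(np.int8)
    return EffectiveNetwork(te, z, Z, config.z_threshold)


# ---------------------------------------------------------------------------
# global efficiency

def global_efficiency(matrix: np.ndarray, mode: str = "synaptic",
                      w_max: float | None = None,
                      te_max: float | None = None,
                      alive: np.ndarray | None = None) -> float:
    """Weighted global efficiency of a nonnegative coupling matrix.

    mode='synaptic': lengths L_ij = w_max / w_ij (w_max defaults to the
    matrix maximum); mode='effective': L_ij = te_max / TE_ij with te_max
    the maximum unnormalized TE across the damage sequence (defaults to
    the matrix maximum).  Entries <= 0 are non-edges.  Averages 1/l_ij over
    ordered pairs of alive nodes; unreachable pairs contribute 0.
    """
    m = np.asarray(matrix, dtype=float)
    if mode not in ("synaptic", "effective"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "synaptic" and np.any(m < 0):
        raise ValueError("synaptic-mode efficiency requires nonnegative "
                         "weights (use the E->E plastic submatrix)")
    if alive is not None:
        idx = np.nonzero(np.asarray(alive, dtype=bool))[0]
        m = m[np.ix_(idx, idx)]
    n = m.shape[0]
    if n < 2:
        return 0.0
    ref = w_max if mode == "synaptic" else te_max
    pos = m > 0
    if not pos.any():
        return 0.0
    if ref is None:
        ref = float(m.max())
    lengths = np.zeros_like(m)
    lengths[pos] = ref / m[pos]
    graph = csr_matrix(lengths)
    dist = dijkstra(graph, directed=True)
    np.fill_diagonal(dist, np.inf)  # exclude i == j
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# communities

def louvain_partition(matrix: np.ndarray, seed: int = 0,
                      n_restarts: int = 10,
                      alive: np.ndarray | None = None) -> np.ndarray:
    """Louvain community labels on the symmetrized nonnegative matrix.

    Directed input is symmetrized as (M + M^T)/2.  Runs ``n_restarts``
    seeded restarts and keeps the partition with the best modularity.
    Returns a label per node (nodes excluded by ``alive`` get label -1).
    """
    m = np.asarray(matrix, dtype=float)
    n_total = m.shape[0]
    labels = np.full(n_total, -1, dtype=np.int64)
    if alive is not None:
        idx = np.nonzero(np.asarray(alive, dtype=bool))[0]
    else:
        idx = np.arange(n_total)
    if idx.size == 0:
        return labels
    sub = m[np.ix_(idx, idx)]
    sym = (sub + sub.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    g = nx.from_numpy_array(sym)
    best, best_q = None, -np.inf
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(g, weight="weight",
                                                 seed=seed + r)
        q = nx.community.modularity(g, comms, weight="weight") \
            if g.number_of_edges() else 0.0
        if q > best_q:
            best, best_q = comms, q
    for label, members in enumerate(best):
        labels[idx[list(members)]] = label
    return labels


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information 2 I / (H + H') between two partitions
    of the same node set; 1 iff identical up to relabeling, 0 for
    independent partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions cover different node sets")
    n = a.size
    if n == 0:
        raise ValueError("empty partitions")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    p = cont / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nzp = p > 0
    mi = float(np.sum(p[nzp] * np.log(p[nzp] / np.outer(pa, pb)[nzp])))
    ha = -float(np.sum(pa[pa > 0] * np.log(pa[pa > 0])))
    hb = -float(np.sum(pb[pb > 0] * np.log(pb[pb > 0])))
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both trivial single-community partitions
    denom = ha + hb
    if denom == 0.0:
        return 0.0
    return float(np.clip(2.0 * mi / denom, 0.0, 1.0))


def save_partition_csv(labels, path) -> None:
    """Two-column CSV (node, community); -1 marks excluded (dead) nodes."""
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        fh.write("node,community\n")
        for node, label in enumerate(labels):
            fh.write(f"{node},{int(label)}\n")


def load_partition_csv(path) -> np.ndarray:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            _, label = line.strip().split(",")
            out.append(int(label))
    return np.asarray(out, dtype=np.int64)
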