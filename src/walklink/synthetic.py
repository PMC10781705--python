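"""Synthetic network generation and link-removal cross-validation.

Experiments in this package run on synthetic graphs: configuration-model
scale-free networks with power-law degree distribution P(k) ~ k^(-gamma)
(the regime 2 < gamma <= 4 typical of real complex networks such as
protein-interaction maps), and Erdos-Renyi G(N, p) graphs as a
homogeneous control.  The scale-free generator is what gives the largest
hub its characteristic growth k_max ~ N^(1/(gamma-1)), the quantity that
drives the quantum-walk sampler's query cost.

Cross-validation folds remove a random fraction of links to form a train
graph and a held-out truth matrix A'; folds are independent resamples,
not a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import Network

_MODEL_REGISTRY: dict[str, str] = {
    "sf": "configuration-model scale-free, P(k) ~ k^(-gamma)",
    "er": "Erdos-Renyi G(N, p) with p = k_av/(N-1)",
}


def available_models() -> dict[str, str]:
    """Registry of synthetic network models (name -> description)."""
    return dict(_MODEL_REGISTRY)


def _subseed(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived child generator, reproducible per (seed, key)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class DegreeSequenceSpec:
    """Parameters of an i.i.d. power-law degree sequence.

    gamma is the power-law exponent (> 2 so the mean degree converges);
    k_min the smallest allowed degree; degrees are truncated at N-1 and
    the sequence sum is forced even by incrementing one random node.
    """

    N: int
    gamma: float
    k_min: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2")
        if self.N < 10:
            raise ValueError("N must be at least 10")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


def sample_powerlaw_degrees(spec: DegreeSequenceSpec,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw N degrees i.i.d. from P(k) ~ k^(-gamma), k in [k_min, N-1]."""
    if rng is None:
        rng = _subseed(spec.seed, 0)
    ks = np.arange(spec.k_min, spec.N, dtype=np.int64)
    probs = ks.astype(float) ** (-spec.gamma)
    probs /= probs.sum()
    degrees = rng.choice(ks, size=spec.N, p=probs)
    if degrees.sum() % 2 == 1:
        idx = rng.integers(spec.N)
        degrees[idx] = min(degrees[idx] + 1, spec.N - 1)
        if degrees.sum() % 2 == 1:  # hit the N-1 cap; bump another node
            idx2 = (idx + 1) % spec.N
            degrees[idx2] += 1
    return degrees


def _simplify_by_rewiring(multigraph: nx.MultiGraph, rng: np.random.Generator,
                          max_tries: int = 50) -> set[tuple[int, int]]:
    """Collapse a configuration-model multigraph to a simple edge set.

    Each self-loop or surplus parallel edge is repaired, where possible,
    by swapping its endpoints with a randomly chosen existing edge (an
    edge swap preserves all degrees); offenders that cannot be placed in
    max_tries attempts are dropped, so a node's final degree may fall
    below its sampled degree.
    """
    simple: set[tuple[int, int]] = set()
    offenders: list[tuple[int, int]] = []
    for u, v in multigraph.edges():
        e = (min(u, v), max(u, v))
        if u == v or e in simple:
            offenders.append((u, v))
        else:
            simple.add(e)
    edge_list = list(simple)
    for a, b in offenders:
        placed = False
        for _ in range(max_tries):
            if not edge_list:
                break
            idx = int(rng.integers(len(edge_list)))
            x, y = edge_list[idx]
            if rng.integers(2):
                x, y = y, x
            e1 = (min(a, x), max(a, x))
            e2 = (min(b, y), max(b, y))
            if a == x or b == y or e1 == e2 or e1 in simple or e2 in simple:
                continue
            old = edge_list[idx]
            simple.discard(old)
            edge_list[idx] = edge_list[-1]
            edge_list.pop()
            simple.add(e1)
            simple.add(e2)
            edge_list.append(e1)
            edge_list.append(e2)
            placed = True
            break
        if not placed:
            continue  # degree loss accepted and documented
    return simple


def generate_scale_free(spec: DegreeSequenceSpec) -> Network:
    """Configuration-model scale-free network from a power-law degree sequence.

    Deterministic under ``spec.seed``.  Self-loops and multi-edges from
    the stub matching are repaired by degree-preserving rewiring where
    possible and dropped otherwise, so the minimum degree can fall below
    ``k_min`` (but the degree distribution tail is preserved).
    """
    rng = _subseed(spec.seed, 1)
    degrees = sample_powerlaw_degrees(spec, _subseed(spec.seed, 0))
    for attempt in range(5):  # resample on (rare) pathological sequences
        mg = nx.configuration_model(
            degrees.tolist(), seed=int(_subseed(spec.seed, 2, attempt).integers(2**31)))
        edges = _simplify_by_rewiring(mg, rng)
        if edges:
            return Network(spec.N, edges)
        degrees = sample_powerlaw_degrees(spec, rng)
    raise RuntimeError("could not build a simple graph from the degree sequence")


def generate_er(N: int, k_av: float, seed: int) -> Network:
    """Erdos-Renyi G(N, p) with p chosen to give average degree k_av."""
    if not 0 < k_av < N - 1:
        raise ValueError("require 0 < k_av < N-1")
    p = k_av / (N - 1)
    g = nx.fast_gnp_random_graph(N, p, seed=int(seed))
    return Network(N, g.edges())


def generate(model: str, N: int, *, gamma: float = 2.5, k_min: int = 2,
             k_av: float = 6.0, seed: int = 0) -> Network:
    """Dispatch by registry name ('sf' or 'er')."""
    if model == "sf":
        return generate_scale_free(DegreeSequenceSpec(N=N, gamma=gamma, k_min=k_min, seed=seed))
    if model == "er":
        return generate_er(N, k_av, seed)
    raise ValueError(f"unknown model {model!r}; available: {sorted(_MODEL_REGISTRY)}")


@dataclass
class CVFold:
    """One link-removal fold: train graph plus held-out truth matrix A'.

    A'_ij = 1 exactly where an original link was removed (both
    orientations); train adjacency + A' reproduces the original A.
    """

    train: Network
    truth: np.ndarray
    fold_index: int
    seed: int

    def __post_init__(self):
        t = self.train.adjacency
        if np.any((self.truth == 1) & (t == 1)):
            raise ValueError("held-out links overlap the train graph")


def cv_split(network: Network, fraction: float, folds: int, seed: int) -> list[CVFold]:
    """Independent random link-removal folds.

    Each fold removes a uniform random subset of round(fraction * |E|)
    links from the full graph (folds are independent resamples, not a
    partition of the edge set).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    edges = sorted(network.edges)
    m = len(edges)
    n_remove = int(round(fraction * m))
    if n_remove < 1:
        raise ValueError("fraction removes fewer than one link")
    if m - n_remove < 1:
        raise ValueError("removal would leave no links")
    out: list[CVFold] = []
    for k in range(folds):
        rng = _subseed(seed, 10, k)
        chosen = rng.choice(m, size=n_remove, replace=False)
        removed = {edges[i] for i in chosen}
        kept = [e for e in edges if e not in removed]
        train = Network(network.node_count, kept)
        truth = np.zeros((network.node_count,) * 2, dtype=np.int64)
        for u, v in removed:
            truth[u, v] = 1
            truth[v, u] = 1
        sub = int(rng.integers(2**31))
        out.append(CVFold(train=train, truth=truth, fold_index=k, seed=sub))
    return out


def kmax_scaling_exponent(gamma: float, sizes, reps: int, seed: int) -> float:
    """Empirical exponent of the hub-size growth k_max ~ N^beta.

    Generates ``reps`` scale-free networks per size, averages k_max, and
    returns the least-squares slope of log(mean k_max) against log(N).
    For a power-law degree distribution the expected slope is
    1/(gamma-1).
    """
    sizes = sorted(set(int(s) for s in sizes))
    if len(sizes) < 3:
        raise ValueError("need at least 3 distinct sizes")
    if reps < 5:
        raise ValueError("need reps >= 5")
    means = []
    for si, n in enumerate(sizes):
        kmaxes = []
        for r in range(reps):
            sub = int(_subseed(seed, 20, si, r).integers(2**31))
            net = generate_scale_free(DegreeSequenceSpec(N=n, gamma=gamma, k_min=2, seed=sub))
            kmaxes.append(net.k_max)
        means.append(float(np.mean(kmaxes)))
    if len(set(means)) == 1:
        raise ValueError("degenerate ensemble: k_max constant across sizes")
    slope, _ = np.polyfit(np.log(sizes), np.log(means), 1)
    return float(slope)
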