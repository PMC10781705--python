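"""Classical samplers for the A^2 and A^3 path-score distributions.

Path-based link prediction scores a node pair (i, j) by the number of
paths of a given length between them, i.e. by entries of powers of the
adjacency matrix.  Rather than computing the full score matrix, the two
samplers here draw pairs directly from the normalized score distribution

    P[(i, j)] = (A^n)_ij / ||A^n||_{1,1},    n = 2 or 3,

using only oracle queries (degree / neighbour / vertex-pair), so that
the exact query cost of producing samples can be accounted:

* the A^2 sampler preprocesses node weights p_v ~ k_v^2 with N degree
  queries and spends 2 neighbour + 1 pair query per draw;
* the A^3 sampler preprocesses edge weights p_uv ~ k_u k_v by reading
  the whole graph (N degree + 2|E| neighbour queries) and draws for
  free thereafter.

Both target laws are verified against :func:`exact_power_distribution`,
the brute-force dense oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import GGMOracle, Network


@dataclass(frozen=True)
class ScoreDistribution:
    """Normalized probability over ordered node pairs induced by f(A).

    ``matrix[i, j]`` is |f(A)_ij|^q / ||f(A)||_q^q; entries sum to 1.
    """

    matrix: np.ndarray
    source: str
    q: int = 1

    def __post_init__(self):
        total = float(self.matrix.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"distribution sums to {total}, not 1")
        if np.any(self.matrix < 0):
            raise ValueError("negative probability entry")


@dataclass(frozen=True)
class LinkSample:
    """One drawn pair with its usefulness flag and per-draw query cost."""

    i: int
    j: int
    useful: bool
    parity: str = "none"  # 'even' / 'odd' for quantum-walk samples
    queries_spent: int = 0


def exact_power_distribution(network: Network, n: int) -> ScoreDistribution:
    """Ground-truth sampling law for A^n scores (dense, L_{1,1}-normalized).

    Serves as the independent oracle that both samplers are checked
    against; entries of A^n are path counts, hence nonnegative.
    """
    if n not in (2, 3):
        raise ValueError("n must be 2 or 3")
    if network.edge_count == 0:
        raise ValueError("network has no edges")
    a = network.adjacency.astype(np.int64)
    power = np.linalg.matrix_power(a, n)
    norm = power.sum()
    if norm == 0:
        raise ValueError(f"A^{n} is identically zero")
    return ScoreDistribution(matrix=power / norm, source=f"A^{n}", q=1)


@dataclass
class A2Sampler:
    """Node-weighted sampler targeting A^2 scores: p_v = k_v^2 / sum k_w^2."""

    node_probs: np.ndarray
    cumulative: np.ndarray
    degrees: np.ndarray
    preprocessing_queries: int


def build_a2(oracle: GGMOracle) -> A2Sampler:
    """Preprocess node weights with exactly N degree queries.

    Note sum_v k_v^2 = ||A^2||_{1,1}, so drawing v ~ k_v^2 and then two
    independent uniform neighbours of v has marginal exactly the A^2 law.
    """
    n = oracle.network.node_count
    before = oracle.degree_queries
    degrees = np.array([oracle.degree(v) for v in range(n)], dtype=np.int64)
    assert oracle.degree_queries - before == n
    weights = degrees.astype(float) ** 2
    total = weights.sum()
    if total == 0:
        raise ValueError("all degrees are zero; A^2 distribution undefined")
    probs = weights / total
    return A2Sampler(node_probs=probs, cumulative=np.cumsum(probs),
                     degrees=degrees, preprocessing_queries=n)


def draw_a2(sampler: A2Sampler, oracle: GGMOracle,
            rng: np.random.Generator) -> LinkSample:
    """One draw from the A^2 law: costs 2 neighbour + 1 pair query.

    Selects v by bisection on the cumulative node array (no queries),
    then i and j as independent uniformly random neighbours of v.  The
    i = j coincidence needs no query but still counts as a bad sample.
    """
    u = rng.random()
    v = int(np.searchsorted(sampler.cumulative, u, side="right"))
    v = min(v, len(sampler.cumulative) - 1)
    k = int(sampler.degrees[v])
    l1 = int(rng.integers(1, k + 1))
    l2 = int(rng.integers(1, k + 1))
    i = oracle.neighbour(v, l1)
    j = oracle.neighbour(v, l2)
    connected = oracle.pair(i, j)
    useful = (i != j) and connected == 0
    return LinkSample(i=i, j=j, useful=useful, queries_spent=3)


@dataclass
class A3Sampler:
    """Edge-weighted sampler targeting A^3 scores: p_uv = k_u k_v / Z.

    Support is the ordered adjacent pairs; Z = sum over them of k_u k_v,
    which equals ||A^3||_{1,1}.  Preprocessing reads the whole graph, so
    neighbour lists and the adjacency are cached and draws are query-free.
    """

    ordered_pairs: np.ndarray  # (2|E|, 2)
    pair_probs: np.ndarray
    cumulative: np.ndarray
    neighbour_lists: tuple
    edge_set: frozenset
    preprocessing_queries: int


def build_a3(oracle: GGMOracle) -> A3Sampler:
    """Enumerate ordered adjacent pairs with N degree + 2|E| neighbour queries."""
    net = oracle.network
    n = net.node_count
    degrees = np.empty(n, dtype=np.int64)
    nbrs: list[list[int]] = []
    for v in range(n):
        k = oracle.degree(v)
        degrees[v] = k
        nbrs.append([oracle.neighbour(v, l) for l in range(1, k + 1)])
    if degrees.sum() == 0:
        raise ValueError("edgeless network; A^3 distribution undefined")
    pairs = []
    weights = []
    for u in range(n):
        for v in nbrs[u]:
            pairs.append((u, v))
            weights.append(degrees[u] * degrees[v])
    pairs_arr = np.array(pairs, dtype=np.int64)
    w = np.array(weights, dtype=float)
    probs = w / w.sum()
    edge_set = frozenset((min(u, v), max(u, v)) for u, v in pairs)
    return A3Sampler(ordered_pairs=pairs_arr, pair_probs=probs,
                     cumulative=np.cumsum(probs),
                     neighbour_lists=tuple(np.array(a, dtype=np.int64) for a in nbrs),
                     edge_set=edge_set,
                     preprocessing_queries=int(n + degrees.sum()))


def draw_a3(sampler: A3Sampler, rng: np.random.Generator) -> LinkSample:
    """One draw from the A^3 law: zero input queries (graph fully cached)."""
    r = rng.random()
    idx = int(np.searchsorted(sampler.cumulative, r, side="right"))
    idx = min(idx, len(sampler.cumulative) - 1)
    u, v = sampler.ordered_pairs[idx]
    nu = sampler.neighbour_lists[u]
    nv = sampler.neighbour_lists[v]
    i = int(nu[rng.integers(len(nu))])
    j = int(nv[rng.integers(len(nv))])
    useful = (i != j) and (min(i, j), max(i, j)) not in sampler.edge_set
    return LinkSample(i=i, j=j, useful=useful, queries_spent=0)


def sample_many(method: str, oracle: GGMOracle, n_draws: int,
                rng: np.random.Generator) -> list[LinkSample]:
    """Draw ``n_draws`` samples with the named method ('a2' or 'a3')."""
    if method == "a2":
        sampler = build_a2(oracle)
        return [draw_a2(sampler, oracle, rng) for _ in range(n_draws)]
    if method == "a3":
        sampler = build_a3(oracle)
        return [draw_a3(sampler, rng) for _ in range(n_draws)]
    raise ValueError("method must be 'a2' or 'a3'")


def empirical_pair_matrix(samples, n: int) -> np.ndarray:
    """Frequency matrix of drawn ordered pairs (rows sum to 1 overall)."""
    counts = np.zeros((n, n), dtype=float)
    for s in samples:
        counts[s.i, s.j] += 1
    return counts / max(len(samples), 1)


def query_cost_report(oracle: GGMOracle, *, preprocessing_queries: int,
                      draws: int, n_useful: int,
                      per_draw_queries: int) -> dict:
    """Summarize query accounting for a completed sampling run.

    Splits the oracle's counters into the preprocessing and per-sample
    phases and reports the empirical useful-sample rate p_hat_G together
    with the draws-per-useful ratio n_s / p_hat_G that the complexity
    bounds are phrased in.
    """
    totals = oracle.counter_snapshot()
    sampling_queries = totals["total"] - preprocessing_queries
    p_hat = n_useful / draws if draws else float("nan")
    return {
        "degree_queries": totals["degree"],
        "neighbour_queries": totals["neighbour"],
        "pair_queries": totals["pair"],
        "total_queries": totals["total"],
        "preprocessing_queries": preprocessing_queries,
        "sampling_queries": sampling_queries,
        "expected_sampling_queries": per_draw_queries * draws,
        "draws": draws,
        "n_useful": n_useful,
        "p_hat_G": p_hat,
        "draws_per_useful": draws / n_useful if n_useful else float("inf"),
    }
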