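"""Quantum-walk link-prediction sampler, simulated classically.

A continuous-time quantum walk e^{-iAt} on the node space splits into
cos(At) (even powers of A — direct similarity) and sin(At) (odd powers —
neighbour similarity).  The sampler's measurement law over ordered pairs
(i, j), with a parity label from the ancilla, is

    p_ij^even(t) = |cos(At)_ij|^2 / N,
    p_ij^odd(t)  = |sin(At)_ij|^2 / N,

which together form a normalized distribution (the L_{2,2} analogue of
the classical L_{1,1}-normalized A^n scores).  No statevector or gate
sequence is simulated: the matrix functions are computed exactly (to
floating point) from the symmetric eigendecomposition A = Q diag(L) Q^T,
and the circuit appears only through its gate/qubit counts and the
query-cost formulas of the d-sparse Hamiltonian-simulation estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import Network
from .samplers import LinkSample

#: Largest N accepted for dense eigendecomposition-based walk matrices.
DENSE_MODE_CAP = 5000


@dataclass(frozen=True)
class WalkMatrices:
    """cos(At) and sin(At) at walk time t (both symmetric, C^2+S^2=I)."""

    C: np.ndarray
    S: np.ndarray
    t: float


def _eigendecomposition(network: Network):
    return np.linalg.eigh(network.adjacency.astype(float))


def walk_matrices(network: Network, t: float) -> WalkMatrices:
    """Compute cos(At), sin(At) via the symmetric eigendecomposition of A."""
    n = network.node_count
    if n > DENSE_MODE_CAP:
        raise ValueError(
            f"N={n} exceeds the dense-mode cap ({DENSE_MODE_CAP}); "
            "walk matrices require a full eigendecomposition — reduce the "
            "network size or raise walklink.qlp.DENSE_MODE_CAP explicitly")
    if t < 0:
        raise ValueError("walk time t must be nonnegative")
    if t == 0:
        # identity walk, exact (avoids eigendecomposition residue at the
        # degenerate point where cos(0) = 1 analytically)
        eye = np.eye(n)
        return WalkMatrices(C=eye, S=np.zeros((n, n)), t=0.0)
    lam, q = _eigendecomposition(network)
    c = (q * np.cos(lam * t)) @ q.T
    s = (q * np.sin(lam * t)) @ q.T
    c = (c + c.T) / 2.0
    s = (s + s.T) / 2.0
    return WalkMatrices(C=c, S=s, t=float(t))


@dataclass(frozen=True)
class QLPDistribution:
    """Paired even/odd measurement distributions of the walk sampler."""

    p_even: np.ndarray
    p_odd: np.ndarray
    p_even_total: float
    p_odd_total: float
    t: float

    @property
    def stacked(self) -> np.ndarray:
        """Even and odd matrices stacked: shape (2, N, N), sums to 1."""
        return np.stack([self.p_even, self.p_odd])


def qlp_distribution(network: Network, t: float) -> QLPDistribution:
    """Measurement distribution p_ij^even, p_ij^odd of the walk sampler at time t."""
    wm = walk_matrices(network, t)
    n = network.node_count
    p_even = wm.C**2 / n
    p_odd = wm.S**2 / n
    te, to = float(p_even.sum()), float(p_odd.sum())
    if abs(te + to - 1.0) > 1e-6:
        raise ArithmeticError(f"parity totals sum to {te + to}, not 1")
    return QLPDistribution(p_even=p_even, p_odd=p_odd,
                           p_even_total=te, p_odd_total=to, t=float(t))


def sample_qlp(dist: QLPDistribution, rng: np.random.Generator,
               n_draws: int, network: Network | None = None) -> list[LinkSample]:
    """Draw parity-labelled pair samples from the walk distribution.

    Equivalent to measuring ancilla + both node registers: one
    categorical draw over the 2 N^2 outcomes (parity, i, j).  The
    ``useful`` flag (A_ij = 0 and i != j) is the post-selection a user
    would apply for link prediction; it requires the network.
    """
    n = dist.p_even.shape[0]
    flat = np.concatenate([dist.p_even.ravel(), dist.p_odd.ravel()])
    flat = flat / flat.sum()  # remove float residue for rng.choice
    draws = rng.choice(flat.size, size=n_draws, p=flat)
    adj = network.adjacency if network is not None else None
    out = []
    for d in draws:
        parity = "even" if d < n * n else "odd"
        r = int(d) % (n * n)
        i, j = divmod(r, n)
        useful = bool(adj is not None and i != j and adj[i, j] == 0)
        out.append(LinkSample(i=i, j=j, useful=useful, parity=parity,
                              queries_spent=0))
    return out


def circuit_gate_counts(N: int) -> tuple[int, int, int]:
    """Gate and qubit counts of the sampling circuit for an N-node network.

    With n = ceil(log2 N) qubits per node register: n + 2 Hadamards,
    n CNOTs, and 2n + 1 qubits total (two node registers plus the parity
    ancilla); networks whose size is not a power of two pad to the next
    one, the padded basis states carrying zero amplitude.
    """
    if N < 2:
        raise ValueError("need at least 2 nodes")
    n = int(np.ceil(np.log2(N)))
    return n + 2, n, 2 * n + 1


@dataclass(frozen=True)
class ResourceEstimate:
    """Inputs of the query-cost estimate for the walk sampler.

    n_s useful samples at useful-probability p_G, walk time t, on a
    network with maximum degree k_max; C_queries optionally gives the
    per-call cost of one e^{-iAt} application under a chosen simulation
    algorithm.  epsilon is the simulation error, entering only
    polylogarithmically and therefore dropped from the arithmetic.
    """

    n_s: int
    p_G: float
    k_max: int
    t: float
    C_queries: float | None = None
    epsilon: float = 1e-3


def dsparse_query_estimate(est: ResourceEstimate) -> dict[str, float]:
    """Query-cost estimate n_s * k_max * t / p_G under d-sparse simulation.

    Each useful sample costs one full circuit run per 1/p_G attempts and
    each run re-queries the input (superposed queries cannot be cached);
    one e^{-iAt} application costs ~ t * d * ||A||_max queries with
    d = k_max and ||A||_max = 1 for a 0/1 adjacency.  Constants and
    polylog factors are set to 1: the estimate is a comparator across
    (n_s, p_G, k_max, t), not an absolute count.  When ``C_queries`` is
    supplied the generic form n_s * C / p_G is reported alongside.
    """
    if est.p_G <= 0:
        raise ValueError("p_G must be positive (no useful mass -> unbounded cost)")
    out = {"dsparse": est.n_s * est.k_max * est.t / est.p_G}
    if est.C_queries is not None:
        out["generic"] = est.n_s * est.C_queries / est.p_G
    return out


def speedup_condition(N: int, gamma: float, n_s: int) -> bool:
    """Whether the walk sampler beats the classical O(N) query cost.

    On a scale-free network the hub degree grows as k_max ~ N^(1/(gamma-1)),
    so n_s samples cost ~ n_s * N^(1/(gamma-1)) queries; this is sub-linear
    in N exactly when n_s < N^((gamma-2)/(gamma-1)) (strict inequality).
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2 (bound degenerates)")
    return n_s < N ** ((gamma - 2) / (gamma - 1))
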