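"""Usefulness and precision metrics for sampling-based link prediction.

A drawn pair (i, j) is *good* (useful) when A_ij = 0 and i != j — only
such pairs can be new-link predictions; the mask of good pairs is
G = J - (A + I).  For any score distribution P over ordered pairs,

    p_B = sum_ij (A + I)_ij P_ij,     p_G = sum_ij G_ij P_ij,

with p_B + p_G = 1.  For the quantum-walk distribution these become
time-dependent curves p_G^even(t), p_G^odd(t), and with a held-out truth
matrix A' marking removed links we get correctness curves p_C^even(t),
p_C^odd(t) and the sampling-conditional precision p_C|G = p_C / p_G that
compares methods.

Curves over a t-grid are computed spectrally: one eigendecomposition of
A yields every needed entry of cos(At) and sin(At) as a cosine/sine
series, and sum_ij (C_ij^2 + S_ij^2) = N (a Frobenius identity), so p_G
needs only the diagonal and edge entries and p_C only the held-out
entries.  The dense route through the full distribution exists too and
the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_io import Network, good_link_matrix
from .qlp import DENSE_MODE_CAP, QLPDistribution
from .samplers import ScoreDistribution, exact_power_distribution
from .synthetic import cv_split

#: p_G components below this floor make the p_C / p_G division unstable;
#: such points are reported as missing (None) rather than divided.
PG_STABILITY_FLOOR = 1e-8


def p_bad(dist: ScoreDistribution | QLPDistribution, network: Network) -> float:
    """Probability of drawing a bad pair (existing link or diagonal)."""
    mask = network.adjacency + np.eye(network.node_count, dtype=np.int64)
    return _mask_probability(dist, mask, network)


def p_good(dist: ScoreDistribution | QLPDistribution, network: Network) -> float:
    """Probability of drawing a good pair: sum_ij G_ij P_ij."""
    return _mask_probability(dist, good_link_matrix(network), network)


def _mask_probability(dist, mask: np.ndarray, network: Network) -> float:
    if isinstance(dist, QLPDistribution):
        p = dist.p_even + dist.p_odd
    else:
        p = dist.matrix
    if p.shape != mask.shape:
        raise ValueError(f"shape mismatch: distribution {p.shape} vs mask {mask.shape}")
    return float((mask * p).sum())


# -- spectral curve machinery ---------------------------------------------


def _pair_series(q: np.ndarray, lam: np.ndarray, rows: np.ndarray,
                 cols: np.ndarray, t_grid: np.ndarray):
    """sum over listed (row, col) pairs of cos(At)_ij^2 and sin(At)_ij^2, per t.

    C_ij(t) = sum_k Q_ik Q_jk cos(lam_k t) — the listed entries are
    assembled for the whole grid with two small matrix products.
    """
    m = q[rows] * q[cols]                       # (P, N)
    phase = np.outer(lam, t_grid)               # (N, T)
    cvals = m @ np.cos(phase)                   # (P, T)
    svals = m @ np.sin(phase)
    return (cvals**2).sum(axis=0), (svals**2).sum(axis=0)


def _bad_pairs(network: Network):
    n = network.node_count
    diag = np.arange(n)
    if network.edge_count:
        e = np.array(sorted(network.edges), dtype=np.int64)
        rows = np.concatenate([diag, e[:, 0], e[:, 1]])
        cols = np.concatenate([diag, e[:, 1], e[:, 0]])
    else:
        rows, cols = diag, diag
    return rows, cols


def p_good_qlp_curve(network: Network, t_grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p_G, p_G^even, p_G^odd) of the walk distribution over a t grid.

    Uses sum_ij (C^2 + S^2)_ij entries = trace identities: the total even
    mass is sum_k cos^2(lam_k t), so only the bad (diagonal + edge)
    entries need explicit assembly and p_G^even = total - bad.
    """
    n = network.node_count
    if n > DENSE_MODE_CAP:
        raise ValueError(f"N={n} exceeds the dense-mode cap ({DENSE_MODE_CAP})")
    t_grid = np.asarray(t_grid, dtype=float)
    lam, q = np.linalg.eigh(network.adjacency.astype(float))
    phase = np.outer(lam, t_grid)
    even_total = (np.cos(phase) ** 2).sum(axis=0)   # = ||cos(At)||_F^2
    odd_total = (np.sin(phase) ** 2).sum(axis=0)
    rows, cols = _bad_pairs(network)
    bad_even, bad_odd = _pair_series(q, lam, rows, cols, t_grid)
    pg_even = np.maximum(even_total - bad_even, 0.0) / n
    pg_odd = np.maximum(odd_total - bad_odd, 0.0) / n
    # t = 0 is the identity walk: no off-diagonal mass, exactly
    zero = t_grid == 0
    pg_even[zero] = 0.0
    pg_odd[zero] = 0.0
    return pg_even + pg_odd, pg_even, pg_odd


def p_good_qlp(network: Network, t: float) -> tuple[float, float, float]:
    """(p_G, p_G^even, p_G^odd) at a single walk time."""
    pg, pe, po = p_good_qlp_curve(network, [t])
    return float(pg[0]), float(pe[0]), float(po[0])


def _validate_truth(train: Network, truth: np.ndarray) -> None:
    truth = np.asarray(truth)
    n = train.node_count
    if truth.shape != (n, n):
        raise ValueError("truth matrix shape mismatch")
    if np.any((truth == 1) & (train.adjacency == 1)):
        raise ValueError("truth marks pairs that are links in the train graph")
    if np.any(np.diag(truth) != 0):
        raise ValueError("truth matrix must have zero diagonal")


def p_correct_qlp_curve(train: Network, truth: np.ndarray, t_grid):
    """(p_C^even, p_C^odd) over a t grid: walk mass on the held-out pairs."""
    _validate_truth(train, truth)
    t_grid = np.asarray(t_grid, dtype=float)
    rows, cols = np.nonzero(truth)
    if rows.size == 0:
        z = np.zeros_like(t_grid)
        return z, z.copy()
    lam, q = np.linalg.eigh(train.adjacency.astype(float))
    ce, so = _pair_series(q, lam, rows, cols, t_grid)
    n = train.node_count
    return ce / n, so / n


def p_correct_qlp(train: Network, truth: np.ndarray, t: float) -> tuple[float, float]:
    """(p_C^even, p_C^odd) at a single walk time."""
    ce, so = p_correct_qlp_curve(train, truth, [t])
    return float(ce[0]), float(so[0])


def precision_given_good(p_c: float, p_g: float,
                         floor: float = PG_STABILITY_FLOOR):
    """Sampling-conditional precision p_C / p_G, or None below the floor."""
    if p_c > p_g + 1e-12:
        raise ValueError(f"p_C={p_c} exceeds p_G={p_g}")
    if p_g < floor:
        return None
    return p_c / p_g


def classical_precision(train: Network, truth: np.ndarray, n: int):
    """p_C|G of the exact A^n score distribution, or None if p_G = 0.

    The denominator is the good mass of the distribution, the numerator
    its mass on the held-out pairs; the ratio is directly comparable to
    the walk sampler's p_C|G curves.
    """
    _validate_truth(train, truth)
    dist = exact_power_distribution(train, n)
    g = good_link_matrix(train)
    denom = float((g * dist.matrix).sum())
    numer = float((np.asarray(truth) * dist.matrix).sum())
    return precision_given_good(numer, denom)


def tv_distance(empirical: np.ndarray, exact: np.ndarray) -> float:
    """Total variation distance (1/2) sum |emp - exact| between two
    distributions given as same-shaped arrays of probabilities."""
    empirical = np.asarray(empirical, dtype=float)
    exact = np.asarray(exact, dtype=float)
    if empirical.shape != exact.shape:
        raise ValueError("shape mismatch")
    return 0.5 * float(np.abs(empirical - exact).sum())


# -- experiment pipelines --------------------------------------------------


def default_t_grid(t_min: float = 0.1, t_max: float = 5.0,
                   points: int = 50) -> np.ndarray:
    """Walk-time grid used for curves; starts above 0 where p_G ~ 0."""
    return np.linspace(t_min, t_max, points)


def fig2_experiment(networks, t_grid) -> dict[str, pd.DataFrame]:
    """Useful-sample probability curves p_G(t) for an ensemble of networks.

    Returns tidy curves (one row per network per t) plus a per-network
    summary with the saturation value max_t p_G(t) against N and k_av —
    the quantities whose N-independence makes 1/p_G a constant overhead.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    curve_rows = []
    summary_rows = []
    for idx, net in enumerate(networks):
        pg, pe, po = p_good_qlp_curve(net, t_grid)
        for t, a, b, c in zip(t_grid, pg, pe, po):
            curve_rows.append({"network": idx, "t": t, "p_G": a,
                               "p_G_even": b, "p_G_odd": c})
        summary_rows.append({"network": idx, "N": net.node_count,
                             "k_av": net.k_av, "k_max": net.k_max,
                             "p_G_saturation": float(pg.max())})
    return {"curves": pd.DataFrame(curve_rows),
            "saturation": pd.DataFrame(summary_rows)}


@dataclass
class PrecisionCurve:
    """Fold-averaged precision/usefulness curves plus classical baselines.

    Missing (unstable) precision points are excluded from the averages;
    ``missing_counts`` records how many folds were excluded per t.
    """

    t_grid: np.ndarray
    p_G_even: np.ndarray
    p_G_odd: np.ndarray
    p_C_even: np.ndarray
    p_C_odd: np.ndarray
    p_CG_even: np.ndarray      # NaN where every fold was missing
    p_CG_odd: np.ndarray
    p_CG_even_sd: np.ndarray
    p_CG_odd_sd: np.ndarray
    missing_even: np.ndarray   # folds excluded per t
    missing_odd: np.ndarray
    p_CG_A2: float
    p_CG_A3: float
    fold_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t_grid,
            "p_G_even": self.p_G_even, "p_G_odd": self.p_G_odd,
            "p_C_even": self.p_C_even, "p_C_odd": self.p_C_odd,
            "p_CG_even": self.p_CG_even, "p_CG_odd": self.p_CG_odd,
            "p_CG_even_sd": self.p_CG_even_sd, "p_CG_odd_sd": self.p_CG_odd_sd,
            "missing_even": self.missing_even, "missing_odd": self.missing_odd,
        })


def _fold_average(ratios: list[np.ndarray | None], t_len: int):
    """Mean/sd over folds skipping None entries, with exclusion counts."""
    mean = np.full(t_len, np.nan)
    sd = np.full(t_len, np.nan)
    missing = np.zeros(t_len, dtype=np.int64)
    stacked = np.array([[np.nan if v is None else v for v in fold] for fold in ratios])
    for k in range(t_len):
        col = stacked[:, k]
        ok = ~np.isnan(col)
        missing[k] = (~ok).sum()
        if ok.any():
            mean[k] = col[ok].mean()
            sd[k] = col[ok].std()
    return mean, sd, missing


def fig3_experiment(network: Network, fraction: float, folds: int,
                    t_grid, seed: int) -> PrecisionCurve:
    """Cross-validated precision of the walk sampler vs the A^2/A^3 baselines.

    For each fold, a random ``fraction`` of links is removed; usefulness
    and correctness curves are computed on the train graph against the
    removed links, and the conditional precisions averaged over folds
    (the classical baselines are scalars, time-independent).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_len = t_grid.size
    fold_list = cv_split(network, fraction, folds, seed)
    pg_e_all, pg_o_all, pc_e_all, pc_o_all = [], [], [], []
    ratios_e, ratios_o = [], []
    a2_vals, a3_vals = [], []
    for fold in fold_list:
        _, pge, pgo = p_good_qlp_curve(fold.train, t_grid)
        pce, pco = p_correct_qlp_curve(fold.train, fold.truth, t_grid)
        pg_e_all.append(pge)
        pg_o_all.append(pgo)
        pc_e_all.append(pce)
        pc_o_all.append(pco)
        ratios_e.append([precision_given_good(c, g) for c, g in zip(pce, pge)])
        ratios_o.append([precision_given_good(c, g) for c, g in zip(pco, pgo)])
        a2 = classical_precision(fold.train, fold.truth, 2)
        a3 = classical_precision(fold.train, fold.truth, 3)
        if a2 is not None:
            a2_vals.append(a2)
        if a3 is not None:
            a3_vals.append(a3)
    mean_e, sd_e, miss_e = _fold_average(ratios_e, t_len)
    mean_o, sd_o, miss_o = _fold_average(ratios_o, t_len)
    return PrecisionCurve(
        t_grid=t_grid,
        p_G_even=np.mean(pg_e_all, axis=0), p_G_odd=np.mean(pg_o_all, axis=0),
        p_C_even=np.mean(pc_e_all, axis=0), p_C_odd=np.mean(pc_o_all, axis=0),
        p_CG_even=mean_e, p_CG_odd=mean_o,
        p_CG_even_sd=sd_e, p_CG_odd_sd=sd_o,
        missing_even=miss_e, missing_odd=miss_o,
        p_CG_A2=float(np.mean(a2_vals)) if a2_vals else float("nan"),
        p_CG_A3=float(np.mean(a3_vals)) if a3_vals else float("nan"),
        fold_count=folds,
    )
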