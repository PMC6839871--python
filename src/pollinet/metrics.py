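"""Network-level structure of bipartite plant-visitor matrices.

Implements the metrics used to describe each site's interaction network:

* **NODF** nestedness (0-100) on the binarized matrix — paired overlap between
  species with strictly decreasing marginal totals;
* **H2'** network specialization (0-1) — the two-dimensional Shannon entropy of
  interaction proportions, standardized between the extreme entropies
  achievable under the observed marginal totals;
* **Barber bipartite modularity Q** for a given partition, plus a simulated
  annealing search and an exhaustive oracle for small networks;
* **robustness R** — area under the secondary-extinction curve as one guild is
  removed in random order;
* basic descriptors (connectance, links per species, pairwise interactions).

Matrix convention throughout: rows = plants, columns = visitors. Empty rows or
columns are dropped (with a warning) before any metric is computed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "NetworkMetrics", "SAConfig", "drop_empty", "nodf", "h2prime",
    "shannon_entropy", "h2_extremes", "h2_extremes_exhaustive",
    "barber_modularity", "optimize_modularity", "exhaustive_max_modularity",
    "robustness", "robustness_exhaustive", "basic_descriptors",
    "compute_network_metrics",
]


@dataclass
class NetworkMetrics:
    """Per-site network-level structural metrics."""

    nodf: float
    h2prime: float
    modularity_q: float
    partition: dict[str, int] | None
    robustness: float
    connectance: float
    links_per_species: float
    n_pairwise_interactions: int


def _as_matrix(matrix) -> np.ndarray:
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a nonempty 2-D matrix")
    if (A < 0).any():
        raise ValueError("counts must be nonnegative")
    return A


def drop_empty(matrix) -> np.ndarray:
    """Remove all-zero rows and columns (species without interactions)."""
    A = _as_matrix(matrix)
    rows = A.sum(axis=1) > 0
    cols = A.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn(
            f"dropping {int((~rows).sum())} empty row(s) and "
            f"{int((~cols).sum())} empty column(s) before metric computation",
            stacklevel=3,
        )
    A = A[rows][:, cols]
    if A.size == 0:
        raise ValueError("matrix has no interactions")
    return A


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_axis_sum(B: np.ndarray) -> float:
    """Sum of paired-overlap percentages over all ordered row pairs of B."""
    totals = B.sum(axis=1)
    n = B.shape[0]
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or totals[i] <= totals[j] or totals[j] == 0:
                continue
            shared = float((B[i] * B[j]).sum())
            s += 100.0 * shared / totals[j]
    return s


def nodf(matrix) -> float:
    """NODF nestedness of the binarized matrix, in [0, 100].

    For every pair of rows (and of columns) with strictly decreasing marginal
    totals, the paired overlap is 100 times the fraction of the poorer
    species' presences shared with the richer one; ties and empty poorer
    species contribute zero. NODF is the grand sum divided by the number of
    row pairs plus column pairs.
    """
    A = _as_matrix(matrix)
    r, c = A.shape
    if r < 2 or c < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    B = (A > 0).astype(float)
    pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return (_nodf_axis_sum(B) + _nodf_axis_sum(B.T)) / pairs


# ---------------------------------------------------------------------------
# H2'
# ---------------------------------------------------------------------------

def shannon_entropy(matrix) -> float:
    """Two-dimensional Shannon entropy of interaction proportions, -sum p ln p."""
    A = np.asarray(matrix, dtype=float)
    m = A.sum()
    if m <= 0:
        raise ValueError("matrix total must be positive")
    p = A[A > 0] / m
    return float(-(p * np.log(p)).sum())


def _h2_min_matrix(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Greedy specialist packing: repeatedly pair the largest remaining row
    with the largest remaining column and allocate as much as possible.
    Concentrates mass, approaching the minimum-entropy filling."""
    r = row_tot.astype(float).copy()
    c = col_tot.astype(float).copy()
    A = np.zeros((len(r), len(c)))
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        q = min(r[i], c[j])
        if q <= 0:
            break
        A[i, j] += q
        r[i] -= q
        c[j] -= q
    return A


def _h2_max_matrix(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Proportional allocation k_i*d_j/m with largest-remainder integer repair.

    Floor the proportional table, then hand out the remaining units one by one
    to the cell with the largest fractional remainder among cells whose row and
    column still fall short of their marginal totals. Spreads mass as evenly as
    the marginals allow, approaching the maximum-entropy filling.
    """
    r = row_tot.astype(float)
    c = col_tot.astype(float)
    m = r.sum()
    expected = np.outer(r, c) / m
    A = np.floor(expected)
    frac = expected - A
    row_def = r - A.sum(axis=1)
    col_def = c - A.sum(axis=0)
    while row_def.sum() > 0.5:
        mask = np.outer(row_def > 0.5, col_def > 0.5)
        if not mask.any():  # numeric safety; marginal sums are equal
            break
        cand = np.where(mask, frac, -1.0)
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        A[i, j] += 1
        row_def[i] -= 1
        col_def[j] -= 1
        frac[i, j] -= 1  # deprioritize a cell already topped up
    return A


def h2_extremes(matrix) -> tuple[float, float]:
    """Heuristic (H2min, H2max) entropies over integer matrices with the
    observed marginal totals."""
    A = _as_matrix(matrix)
    row_tot = A.sum(axis=1)
    col_tot = A.sum(axis=0)
    h2min = shannon_entropy(_h2_min_matrix(row_tot, col_tot))
    h2max = shannon_entropy(_h2_max_matrix(row_tot, col_tot))
    return h2min, h2max


def _enumerate_fixed_marginals(row_tot: list[int], col_tot: list[int]):
    """Yield every nonnegative integer matrix with the given marginals."""
    r = len(row_tot)

    def rows(remaining_cols: tuple[int, ...], i: int, acc: list[tuple[int, ...]]):
        if i == r:
            if all(x == 0 for x in remaining_cols):
                yield acc
            return
        target = row_tot[i]

        def comps(pos: int, left: int, row: list[int]):
            if pos == len(remaining_cols) - 1:
                if left <= remaining_cols[pos]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[pos]) + 1):
                yield from comps(pos + 1, left - v, row + [v])

        for row in comps(0, target, []):
            rem = tuple(remaining_cols[j] - row[j] for j in range(len(row)))
            yield from rows(rem, i + 1, acc + [tuple(row)])

    yield from rows(tuple(col_tot), 0, [])


def h2_extremes_exhaustive(matrix) -> tuple[float, float]:
    """Exact (H2min, H2max) by enumerating every integer matrix with the
    observed marginals. Only feasible for small matrices; serves as the
    oracle bounding the heuristic."""
    A = _as_matrix(matrix)
    row_tot = [int(x) for x in A.sum(axis=1)]
    col_tot = [int(x) for x in A.sum(axis=0)]
    hmin, hmax = math.inf, -math.inf
    for M in _enumerate_fixed_marginals(row_tot, col_tot):
        h = shannon_entropy(np.asarray(M, dtype=float))
        hmin = min(hmin, h)
        hmax = max(hmax, h)
    return hmin, hmax


def h2prime(matrix, extremes: tuple[float, float] | None = None) -> float:
    """Standardized network specialization H2' in [0, 1].

    H2' = (H2max - H2) / (H2max - H2min); 0 means interactions are as even as
    the marginals allow (no specialization), 1 means maximal specialization.
    Extreme entropies default to the heuristic in :func:`h2_extremes`.
    """
    A = _as_matrix(matrix)
    h2 = shannon_entropy(A)
    h2min, h2max = extremes if extremes is not None else h2_extremes(A)
    if h2max - h2min <= 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Barber modularity
# ---------------------------------------------------------------------------

def _modularity_null(A: np.ndarray) -> tuple[np.ndarray, float]:
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    return A - np.outer(k, d) / m, m


def barber_modularity(matrix, partition: Iterable[int]) -> float:
    """Barber bipartite modularity Q of a module partition.

    Q = (1/m) * sum over plant-visitor pairs in the same module of
    (A_ij - k_i d_j / m). The partition lists module labels for the r plants
    followed by the c visitors.
    """
    A = _as_matrix(matrix)
    r, c = A.shape
    g = np.asarray(list(partition))
    if g.shape[0] != r + c:
        raise ValueError(f"partition must label all {r + c} species, got {g.shape[0]}")
    B, m = _modularity_null(A)
    same = g[:r, None] == g[None, r:]
    return float((B * same).sum() / m)


@dataclass
class SAConfig:
    """Simulated-annealing settings for the modularity search.

    The initial temperature is calibrated so roughly ``initial_accept`` of
    uphill (worsening) moves are accepted; cooling is geometric. The search
    stops after ``patience`` temperatures without improvement.
    """

    cooling: float = 0.95
    moves_per_temperature: int | None = None  # default 50 * (r + c)
    initial_accept: float = 0.80
    patience: int = 20
    n_restarts: int = 3


def _partition_modularity(B: np.ndarray, m: float, g: np.ndarray, r: int) -> float:
    same = g[:r, None] == g[None, r:]
    return float((B * same).sum() / m)


def optimize_modularity(matrix, sa_config: SAConfig | None = None,
                        seed: int | np.random.Generator = 0) -> tuple[np.ndarray, float]:
    """Maximize Barber modularity by simulated annealing over partitions.

    Moves are single-species reassignments (to an existing or a fresh module),
    merges of two modules, and random splits of one module. Returns the best
    partition found and its Q; if no split beats a single module, the
    single-module partition (Q = 0) is returned, so Q >= 0 always.
    """
    A = _as_matrix(matrix)
    r, c = A.shape
    n = r + c
    cfg = sa_config or SAConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B, m = _modularity_null(A)
    moves_per_t = cfg.moves_per_temperature or 50 * n

    best_g = np.zeros(n, dtype=int)
    best_q = 0.0

    for _ in range(cfg.n_restarts):
        g = rng.integers(0, max(2, n // 4), size=n)
        q = _partition_modularity(B, m, g, r)

        # calibrate T0 from sampled uphill deltas
        deltas = []
        for _ in range(100):
            node = int(rng.integers(n))
            new_mod = int(rng.integers(g.max() + 2))
            dq = _move_delta(B, m, g, r, node, new_mod)
            if dq < 0:
                deltas.append(-dq)
        t = (float(np.median(deltas)) / -math.log(cfg.initial_accept)) if deltas else 0.01
        t = max(t, 1e-6)

        local_best_q, stall = q, 0
        while stall < cfg.patience:
            improved = False
            for _ in range(moves_per_t):
                kind = rng.random()
                if kind < 0.8:  # single-node reassignment
                    node = int(rng.integers(n))
                    new_mod = int(rng.integers(g.max() + 2))
                    if new_mod == g[node]:
                        continue
                    dq = _move_delta(B, m, g, r, node, new_mod)
                    if dq >= 0 or rng.random() < math.exp(dq / t):
                        g[node] = new_mod
                        q += dq
                elif kind < 0.9:  # merge two modules
                    mods = np.unique(g)
                    if len(mods) < 2:
                        continue
                    a, b = rng.choice(mods, size=2, replace=False)
                    g2 = np.where(g == b, a, g)
                    q2 = _partition_modularity(B, m, g2, r)
                    dq = q2 - q
                    if dq >= 0 or rng.random() < math.exp(dq / t):
                        g, q = g2, q2
                else:  # split one module in half at random
                    mods = np.unique(g)
                    mod = int(rng.choice(mods))
                    members = np.flatnonzero(g == mod)
                    if len(members) < 2:
                        continue
                    take = members[rng.random(len(members)) < 0.5]
                    if len(take) in (0, len(members)):
                        continue
                    g2 = g.copy()
                    g2[take] = g.max() + 1
                    q2 = _partition_modularity(B, m, g2, r)
                    dq = q2 - q
                    if dq >= 0 or rng.random() < math.exp(dq / t):
                        g, q = g2, q2
                if q > local_best_q + 1e-12:
                    local_best_q = q
                    improved = True
                if q > best_q + 1e-12:
                    best_q = q
                    best_g = g.copy()
            stall = 0 if improved else stall + 1
            t *= cfg.cooling

    # relabel modules compactly
    _, best_g = np.unique(best_g, return_inverse=True)
    return best_g, best_q


def _move_delta(B: np.ndarray, m: float, g: np.ndarray, r: int,
                node: int, new_mod: int) -> float:
    old_mod = g[node]
    if node < r:
        cols = g[r:]
        gain = B[node, cols == new_mod].sum() - B[node, cols == old_mod].sum()
    else:
        rows = g[:r]
        j = node - r
        gain = B[rows == new_mod, j].sum() - B[rows == old_mod, j].sum()
    return float(gain / m)


def _set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxlab: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)  # labels[0] fixed at 0


def exhaustive_max_modularity(matrix) -> tuple[np.ndarray, float]:
    """Exact maximum Barber modularity by enumerating all set partitions of
    the species. Oracle for networks with at most ~10 species total."""
    A = _as_matrix(matrix)
    r, c = A.shape
    n = r + c
    if n > 12:
        raise ValueError("exhaustive search is limited to 12 species")
    B, m = _modularity_null(A)
    best_q, best_g = -math.inf, None
    for g in _set_partitions(n):
        q = _partition_modularity(B, m, g, r)
        if q > best_q:
            best_q, best_g = q, g
    return best_g, float(best_q)


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

def _extinction_steps(A: np.ndarray, order: np.ndarray) -> np.ndarray:
    """For each column species, the removal step (1-based) at which its last
    row partner disappears."""
    pos = np.empty(A.shape[0], dtype=float)
    pos[order] = np.arange(1, A.shape[0] + 1)
    return (pos[:, None] * (A > 0)).max(axis=0)


def _curve_from_order(A: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Fraction of column species surviving after t removals, t = 0..r."""
    steps = _extinction_steps(A, order)
    r = A.shape[0]
    t = np.arange(r + 1)
    return (steps[None, :] > t[:, None]).mean(axis=1)


def robustness(matrix, removal_guild: str = "plants", n_orders: int = 100,
               seed: int | np.random.Generator = 0) -> tuple[float, np.ndarray]:
    """Robustness R to sequential species loss.

    One guild is removed in random order; a species of the other guild goes
    secondarily extinct once all of its partners are gone. The survival curve
    (fraction surviving vs fraction removed, endpoints (0,1) and (1,0)
    included) is averaged over ``n_orders`` random orders and R is its
    trapezoidal area. R near 1 means the network tolerates loss.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    A = drop_empty(matrix)
    if removal_guild == "visitors":
        A = A.T
    elif removal_guild != "plants":
        raise ValueError(f"unknown removal_guild {removal_guild!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = A.shape[0]
    acc = np.zeros(r + 1)
    for _ in range(n_orders):
        acc += _curve_from_order(A, rng.permutation(r))
    curve = acc / n_orders
    x = np.arange(r + 1) / r
    return float(np.trapezoid(curve, x)), curve


def robustness_exhaustive(matrix, removal_guild: str = "plants") -> float:
    """Exact robustness: mean over every removal order (r! orders; r <= ~7)."""
    A = drop_empty(matrix)
    if removal_guild == "visitors":
        A = A.T
    r = A.shape[0]
    if r > 8:
        raise ValueError("exhaustive robustness limited to 8 removable species")
    x = np.arange(r + 1) / r
    total, n = 0.0, 0
    for perm in itertools.permutations(range(r)):
        total += float(np.trapezoid(_curve_from_order(A, np.asarray(perm)), x))
        n += 1
    return total / n


# ---------------------------------------------------------------------------
# Descriptors & convenience wrapper
# ---------------------------------------------------------------------------

def basic_descriptors(matrix) -> dict[str, float]:
    """Connectance, links per species and the count of pairwise interactions."""
    A = _as_matrix(matrix)
    r, c = A.shape
    links = int((A > 0).sum())
    return {
        "connectance": links / (r * c),
        "links_per_species": links / (r + c),
        "n_pairwise_interactions": links,
    }


def compute_network_metrics(matrix, species_ids: list[str] | None = None,
                            n_orders: int = 100,
                            sa_config: SAConfig | None = None,
                            seed: int | np.random.Generator = 0,
                            include_modularity: bool = True) -> NetworkMetrics:
    """All network-level metrics on one matrix (empty rows/columns dropped)."""
    A = drop_empty(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    desc = basic_descriptors(A)
    if include_modularity:
        g, q = optimize_modularity(A, sa_config, rng)
        partition = (
            {sid: int(lab) for sid, lab in zip(species_ids, g)}
            if species_ids is not None and len(species_ids) == len(g) else
            {str(i): int(lab) for i, lab in enumerate(g)}
        )
    else:
        q, partition = math.nan, None
    R, _ = robustness(A, n_orders=n_orders, seed=rng)
    return NetworkMetrics(
        nodf=nodf(A),
        h2prime=h2prime(A),
        modularity_q=q,
        partition=partition,
        robustness=R,
        connectance=desc["connectance"],
        links_per_species=desc["links_per_species"],
        n_pairwise_interactions=desc["n_pairwise_interactions"],
    )
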