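"""Degree-proportional (CE) null model and Monte-Carlo significance tests.

Under the CE null the probability that plant i and visitor j interact is the
average of the row's and the column's degree fraction,

    p_ij = (k_i / c + d_j / r) / 2,

with k_i the number of visitor species plant i interacts with, d_j the number
of plant species visitor j visits, and r x c the matrix shape. Null matrices
are independent Bernoulli draws per cell; draws that leave a species with no
interactions are rejected and redrawn up to a cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from pollinet.metrics import SAConfig, nodf, optimize_modularity

logger = logging.getLogger(__name__)

#: replicate counts used for the two significance tests
DEFAULT_REPLICATES = {"nodf": 1000, "modularity_q": 100}


@dataclass
class NullEnsemble:
    """Observed metric vs its distribution under the CE null."""

    metric: str
    observed: float
    values: np.ndarray
    n_replicates: int
    n_degenerate: int = 0  # replicates kept despite an empty row/column

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else math.nan

    @property
    def z(self) -> float:
        sd = self.null_sd
        if not math.isfinite(sd) or sd == 0:
            return 0.0 if math.isclose(self.observed, self.null_mean) else math.nan
        return (self.observed - self.null_mean) / sd

    @property
    def p_value(self) -> float:
        """One-sided: fraction of null values >= observed (large = structured)."""
        return float(np.mean(self.values >= self.observed - 1e-12))

    def summary(self) -> dict:
        return {
            "metric": self.metric,
            "observed": self.observed,
            "n_replicates": self.n_replicates,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_value": self.p_value,
            "n_degenerate": self.n_degenerate,
        }


def ce_probability_matrix(matrix) -> np.ndarray:
    """Cell probabilities of the CE null, p_ij = (k_i/c + d_j/r) / 2."""
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a nonempty 2-D matrix")
    B = (A > 0)
    r, c = B.shape
    k = B.sum(axis=1)
    d = B.sum(axis=0)
    return (k[:, None] / c + d[None, :] / r) / 2.0


def sample_null(probabilities, seed: int | np.random.Generator = 0,
                max_attempts: int = 100) -> tuple[np.ndarray, bool]:
    """One Bernoulli null matrix; redraws matrices with an empty row or
    column up to ``max_attempts``, then keeps the last draw with a flag."""
    P = np.asarray(probabilities, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        M = (rng.random(P.shape) < P).astype(float)
        if (M.sum(axis=1) > 0).all() and (M.sum(axis=0) > 0).all():
            return M, False
    logger.warning("null draw kept with an empty row/column after %d attempts", max_attempts)
    return M, True


def significance_test(matrix, metric: str, n_replicates: int | None = None,
                      seed: int | np.random.Generator = 0,
                      sa_config: SAConfig | None = None) -> NullEnsemble:
    """Monte-Carlo significance of nestedness or modularity under the CE null.

    Defaults to 1000 replicates for NODF and 100 for modularity. For
    modularity each null matrix is re-optimized with the same annealing
    settings as the observed network.
    """
    if metric not in ("nodf", "modularity_q"):
        raise ValueError(f"unknown metric {metric!r}; use 'nodf' or 'modularity_q'")
    if n_replicates is None:
        n_replicates = DEFAULT_REPLICATES[metric]
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    A = np.asarray(matrix, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sa = sa_config or SAConfig(n_restarts=1)

    def evaluate(M: np.ndarray) -> float:
        if metric == "nodf":
            return nodf(M)
        return optimize_modularity(M, sa, rng)[1]

    observed = evaluate((A > 0).astype(float) if metric == "nodf" else A)
    P = ce_probability_matrix(A)
    values = np.empty(n_replicates)
    n_degenerate = 0
    for b in range(n_replicates):
        M, flag = sample_null(P, rng)
        n_degenerate += int(flag)
        values[b] = evaluate(M)
    return NullEnsemble(
        metric=metric,
        observed=observed,
        values=values,
        n_replicates=n_replicates,
        n_degenerate=n_degenerate,
    )
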