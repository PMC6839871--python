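"""Species-level network roles: normalized degree, strength, nestedness contribution.

* Normalized degree — realized partners over possible partners.
* Species strength — sum over partners of the partner's dependency on the
  focal species (for plant i: sum_j a_ij / A_j over visitor column totals A_j).
  Plant strengths sum exactly to the number of visitor species with visits.
* Nestedness contribution — z-score of the observed NODF against the NODF
  distribution obtained when only the focal species' presence/absence vector
  is resampled from its CE null probabilities, everything else held fixed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from pollinet.metrics import nodf
from pollinet.nulls import ce_probability_matrix

__all__ = ["normalized_degree", "species_strength", "nestedness_contribution",
           "species_level_table"]


def normalized_degree(matrix) -> tuple[np.ndarray, np.ndarray]:
    """(plant values, visitor values): realized partners / possible partners."""
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a nonempty 2-D matrix")
    B = A > 0
    r, c = B.shape
    return B.sum(axis=1) / c, B.sum(axis=0) / r


def species_strength(matrix, guild: str = "plants") -> np.ndarray:
    """Strength per species of one guild: sum of its partners' dependencies.

    For plants, visitor columns with zero total carry no dependencies and are
    excluded (with a warning); symmetrically for visitors.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a nonempty 2-D matrix")
    if guild == "visitors":
        A = A.T
    elif guild != "plants":
        raise ValueError(f"unknown guild {guild!r}")
    totals = A.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} partner species with zero visits",
                      stacklevel=2)
    dep = A[:, keep] / totals[keep]
    return dep.sum(axis=1)


def nestedness_contribution(matrix, focal_guild: str, focal_index: int,
                            n_randomizations: int = 100,
                            seed: int | np.random.Generator = 0) -> float:
    """Signed z-score contribution of one species to network nestedness.

    contribution = (NODF_obs - mean NODF*) / sd NODF*, where each NODF* is
    computed after replacing only the focal species' binary interaction
    vector with independent Bernoulli draws at its CE probabilities. Positive
    values mean the species' observed interactions support nestedness beyond
    its degree-based expectation. NaN when the null sd is zero.
    """
    if n_randomizations < 2:
        raise ValueError("need at least 2 randomizations")
    A = np.asarray(matrix, dtype=float)
    B = (A > 0).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = ce_probability_matrix(B)
    if focal_guild == "plant":
        p_vec = P[focal_index, :]
    elif focal_guild == "visitor":
        p_vec = P[:, focal_index]
    else:
        raise ValueError(f"unknown guild {focal_guild!r}")
    obs = nodf(B)
    vals = np.empty(n_randomizations)
    M = B.copy()
    for b in range(n_randomizations):
        draw = (rng.random(p_vec.shape) < p_vec).astype(float)
        if focal_guild == "plant":
            M[focal_index, :] = draw
        else:
            M[:, focal_index] = draw
        vals[b] = nodf(M)
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        return math.nan
    return float((obs - vals.mean()) / sd)


def species_level_table(matrix, plant_ids: list[str], visitor_ids: list[str],
                        n_randomizations: int = 100,
                        seed: int | np.random.Generator = 0) -> list[dict]:
    """All three species-level metrics for every species of both guilds."""
    A = np.asarray(matrix, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nd_p, nd_v = normalized_degree(A)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        st_p = species_strength(A, "plants")
        st_v = species_strength(A, "visitors")
    rows = []
    for i, sid in enumerate(plant_ids):
        rows.append({
            "species_id": sid, "guild": "plant",
            "normalized_degree": float(nd_p[i]), "strength": float(st_p[i]),
            "nestedness_contribution": nestedness_contribution(
                A, "plant", i, n_randomizations, rng),
        })
    for j, sid in enumerate(visitor_ids):
        rows.append({
            "species_id": sid, "guild": "visitor",
            "normalized_degree": float(nd_v[j]), "strength": float(st_v[j]),
            "nestedness_contribution": nestedness_contribution(
                A, "visitor", j, n_randomizations, rng),
        })
    return rows
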