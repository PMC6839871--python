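"""Origin-stratified plant-extinction scenarios and Hedges' g effect sizes.

Four scenarios are compared per site:

* ``intact`` — the observed network;
* ``aliens_removed`` — every alien plant excluded (deterministic);
* ``natives_removed`` — a uniform random subset of native plants, as many as
  the site has alien plants;
* ``random_removal`` — a uniform random subset of all plants of the same size.

Visitor species left without any interaction partner after a removal are
dropped (secondary loss). Network metrics are recomputed on each reduced
matrix; stochastic scenarios are averaged over replicates. Scenario-vs-intact
contrasts are summarized with the bias-corrected Hedges' g standardized mean
difference and the arithmetic percent change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pollinet.community import SiteCommunity
from pollinet.metrics import (
    SAConfig,
    drop_empty,
    h2prime,
    nodf,
    optimize_modularity,
    robustness,
)

__all__ = [
    "SCENARIOS", "ScenarioSpec", "ScenarioResult", "EffectSize",
    "apply_scenario", "run_scenarios", "hedges_g", "percent_change",
]

SCENARIOS = ("intact", "aliens_removed", "natives_removed", "random_removal")
DEFAULT_METRICS = ("nodf", "h2prime", "modularity_q", "robustness")


@dataclass(frozen=True)
class ScenarioSpec:
    """One extinction scenario; ``n_remove`` defaults to the number of alien
    plants at the site for the two stochastic scenarios."""

    scenario: str
    n_remove: int | None = None
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def deterministic(self) -> bool:
        return self.scenario in ("intact", "aliens_removed")


@dataclass
class ScenarioResult:
    """Replicate-level metric values for one site x scenario."""

    site_id: str
    scenario: str
    removed: list[list[str]]
    values: dict[str, np.ndarray]  # metric -> per-replicate values

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.values[metric]))

    def sd(self, metric: str) -> float:
        v = self.values[metric]
        return float(np.nanstd(v, ddof=1)) if len(v) > 1 else math.nan


@dataclass
class EffectSize:
    """Bias-corrected Hedges' g between two groups of metric values."""

    m1: float
    m2: float
    s1: float
    s2: float
    n1: int
    n2: int
    sd_pooled: float
    j: float
    g: float
    ci_low: float
    ci_high: float
    percent_change: float


def apply_scenario(community: SiteCommunity, spec: ScenarioSpec,
                   replicate_seed: int | np.random.Generator = 0) -> SiteCommunity:
    """The reduced community after one realization of the removal scenario.

    Orphaned visitor columns are dropped; ``intact`` returns the community
    unchanged, and ``aliens_removed`` with zero alien plants is the identity.
    """
    if spec.scenario == "intact":
        return community
    aliens = [p.species_id for p in community.alien_plants()]
    natives = [p.species_id for p in community.native_plants()]
    n_remove = spec.n_remove if spec.n_remove is not None else len(aliens)
    rng = (replicate_seed if isinstance(replicate_seed, np.random.Generator)
           else np.random.default_rng(replicate_seed))

    if spec.scenario == "aliens_removed":
        removed = set(aliens)
    elif spec.scenario == "natives_removed":
        if n_remove > len(natives):
            raise ValueError(f"cannot remove {n_remove} of {len(natives)} native plants")
        removed = set(rng.choice(natives, size=n_remove, replace=False)) if n_remove else set()
    else:  # random_removal
        if n_remove > len(community.plants):
            raise ValueError(f"cannot remove {n_remove} of {len(community.plants)} plants")
        all_ids = community.plant_ids
        removed = set(rng.choice(all_ids, size=n_remove, replace=False)) if n_remove else set()
    keep = [pid for pid in community.plant_ids if pid not in removed]
    return community.subset_plants(keep)


def _metric_values(matrix, metrics, rng, n_orders, sa_config) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        A = drop_empty(matrix)
    except ValueError:
        return {m: math.nan for m in metrics}
    for m in metrics:
        if m == "nodf":
            out[m] = nodf(A) if min(A.shape) >= 2 else math.nan
        elif m == "h2prime":
            out[m] = h2prime(A)
        elif m == "modularity_q":
            out[m] = optimize_modularity(A, sa_config, rng)[1]
        elif m == "robustness":
            out[m] = robustness(A, n_orders=n_orders, seed=rng)[0]
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


def run_scenarios(study: list[SiteCommunity],
                  scenarios: tuple[str, ...] = SCENARIOS,
                  metrics: tuple[str, ...] = DEFAULT_METRICS,
                  n_replicates: int = 100,
                  seed: int = 0,
                  n_orders: int = 100,
                  sa_config: SAConfig | None = None) -> list[ScenarioResult]:
    """All requested scenarios on every site.

    Deterministic scenarios run once; stochastic ones run ``n_replicates``
    times with per-replicate removal sets retained. Metrics are recomputed on
    each reduced matrix with the same settings as on the intact network.
    """
    if not study:
        raise ValueError("need at least one site")
    results: list[ScenarioResult] = []
    for s_idx, community in enumerate(study):
        for scenario in scenarios:
            spec = ScenarioSpec(scenario=scenario, n_replicates=n_replicates, seed=seed)
            reps = 1 if spec.deterministic else n_replicates
            removed_sets: list[list[str]] = []
            values: dict[str, list[float]] = {m: [] for m in metrics}
            for b in range(reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, s_idx, SCENARIOS.index(scenario), b]))
                reduced = apply_scenario(community, spec, rng)
                removed_sets.append(
                    sorted(set(community.plant_ids) - set(reduced.plant_ids)))
                vals = _metric_values(reduced.counts, metrics, rng, n_orders, sa_config)
                for m in metrics:
                    values[m].append(vals[m])
            results.append(ScenarioResult(
                site_id=community.site_id,
                scenario=scenario,
                removed=removed_sets,
                values={m: np.asarray(v) for m, v in values.items()},
            ))
    return results


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> EffectSize:
    """Bias-corrected Hedges' g = J * (M1 - M2) / SD_pooled with a normal
    approximation 95% CI and the percent change of group 2 relative to group 1.

    SD_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)) and the
    small-sample correction is J = 1 - 3 / (4(n1+n2) - 9). Antisymmetric under
    group exchange.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("standard deviations must be nonnegative and not both zero")
    sd_pooled = math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if sd_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = j * (m1 - m2) / sd_pooled
    se = math.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2 - 2)))
    return EffectSize(
        m1=m1, m2=m2, s1=s1, s2=s2, n1=n1, n2=n2,
        sd_pooled=sd_pooled, j=j, g=g,
        ci_low=g - 1.96 * se, ci_high=g + 1.96 * se,
        percent_change=percent_change(m1, m2) if m1 != 0 else math.nan,
    )


def percent_change(intact_mean: float, scenario_mean: float) -> float:
    """Signed percent change of a scenario mean relative to the intact mean."""
    if intact_mean == 0:
        raise ValueError("intact mean is zero; percent change undefined")
    return 100.0 * (scenario_mean - intact_mean) / intact_mean
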