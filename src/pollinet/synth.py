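"""Synthetic invaded co-flowering communities for end-to-end testing.

The generator emulates the statistical structure of the coastal sand-dune
study system: nine sites with 8-17 plant and 22-38 visitor species, an alien
species proportion of 22-50%, an alien flower share spanning 11-99% across
sites, per-site visit totals of 504-3335, one super-generalist visitor (the
honey bee) taking about 57.5% of all visits, and native/alien floral traits
drawn from a common distribution (community trait similarity around 0.79).

Interaction propensities follow

    p_ij  ∝  flowers_i**alpha * activity_j**beta * exp(-gamma * mismatch_ij)

where ``mismatch_ij`` is the Gower distance between plant i's traits and a
latent preference point of visitor j. ``gamma = 0`` gives a rank-one,
abundance-driven (nested) regime; large ``gamma`` carves trait-matched
modules. All visits of a site are drawn as a single multinomial of the site
total, so totals match the configured range exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pollinet.community import SiteCommunity, SpeciesRecord, VisitEvent
from pollinet.errors import InfeasibleConfigError
from pollinet.traits import QUANTITATIVE_TRAITS, TraitTable

__all__ = ["GeneratorConfig", "generate_site", "generate_study"]

#: study design: nine survey days per site
N_SURVEY_DAYS = 9


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-community generator.

    Defaults are the study conditions: species counts, alien proportions,
    visit totals and the super-generalist share observed across the nine
    coastal sites. ``gamma`` controls trait matching (0 = purely
    abundance-driven, nested), ``delta`` shifts alien trait means in units of
    the native trait spread (0 = origin-blind), and ``alien_gamma`` may relax
    trait matching for alien plants only (planted-generalist scenarios).
    """

    n_plants: tuple[int, int] = (8, 17)
    n_visitors: tuple[int, int] = (22, 38)
    alien_species_prop: tuple[float, float] = (0.22, 0.50)
    alien_flower_share: float | None = 0.7  # None: no rescaling (origin-blind abundance)
    alien_flower_share_range: tuple[float, float] = (0.11, 0.99)
    total_visits: tuple[int, int] = (504, 3335)
    supergeneralist_share: float = 0.575
    abundance_sigma: float = 1.5
    trait_sigma: float = 2.5
    alpha: float = 0.5
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 0.0
    alien_gamma: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for lo, hi, name in [
            (*self.n_plants, "n_plants"),
            (*self.n_visitors, "n_visitors"),
            (*self.total_visits, "total_visits"),
        ]:
            if lo > hi or lo < 1:
                raise InfeasibleConfigError(f"empty or invalid range for {name}")
        lo, hi = self.alien_species_prop
        if not (0 < lo <= hi < 1):
            raise InfeasibleConfigError("alien_species_prop must lie inside (0, 1)")
        if self.alien_flower_share is not None and not (0 < self.alien_flower_share < 1):
            raise InfeasibleConfigError("alien_flower_share must lie in (0, 1)")
        if not (0 < self.supergeneralist_share < 1):
            raise InfeasibleConfigError("supergeneralist_share must lie in (0, 1)")
        if self.gamma < 0 or self.delta < 0:
            raise InfeasibleConfigError("gamma and delta must be nonnegative")
        if math.floor(self.n_plants[0] * (1 - lo)) < 1:
            raise InfeasibleConfigError("alien proportion leaves no native plant")


# trait-generation scales: log-means of the lognormal draws (mm for the three
# morphological traits) and the spread of the two chromatic coordinates
_TRAIT_LOGMEANS = {
    "flower_height_mm": math.log(15.0),
    "corolla_diameter_mm": math.log(10.0),
    "corolla_opening_mm": math.log(3.0),
}
_CHROMATIC_SCALE = 0.05
_P_TUBULAR = 0.5


def _draw_traits(rng: np.random.Generator, n: int, sigma: float,
                 shift: float = 0.0) -> np.ndarray:
    """Rows of (height, diameter, opening, hex_x, hex_y); ``shift`` moves the
    log-scale (resp. chromatic) means by that many standard deviations.

    Morphological traits are lognormal (sizes are right-skewed: most species
    cluster at moderate values, a few are much larger, which sets the
    community range); chromatic coordinates are signed-lognormal around the
    achromatic centre (most flowers weakly saturated, few strongly coloured).
    """
    cols = []
    for name in ("flower_height_mm", "corolla_diameter_mm", "corolla_opening_mm"):
        x = rng.lognormal(_TRAIT_LOGMEANS[name] + shift * sigma, sigma, size=n)
        if name == "corolla_opening_mm":
            x = np.where(rng.random(n) < _P_TUBULAR, x, 0.0)
        cols.append(x)
    for _ in range(2):
        r = rng.lognormal(0.0, sigma, size=n) * _CHROMATIC_SCALE
        signed = np.where(rng.random(n) < 0.5, -r, r)
        cols.append(signed + shift * _CHROMATIC_SCALE)
    return np.column_stack(cols)


def _gower_mismatch(plant_traits: np.ndarray, pref_points: np.ndarray) -> np.ndarray:
    """Plant x visitor Gower mismatch on jointly rank-transformed traits.

    Plant values and visitor preference points are ranked together per trait
    and scaled to [0, 1]; the mismatch is the mean absolute rank difference.
    Ranking makes gamma act on relative trait matching whatever the trait
    distribution's tail shape (raw ranges are dominated by single outliers,
    which would collapse most pairwise distances toward zero).
    """
    n_p = plant_traits.shape[0]
    pooled = np.vstack([plant_traits, pref_points])
    n = pooled.shape[0]
    ranks = np.empty_like(pooled)
    for k in range(pooled.shape[1]):
        order = np.argsort(pooled[:, k], kind="stable")
        ranks[order, k] = np.arange(n) / max(n - 1, 1)
    rp, rv = ranks[:n_p], ranks[n_p:]
    return np.abs(rp[:, None, :] - rv[None, :, :]).mean(axis=2)


def _site_rng(master_seed: int, site_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, site_index]))


def generate_site(config: GeneratorConfig, site_index: int = 0) -> tuple[SiteCommunity, TraitTable]:
    """One synthetic site community plus its floral-trait table.

    The substream is derived from ``config.seed`` and ``site_index``, so each
    site is independently reproducible.
    """
    config.validate()
    rng = _site_rng(config.seed, site_index)

    n_p = int(rng.integers(config.n_plants[0], config.n_plants[1] + 1))
    n_v = int(rng.integers(config.n_visitors[0], config.n_visitors[1] + 1))
    prop = rng.uniform(*config.alien_species_prop)
    n_alien = int(np.clip(round(prop * n_p), 1, n_p - 1))
    origins = np.array(["alien"] * n_alien + ["native"] * (n_p - n_alien))
    rng.shuffle(origins)
    alien = origins == "alien"

    # flower abundances; aliens rescaled so their summed share hits the target
    # (target None leaves abundances origin-blind)
    flowers = np.maximum(1, np.round(rng.lognormal(math.log(500.0),
                                                   config.abundance_sigma, n_p)))
    target = config.alien_flower_share
    if target is not None:
        native_sum = flowers[~alien].sum()
        factor = (target / (1 - target)) * native_sum / flowers[alien].sum()
        flowers[alien] = np.maximum(1, np.round(flowers[alien] * factor))
    flowers = flowers.astype(int)

    # traits: natives from the shared distribution, aliens shifted by delta
    traits = np.empty((n_p, 5))
    traits[~alien] = _draw_traits(rng, int((~alien).sum()), config.trait_sigma)
    traits[alien] = _draw_traits(rng, int(alien.sum()), config.trait_sigma,
                                 shift=config.delta)

    # visitors: latent preference points from the native trait distribution
    prefs = _draw_traits(rng, n_v, config.trait_sigma)
    activity = rng.lognormal(0.0, 1.0, n_v)
    mismatch = _gower_mismatch(traits, prefs)

    gamma = np.full(n_p, float(config.gamma))
    if config.alien_gamma is not None:
        gamma[alien] = config.alien_gamma
    W = (flowers[:, None] ** config.alpha) * (activity[None, :] ** config.beta) \
        * np.exp(-gamma[:, None] * mismatch)

    # visitor 0 is the super-generalist: no trait matching, column scaled so
    # its expected visit share equals the configured share
    s = config.supergeneralist_share
    col0 = flowers ** config.alpha
    rest = W[:, 1:].sum()
    W[:, 0] = col0 * (s / (1 - s)) * rest / col0.sum()

    total = int(rng.integers(config.total_visits[0], config.total_visits[1] + 1))
    probs = (W / W.sum()).ravel()
    counts = rng.multinomial(total, probs).reshape(n_p, n_v).astype(float)

    site_id = f"site{site_index:02d}"
    plant_ids = [f"{site_id}_p{i:02d}" for i in range(n_p)]
    visitor_ids = [f"{site_id}_v{j:02d}" for j in range(n_v)]
    plants = [
        SpeciesRecord(species_id=pid, guild="plant", origin=origins[i],
                      flower_count=int(flowers[i]))
        for i, pid in enumerate(plant_ids)
    ]
    visitors = [SpeciesRecord(species_id=vid, guild="visitor") for vid in visitor_ids]
    visitors[0].name = "super-generalist"

    # spread each cell's visits over the nine survey days
    surveys: list[VisitEvent] = []
    nz = np.argwhere(counts > 0)
    for i, j in nz:
        per_day = rng.multinomial(int(counts[i, j]), np.full(N_SURVEY_DAYS, 1 / N_SURVEY_DAYS))
        for d, v in enumerate(per_day):
            if v > 0:
                surveys.append(VisitEvent(
                    site_id=site_id, plot_id="all", date_id=f"day{d + 1}",
                    plant_id=plant_ids[i], visitor_id=visitor_ids[j],
                    n_visits=int(v), observation_minutes=150.0,
                ))

    community = SiteCommunity(site_id=site_id, plants=plants, visitors=visitors,
                              counts=counts, surveys=surveys)
    table = TraitTable(
        data=pd.DataFrame(traits, columns=list(QUANTITATIVE_TRAITS),
                          index=pd.Index(plant_ids, name="species_id")),
    )
    return community, table


def generate_study(config: GeneratorConfig, n_sites: int = 9) -> list[tuple[SiteCommunity, TraitTable]]:
    """A study of ``n_sites`` sites spanning the alien-flower-share gradient.

    Per-site share targets are evenly spaced across
    ``config.alien_flower_share_range`` (a single site sits at the midpoint);
    each site uses its own substream of the master seed.
    """
    if n_sites < 1:
        raise InfeasibleConfigError("n_sites must be >= 1")
    lo, hi = config.alien_flower_share_range
    if n_sites == 1:
        targets = [0.5 * (lo + hi)]
    else:
        targets = list(np.linspace(lo, hi, n_sites))
    out = []
    for idx, t in enumerate(targets):
        out.append(generate_site(replace(config, alien_flower_share=float(t)), idx))
    return out
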