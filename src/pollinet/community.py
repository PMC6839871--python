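"""Data model, readers/writers and pollination-environment summaries for site communities.

A site community is a bipartite record: plants (rows, with origin and flower
counts) x floral visitors (columns), with cell values the number of observed
visits. The on-disk contract is two CSV files:

* ``interactions.csv`` — first column ``plant_id``, remaining columns visitor
  ids, integer cells;
* ``species.csv`` — columns ``species_id,guild,origin,family,flower_count``.

Plants that flowered but were never visited stay in the community record; they
simply carry a zero row, which the metric modules drop before computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from pollinet.errors import (
    DimensionMismatchError,
    DuplicateSpeciesError,
    NegativeCountError,
    UnknownSpeciesError,
)

VALID_GUILDS = {"plant", "visitor"}
VALID_ORIGINS = {"native", "alien", "not_applicable"}

#: survey design: three 5-minute observation rounds per plot per day
DEFAULT_PERIOD_MINUTES = 15.0


@dataclass
class SpeciesRecord:
    """One species (plant or floral visitor) with its site-level metadata."""

    species_id: str
    guild: str
    origin: str = "not_applicable"
    name: str = ""
    family: str = ""
    flower_count: int | None = None


@dataclass
class VisitEvent:
    """A single plot/date observation of one plant-visitor interaction."""

    site_id: str
    plot_id: str
    date_id: str
    plant_id: str
    visitor_id: str
    n_visits: int
    observation_minutes: float


@dataclass
class SiteCommunity:
    """One site's plants, visitors and plant x visitor visit-count matrix."""

    site_id: str
    plants: list[SpeciesRecord]
    visitors: list[SpeciesRecord]
    counts: np.ndarray
    surveys: list[VisitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.plants), len(self.visitors)):
            raise DimensionMismatchError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.plants)} plants x {len(self.visitors)} visitors"
            )

    @property
    def plant_ids(self) -> list[str]:
        return [p.species_id for p in self.plants]

    @property
    def visitor_ids(self) -> list[str]:
        return [v.species_id for v in self.visitors]

    @property
    def total_visits(self) -> int:
        return int(self.counts.sum())

    def alien_plants(self) -> list[SpeciesRecord]:
        return [p for p in self.plants if p.origin == "alien"]

    def native_plants(self) -> list[SpeciesRecord]:
        return [p for p in self.plants if p.origin == "native"]

    def subset_plants(self, keep_ids: Sequence[str]) -> "SiteCommunity":
        """Community restricted to the given plants; visitor columns left with
        no interactions are dropped (secondary loss)."""
        keep = set(keep_ids)
        idx = [i for i, p in enumerate(self.plants) if p.species_id in keep]
        sub = self.counts[idx, :]
        vkeep = np.flatnonzero(sub.sum(axis=0) > 0)
        return SiteCommunity(
            site_id=self.site_id,
            plants=[self.plants[i] for i in idx],
            visitors=[self.visitors[j] for j in vkeep],
            counts=sub[:, vkeep],
        )


@dataclass
class PollinationSummary:
    """Per-plant visitor richness and per-flower visitation rates for one site."""

    site_id: str
    plant_ids: list[str]
    richness: np.ndarray
    visitation_rate: np.ndarray  # visits per flower per observation period; NaN if undefined
    visitor_abundance: np.ndarray  # plants x visitors count matrix (composition analysis)


def _read_species_table(species_path: str | Path) -> dict[str, SpeciesRecord]:
    df = pd.read_csv(species_path, dtype={"species_id": str})
    required = {"species_id", "guild"}
    missing = required - set(df.columns)
    if missing:
        raise UnknownSpeciesError(f"species file lacks columns: {sorted(missing)}")
    records: dict[str, SpeciesRecord] = {}
    for row in df.itertuples(index=False):
        sid = str(row.species_id)
        if sid in records:
            raise DuplicateSpeciesError(f"duplicate species_id {sid!r}")
        fc = getattr(row, "flower_count", None)
        fc = None if fc is None or (isinstance(fc, float) and math.isnan(fc)) else int(fc)
        records[sid] = SpeciesRecord(
            species_id=sid,
            guild=str(row.guild),
            origin=str(getattr(row, "origin", "not_applicable")),
            name=str(getattr(row, "name", "") or ""),
            family=str(getattr(row, "family", "") or ""),
            flower_count=fc,
        )
    return records


def load_community(matrix_path: str | Path, species_path: str | Path,
                   site_id: str | None = None) -> SiteCommunity:
    """Load and validate a site community from the CSV contract.

    Row order follows the matrix file's row order; column order follows its
    header order.

    Raises
    ------
    DimensionMismatchError, UnknownSpeciesError, DuplicateSpeciesError,
    NegativeCountError
    """
    try:
        mat = pd.read_csv(matrix_path, dtype={"plant_id": str})
    except pd.errors.EmptyDataError:
        raise DimensionMismatchError(f"empty matrix file: {matrix_path}")
    if mat.shape[0] == 0 or mat.shape[1] < 2 or mat.columns[0] != "plant_id":
        raise DimensionMismatchError(
            f"matrix file must have a plant_id column plus >=1 visitor column, "
            f"got shape {mat.shape}"
        )
    plant_ids = [str(x) for x in mat["plant_id"]]
    visitor_ids = [str(c) for c in mat.columns[1:]]
    if len(set(plant_ids)) != len(plant_ids):
        raise DuplicateSpeciesError("duplicate plant_id rows in matrix file")
    if len(set(visitor_ids)) != len(visitor_ids):
        raise DuplicateSpeciesError("duplicate visitor columns in matrix file")

    records = _read_species_table(species_path)
    for sid in plant_ids + visitor_ids:
        if sid not in records:
            raise UnknownSpeciesError(f"species_id {sid!r} not in species file")

    counts = mat.iloc[:, 1:].to_numpy(dtype=float)
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise NegativeCountError(
            f"negative count at plant {plant_ids[i]!r}, visitor {visitor_ids[j]!r}"
        )
    if site_id is None:
        site_id = Path(matrix_path).resolve().parent.name
    community = SiteCommunity(
        site_id=site_id,
        plants=[records[s] for s in plant_ids],
        visitors=[records[s] for s in visitor_ids],
        counts=counts,
    )
    problems = validate_community(community)
    if problems:
        raise UnknownSpeciesError("; ".join(problems))
    return community


def write_community(community: SiteCommunity, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a community back to the CSV contract; inverse of :func:`load_community`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(
        community.counts.astype(int),
        columns=community.visitor_ids,
    )
    mat.insert(0, "plant_id", community.plant_ids)
    matrix_path = out / "interactions.csv"
    mat.to_csv(matrix_path, index=False)

    rows = []
    for rec in community.plants + community.visitors:
        rows.append({
            "species_id": rec.species_id,
            "guild": rec.guild,
            "origin": rec.origin,
            "family": rec.family,
            "flower_count": rec.flower_count if rec.flower_count is not None else "",
        })
    species_path = out / "species.csv"
    pd.DataFrame(rows).to_csv(species_path, index=False)
    return matrix_path, species_path


def validate_community(community: SiteCommunity) -> list[str]:
    """Return a list of invariant violations (empty iff the community is valid)."""
    problems: list[str] = []
    seen: set[str] = set()
    for rec in community.plants + community.visitors:
        if rec.species_id in seen:
            problems.append(f"duplicate species_id {rec.species_id!r}")
        seen.add(rec.species_id)
        if rec.guild not in VALID_GUILDS:
            problems.append(f"{rec.species_id!r}: unknown guild {rec.guild!r}")
        if rec.origin not in VALID_ORIGINS:
            problems.append(f"{rec.species_id!r}: unknown origin {rec.origin!r}")
    for p in community.plants:
        if p.origin not in {"native", "alien"}:
            problems.append(f"plant {p.species_id!r}: origin must be native or alien, got {p.origin!r}")
        if p.flower_count is not None and p.flower_count < 0:
            problems.append(f"plant {p.species_id!r}: negative flower_count")
    for v in community.visitors:
        if v.origin != "not_applicable":
            problems.append(f"visitor {v.species_id!r}: origin must be not_applicable")
    neg = np.argwhere(community.counts < 0)
    for i, j in neg:
        problems.append(
            f"negative count at ({community.plant_ids[i]!r}, {community.visitor_ids[j]!r})"
        )
    for ev in community.surveys:
        if ev.plant_id not in community.plant_ids:
            problems.append(f"survey references unknown plant {ev.plant_id!r}")
        if ev.visitor_id not in community.visitor_ids:
            problems.append(f"survey references unknown visitor {ev.visitor_id!r}")
        if ev.n_visits < 1:
            problems.append(f"survey visit count < 1 for plant {ev.plant_id!r}")
    return problems


def estimate_inflorescence_flowers(mean_flowers_per_inflorescence: float,
                                   n_inflorescences: int) -> int:
    """Per-plant flower count for species with numerous small flowers:
    average flowers per inflorescence times the number of inflorescences,
    rounded half-up to an integer."""
    if mean_flowers_per_inflorescence < 0 or n_inflorescences < 0:
        raise ValueError("inputs must be nonnegative")
    return int(math.floor(mean_flowers_per_inflorescence * n_inflorescences + 0.5))


def pollination_environment(community: SiteCommunity,
                            period_minutes: float = DEFAULT_PERIOD_MINUTES,
                            observed_minutes: float | None = None) -> PollinationSummary:
    """Per-plant visitor richness and per-flower visitation rate.

    Richness counts visitor species with at least one visit. The rate is total
    visits to the plant divided by its open-flower count, expressed per
    observation period (default one 15-minute plot-day). When
    ``observed_minutes`` is given, counts are rescaled from the observed
    effort to one period; otherwise counts are taken as one period's worth.
    Plants with no recorded flower count (or zero flowers) get a NaN rate.
    """
    counts = community.counts
    richness = (counts > 0).sum(axis=1).astype(int)
    visits = counts.sum(axis=1)
    scale = 1.0 if observed_minutes is None else period_minutes / observed_minutes
    rate = np.full(len(community.plants), np.nan)
    for i, plant in enumerate(community.plants):
        if plant.flower_count and plant.flower_count > 0:
            rate[i] = visits[i] * scale / plant.flower_count
    return PollinationSummary(
        site_id=community.site_id,
        plant_ids=community.plant_ids,
        richness=richness,
        visitation_rate=rate,
        visitor_abundance=counts.copy(),
    )


def bray_curtis_matrix(abundance_vectors: Iterable[Sequence[float]]) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, d = 1 - 2*sum(min)/sum(x+y).

    Input rows are nonnegative abundance vectors of equal length (e.g. one
    visitor-composition vector per sampling date); output is a symmetric
    matrix with zero diagonal and values in [0, 1].
    """
    X = np.asarray(list(abundance_vectors), dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of abundance vectors")
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero abundance vector")
    return squareform(pdist(X, metric="braycurtis"))
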