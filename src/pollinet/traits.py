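"""Floral-trait similarity: Gower distances, per-species similarity indices,
native-vs-alien summaries, and bee colour-hexagon chromatic coordinates.

Traits are mixed-type: quantitative columns (flower height, corolla diameter,
corolla opening — zero in non-tubular species — and the two chromatic
coordinates of trichromatic hymenopteran colour space) plus optional
categorical columns. Gower's distance averages range-normalized absolute
differences for quantitative traits and 0/1 mismatches for categorical ones;
traits with zero community range or missing values drop out of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QUANTITATIVE_TRAITS", "TraitTable", "SimilarityResult",
    "gower_distance", "gower_distance_matrix", "similarity_index",
    "group_similarity_summary", "hexagon_coordinates",
]

QUANTITATIVE_TRAITS = (
    "flower_height_mm",
    "corolla_diameter_mm",
    "corolla_opening_mm",
    "hex_x",
    "hex_y",
)


@dataclass
class TraitTable:
    """Per-species floral traits with the community-level ranges used for
    Gower normalization."""

    data: pd.DataFrame  # indexed by species_id
    quantitative: tuple[str, ...] = QUANTITATIVE_TRAITS
    categorical: tuple[str, ...] = ()
    ranges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "species_id" in self.data.columns:
            self.data = self.data.set_index("species_id")
        for t in self.quantitative:
            if t not in self.data.columns:
                raise ValueError(f"missing quantitative trait column {t!r}")
            if t not in self.ranges:
                col = self.data[t].astype(float)
                self.ranges[t] = float(col.max() - col.min())

    @classmethod
    def from_csv(cls, path: str | Path, categorical: tuple[str, ...] = ()) -> "TraitTable":
        return cls(pd.read_csv(path, dtype={"species_id": str}), categorical=categorical)

    def to_csv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, index=False)

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]


@dataclass
class SimilarityResult:
    """Per-species similarity indices with community and origin-group summaries."""

    species_ids: list[str]
    s: np.ndarray
    mean: float
    sd: float
    native_mean: float  # NaN when the group is empty
    alien_mean: float


def gower_distance(traits_a: dict | pd.Series, traits_b: dict | pd.Series,
                   ranges: dict[str, float],
                   categorical: tuple[str, ...] = ()) -> float:
    """Gower distance between two species' trait vectors, in [0, 1].

    Quantitative traits contribute |x - y| / range; categorical traits
    contribute 0/1 mismatch; traits with zero range or a missing value on
    either side are excluded from the mean.
    """
    parts: list[float] = []
    for t, rng in ranges.items():
        x, y = traits_a.get(t), traits_b.get(t)
        if x is None or y is None or not (math.isfinite(x) and math.isfinite(y)):
            continue
        if rng <= 0:
            continue
        parts.append(abs(x - y) / rng)
    for t in categorical:
        x, y = traits_a.get(t), traits_b.get(t)
        if x is None or y is None:
            continue
        parts.append(0.0 if x == y else 1.0)
    if not parts:
        raise ValueError("no usable trait shared by the two species")
    return float(np.clip(np.mean(parts), 0.0, 1.0))


def gower_distance_matrix(table: TraitTable) -> np.ndarray:
    """Symmetric matrix of pairwise Gower distances over the table's species."""
    n = len(table.data)
    quant = [t for t in table.quantitative if table.ranges.get(t, 0) > 0]
    X = table.data[quant].to_numpy(dtype=float)
    rng = np.array([table.ranges[t] for t in quant])
    valid = np.isfinite(X)
    D = np.zeros((n, n))
    C = (
        table.data[list(table.categorical)].to_numpy()
        if table.categorical else np.zeros((n, 0))
    )
    for i in range(n):
        diff = np.abs(X - X[i]) / rng
        use = valid & valid[i]
        num = np.where(use, diff, 0.0).sum(axis=1)
        cnt = use.sum(axis=1).astype(float)
        if C.shape[1]:
            num += (C != C[i]).sum(axis=1)
            cnt += C.shape[1]
        with np.errstate(invalid="ignore"):
            D[i] = num / cnt
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2, 0.0, 1.0)


def similarity_index(table: TraitTable) -> np.ndarray:
    """Per-species similarity s_i = 1 - mean Gower distance to every other
    species in the community."""
    n = len(table.data)
    if n < 2:
        raise ValueError("similarity index needs at least two species")
    D = gower_distance_matrix(table)
    mean_off = (D.sum(axis=1)) / (n - 1)
    return 1.0 - mean_off


def group_similarity_summary(table: TraitTable, origins: dict[str, str]) -> SimilarityResult:
    """Community mean +/- sd of the similarity index, with native and alien
    subgroup means (NaN for an absent group)."""
    s = similarity_index(table)
    ids = table.species_ids
    missing = [sid for sid in ids if sid not in origins]
    if missing:
        raise ValueError(f"origin missing for species {missing}")
    lab = np.array([origins[sid] for sid in ids])

    def group_mean(name: str) -> float:
        sel = s[lab == name]
        return float(sel.mean()) if len(sel) else math.nan

    return SimilarityResult(
        species_ids=ids,
        s=s,
        mean=float(s.mean()),
        sd=float(s.std(ddof=1)) if len(s) > 1 else math.nan,
        native_mean=group_mean("native"),
        alien_mean=group_mean("alien"),
    )


def hexagon_coordinates(reflectance: np.ndarray, sensitivities: np.ndarray,
                        illuminant: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    """Chromatic (X, Y) of a stimulus in the trichromatic colour hexagon.

    All inputs are sampled on one wavelength grid (300-700 nm is the usual
    span). ``sensitivities`` has one row per receptor channel in the order
    (UV, blue, green). Quantum catches are taken relative to the background
    (von Kries adaptation), receptor excitation is E = q / (q + 1), and

        X = (sqrt(3)/2) * (E_G - E_UV),   Y = E_B - (E_UV + E_G) / 2.

    A stimulus identical to the background lands at the achromatic centre
    (0, 0); coordinates are invariant to uniform scaling of the illuminant.
    """
    refl = np.asarray(reflectance, dtype=float)
    S = np.atleast_2d(np.asarray(sensitivities, dtype=float))
    ill = np.asarray(illuminant, dtype=float)
    bg = np.asarray(background, dtype=float)
    if S.shape[0] != 3:
        raise ValueError("need exactly three receptor channels (UV, blue, green)")
    if not (refl.shape == ill.shape == bg.shape == S[0].shape):
        raise ValueError("wavelength grids do not match")
    catch_bg = (S * ill * bg).sum(axis=1)
    if (catch_bg <= 0).any():
        raise ValueError("nonpositive background quantum catch")
    q = (S * ill * refl).sum(axis=1) / catch_bg
    E = q / (q + 1.0)
    e_uv, e_b, e_g = E
    x = (math.sqrt(3) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return float(x), float(y)
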