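"""Interaction sampling completeness: accumulation curves and Chao1.

The sampling unit is a site-day (nine survey days per site in the study
design). Distinct plant-visitor pairs accumulate over random orderings of the
samples; the asymptotic number of pairwise interactions is estimated with
Chao1 from the singleton and doubleton interaction frequencies, and sampling
completeness is the observed share of that estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from pollinet.community import VisitEvent

__all__ = ["RarefactionResult", "group_events_by_sample",
           "interaction_accumulation", "chao1", "completeness_percent",
           "completeness_summary"]


@dataclass
class RarefactionResult:
    """Accumulation curve plus Chao1-based completeness for one site."""

    mean_curve: np.ndarray
    sd_curve: np.ndarray
    s_obs: int
    f1: int
    f2: int
    chao1_classic: float
    chao1_bias_corrected: float
    completeness: float  # percent, using the variant-switching estimate

    @property
    def chao1(self) -> float:
        """Classic form unless there are no doubletons, then bias-corrected."""
        return self.chao1_classic if self.f2 > 0 else self.chao1_bias_corrected


def group_events_by_sample(events: list[VisitEvent],
                           key: str = "date_id") -> dict[str, set[tuple[str, str]]]:
    """Distinct plant-visitor pairs per sample (default sample = survey day)."""
    if not events:
        raise ValueError("empty event list")
    samples: dict[str, set[tuple[str, str]]] = {}
    for ev in events:
        samples.setdefault(getattr(ev, key), set()).add((ev.plant_id, ev.visitor_id))
    return samples


def interaction_accumulation(samples: dict[str, set[tuple[str, str]]],
                             n_randomizations: int = 500,
                             seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- sd accumulation curve of distinct pairs over sample
    permutations (sampling without replacement)."""
    if not samples:
        raise ValueError("no samples")
    keys = sorted(samples)
    n = len(keys)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curves = np.empty((n_randomizations, n))
    for b in range(n_randomizations):
        seen: set[tuple[str, str]] = set()
        for t, k in enumerate(rng.permutation(n)):
            seen |= samples[keys[k]]
            curves[b, t] = len(seen)
    return curves.mean(axis=0), curves.std(axis=0, ddof=1 if n_randomizations > 1 else 0)


def chao1(frequencies, variant: str = "auto") -> float:
    """Chao1 asymptotic interaction richness estimate.

    ``frequencies`` are the observation counts of each distinct pair; F1 and
    F2 count pairs seen exactly once and twice. The classic form is
    S_obs + F1^2 / (2 F2); the bias-corrected form,
    S_obs + F1(F1-1) / (2(F2+1)), replaces it when F2 = 0 (``variant="auto"``,
    the convention of the usual estimation software) or on request.
    """
    f = np.asarray(list(frequencies), dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency list")
    if (f < 0).any():
        raise ValueError("frequencies must be nonnegative")
    f = f[f > 0]
    s_obs = len(f)
    f1 = int((f == 1).sum())
    f2 = int((f == 2).sum())
    corrected = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if variant == "bias_corrected":
        return float(corrected)
    if f2 == 0:
        if variant == "classic":
            raise ValueError("classic Chao1 undefined with no doubletons")
        return float(corrected)
    if variant not in ("auto", "classic"):
        raise ValueError(f"unknown variant {variant!r}")
    return float(s_obs + f1 ** 2 / (2.0 * f2))


def completeness_percent(s_obs: int, chao1_estimate: float) -> float:
    """Percent of the estimated asymptotic interaction richness observed."""
    if chao1_estimate <= 0:
        raise ValueError("Chao1 estimate must be positive")
    if s_obs <= 0 or s_obs > chao1_estimate + 1e-9:
        raise ValueError("need chao1_estimate >= s_obs > 0")
    return 100.0 * s_obs / chao1_estimate


def completeness_summary(events: list[VisitEvent], n_randomizations: int = 500,
                         seed: int | np.random.Generator = 0) -> RarefactionResult:
    """Full rarefaction/Chao1 summary for one site's visit events."""
    samples = group_events_by_sample(events)
    mean_curve, sd_curve = interaction_accumulation(samples, n_randomizations, seed)
    freq = Counter()
    for ev in events:
        freq[(ev.plant_id, ev.visitor_id)] += ev.n_visits
    s_obs = len(freq)
    f = np.asarray(list(freq.values()))
    f1 = int((f == 1).sum())
    f2 = int((f == 2).sum())
    corrected = chao1(freq.values(), "bias_corrected")
    classic = chao1(freq.values(), "classic") if f2 > 0 else corrected
    est = chao1(freq.values(), "auto")
    return RarefactionResult(
        mean_curve=mean_curve,
        sd_curve=sd_curve,
        s_obs=s_obs,
        f1=f1,
        f2=f2,
        chao1_classic=classic,
        chao1_bias_corrected=corrected,
        completeness=completeness_percent(s_obs, est),
    )
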