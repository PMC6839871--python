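"""Bundled summary data of the Yucatán coastal sand-dune survey.

The raw per-site interaction matrices of the survey are not redistributed
here; what ships is the published per-site summary table (species counts,
alien flower share, floral-trait similarity) and the study-wide counts, which
are the inputs for study-level arithmetic (e.g. the mean alien species
proportion across the nine sites) and the emulation targets of the synthetic
generator.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["yucatan_site_summary", "yucatan_study_counts"]


def _data_path(name: str):
    return resources.files("pollinet").joinpath("data", name)


def yucatan_site_summary() -> pd.DataFrame:
    """Per-site survey summary: native/alien species counts, alien species
    percentage, alien flower percentage, and the community floral-trait
    similarity (mean and SD), one row per site, ordered by alien flower share."""
    with resources.as_file(_data_path("yucatan_site_summary.csv")) as p:
        return pd.read_csv(p)


def yucatan_study_counts() -> dict:
    """Study-wide counts: insect species per order, total distinct pairwise
    interactions, visit and flower totals, and per-site ranges."""
    return json.loads(_data_path("yucatan_study_counts.json").read_text())
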