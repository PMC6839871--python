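"""End-to-end study pipeline: metrics, nulls, species roles, traits,
scenarios and completeness for every site, plus consolidated study tables.

Artifacts per site (under ``<out>/<site_id>/``): ``metrics.json``,
``species_metrics.csv``, ``null_<metric>.json``, ``scenarios.csv``,
``completeness.json``. Study level: ``site_summary.csv`` (species counts,
alien flower share, trait similarity), ``network_metrics.csv`` (one row per
site, all network-level metrics), ``scenario_effects.csv`` (per-metric
scenario means, Hedges' g vs intact and percent change). Every artifact
embeds the configuration and master seed for exact re-runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pollinet.community import SiteCommunity, load_community, write_community
from pollinet.completeness import completeness_summary
from pollinet.metrics import SAConfig, compute_network_metrics
from pollinet.nulls import significance_test
from pollinet.scenarios import SCENARIOS, hedges_g, run_scenarios
from pollinet.species import species_level_table
from pollinet.synth import GeneratorConfig, generate_study
from pollinet.traits import TraitTable, group_similarity_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (``key = value`` file format)."""

    input_dir: str | None = None  # site directories; None -> synthetic study
    n_sites: int = 9
    seed: int = 0
    nodf_replicates: int = 1000
    modularity_replicates: int = 100
    scenario_replicates: int = 100
    robustness_orders: int = 100
    contribution_randomizations: int = 100
    rarefaction_randomizations: int = 500
    sa_cooling: float = 0.95
    sa_restarts: int = 3
    sa_moves: int = 0  # moves per temperature; 0 = 50 * (plants + visitors)
    out_dir: str = "pollinet_out"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ValueError(f"unknown configuration key {key!r}")
            try:
                values[key] = int(raw)
            except ValueError:
                try:
                    values[key] = float(raw)
                except ValueError:
                    values[key] = raw
        values.update(overrides)
        return cls(**values)

    def sa_config(self) -> SAConfig:
        return SAConfig(cooling=self.sa_cooling, n_restarts=self.sa_restarts,
                        moves_per_temperature=self.sa_moves or None)

    def provenance(self) -> dict:
        return {"config": dataclasses.asdict(self), "seed": self.seed}


def _site_loaders(config: PipelineConfig):
    """Yield (site name, loader) pairs so a malformed site fails in isolation."""
    if config.input_dir is None:
        gen = GeneratorConfig(seed=config.seed)
        for community, table in generate_study(gen, config.n_sites):
            yield community.site_id, (lambda c=community, t=table: (c, t))
        return
    root = Path(config.input_dir)
    site_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not site_dirs:
        raise FileNotFoundError(f"no site directories under {root}")

    def load(site_dir: Path) -> tuple[SiteCommunity, TraitTable | None]:
        community = load_community(site_dir / "interactions.csv",
                                   site_dir / "species.csv",
                                   site_id=site_dir.name)
        traits_path = site_dir / "traits.csv"
        table = TraitTable.from_csv(traits_path) if traits_path.exists() else None
        return community, table

    for site_dir in site_dirs:
        yield site_dir.name, (lambda d=site_dir: load(d))


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _analyse_site(community: SiteCommunity, table: TraitTable | None,
                  config: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    sa = config.sa_config()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    m = compute_network_metrics(
        community.counts, n_orders=config.robustness_orders,
        sa_config=sa, seed=rng,
        species_ids=community.plant_ids + community.visitor_ids,
    )
    _write_json(out / "metrics.json", {
        "site_id": community.site_id,
        "nodf": m.nodf, "h2prime": m.h2prime, "modularity_q": m.modularity_q,
        "robustness": m.robustness, "connectance": m.connectance,
        "links_per_species": m.links_per_species,
        "n_pairwise_interactions": m.n_pairwise_interactions,
        **prov,
    })

    rows = species_level_table(
        community.counts, community.plant_ids, community.visitor_ids,
        n_randomizations=config.contribution_randomizations, seed=rng)
    origin = {r.species_id: r.origin for r in community.plants + community.visitors}
    df = pd.DataFrame(rows)
    df.insert(2, "origin", [origin[s] for s in df["species_id"]])
    df.to_csv(out / "species_metrics.csv", index=False)

    nulls = {}
    for metric, reps in (("nodf", config.nodf_replicates),
                         ("modularity_q", config.modularity_replicates)):
        ens = significance_test(community.counts, metric, reps, seed=rng, sa_config=sa)
        nulls[metric] = ens.summary()
        _write_json(out / f"null_{metric}.json", {**ens.summary(), **prov})

    similarity = None
    if table is not None and len(table.data) >= 2:
        sim = group_similarity_summary(
            table, {p.species_id: p.origin for p in community.plants})
        similarity = {"mean": sim.mean, "sd": sim.sd,
                      "native_mean": sim.native_mean, "alien_mean": sim.alien_mean}
        _write_json(out / "trait_similarity.json", {**similarity, **prov})

    comp = None
    if community.surveys:
        res = completeness_summary(community.surveys,
                                   config.rarefaction_randomizations, seed=rng)
        comp = {"s_obs": res.s_obs, "f1": res.f1, "f2": res.f2,
                "chao1": res.chao1, "chao1_classic": res.chao1_classic,
                "chao1_bias_corrected": res.chao1_bias_corrected,
                "completeness_pct": res.completeness}
        _write_json(out / "completeness.json", {**comp, **prov})
        pd.DataFrame({
            "sample_index": np.arange(1, len(res.mean_curve) + 1),
            "mean": res.mean_curve, "sd": res.sd_curve,
        }).to_csv(out / "accumulation_curve.csv", index=False)

    flowers = np.array([p.flower_count or 0 for p in community.plants], dtype=float)
    alien_flowers = sum(float(p.flower_count or 0) for p in community.alien_plants())
    return {
        "site_id": community.site_id,
        "n_plants": len(community.plants),
        "n_visitors": len(community.visitors),
        "n_alien_plants": len(community.alien_plants()),
        "alien_flower_share": alien_flowers / flowers.sum() if flowers.sum() else math.nan,
        "total_visits": community.total_visits,
        "metrics": m,
        "nulls": nulls,
        "similarity": similarity,
        "completeness": comp,
    }


def run_pipeline(config: PipelineConfig) -> int:
    """Run every stage on every site; returns the number of failed sites.

    Per-site failures are isolated and logged; the consolidated tables cover
    the sites that succeeded.
    """
    logging.basicConfig(level=config.log_level)
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    summaries = []
    ok_sites: list[SiteCommunity] = []
    failures = 0
    for site_name, loader in _site_loaders(config):
        try:
            community, table = loader()
            summaries.append(_analyse_site(community, table, config,
                                           out_root / community.site_id))
            ok_sites.append(community)
        except Exception:
            failures += 1
            logger.exception("site %s failed; continuing", site_name)

    if summaries:
        pd.DataFrame([{
            "site_id": s["site_id"],
            "n_plants": s["n_plants"],
            "n_visitors": s["n_visitors"],
            "n_alien_plants": s["n_alien_plants"],
            "alien_flower_share": s["alien_flower_share"],
            "total_visits": s["total_visits"],
            "trait_similarity_mean": (s["similarity"] or {}).get("mean", math.nan),
        } for s in summaries]).to_csv(out_root / "site_summary.csv", index=False)

        pd.DataFrame([{
            "site_id": s["site_id"],
            "nodf": s["metrics"].nodf,
            "nodf_p": s["nulls"]["nodf"]["p_value"],
            "h2prime": s["metrics"].h2prime,
            "modularity_q": s["metrics"].modularity_q,
            "modularity_p": s["nulls"]["modularity_q"]["p_value"],
            "robustness": s["metrics"].robustness,
            "connectance": s["metrics"].connectance,
            "links_per_species": s["metrics"].links_per_species,
            "n_pairwise_interactions": s["metrics"].n_pairwise_interactions,
        } for s in summaries]).to_csv(out_root / "network_metrics.csv", index=False)

    if ok_sites:
        _scenario_tables(ok_sites, config, out_root)
    _write_json(out_root / "run_info.json",
                {**config.provenance(), "n_sites_ok": len(summaries),
                 "n_sites_failed": failures})
    return failures


def _scenario_tables(sites: list[SiteCommunity], config: PipelineConfig,
                     out_root: Path) -> None:
    results = run_scenarios(
        sites, n_replicates=config.scenario_replicates, seed=config.seed,
        n_orders=config.robustness_orders, sa_config=config.sa_config())
    long_rows = []
    for res in results:
        for metric, vals in res.values.items():
            for b, v in enumerate(vals):
                long_rows.append({"site_id": res.site_id, "scenario": res.scenario,
                                  "replicate": b, "metric": metric, "value": v})
    long = pd.DataFrame(long_rows)
    long.to_csv(out_root / "scenarios.csv", index=False)

    # Per-metric across-site means per scenario, with Hedges' g vs intact
    effects: dict[str, dict] = {}
    table_rows = []
    for metric in long["metric"].unique():
        sub = long[long["metric"] == metric]
        per_site = sub.groupby(["scenario", "site_id"])["value"].mean().reset_index()
        intact = per_site[per_site["scenario"] == "intact"]["value"].to_numpy()
        effects[metric] = {}
        for scenario in SCENARIOS:
            vals = per_site[per_site["scenario"] == scenario]["value"].to_numpy()
            vals = vals[np.isfinite(vals)]
            row = {"metric": metric, "scenario": scenario,
                   "mean": float(np.mean(vals)) if len(vals) else math.nan,
                   "se": float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                         if len(vals) > 1 else math.nan}
            if scenario != "intact" and len(vals) > 1 and len(intact) > 1:
                try:
                    es = hedges_g(float(np.mean(intact)), float(np.std(intact, ddof=1)),
                                  len(intact), float(np.mean(vals)),
                                  float(np.std(vals, ddof=1)), len(vals))
                    effects[metric][scenario] = dataclasses.asdict(es)
                    row["hedges_g"] = es.g
                    row["pct_change"] = es.percent_change
                except ValueError:
                    pass
            table_rows.append(row)
    pd.DataFrame(table_rows).to_csv(out_root / "scenario_effects.csv", index=False)
    _write_json(out_root / "effects.json", {**config.provenance(), "effects": effects})


def simulate_to_dir(config: GeneratorConfig, n_sites: int, out_dir: str | Path) -> list[Path]:
    """Write one directory per synthetic site (interactions/species/traits/visits CSVs)."""
    out_root = Path(out_dir)
    paths = []
    for community, table in generate_study(config, n_sites):
        site_dir = out_root / community.site_id
        write_community(community, site_dir)
        table.to_csv(site_dir / "traits.csv")
        if community.surveys:
            pd.DataFrame([dataclasses.asdict(ev) for ev in community.surveys]) \
                .to_csv(site_dir / "visits.csv", index=False)
        paths.append(site_dir)
    return paths
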