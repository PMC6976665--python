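"""End-to-end analysis pipeline behind one configuration.

Stage order mirrors the study workflow: ingest or simulate a count table,
drop very rare taxa, then run two non-interacting branches — (A) rarefy to
the minimum depth and compute alpha diversity on integer counts; (B) TMM-
normalize, aggregate to genus if a taxonomy is supplied, compute Bray-Curtis
distances, PERMANOVA, the dispersion-homogeneity test and SIMPER between
plant types, pick the top discriminant genera, and run the land-use niche
classification for each configured sample subset. Every stochastic stage
draws its seed deterministically from the master seed and the stage name, so
a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import beta, diversity, niche, simdata, tables
from .lui import mean_lui, read_records, region_means, write_lui
from .simdata import SimConfig

__all__ = ["RunConfig", "run_pipeline", "compare_subsets", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    # either a simulation...
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # ...or external inputs
    counts_path: str | None = None
    metadata_path: str | None = None
    records_path: str | None = None
    taxonomy_path: str | None = None
    guilds_path: str | None = None
    # stage parameters
    year_from: int = 2006
    year_to: int = 2014
    min_total: int = 4
    rarefy_depth: int | str = "auto"
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    permanova_terms: list[str] = field(
        default_factory=lambda: ["LUI", "species", "plant_type"]
    )
    n_perm: int = 1000
    simper_k: int = 30
    niche_n_iter: int = 10000
    alpha: float = 0.05
    subsets: dict[str, dict[str, str] | None] = field(
        default_factory=lambda: {
            "total": None,
            "phytometer": {"plant_type": "phytometer"},
            "resident": {"plant_type": "resident"},
        }
    )
    guild_overrides: dict[str, str] = field(
        default_factory=lambda: {"Paraphoma": "pathotroph"}
    )
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        config = cls(**raw)
        config.sim = SimConfig(**sim_raw) if isinstance(sim_raw, dict) else sim_raw
        return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; write TSV/JSON outputs and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "seeds": {},
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage_t0 = time.perf_counter()

    def mark(stage: str, **info) -> None:
        elapsed = time.perf_counter() - stage_t0
        manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3), **info}
        log.info("stage %s done (%.2fs): %s", stage, elapsed, info)

    # -- land use ----------------------------------------------------------
    if config.simulate:
        config.sim.seed = stage_seed(config.master_seed, "simulate")
        manifest["seeds"]["simulate"] = config.sim.seed
        records = simdata.simulate_landuse(config.sim)
    else:
        if not config.records_path:
            raise ValueError("records_path required when not simulating")
        records = read_records(config.records_path)
    means = region_means(records)
    lui = mean_lui(records, means, config.year_from, config.year_to)
    write_lui(lui, out / "lui.tsv")
    mark("lui", n_plots=len(lui), lui_range=[float(lui.min()), float(lui.max())])

    # -- counts ------------------------------------------------------------
    truth = None
    if config.simulate:
        table, truth = simdata.simulate_community(config.sim, lui)
        truth.to_csv(out / "truth.tsv", sep="\t")
        table.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
        tables.write_counts(table, out / "counts.tsv")
    else:
        if not (config.counts_path and config.metadata_path):
            raise ValueError("counts_path and metadata_path required when not simulating")
        metadata = tables.read_metadata(config.metadata_path)
        table = tables.read_counts(config.counts_path, metadata)
    mark("ingest", n_taxa=table.shape[0], n_samples=table.shape[1])
    manifest["n_samples"] = table.shape[1]

    filtered = tables.filter_rare(table, min_total=config.min_total)
    mark("filter_rare", n_taxa=filtered.shape[0])

    # -- branch A: rarefied integer counts -> alpha diversity --------------
    depth = (
        tables.min_depth(filtered)
        if config.rarefy_depth == "auto"
        else int(config.rarefy_depth)
    )
    seed_rarefy = stage_seed(config.master_seed, "rarefy")
    manifest["seeds"]["rarefy"] = seed_rarefy
    rarefied = tables.rarefy(filtered, depth, seed=seed_rarefy)
    alpha = diversity.alpha_diversity(rarefied)
    alpha.to_csv(out / "alpha.tsv", sep="\t")
    venn = tables.venn_partition(rarefied, "plant_type")
    venn.to_csv(out / "venn_plant_type.tsv", sep="\t", index=False)
    mark("alpha", depth=depth, median_observed=float(alpha["observed"].median()))

    # -- branch B: TMM-normalized -> beta + niche --------------------------
    normalized, factors = tables.tmm_normalize(
        filtered, trim_m=config.tmm_trim_m, trim_a=config.tmm_trim_a
    )
    factors.to_csv(out / "tmm_factors.tsv", sep="\t", header=True)
    if config.taxonomy_path:
        taxonomy = tables.read_taxonomy(config.taxonomy_path)
        genus_table = tables.aggregate_rank(normalized, taxonomy, rank="genus")
    else:
        genus_table = normalized  # simulated tables are already genus-level
    dist = beta.bray_curtis(genus_table)
    dist.to_csv(out / "bray_curtis.tsv", sep="\t")

    meta = genus_table.metadata.loc[genus_table.samples].copy()
    meta["LUI"] = lui.loc[meta["plot_id"]].to_numpy()
    terms = [t for t in config.permanova_terms if t == "LUI" or t in meta.columns]
    perm = beta.permanova(
        dist, meta, terms, n_perm=config.n_perm,
        seed=stage_seed(config.master_seed, "permanova"),
    )
    perm.table.to_csv(out / "permanova.tsv", sep="\t")
    disp = beta.dispersion_test(
        dist, meta["plant_type"], n_perm=max(config.n_perm - 1, 1),
        seed=stage_seed(config.master_seed, "dispersion"),
    )
    simper_table = beta.simper(genus_table, meta["plant_type"])
    simper_table.to_csv(out / "simper.tsv", sep="\t", index=False)
    k = min(config.simper_k, (~simper_table["taxon"].str.startswith("unclassified")).sum())
    top_genera, top_cum = beta.top_discriminant_genera(simper_table, k=k)
    mark(
        "beta",
        permanova_terms=terms,
        dispersion_F=disp["F"],
        dispersion_p=disp["p"],
        top_k=k,
        top_cumulative_percent=round(top_cum, 2),
    )

    # -- niche classification per subset ----------------------------------
    guild_table = (
        pd.read_csv(config.guilds_path, sep="\t") if config.guilds_path else None
    )
    top_table = tables.CountTable(
        genus_table.counts.loc[top_genera], genus_table.metadata
    )
    niche_results: dict[str, pd.DataFrame] = {}
    for label, subset in config.subsets.items():
        seed = stage_seed(config.master_seed, f"niche/{label}")
        manifest["seeds"][f"niche/{label}"] = seed
        result = niche.land_use_niche(
            top_table, lui, subset=subset, n_iter=config.niche_n_iter,
            alpha=config.alpha, seed=seed, guild_table=guild_table,
            overrides=config.guild_overrides,
        )
        result.to_csv(out / f"niche_{label}.tsv", sep="\t")
        niche_results[label] = result
        report = niche.niche_report(result, lui)
        mark(
            f"niche/{label}",
            categories=report["category_counts"],
            reference_lui=round(report["reference_lui"], 4),
        )

    if len(niche_results) >= 2:
        agreement = compare_subsets(niche_results)
        agreement.to_csv(out / "subset_agreement.tsv", sep="\t")

    for path in sorted(out.glob("*.tsv")):
        manifest["outputs"][path.name] = _sha256(path)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def compare_subsets(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-genus category agreement between two or more niche-result tables.

    All tables must cover a shared genus set (the intersection must be
    non-empty). Returns one row per shared genus with each subset's category
    and an ``agree`` flag; summary counts live in ``DataFrame.attrs``.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 result tables to compare")
    labels = list(results)
    shared = set(results[labels[0]].index)
    for label in labels[1:]:
        shared &= set(results[label].index)
    if not shared:
        raise ValueError("result tables share no genera")
    shared = sorted(shared)
    out = pd.DataFrame(index=pd.Index(shared, name="genus"))
    for label in labels:
        out[label] = results[label].loc[shared, "category"]
    out["agree"] = out[labels].nunique(axis=1) == 1
    out.attrs["n_concordant"] = int(out["agree"].sum())
    out.attrs["n_discordant"] = int((~out["agree"]).sum())
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
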