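"""End-to-end orchestration: simulate -> weight -> statistics -> correlate.

A :class:`PipelineConfig` either names a simulation preset or points at real
data files (VCF + sample map + regions BED + gene trees + linkage map).  The
stages run in dependency order and produce stage TSVs plus a JSON report of
every parameter, input hash, and headline statistic.  The same config and
seed always produce byte-identical report bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity, dstats, recomb, simulate, weights
from .io import (
    RegionSet,
    TaxonMap,
    read_genotype_vcf,
    read_linkage_map,
    read_newick,
    read_regions_bed,
    write_genotype_vcf,
    write_linkage_map,
    write_newick_file,
    write_regions_bed,
)
from .trees import enumerate_rooted_topologies

logger = logging.getLogger("introscan")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters; either ``preset`` or the data paths must be set."""

    # data source
    preset: str | None = None
    vcf: str | None = None
    sample_map: str | None = None
    regions_bed: str | None = None
    gene_trees: str | None = None
    linkage_map: str | None = None
    # simulation overrides
    n_regions: int | None = None
    samples_per_taxon: dict[str, int] | None = None
    # stage parameters
    seed: int = 1
    window: int = 5
    n_blocks: int = 50
    bin_size: int = 1_000_000
    max_rate: float = 100.0
    regime_threshold: float = 5.0
    weight_threshold: float = 1.0
    alpha: float = 0.01
    weighted_jackknife: bool = False
    # analysis roles (defaults match the bundled five-taxon scenarios)
    d_roles: dict[str, str] = field(default_factory=lambda: {
        "P1": "verb", "P2": "card", "P3": "lew_S", "O": "bic"})
    pairwise_taxa: tuple[str, str] | None = ("lew_S", "card")
    dfoil_roles: dict[str, str] | None = None   # None: first accessions of the 5 taxa
    d2_species_clade: tuple[str, ...] = ("card", "verb")
    d2_intro_clade: tuple[str, ...] = ("card", "lew_N", "lew_S")
    d2_pair: tuple[str, str] = ("lew_S", "verb")
    # outputs
    out_dir: str | None = None
    write_simulated_data: bool = False

    def __post_init__(self):
        has_paths = self.vcf is not None
        if self.preset is None and not has_paths:
            raise ValueError("config must set a preset or real-data paths")
        if self.preset is not None and has_paths:
            raise ValueError("config sets both a preset and real-data paths")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = json.load(handle)
        for key in ("pairwise_taxa", "d2_species_clade", "d2_intro_clade", "d2_pair"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return (and optionally write) the report."""
    config_dict = cfg.to_dict()
    # output paths are environment, not analysis: keep them out of the
    # report body so identical analyses give byte-identical reports
    config_dict.pop("out_dir", None)
    report: dict = {"config": _jsonable(config_dict), "stages": {}}
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- inputs: simulate or load ------------------------------------
    truth = None
    if cfg.preset is not None:
        overrides: dict = {"seed": cfg.seed}
        if cfg.n_regions is not None:
            overrides["n_regions"] = cfg.n_regions
        if cfg.samples_per_taxon is not None:
            overrides["samples_per_taxon"] = cfg.samples_per_taxon
        sc = _stage("simulate")(simulate.preset_scenario)(cfg.preset, **overrides)
        hap_trees, truth = _stage("simulate")(simulate.simulate_gene_trees)(sc)
        gm, rs = _stage("simulate")(simulate.simulate_genotypes)(hap_trees, sc)
        lm = _stage("simulate")(simulate.simulate_linkage_map)(sc)
        gene_trees = [simulate.haplotype_subtree(t) for t in hap_trees]
        taxon_map = sc.taxon_map
        accessible = {r.region_id: r.end - r.start for r in rs}
        report["stages"]["simulate"] = {
            "preset": cfg.preset,
            "n_regions": len(rs),
            "n_sites": gm.n_sites,
            "samples_per_taxon": dict(sc.samples_per_taxon),
            "introgressed_fraction_true": float(truth.introgressed.mean()),
        }
        if out_dir and cfg.write_simulated_data:
            write_genotype_vcf(gm, out_dir / "simulated.vcf")
            write_regions_bed(rs, out_dir / "regions.bed")
            write_newick_file(gene_trees, out_dir / "gene_trees.nwk")
            write_linkage_map(lm, out_dir / "linkage_map.tsv")
            taxon_map.write_tsv(out_dir / "samples.tsv")
    else:
        taxon_map = _stage("load")(TaxonMap.read_tsv)(cfg.sample_map)
        gm = _stage("load")(read_genotype_vcf)(cfg.vcf, taxon_map)
        rs = _stage("load")(read_regions_bed)(cfg.regions_bed)
        gene_trees = _stage("load")(read_newick)(cfg.gene_trees)
        lm = _stage("load")(read_linkage_map)(cfg.linkage_map)
        accessible = {r.region_id: r.end - r.start for r in rs}
        report["stages"]["load"] = {
            "inputs": {
                name: _hash_file(p)
                for name, p in (
                    ("vcf", cfg.vcf), ("sample_map", cfg.sample_map),
                    ("regions_bed", cfg.regions_bed),
                    ("gene_trees", cfg.gene_trees),
                    ("linkage_map", cfg.linkage_map),
                )
            },
            "n_regions": len(rs),
            "n_sites": gm.n_sites,
        }

    # ---- topology weighting ------------------------------------------
    catalog = enumerate_rooted_topologies(taxon_map.taxa)
    region_ids = [r.region_id for r in rs]
    wt = _stage("weight")(weights.weight_gene_trees)(
        gene_trees, region_ids, taxon_map, catalog, seed=cfg.seed
    )
    smoothed = _stage("weight")(weights.window_average_weights)(wt, rs, cfg.window)
    summary = weights.genome_weight_summary(wt)
    intro_clade = list(cfg.d2_intro_clade)
    species_clade = list(cfg.d2_species_clade)
    report["stages"]["weight"] = {
        "n_topologies": len(catalog),
        "window": cfg.window,
        "species_clade_support_pooled": float(
            (summary["pooled"] * np.asarray(catalog.clade_mask(species_clade))).sum()
        ),
        "intro_clade_support_pooled": float(
            (summary["pooled"] * np.asarray(catalog.clade_mask(intro_clade))).sum()
        ),
    }
    if truth is not None and truth.introgressed.any() and not truth.introgressed.all():
        support = weights.aggregate_clade_support(wt, intro_clade)
        values = np.asarray([support[r] for r in region_ids])
        report["stages"]["weight"]["intro_clade_support_by_truth"] = {
            "introgressed": float(values[truth.introgressed].mean()),
            "background": float(values[~truth.introgressed].mean()),
        }
    if out_dir:
        wt.to_tsv(out_dir / "weights.tsv")

    # ---- Patterson's D -----------------------------------------------
    counts = _stage("dstat")(dstats.count_site_patterns)(
        gm, cfg.d_roles, cfg.n_blocks, regions=rs
    )
    dres = _stage("dstat")(dstats.d_statistic)(counts, weighted=cfg.weighted_jackknife)
    report["stages"]["dstat"] = {
        "roles": cfg.d_roles, "D": dres.d, "SE": dres.se, "z": dres.z,
        "p": dres.p, "n_blocks": dres.n_blocks, "n_sites": dres.n_sites,
        "degenerate": dres.degenerate,
    }
    if cfg.pairwise_taxa is not None:
        t3, t2 = cfg.pairwise_taxa
        table = _stage("dstat")(dstats.pairwise_d_scan)(
            gm, t3, t2, cfg.d_roles["P1"], cfg.d_roles["O"], cfg.n_blocks,
            weighted=cfg.weighted_jackknife, regions=rs,
        )
        report["stages"]["dstat"]["pairwise"] = {
            "n_pairs": len(table),
            "D_range": [float(table["D"].min()), float(table["D"].max())],
            "all_positive": bool((table["D"] > 0).all()),
        }
        if out_dir:
            table.to_csv(out_dir / "pairwise_d.tsv", sep="\t", index=False)

    # ---- D_FOIL --------------------------------------------------------
    droles = cfg.dfoil_roles
    if droles is None:
        order = ("lew_N", "lew_S", "card", "verb", "bic")
        if all(t in taxon_map.taxa for t in order):
            droles = {
                role: taxon_map.samples_of(taxon)[0]
                for role, taxon in zip(("P1", "P2", "P3", "P4", "O"), order)
            }
    if droles is not None:
        counts5 = _stage("dfoil")(dstats.count_site_patterns5)(
            gm, droles, cfg.n_blocks, regions=rs
        )
        dfres = _stage("dfoil")(dstats.dfoil)(
            counts5, alpha=cfg.alpha, weighted=cfg.weighted_jackknife
        )
        report["stages"]["dfoil"] = {
            "roles": droles,
            "components": {
                name: {"D": r.d, "z": r.z, "p": r.p}
                for name, r in dfres.components.items()
            },
            "signature": list(dfres.signature),
            "classification": dfres.classification,
            "direction": dstats.dfoil_direction(dfres.signature),
            "alpha": cfg.alpha,
        }

    # ---- diversity / divergence / D2 ---------------------------------
    div = _stage("popgen")(diversity.divergence_table)(
        gm, rs, accessible_sites=accessible
    )
    report["stages"]["popgen"] = div.summary()
    if out_dir:
        div.to_frame().to_csv(out_dir / "divergence.tsv", sep="\t", index=False)
    try:
        d2res = _stage("d2")(diversity.d2_test)(
            div, wt, species_clade, intro_clade, cfg.d2_pair, cfg.weight_threshold
        )
        report["stages"]["d2"] = {
            "pair": list(cfg.d2_pair),
            "D2": d2res.d2, "t": d2res.t, "df": d2res.df, "p": d2res.p,
            "mean_dxy_species_tree": d2res.mean_dxy_species_tree,
            "mean_dxy_intro_tree": d2res.mean_dxy_intro_tree,
            "n_species_class": d2res.n_species_class,
            "n_intro_class": d2res.n_intro_class,
        }
    except StageError as exc:
        if isinstance(exc.cause, ValueError):
            logger.warning("d2 stage skipped: %s", exc.cause)
            report["stages"]["d2"] = {"skipped": str(exc.cause)}
        else:
            raise

    # ---- recombination landscape -------------------------------------
    bins = _stage("recomb")(recomb.estimate_bin_rates)(lm, cfg.bin_size, cfg.max_rate)
    support = smoothed.clade_support(intro_clade)
    corr = _stage("correlate")(recomb.correlate_weights_with_recombination)(
        smoothed.chrom, smoothed.midpoint, support, bins
    )
    regime = recomb.classify_recombination_regime(bins, cfg.regime_threshold)
    n_high = sum(1 for v in regime.values() if v == "high")
    report["stages"]["recomb"] = {
        "n_bins": len(bins),
        "n_usable_bins": len(bins.usable()),
        "n_high_recombination_bins": n_high,
        "regime_threshold": cfg.regime_threshold,
        "spearman_rho": corr.rho,
        "spearman_p": corr.p,
        "n_windows": corr.n,
    }
    if out_dir:
        bins.to_frame().to_csv(out_dir / "recombination_bins.tsv", sep="\t", index=False)

    if out_dir:
        with open(out_dir / "report.json", "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True, allow_nan=True)
            handle.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
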