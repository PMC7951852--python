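"""Per-region nucleotide diversity, divergence, and the D2 direction test.

pi (within a group of k diploids = 2k haplotypes) and dxy (between groups)
are computed from per-site allele counts:

    pi  = sum_sites 2 p (1-p) * n/(n-1)        / n_accessible_sites
    dxy = sum_sites [pX (1-pY) + pY (1-pX)]    / n_accessible_sites

with p the derived-allele frequency over the non-missing haplotypes at the
site (n of them).  The denominator counts all accessible sites — variant
plus invariant — so either the genotype matrix must carry invariant sites
or a per-region accessible-site count must be supplied.

D2 (three-sample direction-of-introgression test): genes are classed by
their topology weights as following the species tree or the introgression
tree; introgression from the inner taxon into the distant one lowers the
diagnostic between-species dxy at introgression-tree genes, while the
reverse direction leaves it untouched.  D2 is the difference of class means
of that dxy, tested with Welch's t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix, RegionSet
from .weights import WeightTable, aggregate_clade_support

logger = logging.getLogger("introscan")

__all__ = [
    "DivergenceTable",
    "D2Result",
    "region_pi",
    "region_dxy",
    "divergence_table",
    "d2_test",
]


def _accessible_counts(
    gm: GenotypeMatrix,
    rs: RegionSet,
    cols: list[int],
    accessible_sites: dict[str, int] | None,
) -> dict[str, int]:
    """Per-region accessible-site denominators for the given sample columns."""
    if accessible_sites is not None:
        return dict(accessible_sites)
    if not gm.includes_invariant:
        raise ValueError(
            "genotype matrix lacks invariant sites; supply accessible_sites "
            "(region_id -> site count) for correct per-site denominators"
        )
    out = {}
    for region in rs:
        idx = gm.sites_in(region.chrom, region.start, region.end)
        if len(idx) == 0:
            out[region.region_id] = 0
        else:
            ok = ~np.any(gm.dosage[np.ix_(idx, cols)] == MISSING, axis=1)
            out[region.region_id] = int(ok.sum())
    return out


def _site_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele frequency and non-missing haplotype count per site."""
    d = dosage.astype(float)
    missing = d == MISSING
    d[missing] = 0.0
    n_hap = 2.0 * (~missing).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=1) / n_hap
    return p, n_hap


def region_pi(
    gm: GenotypeMatrix,
    rs: RegionSet,
    group: str,
    accessible_sites: dict[str, int] | None = None,
) -> dict[str, float]:
    """Mean pairwise per-site diversity within ``group``, per region."""
    cols = gm.columns_of_taxon(group)
    if 2 * len(cols) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 haplotypes")
    denom = _accessible_counts(gm, rs, cols, accessible_sites)
    variant = gm.is_variant()
    out = {}
    for region in rs:
        idx = gm.sites_in(region.chrom, region.start, region.end)
        idx = idx[variant[idx]]
        n_acc = denom.get(region.region_id, 0)
        if n_acc == 0:
            out[region.region_id] = math.nan
            continue
        if len(idx) == 0:
            out[region.region_id] = 0.0
            continue
        p, n_hap = _site_stats(gm.dosage[np.ix_(idx, cols)])
        ok = n_hap >= 2
        contrib = 2.0 * p[ok] * (1.0 - p[ok]) * n_hap[ok] / (n_hap[ok] - 1.0)
        out[region.region_id] = float(contrib.sum() / n_acc)
    return out


def region_dxy(
    gm: GenotypeMatrix,
    rs: RegionSet,
    group_x: str,
    group_y: str,
    accessible_sites: dict[str, int] | None = None,
) -> dict[str, float]:
    """Mean between-group per-site divergence, per region."""
    cols_x = gm.columns_of_taxon(group_x)
    cols_y = gm.columns_of_taxon(group_y)
    if set(cols_x) & set(cols_y):
        raise ValueError("groups overlap")
    if not cols_x or not cols_y:
        raise ValueError("both groups need at least one sample")
    denom = _accessible_counts(gm, rs, cols_x + cols_y, accessible_sites)
    variant = gm.is_variant()
    out = {}
    for region in rs:
        idx = gm.sites_in(region.chrom, region.start, region.end)
        idx = idx[variant[idx]]
        n_acc = denom.get(region.region_id, 0)
        if n_acc == 0:
            out[region.region_id] = math.nan
            continue
        if len(idx) == 0:
            out[region.region_id] = 0.0
            continue
        px, nx = _site_stats(gm.dosage[np.ix_(idx, cols_x)])
        py, ny = _site_stats(gm.dosage[np.ix_(idx, cols_y)])
        ok = (nx >= 1) & (ny >= 1)
        contrib = px[ok] * (1 - py[ok]) + py[ok] * (1 - px[ok])
        out[region.region_id] = float(contrib.sum() / n_acc)
    return out


@dataclass
class DivergenceTable:
    """Per-region pi per group and dxy per group pair."""

    region_ids: list[str]
    pi: dict[str, dict[str, float]]                      # group -> region -> pi
    dxy: dict[tuple[str, str], dict[str, float]]         # pair  -> region -> dxy
    n_accessible: dict[str, int]

    def to_frame(self):
        import pandas as pd

        data = {"region_id": self.region_ids}
        data["n_accessible"] = [self.n_accessible.get(r, 0) for r in self.region_ids]
        for group, values in self.pi.items():
            data[f"pi_{group}"] = [values.get(r, math.nan) for r in self.region_ids]
        for (x, y), values in self.dxy.items():
            data[f"dxy_{x}_{y}"] = [values.get(r, math.nan) for r in self.region_ids]
        return pd.DataFrame(data)

    def summary(self) -> dict:
        """Median and IQR per statistic, over regions with defined values."""
        out = {}
        for group, values in self.pi.items():
            v = np.asarray([x for x in values.values() if not math.isnan(x)])
            if len(v):
                out[f"pi_{group}"] = {
                    "median": float(np.median(v)),
                    "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
                }
        for (x, y), values in self.dxy.items():
            v = np.asarray([w for w in values.values() if not math.isnan(w)])
            if len(v):
                out[f"dxy_{x}_{y}"] = {
                    "median": float(np.median(v)),
                    "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
                }
        return out


def divergence_table(
    gm: GenotypeMatrix,
    rs: RegionSet,
    groups: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    accessible_sites: dict[str, int] | None = None,
) -> DivergenceTable:
    """pi for every group (with >= 2 haplotypes) and dxy for every pair."""
    import itertools

    taxa = groups if groups is not None else list(gm.taxon_map.taxa)
    pi = {}
    for g in taxa:
        if 2 * len(gm.taxon_map.samples_of(g)) >= 2:
            pi[g] = region_pi(gm, rs, g, accessible_sites)
    if pairs is None:
        pairs = list(itertools.combinations(taxa, 2))
    dxy = {
        (x, y): region_dxy(gm, rs, x, y, accessible_sites) for x, y in pairs
    }
    all_cols = [c for g in taxa for c in gm.columns_of_taxon(g)]
    n_acc = _accessible_counts(gm, rs, all_cols, accessible_sites)
    return DivergenceTable(
        region_ids=[r.region_id for r in rs],
        pi=pi,
        dxy=dxy,
        n_accessible=n_acc,
    )


# ---------------------------------------------------------------------------
# D2
# ---------------------------------------------------------------------------

@dataclass
class D2Result:
    d2: float
    mean_dxy_species_tree: float
    mean_dxy_intro_tree: float
    t: float
    df: float
    p: float
    n_species_class: int
    n_intro_class: int


def d2_test(
    div: DivergenceTable,
    wt: WeightTable,
    species_clade,
    intro_clade,
    pair: tuple[str, str],
    weight_threshold: float = 1.0,
) -> D2Result:
    """Welch t-test of the diagnostic dxy between topology classes.

    A gene joins a class when its aggregate topology weight for the class's
    defining clade reaches ``weight_threshold`` (default 1.0: only genes
    whose every subtree supports the simplified topology).  D2 =
    mean(dxy | species class) - mean(dxy | introgression class); positive,
    significant D2 indicates introgression moved the inner taxon's alleles
    into the distant taxon of ``pair`` rather than the reverse.
    """
    if set(species_clade) == set(intro_clade):
        raise ValueError("species and introgression clades must differ")
    key = tuple(pair) if tuple(pair) in div.dxy else (pair[1], pair[0])
    if key not in div.dxy:
        raise ValueError(f"dxy for pair {pair} not in divergence table")
    dxy = div.dxy[key]
    support_sp = aggregate_clade_support(wt, species_clade)
    support_in = aggregate_clade_support(wt, intro_clade)
    eps = 1e-12
    species_vals, intro_vals = [], []
    for rid in wt.region_ids:
        value = dxy.get(rid, math.nan)
        if math.isnan(value):
            continue
        if support_sp.get(rid, 0.0) >= weight_threshold - eps:
            species_vals.append(value)
        elif support_in.get(rid, 0.0) >= weight_threshold - eps:
            intro_vals.append(value)
    if not species_vals or not intro_vals:
        raise ValueError(
            f"empty D2 class (species: {len(species_vals)}, intro: {len(intro_vals)})"
        )
    a = np.asarray(species_vals)
    b = np.asarray(intro_vals)
    welch = sps.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1)
    ) if (va + vb) > 0 else float(len(a) + len(b) - 2)
    logger.info("d2_test: class sizes species=%d intro=%d", len(a), len(b))
    return D2Result(
        d2=float(a.mean() - b.mean()),
        mean_dxy_species_tree=float(a.mean()),
        mean_dxy_intro_tree=float(b.mean()),
        t=float(welch.statistic),
        df=float(df),
        p=float(welch.pvalue),
        n_species_class=len(a),
        n_intro_class=len(b),
    )
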