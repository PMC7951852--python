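"""Site-pattern counting and the D-statistic family.

All statistics use frequency-weighted site patterns: with derived-allele
frequency p_i for the taxon (or diploid accession, p in {0, 0.5, 1}) filling
each role, a site contributes the product of p_i / (1 - p_i) factors for the
derived/ancestral state the pattern assigns to that role.  Sites with a
missing call in any role are excluded.

Patterson's D on roles (P1, P2, P3, O):
    ABBA += (1-p1) p2 p3 (1-pO),  BABA += p1 (1-p2) p3 (1-pO)
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)
D > 0 indicates excess derived-allele sharing between P2 and P3.

Significance is by delete-one block jackknife over contiguous genomic
blocks holding equal numbers of informative sites.

The five-taxon D_FOIL system on (((P1,P2),(P3,P4)),O) — requiring the P1/P2
split to be the more recent — is built from four pair contrasts ("FOIL":
First = P1P3, Outer = P1P4, Inner = P2P3, Last = P2P4 derived-sharing):
    D_FO: does P1 share derived alleles preferentially with P3 or P4?
    D_IL: does P2 share preferentially with P3 or P4?
    D_FI: does P3 share preferentially with P1 or P2?
    D_OL: does P4 share preferentially with P1 or P2?
Each statistic balances its two focal two-derived patterns with the
concordant three-derived and singleton patterns so that every term has a
counterpart of equal null expectation (see DFOIL_PATTERNS).  The joint sign
pattern at level alpha localises and times introgression (SIGNATURE_TABLE).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("introscan")

__all__ = [
    "PatternCounts4",
    "PatternCounts5",
    "DStatResult",
    "DfoilResult",
    "site_frequencies",
    "count_site_patterns",
    "count_site_patterns5",
    "patterson_d",
    "block_jackknife",
    "pairwise_d_scan",
    "dfoil",
    "classify_dfoil_signature",
    "DFOIL_PATTERNS",
    "SIGNATURE_TABLE",
]


# ---------------------------------------------------------------------------
# Role frequencies
# ---------------------------------------------------------------------------

def site_frequencies(gm: GenotypeMatrix, role: str) -> np.ndarray:
    """Per-site derived-allele frequency for a role (NaN where unavailable).

    ``role`` is either a sample id (single-accession mode: p = dosage/2) or
    a taxon label (frequency mode: mean dosage/2 over non-missing samples).
    """
    if role in gm.samples:
        d = gm.dosage[:, gm.sample_column(role)].astype(float)
        d[d == MISSING] = np.nan
        return d / 2.0
    if role in gm.taxon_map.taxa:
        cols = gm.columns_of_taxon(role)
        if not cols:
            raise ValueError(f"taxon {role!r} has no samples")
        d = gm.dosage[:, cols].astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=1) / 2.0
    raise ValueError(f"role {role!r} is neither a sample nor a taxon")


def _make_blocks(
    gm: GenotypeMatrix,
    informative: np.ndarray,
    n_blocks: int,
    regions=None,
) -> list[np.ndarray]:
    """Contiguous genomic blocks of near-equal informative-site count.

    ``informative`` holds the row indices of informative sites in genomic
    order.  When ``regions`` (a RegionSet) is given, sites of one region are
    never split across blocks — linked sites sharing a genealogy must stay
    in the same block or the jackknife underestimates the variance.  Without
    regions, sites within ``linkage_span`` bp (default 20 kb) of each other
    are kept together for the same reason.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(informative) == 0:
        return [informative, informative.copy()]
    # group indices into linkage units that must not straddle blocks
    if regions is not None:
        unit_of = {}
        for u, region in enumerate(regions):
            for idx in gm.sites_in(region.chrom, region.start, region.end):
                unit_of[int(idx)] = u
        units: list[list[int]] = []
        last_unit = None
        for idx in informative:
            u = unit_of.get(int(idx), ("orphan", int(idx)))
            if u != last_unit:
                units.append([])
                last_unit = u
            units[-1].append(int(idx))
    else:
        linkage_span = 20_000
        units = []
        last_chrom, last_pos = None, None
        for idx in informative:
            c, p = gm.chrom[idx], gm.pos[idx]
            if c != last_chrom or last_pos is None or p - last_pos > linkage_span:
                units.append([])
            units[-1].append(int(idx))
            last_chrom, last_pos = c, p
    if len(units) == 1 and len(informative) > 1:
        # a single linkage unit cannot be jackknifed; fall back to per-site
        # blocks (tiny fixtures / single-window data)
        logger.warning("_make_blocks: one linkage unit only; splitting by site")
        units = [[int(i)] for i in informative]
    n_blocks = min(n_blocks, max(2, len(units)))
    total = len(informative)
    blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    seen = 0
    for unit in units:
        b = min(n_blocks - 1, int(seen / total * n_blocks))
        blocks[b].extend(unit)
        seen += len(unit)
    return [np.asarray(b, dtype=int) for b in blocks]


# ---------------------------------------------------------------------------
# Four-taxon pattern counts and Patterson's D
# ---------------------------------------------------------------------------

@dataclass
class PatternCounts4:
    abba: np.ndarray          # per-block weighted counts
    baba: np.ndarray
    n_sites_used: np.ndarray  # informative sites per block
    n_sites_total: int        # sites with no missing call among the roles


def count_site_patterns(
    gm: GenotypeMatrix,
    roles: dict[str, str],
    n_blocks: int = 50,
    regions=None,
) -> PatternCounts4:
    """ABBA/BABA weighted counts per jackknife block.

    ``roles`` maps {"P1","P2","P3","O"} to sample ids or taxon labels.
    ``regions`` (RegionSet, optional) keeps each region's sites in one block.
    """
    required = {"P1", "P2", "P3", "O"}
    if set(roles) != required:
        raise ValueError(f"roles must be exactly {sorted(required)}")
    p1 = site_frequencies(gm, roles["P1"])
    p2 = site_frequencies(gm, roles["P2"])
    p3 = site_frequencies(gm, roles["P3"])
    po = site_frequencies(gm, roles["O"])
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    abba = np.where(usable, (1 - p1) * p2 * p3 * (1 - po), 0.0)
    baba = np.where(usable, p1 * (1 - p2) * p3 * (1 - po), 0.0)
    informative = np.nonzero(usable & ((abba > 0) | (baba > 0)))[0]
    blocks = _make_blocks(gm, informative, n_blocks, regions)
    return PatternCounts4(
        abba=np.asarray([abba[b].sum() for b in blocks]),
        baba=np.asarray([baba[b].sum() for b in blocks]),
        n_sites_used=np.asarray([len(b) for b in blocks]),
        n_sites_total=int(usable.sum()),
    )


def patterson_d(counts: PatternCounts4) -> float:
    """Aggregate D; NaN (UNDEFINED) when no informative sites."""
    num = counts.abba.sum() - counts.baba.sum()
    den = counts.abba.sum() + counts.baba.sum()
    if den == 0:
        logger.warning("patterson_d: zero denominator, D undefined")
        return math.nan
    return float(num / den)


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    n_sites: int
    degenerate: bool = False

    @property
    def undefined(self) -> bool:
        return math.isnan(self.d)


def block_jackknife(
    numerator: np.ndarray,
    denominator: np.ndarray,
    n_sites: np.ndarray | None = None,
    weighted: bool = False,
) -> DStatResult:
    """Delete-one block jackknife for a ratio statistic.

    Unweighted (default): SE^2 = ((g-1)/g) * sum_i (theta_(i) - mean)^2.
    Weighted (block weights m_j = site counts): the unequal-block-size
    delete-one estimator of Busing et al. (1999).
    """
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    nonempty = denominator != 0
    g = int(nonempty.sum())
    if g < 2:
        raise ValueError("block jackknife needs >= 2 non-empty blocks")
    num, den = numerator[nonempty], denominator[nonempty]
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        return DStatResult(math.nan, math.nan, math.nan, math.nan, g, 0)
    theta = total_num / total_den
    loo = (total_num - num) / (total_den - den)
    if weighted:
        if n_sites is None:
            raise ValueError("weighted jackknife requires per-block site counts")
        m = np.asarray(n_sites, dtype=float)[nonempty]
        n = m.sum()
        h = n / m
        pseudo = h * theta - (h - 1.0) * loo
        theta_jack = g * theta - ((1.0 - m / n) * loo).sum()
        var = ((pseudo - theta_jack) ** 2 / (h - 1.0)).sum() / g
    else:
        var = (g - 1) / g * ((loo - loo.mean()) ** 2).sum()
    se = math.sqrt(var)
    total_sites = int(np.asarray(n_sites)[nonempty].sum()) if n_sites is not None else 0
    if se == 0.0:
        logger.warning("block_jackknife: zero variance across blocks (degenerate)")
        return DStatResult(float(theta), 0.0, math.nan, math.nan, g, total_sites,
                           degenerate=True)
    z = float(theta / se)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DStatResult(float(theta), se, z, p, g, total_sites)


def d_statistic(counts: PatternCounts4, weighted: bool = False) -> DStatResult:
    """Patterson's D with block-jackknife SE/z/p."""
    result = block_jackknife(
        counts.abba - counts.baba,
        counts.abba + counts.baba,
        n_sites=counts.n_sites_used,
        weighted=weighted,
    )
    result.n_sites = counts.n_sites_total
    return result


def pairwise_d_scan(
    gm: GenotypeMatrix,
    taxon3: str,
    taxon2: str,
    p1_role: str,
    outgroup_role: str,
    n_blocks: int = 50,
    weighted: bool = False,
    regions=None,
):
    """One D test per (accession in taxon3) x (accession in taxon2) pair.

    taxon3 accessions fill the P3 role and taxon2 accessions the P2 role;
    P1 and O are fixed.  Returns a DataFrame sorted by |z| (descending) with
    a Benjamini-Hochberg q-value column added as a convenience.
    """
    import pandas as pd

    acc3 = gm.taxon_map.samples_of(taxon3)
    acc2 = gm.taxon_map.samples_of(taxon2)
    if not acc3 or not acc2:
        raise ValueError("both taxa need at least one accession")
    rows = []
    for a3, a2 in itertools.product(acc3, acc2):
        counts = count_site_patterns(
            gm, {"P1": p1_role, "P2": a2, "P3": a3, "O": outgroup_role},
            n_blocks, regions=regions,
        )
        res = d_statistic(counts, weighted=weighted)
        rows.append({
            "P3_accession": a3, "P2_accession": a2,
            "D": res.d, "SE": res.se, "z": res.z, "p": res.p,
            "n_blocks": res.n_blocks, "n_sites": res.n_sites,
        })
    frame = pd.DataFrame(rows)
    frame = frame.sort_values("z", key=lambda s: s.abs(), ascending=False)
    frame = frame.reset_index(drop=True)
    p = frame["p"].to_numpy()
    order = np.argsort(p)
    q = np.empty_like(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    frame["q_bh"] = np.clip(q, 0, 1)
    return frame


# ---------------------------------------------------------------------------
# D_FOIL
# ---------------------------------------------------------------------------

# Pattern strings give the derived (B) / ancestral (A) state of
# (P1, P2, P3, P4, O); the outgroup is always ancestral.  Each statistic's
# two four-pattern sets have equal expectation under the null (no
# introgression, P1/P2 split more recent than P3/P4 split).
DFOIL_PATTERNS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DFO": (("BABAA", "BBBAA", "ABABA", "AAABA"),
            ("BAABA", "BBABA", "ABBAA", "AABAA")),
    "DIL": (("ABBAA", "BBBAA", "BAABA", "AAABA"),
            ("ABABA", "BBABA", "BABAA", "AABAA")),
    "DFI": (("BABAA", "BABBA", "ABABA", "ABAAA"),
            ("ABBAA", "ABBBA", "BAABA", "BAAAA")),
    "DOL": (("BAABA", "BABBA", "ABBAA", "ABAAA"),
            ("ABABA", "ABBBA", "BABAA", "BAAAA")),
}

_ALL_PATTERNS = sorted({p for plus, minus in DFOIL_PATTERNS.values()
                        for p in plus + minus})


@dataclass
class PatternCounts5:
    counts: dict[str, np.ndarray]   # pattern -> per-block weighted counts
    n_sites_used: np.ndarray
    n_sites_total: int


def count_site_patterns5(
    gm: GenotypeMatrix,
    roles: dict[str, str],
    n_blocks: int = 50,
    regions=None,
) -> PatternCounts5:
    """Weighted counts of the D_FOIL-informative five-taxon site patterns."""
    required = {"P1", "P2", "P3", "P4", "O"}
    if set(roles) != required:
        raise ValueError(f"roles must be exactly {sorted(required)}")
    freqs = {r: site_frequencies(gm, roles[r]) for r in ("P1", "P2", "P3", "P4", "O")}
    usable = ~np.any([np.isnan(freqs[r]) for r in freqs], axis=0)
    weights = {}
    any_weight = np.zeros(gm.n_sites)
    for pattern in _ALL_PATTERNS:
        w = np.ones(gm.n_sites)
        for state, role in zip(pattern, ("P1", "P2", "P3", "P4", "O")):
            p = freqs[role]
            w = w * (p if state == "B" else (1.0 - p))
        w = np.where(usable, w, 0.0)
        weights[pattern] = np.nan_to_num(w)
        any_weight += weights[pattern]
    informative = np.nonzero(any_weight > 0)[0]
    blocks = _make_blocks(gm, informative, n_blocks, regions)
    return PatternCounts5(
        counts={
            pattern: np.asarray([w[b].sum() for b in blocks])
            for pattern, w in weights.items()
        },
        n_sites_used=np.asarray([len(b) for b in blocks]),
        n_sites_total=int(usable.sum()),
    )


@dataclass
class DfoilResult:
    components: dict[str, DStatResult]     # DFO, DIL, DFI, DOL
    signature: tuple[str, str, str, str]   # '+', '0', '-' at level alpha
    classification: str
    alpha: float

    def __getitem__(self, name: str) -> DStatResult:
        return self.components[name]


def dfoil(
    counts: PatternCounts5,
    alpha: float = 0.01,
    weighted: bool = False,
) -> DfoilResult:
    """The four D_FOIL statistics with jackknife significance and signature."""
    components = {}
    signs = []
    for name, (plus, minus) in DFOIL_PATTERNS.items():
        top = sum(counts.counts[p] for p in plus)
        bot = sum(counts.counts[p] for p in minus)
        res = block_jackknife(top - bot, top + bot,
                              n_sites=counts.n_sites_used, weighted=weighted)
        res.n_sites = counts.n_sites_total
        components[name] = res
        if res.undefined or res.degenerate or math.isnan(res.p) or res.p >= alpha:
            signs.append("0")
        else:
            signs.append("+" if res.d > 0 else "-")
    signature = tuple(signs)
    return DfoilResult(
        components=components,
        signature=signature,
        classification=classify_dfoil_signature(signature),
        alpha=alpha,
    )


# Sign pattern (DFO, DIL, DFI, DOL) -> introgression event, for the fixed
# taxon arrangement (((P1, P2), (P3, P4)), O) with the P1/P2 split the more
# recent.  Ancestral events (older than the P1/P2 split) affect P1 and P2
# equally, zeroing the DFI/DOL contrasts and erasing the direction; terminal
# events leave a directional three-component signature.  Rows derived from
# coalescent expectations and verified against an independent coalescent
# simulator (msprime); see the methods notes.
SIGNATURE_TABLE: dict[tuple[str, str, str, str], tuple[str, str | None]] = {
    ("0", "0", "0", "0"): ("none", None),
    ("+", "+", "0", "0"): ("ancestral", "anc(P1,P2)<->P3"),
    ("-", "-", "0", "0"): ("ancestral", "anc(P1,P2)<->P4"),
    ("+", "0", "+", "+"): ("P1<->P3", "P3=>P1"),
    ("+", "+", "+", "0"): ("P1<->P3", "P1=>P3"),
    ("0", "+", "-", "-"): ("P2<->P3", "P3=>P2"),
    ("+", "+", "-", "0"): ("P2<->P3", "P2=>P3"),
    ("-", "0", "+", "+"): ("P1<->P4", "P4=>P1"),
    ("-", "-", "0", "+"): ("P1<->P4", "P1=>P4"),
    ("0", "-", "-", "-"): ("P2<->P4", "P4=>P2"),
    ("-", "-", "0", "-"): ("P2<->P4", "P2=>P4"),
}


def classify_dfoil_signature(
    signature: tuple[str, str, str, str], alpha: float | None = None
) -> str:
    """Map a sign 4-vector to an introgression label (unknown -> ambiguous)."""
    return SIGNATURE_TABLE.get(tuple(signature), ("ambiguous", None))[0]


def dfoil_direction(signature: tuple[str, str, str, str]) -> str | None:
    """Directional reading of a terminal/ancestral signature, when defined."""
    return SIGNATURE_TABLE.get(tuple(signature), ("ambiguous", None))[1]
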