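"""Multispecies network coalescent simulator with introgression.

Each genomic region ("gene") is one non-recombining locus: lineages sampled
from the tips of a dated species tree coalesce within branches at rate
1/(2Ne) per pair per generation; at an introgression event (donor ->
recipient forward in time, admixture proportion gamma), each lineage sitting
in the recipient branch independently reroutes to the donor branch with
probability gamma when tracing backwards through the event.  Mutations are
laid down under the infinite-sites model at rate mu per site per generation.

The chromosome layout assigns every region to a 1-Mbp recombination-rate
bin; an optional monotone coupling function lets the effective gamma of a
region grow with its local recombination rate, emulating introgressed
ancestry surviving preferentially in freely recombining regions.
"""

from __future__ import annotations

import logging
import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import (
    GenotypeMatrix,
    LinkageMap,
    Marker,
    Region,
    RegionSet,
    TaxonMap,
)
from .trees import Node, parse_newick

logger = logging.getLogger("introscan")

__all__ = [
    "ChromosomeLayout",
    "IntrogressionEvent",
    "SimScenario",
    "SimTruth",
    "species_tree_from_newick",
    "simulate_gene_trees",
    "simulate_genotypes",
    "simulate_linkage_map",
    "preset_scenario",
    "PRESETS",
    "haplotype_subtree",
]


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntrogressionEvent:
    donor: str          # branch (taxon or named ancestor) forward-time donor
    recipient: str      # branch receiving alleles forward in time
    time: float         # generations before present
    gamma: float        # admixture proportion in [0, 1]

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.time < 0:
            raise ValueError("event time must be nonnegative")


@dataclass(frozen=True)
class ChromosomeLayout:
    name: str
    length_bp: int
    rates: tuple[float, ...]    # cM/Mbp per consecutive bin
    bin_size: int = 1_000_000

    def __post_init__(self):
        if any(r < 0 for r in self.rates):
            raise ValueError("recombination rates must be nonnegative")
        if len(self.rates) * self.bin_size < self.length_bp:
            raise ValueError(f"{self.name}: rate bins do not cover the chromosome")

    def rate_at(self, bp: float) -> float:
        return self.rates[min(int(bp // self.bin_size), len(self.rates) - 1)]

    def genetic_position(self, bp: float) -> float:
        """Cumulative map position (cM) = integral of the bin rates."""
        full = int(bp // self.bin_size)
        cm = sum(self.rates[:full]) * (self.bin_size / 1e6)
        cm += self.rates[min(full, len(self.rates) - 1)] * ((bp - full * self.bin_size) / 1e6)
        return cm


@dataclass
class _Branch:
    """One branch (population) of the species tree, as a time interval."""

    name: str
    ne: float
    t_start: float                # time of the node at the branch's base
    t_end: float                  # time it merges into its parent (inf at root)
    parent: str | None
    children: tuple[str, ...] = ()


@dataclass
class SimScenario:
    species_tree: Node                       # dated: tip times 0, node times set
    samples_per_taxon: dict[str, int]
    ne: dict[str, float] | float = 10_000.0  # per-branch or global diploid Ne
    mutation_rate: float = 1e-8              # per site per generation
    sites_per_region: int = 300
    n_regions: int = 1000
    introgression_events: list[IntrogressionEvent] = field(default_factory=list)
    chromosome_layout: list[ChromosomeLayout] = field(default_factory=list)
    introgression_rate_coupling: Callable[[float], float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.branches = _index_branches(self.species_tree, self.ne)
        tips = set(self.species_tree.leaf_labels())
        unknown = set(self.samples_per_taxon) - tips
        if unknown:
            raise ValueError(f"samples requested for unknown taxa: {sorted(unknown)}")
        for ev in self.introgression_events:
            for role, branch in (("donor", ev.donor), ("recipient", ev.recipient)):
                if branch not in self.branches:
                    raise ValueError(f"introgression {role} {branch!r} is not a branch")
                b = self.branches[branch]
                if not (b.t_start <= ev.time < b.t_end):
                    raise ValueError(
                        f"event time {ev.time} outside the lifetime "
                        f"[{b.t_start}, {b.t_end}) of branch {branch!r}"
                    )
        if not self.chromosome_layout:
            # Single uniform chromosome large enough for all regions.
            span = max(2_000_000, self.n_regions * self.sites_per_region * 3)
            nbins = math.ceil(span / 1_000_000)
            self.chromosome_layout = [
                ChromosomeLayout("chr1", span, tuple([1.0] * nbins))
            ]

    @property
    def taxon_map(self) -> TaxonMap:
        entries = {}
        for taxon, k in self.samples_per_taxon.items():
            for i in range(k):
                entries[f"{taxon}_{i}"] = taxon
        return TaxonMap(entries)


def _index_branches(tree: Node, ne) -> dict[str, _Branch]:
    """Flatten a dated species tree into named branches."""
    branches: dict[str, _Branch] = {}
    counter = [0]

    def walk(node: Node, parent_name: str | None, parent_time: float) -> str:
        if node.label is None and node.children:
            counter[0] += 1
            node.label = f"anc{counter[0]}"
        name = node.label
        child_names = tuple(
            walk(c, name, node.time) for c in node.children
        )
        if isinstance(ne, dict):
            branch_ne = ne.get(name, ne.get("default"))
            if branch_ne is None:
                raise ValueError(f"no Ne for branch {name!r} and no 'default'")
        else:
            branch_ne = float(ne)
        branches[name] = _Branch(
            name=name,
            ne=branch_ne,
            t_start=node.time,
            t_end=parent_time,
            parent=parent_name,
            children=child_names,
        )
        return name

    walk(tree, None, math.inf)
    return branches


def species_tree_from_newick(newick: str) -> Node:
    """Dated species tree from Newick with branch lengths in generations.

    Tips are placed at time 0; internal node times are reconstructed from
    the (ultrametric) branch lengths.
    """
    tree = parse_newick(newick)

    def set_times(node: Node) -> float:
        if node.is_leaf:
            node.time = 0.0
            return 0.0
        child_heights = [set_times(c) + (c.length or 0.0) for c in node.children]
        if max(child_heights) - min(child_heights) > 1e-6 * max(child_heights or [1]):
            raise ValueError("species tree must be ultrametric in generations")
        node.time = max(child_heights)
        return node.time

    set_times(tree)
    return tree


# ---------------------------------------------------------------------------
# Region layout
# ---------------------------------------------------------------------------

def plan_regions(sc: SimScenario) -> tuple[RegionSet, np.ndarray]:
    """Place regions evenly along the chromosomes; return their bin rates."""
    total_bp = sum(c.length_bp for c in sc.chromosome_layout)
    counts = []
    remaining = sc.n_regions
    for i, chrom in enumerate(sc.chromosome_layout):
        if i == len(sc.chromosome_layout) - 1:
            counts.append(remaining)
        else:
            k = round(sc.n_regions * chrom.length_bp / total_bp)
            k = min(k, remaining)
            counts.append(k)
            remaining -= k
    regions, rates = [], []
    ndigits = max(4, len(str(sc.n_regions)))
    idx = 0
    for chrom, k in zip(sc.chromosome_layout, counts):
        if k == 0:
            continue
        spacing = chrom.length_bp / k
        if spacing < sc.sites_per_region:
            raise ValueError(f"{chrom.name}: too many regions to place without overlap")
        for j in range(k):
            start = int(j * spacing + (spacing - sc.sites_per_region) / 2)
            regions.append(
                Region(f"g{idx:0{ndigits}d}", chrom.name, start, start + sc.sites_per_region)
            )
            rates.append(chrom.rate_at(start + sc.sites_per_region / 2))
            idx += 1
    return RegionSet(regions), np.asarray(rates, dtype=float)


def effective_gamma(sc: SimScenario, base_gamma: float, rate: float) -> float:
    if sc.introgression_rate_coupling is None:
        return base_gamma
    return float(min(1.0, max(0.0, base_gamma * sc.introgression_rate_coupling(rate))))


# ---------------------------------------------------------------------------
# Gene-tree simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Per-region ground truth emitted alongside the simulated data."""

    region_ids: list[str]
    introgressed: np.ndarray       # bool: any lineage rerouted at any event
    n_rerouted: np.ndarray         # int: lineages that switched
    gamma_eff: np.ndarray          # effective gamma used for the region
    recomb_rate: np.ndarray        # cM/Mbp of the region's bin


def _coalesce_within(
    lineages: list[Node], ne: float, t0: float, t1: float, rng: random.Random
) -> float:
    """Coalesce ``lineages`` (in place) between t0 and t1; return current time."""
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * ne)
        t_next = t + rng.expovariate(rate)
        if t_next >= t1:
            return t1
        i, j = rng.sample(range(k), 2)
        if i > j:
            i, j = j, i
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(Node(time=t_next, children=[a, b]))
        t = t_next
    return t1


def _simulate_one_tree(
    sc: SimScenario, gamma_by_event: Sequence[float], rng: random.Random
) -> tuple[Node, int]:
    """One locus genealogy over 2 haplotypes per diploid; returns (tree, n_rerouted)."""
    pops: dict[str, list[Node]] = {name: [] for name in sc.branches}
    for taxon, k in sc.samples_per_taxon.items():
        for i in range(k):
            for hap in ("a", "b"):
                pops[taxon].append(Node(label=f"{taxon}_{i}_{hap}", time=0.0))

    speciations = sorted(
        (b.t_start, name) for name, b in sc.branches.items() if b.children
    )
    events: list[tuple[float, int, object]] = [
        (t, 0, name) for t, name in speciations
    ]
    events += [
        (ev.time, 1, (ev, gamma_by_event[i]))
        for i, ev in enumerate(sc.introgression_events)
    ]
    events.sort(key=lambda e: (e[0], e[1]))

    t = 0.0
    n_rerouted = 0
    for when, kind, payload in events:
        for name, lineages in pops.items():
            if len(lineages) >= 2:
                branch = sc.branches[name]
                _coalesce_within(lineages, branch.ne, max(t, branch.t_start), when, rng)
        if kind == 0:
            name = payload
            merged = []
            for child in sc.branches[name].children:
                merged.extend(pops.pop(child))
            pops[name].extend(merged)
        else:
            ev, gamma = payload
            if gamma > 0 and pops.get(ev.recipient):
                stay, move = [], []
                for lineage in pops[ev.recipient]:
                    (move if rng.random() < gamma else stay).append(lineage)
                pops[ev.recipient] = stay
                pops[ev.donor].extend(move)
                n_rerouted += len(move)
        t = when

    root_name = speciations[-1][1] if speciations else next(iter(pops))
    lineages = pops[root_name]
    branch = sc.branches[root_name]
    t = max(t, branch.t_start)
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * branch.ne)
        t += rng.expovariate(rate)
        i, j = rng.sample(range(k), 2)
        if i > j:
            i, j = j, i
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(Node(time=t, children=[a, b]))
    root = lineages[0]
    for node in root.postorder():
        for child in node.children:
            child.length = node.time - child.time
    root.length = None
    return root, n_rerouted


def simulate_gene_trees(
    sc: SimScenario, n_loci: int | None = None, seed: int | None = None
) -> tuple[list[Node], SimTruth]:
    """Simulate per-region genealogies (2 haplotypes per diploid sample)."""
    if n_loci is not None and n_loci != sc.n_regions:
        sc = replace(sc, n_regions=n_loci)
    seed = sc.seed if seed is None else seed
    rng = random.Random(f"{seed}:genetrees")
    regions, rates = plan_regions(sc)
    trees = []
    introgressed = np.zeros(len(regions), dtype=bool)
    n_rerouted = np.zeros(len(regions), dtype=int)
    gamma_eff = np.zeros(len(regions), dtype=float)
    for i in range(len(regions)):
        gammas = [effective_gamma(sc, ev.gamma, rates[i]) for ev in sc.introgression_events]
        gamma_eff[i] = max(gammas) if gammas else 0.0
        tree, moved = _simulate_one_tree(sc, gammas, rng)
        trees.append(tree)
        introgressed[i] = moved > 0
        n_rerouted[i] = moved
    truth = SimTruth(
        region_ids=[r.region_id for r in regions],
        introgressed=introgressed,
        n_rerouted=n_rerouted,
        gamma_eff=gamma_eff,
        recomb_rate=rates,
    )
    return trees, truth


def haplotype_subtree(tree: Node, keep_suffix: str = "_a") -> Node:
    """Restrict a haplotype genealogy to one haplotype per diploid.

    Tip ``{sample}_a`` is kept and renamed to ``{sample}``, matching the
    one-haplotype-per-accession gene trees used for topology weighting.
    """

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label.endswith(keep_suffix):
                return Node(
                    label=node.label[: -len(keep_suffix)],
                    length=node.length,
                    time=node.time,
                )
            return None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            return child
        return Node(label=node.label, length=node.length, time=node.time, children=kept)

    out = prune(tree)
    if out is None:
        raise ValueError(f"no tips with suffix {keep_suffix!r}")
    out.length = None
    return out


# ---------------------------------------------------------------------------
# Mutation layer -> genotypes
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_genotypes(
    trees: Sequence[Node],
    sc: SimScenario,
    seed: int | None = None,
    emit_invariant: bool = False,
) -> tuple[GenotypeMatrix, RegionSet]:
    """Drop infinite-sites mutations on each genealogy and build dosages."""
    seed = sc.seed if seed is None else seed
    rng = random.Random(f"{seed}:mutations")
    regions, _ = plan_regions(replace(sc, n_regions=len(trees)))
    taxon_map = sc.taxon_map
    samples = list(taxon_map.entries)
    sample_index = {s: i for i, s in enumerate(samples)}

    chrom_l, pos_l, ref_l, alt_l, dos_l, hap_l = [], [], [], [], [], []
    for tree, region in zip(trees, regions):
        edges, cum, total = [], [], 0.0
        for node in tree.postorder():
            if node.length:
                total += node.length
                edges.append(node)
                cum.append(total)
        n_sites = region.end - region.start
        n_mut = _poisson(sc.mutation_rate * n_sites * total, rng) if total > 0 else 0
        if n_mut > n_sites:
            logger.warning(
                "%s: %d mutations for %d sites; extra collisions dropped",
                region.region_id, n_mut, n_sites,
            )
            n_mut = n_sites
        positions = rng.sample(range(n_sites), n_mut)
        site_rows = []
        for offset in positions:
            u = rng.random() * total
            node = edges[bisect_right(cum, u)] if u < total else edges[-1]
            carriers = set(node.leaf_labels())
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            site_rows.append((offset, ref, alt, carriers))
        site_rows.sort(key=lambda r: r[0])
        mutated = {r[0] for r in site_rows}
        if emit_invariant:
            all_rows = []
            it = iter(site_rows)
            nxt = next(it, None)
            for offset in range(n_sites):
                if nxt is not None and nxt[0] == offset:
                    all_rows.append(nxt)
                    nxt = next(it, None)
                else:
                    all_rows.append((offset, rng.choice(_BASES), ".", set()))
            site_rows = all_rows
        for offset, ref, alt, carriers in site_rows:
            dosage = np.zeros(len(samples), dtype=np.int8)
            haps = np.zeros((len(samples), 2), dtype=np.int8)
            for hap_label in carriers:
                sample, hap = hap_label.rsplit("_", 1)
                j = sample_index[sample]
                haps[j, 0 if hap == "a" else 1] = 1
            dosage = haps.sum(axis=1).astype(np.int8)
            chrom_l.append(region.chrom)
            pos_l.append(region.start + offset)
            ref_l.append(ref)
            alt_l.append(alt)
            dos_l.append(dosage)
            hap_l.append(haps)

    S = len(pos_l)
    gm = GenotypeMatrix(
        chrom=np.asarray(chrom_l, dtype=object),
        pos=np.asarray(pos_l, dtype=np.int64),
        ref=np.asarray(ref_l, dtype=object),
        alt=np.asarray(alt_l, dtype=object),
        dosage=(np.vstack(dos_l) if S else np.empty((0, len(samples)), dtype=np.int8)),
        samples=samples,
        taxon_map=taxon_map,
        includes_invariant=emit_invariant,
        haplotypes=(np.stack(hap_l) if S else None),
    )
    return gm, regions


def _poisson(lam: float, rng: random.Random) -> int:
    """Poisson deviate via inversion (small lambda) or normal tail split."""
    if lam <= 0:
        return 0
    if lam < 30:
        L = math.exp(-lam)
        k, p = 0, 1.0
        while True:
            p *= rng.random()
            if p <= L:
                return k
            k += 1
    # split recursively to keep inversion accurate
    half = int(lam // 2)
    return _poisson(lam - half, rng) + _poisson(float(half), rng)


# ---------------------------------------------------------------------------
# Linkage map simulation
# ---------------------------------------------------------------------------

def simulate_linkage_map(
    sc: SimScenario, seed: int | None = None, markers_per_mbp: float = 10.0
) -> LinkageMap:
    """Uniformly placed markers; cM = cumulative integral of the bin rates."""
    seed = sc.seed if seed is None else seed
    rng = random.Random(f"{seed}:linkagemap")
    markers = []
    for chrom in sc.chromosome_layout:
        n = max(2, int(round(chrom.length_bp / 1e6 * markers_per_mbp)))
        positions = sorted(rng.sample(range(chrom.length_bp), n))
        for i, bp in enumerate(positions):
            markers.append(
                Marker(f"{chrom.name}_m{i:04d}", chrom.name, bp, chrom.genetic_position(bp))
            )
    return LinkageMap(markers)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------
#
# A five-taxon radiation patterned on a monkeyflower-like history: a recent
# sister pair (lew_N, lew_S), a hummingbird-pollinated pair (card, verb)
# splitting earlier, both joining at the base of the radiation with a short
# internal branch (1 coalescent unit => substantial ILS), and a distant
# outgroup (bic).  Times in generations, Ne = 5e4 diploids throughout:
#   lew_N/lew_S split   100k   (1.0 coalescent units)
#   card/verb split     300k   (3.0)
#   radiation base      400k   (internal branches: lew_anc 3.0, cv_anc 1.0)
#   outgroup            1.0M
# mu = 2.5e-8 per site per generation gives theta = 4*Ne*mu = 0.005/site and
# ingroup-outgroup divergence ~0.05/site, in the range typical of wildflower
# nuclear genes.  Chromosome ends recombine freely (~6 cM/Mbp) while broad
# centromeric centres are nearly recombination-free, as in many plant maps.

_NE = 50_000.0
_SPECIES_NEWICK = (
    "(((lew_N:100000,lew_S:100000)lew_anc:300000,"
    "(card:300000,verb:300000)cv_anc:100000)ingroup_anc:600000,bic:1000000)root;"
)
_SAMPLES = {"lew_N": 2, "lew_S": 2, "card": 3, "verb": 2, "bic": 1}


def _u_shaped_rates(n_bins: int, low: float = 0.1, high: float = 6.0) -> tuple[float, ...]:
    mid = (n_bins - 1) / 2.0
    return tuple(
        low + (high - low) * (abs(i - mid) / mid) ** 3 for i in range(n_bins)
    )


def _default_layout() -> list[ChromosomeLayout]:
    return [
        ChromosomeLayout(f"chr{i + 1}", 20_000_000, _u_shaped_rates(20))
        for i in range(4)
    ]


def _coupling(rate: float) -> float:
    """Monotone multiplier on gamma: ~0 in cold bins, ->1 in hot bins."""
    return rate / (rate + 2.0)


def _base_scenario(**overrides) -> SimScenario:
    params = dict(
        species_tree=species_tree_from_newick(_SPECIES_NEWICK),
        samples_per_taxon=dict(_SAMPLES),
        ne=_NE,
        mutation_rate=2.5e-8,
        sites_per_region=300,
        n_regions=1000,
        chromosome_layout=_default_layout(),
        seed=0,
    )
    params.update(overrides)
    return SimScenario(**params)


def preset_scenario(name: str, **overrides) -> SimScenario:
    """Named study scenarios; ``overrides`` replace any SimScenario field."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](**overrides)


def _preset_ils_only(**overrides) -> SimScenario:
    return _base_scenario(introgression_events=[], **overrides)


def _preset_ancestral_lew_into_card(**overrides) -> SimScenario:
    # Ancestral lewisii donates into cardinalis while both branches coexist
    # (after the lew_N/lew_S split, before the card/verb split).
    return _base_scenario(
        introgression_events=[
            IntrogressionEvent(donor="lew_anc", recipient="card", time=200_000, gamma=0.3)
        ],
        **overrides,
    )


def _preset_direction_card_into_lew(**overrides) -> SimScenario:
    # The reversed direction of the ancestral event: cardinalis donates into
    # the ancestral lewisii branch at the same time and proportion.
    return _base_scenario(
        introgression_events=[
            IntrogressionEvent(donor="card", recipient="lew_anc", time=200_000, gamma=0.3)
        ],
        **overrides,
    )


def _preset_recent_sierran(**overrides) -> SimScenario:
    # Recent, post-speciation gene flow between the sympatric pair.
    return _base_scenario(
        introgression_events=[
            IntrogressionEvent(donor="card", recipient="lew_S", time=20_000, gamma=0.2)
        ],
        **overrides,
    )


def _preset_recomb_coupled(**overrides) -> SimScenario:
    # Ancestral introgression whose surviving proportion grows with the
    # local recombination rate.
    return _base_scenario(
        introgression_events=[
            IntrogressionEvent(donor="lew_anc", recipient="card", time=200_000, gamma=0.6)
        ],
        introgression_rate_coupling=_coupling,
        **overrides,
    )


PRESETS: dict[str, Callable[..., SimScenario]] = {
    "ils_only": _preset_ils_only,
    "ancestral_lew_into_card": _preset_ancestral_lew_into_card,
    "direction_card_into_lew": _preset_direction_card_into_lew,
    "recent_sierran": _preset_recent_sierran,
    "recomb_coupled": _preset_recomb_coupled,
}
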