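"""Gene-tree topology weighting and genome-scale summaries.

For a gene tree whose tips belong to groups (species), the weight of a
rooted species topology is the fraction of one-tip-per-group subtrees of the
gene tree whose induced rooted topology matches it.  With G groups of sizes
|g_1|..|g_G| there are prod |g_i| such subtrees; they are enumerated
exhaustively when that product is small and sampled uniformly otherwise.

The induced rooted topology of a tip combination is computed without
rebuilding trees: pairwise MRCAs are precomputed per gene tree, and clusters
are merged in order of decreasing MRCA depth (deepest common ancestor first),
which reconstructs the restriction of the rooted tree to the chosen tips.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

import numpy as np

from .io import RegionSet, TaxonMap
from .trees import Node, TopologyCatalog, canonical_nested, resolve_polytomies

logger = logging.getLogger("introscan")

__all__ = [
    "WeightTable",
    "QuartetSupport",
    "weight_gene_tree",
    "weight_gene_trees",
    "aggregate_clade_support",
    "window_average_weights",
    "quartet_concordance",
    "genome_weight_summary",
    "EXHAUSTIVE_LIMIT",
]

EXHAUSTIVE_LIMIT = 10_000   # max one-tip-per-group combinations enumerated
DEFAULT_N_ITER = 10_000     # sampled-mode draws


# ---------------------------------------------------------------------------
# Per-tree machinery
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Tip ancestor paths and pair-MRCA depths for one gene tree."""

    def __init__(self, tree: Node, tips: list[str]):
        parent: dict[int, Node] = {}
        depth: dict[int, int] = {id(tree): 0}
        tip_node: dict[str, Node] = {}
        stack = [tree]
        while stack:
            node = stack.pop()
            for child in node.children:
                parent[id(child)] = node
                depth[id(child)] = depth[id(node)] + 1
                stack.append(child)
            if node.is_leaf:
                tip_node[node.label] = node
        missing = [t for t in tips if t not in tip_node]
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        # ancestor sets (node id -> depth) per tip of interest
        self._path: dict[str, dict[int, int]] = {}
        for t in tips:
            path: dict[int, int] = {}
            node = tip_node[t]
            while node is not None:
                path[id(node)] = depth[id(node)]
                node = parent.get(id(node))
            self._path[t] = path
        self._pair_cache: dict[tuple[str, str], tuple[int, int]] = {}

    def mrca(self, a: str, b: str) -> tuple[int, int]:
        """(node id, depth) of the MRCA of tips a and b."""
        key = (a, b) if a < b else (b, a)
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        pa, pb = self._path[a], self._path[b]
        best = (-1, -1)
        if len(pa) > len(pb):
            pa, pb = pb, pa
        for node_id, d in pa.items():
            if node_id in pb and d > best[1]:
                best = (node_id, d)
        self._pair_cache[key] = best
        return best

    def induced_form(self, combo: tuple[str, ...], labels: tuple[str, ...]) -> str:
        """Canonical form of the rooted topology induced by one tip per group."""
        clusters = [(labels[i], combo[i]) for i in range(len(combo))]
        while len(clusters) > 1:
            best_depth, best_pair = -1, None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    _, d = self.mrca(clusters[i][1], clusters[j][1])
                    if d > best_depth:
                        best_depth, best_pair = d, (i, j)
            i, j = best_pair
            name_j, _ = clusters.pop(j)
            name_i, rep = clusters.pop(i)
            merged = f"({name_i},{name_j})" if name_i < name_j else f"({name_j},{name_i})"
            clusters.append((merged, rep))
        return clusters[0][0]


def _groups_in_tree(tree: Node, groups: TaxonMap) -> dict[str, list[str]]:
    tips = set(tree.leaf_labels())
    out: dict[str, list[str]] = {g: [] for g in groups.taxa}
    for tip in tips:
        taxon = groups.entries.get(tip)
        if taxon is not None:
            out[taxon].append(tip)
    empty = [g for g, members in out.items() if not members]
    if empty:
        raise ValueError(f"groups with no tips in tree: {empty}")
    return {g: sorted(m) for g, m in out.items()}


def weight_gene_tree(
    tree: Node,
    groups: TaxonMap,
    catalog: TopologyCatalog,
    mode: str = "auto",
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
    resolve_polytomy_seed: int | None = None,
) -> tuple[np.ndarray, int]:
    """Weight vector over ``catalog`` plus the combination count.

    ``mode``: "exhaustive", "sampled", or "auto" (exhaustive iff the number
    of combinations is at most :data:`EXHAUSTIVE_LIMIT`).
    """
    if not tree.is_binary():
        if resolve_polytomy_seed is None:
            raise ValueError(
                "gene tree has polytomies; pass resolve_polytomy_seed to "
                "resolve uniformly at random"
            )
        tree = resolve_polytomies(tree, random.Random(resolve_polytomy_seed))
    members = _groups_in_tree(tree, groups)
    labels = tuple(sorted(members))
    if tuple(sorted(catalog.taxa)) != labels:
        raise ValueError("catalog taxa do not match the groups present in the tree")
    sizes = [len(members[g]) for g in labels]
    n_combos = int(np.prod(sizes))
    if mode == "auto":
        mode = "exhaustive" if n_combos <= EXHAUSTIVE_LIMIT else "sampled"
    all_tips = [t for g in labels for t in members[g]]
    index = _TreeIndex(tree, all_tips)

    counts = np.zeros(len(catalog), dtype=float)
    if mode == "exhaustive":
        for combo in itertools.product(*(members[g] for g in labels)):
            form = index.induced_form(combo, labels)
            counts[catalog.index_of(form)] += 1
        total = n_combos
    elif mode == "sampled":
        rng = random.Random(seed)
        for _ in range(n_iter):
            combo = tuple(rng.choice(members[g]) for g in labels)
            form = index.induced_form(combo, labels)
            counts[catalog.index_of(form)] += 1
        total = n_iter
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts / total, n_combos


# ---------------------------------------------------------------------------
# WeightTable
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Per-region topology weight vectors (rows sum to 1)."""

    region_ids: list[str]
    weights: np.ndarray                # (R, K)
    catalog: TopologyCatalog
    method: str = "exhaustive"
    n_iterations: int | None = None
    seed: int | None = None
    n_combos: np.ndarray | None = None  # combinations available per region

    def __post_init__(self):
        if self.weights.shape != (len(self.region_ids), len(self.catalog)):
            raise ValueError("weight matrix shape does not match regions x catalog")
        sums = self.weights.sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("weight rows must sum to 1")

    def to_tsv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.weights, columns=list(self.catalog.forms))
        frame.insert(0, "region_id", self.region_ids)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, catalog: TopologyCatalog) -> "WeightTable":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        weights = frame[list(catalog.forms)].to_numpy(dtype=float)
        return cls(list(frame["region_id"]), weights, catalog)


def weight_gene_trees(
    trees: list[Node],
    region_ids: list[str],
    groups: TaxonMap,
    catalog: TopologyCatalog,
    mode: str = "auto",
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
) -> WeightTable:
    rows, combos = [], []
    for i, tree in enumerate(trees):
        tree_seed = None if seed is None else seed + i
        w, n_combos = weight_gene_tree(
            tree, groups, catalog, mode=mode, n_iter=n_iter, seed=tree_seed
        )
        rows.append(w)
        combos.append(n_combos)
    return WeightTable(
        region_ids=list(region_ids),
        weights=np.vstack(rows) if rows else np.empty((0, len(catalog))),
        catalog=catalog,
        method=mode,
        n_iterations=(n_iter if mode == "sampled" else None),
        seed=seed,
        n_combos=np.asarray(combos),
    )


# ---------------------------------------------------------------------------
# Aggregation and smoothing
# ---------------------------------------------------------------------------

def aggregate_clade_support(wt: WeightTable, clade) -> dict[str, float]:
    """Per region, total weight of topologies holding ``clade`` monophyletic."""
    mask = np.asarray(wt.catalog.clade_mask(list(clade)), dtype=float)
    support = wt.weights @ mask
    return dict(zip(wt.region_ids, support))


@dataclass
class SmoothedWeights:
    chrom: list[str]
    midpoint: np.ndarray
    weights: np.ndarray
    catalog: TopologyCatalog
    window: int

    def clade_support(self, clade) -> np.ndarray:
        mask = np.asarray(self.catalog.clade_mask(list(clade)), dtype=float)
        return self.weights @ mask


def window_average_weights(
    wt: WeightTable, rs: RegionSet, window: int = 5
) -> SmoothedWeights:
    """Sliding stride-1 windows of ``window`` genes along each chromosome.

    Window midpoint = median of the member regions' midpoints.  Chromosomes
    with fewer than ``window`` regions contribute one whole-chromosome
    window (logged).
    """
    row_of = {rid: i for i, rid in enumerate(wt.region_ids)}
    chroms, mids, rows = [], [], []
    for chrom, regions in rs.by_chromosome().items():
        regions = [r for r in regions if r.region_id in row_of]
        if not regions:
            continue
        if len(regions) < window:
            logger.info(
                "window_average_weights: %s has %d < %d genes; single window",
                chrom, len(regions), window,
            )
            spans = [regions]
        else:
            spans = [regions[i:i + window] for i in range(len(regions) - window + 1)]
        for span in spans:
            idx = [row_of[r.region_id] for r in span]
            chroms.append(chrom)
            mids.append(float(np.median([r.midpoint for r in span])))
            rows.append(wt.weights[idx].mean(axis=0))
    return SmoothedWeights(
        chrom=chroms,
        midpoint=np.asarray(mids),
        weights=np.vstack(rows) if rows else np.empty((0, len(wt.catalog))),
        catalog=wt.catalog,
        window=window,
    )


def genome_weight_summary(wt: WeightTable) -> dict[str, np.ndarray]:
    """Genome-wide topology support, two aggregations.

    ``pooled``: combination-count-weighted mean of per-tree weights (the
    fraction of all subtrees genome-wide matching each topology);
    ``per_tree_mean``: unweighted mean of the per-tree weight vectors.
    """
    if wt.n_combos is None:
        pooled = wt.weights.mean(axis=0)
    else:
        w = wt.n_combos.astype(float)
        pooled = (wt.weights * w[:, None]).sum(axis=0) / w.sum()
    return {"pooled": pooled, "per_tree_mean": wt.weights.mean(axis=0)}


# ---------------------------------------------------------------------------
# Quartet concordance
# ---------------------------------------------------------------------------

@dataclass
class QuartetSupport:
    branch: tuple[frozenset, frozenset]
    q: float
    n_trees_used: int


def quartet_concordance(
    gene_trees: list[Node],
    groups: TaxonMap,
    branch_quartet: tuple,
) -> QuartetSupport:
    """Mean per-tree weight of the unrooted quartet ``{g1,g2} | {g3,g4}``.

    Each gene tree contributes the fraction of its one-tip-per-group
    subtrees (over the four named groups) whose unrooted quartet matches the
    bipartition; q is the unweighted mean over usable trees.
    """
    (g1, g2), (g3, g4) = branch_quartet
    quartet_groups = [g1, g2, g3, g4]
    scores = []
    for tree in gene_trees:
        try:
            members = _groups_in_tree(
                tree,
                TaxonMap({
                    tip: taxon
                    for tip, taxon in groups.entries.items()
                    if taxon in quartet_groups and tip in set(tree.leaf_labels())
                }),
            )
        except ValueError:
            continue
        if any(g not in members or not members[g] for g in quartet_groups):
            continue
        all_tips = [t for g in sorted(members) for t in members[g]]
        index = _TreeIndex(tree, all_tips)
        match = total = 0
        for a, b, c, d in itertools.product(
            members[g1], members[g2], members[g3], members[g4]
        ):
            # The two tips whose MRCA is deepest form one side of the quartet.
            pairs = {
                frozenset((a, b)): index.mrca(a, b)[1],
                frozenset((a, c)): index.mrca(a, c)[1],
                frozenset((a, d)): index.mrca(a, d)[1],
                frozenset((b, c)): index.mrca(b, c)[1],
                frozenset((b, d)): index.mrca(b, d)[1],
                frozenset((c, d)): index.mrca(c, d)[1],
            }
            deepest = max(pairs, key=pairs.get)
            total += 1
            if deepest in (frozenset((a, b)), frozenset((c, d))):
                match += 1
        if total:
            scores.append(match / total)
    if not scores:
        raise ValueError("no gene tree contains all four quartet groups")
    return QuartetSupport(
        branch=(frozenset((g1, g2)), frozenset((g3, g4))),
        q=float(np.mean(scores)),
        n_trees_used=len(scores),
    )
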