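# Methods

## The generative model

Every genomic region ("gene") is one non-recombining locus evolving under
the multispecies network coalescent. A dated species tree assigns each
branch a diploid effective size Ne; sampled haplotype lineages (two per
diploid accession) coalesce within branches at rate 1/(2Ne) per pair per
generation and merge into parent branches at speciation times. An
introgression event (donor, recipient, time t, proportion γ) is applied
backwards in time: every lineage present in the recipient branch at t
independently reroutes into the donor branch with probability γ. This
per-lineage Bernoulli rerouting produces both "clean" introgressed loci and
mixtures when several lineages are sampled, which is what makes partial
topology weights and diluted D2 classes appear in the synthetic data just
as they do in real data.

Mutations follow the infinite-sites model: Poisson(μ · L · total branch
length) mutations per locus, placed on branches proportionally to length at
distinct site positions, each defining the derived allele for all
descendant haplotypes. Inter-locus recombination is implicit (loci are
unlinked given their genealogies); intra-locus recombination is ignored,
matching the per-gene unit of all downstream statistics. Chromosome
layouts tile 1-Mbp bins with recombination rates; a region inherits the
rate of its bin, and an optional monotone coupling function multiplies the
effective γ of a region by a function of its bin rate, so introgressed
ancestry survives preferentially in freely recombining regions.

### Default study conditions

The bundled five-taxon scenarios (two recently split "lewisii" groups, a
"cardinalis"/"verbenaceus" pair, and a distant outgroup "bic") use, in
generations with Ne = 5×10⁴ everywhere:

| parameter | value | rationale |
|---|---|---|
| lew_N/lew_S split | 100 k (1 coalescent unit) | recent, sympatric pair |
| card/verb split | 300 k (3 units) | older sister pair |
| radiation base | 400 k (cv-ancestor branch = 1 unit) | short internal branch ⇒ substantial ILS (≈ 25% discordance at that node) |
| outgroup | 1 M | clean polarisation |
| μ | 2.5×10⁻⁸ /site/gen | θ = 4Neμ = 0.005/site and ingroup–outgroup divergence ≈ 0.05/site, typical of wildflower nuclear genes |
| region length | 300 bp | capture-target scale, ~10 SNVs/region |
| regions | 1000 (preset default) | full pipeline in seconds–minutes on one CPU |
| accessions | 2–3 diploids per ingroup taxon, 1 outgroup | small exhaustive weighting (≤ 24 subtrees/gene) |
| chromosomes | 4 × 20 Mbp, U-shaped rate profile 0.1–6 cM/Mbp | crossovers concentrated at chromosome ends, broad cold centres |

Presets: `ils_only` (no events); `ancestral_lew_into_card` (lew-ancestor →
card, t = 200 k, γ = 0.3: after the lew split, before the card/verb split);
`direction_card_into_lew` (the same event reversed); `recent_sierran`
(card → lew_S at t = 20 k, γ = 0.2: post-speciation gene flow in the
sympatric pair); `recomb_coupled` (the ancestral event with γ = 0.6 scaled
by rate/(rate+2), giving effective γ from ~0.03 in cold bins to ~0.45 at
chromosome ends).

What the generator does **not** emulate: sequencing error, missing data,
reference bias, selection (including adaptive introgression sweeps),
intra-locus recombination, and gene-tree estimation error — synthetic gene
trees are true genealogies. Passing tests therefore demonstrate that the
statistics recover the signals the coalescent model produces, not that
they are robust to estimation noise in real data.

## Topology weighting

The catalog of rooted binary topologies is enumerated by leaf insertion
(each k-taxon tree has 2k−1 insertion positions, giving each (k+1)-taxon
topology exactly once) and canonicalised by sorting children
lexicographically; catalog order is the sorted canonical form, stable
across runs. Enumeration is guarded above 8 taxa.

Exhaustive weighting iterates all one-tip-per-group combinations when
their product is ≤ 10,000, else uniform sampling with 10,000 draws (both
thresholds configurable). The induced rooted topology of a combination is
computed from precomputed pairwise-MRCA depths by greedy deepest-pair
merging, which reconstructs the restriction of the rooted gene tree; this
path is verified exactly against an independent dendropy prune-and-compare
oracle in the tests. Polytomies error by default; an explicit seed
resolves them uniformly at random once per tree. Trees are taken as rooted
as written; an optional re-root-on-outgroup helper is provided but never
applied implicitly.

Genome-wide "percent of subtrees" summaries are reported two ways —
combination-count-weighted (pooled subtree counts) and unweighted mean of
per-gene weights — because the aggregation underlying such summaries is
ambiguous; neither is asserted against external values.

## D statistics and the block jackknife

Pattern counts are frequency-weighted products of per-role derived-allele
frequencies (diploid accession: p ∈ {0, ½, 1}; taxon mode: mean over
non-missing accessions). Sites missing any role are excluded.

Jackknife blocks are contiguous runs of near-equal informative-site count
that never split a region (or, without region definitions, a 20-kb span):
sites of one locus share a genealogy, and splitting them across blocks
demonstrably underestimates the variance (type-I error ~20% instead of 5%
at desk scale). With whole-gene blocks the measured type-I rate of
|z| > 1.96 under ILS-only simulation is ~0.04. The default is the
unweighted delete-one estimator SE² = ((g−1)/g)·Σ(θ₍ᵢ₎−θ̄)²; an
unequal-block-size (Busing) weighted variant is available by flag. Zero
jackknife variance is flagged DEGENERATE rather than reported as infinite
z; zero denominators give UNDEFINED (NaN) statistics with a warning.

### D_FOIL constants

The four statistics are built symmetrically from the FOIL pair contrasts;
each uses four "plus" and four "minus" patterns (two two-derived patterns,
one three-derived, one singleton) chosen so every term has a counterpart of
equal expectation under the null. The sign→event table was derived from
coalescent branch-length expectations computed with an independent
simulator (msprime) under all ten directed events and frozen as a
documented constant: ancestral events give (±,±,0,0) with the direction
unidentifiable; terminal events give directional three-component
signatures (e.g. P3⇒P1 is (+,0,+,+) while P1⇒P3 is (+,+,+,0)). A
consequence worth noting: a single-direction terminal event zeroes exactly
one component — "all four significant" is not the terminal signature.
Unlisted sign patterns classify as `ambiguous`. Component significance
uses the same block jackknife as D (α = 0.01 for sign thresholding).

## Diversity, divergence, D2

π and d_XY come from per-site allele counts with the small-sample factor
n/(n−1) for π; both equal naive all-pairs haplotype enumeration exactly
(tested). Denominators count accessible sites (variant + invariant): the
genotype matrix must either carry invariant sites or be accompanied by a
per-region accessible-site count (the simulator's regions have no missing
data, so region length is exact). Regions with zero accessible sites are
UNDEFINED and excluded from medians; summaries report median and IQR,
unweighted by gene length.

D2 classes require aggregate clade support ≥ 1.0 by default ("full
weighting"; configurable, class sizes logged). The class interface takes
the defining clades of the two simplified topologies (e.g. {card, verb} vs
{card, lew_N, lew_S}); the CLI accepts topology strings and extracts the
clades. Significance is Welch's t (two-sided, Welch–Satterthwaite df).
Note a conditioning subtlety verified in simulation: genes entering the
introgression class through ILS alone coalesce deeper than average, so the
reverse-direction scenario can show a slightly *negative* D2; the direction
call is therefore "significant positive D2", one-sided by construction.
Statistical power follows the introgression-class size; the direction test
is sized at ~500 introgression-class genes (≈ 2000 regions at γ = 0.3 with
one accession per taxon) in the validation suite.

## Recombination landscape

Bins are anchored at coordinate 0 per chromosome (1 Mbp default; the final
partial bin is kept when it holds ≥ 2 markers). The rate is the cM span of
the two most distal in-bin markers over their physical span in Mbp — the
span formula exactly, so sparse bins estimate over short spans and no
correction is applied. Bins with < 2 markers or coincident distal markers
are UNDEFINED; rates > 100 cM/Mbp (marker mislocalisation) are flagged and
excluded downstream; no general mislocalisation detector is attempted.
Smoothed-weight windows are matched to bins by window midpoint (median of
member-region midpoints); windows in UNDEFINED/filtered bins are dropped
with counts logged; Spearman's ρ uses average ranks for ties, and the
all-ties case is reported as ρ = 0. The high/low regime threshold is
5 cM/Mbp, strictly-greater.

## Pipeline and reproducibility

The pipeline config is a dataclass serialisable as JSON (JSON chosen over
TOML: no schema beyond the dataclass, and the report is JSON already).
Output paths are excluded from the report body, so identical config + seed
give byte-identical reports. One global seed expands to per-stage streams
(`f"{seed}:{stage}"`), so adding a stage never perturbs another stage's
draws. Stage failures halt with the stage name; data errors and config
errors exit 3 and 2 respectively from the CLI.

## Known limitations

- The weighting inner loop is pure Python; exhaustive weighting beyond
  ~10⁴ combinations per tree falls back to sampling by design.
- The simulator emits true genealogies; there is no gene-tree inference
  stage, so weighting results are upper bounds on what estimated trees
  would give.
- D_FOIL requires the P1/P2 split to be the more recent; the code does not
  verify this from data (roles are the caller's assertion).
- The linkage-map simulator places markers uniformly; real capture maps
  cluster markers in genes, which mainly affects UNDEFINED-bin rates.
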