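"""Domain containers and readers/writers for the formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open.  BED is
native; VCF positions are converted on read (POS-1) and restored on write.

Genotypes are stored as derived-allele dosage per diploid sample
(0/1/2, :data:`MISSING` = -1), so a sample's derived-allele frequency is
``dosage / 2`` in {0, 0.5, 1} — the quantity all pattern-count statistics
consume.  Multi-allelic and non-ACGT records are dropped on read (counts
logged, never silent); half-calls and ``./.`` both map to MISSING.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trees import Node, read_newick  # noqa: F401  (re-exported for convenience)

logger = logging.getLogger("introscan")

MISSING: int = -1

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


# ---------------------------------------------------------------------------
# TaxonMap
# ---------------------------------------------------------------------------

@dataclass
class TaxonMap:
    """Sample -> taxon assignment; ``taxa`` preserves first-seen order."""

    entries: dict[str, str]

    def __post_init__(self):
        if any(not s or not t for s, t in self.entries.items()):
            raise ValueError("empty sample or taxon label in taxon map")
        seen: list[str] = []
        for taxon in self.entries.values():
            if taxon not in seen:
                seen.append(taxon)
        self.taxa: list[str] = seen

    def samples_of(self, taxon: str) -> list[str]:
        return [s for s, t in self.entries.items() if t == taxon]

    def __getitem__(self, sample: str) -> str:
        return self.entries[sample]

    @classmethod
    def read_tsv(cls, path) -> "TaxonMap":
        """Two-column TSV ``sample<TAB>taxon``; a header line is allowed."""
        entries: dict[str, str] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"line {lineno}: expected 2 columns")
                if lineno == 1 and fields[:2] == ["sample", "taxon"]:
                    continue
                sample, taxon = fields[0], fields[1]
                if sample in entries:
                    raise ValueError(f"line {lineno}: duplicate sample {sample!r}")
                entries[sample] = taxon
        return cls(entries)

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("sample\ttaxon\n")
            for sample, taxon in self.entries.items():
                handle.write(f"{sample}\t{taxon}\n")


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sites x diploid samples, coded as derived/alternate-allele dosage."""

    chrom: np.ndarray          # (S,) str
    pos: np.ndarray            # (S,) int64, 0-based
    ref: np.ndarray            # (S,) str
    alt: np.ndarray            # (S,) str ("." for invariant records)
    dosage: np.ndarray         # (S, N) int8 in {0,1,2,MISSING}
    samples: list[str]
    taxon_map: TaxonMap
    includes_invariant: bool = False
    haplotypes: np.ndarray | None = None   # (S, N, 2) int8, when phase is known

    def __post_init__(self):
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        # positions strictly increasing within each chromosome
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_column(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in genotype matrix") from None

    def columns_of_taxon(self, taxon: str) -> list[int]:
        return [self.sample_column(s) for s in self.taxon_map.samples_of(taxon)]

    def is_variant(self) -> np.ndarray:
        """Sites with at least one derived allele observed (alt present)."""
        return np.asarray([a not in (".", "") for a in self.alt])

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of sites on ``chrom`` in the half-open window."""
        on = np.nonzero(self.chrom == chrom)[0]
        p = self.pos[on]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="left")
        return on[lo:hi]


def read_genotype_vcf(path, taxon_map: TaxonMap, keep_invariant: bool = False) -> GenotypeMatrix:
    """Load biallelic SNV dosages from a VCF (GT required) via cyvcf2.

    Multi-allelic records and records with non-ACGT alleles are dropped and
    counted; invariant records (no ALT) are kept only with ``keep_invariant``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in taxon_map.entries if s not in vcf_samples]
    if missing_samples:
        raise ValueError(f"samples not in VCF header: {', '.join(missing_samples)}")
    columns = [vcf_samples.index(s) for s in taxon_map.entries]
    samples = list(taxon_map.entries)

    chrom, pos, ref, alt, dosages, haps = [], [], [], [], [], []
    n_multi = n_badallele = n_invariant_dropped = 0
    last: dict[str, int] = {}
    phased_all = True
    for rec in vcf:
        alts = [a for a in rec.ALT if a not in (".", "<NON_REF>")]
        if len(alts) > 1:
            n_multi += 1
            continue
        alleles = [rec.REF] + alts
        if any(a not in ("A", "C", "G", "T") for a in alleles):
            n_badallele += 1
            continue
        if not alts and not keep_invariant:
            n_invariant_dropped += 1
            continue
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        last[rec.CHROM] = rec.POS
        gts = rec.genotypes  # [a0, a1, phased] per sample
        row = np.empty(len(columns), dtype=np.int8)
        hrow = np.empty((len(columns), 2), dtype=np.int8)
        for out_i, col in enumerate(columns):
            a0, a1 = gts[col][0], gts[col][1]
            if a0 < 0 or a1 < 0:
                row[out_i] = MISSING
                hrow[out_i] = (MISSING, MISSING)
            else:
                row[out_i] = a0 + a1
                hrow[out_i] = (a0, a1)
            if not gts[col][2]:
                phased_all = False
        chrom.append(rec.CHROM)
        pos.append(rec.POS - 1)
        ref.append(rec.REF)
        alt.append(alts[0] if alts else ".")
        dosages.append(row)
        haps.append(hrow)
    if n_multi:
        logger.info("read_genotype_vcf: dropped %d multi-allelic records", n_multi)
    if n_badallele:
        logger.info("read_genotype_vcf: dropped %d non-ACGT records", n_badallele)
    if n_invariant_dropped:
        logger.info("read_genotype_vcf: dropped %d invariant records", n_invariant_dropped)
    S = len(pos)
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosage=(np.vstack(dosages) if S else np.empty((0, len(samples)), dtype=np.int8)),
        samples=samples,
        taxon_map=taxon_map,
        includes_invariant=keep_invariant,
        haplotypes=(np.stack(haps) if (S and phased_all) else None),
    )


def write_genotype_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (phased GT when haplotypes are known)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=introscan\n")
        for c in dict.fromkeys(gm.chrom.tolist()):
            out.write(f"##contig=<ID={c}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(gm.samples) + "\n")
        sep = "|" if gm.haplotypes is not None else "/"
        for i in range(gm.n_sites):
            calls = []
            for j in range(len(gm.samples)):
                if gm.dosage[i, j] == MISSING:
                    calls.append(f".{sep}.")
                elif gm.haplotypes is not None:
                    a, b = gm.haplotypes[i, j]
                    calls.append(f"{a}{sep}{b}")
                else:
                    d = gm.dosage[i, j]
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            out.write(
                f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------

@dataclass
class Region:
    region_id: str
    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.region_id for r in self.regions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate region ids: {sorted(dupes)}")
        for r in self.regions:
            if r.start >= r.end:
                raise ValueError(f"region {r.region_id}: start >= end")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chromosome(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


def read_regions_bed(path) -> RegionSet:
    """BED3/BED4 -> RegionSet (0-based half-open preserved verbatim)."""
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end")
            name = fields[3] if len(fields) >= 4 else f"region_{lineno}"
            regions.append(Region(name, chrom, start, end))
    rs = RegionSet(regions)
    by_chrom = rs.by_chromosome()
    n_overlap = sum(
        1
        for regs in by_chrom.values()
        for a, b in zip(regs, regs[1:])
        if b.start < a.end
    )
    if n_overlap:
        logger.info("read_regions_bed: %d overlapping region pairs", n_overlap)
    return rs


def write_regions_bed(rs: RegionSet, path) -> None:
    with open(path, "w") as out:
        for r in rs:
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# LinkageMap
# ---------------------------------------------------------------------------

@dataclass
class Marker:
    marker_id: str
    chrom: str
    bp: int
    cm: float


@dataclass
class LinkageMap:
    markers: list[Marker]
    n_monotonicity_violations: int = 0

    def __post_init__(self):
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.bp))
        violations = 0
        by_chrom: dict[str, list[Marker]] = {}
        for m in self.markers:
            if m.cm < 0 or m.bp < 0:
                raise ValueError(f"marker {m.marker_id}: negative bp or cM")
            by_chrom.setdefault(m.chrom, []).append(m)
        for markers in by_chrom.values():
            for a, b in zip(markers, markers[1:]):
                if b.cm < a.cm:
                    violations += 1
        if violations:
            logger.warning("linkage map: %d cM monotonicity violations", violations)
        self.n_monotonicity_violations = violations

    def __len__(self) -> int:
        return len(self.markers)

    def by_chromosome(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chrom, []).append(m)
        return out


def read_linkage_map(path) -> LinkageMap:
    """TSV with header ``marker chrom bp cM`` (tab-separated)."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    required = {"marker", "chrom", "bp", "cM"}
    if not required <= set(table.columns):
        raise ValueError(f"linkage map must have columns {sorted(required)}")
    markers = [
        Marker(str(row.marker), str(row.chrom), int(row.bp), float(row.cM))
        for row in table.itertuples()
    ]
    return LinkageMap(markers)


def write_linkage_map(lm: LinkageMap, path) -> None:
    with open(path, "w") as out:
        out.write("marker\tchrom\tbp\tcM\n")
        for m in lm.markers:
            out.write(f"{m.marker_id}\t{m.chrom}\t{m.bp}\t{m.cm:.6f}\n")


# ---------------------------------------------------------------------------
# Gene alignment export
# ---------------------------------------------------------------------------

def export_gene_alignments(
    gm: GenotypeMatrix,
    rs: RegionSet,
    out_dir,
    haplotype: int | None = None,
) -> list[Path]:
    """One FASTA per region: the variable sites, one sequence per sample.

    Heterozygous calls become IUPAC ambiguity codes unless ``haplotype``
    (0 or 1) selects a phased haplotype; the phased option requires the
    matrix to carry phase.  Regions with no variable sites are skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if haplotype is not None and gm.haplotypes is None:
        raise ValueError("haplotype selection requires phased genotypes")
    variant = gm.is_variant()
    written = []
    for region in rs:
        idx = gm.sites_in(region.chrom, region.start, region.end)
        idx = idx[variant[idx]]
        if len(idx) == 0:
            logger.info("export_gene_alignments: %s has no variable sites, skipped",
                        region.region_id)
            continue
        path = out_dir / f"{region.region_id}.fa"
        with open(path, "w") as out:
            for j, sample in enumerate(gm.samples):
                seq = []
                for i in idx:
                    ref, alt = gm.ref[i], gm.alt[i]
                    if haplotype is not None:
                        h = gm.haplotypes[i, j, haplotype]
                        seq.append("N" if h == MISSING else (alt if h else ref))
                        continue
                    d = gm.dosage[i, j]
                    if d == MISSING:
                        seq.append("N")
                    elif d == 0:
                        seq.append(ref)
                    elif d == 2:
                        seq.append(alt)
                    else:
                        seq.append(IUPAC.get(frozenset((ref, alt)), "N"))
                out.write(f">{sample}\n{''.join(seq)}\n")
        written.append(path)
    return written


def write_newick_file(trees: Iterable[Node], path) -> None:
    from .trees import write_newick

    with open(path, "w") as out:
        for tree in trees:
            out.write(write_newick(tree) + "\n")
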