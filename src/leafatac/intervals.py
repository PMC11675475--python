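"""Genomic interval data model, standard-format I/O and interval algebra.

All internal coordinates are 0-based, half-open (BED convention).  GFF3 input
(1-based, inclusive) is converted at the parsing boundary and converted back
when writing, so a written annotation re-parses identically.

Feature-category classification is *total*: every genomic position maps to
exactly one of {promoter, utr5, utr3, exon, intron, intergenic} under the
precedence promoter > utr5 > utr3 > exon > intron > intergenic.  A peak is
classified by its summit position when a summit is recorded, otherwise by its
midpoint.  The promoter window is the 2 kb strand-upstream of the TSS,
half-open and ending at the TSS, clipped at chromosome edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

PROMOTER_BP = 2000


class FeatureCategory(IntEnum):
    """Genomic feature categories, ordered by classification precedence."""

    PROMOTER = 0
    UTR5 = 1
    UTR3 = 2
    EXON = 3
    INTRON = 4
    INTERGENIC = 5

    @property
    def label(self) -> str:
        return self.name.lower()


CATEGORIES = tuple(FeatureCategory)


@dataclass
class GenomicInterval:
    """A genomic interval: 0-based half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


@dataclass
class Peak:
    """An accessible chromatin region (ATAC-seq peak) with provenance.

    ``counts`` maps sample identifiers to Tn5 fragment counts; replicate-level
    peaks typically carry only their own sample, merged peaks the union.
    """

    interval: GenomicInterval
    peak_id: str
    stage: str | None = None
    replicate: int | str | None = None
    summit_offset: int | None = None
    counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValidationError(
                f"peak {self.peak_id}: summit offset {self.summit_offset} "
                f"outside peak of length {self.interval.length}"
            )
        if self.counts is not None and any(v < 0 for v in self.counts.values()):
            raise ValidationError(f"peak {self.peak_id}: negative count")

    # interval passthroughs keep call sites terse
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    def position(self) -> int:
        """Classification position: absolute summit if known, else midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.interval.midpoint


@dataclass
class GeneModel:
    """A stranded gene model with exon and UTR structure.

    ``tss`` / ``tes`` follow the half-open convention: on the plus strand the
    TSS is ``start``; on the minus strand it is the boundary coordinate
    ``end`` (the first transcribed base is ``end - 1``).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: bad extent")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons) if self.exons else self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def promoter_window(self, chrom_size: int, window: int = PROMOTER_BP) -> tuple[int, int]:
        """Strand-upstream promoter window [a, b), clipped at chromosome edges."""
        if self.strand == "+":
            return max(0, self.tss - window), self.tss
        return self.tss, min(chrom_size, self.tss + window)


class GenomeAnnotation:
    """Chromosome sizes plus gene models, with a per-base category index.

    The index is a uint8 array per chromosome painted in ascending precedence
    (intron, exon, 3'UTR, 5'UTR, promoter last), so a single lookup yields the
    winning category.  Memory scales with genome size, which is appropriate
    for the simulated genomes this package analyses (megabases, not the full
    2.1 Gb maize genome).
    """

    def __init__(self, chrom_sizes: dict[str, int], genes: Sequence[GeneModel],
                 promoter_bp: int = PROMOTER_BP):
        self.chrom_sizes = dict(chrom_sizes)
        self.genes = list(genes)
        self.promoter_bp = promoter_bp
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id} extends beyond chromosome {g.chrom}"
                )
        self._catmap: dict[str, np.ndarray] | None = None

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chrom_sizes}
        for g in self.genes:
            out[g.chrom].append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def category_map(self) -> dict[str, np.ndarray]:
        """Per-chromosome per-base category codes (cached)."""
        if self._catmap is not None:
            return self._catmap
        maps = {
            c: np.full(n, FeatureCategory.INTERGENIC, dtype=np.uint8)
            for c, n in self.chrom_sizes.items()
        }
        # ascending precedence: later paints win
        for g in self.genes:
            maps[g.chrom][g.start:g.end] = FeatureCategory.INTRON
        for g in self.genes:
            for s, e in g.exons:
                maps[g.chrom][s:e] = FeatureCategory.EXON
        for g in self.genes:
            for s, e in g.utr3:
                maps[g.chrom][s:e] = FeatureCategory.UTR3
        for g in self.genes:
            for s, e in g.utr5:
                maps[g.chrom][s:e] = FeatureCategory.UTR5
        for g in self.genes:
            a, b = g.promoter_window(self.chrom_sizes[g.chrom], self.promoter_bp)
            if b > a:
                maps[g.chrom][a:b] = FeatureCategory.PROMOTER
        self._catmap = maps
        return maps

    def classify_point(self, chrom: str, pos: int) -> FeatureCategory:
        if chrom not in self.chrom_sizes:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValidationError(f"position {chrom}:{pos} outside chromosome")
        return FeatureCategory(self.category_map()[chrom][pos])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: non-integer size") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


def read_annotation(gff3_path, sizes_path) -> GenomeAnnotation:
    """Assemble gene models from a GFF3 file plus a chrom.sizes table.

    One model is kept per gene; when a gene has several mRNA children the
    longest transcript wins.  GFF3 1-based inclusive coordinates are converted
    to 0-based half-open here and nowhere else.
    """
    import gffutils

    sizes = read_chrom_sizes(sizes_path)
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        chrom = gene.seqid
        if chrom not in sizes:
            raise ValidationError(f"gene {gene.id}: unknown chromosome {chrom}")
        if gene.end > sizes[chrom]:
            raise ValidationError(
                f"gene {gene.id}: coordinate {gene.end} exceeds size of {chrom}"
            )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            parent = max(mrnas, key=lambda m: (m.end - m.start, m.id))
        else:
            parent = gene
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        utr5 = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="five_prime_UTR")
        ]
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="three_prime_UTR")
        ]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=chrom,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=sorted(exons),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    return GenomeAnnotation(sizes, genes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write gene/mRNA/exon/UTR records; byte-stable for a fixed annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            cols = [g.chrom, "leafatac", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}"]
            fh.write("\t".join(cols) + "\n")
            mid = f"{g.gene_id}.t1"
            fh.write("\t".join([g.chrom, "leafatac", "mRNA", str(g.start + 1),
                                str(g.end), ".", g.strand, ".",
                                f"ID={mid};Parent={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([g.chrom, "leafatac", "exon", str(s + 1), str(e),
                                    ".", g.strand, ".",
                                    f"ID={mid}.exon{i};Parent={mid}"]) + "\n")
            for i, (s, e) in enumerate(g.utr5, 1):
                fh.write("\t".join([g.chrom, "leafatac", "five_prime_UTR", str(s + 1),
                                    str(e), ".", g.strand, ".",
                                    f"ID={mid}.utr5.{i};Parent={mid}"]) + "\n")
            for i, (s, e) in enumerate(g.utr3, 1):
                fh.write("\t".join([g.chrom, "leafatac", "three_prime_UTR", str(s + 1),
                                    str(e), ".", g.strand, ".",
                                    f"ID={mid}.utr3.{i};Parent={mid}"]) + "\n")


def _parse_int(value: str, path, ln: int, what: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"{path}:{ln}: non-integer {what}: {value!r}") from exc


def read_peaks(path, fmt: str | None = None, stage: str | None = None,
               replicate: int | str | None = None) -> list[Peak]:
    """Read BED3/BED6 or 10-column narrowPeak into sorted Peak records.

    narrowPeak column 10 (summit offset) of -1 maps to "no summit".  Output is
    sorted by (chrom, start, end); malformed lines raise with line numbers.
    """
    if fmt is None:
        fmt = "narrowPeak" if str(path).endswith(("narrowPeak", "np")) else "bed"
    if fmt not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {fmt!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: expected >=3 columns")
            if fmt == "narrowPeak" and len(parts) != 10:
                raise ValidationError(
                    f"{path}:{ln}: narrowPeak requires 10 columns, got {len(parts)}"
                )
            chrom = parts[0]
            start = _parse_int(parts[1], path, ln, "start")
            end = _parse_int(parts[2], path, ln, "end")
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start {start} >= end {end}")
            if start < 0:
                raise ValidationError(f"{path}:{ln}: negative start")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"peak{ln}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            score: float | None = None
            summit: int | None = None
            if fmt == "narrowPeak":
                try:
                    score = float(parts[6])
                except ValueError as exc:
                    raise ValidationError(f"{path}:{ln}: bad signalValue") from exc
                summit = _parse_int(parts[9], path, ln, "summit")
                if summit == -1:
                    summit = None
                elif not (0 <= summit < end - start):
                    raise ValidationError(f"{path}:{ln}: summit outside peak")
            elif len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ValidationError(f"{path}:{ln}: bad score") from exc
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand, score),
                    peak_id=name,
                    stage=stage,
                    replicate=replicate,
                    summit_offset=summit,
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    return peaks


def write_bed(peaks: Iterable[Peak], path) -> None:
    """Write BED6 (name = peak_id, score = interval score or 0)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0 if p.interval.score is None else p.interval.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t"
                     f"{p.interval.strand}\n")


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            signal = 0.0 if p.interval.score is None else float(p.interval.score)
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t"
                f"{p.interval.strand}\t{signal:g}\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def _coords(items) -> tuple[list[str], np.ndarray, np.ndarray]:
    chroms = [it.chrom for it in items]
    starts = np.fromiter((it.start for it in items), dtype=np.int64, count=len(items))
    ends = np.fromiter((it.end for it in items), dtype=np.int64, count=len(items))
    return chroms, starts, ends


def _check_sorted(chroms, starts, what: str) -> None:
    for i in range(1, len(chroms)):
        if (chroms[i], starts[i]) < (chroms[i - 1], starts[i - 1]):
            raise ContractError(f"{what} must be sorted by (chrom, start)")


def intersect(a: Sequence, b: Sequence, min_overlap_bp: int = 1) -> list[tuple[int, int]]:
    """All index pairs (i, j) with a[i], b[j] sharing >= min_overlap_bp bases.

    Inputs must be sorted by (chrom, start); anything with .chrom/.start/.end
    (GenomicInterval, Peak, GeneModel) is accepted.  Pairs are returned in
    (a-index, b-index) lexicographic order.
    """
    if min_overlap_bp < 1:
        raise ContractError("min_overlap_bp must be >= 1")
    ac, as_, ae = _coords(a)
    bc, bs, be = _coords(b)
    _check_sorted(ac, as_, "intersect: first collection")
    _check_sorted(bc, bs, "intersect: second collection")
    pairs: list[tuple[int, int]] = []
    # group b indices per chromosome
    b_by_chrom: dict[str, list[int]] = {}
    for j, c in enumerate(bc):
        b_by_chrom.setdefault(c, []).append(j)
    for i, c in enumerate(ac):
        js = b_by_chrom.get(c)
        if not js:
            continue
        jarr = np.asarray(js)
        cs, ce = bs[jarr], be[jarr]
        # candidates must start before a-end (minus the required overlap)
        hi = np.searchsorted(cs, ae[i] - min_overlap_bp, side="right")
        if hi == 0:
            continue
        sel = np.minimum(ce[:hi], ae[i]) - np.maximum(cs[:hi], as_[i]) >= min_overlap_bp
        pairs.extend((i, int(jarr[k])) for k in np.nonzero(sel)[0])
    return pairs


def merge(intervals: Sequence, max_gap: int = 0) -> list[GenomicInterval]:
    """Union of overlapping or <=max_gap-separated intervals.

    Bookended intervals ([0,10) and [10,20)) merge at max_gap=0 — gap zero is
    within "gap <= max_gap" — matching the common merge-tool default.
    Input must be sorted by (chrom, start); output is sorted and disjoint.
    """
    if max_gap < 0:
        raise ContractError("max_gap must be >= 0")
    chroms, starts, ends = _coords(intervals)
    _check_sorted(chroms, starts, "merge: input")
    merged: list[GenomicInterval] = []
    cur = None  # [chrom, start, end]
    for c, s, e in zip(chroms, starts, ends):
        if cur is not None and c == cur[0] and s <= cur[2] + max_gap:
            cur[2] = max(cur[2], int(e))
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [c, int(s), int(e)]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return merged


def classify(peak: Peak | GenomicInterval, annotation: GenomeAnnotation) -> FeatureCategory:
    """Feature category of a peak's summit (midpoint fallback)."""
    pos = peak.position() if isinstance(peak, Peak) else peak.midpoint
    chrom = peak.chrom
    return annotation.classify_point(chrom, pos)


def feature_proportions(peaks: Sequence[Peak], annotation: GenomeAnnotation) -> pd.DataFrame:
    """Counts, proportions and length statistics of peaks per feature category.

    Returns a DataFrame indexed by category label with columns
    count / proportion / mean_length / median_length; proportions sum to 1.
    """
    if len(peaks) == 0:
        warnings.warn("feature_proportions: empty peak set")
        return pd.DataFrame(
            columns=["count", "proportion", "mean_length", "median_length"]
        )
    cats = [classify(p, annotation) for p in peaks]
    lengths = np.array([p.length for p in peaks], dtype=float)
    rows = []
    n = len(peaks)
    codes = np.array([int(c) for c in cats])
    for cat in CATEGORIES:
        mask = codes == int(cat)
        k = int(mask.sum())
        rows.append(
            {
                "category": cat.label,
                "count": k,
                "proportion": k / n,
                "mean_length": float(lengths[mask].mean()) if k else np.nan,
                "median_length": float(np.median(lengths[mask])) if k else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
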