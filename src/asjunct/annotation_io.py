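"""Gene/transcript data model and annotation I/O.

Coordinates are 0-based half-open everywhere inside the package; GFF3/GTF
files are 1-based inclusive and conversion happens only at read/write time.
Exons and introns are indexed in *transcription* order: index 0 is the
5'-most element, which for minus-strand genes is the genomically rightmost.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


# ---------------------------------------------------------------------------
# Core genomic types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EvidenceSource:
    """Origin of a transcript model: a (library, mapper) pair or EST data."""

    library_id: str | None = None
    mapper_id: str | None = None
    is_est: bool = False

    def __post_init__(self) -> None:
        if self.is_est:
            if self.library_id is not None or self.mapper_id is not None:
                raise ValueError("EST sources carry no library/mapper")
        elif self.library_id is None or self.mapper_id is None:
            raise ValueError("non-EST sources need both library_id and mapper_id")

    @property
    def label(self) -> str:
        return "EST" if self.is_est else f"{self.library_id}:{self.mapper_id}"

    @classmethod
    def from_label(cls, label: str) -> "EvidenceSource":
        if label == "EST":
            return EST_SOURCE
        lib, mapper = label.split(":", 1)
        return cls(lib, mapper)


EST_SOURCE = EvidenceSource(is_est=True)


@dataclass
class GeneModel:
    """A gene's primary transcript: ordered exons plus an optional CDS span.

    ``exons`` are in transcription order. ``cds_start``/``cds_end`` are the
    genomic (leftmost/rightmost, half-open) bounds of the translated span;
    both are ``None`` for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene without exons")
        gex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(gex, gex[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.gene_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        expected = tuple(gex) if self.strand == "+" else tuple(reversed(gex))
        if tuple(self.exons) != expected:
            raise AnnotationError(f"{self.gene_id}: exons not in transcription order")
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.gene_id}: half-specified CDS span")
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise AnnotationError(f"{self.gene_id}: empty CDS span")
            # both CDS bounds must land inside exons
            for pos in (self.cds_start, self.cds_end - 1):
                if not any(e.start <= pos < e.end for e in gex):
                    raise AnnotationError(f"{self.gene_id}: CDS outside exons")

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def genomic_exons(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def span(self) -> tuple[int, int]:
        gex = self.genomic_exons
        return gex[0].start, gex[-1].end

    def genomic_gap_index(self, intron_index: int) -> int:
        """Genomic (left-to-right) index of the gap holding a transcription-order intron."""
        if not 0 <= intron_index < self.n_introns:
            raise IndexError(f"{self.gene_id}: intron index {intron_index}")
        return intron_index if self.strand == "+" else self.n_introns - 1 - intron_index

    def genomic_exon_index(self, exon_index: int) -> int:
        if not 0 <= exon_index < self.n_exons:
            raise IndexError(f"{self.gene_id}: exon index {exon_index}")
        return exon_index if self.strand == "+" else self.n_exons - 1 - exon_index


@dataclass(frozen=True)
class Intron:
    """A primary-transcript intron; donor/acceptor follow transcription orientation."""

    gene_id: str
    index: int
    interval: GenomicInterval
    donor_pos: int  # first intronic base, transcription orientation
    acceptor_pos: int  # last intronic base, transcription orientation


def derive_introns(gene: GeneModel) -> list[Intron]:
    """The n-1 introns of a gene in transcription order."""
    gex = gene.genomic_exons
    gaps = [
        GenomicInterval(gene.chrom, a.end, b.start, gene.strand)
        for a, b in zip(gex, gex[1:])
    ]
    if gene.strand == "-":
        gaps.reverse()
    out = []
    for i, iv in enumerate(gaps):
        if gene.strand == "+":
            donor, acceptor = iv.start, iv.end - 1
        else:
            donor, acceptor = iv.end - 1, iv.start
        out.append(Intron(gene.gene_id, i, iv, donor, acceptor))
    return out


# ---------------------------------------------------------------------------
# UTR/CDS region taxonomy
# ---------------------------------------------------------------------------


class IntronRegionType(str, Enum):
    FIVE_UTR = "5UTR-5UTR"
    CDS = "CDS-CDS"
    THREE_UTR = "3UTR-3UTR"


class ExonRegionType(str, Enum):
    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    FIVE_UTR_CDS = "5UTR-CDS"
    CDS_THREE_UTR = "CDS-3UTR"
    FIVE_UTR_THREE_UTR = "5UTR-3UTR"


def classify_intron_region(gene: GeneModel, intron_index: int) -> IntronRegionType | None:
    """Region type of an intron; ``None`` (unclassified) for non-coding genes.

    An intron lying entirely 5' of the CDS in transcription orientation is a
    5'UTR intron, entirely 3' of the CDS a 3'UTR intron, everything else CDS
    (including the malformed case of an intron interrupting the CDS bounds).
    """
    if not gene.is_coding:
        return None
    intron = derive_introns(gene)[intron_index]
    s, e = intron.interval.start, intron.interval.end
    if gene.strand == "+":
        if e <= gene.cds_start:
            return IntronRegionType.FIVE_UTR
        if s >= gene.cds_end:
            return IntronRegionType.THREE_UTR
    else:
        if s >= gene.cds_end:
            return IntronRegionType.FIVE_UTR
        if e <= gene.cds_start:
            return IntronRegionType.THREE_UTR
    return IntronRegionType.CDS


def classify_exon_region(gene: GeneModel, exon_index: int) -> ExonRegionType | None:
    """Region type of an exon; ``None`` for non-coding genes."""
    if not gene.is_coding:
        return None
    exon = gene.exons[exon_index]
    cs, ce = gene.cds_start, gene.cds_end
    if exon.end <= cs or exon.start >= ce:  # no CDS overlap
        if gene.strand == "+":
            return ExonRegionType.FIVE_UTR if exon.end <= cs else ExonRegionType.THREE_UTR
        return ExonRegionType.FIVE_UTR if exon.start >= ce else ExonRegionType.THREE_UTR
    has_first = exon.start <= cs < exon.end  # contains genomic CDS start
    has_last = exon.start < ce <= exon.end  # contains genomic CDS end
    if has_first and has_last:
        return ExonRegionType.FIVE_UTR_THREE_UTR
    if gene.strand == "+":
        contains_tss, contains_stop = has_first, has_last
    else:
        contains_tss, contains_stop = has_last, has_first
    if contains_tss:
        return ExonRegionType.FIVE_UTR_CDS
    if contains_stop:
        return ExonRegionType.CDS_THREE_UTR
    return ExonRegionType.CDS


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """An assembled (Cufflinks-style) or EST transcript model.

    Exons are stored genomically sorted; transcription order follows strand.
    """

    model_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str | None = None
    source: EvidenceSource | None = None
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise AnnotationError(f"{self.model_id}: overlapping model exons")
        self.exons = tuple(ex)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def junctions(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of the model's introns, left to right."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]


# ---------------------------------------------------------------------------
# GFF3 / GTF readers and writers
# ---------------------------------------------------------------------------


def read_annotation(gff3_path: str, strict: bool = True) -> dict[str, GeneModel]:
    """Load one primary transcript per gene from a GFF3 file.

    The primary transcript is the mRNA carrying a truthy ``canonical``
    attribute if any, otherwise the first mRNA of the gene. Genes whose
    primary transcript has overlapping/duplicated exons or a CDS outside the
    exons raise :class:`AnnotationError` (or are skipped with a warning when
    ``strict`` is false).
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=False,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        if not mrnas:
            continue
        primary = next(
            (m for m in mrnas if m.attributes.get("canonical", ["0"])[0] in ("1", "true")),
            mrnas[0],
        )
        try:
            exons = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in db.children(primary, featuretype="exon")
            ]
            if len({(e.start, e.end) for e in exons}) != len(exons):
                raise AnnotationError(f"{g.id}: duplicated exon lines")
            exons.sort(key=lambda e: e.start)
            if g.strand == "-":
                exons.reverse()
            cds = [(f.start - 1, f.end) for f in db.children(primary, featuretype="CDS")]
            cds_start = min(c[0] for c in cds) if cds else None
            cds_end = max(c[1] for c in cds) if cds else None
            genes[g.id] = GeneModel(
                g.id, g.seqid, g.strand, tuple(exons), cds_start, cds_end
            )
        except AnnotationError as exc:
            if strict:
                raise
            logger.warning("skipping gene %s: %s", g.id, exc)
    return genes


def write_annotation(genes: Mapping[str, GeneModel], path: str) -> None:
    """Write gene models as GFF3 (1-based inclusive), one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, gene in genes.items():
            lo, hi = gene.span
            base = f"{gene.chrom}\tasjunct\t"
            tail = f"\t.\t{gene.strand}\t"
            fh.write(f"{base}gene\t{lo + 1}\t{hi}{tail}.\tID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(
                f"{base}mRNA\t{lo + 1}\t{hi}{tail}.\tID={tid};Parent={gid};canonical=1\n"
            )
            for e in gene.genomic_exons:
                fh.write(f"{base}exon\t{e.start + 1}\t{e.end}{tail}.\tParent={tid}\n")
            if gene.is_coding:
                for e in gene.genomic_exons:
                    lo_c = max(e.start, gene.cds_start)
                    hi_c = min(e.end, gene.cds_end)
                    if lo_c < hi_c:
                        fh.write(f"{base}CDS\t{lo_c + 1}\t{hi_c}{tail}0\tParent={tid}\n")


def read_models(gtf_path: str, source: EvidenceSource | None = None) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features grouped by transcript_id)."""
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=False,
    )
    grouped: dict[str, list] = defaultdict(list)
    for f in db.features_of_type("exon"):
        grouped[f.attributes["transcript_id"][0]].append(f)
    models = []
    for tid in sorted(grouped):
        feats = grouped[tid]
        exons = tuple(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            for f in sorted(feats, key=lambda f: f.start)
        )
        models.append(
            TranscriptModel(tid, feats[0].seqid, feats[0].strand, exons, source=source)
        )
    return models


def write_models(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as GTF exon lines."""
    with open(path, "w") as fh:
        for m in models:
            gid = m.gene_id or m.model_id
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tasjunct\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{m.model_id}";\n'
                )


# ---------------------------------------------------------------------------
# Chimera filter
# ---------------------------------------------------------------------------


def filter_chimeric_models(
    models: Iterable[TranscriptModel], genes: Mapping[str, GeneModel]
) -> tuple[list[TranscriptModel], list[tuple[TranscriptModel, str]]]:
    """Assign each model to exactly one gene span; reject chimeric/intergenic models.

    A model is kept iff its exon span overlaps exactly one gene's
    primary-transcript span. Kept models are returned with ``gene_id`` set.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gid, gene in genes.items():
        lo, hi = gene.span
        trees[gene.chrom].addi(lo, hi, gid)
    kept: list[TranscriptModel] = []
    rejected: list[tuple[TranscriptModel, str]] = []
    for m in models:
        lo, hi = m.span
        hits = sorted(iv.data for iv in trees[m.chrom].overlap(lo, hi))
        if not hits:
            rejected.append((m, "intergenic"))
        elif len(hits) > 1:
            rejected.append((m, "chimeric:" + ",".join(hits)))
        else:
            m.gene_id = hits[0]
            kept.append(m)
    return kept, rejected
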