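"""Alternative-splicing event calling against annotated primary transcripts.

Seven local event types are recognized by comparing a transcript model's
junctions and exons to the reference primary transcript:

====  =======================  =========================================
type  affected element          definition
====  =======================  =========================================
AA    intron                    acceptor (3' splice site) shifted
AD    intron                    donor (5' splice site) shifted
ASS   intron                    both splice sites shifted
ES    exon                      reference exon skipped by a junction
IR    intron                    intron retained inside a model exon
NI    exon                      novel junction inside a reference exon
RE    intron                    novel exon inside a reference intron
====  =======================  =========================================

Junction events use an ordered decision procedure (match, ES, AA/AD, NI,
ASS) so that every candidate junction yields at most one event type.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    EST_SOURCE,
    EvidenceSource,
    GeneModel,
    GenomicInterval,
    Intron,
    TranscriptModel,
    derive_introns,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class EventType(str, Enum):
    AA = "AA"
    AD = "AD"
    ASS = "ASS"
    ES = "ES"
    IR = "IR"
    NI = "NI"
    RE = "RE"


INTRON_KINDS = frozenset({EventType.AA, EventType.AD, EventType.ASS, EventType.IR, EventType.RE})
EXON_KINDS = frozenset({EventType.ES, EventType.NI})


def affected_kind(event_type: EventType) -> str:
    return "intron" if event_type in INTRON_KINDS else "exon"


class MotifClass(str, Enum):
    U2_CANONICAL = "U2"  # GT..AG
    U12 = "U12"  # AT..AC
    NONCANONICAL = "NC"


@dataclass
class ASEvent:
    """One alternative-splicing event on a reference intron or exon."""

    gene_id: str
    event_type: EventType
    affected_kind: str
    affected_index: int
    novel_coords: tuple[tuple[int, int], ...]
    motif: MotifClass | None = None
    evidence: set[EvidenceSource] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.affected_kind != affected_kind(self.event_type):
            raise ValueError(
                f"{self.event_type.value} events affect "
                f"{affected_kind(self.event_type)}s, not {self.affected_kind}s"
            )

    @property
    def key(self) -> tuple[str, EventType, str, int]:
        """Redundancy key: same type on the same element collapses."""
        return (self.gene_id, self.event_type, self.affected_kind, self.affected_index)


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one candidate junction: match/event/unclassified."""

    status: str
    events: tuple[ASEvent, ...] = ()
    reason: str = ""


MATCH = Classification("match")


# ---------------------------------------------------------------------------
# Reference geometry cache
# ---------------------------------------------------------------------------


class _GeneIndex:
    """Precomputed boundary maps for one gene's primary transcript."""

    def __init__(self, gene: GeneModel):
        self.gene = gene
        self.introns = derive_introns(gene)
        self.intron_set = {(i.interval.start, i.interval.end): i.index for i in self.introns}
        # same-role boundary -> transcription-order intron index
        self.donors: dict[int, int] = {}
        self.acceptors: dict[int, int] = {}
        for i in self.introns:
            if gene.strand == "+":
                self.donors[i.interval.start] = i.index
                self.acceptors[i.interval.end] = i.index
            else:
                self.donors[i.interval.end] = i.index
                self.acceptors[i.interval.start] = i.index


def _junction_roles(j: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor boundary, acceptor boundary) of a genomic junction on a strand."""
    s, e = j
    return (s, e) if strand == "+" else (e, s)


# ---------------------------------------------------------------------------
# Junction classification (ordered decision procedure)
# ---------------------------------------------------------------------------


def classify_model_intron(
    j: tuple[int, int], gene: GeneModel, index: _GeneIndex | None = None
) -> Classification:
    """Classify a candidate junction (genomic start, end) against a gene.

    Decision order: exact reference intron match; exon skipping (both
    boundaries match different reference introns); AA/AD (one same-role
    boundary matches); NI (junction strictly inside a reference exon); ASS
    (junction confined to one reference intron and its flanking exons);
    otherwise unclassified.
    """
    idx = index or _GeneIndex(gene)
    s, e = j
    lo, hi = gene.span
    if e <= lo or s >= hi:
        return Classification("unclassified", reason="outside gene span")
    if (s, e) in idx.intron_set:
        return MATCH
    donor_b, acceptor_b = _junction_roles(j, gene.strand)
    k = idx.donors.get(donor_b)
    l = idx.acceptors.get(acceptor_b)
    if k is not None and l is not None and l > k:
        events = tuple(
            ASEvent(gene.gene_id, EventType.ES, "exon", t, ((s, e),))
            for t in range(k + 1, l + 1)
        )
        return Classification("event", events)
    if k is not None and l is None:
        ev = ASEvent(gene.gene_id, EventType.AA, "intron", k, ((s, e),))
        return Classification("event", (ev,))
    if l is not None and k is None:
        ev = ASEvent(gene.gene_id, EventType.AD, "intron", l, ((s, e),))
        return Classification("event", (ev,))
    if k is None and l is None:
        for t, exon in enumerate(gene.exons):
            if exon.start < s and e < exon.end:
                ev = ASEvent(gene.gene_id, EventType.NI, "exon", t, ((s, e),))
                return Classification("event", (ev,))
        overlapped = [
            i for i in idx.introns if s < i.interval.end and i.interval.start < e
        ]
        if len(overlapped) == 1:
            intron = overlapped[0]
            g = gene.genomic_gap_index(intron.index)
            gex = gene.genomic_exons
            if gex[g].start <= s and e <= gex[g + 1].end:
                ev = ASEvent(
                    gene.gene_id, EventType.ASS, "intron", intron.index, ((s, e),)
                )
                return Classification("event", (ev,))
    return Classification("unclassified", reason="no rule")


def detect_exonic_events(model: TranscriptModel, gene: GeneModel) -> list[ASEvent]:
    """Intron-retention and retained-exon events of one model.

    IR at reference intron k: a model exon fully contains intron k and
    reaches >= 1 nt into both flanking reference exons. RE at intron k: a
    model exon lies strictly inside intron k and its two flanking model
    introns share their outer boundaries with intron k.
    """
    events: list[ASEvent] = []
    introns = derive_introns(gene)
    for intron in introns:
        s, e = intron.interval.start, intron.interval.end
        for ex in model.exons:
            if ex.start < s and e < ex.end:
                events.append(
                    ASEvent(
                        gene.gene_id,
                        EventType.IR,
                        "intron",
                        intron.index,
                        ((ex.start, ex.end),),
                    )
                )
                break
    if len(model.exons) >= 3:
        for pos in range(1, len(model.exons) - 1):
            ex = model.exons[pos]
            left_outer = model.exons[pos - 1].end
            right_outer = model.exons[pos + 1].start
            for intron in introns:
                s, e = intron.interval.start, intron.interval.end
                if s < ex.start and ex.end < e and left_outer == s and right_outer == e:
                    events.append(
                        ASEvent(
                            gene.gene_id,
                            EventType.RE,
                            "intron",
                            intron.index,
                            ((ex.start, ex.end),),
                        )
                    )
    return events


def _re_consumed_junctions(event: ASEvent, gene: GeneModel) -> set[tuple[int, int]]:
    """The two component junctions of an RE event (skipped during classification)."""
    intron = derive_introns(gene)[event.affected_index]
    (a, b), = event.novel_coords
    return {(intron.interval.start, a), (b, intron.interval.end)}


# ---------------------------------------------------------------------------
# Splice-site motifs
# ---------------------------------------------------------------------------


def junction_motif(genome, chrom: str, s: int, e: int, strand: str) -> MotifClass:
    """Motif class from the first/last two intronic bases in transcription orientation.

    ``genome`` is any mapping of chromosome name to sliceable sequence
    (e.g. a :class:`pyfaidx.Fasta`).
    """
    left = str(genome[chrom][s : s + 2]).upper()
    right = str(genome[chrom][e - 2 : e]).upper()
    if strand == "+":
        donor, acceptor = left, right
    else:
        donor = right.translate(_COMPLEMENT)[::-1]
        acceptor = left.translate(_COMPLEMENT)[::-1]
    if donor == "GT" and acceptor == "AG":
        return MotifClass.U2_CANONICAL
    if donor == "AT" and acceptor == "AC":
        return MotifClass.U12
    return MotifClass.NONCANONICAL


def gene_intron_motifs(gene: GeneModel, genome) -> list[MotifClass]:
    """Motif class of every reference intron, transcription order."""
    return [
        junction_motif(genome, gene.chrom, i.interval.start, i.interval.end, gene.strand)
        for i in derive_introns(gene)
    ]


# ---------------------------------------------------------------------------
# Event calling across models
# ---------------------------------------------------------------------------

_MOTIF_TYPES = frozenset(
    {EventType.AA, EventType.AD, EventType.ASS, EventType.NI, EventType.ES}
)


def call_events(
    models: Iterable[TranscriptModel],
    genes: Mapping[str, GeneModel],
    genome=None,
) -> list[ASEvent]:
    """Call AS events over all models; identical events merge their evidence.

    Models must already be chimera-filtered (``gene_id`` set). Junctions that
    are components of a detected RE event are not re-classified as AA/AD/ASS.
    Events with the same (gene, type, element, novel coordinates) from
    different sources are merged. Motifs are annotated when a genome is given
    (events defining a single novel junction only).
    """
    indexes: dict[str, _GeneIndex] = {}
    merged: dict[tuple, ASEvent] = {}

    def _add(ev: ASEvent, source: EvidenceSource | None) -> None:
        key = (ev.gene_id, ev.event_type, ev.affected_index, ev.novel_coords)
        target = merged.get(key)
        if target is None:
            merged[key] = ev
            target = ev
        if source is not None:
            target.evidence.add(source)

    for m in models:
        if m.gene_id is None or m.gene_id not in genes:
            raise ValueError(f"model {m.model_id} is not assigned to a known gene")
        gene = genes[m.gene_id]
        idx = indexes.get(m.gene_id)
        if idx is None:
            idx = indexes[m.gene_id] = _GeneIndex(gene)
        consumed: set[tuple[int, int]] = set()
        for ev in detect_exonic_events(m, gene):
            if ev.event_type is EventType.RE:
                consumed |= _re_consumed_junctions(ev, gene)
            _add(ev, m.source)
        for j in m.junctions():
            if j in consumed:
                continue
            result = classify_model_intron(j, gene, idx)
            for ev in result.events:
                _add(ev, m.source)

    events = sorted(
        merged.values(),
        key=lambda e: (e.gene_id, e.event_type.value, e.affected_index, e.novel_coords),
    )
    if genome is not None:
        for ev in events:
            if ev.event_type in _MOTIF_TYPES:
                (s, e), = ev.novel_coords
                strand = genes[ev.gene_id].strand
                ev.motif = junction_motif(genome, genes[ev.gene_id].chrom, s, e, strand)
    return events


# ---------------------------------------------------------------------------
# Evidence filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceDesign:
    """Experimental design: samples with replicate libraries and two mappers."""

    samples: Mapping[str, tuple[str, ...]]
    mappers: tuple[str, str]
    has_est: bool = True

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sample, libs in self.samples.items():
            for lib in libs:
                if lib in seen:
                    raise ValueError(f"library {lib} in samples {seen[lib]} and {sample}")
                seen[lib] = sample
        if len(self.mappers) != 2 or self.mappers[0] == self.mappers[1]:
            raise ValueError("exactly two distinct mappers are required")

    @property
    def library_sample(self) -> dict[str, str]:
        return {lib: s for s, libs in self.samples.items() for lib in libs}


def read_design(path: str) -> EvidenceDesign:
    """Read a design TSV with header sample_id, library_id, mapper_id."""
    samples: dict[str, list[str]] = defaultdict(list)
    mappers: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample, lib, mapper = (
                parts[cols["sample_id"]],
                parts[cols["library_id"]],
                parts[cols["mapper_id"]],
            )
            if lib not in samples[sample]:
                samples[sample].append(lib)
            if mapper not in mappers:
                mappers.append(mapper)
    return EvidenceDesign(
        {s: tuple(libs) for s, libs in samples.items()}, tuple(mappers[:2])
    )


def event_accepted(event: ASEvent, design: EvidenceDesign) -> bool:
    """Multi-source evidence rule for one event.

    Accept iff the event is seen in ESTs, or by both mappers in a single
    library, or in at least half (ceiling) of a sample's replicate libraries
    under one mapper.
    """
    lib_sample = design.library_sample
    per_lib: dict[str, set[str]] = defaultdict(set)
    per_sample_mapper: dict[tuple[str, str], set[str]] = defaultdict(set)
    for src in event.evidence:
        if src.is_est:
            return True
        if src.library_id not in lib_sample:
            raise ValueError(f"evidence source {src.label} is not in the design")
        if src.mapper_id not in design.mappers:
            raise ValueError(f"evidence source {src.label} uses an unknown mapper")
        per_lib[src.library_id].add(src.mapper_id)
        per_sample_mapper[(lib_sample[src.library_id], src.mapper_id)].add(src.library_id)
    if any(len(mappers) == 2 for mappers in per_lib.values()):
        return True
    for (sample, _mapper), libs in per_sample_mapper.items():
        if len(libs) >= math.ceil(len(design.samples[sample]) / 2):
            return True
    return False


def filter_events_by_evidence(
    events: Iterable[ASEvent], design: EvidenceDesign
) -> list[ASEvent]:
    """Keep events passing :func:`event_accepted`."""
    return [e for e in events if event_accepted(e, design)]


# ---------------------------------------------------------------------------
# Redundancy collapsing
# ---------------------------------------------------------------------------


def collapse_redundant(events: Iterable[ASEvent]) -> list[ASEvent]:
    """Collapse same-type events on the same intron/exon into one.

    The representative keeps the lexicographically sorted union of novel
    coordinates and the union of evidence; its motif is retained only when
    unambiguous across members.
    """
    groups: dict[tuple, list[ASEvent]] = defaultdict(list)
    for ev in events:
        groups[ev.key].append(ev)
    out = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value, k[2], k[3])):
        members = groups[key]
        coords = tuple(sorted({c for m in members for c in m.novel_coords}))
        evidence = set().union(*(m.evidence for m in members))
        motifs = {m.motif for m in members}
        motif = motifs.pop() if len(motifs) == 1 else None
        out.append(
            ASEvent(key[0], key[1], key[2], key[3], coords, motif, evidence)
        )
    return out
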