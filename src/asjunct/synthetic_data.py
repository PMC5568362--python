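"""Paired synthetic genomes with planted alternative-splicing events.

The generator emulates the statistical structure the analysis assumes for a
common-bean-like species A and a soybean-like species B: genes of 1-20 exons
with mostly CDS-CDS introns (~94%), ~98% canonical GT..AG splice sites, a
homology map with 1:1 and 1:2 relations (the 1:2 share reflecting a recent
whole-genome duplication in B), planted AS events with per-type proportions,
per-type cross-species conservation probabilities, optional position/region
biases, and evidence spread over two mappers, replicated libraries and ESTs.

Everything is deterministic given the seed; with the same seed the emitted
files are byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    EST_SOURCE,
    EvidenceSource,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    derive_introns,
    write_annotation,
    write_models,
)
from .characterization import relative_position
from .conservation import HomologyEntry, write_homology
from .event_caller import (
    EventType,
    EvidenceDesign,
    INTRON_KINDS,
    affected_kind,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_REVCOMP = {"GT": "AC", "AG": "CT", "AT": "AT", "AC": "GT", "CA": "TG", "TG": "CA",
            "GG": "CC", "CC": "GG", "TT": "AA", "AA": "TT", "CT": "AG", "GC": "GC"}

# non-canonical splice dinucleotide pairs (never GT..AG or AT..AC)
_NONCANONICAL_SITES = [("CA", "TG"), ("GG", "TT"), ("CT", "GC")]

MIN_OFFSET = 10  # planted novel boundaries keep >= 10 nt from element edges


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_PROPORTIONS_A = {
    "IR": 0.39, "AA": 0.21, "AD": 0.15, "ES": 0.05, "RE": 0.08, "NI": 0.04, "ASS": 0.07,
}
_DEFAULT_PROPORTIONS_B = {
    "IR": 0.32, "AA": 0.24, "AD": 0.18, "ES": 0.08, "RE": 0.08, "NI": 0.06, "ASS": 0.04,
}
_DEFAULT_CONSERVATION = {
    "IR": 0.45, "AA": 0.37, "AD": 0.35, "ASS": 0.25, "ES": 0.25, "NI": 0.30, "RE": 0.30,
}
_DEFAULT_POSITION_BIAS = {
    "AA": -0.8, "AD": -0.8, "ES": -0.8, "RE": -0.8, "IR": 0.8, "ASS": 0.0, "NI": 0.0,
}
_DEFAULT_CHANNELS = {"est": 0.25, "dual": 0.40, "replicate": 0.35}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genome pair.

    Defaults emulate the observed legume structure: exon counts 1-20
    (truncated geometric), ~94% CDS-CDS introns, 98% canonical reference
    junctions, 51% of A genes with two B homologs, per-type event
    proportions and position biases from the genome-wide survey, ~2.5
    planted events per expressed gene, and a three-channel evidence design
    (EST / both mappers in one library / half the sample replicates).
    """

    n_genes: int = 2000
    extra_b_gene_fraction: float = 0.25  # B genes without an A homolog
    exon_count_p: float = 0.16
    max_exons: int = 20
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 600)
    utr5_extension_p: float = 0.19
    utr3_extension_p: float = 0.10
    intergenic_spacer: int = 200
    genes_per_chrom: int = 250
    canonical_fraction: float = 0.98
    u12_share: float = 0.5  # among non-canonical reference junctions
    novel_canonical_fraction: float = 0.78
    frac_one_to_two: float = 0.51
    frac_one_to_one: float = 0.21
    p_same_model: float = 0.85
    expressed_fraction: float = 0.9
    events_per_gene: float = 2.8
    events_per_gene_b: float | None = None  # None -> same as species A
    event_proportions_a: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS_A)
    )
    event_proportions_b: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS_B)
    )
    conservation_p: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONSERVATION)
    )
    paralog_conservation: float = 0.40
    position_bias: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_POSITION_BIAS)
    )
    region_bias: dict[str, dict[str, float]] | None = None
    n_samples: int = 2
    replicates_per_sample: int = 3
    mappers: tuple[str, str] = ("tophat", "gsnap")
    channel_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHANNELS)
    )
    noise_fraction: float = 0.1
    est_primary_coverage: float = 0.3
    fpkm_log_mean: float = 2.0
    fpkm_log_sigma: float = 0.8
    min_fpkm: float = 1.5
    alt_model_fpkm_factor: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "canonical_fraction", "novel_canonical_fraction", "frac_one_to_two",
            "frac_one_to_one", "p_same_model", "expressed_fraction", "noise_fraction",
            "paralog_conservation", "u12_share", "est_primary_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_one_to_two + self.frac_one_to_one > 1.0:
            raise ValueError("homolog fractions exceed 1")
        for props in (self.event_proportions_a, self.event_proportions_b):
            if abs(sum(props.values()) - 1.0) > 0.05:
                raise ValueError("event proportions must sum to ~1")
        for p in self.conservation_p.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("conservation probabilities must be in [0, 1]")
        if self.noise_fraction > 0 and self.replicates_per_sample < 3:
            raise ValueError(
                "noise events need >= 3 replicates per sample to fail the replicate rule"
            )
        self.mappers = tuple(self.mappers)  # YAML round-trip gives lists
        self.exon_length = tuple(self.exon_length)
        self.intron_length = tuple(self.intron_length)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["mappers"] = list(self.mappers)
        data["exon_length"] = list(self.exon_length)
        data["intron_length"] = list(self.intron_length)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PlantedEvent:
    """Ground-truth ledger entry for one planted AS event."""

    species: str
    gene_id: str
    event_type: EventType
    affected_kind: str
    affected_index: int
    novel_coords: tuple[tuple[int, int], ...]
    channel: str = ""
    sources: tuple[EvidenceSource, ...] = ()
    conserved_partner: str | None = None

    @property
    def key(self) -> tuple[str, EventType, str, int]:
        return (self.gene_id, self.event_type, self.affected_kind, self.affected_index)


@dataclass
class SimulatedDataset:
    """In-memory handles (and optional on-disk layout) of one simulation."""

    config: GeneratorConfig
    seed: int
    genes_a: dict[str, GeneModel]
    genes_b: dict[str, GeneModel]
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    homology: list[HomologyEntry]
    ledger: list[PlantedEvent]
    design: EvidenceDesign
    flagged_expressed_a: set[str]
    flagged_expressed_b: set[str]
    models_a: dict[EvidenceSource, list[TranscriptModel]]
    models_b: dict[EvidenceSource, list[TranscriptModel]]
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    out_dir: Path | None = None

    def ledger_for(self, species: str) -> list[PlantedEvent]:
        return [e for e in self.ledger if e.species == species]

    def genes(self, species: str) -> dict[str, GeneModel]:
        return self.genes_a if species == "A" else self.genes_b

    def models(self, species: str) -> dict[EvidenceSource, list[TranscriptModel]]:
        return self.models_a if species == "A" else self.models_b


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------


def _draw_exon_count(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    ks = np.arange(1, cfg.max_exons + 1)
    pmf = (1 - cfg.exon_count_p) ** (ks - 1) * cfg.exon_count_p
    return int(rng.choice(ks, p=pmf / pmf.sum()))


def _build_gene(
    gene_id: str,
    chrom: str,
    offset: int,
    n_exons: int,
    strand: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[GeneModel, int]:
    """Lay one gene down at ``offset``; returns the model and its genomic end."""
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons)
    intron_lens = rng.integers(
        cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(0, n_exons - 1)
    )
    exons_genomic = []
    pos = offset
    for i in range(n_exons):
        exons_genomic.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    exons_tx = exons_genomic if strand == "+" else list(reversed(exons_genomic))

    # CDS: geometric extensions push the start/stop away from the gene ends
    k5 = min(int(rng.geometric(1 - cfg.utr5_extension_p) - 1), n_exons - 1)
    k3 = min(int(rng.geometric(1 - cfg.utr3_extension_p) - 1), n_exons - 1 - k5)
    j3 = n_exons - 1 - k3
    ex5, ex3 = exons_tx[k5], exons_tx[j3]
    if k5 == j3:  # CDS within one exon: keep the start 5' of the stop
        d5 = int(rng.integers(3, ex5.length // 2))
        d3 = int(rng.integers(3, max(4, ex5.length - d5 - 4)))
    else:
        d5 = int(rng.integers(3, ex5.length - 3))
        d3 = int(rng.integers(3, ex3.length - 3))
    # transcription -> genomic positions of translation start / last coding base
    if strand == "+":
        tss = ex5.start + d5
        stop = ex3.end - 1 - d3
    else:
        tss = ex5.end - 1 - d5
        stop = ex3.start + d3
    cds_start, cds_end = min(tss, stop), max(tss, stop) + 1
    gene = GeneModel(gene_id, chrom, strand, tuple(exons_tx), cds_start, cds_end)
    return gene, pos


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------


def _eligible_indices(gene: GeneModel, etype: EventType) -> list[int]:
    if etype in INTRON_KINDS:
        return list(range(gene.n_introns))
    if etype is EventType.ES:
        return list(range(1, gene.n_exons - 1))
    return list(range(gene.n_exons))  # NI


def _element_weights(
    gene: GeneModel, etype: EventType, indices: Sequence[int], cfg: GeneratorConfig
) -> np.ndarray:
    from .annotation_io import classify_exon_region, classify_intron_region

    n = gene.n_introns if etype in INTRON_KINDS else gene.n_exons
    slope = cfg.position_bias.get(etype.value, 0.0)
    w = np.array(
        [max(0.1, 1.0 + slope * (relative_position(i, n) - 0.5)) for i in indices]
    )
    bias = (cfg.region_bias or {}).get(etype.value)
    if bias and gene.is_coding:
        for pos, i in enumerate(indices):
            region = (
                classify_intron_region(gene, i)
                if etype in INTRON_KINDS
                else classify_exon_region(gene, i)
            )
            w[pos] *= bias.get(region.value, 1.0)
    return w  # unnormalized: one unit per element, tilted by position/region bias


def _draw_novel_coords(
    gene: GeneModel, etype: EventType, index: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """Novel coordinates for an event, >= MIN_OFFSET from element boundaries."""
    off = MIN_OFFSET
    if etype in INTRON_KINDS:
        gap = derive_introns(gene)[index].interval
        s, e = gap.start, gap.end
        if etype is EventType.IR:
            g = gene.genomic_gap_index(index)
            gex = gene.genomic_exons
            return ((gex[g].start, gex[g + 1].end),)
        if etype is EventType.AA:
            a = int(rng.integers(s + off, e - off + 1))
            return ((s, a) if gene.strand == "+" else (a, e),)
        if etype is EventType.AD:
            d = int(rng.integers(s + off, e - off + 1))
            return ((d, e) if gene.strand == "+" else (s, d),)
        if etype is EventType.ASS:
            a = int(rng.integers(s + off, e - off - 4))
            b = int(rng.integers(a + 4, e - off + 1))
            return ((a, b),)
        # RE: a novel exon strictly inside the intron
        a = int(rng.integers(s + off, e - off - 20))
        b = int(rng.integers(a + 20, e - off + 1))
        return ((a, b),)
    if etype is EventType.ES:
        g = gene.genomic_exon_index(index)
        gex = gene.genomic_exons
        return ((gex[g - 1].end, gex[g + 1].start),)
    # NI: a novel junction strictly inside the exon
    ex = gene.exons[index]
    a = int(rng.integers(ex.start + off, ex.end - off - 20))
    b = int(rng.integers(a + 20, ex.end - off + 1))
    return ((a, b),)


def alt_model_exons(gene: GeneModel, event: PlantedEvent) -> tuple[GenomicInterval, ...]:
    """Exon chain of a transcript model embodying exactly one planted event."""
    gex = list(gene.genomic_exons)
    chrom, strand = gene.chrom, gene.strand
    etype, idx = event.event_type, event.affected_index
    coords = event.novel_coords[0]
    if etype is EventType.IR:
        g = gene.genomic_gap_index(idx)
        merged = GenomicInterval(chrom, gex[g].start, gex[g + 1].end, strand)
        out = gex[:g] + [merged] + gex[g + 2 :]
    elif etype in (EventType.AA, EventType.AD, EventType.ASS):
        g = gene.genomic_gap_index(idx)
        s, e = coords
        out = (
            gex[:g]
            + [
                GenomicInterval(chrom, gex[g].start, s, strand),
                GenomicInterval(chrom, e, gex[g + 1].end, strand),
            ]
            + gex[g + 2 :]
        )
    elif etype is EventType.RE:
        g = gene.genomic_gap_index(idx)
        out = gex[: g + 1] + [GenomicInterval(chrom, *coords, strand)] + gex[g + 1 :]
    elif etype is EventType.ES:
        g = gene.genomic_exon_index(idx)
        out = gex[:g] + gex[g + 1 :]
    else:  # NI
        g = gene.genomic_exon_index(idx)
        ex = gex[g]
        s, e = coords
        out = (
            gex[:g]
            + [
                GenomicInterval(chrom, ex.start, s, strand),
                GenomicInterval(chrom, e, ex.end, strand),
            ]
            + gex[g + 1 :]
        )
    return tuple(out)


def _novel_junction_boundaries(
    gene: GeneModel, event: PlantedEvent
) -> list[tuple[tuple[int, int], str]]:
    """(junction, new-boundary role) pairs whose splice-site motifs must be written."""
    etype, idx = event.event_type, event.affected_index
    coords = event.novel_coords[0]
    if etype is EventType.IR:
        return []
    if etype in (EventType.AA, EventType.AD, EventType.ASS, EventType.NI):
        roles = {
            EventType.AA: ["acceptor"],
            EventType.AD: ["donor"],
            EventType.ASS: ["donor", "acceptor"],
            EventType.NI: ["donor", "acceptor"],
        }[etype]
        return [(coords, r) for r in roles]
    if etype is EventType.RE:
        gap = derive_introns(gene)[idx].interval
        a, b = coords
        j1, j2 = (gap.start, a), (b, gap.end)
        # the inner boundaries are new; their role depends on strand
        if gene.strand == "+":
            return [(j1, "acceptor"), (j2, "donor")]
        return [(j1, "donor"), (j2, "acceptor")]
    return []  # ES reuses reference boundaries


# ---------------------------------------------------------------------------
# Genome sequence with splice-site motifs
# ---------------------------------------------------------------------------


def _set_dinuc(seq: np.ndarray, pos: int, dinuc: str) -> None:
    seq[pos : pos + 2] = np.frombuffer(dinuc.encode(), dtype=np.uint8)


def _write_site(seq: np.ndarray, junction: tuple[int, int], strand: str,
                role: str, donor: str, acceptor: str) -> None:
    s, e = junction
    if role == "donor":
        if strand == "+":
            _set_dinuc(seq, s, donor)
        else:
            _set_dinuc(seq, e - 2, _REVCOMP[donor])
    else:
        if strand == "+":
            _set_dinuc(seq, e - 2, acceptor)
        else:
            _set_dinuc(seq, s, _REVCOMP[acceptor])


def _draw_motif_pair(
    rng: np.random.Generator, canonical_fraction: float, u12_share: float
) -> tuple[str, str]:
    u = rng.random()
    if u < canonical_fraction:
        return "GT", "AG"
    if rng.random() < u12_share:
        return "AT", "AC"
    return _NONCANONICAL_SITES[int(rng.integers(0, len(_NONCANONICAL_SITES)))]


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------


def _plant_species_events(
    genes: Mapping[str, GeneModel],
    gene_ids: Sequence[str],
    props: dict[EventType, float],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    occupied: set,
    species: str,
    rate: float,
) -> list[PlantedEvent]:
    """Plant events uniformly over eligible *elements* across expressed genes.

    The total event count is Poisson(rate x number of expressed genes), split
    over types by the configured proportions; within a type, elements are
    drawn in proportion to their position/region weights, so genes with more
    introns/exons carry proportionally more events. Draws colliding with an
    occupied (gene, type, element) slot are redrawn once, then dropped.
    """
    n_total = int(rng.poisson(rate * len(gene_ids)))
    types = list(props)
    split = rng.multinomial(n_total, np.array([props[t] for t in types]))
    out: list[PlantedEvent] = []
    for etype, n_type in zip(types, split):
        if n_type == 0:
            continue
        elements: list[tuple[str, int]] = []
        weights: list[float] = []
        for gid in gene_ids:
            gene = genes[gid]
            indices = _eligible_indices(gene, etype)
            if not indices:
                continue
            w = _element_weights(gene, etype, indices, cfg)
            elements.extend((gid, i) for i in indices)
            weights.extend(w)
        if not elements:
            raise ValueError(f"no eligible element for {etype.value} events")
        p = np.array(weights)
        p /= p.sum()
        picks = list(rng.choice(len(elements), size=n_type, p=p))
        for _pass in range(2):
            redraw = 0
            for pick in picks:
                gid, idx = elements[int(pick)]
                key = (gid, etype, affected_kind(etype), idx)
                if key in occupied:
                    redraw += 1
                    continue
                occupied.add(key)
                coords = _draw_novel_coords(genes[gid], etype, idx, rng)
                out.append(
                    PlantedEvent(species, gid, etype, affected_kind(etype), idx, coords)
                )
            if redraw == 0:
                break
            picks = list(rng.choice(len(elements), size=redraw, p=p))
    out.sort(key=lambda e: (e.gene_id, e.event_type.value, e.affected_index))
    return out


def _plant_copy(
    gene: GeneModel,
    template: PlantedEvent,
    species: str,
    rng: np.random.Generator,
    occupied: set,
    partner: str,
) -> PlantedEvent | None:
    key = (gene.gene_id, template.event_type, template.affected_kind, template.affected_index)
    if key in occupied:
        return None
    coords = _draw_novel_coords(gene, template.event_type, template.affected_index, rng)
    occupied.add(key)
    return PlantedEvent(
        species,
        gene.gene_id,
        template.event_type,
        template.affected_kind,
        template.affected_index,
        coords,
        conserved_partner=partner,
    )


def simulate(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate the paired annotated genomes, evidence and ground-truth ledger."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    # ---- gene structures and homology -------------------------------------
    a_ids = [f"PvG{i:05d}" for i in range(cfg.n_genes)]
    a_counts = {gid: _draw_exon_count(cfg, rng) for gid in a_ids}
    relations: dict[str, int] = {}
    for gid in a_ids:
        u = rng.random()
        relations[gid] = 2 if u < cfg.frac_one_to_two else (
            1 if u < cfg.frac_one_to_two + cfg.frac_one_to_one else 0
        )
    b_specs: list[tuple[str, int, bool, str | None]] = []  # (id, exons, same_model, gene_a)
    homology: list[HomologyEntry] = []
    same_model_of: dict[str, bool] = {}
    bi = 0
    for gid in a_ids:
        partners = []
        for _copy in range(relations[gid]):
            b_id = f"GmG{bi:05d}"
            bi += 1
            same = bool(rng.random() < cfg.p_same_model)
            n_ex = a_counts[gid] if same else _draw_exon_count(cfg, rng)
            b_specs.append((b_id, n_ex, same, gid))
            same_model_of[b_id] = same
            partners.append(b_id)
        if partners:
            homology.append(HomologyEntry(gid, tuple(partners)))
    for _ in range(int(round(cfg.extra_b_gene_fraction * cfg.n_genes))):
        b_id = f"GmG{bi:05d}"
        bi += 1
        b_specs.append((b_id, _draw_exon_count(cfg, rng), False, None))

    # ---- genome layout -----------------------------------------------------
    def _layout(ids_counts: list[tuple[str, int]], prefix: str):
        genes: dict[str, GeneModel] = {}
        chrom_len: dict[str, int] = {}
        for i, (gid, n_ex) in enumerate(ids_counts):
            chrom = f"{prefix}Chr{i // cfg.genes_per_chrom + 1}"
            offset = chrom_len.get(chrom, 0) + cfg.intergenic_spacer
            strand = "+" if rng.random() < 0.5 else "-"
            gene, end = _build_gene(gid, chrom, offset, n_ex, strand, cfg, rng)
            genes[gid] = gene
            chrom_len[chrom] = end
        chrom_len = {c: l + cfg.intergenic_spacer for c, l in chrom_len.items()}
        return genes, chrom_len

    genes_a, chrom_len_a = _layout([(g, a_counts[g]) for g in a_ids], "Pv")
    genes_b, chrom_len_b = _layout([(gid, n) for gid, n, _s, _a in b_specs], "Gm")

    # ---- expression flags --------------------------------------------------
    expressed_a = {g for g in a_ids if rng.random() < cfg.expressed_fraction}
    expressed_b = {
        gid for gid, _n, _s, _a in b_specs if rng.random() < cfg.expressed_fraction
    }

    # ---- plant events ------------------------------------------------------
    props_a = _normalize_props(cfg.event_proportions_a)
    props_b = _normalize_props(cfg.event_proportions_b)
    occupied: set = set()
    ledger: list[PlantedEvent] = []
    events_a = _plant_species_events(
        genes_a,
        [g for g in a_ids if g in expressed_a],
        props_a,
        cfg,
        rng,
        occupied,
        "A",
        cfg.events_per_gene,
    )
    ledger.extend(events_a)

    partners_of = {e.gene_a: e.genes_b for e in homology}
    q_paralog = cfg.paralog_conservation / (2.0 - cfg.paralog_conservation)
    for ev in events_a:
        p = cfg.conservation_p.get(ev.event_type.value, 0.0)
        if rng.random() >= p:
            continue
        eligible = [
            b
            for b in partners_of.get(ev.gene_id, ())
            if same_model_of.get(b)
            and b in expressed_b
            and genes_b[b].n_exons == genes_a[ev.gene_id].n_exons
        ]
        if not eligible:
            continue
        if len(eligible) == 2 and rng.random() < q_paralog:
            chosen = eligible
        else:
            chosen = [eligible[int(rng.integers(0, len(eligible)))]]
        planted_ids = []
        for b in chosen:
            copy = _plant_copy(genes_b[b], ev, "B", rng, occupied, ev.gene_id)
            if copy is not None:
                if len(chosen) == 2:
                    sibling = chosen[0] if b == chosen[1] else chosen[1]
                    copy.conserved_partner = f"{ev.gene_id}|{sibling}"
                ledger.append(copy)
                planted_ids.append(b)
        if planted_ids:
            ev.conserved_partner = planted_ids[0]

    # independent species-B events (plus paralog sharing among same-model pairs)
    sibling_of: dict[str, str] = {}
    for entry in homology:
        if len(entry.genes_b) == 2:
            b1, b2 = entry.genes_b
            if same_model_of[b1] and same_model_of[b2] and genes_b[b1].n_exons == genes_b[b2].n_exons:
                sibling_of[b1], sibling_of[b2] = b2, b1
    rate_b = cfg.events_per_gene if cfg.events_per_gene_b is None else cfg.events_per_gene_b
    events_b_ind: list[PlantedEvent] = []
    if rate_b > 0:
        events_b_ind = _plant_species_events(
            genes_b,
            [gid for gid, _n, _s, _a in b_specs if gid in expressed_b],
            props_b,
            cfg,
            rng,
            occupied,
            "B",
            rate_b,
        )
    ledger.extend(events_b_ind)
    for ev in events_b_ind:
        sib = sibling_of.get(ev.gene_id)
        if sib is not None and sib in expressed_b and rng.random() < q_paralog:
            copy = _plant_copy(genes_b[sib], ev, "B", rng, occupied, ev.gene_id)
            if copy is not None:
                ev.conserved_partner = sib
                ledger.append(copy)

    # ---- evidence design and channel routing -------------------------------
    samples = {
        f"S{si + 1}": tuple(
            f"S{si + 1}R{ri + 1}" for ri in range(cfg.replicates_per_sample)
        )
        for si in range(cfg.n_samples)
    }
    design = EvidenceDesign(samples, cfg.mappers)
    all_libs = [lib for libs in samples.values() for lib in libs]
    channel_names = sorted(cfg.channel_weights)
    channel_p = np.array([cfg.channel_weights[c] for c in channel_names], dtype=float)
    channel_p /= channel_p.sum()
    half = math.ceil(cfg.replicates_per_sample / 2)
    sample_ids = sorted(samples)
    for ev in ledger:
        if rng.random() < cfg.noise_fraction:
            ev.channel = "noise"
            lib = all_libs[int(rng.integers(0, len(all_libs)))]
            mapper = cfg.mappers[int(rng.integers(0, 2))]
            ev.sources = (EvidenceSource(lib, mapper),)
            continue
        ev.channel = channel_names[int(rng.choice(len(channel_names), p=channel_p))]
        if ev.channel == "est":
            ev.sources = (EST_SOURCE,)
        elif ev.channel == "dual":
            lib = all_libs[int(rng.integers(0, len(all_libs)))]
            ev.sources = (
                EvidenceSource(lib, cfg.mappers[0]),
                EvidenceSource(lib, cfg.mappers[1]),
            )
        else:  # replicate channel
            sample = sample_ids[int(rng.integers(0, len(sample_ids)))]
            mapper = cfg.mappers[int(rng.integers(0, 2))]
            libs = list(samples[sample])
            picks = rng.choice(len(libs), size=half, replace=False)
            ev.sources = tuple(EvidenceSource(libs[i], mapper) for i in sorted(picks))

    # ---- genome sequences with splice-site motifs ---------------------------
    def _genome(genes: Mapping[str, GeneModel], chrom_len: Mapping[str, int],
                ledger_events: Iterable[PlantedEvent]) -> dict[str, str]:
        arrays = {
            c: _BASES[rng.integers(0, 4, size=l + 10)] for c, l in chrom_len.items()
        }
        for gid in genes:
            gene = genes[gid]
            seq = arrays[gene.chrom]
            for intron in derive_introns(gene):
                donor, acceptor = _draw_motif_pair(rng, cfg.canonical_fraction, cfg.u12_share)
                j = (intron.interval.start, intron.interval.end)
                _write_site(seq, j, gene.strand, "donor", donor, acceptor)
                _write_site(seq, j, gene.strand, "acceptor", donor, acceptor)
        for ev in ledger_events:
            gene = genes[ev.gene_id]
            seq = arrays[gene.chrom]
            sites = _novel_junction_boundaries(gene, ev)
            if not sites:
                continue
            donor, acceptor = _draw_motif_pair(
                rng, cfg.novel_canonical_fraction, cfg.u12_share
            )
            for junction, role in sites:
                _write_site(seq, junction, gene.strand, role, donor, acceptor)
        return {c: arrays[c].tobytes().decode() for c in arrays}

    ledger_a = [e for e in ledger if e.species == "A"]
    ledger_b = [e for e in ledger if e.species == "B"]
    genome_a = _genome(genes_a, chrom_len_a, ledger_a)
    genome_b = _genome(genes_b, chrom_len_b, ledger_b)

    # ---- transcript models and expression ----------------------------------
    def _evidence(genes: Mapping[str, GeneModel], expressed: set[str],
                  ledger_events: list[PlantedEvent]):
        base: dict[tuple[str, str], float] = {}
        for gid in genes:
            if gid not in expressed:
                continue
            for lib in all_libs:
                base[(gid, lib)] = cfg.min_fpkm + float(
                    rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sigma)
                )
        models: dict[EvidenceSource, list[TranscriptModel]] = defaultdict(list)
        expr_rows: list[dict] = []
        for lib in all_libs:
            for mapper in cfg.mappers:
                src = EvidenceSource(lib, mapper)
                for gid in genes:
                    if gid not in expressed:
                        continue
                    gene = genes[gid]
                    fpkm = base[(gid, lib)] * float(rng.lognormal(0.0, 0.05))
                    mid = f"{gid}.p.{lib}.{mapper}"
                    m = TranscriptModel(
                        mid, gene.chrom, gene.strand, gene.genomic_exons,
                        gene_id=gid, source=src, fpkm=fpkm,
                    )
                    models[src].append(m)
                    expr_rows.append(
                        {"model_id": mid, "library_id": lib, "mapper_id": mapper,
                         "fpkm": round(fpkm, 6), "length": m.length}
                    )
        for ei, ev in enumerate(ledger_events):
            gene = genes[ev.gene_id]
            exons = alt_model_exons(gene, ev)
            for src in ev.sources:
                tag = "EST" if src.is_est else f"{src.library_id}.{src.mapper_id}"
                mid = f"{ev.gene_id}.e{ei}.{ev.event_type.value}{ev.affected_index}.{tag}"
                fpkm = 0.0
                if not src.is_est:
                    fpkm = cfg.alt_model_fpkm_factor * base[(ev.gene_id, src.library_id)]
                m = TranscriptModel(
                    mid, gene.chrom, gene.strand, exons,
                    gene_id=ev.gene_id, source=src, fpkm=fpkm,
                )
                models[src].append(m)
                if not src.is_est:
                    expr_rows.append(
                        {"model_id": mid, "library_id": src.library_id,
                         "mapper_id": src.mapper_id, "fpkm": round(fpkm, 6),
                         "length": m.length}
                    )
        # EST coverage of primary transcripts
        est_models = models[EST_SOURCE]
        for gid in genes:
            if gid in expressed and rng.random() < cfg.est_primary_coverage:
                gene = genes[gid]
                est_models.append(
                    TranscriptModel(
                        f"{gid}.p.EST", gene.chrom, gene.strand, gene.genomic_exons,
                        gene_id=gid, source=EST_SOURCE,
                    )
                )
        models[EST_SOURCE] = est_models
        expr = pd.DataFrame(
            expr_rows, columns=["model_id", "library_id", "mapper_id", "fpkm", "length"]
        )
        return dict(models), expr

    models_a, expression_a = _evidence(genes_a, expressed_a, ledger_a)
    models_b, expression_b = _evidence(genes_b, expressed_b, ledger_b)

    ds = SimulatedDataset(
        cfg, seed, genes_a, genes_b, genome_a, genome_b, homology, ledger, design,
        expressed_a, expressed_b, models_a, models_b, expression_a, expression_b,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def _normalize_props(props: Mapping[str, float]) -> dict[EventType, float]:
    total = sum(props.values())
    return {EventType(t): props[t] / total for t in sorted(props)}


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def write_ledger(ledger: Sequence[PlantedEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\tgene_id\tevent_type\taffected_kind\taffected_index\t"
            "novel_coords\tchannel\tsources\tconserved_partner\n"
        )
        for e in ledger:
            coords = ";".join(f"{s}-{t}" for s, t in e.novel_coords)
            sources = ";".join(s.label for s in e.sources)
            fh.write(
                f"{e.species}\t{e.gene_id}\t{e.event_type.value}\t{e.affected_kind}\t"
                f"{e.affected_index}\t{coords}\t{e.channel}\t{sources}\t"
                f"{e.conserved_partner or ''}\n"
            )


def read_ledger(path: str) -> list[PlantedEvent]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (species, gid, etype, kind, idx, coords, channel, sources, partner) = (
                line.rstrip("\n").split("\t")
            )
            out.append(
                PlantedEvent(
                    species,
                    gid,
                    EventType(etype),
                    kind,
                    int(idx),
                    tuple(
                        tuple(int(x) for x in c.split("-")) for c in coords.split(";")
                    ),
                    channel,
                    tuple(EvidenceSource.from_label(s) for s in sources.split(";") if s),
                    partner or None,
                )
            )
    return out


def write_design(design: EvidenceDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlibrary_id\tmapper_id\n")
        for sample in sorted(design.samples):
            for lib in design.samples[sample]:
                for mapper in design.mappers:
                    fh.write(f"{sample}\t{lib}\t{mapper}\n")


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the full dataset layout (annotations, genomes, GTFs, tables)."""
    out = Path(out_dir)
    ds.out_dir = out
    for species in ("A", "B"):
        sdir = out / f"species_{species}"
        (sdir / "models").mkdir(parents=True, exist_ok=True)
        genes = ds.genes(species)
        write_annotation(genes, sdir / "annotation.gff3")
        write_fasta(ds.genome_a if species == "A" else ds.genome_b, sdir / "genome.fa")
        for src, models in sorted(
            ds.models(species).items(), key=lambda kv: kv[0].label
        ):
            if src.is_est:
                path = sdir / "est.gtf"
            else:
                path = sdir / "models" / f"{src.library_id}__{src.mapper_id}.gtf"
            write_models(models, path)
        expr = ds.expression_a if species == "A" else ds.expression_b
        expr.to_csv(sdir / "expression.tsv", sep="\t", index=False)
        write_design(ds.design, sdir / "design.tsv")
    write_homology(ds.homology, out / "homology.tsv")
    write_ledger(ds.ledger, out / "ledger.tsv")
    ds.config.to_yaml(out / "config.yaml")
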