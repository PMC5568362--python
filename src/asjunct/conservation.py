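"""Cross-species and paralog conservation of alternative-splicing events.

Conservation uses a junction approach: an event is conserved when a homolog
carries an event of the same type on the same ordinal intron/exon, regardless
of exact coordinates. Index matching is only meaningful between genes with
the same gene model (equal exon counts), so the homolog universe enforces
that, plus expression in at least one sample, before any comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneModel
from .event_caller import ASEvent, EventType


@dataclass(frozen=True)
class HomologyEntry:
    """One species-A gene with its one (1:1) or two (1:2) species-B homologs."""

    gene_a: str
    genes_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.genes_b) <= 2:
            raise ValueError(f"{self.gene_a}: homology entries carry 1 or 2 B genes")
        if len(set(self.genes_b)) != len(self.genes_b):
            raise ValueError(f"{self.gene_a}: duplicated homolog ids")


def read_homology(path: str) -> list[HomologyEntry]:
    """Read a homology TSV: gene_a <tab> gene_b1 [<tab> gene_b2]."""
    entries = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError("homology table must start with a gene_a header")
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p]
            entries.append(HomologyEntry(parts[0], tuple(parts[1:])))
    return entries


def write_homology(entries: Sequence[HomologyEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b1\tgene_b2\n")
        for e in entries:
            b = list(e.genes_b) + [""] * (2 - len(e.genes_b))
            fh.write(f"{e.gene_a}\t{b[0]}\t{b[1]}\n")


@dataclass
class ConservationUniverse:
    """Homolog pairs/triples eligible for junction-based matching."""

    pairs: list[HomologyEntry]

    @property
    def a_partners(self) -> dict[str, tuple[str, ...]]:
        return {e.gene_a: e.genes_b for e in self.pairs}

    @property
    def b_partners(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, tuple[str, ...]] = defaultdict(tuple)
        for e in self.pairs:
            for b in e.genes_b:
                out[b] = out[b] + (e.gene_a,)
        return dict(out)

    @property
    def paralog_pairs(self) -> list[tuple[str, str]]:
        return [tuple(e.genes_b) for e in self.pairs if len(e.genes_b) == 2]


def build_universe(
    homology: Iterable[HomologyEntry],
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
    expressed_a: set[str],
    expressed_b: set[str],
) -> ConservationUniverse:
    """Filter homology entries to expressed, same-gene-model pairs.

    1:2 entries are kept as such only when the A gene and both B copies are
    expressed with equal exon counts; entries where exactly one copy
    qualifies demote to 1:1; entries with no qualifying copy are dropped.
    """
    kept = []
    for entry in homology:
        if entry.gene_a not in genes_a:
            raise KeyError(f"unknown species-A gene {entry.gene_a} in homology table")
        for b in entry.genes_b:
            if b not in genes_b:
                raise KeyError(f"unknown species-B gene {b} in homology table")
        if entry.gene_a not in expressed_a:
            continue
        n_exons = genes_a[entry.gene_a].n_exons
        qualifying = tuple(
            b
            for b in entry.genes_b
            if b in expressed_b and genes_b[b].n_exons == n_exons
        )
        if qualifying:
            kept.append(HomologyEntry(entry.gene_a, qualifying))
    return ConservationUniverse(kept)


# ---------------------------------------------------------------------------
# Conservation scoring
# ---------------------------------------------------------------------------


@dataclass
class TypeStats:
    """Counts and conservation rates for one event type (or overall)."""

    n_total: int = 0
    n_in_universe: int = 0
    n_conserved: int = 0

    @property
    def rate_max(self) -> float:
        return self.n_conserved / self.n_in_universe if self.n_in_universe else float("nan")

    @property
    def rate_min(self) -> float:
        return self.n_conserved / self.n_total if self.n_total else float("nan")


@dataclass
class ConservationResult:
    per_type: dict[EventType, TypeStats]
    overall: TypeStats

    def to_frame(self, direction: str = "") -> pd.DataFrame:
        rows = []
        for name, st in [("overall", self.overall)] + [
            (t.value, s) for t, s in sorted(self.per_type.items(), key=lambda kv: kv[0].value)
        ]:
            rows.append(
                {
                    "direction": direction,
                    "type": name,
                    "n_total": st.n_total,
                    "n_in_universe": st.n_in_universe,
                    "n_conserved": st.n_conserved,
                    "rate_max": st.rate_max,
                    "rate_min": st.rate_min,
                }
            )
        return pd.DataFrame(rows)


def event_keys(events: Iterable[ASEvent]) -> set[tuple[str, EventType, str, int]]:
    return {e.key for e in events}


def _validate_indices(events: Iterable[ASEvent], genes: Mapping[str, GeneModel]) -> None:
    for e in events:
        gene = genes.get(e.gene_id)
        if gene is None:
            continue
        bound = gene.n_introns if e.affected_kind == "intron" else gene.n_exons
        if e.affected_index >= bound:
            raise ValueError(
                f"event {e.event_type.value}@{e.gene_id} index {e.affected_index} "
                f"exceeds {e.affected_kind} count {bound}"
            )


def conserved_events(
    events_src: Sequence[ASEvent],
    events_tgt: Sequence[ASEvent],
    partner_map: Mapping[str, tuple[str, ...]],
    genes_src: Mapping[str, GeneModel] | None = None,
    require_both: bool = False,
) -> ConservationResult:
    """Score junction conservation of source events in target homologs.

    ``partner_map`` maps a source gene to its target homolog(s) as retained
    in the universe (use ``universe.a_partners`` or ``universe.b_partners``
    depending on direction). A source event counts as conserved when at least
    one homolog (all homologs with ``require_both``) carries a non-redundant
    event with the same type and ordinal element index.
    """
    if genes_src is not None:
        _validate_indices(events_src, genes_src)
    tgt = event_keys(events_tgt)
    per_type: dict[EventType, TypeStats] = defaultdict(TypeStats)
    overall = TypeStats()
    for e in events_src:
        st = per_type[e.event_type]
        st.n_total += 1
        overall.n_total += 1
        partners = partner_map.get(e.gene_id)
        if not partners:
            continue
        st.n_in_universe += 1
        overall.n_in_universe += 1
        matches = [
            (p, e.event_type, e.affected_kind, e.affected_index) in tgt for p in partners
        ]
        hit = all(matches) if require_both else any(matches)
        if hit:
            st.n_conserved += 1
            overall.n_conserved += 1
    return ConservationResult(dict(per_type), overall)


def paralog_conservation(
    events_b: Sequence[ASEvent], paralog_pairs: Sequence[tuple[str, str]]
) -> ConservationResult:
    """Conservation between species-B paralog copies (1:2 entries).

    Scored symmetrically over the union of both paralogs' events: an event in
    one copy is conserved iff the sibling copy carries the same type at the
    same element index.
    """
    sibling: dict[str, str] = {}
    for b1, b2 in paralog_pairs:
        sibling[b1] = b2
        sibling[b2] = b1
    keys = event_keys(events_b)
    per_type: dict[EventType, TypeStats] = defaultdict(TypeStats)
    overall = TypeStats()
    for e in events_b:
        st = per_type[e.event_type]
        st.n_total += 1
        overall.n_total += 1
        partner = sibling.get(e.gene_id)
        if partner is None:
            continue
        st.n_in_universe += 1
        overall.n_in_universe += 1
        if (partner, e.event_type, e.affected_kind, e.affected_index) in keys:
            st.n_conserved += 1
            overall.n_conserved += 1
    return ConservationResult(dict(per_type), overall)
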