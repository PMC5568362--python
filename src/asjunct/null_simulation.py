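"""Randomization null models for AS-event conservation.

Four schemes probe whether observed conservation exceeds chance:

- ``random_events``: every source event keeps its type but is reassigned to a
  uniformly random eligible element across all expressed source genes;
  homology is untouched.
- ``random_genes``: homolog assignments are permuted over expressed target
  genes; events stay put and the equal-exon-count constraint is dropped.
- ``random_genes_same_model``: as above, but each slot is refilled by a
  target gene with the same exon count as the original partner.
- ``random_genes_random_events``: gene permutation followed by event
  reassignment.

Per-type event multiset sizes are preserved by every scheme. Replicates are
seeded deterministically from (seed, replicate).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneModel
from .conservation import ConservationUniverse
from .event_caller import ASEvent, EventType, INTRON_KINDS, affected_kind

EventKey = tuple[str, EventType, str, int]


class Scheme(str, Enum):
    RANDOM_EVENTS = "random_events"
    RANDOM_GENES = "random_genes"
    RANDOM_GENES_SAME_MODEL = "random_genes_same_model"
    RANDOM_GENES_RANDOM_EVENTS = "random_genes_random_events"


# ---------------------------------------------------------------------------
# Element pools
# ---------------------------------------------------------------------------


class ElementPools:
    """Flat, uniformly samplable pools of introns/exons of expressed genes."""

    def __init__(self, genes: Mapping[str, GeneModel], expressed: set[str]):
        def _build(counts: list[tuple[str, int]]):
            names = [g for g, c in counts if c > 0]
            sizes = np.array([c for _g, c in counts if c > 0], dtype=np.int64)
            return names, sizes, np.cumsum(sizes)

        gids = sorted(g for g in genes if g in expressed)
        self.introns = _build([(g, genes[g].n_introns) for g in gids])
        self.exons_all = _build([(g, genes[g].n_exons) for g in gids])
        self.exons_multi = _build(
            [(g, genes[g].n_exons) for g in gids if genes[g].n_exons > 1]
        )

    @staticmethod
    def sample(pool, rng: np.random.Generator, size: int) -> list[tuple[str, int]]:
        names, sizes, cum = pool
        if len(names) == 0:
            raise ValueError("no eligible elements to sample from")
        flat = rng.integers(0, cum[-1], size=size)
        gi = np.searchsorted(cum, flat, side="right")
        offs = flat - (cum[gi] - sizes[gi])
        return [(names[i], int(o)) for i, o in zip(gi, offs)]


def _pool_for(event_type: EventType, pools: ElementPools):
    if event_type in INTRON_KINDS:
        return pools.introns
    if event_type is EventType.ES:
        return pools.exons_multi
    return pools.exons_all  # NI


def randomize_events(
    keys: Sequence[EventKey],
    pools: ElementPools,
    rng: np.random.Generator,
    genes: Mapping[str, GeneModel] | None = None,
    within_gene: bool = False,
) -> set[EventKey]:
    """Reassign each event to a random eligible element (sampled with
    replacement); events landing on the same element collapse as redundant.

    ``within_gene=True`` keeps each event's gene and only redraws its element
    index — the stricter reading of "shuffling events".
    """
    out: set[EventKey] = set()
    if within_gene:
        if genes is None:
            raise ValueError("within_gene reassignment needs the gene models")
        for gene_id, etype, kind, _idx in keys:
            n = genes[gene_id].n_introns if kind == "intron" else genes[gene_id].n_exons
            if n == 0:
                raise ValueError(f"{gene_id}: no eligible element for {etype.value}")
            out.add((gene_id, etype, kind, int(rng.integers(0, n))))
        return out
    by_type: dict[EventType, int] = Counter(k[1] for k in keys)
    for etype in sorted(by_type, key=lambda t: t.value):
        kind = affected_kind(etype)
        for gene_id, idx in ElementPools.sample(_pool_for(etype, pools), rng, by_type[etype]):
            out.add((gene_id, etype, kind, idx))
    return out


def randomize_genes(
    universe: ConservationUniverse,
    genes_tgt: Mapping[str, GeneModel],
    expressed_tgt: set[str],
    rng: np.random.Generator,
    same_model: bool = False,
) -> dict[str, tuple[str, ...]]:
    """Permute homolog partners over expressed target genes (without replacement)."""
    slots: list[tuple[str, int, str]] = []  # (gene_a, slot position, original partner)
    for entry in universe.pairs:
        for pos, b in enumerate(entry.genes_b):
            slots.append((entry.gene_a, pos, b))
    new_partners: dict[str, list[str | None]] = {
        e.gene_a: [None] * len(e.genes_b) for e in universe.pairs
    }
    if same_model:
        by_count: dict[int, list[tuple[str, int]]] = defaultdict(list)
        for a, pos, b in slots:
            by_count[genes_tgt[b].n_exons].append((a, pos))
        pool_by_count: dict[int, list[str]] = defaultdict(list)
        for b in sorted(expressed_tgt):
            if b in genes_tgt:
                pool_by_count[genes_tgt[b].n_exons].append(b)
        for count, slot_list in by_count.items():
            pool = pool_by_count[count]
            if len(pool) < len(slot_list):
                raise ValueError(f"not enough expressed target genes with {count} exons")
            picks = rng.choice(len(pool), size=len(slot_list), replace=False)
            for (a, pos), pi in zip(slot_list, picks):
                new_partners[a][pos] = pool[pi]
    else:
        pool = sorted(b for b in expressed_tgt if b in genes_tgt)
        if len(pool) < len(slots):
            raise ValueError("not enough expressed target genes to permute over")
        picks = rng.choice(len(pool), size=len(slots), replace=False)
        for (a, pos, _b), pi in zip(slots, picks):
            new_partners[a][pos] = pool[pi]
    return {a: tuple(v) for a, v in new_partners.items()}


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Per-replicate conservation percentages under one randomization scheme.

    Percentages are over *all* source non-redundant events (the constant
    denominator), so replicates are comparable across schemes.
    """

    scheme: Scheme
    n_reps: int
    seed: int
    percents: dict[str, np.ndarray]  # "overall" and each EventType value

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.percents.items():
            sd = float(np.std(arr, ddof=1)) if self.n_reps > 1 else 0.0
            rows.append(
                {
                    "scheme": self.scheme.value,
                    "type": name,
                    "n_reps": self.n_reps,
                    "mean": float(np.mean(arr)),
                    "sd": sd,
                    "sd_defined": self.n_reps > 1,
                    "min": float(np.min(arr)),
                    "max": float(np.max(arr)),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.percents.items():
            for r, v in enumerate(arr):
                rows.append(
                    {"scheme": self.scheme.value, "replicate": r, "type": name, "percent": v}
                )
        return pd.DataFrame(rows)


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """One-sided (1 + #{null >= observed}) / (1 + n) empirical p-value."""
    return (1.0 + int(np.sum(null_values >= observed))) / (1.0 + len(null_values))


def _score(
    src_keys: Sequence[EventKey] | set[EventKey],
    tgt_keys: set[tuple],
    partner_map: Mapping[str, tuple[str, ...]],
    totals: Mapping[EventType, int],
) -> dict[str, float]:
    conserved: Counter = Counter()
    for gene_id, etype, kind, idx in src_keys:
        partners = partner_map.get(gene_id)
        if not partners:
            continue
        if any((p, etype, kind, idx) in tgt_keys for p in partners):
            conserved[etype] += 1
    out = {"overall": 100.0 * sum(conserved.values()) / max(1, sum(totals.values()))}
    for etype, n in totals.items():
        out[etype.value] = 100.0 * conserved[etype] / n if n else 0.0
    return out


def run_null(
    scheme: Scheme,
    n_reps: int,
    seed: int,
    events_src: Sequence[ASEvent],
    events_tgt: Sequence[ASEvent],
    universe: ConservationUniverse,
    genes_src: Mapping[str, GeneModel],
    expressed_src: set[str],
    genes_tgt: Mapping[str, GeneModel],
    expressed_tgt: set[str],
    within_gene: bool = False,
) -> NullDistribution:
    """Monte-Carlo null distribution of conservation percentages."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scheme = Scheme(scheme)
    src_keys = [e.key for e in events_src]
    tgt_keys = {e.key for e in events_tgt}
    totals = Counter(k[1] for k in src_keys)
    pools = ElementPools(genes_src, expressed_src)
    observed_map = universe.a_partners
    names = ["overall"] + [t.value for t in sorted(totals, key=lambda t: t.value)]
    percents = {name: np.empty(n_reps) for name in names}
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        partner_map: Mapping[str, tuple[str, ...]] = observed_map
        keys: Sequence[EventKey] | set[EventKey] = src_keys
        if scheme in (Scheme.RANDOM_GENES, Scheme.RANDOM_GENES_SAME_MODEL, Scheme.RANDOM_GENES_RANDOM_EVENTS):
            partner_map = randomize_genes(
                universe,
                genes_tgt,
                expressed_tgt,
                rng,
                same_model=scheme is Scheme.RANDOM_GENES_SAME_MODEL,
            )
        if scheme in (Scheme.RANDOM_EVENTS, Scheme.RANDOM_GENES_RANDOM_EVENTS):
            keys = randomize_events(src_keys, pools, rng, genes_src, within_gene)
        scores = _score(keys, tgt_keys, partner_map, totals)
        for name in names:
            percents[name][rep] = scores[name]
    return NullDistribution(scheme, n_reps, seed, percents)
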