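"""Where in the gene do AS events fall: UTR/CDS region composition of the
affected introns/exons versus the genome background, and linear modeling of
event density against relative element position."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    ExonRegionType,
    GeneModel,
    IntronRegionType,
    classify_exon_region,
    classify_intron_region,
)
from .event_caller import ASEvent, EventType, INTRON_KINDS

INTRON_REGIONS = [r.value for r in IntronRegionType]
EXON_REGIONS = [r.value for r in ExonRegionType]


def _percent_row(counts: Counter, labels: Sequence[str]) -> dict[str, float]:
    total = sum(counts.values())
    return {lab: (100.0 * counts[lab] / total if total else 0.0) for lab in labels}


def region_composition(
    events: Iterable[ASEvent],
    genes: Mapping[str, GeneModel],
    background_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-type region composition of AS-affected elements plus background.

    Intron-kind events are classified by the affected intron's region type,
    exon-kind events by the affected exon's. The background rows give the
    region distribution of all introns/exons of the (coding) genes listed in
    ``background_genes`` (default: all coding genes). Events in non-coding
    genes are skipped. Enrichment is reported as observed minus background
    percentage.
    """
    per_type: dict[EventType, Counter] = defaultdict(Counter)
    for ev in events:
        gene = genes[ev.gene_id]
        if not gene.is_coding:
            continue
        if ev.affected_kind == "intron":
            region = classify_intron_region(gene, ev.affected_index)
        else:
            region = classify_exon_region(gene, ev.affected_index)
        per_type[ev.event_type][region.value] += 1

    bg_ids = list(background_genes) if background_genes is not None else list(genes)
    bg_introns: Counter = Counter()
    bg_exons: Counter = Counter()
    for gid in bg_ids:
        gene = genes[gid]
        if not gene.is_coding:
            continue
        for i in range(gene.n_introns):
            bg_introns[classify_intron_region(gene, i).value] += 1
        for i in range(gene.n_exons):
            bg_exons[classify_exon_region(gene, i).value] += 1

    rows = []
    for etype in sorted(per_type, key=lambda t: t.value):
        labels = INTRON_REGIONS if etype in INTRON_KINDS else EXON_REGIONS
        bg = bg_introns if etype in INTRON_KINDS else bg_exons
        obs = _percent_row(per_type[etype], labels)
        back = _percent_row(bg, labels)
        for lab in labels:
            rows.append(
                {
                    "type": etype.value,
                    "region": lab,
                    "n": per_type[etype][lab],
                    "percent": obs[lab],
                    "background_percent": back[lab],
                    "enrichment": obs[lab] - back[lab],
                }
            )
    for name, bg, labels in (
        ("background_intron", bg_introns, INTRON_REGIONS),
        ("background_exon", bg_exons, EXON_REGIONS),
    ):
        back = _percent_row(bg, labels)
        for lab in labels:
            rows.append(
                {
                    "type": name,
                    "region": lab,
                    "n": bg[lab],
                    "percent": back[lab],
                    "background_percent": back[lab],
                    "enrichment": 0.0,
                }
            )
    return pd.DataFrame(rows)


def relative_position(index: int, n_elements: int) -> float:
    """Relative gene position of element ``index``: 0 = 5'-most, 1 = terminal."""
    if not 0 <= index < n_elements:
        raise ValueError(f"element index {index} out of range for {n_elements}")
    if n_elements == 1:
        return 0.0
    return index / (n_elements - 1)


def event_relative_position(event: ASEvent, genes: Mapping[str, GeneModel]) -> float:
    gene = genes[event.gene_id]
    n = gene.n_introns if event.affected_kind == "intron" else gene.n_exons
    return relative_position(event.affected_index, n)


@dataclass
class LinearFit:
    """OLS of per-bin affected percentage on bin-midpoint relative position."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n_bins_used: int
    flagged: bool = False


def position_fit(
    positions: Sequence[float],
    n_bins: int = 20,
    element_positions: Sequence[float] | None = None,
) -> LinearFit:
    """Bin relative positions and fit a simple linear model of percentage on
    bin midpoint.

    With ``element_positions`` (the relative positions of *all* eligible
    introns/exons), each bin's percentage is the fraction of its elements
    affected by AS — the availability-normalized reading, under which
    placement that is uniform per element is flat. Without it, percentages
    are the raw distribution of the events over bins (summing to 100).
    Bins with nothing to normalize by (or, in raw mode, no events) are
    dropped rather than zero-filled. Fewer than three distinct positions
    leave the fit undefined (returned flagged, with NaN coefficients).
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) == 0 or len(np.unique(pos)) < 3:
        return LinearFit(np.nan, np.nan, np.nan, np.nan, 0, flagged=True)
    counts, edges = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    mids = (edges[:-1] + edges[1:]) / 2.0
    if element_positions is not None:
        denom, _ = np.histogram(
            np.asarray(element_positions, dtype=float), bins=n_bins, range=(0.0, 1.0)
        )
        mask = denom > 0
        percent = 100.0 * counts[mask] / denom[mask]
    else:
        mask = counts > 0
        percent = 100.0 * counts[mask] / counts.sum()
    if mask.sum() < 3:
        return LinearFit(np.nan, np.nan, np.nan, np.nan, int(mask.sum()), flagged=True)
    fit = stats.linregress(mids[mask], percent)
    return LinearFit(
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
        int(mask.sum()),
    )


def element_positions(
    genes: Mapping[str, GeneModel],
    event_type: EventType,
    gene_ids: Iterable[str] | None = None,
) -> list[float]:
    """Relative positions of every element eligible for one event type."""
    ids = gene_ids if gene_ids is not None else genes.keys()
    out: list[float] = []
    for gid in ids:
        gene = genes[gid]
        if event_type in INTRON_KINDS:
            out.extend(relative_position(i, gene.n_introns) for i in range(gene.n_introns))
        elif event_type is EventType.ES:
            out.extend(
                relative_position(i, gene.n_exons) for i in range(1, gene.n_exons - 1)
            )
        else:  # NI
            out.extend(relative_position(i, gene.n_exons) for i in range(gene.n_exons))
    return out


def fit_all_types(
    events: Iterable[ASEvent],
    genes: Mapping[str, GeneModel],
    n_bins: int = 20,
    gene_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-type availability-normalized position fits as a tidy frame.

    ``gene_ids`` restricts the element availability background (typically the
    expressed genes); by default all genes count.
    """
    ids = list(gene_ids) if gene_ids is not None else list(genes)
    by_type: dict[EventType, list[float]] = defaultdict(list)
    for ev in events:
        by_type[ev.event_type].append(event_relative_position(ev, genes))
    rows = []
    for etype in sorted(by_type, key=lambda t: t.value):
        fit = position_fit(by_type[etype], n_bins, element_positions(genes, etype, ids))
        rows.append(
            {
                "type": etype.value,
                "n_events": len(by_type[etype]),
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "p_value": fit.p_value,
                "n_bins_used": fit.n_bins_used,
                "flagged": fit.flagged,
            }
        )
    return pd.DataFrame(rows)
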