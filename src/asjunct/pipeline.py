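"""End-to-end orchestration: annotation -> events -> expression -> collapse ->
conservation -> null models -> characterization, with deterministic seeding
and a machine-readable run manifest.

The pipeline consumes the on-disk dataset layout written by
:func:`asjunct.synthetic_data.write_dataset` (or an equivalently organised
real dataset): per-species ``annotation.gff3``, ``genome.fa`` (optional),
``models/<library>__<mapper>.gtf``, ``est.gtf``, ``expression.tsv`` and
``design.tsv``, plus a top-level ``homology.tsv``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import characterization as charac
from . import conservation as cons
from . import expression as expr
from .annotation_io import GeneModel, filter_chimeric_models, read_annotation, read_models
from .event_caller import (
    ASEvent,
    EST_SOURCE,
    EventType,
    EvidenceDesign,
    MotifClass,
    call_events,
    collapse_redundant,
    filter_events_by_evidence,
    gene_intron_motifs,
    read_design,
)
from .null_simulation import NullDistribution, Scheme, empirical_p, run_null

logger = logging.getLogger(__name__)

ALL_SCHEMES = tuple(s.value for s in Scheme)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    data_dir: str
    out_dir: str
    seed: int = 0
    n_reps: int = 1000
    schemes: tuple[str, ...] = ALL_SCHEMES
    n_bins: int = 20
    require_both_homologs: bool = False
    within_gene_events: bool = False
    use_genome: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        return cfg

    def __post_init__(self) -> None:
        self.schemes = tuple(self.schemes)
        unknown = set(self.schemes) - set(ALL_SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")


@dataclass
class SpeciesResult:
    """Per-species stage outputs."""

    genes: dict[str, GeneModel]
    design: EvidenceDesign
    events_called: list[ASEvent]
    events_accepted: list[ASEvent]
    events_nonredundant: list[ASEvent]
    gene_expression: pd.DataFrame
    expressed: set[str]
    n_models_kept: int
    n_models_rejected: int
    reference_motifs: dict[str, int] = field(default_factory=dict)


def _load_genome(path: Path):
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=False, sequence_always_upper=True)


def run_species(species_dir: str | Path, use_genome: bool = True) -> SpeciesResult:
    """Run annotation loading, chimera filtering, event calling, the evidence
    filter, redundancy collapsing and expression for one species directory."""
    sdir = Path(species_dir)
    genes = read_annotation(sdir / "annotation.gff3")
    design = read_design(sdir / "design.tsv")

    from .annotation_io import EvidenceSource

    models = []
    for sample in sorted(design.samples):
        for lib in design.samples[sample]:
            for mapper in design.mappers:
                path = sdir / "models" / f"{lib}__{mapper}.gtf"
                if path.exists():
                    models.extend(read_models(path, EvidenceSource(lib, mapper)))
    est_path = sdir / "est.gtf"
    if est_path.exists():
        models.extend(read_models(est_path, EST_SOURCE))

    kept, rejected = filter_chimeric_models(models, genes)
    genome = None
    genome_path = sdir / "genome.fa"
    if use_genome and genome_path.exists():
        genome = _load_genome(genome_path)

    events_called = call_events(kept, genes, genome=genome)
    events_accepted = filter_events_by_evidence(events_called, design)
    events_nonredundant = collapse_redundant(events_accepted)

    expression_table = expr.read_expression_table(sdir / "expression.tsv")
    model_gene = {m.model_id: m.gene_id for m in kept}
    primary_lengths = {g: sum(e.length for e in genes[g].exons) for g in genes}
    gene_expression = expr.compute_gene_expression(
        expression_table, model_gene, primary_lengths, design
    )
    expressed = expr.expressed_genes(gene_expression)

    reference_motifs: dict[str, int] = {m.value: 0 for m in MotifClass}
    if genome is not None:
        for gene in genes.values():
            for motif in gene_intron_motifs(gene, genome):
                reference_motifs[motif.value] += 1

    return SpeciesResult(
        genes,
        design,
        events_called,
        events_accepted,
        events_nonredundant,
        gene_expression,
        expressed,
        len(kept),
        len(rejected),
        reference_motifs,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_events(events: Sequence[ASEvent], path: str | Path, accepted: set | None = None) -> None:
    """Events TSV: gene, type, element, coordinates (1-based inclusive), motif,
    evidence count and acceptance flag."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttype\taffected_kind\taffected_index\tnovel_coords\tmotif\t"
            "n_sources\taccepted\n"
        )
        for e in events:
            coords = ";".join(f"{s + 1}-{t}" for s, t in e.novel_coords)
            ok = "1" if accepted is None or id(e) in accepted else "0"
            fh.write(
                f"{e.gene_id}\t{e.event_type.value}\t{e.affected_kind}\t"
                f"{e.affected_index}\t{coords}\t{e.motif.value if e.motif else ''}\t"
                f"{len(e.evidence)}\t{ok}\n"
            )


def event_type_counts(events: Iterable[ASEvent]) -> pd.DataFrame:
    counts: dict[str, int] = {t.value: 0 for t in EventType}
    for e in events:
        counts[e.event_type.value] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        [
            {"type": t, "n_events": n, "percent": 100.0 * n / total if total else 0.0}
            for t, n in counts.items()
        ]
    )


def compute_gene_level_summary(
    events: Sequence[ASEvent], expressed: set[str], gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-type and overall counts of genes carrying >= 1 event, with
    percentages over all genes and over expressed genes."""
    n_genes = len(gene_ids)
    n_expressed = len(expressed)
    by_type: dict[str, set[str]] = {t.value: set() for t in EventType}
    overall: set[str] = set()
    for e in events:
        by_type[e.event_type.value].add(e.gene_id)
        overall.add(e.gene_id)
    rows = []
    for name, gset in list(by_type.items()) + [("overall", overall)]:
        n = len(gset)
        n_expr = len(gset & expressed)
        rows.append(
            {
                "type": name,
                "n_genes": n,
                "pct_all_genes": 100.0 * n / n_genes if n_genes else 0.0,
                "pct_expressed_genes": 100.0 * n_expr / n_expressed if n_expressed else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the summary report."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: dict[str, SpeciesResult] = {}
    for species in ("A", "B"):
        sdir = data / f"species_{species}"
        logger.info("stage species_%s: calling events", species)
        res = run_species(sdir, use_genome=config.use_genome)
        results[species] = res
        accepted_ids = {id(e) for e in res.events_accepted}
        write_events(res.events_called, out / f"events_{species}.tsv", accepted_ids)
        write_events(res.events_nonredundant, out / f"events_nonredundant_{species}.tsv")
        res.gene_expression.to_csv(out / f"expression_{species}.tsv", sep="\t", index=False)

    res_a, res_b = results["A"], results["B"]
    homology = cons.read_homology(data / "homology.tsv")
    universe = cons.build_universe(
        homology, res_a.genes, res_b.genes, res_a.expressed, res_b.expressed
    )
    conservation_ab = cons.conserved_events(
        res_a.events_nonredundant,
        res_b.events_nonredundant,
        universe.a_partners,
        genes_src=res_a.genes,
        require_both=config.require_both_homologs,
    )
    conservation_ba = cons.conserved_events(
        res_b.events_nonredundant,
        res_a.events_nonredundant,
        universe.b_partners,
        genes_src=res_b.genes,
        require_both=False,
    )
    paralog = cons.paralog_conservation(res_b.events_nonredundant, universe.paralog_pairs)
    conservation_frame = pd.concat(
        [
            conservation_ab.to_frame("A_in_B"),
            conservation_ba.to_frame("B_in_A"),
            paralog.to_frame("paralog_B"),
        ],
        ignore_index=True,
    )
    conservation_frame.to_csv(out / "conservation.tsv", sep="\t", index=False)

    # null models (A -> B direction)
    nulls: dict[str, NullDistribution] = {}
    null_rows = []
    for si, scheme in enumerate(config.schemes):
        if config.n_reps < 1:
            break
        logger.info("stage null %s: %d replicates", scheme, config.n_reps)
        nd = run_null(
            Scheme(scheme),
            config.n_reps,
            config.seed + si + 1,
            res_a.events_nonredundant,
            res_b.events_nonredundant,
            universe,
            res_a.genes,
            res_a.expressed,
            res_b.genes,
            res_b.expressed,
            within_gene=config.within_gene_events,
        )
        nulls[scheme] = nd
        nd.to_frame().to_csv(out / f"null_{scheme}.tsv", sep="\t", index=False)
        summ = nd.summary()
        observed_pct = 100.0 * conservation_ab.overall.rate_min
        summ["observed_overall"] = observed_pct
        summ["empirical_p_overall"] = empirical_p(observed_pct, nd.percents["overall"])
        null_rows.append(summ)
    if null_rows:
        pd.concat(null_rows, ignore_index=True).to_csv(
            out / "null_summary.tsv", sep="\t", index=False
        )

    # characterization
    summary: dict = {"seed": config.seed, "species": {}}
    for species, res in results.items():
        coding_expressed = [
            g for g in res.genes if res.genes[g].is_coding and g in res.expressed
        ]
        composition = charac.region_composition(
            res.events_nonredundant, res.genes, coding_expressed
        )
        composition.to_csv(out / f"composition_{species}.tsv", sep="\t", index=False)
        fits = charac.fit_all_types(res.events_nonredundant, res.genes, config.n_bins)
        fits.to_csv(out / f"fits_{species}.tsv", sep="\t", index=False)
        gene_summary = compute_gene_level_summary(
            res.events_nonredundant, res.expressed, list(res.genes)
        )
        gene_summary.to_csv(out / f"gene_summary_{species}.tsv", sep="\t", index=False)
        type_counts = event_type_counts(res.events_nonredundant)
        type_counts.to_csv(out / f"event_type_counts_{species}.tsv", sep="\t", index=False)
        summary["species"][species] = {
            "n_genes": len(res.genes),
            "n_expressed": len(res.expressed),
            "n_models_kept": res.n_models_kept,
            "n_models_rejected": res.n_models_rejected,
            "n_events_called": len(res.events_called),
            "n_events_accepted": len(res.events_accepted),
            "n_events_nonredundant": len(res.events_nonredundant),
            "event_type_percent": dict(
                zip(type_counts["type"], type_counts["percent"])
            ),
            "reference_motif_counts": res.reference_motifs,
            "pct_expressed_genes_with_AS": float(
                gene_summary.loc[gene_summary["type"] == "overall", "pct_expressed_genes"].iloc[0]
            ),
        }
    summary["conservation"] = {
        "A_in_B": {
            "rate_max": conservation_ab.overall.rate_max,
            "rate_min": conservation_ab.overall.rate_min,
        },
        "B_in_A": {
            "rate_max": conservation_ba.overall.rate_max,
            "rate_min": conservation_ba.overall.rate_min,
        },
        "paralog_B": {"rate_max": paralog.overall.rate_max},
        "n_universe_pairs": len(universe.pairs),
    }
    summary["null_means"] = {
        scheme: float(nd.percents["overall"].mean()) for scheme, nd in nulls.items()
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {
            str(p.relative_to(data)): _sha256(p)
            for p in sorted(data.rglob("*"))
            if p.is_file() and p.suffix != ".fai"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
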