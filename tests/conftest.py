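import pytest

from asjunct.annotation_io import GeneModel, GenomicInterval
from asjunct.event_caller import call_events, collapse_redundant, filter_events_by_evidence
from asjunct.expression import compute_gene_expression, expressed_genes
from asjunct.synthetic_data import GeneratorConfig, SimulatedDataset, simulate


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exons=((0, 100), (200, 300), (400, 500)),
    cds=None,
):
    """Construct a GeneModel from genomic exon tuples (transcription-ordered per strand)."""
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons)]
    if strand == "-":
        ivs.reverse()
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(gene_id, chrom, strand, tuple(ivs), cds_start, cds_end)


def species_events(ds: SimulatedDataset, species: str, genome: bool = False):
    """Run chimera-free calling + evidence filter + collapse on in-memory models."""
    genes = ds.genes(species)
    models = [m for lst in ds.models(species).values() for m in lst]
    gen = (ds.genome_a if species == "A" else ds.genome_b) if genome else None
    called = call_events(models, genes, genome=gen)
    accepted = filter_events_by_evidence(called, ds.design)
    return called, accepted, collapse_redundant(accepted)


def species_expressed(ds: SimulatedDataset, species: str) -> set[str]:
    genes = ds.genes(species)
    table = ds.expression_a if species == "A" else ds.expression_b
    model_gene = {m.model_id: m.gene_id for lst in ds.models(species).values() for m in lst}
    lengths = {g: sum(e.length for e in genes[g].exons) for g in genes}
    return expressed_genes(compute_gene_expression(table, model_gene, lengths, ds.design))


@pytest.fixture(scope="session")
def small_ds() -> SimulatedDataset:
    """A small noise-free dataset reused by read-only tests."""
    return simulate(GeneratorConfig(n_genes=150, noise_fraction=0.0), seed=11)


@pytest.fixture(scope="session")
def small_ds_dir(tmp_path_factory):
    """The same small dataset written to disk (independent instance)."""
    out = tmp_path_factory.mktemp("dataset")
    ds = simulate(GeneratorConfig(n_genes=150, noise_fraction=0.0), seed=11, out_dir=out)
    return ds, out
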