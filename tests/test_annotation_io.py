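"""Gene model construction, GFF3 I/O, intron derivation, region taxonomy and
the chimera filter."""

import pytest

from asjunct.annotation_io import (
    AnnotationError,
    ExonRegionType,
    GenomicInterval,
    IntronRegionType,
    TranscriptModel,
    classify_exon_region,
    classify_intron_region,
    derive_introns,
    filter_chimeric_models,
    read_annotation,
    write_annotation,
)
from conftest import make_gene

GFF_HEADER = "##gff-version 3\n"


def _gff(lines):
    return GFF_HEADER + "\n".join(lines) + "\n"


def _write(tmp_path, text):
    p = tmp_path / "ann.gff3"
    p.write_text(text)
    return p


def test_gff3_coordinates_convert_to_zero_based_half_open(tmp_path):
    text = _gff(
        [
            "chr1\t.\tgene\t1\t300\t.\t+\t.\tID=gA",
            "chr1\t.\tmRNA\t1\t300\t.\t+\t.\tID=gA.t1;Parent=gA",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tParent=gA.t1",
            "chr1\t.\texon\t201\t300\t.\t+\t.\tParent=gA.t1",
        ]
    )
    genes = read_annotation(_write(tmp_path, text))
    assert [(e.start, e.end) for e in genes["gA"].exons] == [(0, 100), (200, 300)]


def test_minus_strand_exons_in_transcription_order(tmp_path):
    text = _gff(
        [
            "chr1\t.\tgene\t1\t300\t.\t-\t.\tID=gA",
            "chr1\t.\tmRNA\t1\t300\t.\t-\t.\tID=gA.t1;Parent=gA",
            "chr1\t.\texon\t1\t100\t.\t-\t.\tParent=gA.t1",
            "chr1\t.\texon\t201\t300\t.\t-\t.\tParent=gA.t1",
        ]
    )
    genes = read_annotation(_write(tmp_path, text))
    assert (genes["gA"].exons[0].start, genes["gA"].exons[0].end) == (200, 300)


def test_duplicated_exon_lines_raise(tmp_path):
    text = _gff(
        [
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=gA",
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=gA.t1;Parent=gA",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tParent=gA.t1",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tParent=gA.t1",
        ]
    )
    with pytest.raises(AnnotationError):
        read_annotation(_write(tmp_path, text))


def test_cds_outside_exons_rejected():
    with pytest.raises(AnnotationError):
        make_gene(exons=((0, 100), (200, 300)), cds=(120, 180))


def test_derive_introns_plus_strand():
    gene = make_gene()
    introns = derive_introns(gene)
    assert [(i.interval.start, i.interval.end) for i in introns] == [(100, 200), (300, 400)]
    assert [i.index for i in introns] == [0, 1]
    assert introns[0].donor_pos == 100 and introns[0].acceptor_pos == 199


def test_derive_introns_single_exon_gene():
    assert derive_introns(make_gene(exons=((0, 100),))) == []


def test_derive_introns_minus_strand_donor_follows_strand():
    gene = make_gene(strand="-", exons=((0, 100), (200, 300)))
    (intron,) = derive_introns(gene)
    assert (intron.interval.start, intron.interval.end) == (100, 200)
    assert intron.index == 0
    assert intron.donor_pos == 199
    assert intron.acceptor_pos == 100


@pytest.mark.parametrize("strand", ["+", "-"])
def test_intron_regions_cds_in_middle_exon(strand):
    # CDS confined to the middle exon: one 5'UTR and one 3'UTR intron
    gene = make_gene(strand=strand, cds=(220, 280))
    regions = [classify_intron_region(gene, i) for i in range(2)]
    assert regions == [IntronRegionType.FIVE_UTR, IntronRegionType.THREE_UTR]


def test_intron_regions_all_cds_when_cds_spans_gene():
    gene = make_gene(cds=(10, 490))
    assert all(
        classify_intron_region(gene, i) is IntronRegionType.CDS for i in range(2)
    )


def test_noncoding_gene_regions_unclassified():
    gene = make_gene()
    assert classify_intron_region(gene, 0) is None
    assert classify_exon_region(gene, 0) is None


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exon_regions_cds_spanning_three_exons(strand):
    gene = make_gene(strand=strand, cds=(50, 450))
    assert [classify_exon_region(gene, i) for i in range(3)] == [
        ExonRegionType.FIVE_UTR_CDS,
        ExonRegionType.CDS,
        ExonRegionType.CDS_THREE_UTR,
    ]


def test_single_exon_coding_gene_is_five_three_utr():
    gene = make_gene(exons=((0, 200),), cds=(20, 150))
    assert classify_exon_region(gene, 0) is ExonRegionType.FIVE_UTR_THREE_UTR


def test_region_counts_sum_to_element_counts(small_ds):
    for gene in list(small_ds.genes_a.values())[:200]:
        if not gene.is_coding:
            continue
        introns = [classify_intron_region(gene, i) for i in range(gene.n_introns)]
        exons = [classify_exon_region(gene, i) for i in range(gene.n_exons)]
        assert len(introns) == gene.n_exons - 1 and None not in introns
        assert len(exons) == gene.n_exons and None not in exons


def test_exons_and_introns_tile_the_gene_span(small_ds):
    for gene in list(small_ds.genes_a.values())[:100]:
        pieces = sorted(
            [(e.start, e.end) for e in gene.exons]
            + [(i.interval.start, i.interval.end) for i in derive_introns(gene)]
        )
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2
        assert (pieces[0][0], pieces[-1][1]) == gene.span


def test_annotation_round_trip_preserves_coordinates(small_ds, tmp_path):
    path = tmp_path / "rt.gff3"
    write_annotation(small_ds.genes_a, path)
    back = read_annotation(path)
    assert set(back) == set(small_ds.genes_a)
    for gid, gene in small_ds.genes_a.items():
        assert back[gid].exons == gene.exons
        assert (back[gid].cds_start, back[gid].cds_end) == (gene.cds_start, gene.cds_end)


class TestChimeraFilter:
    def _genes(self):
        a = make_gene("A", exons=((0, 100), (900, 1000)))
        b = make_gene("B", exons=((2000, 2100), (2400, 2500)))
        nested = make_gene("N", exons=((300, 350), (500, 550)))  # inside A's intron
        return {"A": a, "B": b, "N": nested}

    def _model(self, mid, exons):
        return TranscriptModel(
            mid, "chr1", "+", tuple(GenomicInterval("chr1", s, e, "+") for s, e in exons)
        )

    def test_model_within_one_gene_kept_and_assigned(self):
        kept, rejected = filter_chimeric_models(
            [self._model("m1", [(2000, 2100), (2400, 2450)])], self._genes()
        )
        assert [m.gene_id for m in kept] == ["B"] and not rejected

    def test_model_spanning_two_genes_rejected(self):
        kept, rejected = filter_chimeric_models(
            [self._model("m1", [(50, 100), (2000, 2100)])], self._genes()
        )
        assert not kept and "chimeric" in rejected[0][1]

    def test_model_over_nested_gene_rejected(self):
        kept, rejected = filter_chimeric_models(
            [self._model("m1", [(0, 100), (500, 560), (900, 1000)])], self._genes()
        )
        assert not kept and rejected[0][1].startswith("chimeric")

    def test_intergenic_model_rejected_with_reason(self):
        kept, rejected = filter_chimeric_models(
            [self._model("m1", [(5000, 5100)])], self._genes()
        )
        assert not kept and rejected[0][1] == "intergenic"
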