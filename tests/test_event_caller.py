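"""Junction classification, exonic event detection, motif typing, the
multi-source evidence filter and redundancy collapsing."""

import pytest

from asjunct.annotation_io import EST_SOURCE, EvidenceSource, GenomicInterval, TranscriptModel
from asjunct.event_caller import (
    ASEvent,
    EventType,
    EvidenceDesign,
    MotifClass,
    call_events,
    classify_model_intron,
    collapse_redundant,
    detect_exonic_events,
    event_accepted,
    filter_events_by_evidence,
    junction_motif,
)
from conftest import make_gene
from oracle_rules import brute_force_classify, grid_genes


@pytest.fixture
def gene3():
    return make_gene()  # exons (0,100),(200,300),(400,500) on +


def _model(gene, exons, mid="m", source=None):
    return TranscriptModel(
        mid,
        gene.chrom,
        gene.strand,
        tuple(GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in exons),
        gene_id=gene.gene_id,
        source=source,
    )


class TestJunctionClassification:
    def test_reference_intron_is_a_match(self, gene3):
        assert classify_model_intron((100, 200), gene3).status == "match"

    def test_junction_bridging_two_introns_skips_the_exon_between(self, gene3):
        (ev,) = classify_model_intron((100, 400), gene3).events
        assert (ev.event_type, ev.affected_kind, ev.affected_index) == (
            EventType.ES,
            "exon",
            1,
        )

    @pytest.mark.parametrize(
        "junction,expected_type,index",
        [
            ((100, 210), EventType.AA, 0),  # donor kept, acceptor shifted
            ((110, 200), EventType.AD, 0),  # acceptor kept, donor shifted
            ((30, 60), EventType.NI, 0),  # junction inside an exon
            ((105, 195), EventType.ASS, 0),  # both sites shifted within intron 0
        ],
    )
    def test_single_junction_event_types(self, gene3, junction, expected_type, index):
        (ev,) = classify_model_intron(junction, gene3).events
        assert (ev.event_type, ev.affected_index) == (expected_type, index)

    def test_minus_strand_roles_swap(self):
        gene = make_gene(strand="-")
        # transcription intron 0 is the genomic (300,400) gap; its acceptor is 300
        (ev,) = classify_model_intron((290, 400), gene).events
        assert (ev.event_type, ev.affected_index) == (EventType.AA, 0)
        (ev,) = classify_model_intron((300, 410), gene).events
        assert (ev.event_type, ev.affected_index) == (EventType.AD, 0)

    def test_junction_outside_gene_unclassified(self, gene3):
        assert classify_model_intron((600, 700), gene3).status == "unclassified"

    @pytest.mark.parametrize("gene_idx", range(12))
    def test_ordered_procedure_agrees_with_brute_force_on_small_grid(self, gene_idx):
        gene = grid_genes()[gene_idx]
        span = gene.span
        for s in range(span[0], span[1], 3):
            for e in range(s + 2, span[1] + 1, 3):
                label, detail = brute_force_classify((s, e), gene)
                result = classify_model_intron((s, e), gene)
                if label == "MATCH":
                    assert result.status == "match"
                elif label == "UNCLASSIFIED":
                    assert result.status == "unclassified"
                elif label == "ES":
                    assert tuple(ev.affected_index for ev in result.events) == detail
                    assert {ev.event_type for ev in result.events} == {EventType.ES}
                else:
                    (ev,) = result.events
                    assert (ev.event_type.value, ev.affected_index) == (label, detail)


class TestExonicEvents:
    def test_intron_retention_detected(self, gene3):
        model = _model(gene3, [(0, 300), (400, 500)])
        (ev,) = detect_exonic_events(model, gene3)
        assert (ev.event_type, ev.affected_index) == (EventType.IR, 0)

    def test_retained_exon_requires_matching_outer_boundaries(self, gene3):
        model = _model(gene3, [(0, 100), (130, 160), (200, 300), (400, 500)])
        (ev,) = detect_exonic_events(model, gene3)
        assert (ev.event_type, ev.affected_index) == (EventType.RE, 0)
        assert ev.novel_coords == ((130, 160),)
        # shifted outer boundary: no RE
        shifted = _model(gene3, [(0, 98), (130, 160), (200, 300), (400, 500)])
        assert detect_exonic_events(shifted, gene3) == []

    def test_primary_identical_model_yields_nothing(self, gene3):
        model = _model(gene3, [(0, 100), (200, 300), (400, 500)])
        assert detect_exonic_events(model, gene3) == []
        assert all(
            classify_model_intron(j, gene3).status == "match" for j in model.junctions()
        )


class TestCallEvents:
    def test_same_event_from_two_sources_merges_evidence(self, gene3):
        s1, s2 = EvidenceSource("L1", "m1"), EvidenceSource("L2", "m1")
        models = [
            _model(gene3, [(0, 300), (400, 500)], "a", s1),
            _model(gene3, [(0, 300), (400, 500)], "b", s2),
        ]
        (ev,) = call_events(models, {gene3.gene_id: gene3})
        assert ev.event_type is EventType.IR and ev.evidence == {s1, s2}

    def test_re_component_junctions_not_double_counted(self, gene3):
        model = _model(gene3, [(0, 100), (130, 160), (200, 300), (400, 500)])
        events = call_events([model], {gene3.gene_id: gene3})
        assert [e.event_type for e in events] == [EventType.RE]

    def test_motifs_annotated_from_genome_both_strands(self):
        # + strand: GT..AG ; - strand: top-strand CT..AC reads GT..AG
        plus = make_gene("gp", exons=((0, 10), (20, 30)))
        minus = make_gene("gm", strand="-", exons=((0, 10), (20, 30)))
        genome = {"chr1": "A" * 10 + "GT" + "A" * 6 + "AG" + "C" * 10}
        (ev,) = call_events(
            [_model(plus, [(0, 8), (22, 30)], source=EST_SOURCE)], {"gp": plus}, genome
        )
        assert ev.motif is MotifClass.NONCANONICAL  # shifted sites hit random bases
        genome_m = {"chr1": "A" * 10 + "CT" + "A" * 6 + "AC" + "C" * 10}
        assert junction_motif(genome_m, "chr1", 10, 20, "-") is MotifClass.U2_CANONICAL
        assert junction_motif(genome, "chr1", 10, 20, "+") is MotifClass.U2_CANONICAL

    def test_u12_and_gc_ag_classification(self):
        genome = {"c": "AT" + "A" * 6 + "AC" + "GC" + "A" * 6 + "AG"}
        assert junction_motif(genome, "c", 0, 10, "+") is MotifClass.U12
        # GC..AG is counted non-canonical (only GT..AG is U2 here)
        assert junction_motif(genome, "c", 10, 20, "+") is MotifClass.NONCANONICAL


class TestEvidenceFilter:
    design = EvidenceDesign(
        {"S1": ("L1", "L2", "L3", "L4"), "S2": ("L5", "L6", "L7")}, ("m1", "m2")
    )

    def _event(self, sources):
        return ASEvent("g", EventType.IR, "intron", 0, ((0, 1),), evidence=set(sources))

    @pytest.mark.parametrize(
        "sources,expected",
        [
            ([EST_SOURCE], True),  # EST channel
            ([("L1", "m1"), ("L1", "m2")], True),  # both mappers, one library
            ([("L1", "m1"), ("L2", "m2")], False),  # mappers split across libraries
            ([("L5", "m1"), ("L6", "m1")], True),  # 2 of 3 replicates
            ([("L5", "m1")], False),  # 1 of 3 replicates
            ([("L1", "m1"), ("L2", "m1")], True),  # 2 of 4 replicates (ceil(4/2)=2)
            ([("L1", "m1"), ("L5", "m1")], False),  # 1 replicate in each sample
            ([("L1", "m1"), ("L2", "m2"), ("L5", "m2"), ("L6", "m2")], True),  # S2 rule
            ([], False),
        ],
    )
    def test_acceptance_channels(self, sources, expected):
        srcs = [s if isinstance(s, EvidenceSource) else EvidenceSource(*s) for s in sources]
        assert event_accepted(self._event(srcs), self.design) is expected

    def test_unknown_source_raises_with_its_name(self):
        with pytest.raises(ValueError, match="LX:m1"):
            event_accepted(self._event([EvidenceSource("LX", "m1")]), self.design)

    def test_filter_returns_only_accepted(self):
        events = [
            self._event([EST_SOURCE]),
            self._event([EvidenceSource("L5", "m1")]),
        ]
        assert filter_events_by_evidence(events, self.design) == [events[0]]


class TestCollapse:
    def _aa(self, index, coords):
        return ASEvent("g", EventType.AA, "intron", index, (coords,), evidence={EST_SOURCE})

    def test_same_intron_same_type_collapses(self):
        out = collapse_redundant([self._aa(3, (0, 10)), self._aa(3, (0, 12))])
        assert len(out) == 1 and out[0].novel_coords == ((0, 10), (0, 12))

    def test_different_introns_do_not_collapse(self):
        assert len(collapse_redundant([self._aa(1, (0, 10)), self._aa(2, (0, 10))])) == 2

    def test_collapse_is_idempotent(self):
        once = collapse_redundant([self._aa(3, (0, 10)), self._aa(3, (0, 12))])
        twice = collapse_redundant(once)
        assert [(e.key, e.novel_coords) for e in once] == [
            (e.key, e.novel_coords) for e in twice
        ]
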