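"""Homolog universe construction and junction-based conservation scoring."""

import pytest

from asjunct.conservation import (
    HomologyEntry,
    build_universe,
    conserved_events,
    paralog_conservation,
)
from asjunct.event_caller import ASEvent, EventType
from conftest import make_gene, species_events


def _gene(gid, n_exons):
    exons = tuple((i * 200, i * 200 + 100) for i in range(n_exons))
    return make_gene(gid, exons=exons)


def _ev(gene, etype, index, kind=None):
    kind = kind or ("intron" if etype is not EventType.NI and etype is not EventType.ES else "exon")
    return ASEvent(gene, etype, kind, index, ((0, 1),))


class TestBuildUniverse:
    genes_a = {"a1": _gene("a1", 5), "a2": _gene("a2", 5)}
    genes_b = {"b1": _gene("b1", 5), "b2": _gene("b2", 5), "b3": _gene("b3", 4)}

    def test_full_one_to_two_kept(self):
        uni = build_universe(
            [HomologyEntry("a1", ("b1", "b2"))],
            self.genes_a, self.genes_b, {"a1"}, {"b1", "b2"},
        )
        assert uni.a_partners == {"a1": ("b1", "b2")}
        assert uni.paralog_pairs == [("b1", "b2")]

    def test_copy_with_different_model_demotes_to_one_to_one(self):
        uni = build_universe(
            [HomologyEntry("a1", ("b1", "b3"))],
            self.genes_a, self.genes_b, {"a1"}, {"b1", "b3"},
        )
        assert uni.a_partners == {"a1": ("b1",)} and uni.paralog_pairs == []

    def test_unexpressed_copy_demotes_and_unexpressed_a_drops(self):
        uni = build_universe(
            [HomologyEntry("a1", ("b1", "b2")), HomologyEntry("a2", ("b2",))],
            self.genes_a, self.genes_b, {"a1"}, {"b1"},
        )
        assert uni.a_partners == {"a1": ("b1",)}

    def test_unknown_gene_id_is_named_in_error(self):
        with pytest.raises(KeyError, match="zz"):
            build_universe(
                [HomologyEntry("zz", ("b1",))],
                self.genes_a, self.genes_b, {"zz"}, {"b1"},
            )


class TestConservedEvents:
    def test_counts_and_rates_arithmetic(self):
        # 20 source events, 10 in universe genes, 4 conserved
        partner = {f"g{i}": (f"h{i}",) for i in range(10)}
        src = [_ev(f"g{i}", EventType.IR, 0) for i in range(10)] + [
            _ev(f"x{i}", EventType.IR, 0) for i in range(10)
        ]
        tgt = [_ev(f"h{i}", EventType.IR, 0) for i in range(4)]
        res = conserved_events(src, tgt, partner)
        st = res.overall
        assert (st.n_total, st.n_in_universe, st.n_conserved) == (20, 10, 4)
        assert st.rate_max == pytest.approx(0.4)
        assert st.rate_min == pytest.approx(0.2)
        # brute-force pairwise cross-check
        tgt_keys = {(e.gene_id, e.event_type, e.affected_kind, e.affected_index) for e in tgt}
        brute = sum(
            1
            for e in src
            for p in partner.get(e.gene_id, ())
            if (p, e.event_type, e.affected_kind, e.affected_index) in tgt_keys
        )
        assert brute == st.n_conserved

    def test_same_type_different_intron_not_conserved(self):
        res = conserved_events(
            [_ev("g", EventType.IR, 2)], [_ev("h", EventType.IR, 3)], {"g": ("h",)}
        )
        assert res.overall.n_conserved == 0

    def test_index_match_requires_same_type(self):
        res = conserved_events(
            [_ev("g", EventType.AA, 1)], [_ev("h", EventType.AD, 1)], {"g": ("h",)}
        )
        assert res.overall.n_conserved == 0

    def test_corrupt_index_raises(self):
        genes = {"g": _gene("g", 3)}
        with pytest.raises(ValueError, match="exceeds"):
            conserved_events(
                [_ev("g", EventType.IR, 7)], [], {"g": ("h",)}, genes_src=genes
            )

    def test_require_both_homologs_is_stricter(self):
        src = [_ev("g", EventType.IR, 0)]
        tgt = [_ev("h1", EventType.IR, 0)]
        pm = {"g": ("h1", "h2")}
        assert conserved_events(src, tgt, pm).overall.n_conserved == 1
        assert conserved_events(src, tgt, pm, require_both=True).overall.n_conserved == 0


class TestParalogConservation:
    def test_shared_event_conserved_in_both_copies(self):
        events = [_ev("b1", EventType.AA, 0), _ev("b2", EventType.AA, 0)]
        res = paralog_conservation(events, [("b1", "b2")])
        assert res.overall.n_conserved == 2 and res.overall.n_in_universe == 2

    def test_disjoint_event_sets_unconserved(self):
        events = [_ev("b1", EventType.AA, 0), _ev("b2", EventType.AD, 1)]
        assert paralog_conservation(events, [("b1", "b2")]).overall.n_conserved == 0


class TestOnSyntheticData:
    def test_rate_max_at_least_rate_min(self, small_ds):
        _, _, nr_a = species_events(small_ds, "A")
        _, _, nr_b = species_events(small_ds, "B")
        from asjunct.conservation import build_universe

        uni = build_universe(
            small_ds.homology,
            small_ds.genes_a,
            small_ds.genes_b,
            small_ds.flagged_expressed_a,
            small_ds.flagged_expressed_b,
        )
        res = conserved_events(nr_a, nr_b, uni.a_partners, genes_src=small_ds.genes_a)
        for st in list(res.per_type.values()) + [res.overall]:
            assert st.n_conserved <= st.n_in_universe <= st.n_total
            if st.n_in_universe:
                assert st.rate_max >= st.rate_min

    def test_one_to_one_restriction_symmetry(self, small_ds):
        """On 1:1 same-model pairs the conserved sets match key-for-key."""
        _, _, nr_a = species_events(small_ds, "A")
        _, _, nr_b = species_events(small_ds, "B")
        from asjunct.conservation import build_universe

        uni = build_universe(
            small_ds.homology,
            small_ds.genes_a,
            small_ds.genes_b,
            small_ds.flagged_expressed_a,
            small_ds.flagged_expressed_b,
        )
        pairs = [(e.gene_a, e.genes_b[0]) for e in uni.pairs if len(e.genes_b) == 1]
        a_of = {b: a for a, b in pairs}
        b_of = dict(pairs)
        keys_a = {e.key for e in nr_a}
        keys_b = {e.key for e in nr_b}
        fwd = {
            (a, t, k, i)
            for (a, t, k, i) in keys_a
            if a in b_of and (b_of[a], t, k, i) in keys_b
        }
        rev = {
            (a_of[b], t, k, i)
            for (b, t, k, i) in keys_b
            if b in a_of and (a_of[b], t, k, i) in keys_a
        }
        assert fwd == rev
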