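"""Randomization schemes: determinism, constraint preservation, degenerate
cases and agreement with an independent brute-force null."""

import numpy as np
import pytest

from asjunct.conservation import ConservationUniverse, HomologyEntry
from asjunct.event_caller import ASEvent, EventType
from asjunct.null_simulation import (
    ElementPools,
    Scheme,
    empirical_p,
    randomize_events,
    randomize_genes,
    run_null,
)
from conftest import make_gene


def _gene(gid, n_exons):
    exons = tuple((i * 200, i * 200 + 100) for i in range(n_exons))
    return make_gene(gid, exons=exons)


def _ir(gene, index):
    return ASEvent(gene, EventType.IR, "intron", index, ((0, 1),))


def _setup(n=30, exons=2):
    """n 1:1 pairs, each gene with `exons` exons."""
    genes_a = {f"a{i}": _gene(f"a{i}", exons) for i in range(n)}
    genes_b = {f"b{i}": _gene(f"b{i}", exons) for i in range(n)}
    uni = ConservationUniverse([HomologyEntry(f"a{i}", (f"b{i}",)) for i in range(n)])
    return genes_a, genes_b, uni


def test_same_seed_reproduces_the_distribution():
    genes_a, genes_b, uni = _setup()
    ev_a = [_ir(f"a{i}", 0) for i in range(10)]
    ev_b = [_ir(f"b{i}", 0) for i in range(5)]
    args = (ev_a, ev_b, uni, genes_a, set(genes_a), genes_b, set(genes_b))
    d1 = run_null(Scheme.RANDOM_GENES_RANDOM_EVENTS, 20, 42, *args)
    d2 = run_null(Scheme.RANDOM_GENES_RANDOM_EVENTS, 20, 42, *args)
    d3 = run_null(Scheme.RANDOM_GENES_RANDOM_EVENTS, 20, 43, *args)
    assert np.array_equal(d1.percents["overall"], d2.percents["overall"])
    assert not np.array_equal(d1.percents["overall"], d3.percents["overall"])


def test_event_types_and_gene_slots_preserved_by_randomization():
    genes_a, genes_b, uni = _setup(40, exons=6)
    rng = np.random.default_rng(0)
    keys = [(f"a{i}", t, "intron", 0) for i, t in zip(range(30), 3 * [EventType.IR, EventType.AA])]
    pools = ElementPools(genes_a, set(genes_a))
    out = randomize_events(keys, pools, rng)
    # types preserved; count shrinks only by same-element collisions
    assert {k[1] for k in out} == {EventType.IR, EventType.AA}
    assert len(out) <= len(keys)
    pm = randomize_genes(uni, genes_b, set(genes_b), rng)
    assert sorted(pm) == sorted(uni.a_partners)
    partners = [b for v in pm.values() for b in v]
    assert len(partners) == len(set(partners))  # without replacement


def test_same_model_permutation_with_unique_exon_counts_is_identity():
    genes_a = {f"a{i}": _gene(f"a{i}", i + 2) for i in range(8)}
    genes_b = {f"b{i}": _gene(f"b{i}", i + 2) for i in range(8)}
    uni = ConservationUniverse([HomologyEntry(f"a{i}", (f"b{i}",)) for i in range(8)])
    rng = np.random.default_rng(1)
    pm = randomize_genes(uni, genes_b, set(genes_b), rng, same_model=True)
    assert pm == uni.a_partners


def test_random_events_mean_matches_independent_simulation():
    """One intron per gene, all-IR events: the null conservation has a closed
    sampling form; compare run_null's mean with a from-scratch simulation."""
    n, m_a, m_b = 25, 10, 8
    genes_a, genes_b, uni = _setup(n, exons=2)
    ev_a = [_ir(f"a{i}", 0) for i in range(m_a)]
    ev_b = [_ir(f"b{i}", 0) for i in range(m_b)]
    nd = run_null(
        Scheme.RANDOM_EVENTS, 4000, 7, ev_a, ev_b, uni,
        genes_a, set(genes_a), genes_b, set(genes_b),
    )
    # independent oracle: throw m_a balls into n boxes; conserved = distinct
    # boxes hit among the m_b paired boxes (collisions collapse)
    rng = np.random.default_rng(123)
    sims = []
    for _ in range(4000):
        hit = set(rng.integers(0, n, size=m_a))
        sims.append(100.0 * len([i for i in hit if i < m_b]) / m_a)
    se = np.std(sims, ddof=1) / np.sqrt(len(sims)) * 4
    assert nd.percents["overall"].mean() == pytest.approx(np.mean(sims), abs=3 * se + 0.5)


def test_same_model_null_lower_when_target_events_concentrate_in_large_genes():
    """When target-side events sit in high-exon-count genes, the same-model
    constraint pins small-gene slots to event-poor small partners, while the
    free permutation can draw the event-rich large genes -- so the same-model
    null cannot exceed the free-gene null."""
    genes_a = {f"a{i}": _gene(f"a{i}", 2) for i in range(30)}
    genes_b = {f"b{i}": _gene(f"b{i}", 2) for i in range(30)}
    genes_b.update({f"c{i}": _gene(f"c{i}", 10) for i in range(10)})
    uni = ConservationUniverse([HomologyEntry(f"a{i}", (f"b{i}",)) for i in range(30)])
    ev_a = [_ir(f"a{i}", 0) for i in range(30)]
    ev_b = [_ir(f"c{i}", j) for i in range(10) for j in range(9)]
    args = (ev_a, ev_b, uni, genes_a, set(genes_a), genes_b, set(genes_b))
    free = run_null(Scheme.RANDOM_GENES, 300, 5, *args)
    same = run_null(Scheme.RANDOM_GENES_SAME_MODEL, 300, 5, *args)
    assert free.percents["overall"].mean() > 0
    assert same.percents["overall"].mean() <= free.percents["overall"].mean()


def test_single_replicate_sd_reported_as_zero_with_flag():
    genes_a, genes_b, uni = _setup()
    nd = run_null(
        Scheme.RANDOM_EVENTS, 1, 0, [_ir("a0", 0)], [_ir("b0", 0)], uni,
        genes_a, set(genes_a), genes_b, set(genes_b),
    )
    summ = nd.summary()
    assert (summ["sd"] == 0).all() and not summ["sd_defined"].any()


def test_empirical_p_definition():
    assert empirical_p(5.0, np.array([1.0, 2.0, 6.0])) == pytest.approx(2 / 4)
    assert empirical_p(10.0, np.array([1.0, 2.0, 6.0])) == pytest.approx(1 / 4)
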