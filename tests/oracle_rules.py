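"""Brute-force junction classifier used as an independent oracle in tests.

Each rule is evaluated standalone (with its own exclusivity guards, not an
ordering); the oracle asserts that at most one rule fires for any junction,
then reports it. The ordered decision procedure in the package must agree.
"""

from asjunct.annotation_io import GeneModel, derive_introns


def brute_force_classify(j: tuple[int, int], gene: GeneModel):
    """Return (label, detail): MATCH/AA/AD/ES/NI/ASS/UNCLASSIFIED."""
    s, e = j
    introns = derive_introns(gene)
    by_coords = {(i.interval.start, i.interval.end): i.index for i in introns}
    if gene.strand == "+":
        donors = {i.interval.start: i.index for i in introns}
        acceptors = {i.interval.end: i.index for i in introns}
        dj, aj = s, e
    else:
        donors = {i.interval.end: i.index for i in introns}
        acceptors = {i.interval.start: i.index for i in introns}
        dj, aj = e, s
    k = donors.get(dj)
    l = acceptors.get(aj)

    fired = []
    if (s, e) in by_coords:
        fired.append(("MATCH", by_coords[(s, e)]))
    if k is not None and l is not None and l > k:
        fired.append(("ES", tuple(range(k + 1, l + 1))))
    if k is not None and l is None:
        fired.append(("AA", k))
    if l is not None and k is None:
        fired.append(("AD", l))
    inside = [t for t, ex in enumerate(gene.exons) if ex.start < s and e < ex.end]
    if inside:
        fired.append(("NI", inside[0]))
    if k is None and l is None and not inside:
        overlapped = [i for i in introns if s < i.interval.end and i.interval.start < e]
        if len(overlapped) == 1:
            g = gene.genomic_gap_index(overlapped[0].index)
            gex = gene.genomic_exons
            if gex[g].start <= s and e <= gex[g + 1].end:
                fired.append(("ASS", overlapped[0].index))
    assert len(fired) <= 1, f"rules not exclusive for {j}: {fired}"
    return fired[0] if fired else ("UNCLASSIFIED", None)


def grid_genes(max_exons: int = 6, exon_len: int = 8, intron_len: int = 8):
    """Small genes of 1..max_exons exons on both strands for exhaustive grids."""
    from asjunct.annotation_io import GenomicInterval

    genes = []
    for n in range(1, max_exons + 1):
        exons = []
        pos = 0
        for _ in range(n):
            exons.append((pos, pos + exon_len))
            pos += exon_len + intron_len
        for strand in "+-":
            ivs = [GenomicInterval("c", s, e, strand) for s, e in exons]
            if strand == "-":
                ivs.reverse()
            genes.append(GeneModel(f"g{n}{strand}", "c", strand, tuple(ivs)))
    return genes
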