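# Methods

## Scope and assumptions

The package analyses *local* splicing decisions against a single annotated
primary transcript per gene. It assumes (i) the annotation provides one
designated isoform per gene (a `canonical=1` mRNA attribute, else the first
mRNA in file order); (ii) transcript models arrive pre-assembled (GTF) from
two mappers across replicated libraries, plus EST-derived models; and (iii)
per-model FPKM values are supplied, not computed. Full-isoform questions —
alternative transcription start/polyadenylation sites, trans-splicing,
quantitative inclusion levels (PSI) — are out of scope by construction, as
they are not identifiable from local junction evidence.

All coordinates are 0-based half-open internally and converted to 1-based
inclusive only at GFF3/GTF boundaries. Exons and introns are indexed in
transcription order (index 0 = 5′-most), so all downstream logic is
strand-free once models are loaded.

## Event classification

Candidate junctions of a model are classified by an ordered decision
procedure: exact intron match; exon skipping (donor matches reference intron
*k*, acceptor matches reference intron *l* > *k*; one ES event is emitted per
skipped exon, matching per-element accounting); alternative acceptor or donor
(exactly one same-role boundary matches); new intron (junction strictly
inside one reference exon); alternative splice sites (no boundary match,
junction confined to one reference intron and its flanking exons). The
ordering resolves junctions that would satisfy several descriptions — a
junction matching two reference boundaries is more parsimoniously one ES than
an AA+AD pair. Anything else is unclassified and excluded. Written with the
exclusivity guards each rule carries, the rules are mutually disjoint; the
test suite verifies the ordered procedure against a brute-force evaluator
that checks every rule independently and asserts exactly one fires, over an
exhaustive junction grid on all exon layouts up to six exons.

Exon-level events are read from model exons directly. IR requires a model
exon to contain the whole reference intron and extend at least 1 nt into both
flanking exons; a model exon merely ending inside an intron is left
unclassified, since it could be an unannotated transcript end. RE requires
both flanking model junctions to share their outer boundaries with the
reference intron; those two component junctions are then consumed and not
re-classified as AA/AD (partial boundary matches fall through to the junction
rules instead).

Splice-site motifs are read from the genome as the first and last two
intronic bases in transcription orientation: GT..AG is U2-canonical, AT..AC
is U12, everything else (including GC..AG, which is tallied with the rest)
is non-canonical.

## Evidence rule, redundancy, expression

An event is accepted when it is seen in ESTs, or by both mappers in a single
library, or by one mapper in at least ⌈n/2⌉ of a sample's n replicate
libraries. Accepted same-type events on the same intron/exon are collapsed
into one non-redundant event (coordinates merged sorted, evidence unioned).

Gene expression per library and mapper is Σ(FPKM·model length) divided by
the primary-transcript length; the library value is the mean of the two
mappers (a mapper with no models contributes 0, with a warning), the sample
value the median over replicates (even counts: mean of the central pair), and
a gene is expressed in a sample when the value is strictly above 1 — the
boundary value 1.0 is *not* expressed. A gene is globally expressed when
expressed in at least one sample.

## Conservation

The homolog universe keeps entries whose genes are expressed and share the
gene model (equal exon counts): a 1:2 entry with both copies qualifying stays
1:2 (and contributes a paralog pair), with exactly one it demotes to 1:1,
with none it is dropped. An event in gene *gA* is conserved when at least one
retained homolog carries a non-redundant event of the same type on the same
ordinal element (a `require_both` switch makes 1:2 matching conjunctive;
the disjunctive reading matches the maximum-rate framing and is the default).
`rate_max` divides by events in universe genes, `rate_min` by all
non-redundant events; the former is an upper and the latter a lower bound on
the true conservation rate, since genes outside the universe are unscorable
rather than unconserved. Paralog conservation is scored symmetrically over
the union of both copies' events in 1:2 pairs.

## Null models

Four randomization schemes generate conservation null distributions:
`random_events` reassigns each source event (type fixed) to a uniformly
random eligible element across all expressed source genes — introns for
intron types, any exon for NI, internal exons of multi-exon genes for ES —
sampled with replacement, with same-element collisions collapsing as
redundant before scoring; `random_genes` permutes homolog partners uniformly
(without replacement) over expressed target genes, dropping the equal-model
constraint; `random_genes_same_model` restricts each slot's replacement to
target genes with the original partner's exon count; the combined scheme
applies the gene permutation then the event reassignment. Per-type event
counts are preserved by construction. Replicate *r* derives its generator
from `SeedSequence(seed, spawn_key=(r,))`, so distributions are fully
reproducible. Percentages use the constant denominator of all source
non-redundant events, making replicates comparable across schemes; an
empirical one-sided p-value `(1 + #{null ≥ observed}) / (1 + reps)` is
reported as a convenience on top of the distributions themselves. Whether
"shuffling events" keeps each event in its gene is genuinely ambiguous; the
global reassignment is the default and a `within_gene` flag provides the
stricter variant.

## Region and position characterization

Introns of coding genes are typed by the exons they join (5′UTR–5′UTR,
CDS–CDS, 3′UTR–3′UTR); exons take six types (5′UTR, CDS, 3′UTR, the two
boundary classes holding the translation start or stop, and 5′UTR–3′UTR for
exons containing the entire CDS — single-exon coding genes). Non-coding genes
are excluded from region analysis. Region composition compares the
distribution of AS-affected elements per event type against the genome
background of all introns/exons of coding expressed genes; enrichment is the
percentage difference (descriptive only — no test statistic is attached).

Relative position maps element index *i* of *n* to *i*/(*n*−1), with
single-element genes at 0. Because every gene contributes a first element at
position 0 but only multi-element genes reach position 1, the raw
distribution of events over positions is structurally non-flat even under
uniform placement. Position fits therefore normalize by availability: events
and eligible elements are binned together (20 equal-width bins by default,
configurable) and the per-bin percentage is *affected elements / elements in
the bin*; a simple unweighted OLS of percentage on bin midpoint provides
slope, r² and the two-sided slope p-value. Under placement uniform per
element this statistic is flat by construction, which is what makes planted
position biases recoverable as signed slopes. The un-normalized per-bin
event percentages (summing to 100) remain available by omitting the element
positions. Bins without elements are dropped, not zero-filled; fits on fewer
than three distinct positions are returned flagged with NaN coefficients.
Note that with *k* usable bins the r² of a true-zero slope has expectation
1/(k−1), so flatness checks use finer binning (50 bins in the acceptance
suite) and aggregate across event types.

## The synthetic-data generator

The generator is the package's study-conditions module, not a test fixture.
Defaults encode the structure the analysis assumes for a common-bean-like
species A and soybean-like species B:

- **Gene models**: exon counts 1–20, truncated geometric (p = 0.16, ~16%
  single-exon genes, mean ≈ 5.6 exons); exon lengths 80–300 nt, introns
  60–600 nt (minima leave ≥10 nt offsets for planted coordinates); UTR
  extension probabilities 0.19/0.10 chosen so that ~94% of introns are
  CDS–CDS, ~4% 5′UTR and ~2% 3′UTR.
- **Splice sites**: 98% of reference junctions GT..AG; half the remainder
  AT..AC; 78% of novel (planted) junctions canonical.
- **Homology**: 51% of A genes have two B copies, 21% one, the rest none;
  each copy shares the A gene's exon count with probability 0.85; B carries
  an extra 25% of homolog-free genes. 90% of genes are expressed (log-normal
  FPKM, floored so flagged-expressed genes always clear the threshold).
- **Events**: 2.8 planted events per expressed gene on average, split by the
  per-type proportions of the two species' genome-wide profiles (A: IR .39,
  AA .21, AD .15, RE .08, ASS .07, ES .05, NI .04, normalized; B: IR .32,
  AA .24, AD .18, ES/RE .08, NI .06, ASS .04). Events are planted per
  *element*, uniformly across all eligible elements of expressed genes (so
  exon-rich genes carry proportionally more events), tilted by per-type
  linear position weights (default −0.8 for AA/AD/ES/RE, +0.8 for IR, 0 for
  ASS/NI) and optional per-region weights. Novel coordinates keep ≥10 nt
  from element boundaries so no planted event is coincidentally another type.
- **Conservation**: each A event is copied to a same-model expressed homolog
  with a per-type probability (defaults 0.25–0.45, IR highest); sibling
  copies within 1:2 pairs are planted with probability q = p/(2−p) so the
  symmetric paralog rate over the union of both copies' events equals the
  configured p (default 0.40).
- **Evidence**: two samples × three replicate libraries × two mappers plus
  ESTs; each event is routed through one acceptance channel (EST 25%,
  dual-mapper 40%, replicate 35%) or, with probability 0.1, becomes a noise
  event carried by a single library × mapper, which by design fails every
  channel (hence noise requires ≥3 replicates per sample).

Same seed ⇒ byte-identical output files. What the generator does *not*
emulate: read-level data (no FASTQ), sequence evolution or indel divergence
(1:2 copies are structural duplicates; sequence outside splice-site
dinucleotides is uniform random), assembly artifacts other than the planted
noise channel, overlapping genes, multi-isoform annotations, and expression
noise strong enough to flip an expressed call. Green tests therefore show
the *method* is correct and calibrated under these conditions; they do not
certify behavior on real assemblies with fragmented or chimeric models
beyond the span-based chimera filter.

## Problem sizes and numerical choices

The acceptance suite runs the generator at 2,000 genes per species
(~5,000 planted A events, ~8,500 B events) and 1,000 replicates per null
scheme; the full pipeline check uses 800 genes. Statistical acceptance bands
are 99% binomial intervals for parameter recovery and 3-sigma bands for
calibration checks. The chimera filter compares model spans to gene spans
irrespective of strand (an ambiguous overlap is ambiguous on either strand).
Evidence-merging ties are broken by lexicographic sorting of novel
coordinates; collapsed events keep a motif only when unambiguous across
members. Expression of a gene absent from a library is 0, entering the
mapper mean and replicate median as such.

## Known limitations

- Junction conservation by ordinal index requires equal exon counts; genes
  with conserved splicing but diverged gene models are invisible to it
  (reflected in the rate_min/rate_max bracket, not solved by it).
- The evidence rule treats mappers symmetrically and has no notion of read
  support depth; FPKM enters expression only, never event acceptance.
- Motif annotation covers events defining a single novel junction; IR has no
  novel junction and RE has two, so both carry no motif.
- The region-composition report is descriptive; it attaches no enrichment
  test.
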