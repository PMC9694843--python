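# Methods

## Scope and data model

The package consumes *annotated* circular mitogenomes; it does not assemble
reads or predict genes. The central record is an `AnnotatedMitogenome`: the
deposited J-strand (majority-strand) sequence plus ordered, strand-aware
`GeneFeature`s with 1-based inclusive GenBank coordinates, where
`end < start` encodes a feature wrapping the origin of the circle. Gene
labels are normalized through an editable synonym table
(`data/gene_synonyms.tsv`) so heterogeneous GenBank annotations (COI vs
COX1, 16S vs rrnL, tRNA products with anticodon classes) map to one
vocabulary; unmappable labels are kept verbatim with a warning rather than
dropped.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed from counts.
N bases are excluded from every denominator while reported lengths keep
them, so the size column of a composition report stays faithful to the
deposited record. A zero denominator yields an undefined (None-flagged)
skew, never a NaN that could silently propagate. Whole-genome values are
computed on the J-strand by convention, matching how mitogenomes are
deposited; strand-partitioned PCG summaries concatenate genes in reading
direction. Report rounding (one decimal for percentages, three for skews)
is applied only at output; all comparisons in tests use unrounded values.
A consequence worth knowing: skews recomputed *from printed, rounded
percentages* of a published table can differ from the printed skews (which
were computed from raw counts) by one unit in the third decimal.

## Codon usage

Translation uses NCBI code tables keyed by id (default 5, invertebrate
mitochondrial: ATA=Met, TGA=Trp, AGA/AGG=Ser), sourced from Biopython.
Start codons are reported verbatim — cox1 genes genuinely start with CGA,
AAA, AAG, TTG in moths — and never "corrected" to ATN. A CDS whose length
is not a codon multiple carries a trailing 1–2 nt remnant; T and TA
remnants are classified as incomplete stops (completed to TAA by transcript
polyadenylation in vivo), anything else is flagged as a non-stop terminal
and reported verbatim. Incomplete remnants and stop codons are excluded
from codon counts, RSCU, and amino-acid usage. RSCU families follow the
amino acid with Leu split into Leu1 (CTN) / Leu2 (TTA, TTG) and Ser into
Ser1 (AGN) / Ser2 (TCN), the conventional presentation for mitogenome
reports; a family with zero total count has undefined (flagged) RSCU rather
than zeros, preserving the family-sum invariant Σ RSCU = family size.

## Junctions and control regions

Adjacent features on the circle either overlap, abut, or leave a spacer.
Overlaps are computed on genomic coordinates regardless of strand (the
conserved trnW/trnC overlap spans opposite-strand tRNAs) and junction
sequences are reported on the J-strand. Features sharing a start are
ordered longer-first; a fully nested feature is reported as an overlap of
the inner length with a warning, and the covering feature carries the next
junction. A junction is *universal* across a panel only when every genome
has that gene pair adjacent with an identical sequence; otherwise the modal
motif and its supporting taxa are reported, so a single mutated taxon
demotes a motif from universal to 16/17 support rather than hiding it.
Control-region inference is a separate opt-in step that reports unannotated
stretches ≥ 200 bp (configurable) with their flanking genes; 200 bp cleanly
separates control regions from ordinary spacers, whose observed maximum in
the emulated panel is 87 bp. The canonical lepidopteran control region is
recognized by its rrnS/trnM flanks.

## Gene order

Orders are token sequences (gene, strand) in genomic order, rotated to a
cox1 anchor. Comparison is at the adjacency level only: the multiset of
strand-aware circular adjacencies, each canonicalized against its
reverse-complement reading (so (a+, b+) ≡ (b−, a−)), with breakpoints =
adjacencies of one order absent from the other. This reproduces classic
signed-breakpoint behaviour — an adjacent swap of two genes in a five-gene
circle costs three breakpoints — without computing inversion/DCJ distances,
which the package deliberately does not attempt. Control-region tokens are
excluded from breakpoint counts by default because CR position varies
independently of gene rearrangement. Three references are shipped:
ancestral insect (trnI-trnQ-trnM), typical Lepidoptera (trnM-trnI-trnQ),
and the chironomid trnI-trnM-trnQ variant.

## Ka/Ks (NG86)

The method is Nei–Gojobori (1986) with equal pathway weighting: per-codon
synonymous site counts are the fraction of possible single-nucleotide
changes at each position that are synonymous, with stop-creating changes
excluded from the denominator (so syn + nonsyn = 3 per codon exactly);
substitution counts between differing codons average over all minimal
mutational pathways that avoid stop codons, and codons whose every pathway
crosses a stop are excluded with a warning. Site counts are averaged over
the two sequences, proportions are corrected by Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3), and p ≥ 3/4 flags the pair saturated. Ks = 0
yields a flagged undefined Ka/Ks, never infinity. Codons containing gaps,
ambiguity, or stops are excluded, as is standard. Panel summaries default
to all-pairs means; a reference-taxon mode can be had by passing a
two-genome panel per comparison.

## TN93 distances and saturation

The Tamura–Nei (1993) closed form with empirical base frequencies averaged
over the two sequences (the pairwise-distance convention), distinguishing
A↔G and C↔T transition proportions from transversions. Sites with anything
but A/C/G/T in either sequence are excluded pairwise. Any non-positive
logarithm argument flags the pair saturated/undefined; such pairs are
excluded from the saturation regressions but kept, flagged, in the output
table. The saturation table reports per-pair transition and transversion
proportions against TN93 distance plus least-squares slope and Pearson r of
each against distance — the quantities used to judge whether a
concatenated-PCG matrix retains phylogenetic signal. In the equal-frequency
limits the implementation agrees with the K2P and JC closed forms to 1e−9,
and TN93 ≥ p-distance wherever defined.

## Supermatrix preparation

Alignment and heuristic trimming belong to external tools; the package
performs faithful plumbing. Its column filter is an explicit, logged rule —
drop columns whose gap fraction exceeds a threshold (default 0) and,
optionally, columns containing ambiguity codes — and is idempotent by
construction. Genes are trimmed to whole codons, concatenated in a fixed
alphabetical order (atp6 … nad6) recorded as NEXUS charsets, and taxa
missing a gene are gap-filled with a warning. Charset ranges are asserted
to tile the matrix on every run.

## Synthetic data generator

The generator emulates the observed structure of moth mitogenome panels:
37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus a control region on a ~15 kb
circle; the lepidopteran trnM-trnI-trnQ block; nine J-strand and four
N-strand PCGs; conserved junction motifs ATGATAA (atp8/atp6 overlap),
TCTAA (cox1/trnL2), AAGCCTTA (trnW/trnC), ATACTAA (trnS2/nad1 spacer); an
A+T-rich trnQ/nad2 spacer of 48–87 bp; Table-style start/stop plans
including CGA-starting cox1 and incomplete T/TA stops; per-clade A+T
content drawn uniformly in 76.0–81.7% with AT skew +0.01 and GC skew −0.20.
These defaults are the study conditions, not tuning knobs.

Construction order matters: constrained elements (start/stop codons,
junction motifs) are placed first; PCG bodies are built from sense codons
sampled from a distribution calibrated by fixed-point iteration so that the
*non-stop conditional* nucleotide frequencies match the target (naive
rejection of stop codons would depress A+T by about one point at 80% A+T);
motif overwrites that create in-frame stops are repaired by resampling only
unconstrained bases. Finally a deterministic balancing pass flips surplus
bases to deficit bases at free positions of tRNA/rRNA/CR genes until
whole-genome counts match the target exactly, so composition recovery is
limited by constraint density, not sampling noise. Declared tolerances
(A+T ±1.0 point, skews ±0.03) are asserted by a self-validation pass that
re-checks every planted property — gene order, start/stops, absence of
internal stops, junction motifs and lengths, composition — before a genome
is returned.

What the generator does *not* emulate: tRNA cloverleaf structure, rRNA
conservation, codon-usage realism beyond base composition, control-region
tandem repeats, and any phylogenetic correlation between clade members
(taxa are independent draws, not a tree). Passing tests therefore
demonstrate correctness of the *analyses* on data with known truth, not
that real mitogenomes will show these exact values.

Divergence scenarios are separate. Codon mode plants Poisson-sampled
synonymous and nonsynonymous events (expected counts = rate × NG86 sites of
the ancestor), choosing uniformly among candidate single-nucleotide changes
of the required class and never creating stops; truth records realized
event counts. Nucleotide mode evolves chains of taxa under a continuous-time
TN93 process (matrix exponential of the scaled generator), with transition
rate ratios κ1 = κ2 = 4 and stationary frequencies (0.4, 0.1, 0.1, 0.4) by
default; truth is the expected distance per step.

## Problem sizes and numerical choices

Seeded simulations use sizes chosen to make sampling error small relative
to the assertions: TN93 recovery at 10 kb × 20 replicates (median error
< 0.01 at d = 0.1), Ka/Ks recovery at 500 codons × 100 replicates (mean
Ka/Ks within 25% of the true 0.1), clade analyses at the study's n = 17.
All random number generation flows from explicit integer seeds through
numpy `default_rng`; sequence construction uses integer RNG state only, so
outputs are byte-stable across platforms. Undefined quantities (zero-
denominator skews, Ks = 0 ratios, saturated distances) are represented as
flagged `None`, and every table writer preserves the flag rather than
substituting a number.
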