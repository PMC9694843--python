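# mitocomp

Comparative analysis of annotated mitochondrial genomes, built for the kind
of question asked of insect (especially lepidopteran) mitogenome panels: how
is the circular ~15 kb molecule organized, how biased is its composition and
codon usage, which gene junctions are conserved across taxa, has the tRNA
gene order been rearranged, and how fast is each protein-coding gene
evolving?

It is a library plus a `mitocomp` command line, aimed at researchers who have
annotated mitogenomes (GenBank flat files, or FASTA + feature tables) and
want the standard comparative battery without stitching together half a
dozen GUI tools.

## What it computes

- **Composition and strand asymmetry.** Base percentages, A+T content, and
  the skews AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), for whole
  genomes and for J-/N-strand protein-coding gene (PCG) sets.
- **Codon usage.** Start/stop codon classification under NCBI translation
  table 5 (invertebrate mitochondrial), including incomplete T/TA stops;
  relative synonymous codon usage RSCU(c) = n_c / mean(n over c's synonymous
  family), with the conventional Leu1/Leu2 and Ser1/Ser2 family split;
  amino-acid usage.
- **Junction conservation.** Overlaps, abutments and intergenic spacers of
  adjacent genes on the circle, cross-taxon motif conservation (e.g. the
  lepidopteran ATGATAA atp8/atp6 overlap), and control-region localization
  from unannotated gaps.
- **Gene order.** Signed circular gene-order extraction and breakpoint
  comparison against shipped references: the ancestral insect arrangement
  (trnI-trnQ-trnM), the typical lepidopteran rearrangement (trnM-trnI-trnQ),
  and a chironomid variant (trnI-trnM-trnQ).
- **Molecular evolution.** Pairwise Ka/Ks by the Nei–Gojobori (1986)
  pathway-counting method with Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3), and Tamura–Nei (1993) distances with
  transition/transversion proportions for substitution-saturation checks.
- **Supermatrix preparation.** 13-PCG harvest, a simple logged column
  filter, concatenation with per-gene charsets, and NEXUS/PHYLIP/FASTA
  export for external tree inference.
- **Synthetic data.** A generator of annotated mitogenomes and divergence
  scenarios with machine-checkable ground truth, so every stage is testable
  without downloads.

## Worked example

```python
from mitocomp import make_clade
from mitocomp.composition import composition_table
from mitocomp.junction_scan import conserved_junctions
from mitocomp.gene_order import classify_against_references

clade = [g for g, _ in make_clade(n=3, seed=1, taxon_prefix="moth")]
print(composition_table(clade).to_string(index=False))
for c in conserved_junctions(clade):
    if c.is_universal and c.motif:
        print(c.gene_pair, c.relation, c.motif)
name, cmp_, _ = classify_against_references(clade[0])
print("gene order:", name, cmp_.breakpoints, "breakpoints")
```

prints

```
Species  Size (bp)  T (%)  C (%)  A (%)  G (%)  AT (%)  GC (%)  GT (%)  AT skew  GC skew
 moth00      15251   39.1   12.6   39.9    8.4    78.9    21.1    47.5     0.01     -0.2
 moth01      15249   38.0   13.9   38.8    9.3    76.8    23.2    47.3     0.01     -0.2
 moth02      15250   38.5   13.3   39.3    8.9    77.8    22.2    47.4     0.01     -0.2
('atp8', 'atp6') overlap ATGATAA
('cox1', 'trnL2') overlap TCTAA
('trnS2', 'nad1') spacer ATACTAA
('trnW', 'trnC') overlap AAGCCTTA
gene order: lepidoptera_typical 0 breakpoints
```

Each row is one genome: size, base percentages, A+T and G+C content, and the
two skews (A+T-rich, negative GC skew — typical of moth mitogenomes). The
conserved-junction lines are the motifs shared identically by every taxon,
and the gene order matches the derived lepidopteran trnM-trnI-trnQ
arrangement with zero breakpoints.

The same analyses run from the shell:

```sh
mitocomp simulate --n 17 --seed 1 --out genomes/
mitocomp all --in genomes/ --out-dir reports/
```

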