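# ecoconverge

Convergence genomics on time-calibrated phylogenies.

When the same phenotype evolves repeatedly — such as the gleaning,
trawling and aerial-hawking foraging ecomorphs of *Myotis* bats, each of
which arose independently in several biogeographic regions — a central
question is whether the repeated phenotype is built from the **same genes**
(gene reuse) or from **different genes with similar functions**.
`ecoconverge` implements the downstream analysis layer that answers this
question from three standard streams of per-gene evidence:

1. **Selection screens** — per-branch p-values from a branch-site
   random-effects test (e.g. aBSREL), corrected by Benjamini–Hochberg FDR
   *within each gene across its tested branches*, and aggregated into a
   gene × branch selection matrix that distinguishes selected / tested /
   absent cells.
2. **Relative evolutionary rates (RER)** — per-gene branch lengths are
   regressed (after a variance-stabilizing transform, with per-branch
   heteroscedasticity correction) on genome-average branch lengths; the
   standardized residuals r_gb are associated with a 0/1 foreground
   indicator (terminal branches of one ecomorph) via Kendall's tau-b,
   with exact p-values where tractable.
3. **Protein convergence (omega_c)** — branch-pair convergence records are
   filtered at omega_c >= 3 in `any2spe` mode with foreground restriction.

On top of these it computes the ecomorph-level quantities of interest:
per-group gene sets and their Venn partition (exclusive fractions),
three-way evidence overlap, **gene reuse versus divergence time** — for a
species pair (a, b) the node age is `t_ab = (d(a, MRCA) + d(b, MRCA)) / 2`
and the reuse proportion is `s_ab = n_shared(a,b) / max_pairs n_shared`,
regressed as `s_ab ~ t_ab` by OLS — and hypergeometric GO enrichment with
BH q-values, GO-depth filtering, a matched-size randomization null, and
per-species robustness checks.

Because the derived tables of a real 30-genome screen are bulky, the
package ships a first-class synthetic-data generator (`ecoconverge.synth`)
that emulates the assumed statistical structure end to end: an
ultrametric pure-birth ingroup with repeatedly evolved ecomorphs plus an
outgroup ladder, foreground-accelerated rate matrices, selection screens
with age-decaying within-ecomorph sharing, and GO annotations with
planted enriched terms. Every stage is seeded and bit-reproducible.

## Worked example

Run the full pipeline on simulated data (2,000 genes, 30 taxa):

```bash
ecoconverge pipeline --seed 11 --out demo_run
```

which prints and writes (`demo_run/summary.json`, abridged):

```
group sizes: {'aerial_hawker': 427, 'gleaner': 270, 'trawler': 379}
exclusive fractions: {'aerial_hawker': 0.684, 'gleaner': 0.637, 'trawler': 0.628}
reuse (all same-ecomorph pairs): slope=-0.0142  R2=0.406  P<1e-12  (74 pairs)
branch bias check: R2=0.062  P=0.059
RER-significant genes: {'aerial_hawker': 113, 'gleaner': 112, 'trawler': 123}
omega_c-significant genes: {'aerial_hawker': 29, 'gleaner': 27, 'trawler': 30}
enrichment (gleaner): 1 term at q<0.05: T0001 (the planted term)
```

Reading these numbers: each ecomorph's gene set is the union of genes
selected on its species' terminal branches; ~63–68% of each set is
exclusive to that ecomorph. The reuse regression slope is negative
because the generator's sharing probability decays with pair age
(`lambda_age = 0.05` per My), so recently diverged pairs reuse more
genes. The branch-representation bias check is non-significant, i.e.
selection counts are not driven by how often a branch appears in gene
alignments. The planted GO term is recovered at q < 0.05.

The same stages are available individually (`ecoconverge simulate`,
`screen`, `rer`, `converge`, `reuse`, `enrich`, `validate`) and as
library functions.

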