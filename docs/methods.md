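# Methods

This note documents the models, numerical choices and limitations of
`ecoconverge`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Branch identity

All analyses match branches between a species tree and per-gene
(possibly pruned) trees. A branch is identified by the set of tip labels
descending from its child node (`BranchID`). Under pruning to a taxon
subset K, the surviving branch's identity is the original clade tip set
intersected with K, so the same biological branch keeps one identity
across thousands of gene trees. Terminal branches are singleton sets,
which is what makes "the terminal branch of species X" a stable handle
for foreground definitions. Pruning collapses degree-2 nodes by summing
branch lengths; pairwise path lengths among kept tips are preserved to
float precision (tested at 1e-9).

Node age for a pair (a, b) is the mean of the two tip-to-MRCA path
lengths. On an ultrametric chronogram this equals MRCA depth;
ultrametricity is checked (absolute tolerance 1e-6 My) and reported, not
enforced, since penalized-likelihood chronograms can deviate slightly.

## Selection screen aggregation

Branch-site tests report one p-value per tested branch per gene.
Correction is Benjamini–Hochberg, applied **within each gene across its
tested branches** (never across genes); the flavor and the default
threshold alpha = 0.05 are configuration. The gene × branch matrix keeps
three states — selected (q <= alpha), tested-but-not-selected, absent —
because a branch missing from a gene's alignment is not evidence of no
selection; every downstream count respects the distinction (e.g. pair
sharing can only count genes tested in both species).

The branch-representation bias check regresses per-branch selected-gene
counts on per-branch test counts (simple OLS; R², F = t², two-sided p).
A strong positive fit would indicate that patchy genome completeness,
not biology, drives the screen.

## Relative evolutionary rates

For gene g, let L_gb be its branch lengths and M_b the per-branch mean
over genes ("master" lengths, requiring >= `min_genes` = 5 observations
per branch). After a square-root transform (log1p switchable), each gene
is regressed on the transformed master lengths and the residuals are the
RERs. Heteroscedasticity is handled in three steps:

1. an unweighted first pass estimates residual variance per branch
   (default `branch-variance`; a 10-bin master-length binning is the
   `binned-variance` alternative — each branch here is observed across
   many genes, so the direct per-branch estimate is sharper than a bin
   average when noise scales differ within a bin);
2. a weighted refit uses inverse-variance weights, and residuals are
   internally studentized (scaled by sqrt(w) and sqrt(1 - h), h the
   weighted leverage) so heavily weighted or extreme-master branches are
   not artificially shrunk;
3. each branch's residual column is empirically rescaled to unit
   across-gene scale (two iterations), making ranks comparable between
   branches.

Without steps 2–3 the trait-association null is visibly conservative
(short branches acquire huge weights, near-unit leverage, and near-zero
residuals), which is why the construction is more elaborate than a plain
weighted regression. Residuals below float-noise scale are zeroed so an
exactly proportional gene reports RER = 0 rather than amplified rounding
error. Genes with fewer than `min_n` = 10 usable branches are skipped.

Phylogenetic covariance of residuals beyond the master-tree regression
is **not** modeled. This is a stated limitation: closely related branches
share unmodeled rate variation, and on real data the association test is
accordingly optimistic for clustered foregrounds. The synthetic
generator draws branch noise independently, so passing calibration tests
here does not certify calibration under real phylogenetic correlation.

## Trait association and Kendall p-values

Association per gene is Kendall's tau-b between RERs and a 0/1
foreground indicator (terminal branches of one ecomorph), alpha = 0.01.
P-values are exact wherever an exact null is tractable:

- n <= 9: full permutation enumeration of the y ranks (the tau-b
  denominator is permutation-invariant, so numerators are compared);
- binary indicator, untied residuals (the pipeline's standard case): the
  exact Mann–Whitney null, since for a 0/1 grouping |tau_b| is monotone
  in |U − m(n−m)/2|; the two routes agree exactly on their overlap
  (tested);
- otherwise: the tie-corrected normal approximation.

The exact binary branch matters: with 5 foreground branches out of ~55
the normal approximation is conservative by 2–4x at the 0.01 tail, which
would break the type-I calibration the test suite checks (fraction of
null genes at p <= 0.01 inside the binomial 99% CI of 0.01, pooled over
the three foregrounds at 2,000 genes).

## Convergence aggregation and gene reuse

Ecomorph gene sets use the **at-least-one-species** rule over terminal
branches. Venn partitions report the seven exclusive region counts and
each set's exclusive fraction. The omega_c filter retains genes with at
least one branch-pair record at omega_c >= 3 (inclusive), mode
`any2spe`, and >= 1 branch of the pair in the foreground (a flag demands
both; the published analyses do not state which, so >= 1 is the default).
Evidence overlap reports the three-way partition plus the share of
screen-selected genes carrying each convergence signal.

Gene reuse: for every same-ecomorph species pair, the shared selected
gene count is normalized by the maximum observed count, so the
max-attaining pair scores exactly 1.0 — normalizing by the full gene
universe would compress all values into a sliver and require a log
rescale to read. Proportions are regressed on node age by OLS (raw-count
regression is offered as sensitivity; it has the identical R² and a
slope scaled by the maximum, tested to 1e-12). Node ages always come
from the full, unpruned chronogram. Cross-ecomorph pairs are excluded by
default; outgroup pairs can be included for contrast. GO-restricted
variants recompute counts over one term's annotated genes (descendants
folded in when a term graph is supplied) and renormalize by the
restricted maximum. Genes untested in either species of a pair cannot
contribute to its shared count — a documented decision, since published
descriptions leave the handling of missing tests open.

## Enrichment

One-sided hypergeometric upper tail P(X >= k) per term, BH across terms,
significance at q < 0.05, `log_q = log10(q)`. The default background is
the screened/annotatable gene universe, not the whole genome —
conditioning on testability. With a term graph, genes annotated to a
term count for all its ancestors; flat GMT mode skips propagation. The
GO-depth filter keeps terms within 5 is_a steps below a configured root
term.

The randomization null redraws gene sets of the observed size uniformly
from the background and recomputes each term's p. Two summaries are
reported: `empirical_p = (1 + #{null <= obs}) / (1 + draws)` (add-one,
conservative under ties) and `empirical_mid_p`, which splits ties
between null and observed values. The hypergeometric statistic is
discrete, so the add-one form is systematically conservative; the mid-p
is the uniform-under-null quantity and is what the calibration test
checks (KS against U(0,1)). Draws default to 1,000 in configuration and
are reduced in test/acceptance runs for speed; the seed is mandatory.

Per-species enrichment reruns the test on each species' own selected
set and reports terms significant in >= m species, guarding against a
single species driving a group-level signal.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions and were chosen once:

- **Tree**: 30 taxa = 22 ingroup (5 gleaners, 8 trawlers, 9 aerial
  hawkers — the sampled radiation's proportions) + 8 outgroups. The
  ingroup is a pure-birth (Yule) tree scaled to a 22 My crown;
  outgroups attach as a ladder up to the 52 My root. Ecomorph labels
  are shuffled until every ecomorph is non-monophyletic (repeated
  evolution); regions are clade-contiguous blocks. A fixed 30-taxon
  fixture (seed 2024) ships in `ecoconverge/data/`.
- **Rates**: cell = time length × per-gene rate (lognormal, sigma 0.25)
  × mu_fg on foreground branches of convergent genes × lognormal noise
  (sigma 0.3), ~0.002 subst/site/My baseline; 5% absent cells.
- **Screen**: baseline cells selected at pi0 = 0.02; a convergent gene
  (rho_conv = 0.05 per ecomorph) picks a focal species and selects each
  member with probability p_fg × exp(−lambda_age × age(member, focal)),
  p_fg = 0.8, lambda_age = 0.05/My — a latent shared pool whose
  retention decays with divergence time. P-values are Beta(0.05, 10)
  for planted cells, Uniform(0,1) otherwise, then adjusted in both
  directions (planted failing within-gene BH are shrunk; unplanted
  passing are resampled upward) until the BH call at alpha exactly
  reproduces the planted truth — so readers recover the intended matrix
  and a zero-rate configuration yields an exactly empty screen.
- **Annotations**: 40 terms of 10–120 genes; planted terms over-sample
  convergent genes with weight 8.

Not emulated: sequence-level evolution (no alignments or codons),
phylogenetically correlated rate noise, gene-tree/species-tree
discordance, and the internals of the selection or convergence
statistics themselves (their outputs are simulated directly). Tests that
pass on this generator therefore validate the analysis layer's
statistics and bookkeeping, not the upstream inference tools.

## Problem sizes and determinism

Calibration runs use 2,000 genes × 30 taxa; replicate-heavy recovery
runs use 100 seeded replicates of 300-gene screens and 40 seeds of
600-gene annotation draws — sizes at which every Monte-Carlo band in the
tests is stable. Each generator stage draws from an independent
substream of one configured seed; identical configs are bit-identical,
and the pipeline's `summary.json` is byte-reproducible under a fixed
config (tested). Degenerate inputs have defined behavior: alpha = 0
yields empty gene sets that propagate cleanly, an all-zero shared-count
table is an error at normalization, all-tied Kendall input is an error,
and a constant OLS response returns slope 0 with R² = 0 by convention.
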