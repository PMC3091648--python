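# Methods

## Model and assumptions

`tfnet` treats regulatory inference as evidence fusion. The working
assumptions are the classic ones of integrative network reconstruction:
target genes sharing expression and functional similarity are likely to be
regulated by the same TF(s); functional binding sites are conserved and
concentrate near the transcription start site; positive TF–target expression
correlation is supportive evidence; and independently curated interaction
records raise confidence multiplicatively rather than absolutely. None of the
four layers is trusted alone — each is noisy and biased in a different way —
so the pipeline scales each to `[0, 1]`, sums, renormalizes, and only then
ranks.

### Differential filtering

Per two-group experiment, an unpaired Student t-test on log2 values
(pooled-variance form; Welch available via `equal_var=False`), an absolute
fold change on the linear scale (`max(r, 1/r) ≥ fc_min` with `r` the ratio of
linear group means), and a minimum Present-call fraction computed over all
samples of the experiment. No multiple-testing correction is applied: the
filters are a conjunction and the downstream analysis is robust to a
calibrated false-positive floor. Zero-variance degenerate groups return
p = 1 when the group means agree and p = 0 when they differ, so constant
synthetic fixtures behave sensibly. Genes flagged in `min_experiments`
distinct experiments become candidates; the default of 5 suits a large
perturbation compendium, while the synthetic benchmark — one perturbation per
TF, so a gene can respond in at most one condition — runs at 1.

### FLAME clustering

Fuzzy clustering by local approximation of membership. Distances default to
1 − Pearson correlation between expression profiles (co-expression is a
pattern, not a magnitude). Each gene gets k = 7 nearest neighbours; density
is the reciprocal of the mean kNN distance; neighbour weights are
proportional to the neighbour's density and normalized per gene. A gene is a
cluster-supporting object (CSO) when its density strictly exceeds all its
neighbours' (ties resolved toward the lexicographically smallest identifier,
making the all-identical corner case deterministic); it is an outlier when
its density lies below mean − 2·SD of all densities and below all its
neighbours'. CSO and outlier rows are fixed indicator vectors; every other
row is iteratively replaced by the weighted average of its neighbours' rows
(row-stochasticity is invariant) until the maximum absolute row change drops
below 1e-6 or 500 steps elapse. Non-convergence is reported, not fatal. The
fixed point is also available exactly as the solution of the linear system
`(I − W_RR) M_R = W_RF M_F`, which the tests use as an independent oracle.
Genes join every cluster where membership ≥ 0.35 — the membership range is
read as an assignment cutoff, so a gene can belong to at most two clusters.

### Annotation similarity and enrichment

Kappa is Cohen's chance-corrected agreement on the 2×2 term
presence/absence table over the catalog's term universe; negative raw values
are clamped to 0 so the statistic lives on `[0, 1]`. Pairs with an
unannotated side are recorded as missing, never as 0. Cluster themes use a
one-sided Fisher exact (hypergeometric upper-tail) test against the annotated
universe, reported when p < 0.01 and the term covers > 20% of the cluster.
The universe is whatever the supplied catalog annotates — the pipeline is
agnostic to whether terms are GO classes or any other vocabulary.

### Motif analysis

Only conserved hits count. The TFBS score per (motif family, gene) is 0 /
1 / 2 for zero, one, or multiple conserved occurrences; family→TF expansion
happens at reporting time, scoring stays at family level. Over-representation
per cluster is an exact hypergeometric test on hit-bearing gene counts
against the hit-table universe minus the cluster (configurable to a supplied
background). The conserved-region analysis uses the 3-kb upstream window at
α = 0.005; the proximal analysis uses −1000..+200 around the TSS at
α = 0.05 (the two published descriptions of the proximal window, "1.2 kb"
and "1 kb + 200 bp", are treated as the same −1000..+200 window). Hit
frequency (mean conserved proximal hits per cluster gene) is only determined
for promoter-enriched motifs — others are ND and excluded from the frequency
ranking. The average of the three available ranks (fractional ranking,
ties averaged) maps linearly onto the heatmap scale `[−2.5, 2.5]` and onto
the importance weight `I ∈ [0.8, 1.2]`, best rank highest; a single motif or
an all-tied field sits at the midpoint (0 and 1.0). This exact-test ranking
deliberately replaces score-based scanner statistics: it makes the
enriched/not-enriched decision reproducible and unit-testable while keeping
the same decision structure.

### Interaction evidence

Per pair, the maximum applicable level: 1 for any single computational or
high-throughput record or co-citation ≤ 10; 2 for evidence from more than
one resource with co-citation ≥ 10; 3 for direct experimental evidence or
the multi-source class. The published level-2/level-3 wordings overlap
("multiple resources" appears in both); the implementation distinguishes
them by record class — a record explicitly curated as multi-source is
level 3, while two independent single-source records with high co-citation
are level 2 — and conflicts always resolve upward (higher score, more
certainty).

### Integration

Scaling: TFBS `{0,1,2} → {0, 0.5, 1}`; interaction `{0..3} → {0, ⅓, ⅔, 1}`;
kappa unchanged; correlation rectified (`max(r, 0)`) because a positive
TF–target correlation is the supportive direction — a signed mode mapping
`[−1,1]` linearly onto `[0,1]` is available behind a flag. Missing entries
impute to 0: absent evidence contributes nothing. The entry-wise sum is
min-max normalized over the whole matrix into Score; a constant all-zero
matrix stays 0 and a constant positive one maps to 1. Axis grouping uses
average-linkage agglomerative clustering on Euclidean distances over each
item's concatenated scaled-layer profile, with `ceil(n/8)` clusters when no
count or cut height is given — small co-regulated groups. Support is the
block mean of Score; pairs at or above 0.25 are kept. Confidence multiplies
five equally weighted factors, each floored above zero (`L ∈ [0.5, 1]`,
support factor likewise, `I ∈ [0.8, 1.2]`): the floors-and-straddling-1
construction is the signature of multiplicative modifiers, so the factors
combine by product with no exponents. Only four factors are fully pinned
down by the published prose; the remaining inter-cluster factor is
instantiated as the cluster-pair Support rescaled into `[0.5, 1]` — the only
defined quantity at that granularity — and can be switched off. Confidence
is min-max normalized globally over the scored pairs of **all** clusters
(per-cluster normalization is available but destroys cross-cluster
comparability and compresses tight high-confidence clusters; the global
choice is the default for exactly that reason). Ranking is by descending
confidence with deterministic (TF, gene) tie-breaks.

### Validation

The overlap test is an exact upper-tail binomial: with background rate the
response-set fraction of the analysis universe, `P(X ≥ overlap)` for the
predicted set. High-confidence predictions use score > 0.55, low-confidence
negative controls score < 0.45, with never-scored genes counting as
confidence 0. Response calls from a held-out deletion experiment default to
decreased-only (a knockout should lower its direct targets); any-direction
mode is available. Synthetic runs additionally report edge-level
precision/recall over a cutoff grid and rank AUROC over all TF×gene pairs of
the planted axes.

## Synthetic data: what it emulates, and what it does not

The generator plants one module of co-regulated genes per TF and simulates,
per TF, one knockout-style experiment in which the TF and its module drop by
`effect_size` (log2) in the mutant group; everything else is i.i.d. Gaussian
noise around gene-specific baselines. Annotation, motif and evidence layers
are drawn so that co-module genes share term blocks (`p_shared_term`), true
targets carry their regulator's motif more often than background
(`p_motif_true` vs `p_motif_bg`, hit counts 1 + Poisson(0.7) so single and
multiple occurrences both occur, placed 60/40 in proximal vs upstream
conserved windows), and a `p_evidence` fraction of true edges has a curated
record (geometric co-citations, mean 6, exercising both sides of the
co-citation threshold).

Default configuration: 200 genes + 6 TFs, modules of 12, 6 experiments with
3+3 replicates, `effect_size = 1.0` on log2 (= 4 × the within-group SD of
0.25 — well-separated but not trivial), Present rate 0.9, 60-term catalog
with 5 terms per module, `p_shared_term = 0.8`, `p_motif_true = 0.8`,
`p_motif_bg = 0.1`, 6 decoy motif families, `p_evidence = 0.3`. The module
size of 12 is deliberately larger than the FLAME neighbourhood (k = 7):
density seeding resolves one cluster per module only when modules exceed the
neighbourhood, which mirrors real compendia where co-expression clusters
(tens to hundreds of genes) dwarf k. The problem size keeps a full
20-seed benchmark under ten seconds on one CPU.

What the generator does **not** emulate — so what passing tests do not show:
probe-level artifacts and normalization residue; correlated noise between
experiments; TFs regulating several modules or modules with several
regulators; motif positional structure (no sequence, no PWM scanning — hits
are simulated at the table level); biased or adversarial curation in the
evidence layer; and any indirect (cascade) regulation. Recovery numbers on
this benchmark are an internal-consistency check of the pipeline, not an
estimate of accuracy on real tissue data.

## Numerical choices

* Densities use `1/(mean kNN distance + 1e-12)`; correlation distances of
  constant profiles are treated as maximal (2.0).
* Membership convergence: max absolute row change < 1e-6, cap 500 steps.
* All hypergeometric/binomial tails are exact (scipy survival functions);
  tests pin them to brute-force enumeration at 1e-12.
* Min-max normalizations map degenerate all-equal inputs to 1.0 (equally
  supported), except the integrated Score of an all-zero matrix, which
  stays 0.
* Ties: fractional (average) ranks in motif analyses; lexicographic
  identifiers for CSO seeding, prediction ranking and hub selection.
* Importance and heatmap scales are clipped to their nominal intervals to
  absorb floating-point spill at the endpoints.

## Known limitations

* The Confidence factor set includes one instantiated (not published-prose)
  inter-cluster factor; it is configurable off, and the multiplicative
  combination is a design reading of "equally weighted".
* Hierarchical clustering granularity (`ceil(n/8)`) is a heuristic; the cut
  is exposed (`n_clusters`, `cut_height`) because no principled default
  exists at this problem size.
* Negative correlations are discarded by default; repressive regulation is
  only visible in the signed-correlation mode.
* The per-experiment Present-call filter (67%) is aggressive for small
  groups: with 6 samples it effectively demands 5 Present calls.
* FLAME cluster count is emergent (one per CSO); there is no cluster-number
  selection, by design.
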