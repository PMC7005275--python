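# Methods

`anchorscreen` implements the analysis of *anchor screens*: genome-wide
pooled CRISPR knockout screens run in a population carrying a pre-delivered
anchor-gene perturbation, compared against a matched control population.
The readout is a map of genetic interactions with the anchor gene —
synthetic-lethal partners (knockout hurts more in the anchor background)
and buffering partners (knockout hurts less).

## Read deconvolution

Library guides are recovered from sequencing reads by scanning for the
vector sequence `CACCG` that sits immediately 5′ of every sgRNA insert; the
20 nt that follow its first occurrence are the spacer. A read is assigned
to a cell of the guide-by-condition count matrix only when the spacer
matches a library spacer exactly and the read's 8-nt sample barcode (from
the P7 primer, carried as a per-read field) matches a known condition
exactly. Reads with no anchor, a truncated spacer, an `N` basecall in the
spacer window, or an unknown spacer/barcode are tallied in the run
statistics and otherwise ignored; nothing is error-corrected. Exact
matching keeps counting deterministic and order-independent — the suite
asserts that shuffling the read stream or round-tripping a count matrix
through simulated FASTQ reproduces counts bit for bit. Guides never
observed still get explicit zero rows, which the pseudocount below relies
on.

## Normalization and fold-changes

Counts are normalized within each condition to reads per million, then
log2-transformed after adding a pseudocount of one:

    norm(g, c) = log2( count(g, c) / total(c) × 1e6 + 1 )

The pseudocount is applied after RPM scaling, so zero counts map exactly to
zero and RPM values stay scale-invariant. The guide-level log2 fold-change
is `norm(g, c) − norm(g, pDNA)`, where the pDNA column is the sequenced
plasmid library that defines initial abundance. Biological replicates are
averaged at the LFC level (arithmetic mean per arm) before model fitting;
per-replicate scoring is available by passing replicate columns directly.
Guides with zero pDNA reads are kept by default (their LFC is finite via
the pseudocount) but can be listed and dropped.

## Interaction scoring

For each perturbed arm, the arm's guide LFCs (y) are regressed on the
control arm's guide LFCs (x) with a least-squares natural cubic spline with
three degrees of freedom plus an intercept. The spline absorbs the shared
fitness trend between the arms, including the mild nonlinearity introduced
by normalization and saturation; the residual of each guide is its
interaction phenotype (positive = buffering, negative = synthetic lethal).

Basis conventions (configurable, defaults documented here): three basis
columns built by the truncated-power natural-spline construction on four
knots — boundary knots at min(x) and max(x), two interior knots at the 1/3
and 2/3 quantiles of x. The span contains all affine functions of x and is
linear beyond the boundary knots, so extrapolation is tame. The fit is
solved by `numpy.linalg.lstsq`; tests check predictions against an
independent normal-equations solve on the explicitly constructed basis to
1e−8.

Gene-level aggregation: with r̄_g the mean residual of gene g's n_g guides,
r̄ and s the mean and sample (n−1) standard deviation of all guide
residuals,

    Z_g = ( r̄_g − r̄ ) / ( s / √n_g )

assuming residuals are approximately normal and the all-guide moments
represent the null. r̄ is ≈ 0 by construction (the fit has an intercept)
but is subtracted explicitly. Genes are ranked ascending (rank 1 = most
synthetic lethal) and descending (rank 1 = most buffering), ties broken by
gene symbol so output is deterministic. Z-scores from several screens of
the same anchor are combined as a plain arithmetic mean per gene (genes
missing from a screen are excluded from that screen's average, not
imputed), re-ranked by |avg Z|. Screens report no p-values: Z and rank are
the interface, which avoids overstating calibration under guide-to-guide
variance heterogeneity (see limitations).

## Gene-set benchmarking

A scored screen is benchmarked against a curated gene set with the
one-sided two-sample Kolmogorov–Smirnov statistic
D⁺ = sup_x [F_in(x) − F_out(x)], where F_in / F_out are empirical CDFs of
Z for set members and non-members among scored genes (members absent from
the screen are dropped and logged). The default alternative targets
sensitizer sets (in-set shifted toward negative Z); a flag flips the
direction for resistance sets. The p-value uses the asymptotic
approximation exp(−2 D⁺² m n/(m+n)), capped at 1; it is set-size dependent,
so D⁺ is the quantity to compare across sets. The sup is evaluated at the
observed breakpoints only, which is exact for step CDFs; tests verify
equality with a brute-force double loop on thousands of small instances,
including heavy ties.

## Hit networks

Genes with |avg Z| strictly above a threshold (default 2.0) become nodes.
Edges come from an external association source: a co-essentiality Pearson
correlation matrix (edge iff |r| > 0.2, weight |r|) or a combined-score
pair list on the 0–1000 scale normalized to [0, 1] (edge iff score > 0.4,
weight score). Cutoffs are strict inequalities; hit genes absent from the
edge source remain as isolated nodes.

Communities are found by weighted-modularity optimization. The optimizer
is Louvain-style greedy ascent hardened in two ways, both deterministic
given the seed: (1) four seeded Louvain restarts plus eight
random-partition starts; (2) every candidate partition is polished by a
Kernighan–Lin move sweep — repeatedly apply the globally best single-node
move (to any community or a fresh singleton) even when its immediate gain
is negative, lock the moved node, and rewind to the best partition seen.
The sweep escapes the local optima that pure Louvain aggregation locks in;
on random ≤8-node weighted graphs the returned modularity matched
exhaustive enumeration over all partitions in 1,000/1,000 instances, and a
210-node network clusters in about two seconds. Gains are computed
incrementally from node-to-community weight tables, so the polish is
O(n²·k) per sweep.

Edge enrichment of the hit set is tested against a null of uniform random
gene subsets of the same size drawn without replacement from a declared
universe (default: all genes scored), re-thresholded identically; the
add-one empirical p-value (1 + #{null ≥ observed})/(1 + n_draws) never
returns zero. Layout/visualization is exported (edge list, cluster table,
GraphML), not rendered.

## Synthetic screens and ground truth

The generator emulates the structure of the real screens so every stage is
testable at desk scale, with all planted quantities returned as ground
truth:

- **Library**: `n_genes × guides_per_gene` guides, default 4 guides/gene
  (Brunello-like); random unique 20-nt spacers and 8-nt condition barcodes
  for FASTQ emission.
- **Plasmid pool**: lognormal guide abundance, log-sd 0.5 (a realistically
  tight modern library; the real pools' spread is not published), scaled to
  the sequencing depth.
- **Fitness and interactions**: 10% of genes get a fitness cost f_g ≤ 0
  drawn as −Gamma(2, 0.5) log2 units over the screen (mean −1); 5% of genes
  carry an interaction δ_g of magnitude 1, half buffering (δ > 0) and half
  synthetic lethal (δ < 0), planted independently of fitness. Expected
  abundance changes by 2^(e·f) in the control arm and 2^(e·(f+δ)) in the
  anchor arm — the interaction is additive on the expected log2 scale,
  which is exactly what residual-from-control-trend scoring measures.
  Incomplete anchor editing is a mixture weight on the anchor term
  (default 1 = fully edited).
- **Guide efficacy**: e ~ Beta(5, 1) (mean 0.83, most guides effective),
  scaling both fitness and interaction.
- **Counts**: negative binomial per replicate with var = μ + α μ²,
  dispersion α = 0.05 (mild overdispersion typical of pooled screens;
  α = 0 gives Poisson), two replicates per arm, 500 reads/guide.

What the generator does *not* emulate: off-target editing, indel spectra,
copy-number artifacts, guide-guide competition, time dynamics within the
screen, or mechanistic drug response (inhibitor arms are just alternative
δ profiles). Passing recovery tests therefore demonstrates that the
statistics behave as designed under the stated generative model, not that
real screens are free of these additional effects.

The knockout-dilution growth model motivating the anchor design is
included: a knockout subpopulation at initial fraction f₀ growing at
`relative_rate` times the wild-type rate (wild type doubling daily) has

    f(t) = f₀·2^(r·t) / ( f₀·2^(r·t) + (1−f₀)·2^t )

With f₀ = 0.9 and r = 0.8, f(21 days) = 0.329 — a 90% knockout pool decays
below half the population in three weeks of pre-screen expansion, which is
why anchor editing is triggered simultaneously with the library. A "20%
slower growth" is read as rate × 0.8; reading it as doubling time / 0.8
gives the same exponent.

Planted co-essentiality structure for network tests uses a one-factor-per-
block model (members load √r on a shared factor), giving exactly r within
blocks and 0 elsewhere; a background-noise sd of σ is realized by sampling
⌈1/σ²⌉ profiles and returning their sample correlation, so σ → 0 recovers
the exact matrix and the result is always symmetric, unit-diagonal and
positive semidefinite.

## Calibration and recovery (what the tests compute)

- **Null calibration**: on a 5,000-gene screen with no interactions and
  i.i.d. guide noise (uniform pDNA abundance, no fitness genes — so NB
  variance is identical across guides), the gene Z distribution is standard
  normal: 5% ± 1% beyond |Z| = 1.96, mean within ±0.05, sd within 1 ± 0.05.
  With the default lognormal abundance the guide variances are
  heterogeneous and gene Z is slightly heavy-tailed (≈6% beyond 1.96) —
  a real property of pooled-sd Z-scores worth remembering when reading
  screen output.
- **Recovery**: interactions planted at |δ| = 2× the guide residual sd
  (measured on a matched null run) in 5% of 1,000 genes are recovered with
  the correct sign in ≥95% of cases, and the median ascending rank of
  synthetic-lethal genes lands in the top 5%.

## Numerical and degenerate-input choices

- Spline fitting requires ≥10 points and non-constant x; duplicated knots
  (x with too little spread) raise rather than silently degrade.
- `gene_z` raises on zero overall residual sd (degenerate screen) and on
  unmapped guides; guides mapping to multiple genes are rejected at load.
- Zero-total count columns raise, naming the condition.
- KS enrichment raises when a set covers none or all of the scored
  universe.
- Empirical edge-enrichment p-values use the add-one estimator, bounded
  away from 0.
- All stochastic components (simulation, Louvain restarts, null draws)
  take explicit seeds and are bitwise reproducible.

## Problem sizes

Desk-scale defaults are used throughout the suite: 5,000 genes for
calibration, 1,000 for recovery, hundreds of guides for deconvolution
round-trips, ≤8 nodes where exhaustive partition enumeration serves as the
clustering oracle, and 50–1,000 random instances per oracle equivalence.
These sizes give stable Monte-Carlo estimates at interactive runtimes; the
pipeline itself is linear in guides and handles genome-scale tables.
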