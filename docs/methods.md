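# Methods

This note documents the models behind each stage, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## Input transform

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes with no zero count), transformed to log2(x+1), and
gene-centered **once over the full cohort**. The plaid model assumes
roughly additive data, which raw counts are not; the log transform with a
pseudo-count is the standard compromise. Centering happens once rather
than per clustering round so that every layer is an excursion from the
same cohort-wide baseline; re-centering on a shrinking remainder makes the
"background" (signature-free) samples look like the strongest block as
soon as they become the minority, inverting the intended semantics.

## Plaid biclustering

Model: the matrix is a sum of layers, each contributing
`theta_ij = mu + alpha_i + beta_j` on member genes (binary rho) and member
samples (binary kappa), alpha and beta constrained to sum to zero over the
members. One layer is fitted by alternating:

1. least-squares effects given memberships (block means);
2. membership updates — a gene/sample joins iff including it (with its own
   least-squares row/column effect) strictly reduces residual SS; an
   exactly-zero change excludes, so ties shrink the layer;
3. after convergence or `inner_iters` (default 10) sweeps, release
   pruning: members whose fitted contribution (sum of theta^2 over the
   member cross-section) falls below `row_release`/`col_release` (default
   0.7) of the mean member contribution are dropped and effects refitted.

Initialization is deterministic: the four candidate blocks given by top-
and bottom-quartile loadings of the leading singular vectors; the block
with the largest absolute mean seeds the memberships. Reported layers need
at least 2 genes and 2 samples.

Retention: the fitted layer's SS must strictly exceed the best layer refit
on each of `n_shuffles` copies of the matrix with every gene's values
independently permuted. The false-retention rate of this rule is
~1/(n_shuffles+1); the default is 10 shuffles (~9%). Three shuffles — the
default of classic plaid implementations — gives ~25% and demonstrably
admits noise layers in null simulations.

`fit_plaid` subtracts each retained layer from the residual and backfits
the effect parameters of all retained layers (memberships fixed,
`backfit_iters` = 3 sweeps); by least-squares orthogonality the total SS
drops by exactly the layer SS at each subtraction.

## Sequential clustering

One retained layer per round on the remaining samples' columns; its
samples become the next cluster and are removed; genes are *not* removed,
so one gene may help define several clusters. The loop stops when no layer
is retained or when a retained layer has fewer than
`ceil(min_frac * n_total)` samples, with `n_total` the **original** cohort
size (min_frac default 0.05) — percentages under a shrinking denominator
would be meaningless, and cluster-size summaries report percentages under
both the original-cohort and the clustered-patients denominators for the
same reason.

The retention null in the sequential loop is exchangeability of each
gene's values across the **whole cohort**: permutations shuffle full
cohort rows and truncate to the remaining width. A within-subset shuffle
would leave a layer spanning all remaining samples untouched, so the last
homogeneous group could never be retained; under the cohort-wide null it
is retained exactly when its profile could not arise from random columns.

## Differential expression

Per cluster, each gene is tested against the pooled adjacent normals:

- size factors: median-of-ratios, rescaled to geometric mean 1 so results
  are invariant to a common factor multiple;
- dispersion: per-gene method of moments pooled over the two groups,
  `alpha = max(1e-8, (var - mean)/mean^2)` on normalized counts, with the
  within-group variance on n-2 denominators;
- Wald test: `log2FC = log2((m1 + 0.5)/(m0 + 0.5))` with a 0.5 pseudo-count
  for stability at zero counts; the standard error comes from the delta
  method with NB group-mean variances `(m + alpha m^2)/n`; p is the
  two-sided normal tail. Identical groups give log2FC = 0 and p = 1; when
  both group means are zero the statistic is defined as 0 (p = 1).
- BH step-up adjustment; classes: padj < 0.05 and log2FC > 2 → `up`
  (< −2 → `down`); significant but |log2FC| ≤ 2 → `minimal_up` /
  `minimal_down`; otherwise `ns`.

Null simulations (1000 NB genes, 50 vs 50, dispersion 0.1) put the
empirical rejection rate at nominal 0.05 within [0.03, 0.07]. No
dispersion shrinkage, covariates, or independent filtering: the contract
is the thresholds and classes the annotation stage consumes, at sample
sizes (tens of samples per group) where moment estimators are adequate.

## Evasion annotation

The panel is data (`resources/cancer_immunity_panel.json`): seven cycle
steps with gene sets, checkpoint sets (CTLA4; PD-1; PD-L1/2; TGF-β), decoy
sets (DcR3; TRAILR4). A gene is *up-called* when its DE class is `up` or
`minimal_up` with padj < `alpha` (0.05) and log2FC > `up_call_lfc`
(default 1). The mechanism fold-change cut is deliberately looser than the
headline DE cut of 2: a checkpoint shift need not be 4-fold to matter, and
both cuts are exposed. A step is *active* with ≥ `min_step_genes` (1)
up-called genes. Rules:

- no active step → **ignorance**;
- some step active, antigen presentation inactive, and killing or
  infiltration inactive → **impaired antigen presentation** (mutually
  exclusive with ignorance by construction);
- each checkpoint/decoy set with an up-called gene adds its
  tolerance/counterattack tag; tags combine freely with the two above.

Prevalence of a mechanism set M is the patient-weighted share of clusters
whose mechanism set contains M (or equals M in exact mode), under a caller
chosen denominator; the empty query yields the clustered fraction.
Prevalence is monotone decreasing in M by construction.

## Clinical association

`fisher_exact_2xk` enumerates every 2×k table with the observed margins
(recursive composition of the first row), weights by the multivariate
hypergeometric probability, and sums tables whose probability is at most
the observed one (relative tolerance 1e-7 against float round-off). At
k=2 this is exactly the classical two-sided Fisher test. All-zero
categories are dropped before enumeration.

Each cluster's counts are compared against the **column totals over all
clustered samples** — the cluster is included in the comparison row. This
construction, rather than cluster-vs-complement, is what reproduces the
published contingency arithmetic this pipeline mirrors, and is the
natural reading of "cluster against the overall pattern". It is slightly
conservative (the cluster contributes to both rows).

## Immune composition

Lymphocyte totals sum the LM22 B-cell (naive, memory), T-cell (all seven
subsets) and NK (resting, activated) columns. Plasma cells are excluded:
LM22 carries them as a separate population and the aggregate is defined
over B, T and NK cells; the column set is a parameter for users who want
them in. Cluster-vs-normal comparisons use Welch's t-test per cell type
with significance stars (0.05 / 0.01 / 0.001) and no multiplicity
correction — the summaries are descriptive, mirroring pairwise-test
practice for fraction panels.

## Biomarker tree

Deterministic CART: greedy binary splits maximizing Gini decrease over
all (gene, midpoint-between-consecutive-distinct-values) candidates;
values below the threshold go left, at-or-above right. Ties break toward
the smallest gene index, then the smallest threshold, making the fit
invariant to sample order. Stopping: purity, `min_leaf` (5), `max_depth`
(6), or best decrease ≤ `complexity` (0 — splits must strictly reduce
impurity; set negative to admit zero-gain splits, which XOR-like
interactions require). No cost-complexity pruning by default; resubstitution
accuracy is reported and k-fold validation is left to the caller. The
biomarker list is the distinct split genes in breadth-first order.

## Synthetic cohorts

The generator emulates the structure the pipeline targets, with planted
truth for every stage:

- counts: NB via gamma–Poisson (`var = mu + alpha mu^2`), baseline
  log2-mean per gene uniform on [3, 8] (≈ 8–256 counts);
- clusters: disjoint sample groups (default 4 groups covering 90% of 300
  tumors: fractions 0.30/0.25/0.20/0.15, remainder background) each with
  a signature of 40 filler genes, half at +layer_effect and half at
  −layer_effect (default 4) on the log2 scale — additive plaid layers by
  construction; panel genes are excluded from signatures so mechanism
  calls stay a closed loop;
- evasion patterns: per-cluster mechanism sets write +layer_effect into
  the corresponding panel genes (checkpoints, decoys, or
  trafficking+infiltration steps for impaired presentation); ignorance
  plants nothing — cycle genes stay at the normal baseline;
- clinical: categories drawn from baseline simplexes (Gleason ≤6/7/≥8 at
  0.10/0.49/0.41; T1–T4 at 0.02/0.37/0.58/0.03, resembling a
  prostatectomy cohort) reweighted by per-cluster odds multipliers;
- fractions: Dirichlet rows over the 22 LM22 cell types (base
  concentration 2) with per-cluster concentration multipliers.

Defaults are the study conditions for the closed-loop tests: 300 tumors,
30 normals, 400 genes, layer effect 4, NB dispersion 0.05. Problem sizes
in the test suite (100-tumor three-cluster cohorts, 1000-gene null
simulations, 20×20 plaid fixtures) were chosen as the smallest instances
where the statistical claims are comfortably testable.

What the generator does **not** emulate: library-size heterogeneity,
batch effects, tumor purity, gene–gene correlation within steps, or
overlapping/hierarchical cluster structure. Passing closed-loop tests
therefore demonstrate algorithmic correctness under the stated model, not
performance on real cohorts, where effect sizes are smaller and layers
are noisier.

## Numerical choices and degenerate inputs

- All randomness flows through seeded `numpy` generators; identical
  config + seed reproduces cohorts and reports byte-for-byte.
- An all-zero matrix, or any membership update leaving fewer than 2
  genes/samples, yields an empty layer (never an error).
- Counts with a gene that is zero somewhere in every gene row make the
  median-of-ratios reference undefined; this raises with a pointer to a
  pseudo-reference fallback rather than guessing.
- Zero-variance groups make the Welch test undefined and raise.
- The background block caveat: on a cohort-centered matrix the absence of
  every signature is itself a coherent profile, so a signature-free
  background group can be retained as a final cluster (it annotates as
  ignorance, consistently with carrying no planted mechanism). Closed-loop
  scoring matches recovered clusters to planted groups by majority overlap
  and scores mechanism recovery on those matches.

## Known limitations

- The Wald test is mildly anticonservative below ~20 samples per group
  (moment dispersion, normal tail); the calibration band is verified at
  50 per group.
- Exact 2×k enumeration is feasible for the k ≤ 4, n ≤ a few hundred
  tables this pipeline produces; it scales poorly beyond that.
- The plaid fit is a greedy local optimizer; the permutation retention
  rule controls false layers but nothing guarantees global optimality.
- Mechanism rules are single-gene threshold calls on DE output; they do
  not model pathway-level coherence beyond the step gene sets.
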