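# Methods

This note documents the models, parameter choices and numerical
conventions behind `hallnet`, and what the synthetic validation does and
does not establish about real data.

## Analysis model

The pipeline treats each subject as a weighted undirected graph over a
fixed parcellation; edge weights are FA-like values in (0, 1) interpreted
as white-matter integrity surrogates. The scientific question is whether a
continuous severity phenotype co-varies with connectivity strength and
with the modular roles of individual regions.

**Severity (HSS).** The composite score is the sum of the two z-scored
components. Standardization uses the cohort mean and the *sample* (n−1)
standard deviation — the cohort is a sample, and the choice only rescales
the composite by a common factor, so all rank-based and correlation-based
downstream inferences are unaffected. Zero variance in either component is
a fatal degenerate input rather than something to impute. Demographic
correlations switch between Pearson and Spearman via a Shapiro–Wilk screen
at α = 0.05 on both variables; the screen is a pragmatic rule, not a claim
that p > 0.05 establishes normality.

**Group mask.** "Present in a subject" means strictly positive weight. The
plain mask keeps edges present in at least ⌈fraction × n_subjects⌉
subjects (default fraction 0.5). The distance-binned variant sorts
candidate edges (present in ≥1 subject) by Euclidean centroid distance —
centroid distance proxies fiber length since no tractograms are in scope —
splits them into `n_bins` equal-count bins (default 10), and fills each
bin's proportional quota with its most consistent edges until the overall
target density is met; rounding is absorbed by later bins, so the realized
density is within `n_bins` edges of the target. Ties in consistency break
toward shorter edges (stable sort), a deterministic and declared rule.
The group-mean matrix averages retained edges over *all* subjects, zeros
included, so inconsistently present edges are down-weighted; a
`nonzero_only` flag provides the alternative convention.

**Modules.** Louvain maximization of weighted modularity at resolution γ
is delegated to networkx's seed-deterministic implementation; quality Q is
reported at the same γ. The resolution sweep (γ = 0.5–2.0, step 0.1 by
default) repeats Louvain `n_runs` times per γ with distinct derived seeds
and scores each γ by the mean pairwise normalized mutual information
(average-entropy normalization — symmetric, bounded, and equal to 1 for two
single-module partitions by convention); ties resolve toward the smaller,
coarser γ. Consensus clustering follows the agreement-matrix scheme: the
co-assignment fraction over runs is thresholded at the chance level
(the maximum off-diagonal agreement among label-permuted copies of the
same runs), the thresholded matrix is re-clustered at γ = 1, and the loop
repeats until all runs coincide, failing with a convergence error after 50
iterations. If thresholding empties the matrix the raw agreement matrix is
used for that iteration.

**Node metrics.** W uses the population (n) standard deviation within each
module, matching the convention of the standard brain-connectivity
toolboxes; singleton modules and zero-variance modules yield W = 0, and
isolated nodes yield B = 0 — the formulas are undefined there and the zero
conventions are explicit. Both metrics are validated against naive
double-loop oracles to 1e-12.

**Diverse club.** The candidate set is the top ⌈0.2 n⌉ nodes by B. The
published null ("randomizing the mean participation coefficient … with a
preserved modular structure") is ambiguous; this package realizes it as a
whole-vector shuffle of B across nodes, recording per iteration the
candidate-selection cutoff (the ⌈0.2 n⌉-th largest value of the shuffled
vector) and admitting to the club every candidate strictly above the 95th
percentile of the pooled cutoffs. Under exchangeable (e.g., all-equal) B
the club is provably empty, and a single integrative hub in an otherwise
module-internal graph is selected alone — the two boundary behaviors the
design must satisfy.

**NBS.** The edge statistic is the correlation-derived t
(t = r·√(df/(1−r²)), df = n−2), not a two-group contrast, because the
design regresses a continuous severity score on connectivity; the default
threshold 1.7 is the one-sided 0.05 critical value at df = 27 (29
subjects). Testing is one-sided per run with a `direction` flag; the
threshold applies to the signed t in the configured direction. With a
covariate, both edge weights and regressor are residualized on
[1, covariate] and df = n−3; permutations shuffle the residualized
regressor (a Freedman–Lane-style residual permutation, the standard
exchangeability-preserving choice for a single regressor of interest).
The component statistic is extent (edge count). p-values use the +1
correction, guaranteeing validity under permutation; when n! fits within
the permutation budget the null is enumerated exactly and the +1 is
unnecessary (the identity ordering is part of the orbit). Degenerate
|r| → 1 edges are capped at |t| = 1e6; edges constant across subjects get
t = 0 with a log note.

**Permutation inference.** The RSN overlap test permutes the
network-identity vector across nodes (subcortical regions form their own
label) and compares each label's observed percentage-in-subnetwork with
the null's 2.5th/97.5th percentiles. Contrasts of mean W/B inside vs
outside the subnetwork shuffle the membership labels (two-sided).
Club-in-subnetwork enrichment re-draws subnetwork membership uniformly
(one-sided) and converges to the hypergeometric upper tail, which serves
as its closed-form oracle. The nodewise screen computes Spearman rho per
node and corrects over nodes with the max-|rho| permutation device (weak
familywise control); the partial variant rank-transforms all three
variables and residualizes metric and severity ranks on the covariate
ranks. Per-subject metric stacks are computed on each subject's masked
matrix under the single group consensus partition — the group partition is
the reference frame for all per-subject metrics.

## Synthetic cohort generator

The generator defines the study-like conditions all validation runs use.
Defaults: 29 subjects, 90 nodes in 6 modules (233 nodes for full-scale
runs, with ~6% of nodes in a separate subcortical block), stochastic block
model with within/between edge probabilities 0.8/0.1, Beta-distributed
weights (mean 0.55 within, 0.35 between, concentration 20, clipped to
[0.05, 0.95]) giving FA-like bounded weights, per-subject Gaussian weight
noise (SD 0.03) and Bernoulli presence jitter (0.10). The two severity
components come from a bivariate normal at correlation 0.5 (the reported
cohort-level association between task and questionnaire is of this size);
the misperception percentage is a scaled logistic of the first component
(right-skewed, mean ≈ 18.5%, respecting the [0, 100] scale), the
questionnaire total an affine map clipped at zero. The motor covariate
tracks the standardized composite at correlation 0.3 by default. The
planted effect subtracts `effect_beta` × standardized HSS from the weights
of a *connected* subnetwork grown edge-by-edge over the backbone —
connectedness matters because the NBS infers at the component level, so
scattered single planted edges would be undetectable by design. "Strong
effect" in recovery tests means effect_beta = 0.3 (ten times the subject
noise SD) with a 40-edge planted subnetwork, i.e., a topologically
extended effect of roughly the relative size such analyses report. All
randomness derives from one seed via SHA-256 hashes of stage names, so a
(config, seed) pair reproduces a cohort byte-identically.

What the generator does **not** emulate: streamline-count weighting,
distance-dependent edge probability, scanner artifacts, head motion,
parcellation error, hemispheric asymmetry, or realistic spatial embedding
beyond module-clustered centroids. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under a known
generative model — not that any particular clinical dataset will yield the
published findings, which depend on unavailable patient scans.

## Problem sizes used in validation

Calibration suites run at deliberately compact sizes chosen to keep the
Monte-Carlo error meaningful: the NBS familywise-error check uses 200
independent null cohorts of 20 subjects × 30 nodes with 500 permutations
each (binomial SE ≈ 1.5 percentage points at the nominal 0.05); the
nodewise-screen null check uses 100 cohorts × 500 iterations; parameter
recovery uses the full 29 × 90 default cohort. The γ sweep and consensus
default to 100 and 500 runs respectively in production configurations,
while tests use smaller run counts where the graph is unambiguous.

## Known limitations

- Louvain is a local optimizer; the consensus loop stabilizes but does not
  certify global optimality of Q.
- The distance-binned mask's equal-count bins depend on candidate-edge
  ordering only through deterministic stable sorts; different bin counts
  change which long edges survive.
- The diverse-club null is one defensible reading of an ambiguous
  published procedure; alternative nulls (e.g., recomputing B on
  degree-preserving rewirings) would be stricter.
- Exact NBS enumeration triggers only when n! ≤ the permutation budget
  (n ≤ 7 at the 5,000 default); beyond that the Monte-Carlo null's
  resolution is 1/(n_perm + 1).
- The pipeline applies one group partition to all subjects; per-subject
  partitions are out of scope.
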