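# Methods

## Data model

Expression is a genes × samples matrix of log2 intensities with a sample
design of (genotype, treatment, timepoint, replicate).  Treatments are WW
(well-watered), WS (water-stressed) and RWS (re-watered); timepoints are
ordinal indices with a calendar label map (2, 6, 27 days after stress
onset by default).  All algorithms consume the indices — the profile
methods rank occasions, they do not space them.  Fold change is always the
difference of group means on the log2 scale, so "FC ≥ 2" means
|Δlog2| ≥ 1 and the RWS filter "FC ≥ 3 or ≤ −3" means |Δlog2| ≥ log2 3.
Missing or unparseable values cause the whole gene row to be dropped at
load, with a logged count; there is no imputation, because both the
correlation network and the permutation statistics respond badly to
silently imputed replicates.

## Staged selection cascade

1. **Multiclass SAM.**  For K design groups, the per-gene statistic is
   d = r/(s + s₀), with r = √SSB (between-class sum of squares) and
   s = √(Σ_k 1/n_k · SSW/(n−K)) the pooled standard error, the multiclass
   analogue of the two-class SAM denominator.  The fudge factor s₀ is
   chosen among the percentiles {0, 5, …, 100} of s to minimize the
   coefficient of variation of the spread (MAD) of d across ~100
   equal-occupancy windows of s.  Significance compares the ordered
   observed d with the mean ordered d over column-permuted datasets; the
   threshold Δ is the smallest value whose estimated FDR — the median
   permuted exceedance count over the number of called genes — is at or
   below the target (default 0.1 %, configurable; the multiclass d is
   nonnegative so only an upper cut applies).  π₀ is taken as 1, which is
   conservative.
2. **ANOVA + Bonferroni.**  One-way F per gene over the same groups,
   restricted to the SAM survivors; a gene is selected iff
   p · n_tested ≤ α (default α = 0.01), where n_tested is the family
   actually tested.  Rows with zero within-group variance select with
   p = 0 when means differ and are dropped (logged) when they do not.
3. **Fold-change / t-test filters.**  Route A keeps survivors with
   |Δlog2| ≥ 1 in at least one per-genotype per-timepoint WS vs WW
   contrast; route B reruns the screens on 6 treatment × timepoint groups
   (genotype pooled) and filters on the pooled per-timepoint fold change.
   The biomarker-style selection uses Welch's unequal-variance t-test
   (p < 0.01) plus the FC filter per cell.  The ledger reports |A|, |B|,
   |A∩B| and the inclusion–exclusion union.
4. **Final-occasion network input.**  WS vs WW at the last timepoint with
   genotype pooled, p < 0.08 and FC > 1.7 (strict), kept verbatim as
   config defaults.

The t-test is Welch rather than pooled-variance: with three replicates per
cell, variance heterogeneity between watering regimes is common and the
pooled test is anti-conservative under it.

## Profile clustering

Candidate profiles are all (2c+1)^T zero-anchored integer step sequences
with per-step change bounded by c (defaults c = 2, T = 3; the flat profile
is dropped).  A catalog of m = 30 model profiles is chosen by greedy
max–min selection under the 1 − Pearson distance on level vectors, seeded
with the most distant pair; ties break to the lowest enumeration id.  The
greedy rule guarantees at least half the exhaustive-optimal minimum
pairwise distance.  Genes are assigned to the catalog profile maximizing
the Pearson correlation of their zero-anchored fold-change series with the
profile levels (ties to the lowest id; flat series go to the flat profile
if present, else remain unassigned).  Per-profile significance permutes
each gene's observed occasions (anchor fixed), exhaustively when T! is
small, and compares the observed count with a binomial upper tail at the
null assignment frequency; profiles pass iff p·m < α (default α = 0.05).
Cross-genotype comparison matches each significant profile of one genotype
to the best level-correlated significant profile of the other and scores
the gene overlap with a hypergeometric upper tail over the shared
universe.

A known blind spot of the permutation null: a profile whose observed
occasions are all equal (e.g. an immediate step that stays flat) is
invariant under time permutation, so its observed count always equals its
expected count and it can never be flagged.  Planted-profile benchmarks
therefore use shapes with at least two distinct observed levels.

## Network cartography

Edges join gene pairs with |Pearson r| at or above the threshold (default
0.6 — the threshold is a config key; no published cutoff exists for this
kind of data, and the benchmark conclusions are threshold-robust for tight
modules).  Modules come from k-means on row-standardized expression with k
chosen by maximal mean silhouette over a configurable range (default
2–10), 10 restarts, fixed seed.  Per node:

- **Z**, within-module degree z-score: (κ − mean)/sd over the node's
  module, 0 when the module's degrees are uniform;
- **P**, participation: the default is the *clusterphobic* form
  1 − (κ/k)², the fraction-of-external-links measure; the classical
  Guimerà form 1 − Σ_m (k_m/k)² is computed alongside and selectable.
  The Guimerà form is bounded by 1 − 1/M for M modules, so in small
  planted networks (2–4 modules) it cannot reach the kinless band
  (P > 0.8) at all — exactly the band that defines switch genes — which is
  why the external-fraction form is the default for role assignment;
- **APCC**, the mean signed correlation with network neighbors (undefined
  for isolated nodes, reported missing).

The (Z, P) plane splits into seven regions: non-hubs (Z < 2.5) R1–R4 at
P ≤ 0.05, ≤ 0.62, ≤ 0.80, > 0.80; hubs R5–R7 at P ≤ 0.30, ≤ 0.75, > 0.75.
All boundaries are config keys.  APCC classifies nodes as fight-club
(APCC < 0), date (0 < APCC ≤ 0.5) or party (APCC > 0.5) — applied to all
nodes by default, with a hubs-only flag.  **Switch genes** = region R4 ∧
APCC < 0; by construction they are a subset of the fight-club class.

## Enrichment

Hypergeometric upper tail P(X ≥ k) for k study hits of a K-member term in
an n-gene study drawn from the N-gene array population.  Default
correction is none at α = 0.01 (the leaf preset; 0.05 and 0.1 are the
berry and visualization presets), with Bonferroni and Benjamini–Hochberg
available.  Slim mapping reattributes each term's genes to its slim
ancestors through the (acyclic) ancestry relation.

## Synthetic generator

`simulate_experiment` draws per-gene baselines N(8.0, 1.5²) log2 units and
adds i.i.d. N(0, 0.25²) replicate noise — additive Gaussian on the log2
scale, i.e. log-normal intensities, the usual first-order microarray noise
model.  A fraction of genes (default 10 %) receive a WS − WW offset
following an integer temporal profile scaled so the peak |offset| equals
`effect_size_log2` (default 2.0); with `genotype_lag` the offset appears
one timepoint later in the second genotype, emulating a delayed-responder
cultivar and producing the cluster-swap behavior the cross-genotype
profile comparison is meant to detect.  The lag is a modeling device of
the simulator, not a claim about mechanism.

`plant_network_structure` builds module members as √r·z_m + √(1−r)·ε
around a baseline (latent z_m per module across samples), hitting the
intra-module correlation target r in expectation; switch nodes load
negatively on two modules' latents, −(z_a + z_b)/√2, giving expected
correlation −√(r_s·r/2) ≈ −0.64 to both modules' members for r = 0.9 —
negative, and above the default edge threshold for most pairs.
`plant_enrichment` overlaps one term with the responsive set far above
hypergeometric expectation against uniform random background terms.

What the generator does **not** emulate: probe-level effects,
cross-hybridization, intensity-dependent variance, correlated replicate
structure, and any berry phenology.  Passing benchmarks therefore
demonstrate the statistical machinery recovers structure of the planted
kind at study-like sizes and noise; they do not certify performance on
real arrays.

## Benchmark problem sizes and thresholds

Null calibration uses 50 pure-noise datasets of 1,000 genes × 36 samples;
the cascade's median final union must be 0 and the SAM screen must flag at
most 5 genes in ≥ 95 % of seeds.  Switch recovery sweeps 50 planted
networks over 2–4 modules (20 genes each, r = 0.9) and 1–5 switch nodes
and requires mean F1 ≥ 0.9 with the switch ⊆ fight-club containment
holding on every run.  Profile recovery plants 30 % of 200 genes on a
ramp-up shape at noise 0.1 and requires Bonferroni significance in ≥ 95 %
of 50 seeds; term recovery plants a 40-gene term overlapping 30 of 50
responsive genes in a 500-gene universe and requires rank 1 in ≥ 95 % of
100 seeds.  Unit-level statistics (SAM d, F, Welch t, edges, Z, P, APCC,
regions, hypergeometric p) are checked against independent brute-force
oracles at 1e-10 on ≤ 36-sample fixtures.

## Numerical notes and edge cases

Constant genes score d = 0 and are never SAM-significant; constant
matrices yield no calls.  Zero-variance genes are excluded from networks
(no undefined correlations); zero-variance rows get correlation distance 1
in hierarchical ordering.  PCA loading signs are canonicalized (largest
|loading| positive) so percentile tails are decomposition-invariant.  All
stochastic steps (simulation, SAM permutations, k-means restarts, sampled
profile permutations) take explicit seeds; a fixed seed reproduces results
byte-for-byte.

## Known limitations

- SAM's median-FDR rule with π₀ = 1 is conservative near strict FDR
  targets: a few genuinely shifted genes whose permuted scores mix into
  the null tail can be missed (observed: 46/50 planted 5σ one-class
  shifts recovered at FDR 0.1 % with zero false calls).
- k-means module detection assumes roughly balanced, convex expression
  clusters; silhouette selection can absorb a lone switch node into a
  module when it is the only anti-correlated gene, which is the main
  failure mode of switch recovery at a marginal edge threshold.
- The permutation null for profiles cannot flag permutation-invariant
  shapes (above), and with T = 3 the exhaustive null has only 6 atoms, so
  per-profile p-values are coarse.
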