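# Methods

## Scope and model

The package implements a differential TF–target coupling analysis between
two sample cohorts.  Its core quantity is, per cohort, the number of genes
in a TF's target panel whose expression correlates with the TF's
expression at a given FDR, and the Fisher's-exact comparison of those
counts between cohorts.  Around that core sit: consensus panel
construction from gene-level ChIP-Seq binding scores, regulator
(receptor/corepressor) cross-cohort statistics, receptor-to-corepressor
log-ratio analysis, a ΔΔCt qPCR utility, and a synthetic data generator
that serves as the test bed for everything else.

## Statistical conventions

* **Pearson correlation p-values** are two-sided, from the t transform
  t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.  Missing values are
  removed pairwise per gene and the complete-pair count n_used is
  recorded; at least three complete pairs and non-zero variance are
  required, otherwise the gene is skipped (insufficient pairs) or the run
  fails naming the gene (zero variance).  |r| = 1 returns p = 0 by
  convention (applied within machine precision of the bound, since exactly
  collinear input can round to just under 1).
* **FDR control** is Benjamini–Hochberg step-up: q_(i) = min_{j≥i} m·p_(j)/j,
  restored to input order, so q < α reproduces the classic BH rejection
  set at level α.  The family is the panel within one cohort; a pooled
  two-cohort family is available as an option (`pooled_fdr=True`).  The
  "largest rejected raw p" per cohort is reported as the constant
  threshold line a volcano plot would draw.
* **Fisher's exact test** is two-sided under the probability-mass rule
  (sum of hypergeometric probabilities of all tables with the observed
  margins whose probability does not exceed the observed table's).  The
  reported odds ratio is the sample estimate a·d/(b·c), infinite for a
  zero off-diagonal cell.  The Fisher margins default to the genes
  actually tested per cohort; counting skipped panel genes in the
  denominator is available via `denominator="panel"` since the choice is
  not neutral when genes are missing from the matrix.
* **Mann–Whitney U** uses midrank tie handling; the p-value is exact (full
  enumeration) when both groups have ≤ 8 observations and no ties, else a
  tie-corrected normal approximation with continuity correction.  The
  Bonferroni family for regulator comparisons defaults to the number of
  regulators actually tested in the call and can be overridden.
* **Median centering** uses the conventional even-length median (mean of
  the two central order statistics).  This matters: centering affects
  every downstream value, so the convention is fixed and tested.
* **ΔΔCt** averages replicate Ct values *before* differencing (the classic
  convention, rather than averaging per-replicate folds) and assumes
  perfect per-cycle doubling (efficiency 2); efficiency-corrected variants
  are out of scope.

## Panel construction choices

* Multi-list membership is counted over **post-averaging** lists (the five
  replicate-group lists in the default fixture geometry), since replicate
  averaging is described as producing merged per-condition lists before
  selection.
* Ortholog handling: non-human symbols are translated to human symbols
  before membership counting, so a mouse and a human dataset corroborate
  the same human gene.  A non-human symbol with no ortholog entry retains
  its source symbol; if it passes the membership filter it is then dropped
  and counted as an ortholog exclusion.  This ordering reproduces the
  natural bookkeeping "multi-list → minus no-ortholog → minus
  not-expressed → plus canonical".
* "Expressed in the dataset" means: present as a matrix row **and**
  non-missing in at least a configurable fraction of samples (default
  50%).  Absence-from-matrix alone would make the filter vacuous for
  complete matrices.
* Top-k selection breaks score ties by ascending symbol so panels are
  reproducible; users wanting all tied genes should widen k.
* Canonical-list genes are exempt from every filter; a canonical gene that
  a filter had dropped is rescued by the union and marked
  `+canonical_rescued` in the provenance.

## The synthetic generator

Per sample j (cohort-specific means):

* TF: x_j ~ N(μ_tf, σ_tf²)
* corepressors (3): z_cj = μ_cor + σ_cor·(√ρ·s_j + √(1−ρ)·ε_cj) with a
  shared standard-normal factor s_j, giving pairwise corepressor
  correlation ρ while keeping each marginal N(μ_cor, σ_cor²)
* repression index: r̄_j = mean_c z_cj
* coupling weight: w_j = 1/(1+exp(−κ(x_j − r̄_j − θ)))
* true target i: y_ij = β_i·w_j·x_j + N(0, σ_y²), β_i ~ U(β_lo, β_hi)
* decoy: N(0, σ_y²)

then optional per-gene median centering (on by default, mimicking
array-median-centered public expression extracts; it shifts each gene by a
constant and does not change within-cohort correlations or rank tests).

The logistic weight is the simplest monotone map from the TF-to-
corepressor log-ratio to a coupling strength in [0, 1]; the underlying
hypothesis it encodes is that the *balance* of receptor and corepressor,
not receptor abundance alone, determines whether targets respond.

Defaults (log-expression units): n_A = 81, n_B = 234, 135 targets,
865 decoys, μ_tf = 1.2/0.8 (A/B), σ_tf = 1, μ_cor = 0.0/2.6 (A/B),
σ_cor = 1, ρ = 0.9, κ = 4, θ = 0, β ~ U(0.15, 0.5), σ_y = 1.  Cohort A is
de-repressed (w near 1), cohort B repressed (w near 0 but modulated by
corepressor load).  The effect sizes were calibrated once, at design time,
so that the default scenario reproduces the qualitative asymmetry the
pipeline is meant to detect — a large significant-count excess in the
de-repressed cohort (means ≈ 50 vs ≈ 5 of 135 at q < 0.01) — rather than
any exact count, which would depend on an unrecoverable real-data
snapshot.  The corepressor correlation ρ = 0.9 encodes co-regulated
corepressor expression; it is what makes a *single*
receptor/corepressor log-ratio informative about the three-corepressor
repression index (with ρ = 0 one corepressor carries only a third of the
repression signal but the full variance penalty, and the single-pair
ratio correlation no longer beats the receptor-alone correlation).
Setting `rho_cor=0` restores independent corepressors.

Randomness: one `numpy.random.default_rng` (PCG64) per artifact, draw
order fixed and documented in the generator docstring (TF, shared factor,
corepressor noise, betas, target noise, decoy noise), so a seed pins every
output byte-for-byte across runs and platforms.  The binding-score fixture
derives its RNG from seed+1 so expression and binding draws do not
interact.

The companion ChIP-Seq fixture builds seven binding-score tables in five
replicate groups (two mouse singletons, two duplicated human groups, one
human singleton).  Non-canonical targets are placed in exactly two (some
three) of the post-averaging top-k lists; a configurable number of
human-symbol genes with high scores are withheld from the expression
matrix (default 26) and a configurable number of mouse-only genes are
left out of the ortholog map (default 11); single-list padding comes from
the decoy pool.  Running the default fixture through the panel builder
therefore yields exactly 148 multi-list genes, 11 ortholog drops, 26
expression drops, 111 filtered genes and a 135-gene final panel — the
bookkeeping the pipeline's provenance reporting is designed to expose.

### What the generator does and does not emulate

It emulates cohort-size asymmetry, log-scale median-centered expression,
corepressor-gated coupling, decoy genes for false-positive calibration,
and the multi-species, replicate-structured binding-score geometry.  It
does **not** emulate RNA-Seq count noise (negative binomial dispersion,
library-size effects), batch effects, gene–gene correlation beyond the
TF/corepressor circuit, heavy-tailed expression, or missing values.
Passing tests on this generator therefore demonstrate correctness of the
pipeline's statistics and bookkeeping under a clean generative model, not
robustness to real-data artefacts.

## Calibration facts worth knowing

Under the global null (κ = 0, all β = 0) the raw two-sided correlation
p-values are uniform, so the fraction below 0.01 concentrates at 0.01 —
but the fraction of genes *flagged at q < 0.01* is far smaller (~1e-4),
because under the global null BH controls the family-wise error: the
probability that a cohort yields *any* discovery is ≈ α (Simes), measured
at ≈ 0.012 over 500 runs.  Consequently the Fisher comparison of two
near-zero discrete counts almost never rejects (measured rejection rate
0.000 at nominal 0.05 over 500 runs): Fisher's exact test is conservative
in this regime.  These are properties of the procedures, not bugs; the
test suite asserts them as such.

## Problem sizes used in tests and the acceptance script

Monte-Carlo suites use 200 seeded simulations for parameter recovery and
500 for null calibration at the full 81-vs-234, 1000-gene geometry (a few
tens of milliseconds per simulated screen); unit-level property tests use
smaller replicate counts (12–20 seeds) with thresholds set from
measured behaviour with margin.  The Fisher kernel is verified against
exact hypergeometric enumeration for every 2×2 table with total ≤ 40, the
BH kernel against the brute-force step-up definition on 1000 random
vectors, and the exact Mann–Whitney branch against full label enumeration
for combined samples ≤ 10.

## Known limitations

* The screen is marginal Pearson correlation per gene; no partial
  correlations, regression adjustment, or multi-TF modelling.
* One TF per screen call; run per TF for multi-TF studies.
* The ratio analysis uses one receptor–corepressor pair per profile;
  composite (multi-corepressor) ratios can be emulated by correlating
  against the mean corepressor externally.
* Symbol handling is canonicalization only (uppercase/strip); alias
  resolution is deliberately an input concern (the ortholog map).
* ΔΔCt assumes amplification efficiency 2 and does not estimate
  efficiencies from standard curves.
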