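# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `peptimark`, and what the synthetic-data validation does
and does not demonstrate.

## Profile matching

A CE-MS peptide is a triple (monoisotopic mass in Da, normalized CE
migration time in min, ion signal). Two detections are the same peptide when
their relative mass deviation is within the mass tolerance and their
relative migration-time deviation within the migration tolerance.

* **Mass tolerance.** 50 ppm for peptides up to `small_mass_cutoff`
  (default 6000 Da, boundary inclusive), 75 ppm above. The small/large
  boundary is not standardized in the field; 6 kDa covers the typical
  peptidome analysis window (≈ 0.8–20 kDa) with everything below usual
  protein masses treated as "small", and is exposed in `MatchingParams`.
* **Migration tolerance.** CE peaks broaden by diffusion late in the run, so
  the accepted percentage deviation rises linearly from 2% at 19 min to 5%
  at 45 min and is clamped outside that window.
* **Clustering.** Only the pairwise criterion is physically determined; the
  grouping rule is a design choice. We use greedy seeded clustering in
  descending intensity order (ties: ascending mass, then time, then sample
  id), which is deterministic and independent of input order. A peptide
  joins the admissible cluster with the smallest combined relative
  deviation; cluster consensus mass/time are intensity-weighted means.
  Deviations are computed **relative to the running consensus** — whether
  the original database software compared to the smaller, larger or
  consensus mass is not documented, so this is an explicit contract of this
  implementation, not a claim about the original.
* **Absent peptides** are recorded as intensity 0, not missing: absence is
  informative in marker profiles and keeps group sizes constant in the
  downstream fold-change arithmetic.

## Internal-standard normalization

Matched standards (≥ 3 required; fewer is an error, never a silent pass)
define a regression `log I_obs = a + b·log I_ref`; all intensities are
corrected by the inverse map. When the references carry no spread the slope
is fixed at 1 (offset-only correction). Normalization is idempotent to
numerical precision. An optional local pass removes per-window offsets over
four equal-width migration-time windows (windows with < 2 standards are left
alone). Standards drifting ≥ 0.45 min in migration time trigger a QC
warning; the bound is a calibration control, not a matching tolerance.

## Protease mapping

* **Scoring.** The original analysis delegates motif→protease prediction to
  external software without published formulas. We score a P4–P4′ octapeptide
  against a specificity weight matrix by additive log2 odds versus the
  background residue distribution (uniform by default). Positions outside
  the parent protein are padded with `X` and contribute zero, so peptides at
  protein termini remain mappable.
* **Threshold.** Per matrix, the default score threshold is the 95th
  percentile of the matrix's score distribution on random decoy
  octapeptides — self-calibrating and reproducible without access to any
  curated matrix collection. Users may supply their own matrices and
  thresholds via the documented JSON.
* **Decoy PPV.** Decoy hits are scaled linearly by
  `n_targets / n_decoys` to an expected false-positive count (the original
  scaling rule is unstated; linear scaling is the natural choice), giving
  PPV = TP / (TP + FP). Retention requires PPV **strictly** greater than
  0.65 and ≥ 4 **distinct cleavage sites** (duplicate (protease, site) pairs
  are collapsed before counting — sites, not peptides, are counted). Both
  target and decoy motifs are mapped in the same matrix mode. The default
  decoy count is 1000 per run, seedable.

## Protease activity

"Integrated by their ion signals" is read as the per-patient **sum** over a
protease's distinct assigned markers (a marker whose two termini map to the
same protease counts once); the group statistic is the across-patient mean ±
sample SD of those sums — the only reading consistent with reporting
average ion counts per group. A `mean` aggregation switch is provided.
Group comparison uses the two-sided Mann–Whitney U test: exact enumeration
for n ≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections. Raw p-values are reported per protease (no
correction across proteases, matching common practice in such tables); a
Benjamini–Hochberg column is emitted as supplementary output.

## Classification

The fluid classifier is a soft-margin **linear** SVM (the published
description speaks of a separating hyperplane; no kernel is documented) on
natural-log intensities with pseudo-count 1 — the log base only rescales
weights. The membership probability is the signed Euclidean distance to the
hyperplane, hard-clipped into the fluid's published range ([−2.5, 2.5] bile,
[−3.5, 3.5] urine). How the original software maps distances into those
ranges is not described; the clip is this package's explicit contract. Only
the linear kernel is supported: the model contract stores an explicit
weight vector and defines the score geometrically on it, which does not
extend to implicit feature spaces. All
three decision thresholds (bile 0.08, urine −0.89, combined −0.52) are
strict: a score exactly at the threshold is negative.

The combined score is the published affine equation with coefficients
1.6128 / 1.8325 / 2.6363; `fit_combination` re-estimates such coefficients
by Newton (equivalently IRLS) maximum likelihood, tolerance 1e-8, at most
100 iterations, flagging perfect separation and capping coefficients at ±25
instead of diverging.

## Enrichment and survival statistics

* **Two-sided hypergeometric** p uses the minimum-likelihood definition
  (sum of all outcome probabilities ≤ P(X = k), capped at 1), matching
  common enrichment tools; it detects enrichment and depletion.
* **"Bonferroni step-down"** is implemented as Holm's procedure, the
  standard reading of that phrase.
* **Functional groups** are connected components of the term graph with
  edges at Cohen's kappa ≥ 0.45 between gene-membership vectors. This is a
  documented divergence from iterative leading-term merging used by some GUI
  tools; only the kappa threshold is published.
* **Survival.** Kaplan–Meier product-limit curves per test stratum
  (lifelines); log-rank chi-square with 1 df; the one-year outcome censors
  events after a 365-day horizon. The stratified report also prints death
  rates (1 decimal) and a 2×2 Wald odds ratio — the published "10.3-fold
  risk" is framed as a log-rank result with a CI; we report both the
  log-rank p and the 2×2 odds ratio without asserting which produced the
  published multiplier.
* **Odds ratios** are `e^β` with CI `e^{β ± 1.959964·se}`, presented to two
  decimals.

## The synthetic cohort generator

The generator defines the study conditions for all recovery and calibration
tests.

* **Cohort.** Default 52 cases vs 76 controls, emulating a biliary-stricture
  cohort; sample labels map to CCA vs PSC groups.
* **Proteome and matrices.** Random proteins (default 20 × 400 residues,
  uniform residue background; a SwissProt-like table is available).
  Specificity matrices have one preferred residue per position boosted by
  `exp(sharpness)` (default 6) over a continuous Dirichlet base — continuous
  columns keep the decoy score distribution tie-free so the 95th-percentile
  threshold is stable, and preferred residues are drawn **without
  replacement across proteases** at each position, representing a panel of
  distinct specificities.
* **Cleavage.** Octapeptides drawn from the generating matrix are implanted
  at spaced positions (every 16 residues, non-overlapping windows), so every
  recorded site genuinely scores highly on its matrix; peptides are the
  fragments between consecutive same-protease cuts, with protein-terminal
  fragments discarded so both termini of every marker are real cuts.
* **Intensities.** Marker base abundances are log-normal (median 200,
  sigma 1 — ion counts are positive and heavy-tailed, consistent with
  reported group SDs exceeding means); per-sample multiplicative log-normal
  noise (default sigma 0.5); a case sample multiplies the signals of an
  affected protease's peptides by that protease's effect ratio; Bernoulli
  dropout (default 0.1) removes peptides from individual profiles. Masses
  and migration times get small per-sample jitter (8 ppm, 0.08 min — well
  inside the matching tolerances).
* **Survival.** Exponential times with stratum hazard ratio 10.3 (the
  published risk multiplier) over a baseline fixed so the test-negative
  stratum has 1.5% one-year mortality — both values anchored to the
  published cohort — censored at 365 days.

What the generator does **not** emulate: real marker sequences or curated
protease matrices, correlated marker co-regulation, batch/run effects,
missingness that depends on abundance, or non-exponential hazards. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own assumptions, not that those assumptions hold for any
particular clinical cohort.

## Validation sizes and observed behaviour

The test suite runs the full pipeline at n = 50 + 50 with a 7-fold effect
over 50 seeds (true protease ranked first by p-value in ≥ 90% of seeds,
fold-change estimate within [4.5, 10.5] in ≥ 95%), and 200 null replicates
at a reduced cohort size (20 + 20 samples, 8 proteins — the Mann–Whitney
level does not depend on cohort scale) where the fraction of proteases at
p < 0.05 is 0.05 ± 0.02. Decoy-only mapping retains no protease at the 0.65
PPV cutoff across 100 seeds.

One known limitation is intrinsic to the anchored survival conditions: at
1.5% control mortality and hazard ratio 10.3 with 62/66 patients over one
year, only about ten deaths are expected, and the log-rank test reaches
p < 0.01 in roughly two thirds of simulated cohorts (the median simulated p
is ≈ 0.006). A materially higher power would require assuming more events
than such a cohort exhibits; the corresponding power test in the suite
documents this as a failing expectation rather than inflating the baseline
hazard.

Cross-assignment is the main source of bias in activity fold changes: about
5% of another protease's motifs pass a given matrix's decoy-calibrated
threshold by construction, diluting a true k-fold effect toward
`(k + d) / (1 + d)` for a contamination fraction d. With the default panel
this keeps a 7-fold effect within the tested recovery band.
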