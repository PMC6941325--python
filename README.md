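# peptimark

Degradome analysis of body-fluid peptide profiles for biliary-tract cancer
cohorts.

Naturally occurring peptides in bile and urine are proteolysis products:
their abundance pattern separates cholangiocarcinoma (CCA) from benign
biliary strictures, and the residues flanking each peptide's termini reveal
which proteases were at work. `peptimark` implements the full analysis chain
used in such CE-MS (capillary electrophoresis–mass spectrometry) peptide
biomarker studies, for bioinformaticians who have per-sample peptide lists
(mass, migration time, ion signal) and want protease-activity inference,
classification and the accompanying cohort statistics — plus a synthetic
cohort generator with known ground truth, so every stage can be validated
without access to patient data.

## What it computes

1. **Profile matching** (`peptimark.profiles`). Peptides are matched across
   samples when their relative mass deviation is below 50 ppm (small
   peptides, ≤ 6 kDa) or 75 ppm (larger), and their CE migration-time
   deviation is below a tolerance rising linearly from 2% at 19 min to 5% at
   45 min. Ion signals are normalized against internal-standard peptides by
   linear regression on the log scale. The result is a marker × sample
   intensity matrix.

2. **Protease mapping** (`peptimark.mapping`). Each sequenced marker yields
   two octapeptide cleavage motifs (P4–P4′ around its N- and C-terminal
   cuts). A motif is scored against a protease's specificity weight matrix
   *W* by additive log-odds, `S = Σ_j log2 W_j(r_j) / b(r_j)`, and assigned
   when *S* reaches the matrix threshold (default: 95th percentile of the
   matrix's score distribution on random octapeptides). Random decoy
   octapeptides, mapped identically, calibrate a positive predictive value
   PPV = TP / (TP + FP); only proteases with PPV > 0.65 and ≥ 4 distinct
   cleavage sites are retained.

3. **Protease activity** (`peptimark.activity`). Per patient, a protease's
   activity is the summed ion signal of its assigned substrate markers;
   groups are compared by fold change of group means and a two-sided
   Mann–Whitney U test (exact for n ≤ 12 without ties).

4. **Classification** (`peptimark.classify`). A linear SVM per fluid on
   log-transformed intensities; the membership probability is the signed
   Euclidean distance to the separating hyperplane, saturated into
   [−2.5, 2.5] (bile) or [−3.5, 3.5] (urine), with positivity thresholds
   0.08 (bile) and −0.89 (urine). The two scores combine as

       BPA/UPA match = 1.6128 + 1.8325·BPA + 2.6363·UPA

   with a positive combined call when the value strictly exceeds −0.52.

5. **Downstream statistics** (`peptimark.enrichment`, `peptimark.survival`).
   GO-style term enrichment by a two-sided hypergeometric test with Holm
   (Bonferroni step-down) correction and Cohen's-kappa functional grouping
   (threshold 0.45); Kaplan–Meier curves and log-rank tests by proteomic
   test stratum; multivariate logistic regression of one-year mortality with
   Wald odds ratios, `OR = e^β`, CI `e^{β ± 1.96·se}`.

6. **Simulation** (`peptimark.simulate`). Cohorts with implanted cleavage
   sites, per-protease case/control activity ratios, log-normal intensity
   noise, peptide dropout, clinical covariates and exponential survival —
   all reproducible from one seed, with the ground truth returned alongside.

## Worked example

```python
from peptimark import SimulationConfig, simulate_cohort, combine_scores
from peptimark.pipeline import run_protease_pipeline

cfg = SimulationConfig(n_case=52, n_control=76, effects={"PR1": 7.0}, seed=7)
cohort = simulate_cohort(cfg)
res = run_protease_pipeline(cohort.profiles, cohort.proteome,
                            cohort.matrices, cohort.truth.labels, seed=7)
print(res.comparison[["protease_id", "case_mean", "control_mean",
                      "fold_change", "p"]].round(2).to_string(index=False))
```

```
protease_id  case_mean  control_mean  fold_change    p
        PR1  134017.97      19799.64         6.77 0.00
        PR2   20387.57      20472.02         1.00 0.85
        PR3   30400.78      29060.65         1.05 0.06
        PR4   34207.32      32612.67         1.05 0.09
        PR5   22353.14      23078.49         0.97 0.04
```

The cohort was simulated with protease PR1 seven-fold more active in cases;
the pipeline — matching 370 markers across 128 samples, mapping their
terminal motifs, filtering by decoy-calibrated PPV and integrating substrate
signals — recovers a fold change of 6.77 for PR1 at a vanishing Mann–Whitney
p, while the four null proteases sit near fold 1. The combined classifier
arithmetic is exact:

```python
>>> combine_scores(0.0, 0.0)
1.6128
```

A command-line interface mirrors the library (`peptimark simulate`,
`match`, `map-proteases`, `activity`, `classify`, `enrich`, `survival`).

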