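# Methods

## Variant data model

A variant is a single amino-acid substitution `<wt><pos><mut>` with
1-based positions in the query protein's numbering; no 0-based
coordinates appear anywhere. The packaged fixture transcribes the
69-variant MLH1 panel (steady-state % of wild type, ddG, ClinVar class,
DME). Three conventions matter downstream:

- **Censored ddG.** Stability predictions above 15 kcal/mol mostly
  reflect steric clashes in the underlying models, so source tables print
  them as a lower bound (">15"). They are stored as 15.0 plus a censored
  flag: every threshold at or below 15 treats them as destabilized
  without inventing a magnitude.
- **ClinVar grouping.** The five-level scale collapses to
  positive = (likely) pathogenic, negative = (likely) benign, and
  VUS/missing excluded from training and labeled counts. The fixture
  stores the printed "(likely)" composites as the `likely_*` levels; the
  binary grouping makes the choice inconsequential.
- **Missing data.** NA is encoded as "."/empty in the TSV dialect. A DME
  of NA (one variant, I36S) removes that record from every DME-stratified
  universe. Allele frequency 0 is a valid value distinct from NA: it
  marks variants seen in patients but absent from the population
  database, and forms the explicit zero lane of the fishtail plot.

## Saturation ddG handling

Replicate prediction runs are averaged (arithmetic mean) **before**
truncation at the 15 kcal/mol cap; the order is fixed because
mean-then-truncate and truncate-then-mean differ (e.g. replicates
{14, 16} give 15.0 vs 14.5). Raw means are retained internally; exported
and classifier-facing values are truncated. Wild-type cells are exactly 0
and never counted among substitutions. The "near-neutral" bin uses
|ddG| < 0.7 kcal/mol — the absolute value, because 0.7 is the typical
symmetric error of such predictors — and the "substantial
destabilization" bin uses ddG > 2.5, both strict.

## Evolutionary sequence energies

The family model is a q = 21 Potts model (20 amino acids + gap; the gap
participates in fitting but is never a substitution target). Fitting
maximizes the weighted, L2-regularized pseudolikelihood

    Σ_s w_s Σ_i log P(x_i^s | x_-i^s; h, J) − λ_h‖h‖² − λ_J‖J‖²,

where the conditional at column i is the softmax of
`h_i(a) + Σ_{j≠i} J_ij(a, x_j^s)`. Choices and defaults:

- **Sequence weights**: inverse cluster size at 80% identity
  (`w_s = 1/|{t : id(s,t) ≥ 0.8}|`), the conventional reweighting for
  this model family; `n_eff = Σ w_s`.
- **Regularization**: λ_h = 0.01 and λ_J = 0.01·(L−1)·(q−1), the usual
  length-scaled coupling penalty; both configurable.
- **Optimization**: L-BFGS from zero parameters — deterministic, so fits
  are bit-reproducible. The full symmetric J array is optimized with a
  symmetrized gradient; non-convergence sets a status flag on the model
  rather than raising.
- **Gauge**: after fitting, block means of J are transferred into the
  fields (zero-sum gauge: `Σ_a h_i(a) = 0`, `Σ_a J_ij(a,b) = 0`). Gauge
  moves change no energy difference; a property test asserts this.
- **Scoring**: `dE = E(mut) − E(wt)` computed in O(L) from the terms
  touching the mutated column; the negative-log-score sign convention
  makes high dE = rarely tolerated. Rank normalization maps the non-NA
  scores of the **whole** position × 19 matrix (one common scale, not per
  column) to r/(N+1) with average ranks for ties, keeping the open
  interval (0,1).
- **Coverage mask**: a column is unscorable when its weighted non-gap
  count falls below 50 effective sequences or its weighted gap fraction
  exceeds 0.5 (both strict comparisons; configurable). The source
  analyses state only that shallow columns were set to NA; these defaults
  are this package's own, declared rather than inferred.

## Classifier and evaluation

Unregularized logistic regression, fit by IRLS from zero (deterministic).
Perfect separation is flagged — coefficients are capped at the last
stable iterate and a statsmodels-style perfect-prediction check marks the
model — instead of silently ridge-penalizing or diverging. Features enter
as (truncated ddG in kcal/mol, rank-normalized evolutionary energy) in
that order. The jackknife refits on all-but-one point and classifies the
held-out point at probability 0.5 (a single decision boundary matches how
the accuracy is reported); points whose training set collapses to a
single class are marked unclassifiable and leave the accuracy
denominator with a warning.

AUC is the tie-corrected rank statistic (equals P(s⁺ > s⁻) + ½P(tie));
the ROC curve sweeps grouped unique thresholds so its trapezoidal area
equals the rank statistic exactly — the two computations cross-check each
other in tests, with exhaustive pairwise brute force and
scikit-learn as independent oracles. Balanced AUC keeps the minority
class whole and repeatedly draws equal-size majority subsets without
replacement (100 by default), reporting mean and population SD over
resamples; with already-balanced input every resample is the full set and
the SD is exactly 0. All resampling is seed-determined.

## Contingency conventions

Printed thresholds use the printed comparators: strict for >3, >2, >1.5,
<75, <70, >70; "destabilized by **at least** 3 kcal/mol" uses ≥. No
fixture value sits exactly on a strict boundary, so the distinction is
observable only for the ≥ case. Censored ddG participates as 15.0.
Group summaries report mean and SEM = sd/√n (sample sd; NA for n < 2).
Landscape quadrant assignment puts records exactly at a threshold on the
lower/left side.

## Structure geometry

One C-alpha per residue is extracted from PDB ATOM records (Biopython);
altlocs resolve to highest occupancy, first-listed on ties. The
clustering statistic is the mean pairwise distance of the affected
position set; the baseline draws random same-size position sets from the
domain (the affected-set statistic is a mean over pairs *within a set*,
so the baseline matches that shape; the simpler all-domain-pairs mean is
also exposed). The baseline's expectation equals the exhaustive
all-subsets average, verified by enumeration on small instances.
Reproducing the published distances requires the original structures and
affected-position sets, and is a documented workflow rather than a test.

## Synthetic data: what it emulates, what it does not

The generators provide every pipeline input with known ground truth:

- **MSAs**: exact independent-column sampling from softmax fields, and
  Gibbs sampling from a full Potts model (n parallel chains,
  independent-site initialization, default 200 full sweeps of burn-in).
  The random generating models use fields of SD 1.0 over the amino
  acids, gap pushed far down, and couplings on 40 random column pairs
  (about two contacts per column) with per-entry SD 0.6 — a regime in
  which co-variation genuinely shapes substitution scores rather than
  being a small correction. Burn-in must scale with coupling strength;
  for this regime 50 sweeps is visibly short of equilibrium while 200
  sweeps suffices, which is why 200 is the default.
- **Variant tables**: benign ddG ~ N(0.3, 0.7²) clipped to [−2, 2];
  pathogenic ddG ~ N(6, 3²) clipped to [1, 15] with probability 0.6 (the
  destabilization-driven fraction) else N(0.5, 0.8²); evolutionary
  energies Beta(2,6) for benign and Beta(6,2) for pathogenic; labels
  either drawn from the logistic model with (w_ddg, w_evo, b) =
  (0.5, 3.5, −1.5) or set by generating class. Steady state follows
  `SS% = 100·(1 − 0.9·σ(ddG − 3)) + N(0, 8)` clipped at 0, placing the
  half-drop at the ~3 kcal/mol degradation threshold.

What passing these tests shows: the estimators recover known truth under
the stated noise and effect sizes, at the stated sample sizes. What they
do not show: real alignments have phylogenetic correlation, gap
structure, and depth heterogeneity that the samplers do not emulate; real
ddG predictions have structured (position- and contact-dependent) error,
not the clipped-Gaussian class mixtures used here; and real
steady-state measurements include assay-specific normalization effects.
Absolute accuracies on real panels are therefore established by the
fixture analyses, not by the synthetic benchmarks.

## Problem sizes and numerical choices

The Potts recovery benchmark uses a 20-site model and 5000 sampled
sequences — large enough that pseudolikelihood recovers the generating
substitution ranking (Spearman ≈ 0.9) yet small enough to fit in minutes
on one CPU. Logistic recovery uses n = 2000 tables over 10 seeds.
Optimizer tolerances: L-BFGS projected-gradient tolerance 1e-4 for Potts
fits (tighter for the field-only consistency check), IRLS gradient
tolerance 1e-8. Ties in ranks are averaged; all stochastic operations
take explicit seeds and are reproducible bit-for-bit.

## Known limitations

- The stability force field itself is out of scope; ddG values are
  consumed, never computed, and the 15 kcal/mol cap is inherited from the
  upstream predictor's clash behaviour.
- Homology search / alignment construction is out of scope; alignments
  arrive as FASTA/A2M.
- The pseudolikelihood fit materializes the full (L, L, q, q) coupling
  array; memory grows as L²q², which is fine for domains of a few hundred
  columns but not for very long concatenated alignments.
- Rank-normalized scores are alignment-dependent: scores fit on different
  alignments are not comparable except through their ranks.
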