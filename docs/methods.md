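# Methods

## Map features

A dataset is described by the resolution of its diffraction data (Å, supplied
as metadata — it is a property of the experiment, not of a sampled grid) and
four global statistics of the starting electron-density map: r.m.s.d. about
the map mean, the third central moment (skew), and the minimum and maximum
density. Molecular-replacement datasets additionally carry the sequence
identity of the search model (a fraction in [0, 1], computed upstream by a
superposition tool and ingested as a number; this package never aligns
sequences). Feature vectors are strict about mode: sequence identity is
required for MR and rejected for experimental phasing, to catch wiring errors
early.

Conventions, chosen where the problem leaves them open:

* statistics run over **all grid points** of the stored map — no masking and
  no asymmetric-unit reduction. No masking rule is canonical here, and a
  consistent convention is all the regression layer needs;
* **population moments** (divisor N), matching the plain reading of
  "deviation from the map mean";
* skew defaults to the **scale-dependent** raw third moment (map-units³); a
  standardized mode (divided by rmsd³) is available behind a flag and is
  undefined on constant maps. Scale-dependent and scale-free variants carry
  the same ranking information once a forest has factored out scale, so the
  simpler raw form is the default;
* maps are written as CCP4/MRC mode 2 (32-bit float). Reading validates the
  declared grid size against the stored data block before parsing, so
  truncation, header/data mismatch, and non-map files raise distinct errors.

## Structure completeness

Completeness is the fraction of deposited-model residues reproduced in the
built model. A deposited residue counts as reproduced when some built residue
has the same three-letter residue type and its Cα lies **strictly** within
1.0 Å (configurable) of the deposited Cα. Matching is one-to-one in both
directions, assigned greedily by ascending Cα–Cα distance; deposited residues
without a Cα are excluded from the denominator, and both models are assumed
to share a crystal frame (no superposition).

Greedy assignment is deterministic and, on protein-like geometry (deposited
Cα at least ~3.5 Å apart, so a built atom can be eligible for at most a
couple of deposited residues), recovers the maximum-cardinality matching —
verified against an exhaustive bipartite-matching oracle on thousands of
random instances. On adversarially dense instances (many same-typed points
packed within the cutoff, which no backbone can produce) greedy is only
maximal, not maximum, and can undercount by a pair; this is a documented
limitation, not a failure mode of the metric's actual domain. Residue types
compare verbatim (MSE ≠ MET): no modified-residue table is applied.

## Predictive model

One regression forest per applicable (variant, measure) cell: 1024 trees,
unlimited depth, bootstrap aggregation, scikit-learn's default per-split
feature subsampling for regression. Predictions are tree means, so they
cannot leave the training-outcome range; completeness predictions are
additionally clamped to [0, 1] to document the bound. All cells share one
random 80/20 split by dataset id (train size = round(0.8·n)), unstratified;
the split seed is recorded in the suite manifest. Each cell's forest seed is
derived deterministically from the suite seed and the cell index. The Zero-R
baseline predicts the training median (even count → midpoint of the middle
two) for every input.

R_free is inapplicable when the variant's final output is unrefined: a
single-stage variant ending in ARP/wARP or SHELXE, with or without Parrot.
The shipped experimental registry — 4 singles, all 12 ordered pairs, and 8
Parrot-preconditioned recipes (the Buccaneer/AutoBuild/SHELXE singles plus
five common pairs) — is a reconstruction totalling 24 variants and 69
applicable cells; the MR registry is the 4 single pipelines (10 cells). Both
are configuration, not constants: any variant list can be registered.

## Prediction intervals

Calibration residuals are **out-of-bag**: each training row is predicted only
by trees whose bootstrap resample excluded it (rows in every bag are skipped;
with 1024 trees that is vanishingly rare). If bagging is disabled there is no
out-of-bag sample and 10-fold cross-validated residuals are used instead,
with a logged notice. A Gaussian-kernel density with Silverman's rule-of-thumb
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) (floor 10⁻⁶) is fitted to the
residuals; the interval is the point prediction shifted by the density's
central quantiles, found by bisection on the kernel CDF — deterministic, and
possibly asymmetric about the point when the residuals are skewed. One global
residual set per cell (homoscedastic): interval width varies between cells,
not between inputs. The confidence level defaults to 0.95 and is
configurable; coverage is validated empirically on synthetic held-out data
(within ±5 percentage points of nominal at 0.90 and 0.95).

## Ranking, grouping, recommendation

Per dataset and measure, records sort by ascending interval width (ties: the
better point prediction, then variant id). Grouping is **greedy anchored
relative**: the first ungrouped record anchors a group at width w₀ and
records join while width ≤ w₀·(1 + 0.05). Relative-to-anchor was chosen
because widths live on different scales across measures, and anchoring (as
opposed to chaining neighbours) prevents unbounded drift in a group's total
spread; an absolute-difference mode sits behind a flag. The recommended
variant is the best **point** prediction (max completeness, min R factor;
ties: narrower width, then variant id) — grouping communicates confidence but
does not veto the recommendation.

## Evaluation protocol

* MAE/RMSE per cell for forest and Zero-R, on held-out and training rows
  (the train/test gap diagnoses over-fit);
* ablation: retrain the entire suite without one feature at a time, same
  seeds and split, and report ΔMAE/ΔRMSE against the all-features suite —
  positive delta means the feature was informative;
* resolution-binned mean/SD (sample convention, n−1) of predicted vs actual
  outcomes, default bin width 0.1 Å over the observed range, empty bins
  reported with n = 0;
* group hit rate: the fraction of datasets whose best variant lands in the
  first (most certain) group, where "best" defaults to smallest
  |predicted − actual| (an actual-outcome criterion is available);
* within-k: fraction of datasets whose recommended variant's actual outcome
  is within k of the best achievable across variants, cumulative in k
  (defaults 0.01 and 0.05).

Wall-clock analyses are out of scope (hardware-bound); the CLI logs timing
only.

## Synthetic data

The generators define the study conditions and provide exact ground truth:

* **maps** — isotropic Gaussian blobs at uniform-random positions plus white
  noise on a cubic grid. Histogram statistics are controllable (no blobs +
  noise σ → rmsd → σ; a blob → positive skew), but there is no
  crystallographic physics: no structure factors, no Fourier synthesis, no
  symmetry;
* **model pairs** — deposited Cα trace at 3.8 Å spacing on a jittered path;
  the built model reproduces round(match_fraction·n) residues displaced by a
  fixed sub-cutoff distance, mutates round(wrong_type_fraction·n) types in
  place, and omits the rest, making the true completeness exact by
  construction;
* **outcome tables** — features sampled with resolution uniform on
  [1.0, 4.0] Å and map statistics tied to a latent map-quality variable that
  decays with resolution; per-variant responses are smooth
  logistic-in-resolution curves (completeness high near 1–2 Å, collapsing
  beyond ~3.5 Å; R factors rising with resolution, R_free offset above
  R_work) with variant-specific midpoints, a secondary skew dependence, and
  an MR sequence-identity term, plus Gaussian noise (σ = 0.05 for
  completeness, 0.02 for R factors) clamped to the valid range. Custom
  response functions can be supplied per cell, and the noiseless truth is
  returned alongside for recovery tests.

Passing tests on these fixtures show that the machinery — feature extraction,
training, calibration, ranking, evaluation — behaves correctly when its
statistical assumptions hold. They do not show that real model-building
outcomes are this predictable: real maps have correlated, non-Gaussian errors,
real pipelines have stochastic failure modes, and real feature→outcome
relationships are not smooth logistics. Numbers computed on fixtures
characterize the method, not the pipelines.

## Problem sizes and numerical choices

Statistical tests run at the sizes their claims need: learner-vs-baseline and
interval coverage at n = 2000 datasets with the full 1024-tree configuration;
ablation at n = 500 with 128 trees over 10 seeds (the ablation contrast is a
large-effect comparison and does not need the full ensemble); the end-to-end
CLI run at n = 300 with 128 trees. The acceptance script trains both default
suites at 1024 trees on n = 400 (experimental) and n = 300 (MR) datasets.
Degenerate inputs are defined rather than left to chance: empty maps,
constant maps under standardized skew, deposited models without Cα, tables
with fewer than 2 rows, fewer than 10 residuals, and zero-spread residual
sets all have specified behaviour (error or documented floor).
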