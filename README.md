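# buildrank

Predict — before running anything — how well each automated crystallographic
model-building pipeline would perform on a given X-ray dataset, and rank the
options by how much the prediction can be trusted.

## The problem

After phasing (experimentally or by molecular replacement), a crystallographer
has an electron-density map and a choice of model-building pipelines:
ARP/wARP, Buccaneer, Phenix AutoBuild, SHELXE — run alone, in ordered pairs
(the first pipeline's model seeding the second), optionally after Parrot
density modification. Which variant builds the best structure differs from
dataset to dataset, and each run can take hours to days. Pipeline choice in
practice correlates more with habit and geography than with the data.

`buildrank` treats this as a per-instance algorithm-selection problem. For a
dataset described by six cheap features — the resolution *d* of the data and
five statistics of the starting map: its r.m.s.d.
σ(ρ) = √⟨(ρ − ⟨ρ⟩)²⟩, raw skew ⟨(ρ − ⟨ρ⟩)³⟩, maximum and minimum density,
and (for MR) the search-model sequence identity — one random-forest regressor
per (pipeline variant, evaluation measure) cell predicts the outcome of that
variant:

* **structure completeness** — the fraction of deposited-model residues
  reproduced in the built model (same residue type, Cα–Cα distance < 1 Å,
  one-to-one matching),
* **R_work** and **R_free** — refinement agreement statistics, ingested as
  numbers (never computed here).

Each forest has 1024 unlimited-depth bagged trees; prediction is the mean
over trees. Uncertainty comes from the forest's out-of-bag residuals: a
Gaussian-kernel density (Silverman bandwidth) over the residuals gives a
prediction interval `point + [q_{(1−c)/2}, q_{(1+c)/2}]` at confidence *c*
(default 0.95). Variants are reported in increasing interval-width order,
with near-ties (width within 5% of the group's narrowest member) grouped
together, and the variant with the best point prediction is recommended.
A Zero-R baseline (training-median predictor) accompanies every cell, and the
evaluation module reproduces the full protocol: MAE/RMSE vs baseline,
train/test gap, leave-one-feature-out ablation, resolution-binned
predicted-vs-actual statistics, first-group hit rate, and the within-1%/5%
recommendation analysis.

R_free only exists for variants whose final model is refined, so the default
experimental-phasing registry (4 single pipelines, 12 ordered pairs, 8
Parrot-preconditioned variants) trains 69 regressors, and the MR registry
(the 4 single pipelines) trains 10.

Real training corpora are not shipped. The `synthetic` module generates
everything with known ground truth: Gaussian-blob density maps, built/deposited
model pairs with constructed completeness, and feature→outcome tables with
known response functions — see `docs/methods.md` for what these fixtures do
and do not emulate.

## Worked example

Everything is available from Python (`import buildrank`) or the `buildrank`
CLI. A complete synthetic study:

```sh
buildrank fixtures --n-datasets 200 --seed 7 --outdir data
buildrank train    --features data/features.csv --outcomes data/outcomes.csv \
                   --model-dir suite --n-trees 256 --seed 7
buildrank predict  --model-dir suite --features data/features.csv --out predictions.csv
buildrank rank     --predictions predictions.csv --dataset-id synth-00003 \
                   --measure completeness
```

prints (truncated):

```
measure: completeness   recommended: parrot-buccaneer-then-arpwarp
group 1 (width anchor 0.1981):
  autobuild-then-buccaneer         point=0.7860 width=0.1981
group 2 (width anchor 0.2117):
  parrot-shelxe-then-autobuild     point=0.7786 width=0.2117
  autobuild-then-arpwarp           point=0.7805 width=0.2170
  ...
```

Reading: for dataset `synth-00003` the most *certain* prediction is for the
AutoBuild→Buccaneer pair (narrowest 95% interval, width 0.198); the variant
*predicted to build the most complete model* is Parrot + Buccaneer→ARP/wARP.
Certainty and quality are deliberately separate signals.

`buildrank evaluate` scores the suite on its held-out 20% split. On the run
above it reports a mean held-out MAE of 0.0267 for the forests against
0.1203 for the Zero-R baseline across the 69 cells, plus per-measure
first-group hit rates and within-1%/5% recommendation fractions.

Map features and completeness are also available directly:

```sh
buildrank extract-features --map mymap.map --resolution 2.0
buildrank completeness --built built.pdb --deposited deposited.pdb
buildrank gen-scripts --outdir scripts-out   # one runnable script per variant
```

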