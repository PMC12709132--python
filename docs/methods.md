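# Methods

`kinoreg` predicts quantitative kinase inhibition — the percent-inhibition
readout of a competition-based kinase screen, on a 0–100 scale — for
kinase–compound pairs, from a fixed-width featurization of the kinase
binding pocket and of the compound. This note documents the model, the
featurization, the synthetic-data generator, the numerical choices, and
what the shipped tests do and do not demonstrate.

## Input representation

**Kinase (8,551 values).** The binding pocket is summarised by four
feature families computed from its per-residue annotation:

| block | width | content |
|---|---|---|
| `aa_*` | 20 | amino-acid composition (relative frequencies) |
| `aa3_*` | 8,000 | overlapping amino-acid 3-mer frequencies (20³) |
| `ss_*` | 8 | 8-state secondary-structure composition (DSSP states G,H,I,T,E,B,S,C) |
| `ss3_*` | 512 | secondary-structure 3-mer frequencies (8³) |
| `exp_*` | 2 | exposure-state composition (exposed/buried) |
| `exp3_*` | 8 | exposure 3-mer frequencies (2³) |
| `pocket_volume` | 1 | pocket volume (Å³) |

A residue is *exposed* when its relative solvent accessibility (RSA =
observed ASA / maximal ASA) is ≥ 0.5, *buried* otherwise; the boundary
value counts as exposed. When absolute ASA is supplied (classic DSSP
output), it is converted to RSA with the theoretical maximal-ASA table of
Tien et al. (2013), shipped as package data and overridable. All
frequencies are *relative*: counts divided by the number of valid residues
(composition) or valid 3-mer windows (3-mers), so pockets of different
lengths are comparable. k-mer blocks are indexed lexicographically over
fixed alphabet orderings (`ACDEFGHIKLMNPQRSTVWY`, `GHITEBSC`, `EB`).
Non-standard residues are dropped from composition denominators and
invalidate any window containing them; a pocket shorter than 3 residues is
rejected. Whether pocket volume should be rescaled before training is left
to the standardizer (see below), which z-scores every column anyway.

**Compound (2,757 values).** A fixed-width molecular-descriptor vector
(canonically 2,756 columns, PaDEL-style, consumed from CSV — the package
does not compute descriptors) plus the assay concentration as the final
element. Concentration is stored in molar units and encoded as
−log10(molar) by default (configurable: identity / log10 / neg_log10).
Missing descriptor cells are imputed to the column median. The descriptor
width is configurable so reduced-width synthetic studies can run; the
canonical mode enforces 2,756.

A pair row is the concatenation: 8,551 + 2,757 = 11,308 columns.

## Dataset construction

Pairs are split 6:2:2 into train/validation/test at the pair level
(validation and test sizes are `round(ratio·n)`, train is the remainder;
the unit is the row — grouping by kinase or compound for leakage-aware
splits is available as an option but not the default). Percent-inhibition
screens are strongly bimodal (most mass at 0 and 100), so plain **random
oversampling (ROS)** duplicates mid-range *training* rows — percent
inhibition in the closed interval [1, 99] — with replacement until their
count reaches `ceil(target_ratio × n_extreme)` (default ratio 1.0, never
reducing a count). Extreme rows are never duplicated; validation and test
rows are never touched, so no oversampled copy can leak across splits.

## The regression network

The regressor is a 1D convolutional network over the 11,308-element input
treated as a signal: per layer and kernel

Conv(x)ᵢₖ = F( Σₘ wᵏₘ · xᵢ₊ₘ + bₖ ),

with ReLU activations in the body and a linear scalar output. The
canonical stack is **20 convolutional layers, two max-pooling layers
(window 2, after conv layers 10 and 20) and three fully connected layers**,
trained with **RMSprop on an RMSE loss** at learning rate 1e-6 for 150
epochs. Those layer counts, activations, optimizer, loss, learning rate
and epoch count are the fixed canonical choices; everything else is not
determined by that description and is therefore an explicit, overridable
`ModelConfig` default chosen here: kernel size 3, 'same' padding, 32
filters doubling after each pooling layer, FC sizes 512/128/1, batch 64,
no dropout, RMSprop ρ=0.9/ε=1e-7.

Implementation notes:

- Pure numpy on CPU. Convolutions are im2col + GEMM in channels-last
  layout with float32 parameters; training is bit-reproducible for a fixed
  seed on a single thread (the test suite asserts history equality to
  1e-6). The standalone `conv1d_forward` reference operation is float64
  and is verified against an explicit double-loop oracle to 1e-6.
- Inputs are z-scored per column with statistics from the **training rows
  only** (a raw-scale input with lr 1e-6 would not train); the scaler is
  stored in the checkpoint and re-applied at prediction time.
- The regression target may be trained as-is (`identity`, default) or
  scaled to [0,1] (`scale01`); predictions are always returned on the
  0–100 scale, optionally clipped (off by default). The transform is
  deliberately configurable: reported headline errors for models of this
  family are not always interpretable on the raw percent scale, and no
  single transform is canonical.
- `fit()` returns a results object holding the per-epoch train/validation
  RMSE history and the parameters at the best validation loss (the final
  parameters when no validation split exists); `epochs=0` returns the
  initialized network unchanged. A NaN/inf loss aborts with a diagnostic
  suggesting a lower learning rate.

## Evaluation

Five metrics: RMSE, MAE, R² (1 − SSres/SStot, may be negative), Pearson
correlation (PCC), and the **acceptance interval ratio (AIR)** — the
fraction of predictions within ±10 percent-inhibition points of the
observation. The tolerance is read as *absolute points on the 0–100
scale* (the targets are percents) and the boundary is inclusive; both
choices are configurable. The feature-selection sweep ranks features by
random-forest importance (any nonnegative importance provider can be
plugged in), takes nested top-N sets (default sizes 2,000–10,000, ties
broken towards the lower index) and refits every registered model per
size; baselines (ridge, lasso, random forest, gradient boosting, global
mean) are scikit-learn estimators behind a plain fit/predict contract.

## Explanations

Per-kinase prediction quality is the Pearson correlation between observed
and predicted inhibition over that kinase's pairs (kinases with fewer than
3 pairs or constant observations are excluded); the default report takes
the top five kinases. Individual predictions are explained with a local
surrogate in the LIME style: perturbed copies of the instance are drawn
feature-wise from background statistics (Gaussian for continuous columns,
Bernoulli at the background frequency for binary fingerprint-like
columns), weighted by exp(−d²/κ²) on standardized distance with
κ = 0.75·√width, and a weighted sparse linear surrogate restricted to the
10 strongest features (ridge pre-selection, weighted least-squares refit)
is fitted to the model outputs. Defaults (2,000 samples, κ, 10 features)
follow common tabular-surrogate conventions; all are configurable, and
explanations are deterministic given a seed. Coefficients are reported on
the standardized feature scale so magnitudes are comparable across
features. Per-instance weights aggregate to a ranking by the **mean
absolute weight** across instances (features not selected in an
explanation contribute zero), with ties broken by feature name; amino-acid
3-mer features containing the phospho-acceptor residues S, T or Y are
flagged.

## Synthetic screens

The generator emulates the structure of a kinase-panel screen at the
canonical scale — 234 kinases × 163 compounds with ~49.2% of the grid
measured (≈18,771 pairs) — with a bimodal percent-inhibition distribution
and a *learnable, recorded* signal. Per pair (kinase i, compound j):

y = clamp( base + s·(uᵢ·vⱼ + c·logconc ⱼ) + ε, 0, 100 )

- **base** is a three-component mixture: point mass at 0 (weight 0.4 by
  default), point mass at 100 (0.4), and Beta(2,2) rescaled to (1,99) for
  the sparse mid-range. Point masses (rather than narrow continuous
  components) mirror the floor/ceiling clamping of real assay readouts and
  make the degenerate no-noise case exactly two-valued; the noise term
  spreads them into the [0,1] and [99,100] neighbourhoods.
- **uᵢ** is observable by construction: a seeded random projection of the
  pocket's amino-acid composition, plus a constant coordinate. **vⱼ** is
  read off designated continuous descriptor columns (standardized), plus a
  constant coordinate. The constant coordinates make the dot product
  decompose as kinase main effect + compound main effect + interaction
  (one interaction dimension per `latent_dim`). Ground truth (latents,
  driver columns, per-pair scores) is written as a sidecar JSON so
  recovery tests never re-derive it.
- **logconc** is the standardized log10 assay concentration (log-uniform
  over 1 nM–10 µM by default, stored in molar units).
- ε is Gaussian with sd `noise_sd` (default 5).

What the generator does **not** emulate: real protein structure (pocket
sequences are uniform random, so 3-mer composition carries no biology),
chemically meaningful descriptors, SMILES, assay-specific error structure,
or kinase-family correlation. Tests passing on these screens demonstrate
that the pipeline's machinery works — geometry, oversampling contract,
optimization, signal recovery, explanation plumbing — not that the model
attains any particular accuracy on real screening data.

## The signal-recovery experiment

`kinoreg.experiments.run_recovery_experiment` is the package's standard
self-check, also driven by `scripts/acceptance.py`: a reduced-scale screen
(full 40×50 grid = 2,000 pairs, 30 descriptors, `signal_strength=80`,
`noise_sd=2`, extreme weights 0.05/0.05, `latent_dim=1`) is featurized,
split, oversampled, reduced to the top 256 features by random-forest
importance, and fitted with a narrow canonical stack (20 conv layers, 8
filters, FC 64/32/1, lr 1e-3, 150 epochs, target scaled to [0,1]). At
signal strength 80 the clipped link itself reproduces the 0/100 bimodality
(~70% extreme mass) and the generator satisfies its own stated property
that with large signal and no noise the Spearman correlation between the
planted score and the generated inhibition exceeds 0.9. The experiment
reports test-set metrics for the CNN, a default ridge pipeline and the
global-mean predictor. Typical values at these conditions: CNN PCC ≈
0.83–0.88 (information ceiling ≈ 0.96), ridge ≈ 0.71–0.76. Problem sizes
were chosen so the whole experiment runs in a few minutes on one CPU core.

## Explanation recovery and an identifiability caveat

Validating the explainer against planted drivers turned up a real
limitation of screen-shaped data. In a panel with few distinct compounds,
every compound descriptor column is a perfect proxy for compound identity,
so a network free to key on any informative column may predict compound
effects from non-causal columns — and a faithful local surrogate then
correctly attributes to those proxies. Permutation-importance diagnostics
on screen-trained networks confirmed exactly this (the causal driver
columns can rank far below identity-proxy columns in the model's own
sensitivity). Driver recovery through a screen-trained model is therefore
*unidentifiable* and is not used as a check; the screen-based measurement
remains available (`RecoveryResult.xai_*`, off by default) as a
demonstration of the effect.

The identifiable check, `run_xai_recovery_experiment`, draws every row's
features independently (30 continuous + 10 binary columns, no entity
structure, so no column can proxy another) and generates the target from
exactly five known drivers — three continuous main effects, one continuous
driver with main effect plus a continuous×continuous interaction, and one
binary effect — with small Gaussian noise, clipped to [0, 100]. A narrow
canonical network is fitted and test rows are explained under five
independent surrogate seeds; recovery is the fraction of the five drivers
in the aggregated top-5 table, averaged over the seeds. Measured recovery
is ≥ 0.6 (typically 0.8–1.0) across seeds. The same caveat applies to
interpreting attributions on real screens: feature importances identify
what the model uses, which coincides with mechanism only when the design
decorrelates the candidate features.

## Known limitations

- The canonical full-width network (11,308 inputs, 512-unit FC head) is
  buildable and trainable but slow in numpy; the recovery experiment and
  tests run the narrow configuration instead.
- ROS duplicates rows only (no interpolation); the stopping rule
  (`target_ratio`) is an explicit knob because no single rule is canonical.
- The per-kinase ranking uses plain PCC and excludes low-count kinases;
  no shrinkage across kinases is applied.
- Surrogate explanations perturb features independently (no correlation
  structure), the standard trade-off of the LIME family; aggregated
  importances are means of absolute weights and carry no sign.
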