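# Methods

## Signatures and aggregation

All computation operates on *signatures*: vectors of per-gene
differential-expression z-scores for one perturbagen in one cell line,
aligned to a fixed ordered gene space (978 landmark genes by default,
mirroring the directly measured genes of L1000-class platforms). Raw plates
are normalized per gene against the plate's control wells,
`z = (x − mean_ctl) / sd_ctl`, with the **population** standard deviation
(ddof = 0) over controls; at least two control wells are required, and
genes whose control sd is below 1e-8 get z = 0 with a logged warning rather
than an infinity. Replicate wells are collapsed by unweighted mean.

A perturbagen profiled in several cell lines is reduced to a single feature
vector by one of two operators: **cell-averaging** (element-wise mean over
the cell lines actually profiled; no imputation) or **cell-concatenating**
(blocks in a fixed dataset-wide cell-line order; absent cell lines are
zero-filled, the z-score of "no change", so every entity has the same
feature length). Averaging is the default everywhere: it is insensitive to
which cell lines a perturbagen happened to be profiled in, whereas
concatenation preserves cell-specific responses at the cost of zero blocks.

## Gold standard

Raw interaction records carry a free-text role field, an affinity type and
value (µM), and an optional active flag. A record is kept if flagged active
or if its affinity is below 30 µM (the cutoff applies to any affinity type
present). Mode assignment: role text containing *inhibitor*/*antagonist* →
inhibition; *activator*/*agonist* → activation; otherwise an inhibitory
assay unit (IC50 or Ki) → inhibition; otherwise the record is unusable.
Because "antagonist" contains "agonist" as a substring, inhibitory keywords
are matched first and removed from the text before the activatory check;
records whose text genuinely matches both families are dropped with a
logged conflict. A pair annotated with both modes in different records is a
positive in both matrices.

Negatives are **all** compound × protein pairs over the declared universes
that are not positives of the mode — at curated-database scale this makes
negatives outnumber positives by ~200:1, which is why per-protein AUPR runs
low and why the package also supports per-protein balanced negative
subsampling (1:ratio, training only).

## Direct correlation

`score(i, m) = corr(φ(Xᵢ), ψ(Pₘ))` with knock-down profiles for inhibition
and over-expression profiles for activation. Pearson on z-scores is the
default (the inputs are already variance-stabilized); Spearman is available
for heavy-tailed data. For concatenated profiles the correlation runs over
the full vector including zero blocks. Pairs involving a constant profile
are undefined and skipped with a log message. The known-vs-other sanity
check is a one-sided Mann–Whitney rank-sum (positives greater) with tie
correction; when every score is tied the tie-corrected z is 0/0 and the
package returns p = 0.5 by the z = 0 convention.

## Joint learning

Squared loss on ±1 labels with ridge (λ₁) and similarity fusion (λ₂):
the solution satisfies `(XᵀX + λ₁I)W + λ₂WL = XᵀY` with `L = diag(S·1) − S`.
Similarities are clipped at zero so L is positive semidefinite and the
system is uniquely solvable for any λ₁ > 0. With complete labels the
system is solved exactly: eigendecompose L once, rotate, and solve one
ridge system per Laplacian eigencomponent in the shared eigenbasis of XᵀX;
the stationarity residual is checked to 1e-6 relative norm. With a pair
mask (balanced subsampling) the per-protein designs differ and the coupled
block system is solved by conjugate gradients to 1e-10 relative tolerance.

Two numerical choices matter in practice:

* **Feature centering (default on).** With ±1 labels, an uncentered fit
  adds `(XᵀX + λ₁I)⁻¹Xᵀ1` — the same vector for every protein — to each
  column's solution. This component lives in the fusion penalty's consensus
  null space, so no amount of coupling removes it; it contributes an
  identical compound-leverage term to every protein's scores, which is pure
  noise for per-protein ranking. Centering features on the training mean
  removes it exactly and makes rankings invariant to 0/1-vs-±1 label
  coding. `center=False` restores the literal uncentered fit.
* **Scale of λ₂.** The fusion term competes with XᵀX, whose spectrum scales
  with the number of training compounds times the per-feature variance.
  With the defaults λ₁ = λ₂ = 1 the coupling is a mild regularizer; for
  coupling to materially transfer information between proteins, λ₂·S must
  reach the scale of XᵀX's eigenvalues. `select_jl_hyperparameters` does a
  small grid search by inner compound-wise CV on mean per-protein AUC.

## Evaluation protocol

Compounds (not pairs) are split into k = 5 folds (sizes differing by at
most one, seeded); each fold's compounds are scored by a model trained on
the rest (DC involves no training but follows the identical fold protocol,
so both methods are evaluated on exactly the same test sets). Test scores
are pooled across folds before computing per-protein AUROC (tie-averaged
Mann–Whitney identity) and AUPR (step-wise average precision); pooling
rather than per-fold averaging keeps proteins with very few positives
evaluable. Proteins whose pooled test set is single-class are excluded and
listed. Balanced subsampling, when requested, is applied to training folds
only. Degree stratification reports per-bin counts and mean/median
AUC/AUPR over inclusive degree bins.

## Indications

A drug's target profile is the union of its known (protein, mode) targets
and the globally top-`fraction` scoring predicted pairs per mode (ties at
the cut broken lexicographically for determinism; known provenance wins on
overlap). A disease's profile lists its therapeutic targets with the mode
required for benefit. With mode distinction, drug and disease must share a
(protein, mode) pair; without it (the baseline of earlier repositioning
methods) any shared protein links them. The link score is the count of
shared mode-matched targets, which reduces to the binary linking rule at
threshold ≥ 1 and gives per-disease drug rankings for AUC/AUPR.

## Synthetic data generator

Each protein *m* has two latent transcriptional programs: g_m (knock-down
direction) and h_m (over-expression direction), drawn independently of each
other — over-expression need not mirror knock-down. Programs are i.i.d.
Gaussian per gene with sd = `signal_strength × noise_sd`, so
`signal_strength` (s) is the program-to-noise amplitude ratio and the
expected planted-pair correlation is ≈ s²/(s²+1) before cell effects.
Observed signatures add a per-cell-line offset (Gaussian, sd
`cell_effect_sd`, shared by all perturbagens within a cell line) and
i.i.d. Gaussian noise:

```
knockdown(m, c)      = g_m + offset_c + ε
overexpression(m, c) = h_m + offset_c + ε
inhibitor of T (c)   = Σ_{m∈T} g_m + offset_c + ε
activator of T (c)   = a · Σ_{m∈T} h_m + offset_c + ε
```

with `a = activator_attenuation ∈ [0, 1]` modelling the negative-feedback
damping that makes activator signatures correlate more weakly with
over-expression than inhibitors do with knock-down. Compound target counts
come from a fixed or geometric degree distribution, or from an explicit
per-protein ligand-count vector (used to construct degree-stratified
worlds); `protein_program_correlation` with `cluster_size` gives
consecutive proteins correlated programs, inducing clustered protein
similarity. Everything is deterministic under (config, seed).

Defaults (chosen once): 978 genes; 3 / 2 / 2 cell lines for chemical /
knock-down / over-expression (real screens use tens of cell lines; the
scaled-down counts keep the multi-cell-line structure at desk scale);
noise_sd = 1 (z-score scale); signal_strength = 1; fraction_activators =
0.2 (activator annotations are much rarer than inhibitor annotations in
curated databases); activator_attenuation = 0.5; cell_effect_sd = 0.3.

What the generator does *not* emulate: structured (correlated) biological
noise, dose/time covariates, off-target transcriptional programs, false
negatives in the gold standard, and systematic chemical-vs-genetic
discordance. Tests passing on this generator therefore show protocol and
solver correctness and the stated directional effects under clean
assumptions — not performance on real screens.

## Benchmark studies (`sigtarget.benchmarks`)

Problem sizes were fixed once, large enough for stable means and small
enough that the full suite runs in seconds:

* **Negative-set construction** at the curated-database universe sizes
  (2,445 × 769 with 10,031 positives; 350 × 77 with 432).
* **Oracle exactness**: rank-based AUC vs exhaustive pair enumeration on
  1,000 random instances (≤ 200 items); the joint solver vs a dense
  vectorized normal-equation solve on 50 small instances.
* **Null calibration**: s = 0, 300 compounds, 20 proteins — DC and JL mean
  CV AUC should sit in [0.45, 0.55].
* **Signal recovery**: s = 10, same sizes — DC mean CV AUC ≈ 1.
* **Low-degree transfer**: program clusters of four proteins (three with
  ten ligands, one with a single ligand, within-cluster program
  correlation 0.9), s = 0.11, 20 knock-down cell lines, λ₁ = 300,
  λ₂ = 1000 — reports DC and JL AUC split by degree.
* **Mode distinction**: ten diseases, six drugs each sharing the disease
  protein, half in the wrong mode — per-disease AUC with vs without the
  distinction.
* **Activator attenuation**: generator defaults with a = 0.3 — mean
  planted-pair correlation per mode.

## Known limitations

* **Low-degree transfer does not beat direct correlation in this synthetic
  world.** In the generator, the knock-down profile *is* a direct noisy
  measurement of the exact direction that generates inhibitor signatures,
  so DC at degree 1 is essentially a matched filter with the true template
  and is near-optimal. The joint model's borrowed template is capped at
  the between-program correlation (0.9) times the neighbor-ensemble
  quality, and loses further to fusion-operator noise amplification and to
  spurious similarity edges (partly systematic: knock-down cell-offset
  means are shared across proteins). Across wide scans of λ₁ × λ₂,
  knock-down replication, signal strength, gene count, and cluster design,
  JL's degree-1 AUC stays below DC's, while JL consistently *wins* on
  well-annotated proteins and often overall. On real screens the balance
  differs: knock-down templates are degraded by seed effects and
  off-target responses, gold standards are contaminated by unknown true
  positives (depressing measured DC accuracy), and structured noise favors
  models that learn discriminative directions — none of which this
  generator models. The corresponding benchmark assertion is left failing
  by design rather than tuned into passing.
* The exact formulation of the similarity-coupled objective (squared loss,
  ±1 coding, Laplacian fusion, clipped-correlation similarity) is one
  concrete realization of "simultaneous learning under shared protein
  similarity"; published variants differ and per-protein AUC tables from
  real data should not be expected to match numerically.
* z-scoring is implemented per plate against that plate's controls; screens
  that normalize per cell line or use moderated variance estimates will
  differ in scale.
* Identifier handling is by opaque string equality; no cross-database
  identifier translation is attempted.
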