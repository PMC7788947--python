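# Methods

## Model and procedure

The package predicts a viability phenotype `cv` from differential-expression
signatures `x` over the 978 landmark genes. The prediction is a sum of
regression trees, `cv̂ᵢ = Σₖ fₖ(xᵢ[DEGs])`, built stagewise so that the
prediction after `t` rounds equals the prediction after `t−1` rounds plus
the `t`-th tree's scores. Tree construction is delegated to xgboost
(`reg:squarederror`, histogram method, fixed base score = training-target
mean); the package owns the gene-restriction wrapper, the staged-prediction
probes that verify the additive contract, seeding, and the fitness bridge to
the swarm optimiser.

Upstream of the regressor sit three components authored here:

1. **Association** (`association`). Compound signatures match viability
   records on (cell line, perturbagen) with the log-scale dose rule
   `|log₁₀ Cdose − log₁₀ Ldose| ≤ 0.2`; shRNA signatures match on
   (cell line, perturbagen) alone. All passing records are averaged into
   the target — the stated behaviour is averaging over batches at the same
   concentration; we extend the mean to every passing record and record the
   multiplicity per row, so tests can assert exact counts. Keys compare
   after whitespace/case normalisation. Instances matching nothing are
   dropped and counted. Time subsetting happens after matching
   (`subset_by_time`), and the S2 variant appends `log₁₀(dose)` as one
   non-gene predictor column.

2. **WRFEN** (`wrfen`). Random forest: 40 trees, per-node subspace of
   ⌈M/3⌉ genes (the regression convention; the subspace size is otherwise
   unspecified), impurity-reduction importance, zero-importance genes
   dropped. Elastic net: predictors standardised on the training fold,
   grid over l1-ratio {0.1, 0.2, 0.5, 0.7, 0.95, 1} × penalty
   {0.1 … 1.0 step 0.1}, best pair chosen by validation Pearson, importance
   = |coefficient|, zero-coefficient genes dropped. Both use one seeded
   80/20 split of the training partition for their validation Pearson.
   Fusion: per-gene weighted mean of the two ranks with weights
   `e^Pearson`; a gene retained by only one method takes the other
   method's worst-plus-one rank (the minimal completion consistent with
   per-method removal of non-contributing genes); the automatic selected
   count applies the same weights to the two retained counts. Ties in
   importance break by gene id, and both rankers sort columns canonically
   before fitting, so the selected set is invariant to table layout.

3. **FEBPSO** (`febpso`). 48-bit particles, six bits per parameter, value
   `i ∈ [0, 63]` mapping linearly onto the parameter's bounds (integer
   parameters rounded). Default bounds — learning_rate [0.01, 0.3],
   gamma [0, 2], max_depth [3, 10], min_child_weight [1, 15],
   subsample [0.1, 1], colsample_bytree [0, 1] (a decoded 0 is clamped to
   the one-feature minimum at fit time), lambda [0.01, 2],
   iteration_times [100, 6000] — are config-overridable; they cover the
   published optimal combinations, whose colsample values are exactly
   i/63 grid points. Velocity update
   `v′ = w(k)v + c₁r₁(pbest − x) + c₂r₂(gbest − x)` with r₁, r₂ fresh
   uniforms per component per iteration (more exploratory than per-particle
   scalars), clamped to ±10; bits resample with probability sigmoid(v′)
   (the standard binary-PSO transfer; the update rule for bits is otherwise
   unspecified). Inertia weight
   `w(k) = α₁e^(−ψk/T) + α₂e^(ψk/T)` with α₁, α₂ fixed by w(0) = w₁ and
   w(T) = w₂. Note the schedule is not confined to [w₁, w₂]: for ψ = 2.6
   it dips below w₁ in the interior (and does so even when w₁ = w₂) before
   rising to w₂ — tests assert the closed form and the boundary
   identities, not interior bounds. Personal/global bests update on strict
   improvement (no update on ties); fitness is evaluated on the same
   validation fold at every iteration for comparability; non-finite
   fitness is treated as −∞ and counted. Initial positions are fair coin
   flips, initial velocities uniform on [−1, 1].

The fitness is the validation-fold Pearson correlation of observed vs
predicted viability; constant predictions map to −1 so degenerate
parameter regions (e.g. gamma and min_child_weight at their maxima, which
admit no split) remain comparable.

## Validation statistics (`sensitivity`)

GI50 rule: Δ = GI50 − max tested concentration; effective iff Δ < 0, with
the Δ = 0 boundary (no inhibition reached within the tested range, GI50
recorded at the highest concentration) ineffective. Active-area rule:
centre by the mean; effective above +0.8·s, ineffective below −0.8·s,
excluded between, where s is the **sample standard deviation** — the rule
is sometimes phrased as "0.8 variance", but a literal variance would be
unit-inconsistent, so the SD reading is used (the band is configurable).
Excluded records do not enter ROC/PR. Multiple signatures per (drug, cell
line) collapse to the minimum predicted viability; a ≥ 10 µM concentration
filter (boundary retained) is available for active-area panels. ROC/PR
rank by **negated predicted viability** (lower viability ⇒ more effective;
the orientation is recorded in the report); AUCs are trapezoidal, with
tied scores collapsed into single threshold steps, and the PR curve is
integrated along its native decreasing-recall order so tied-recall points
contribute zero width. Mann–Whitney uses exact enumeration for combined
n ≤ 12 without ties and the tie-corrected normal approximation otherwise;
the pipeline's default alternative is one-sided ("effective drugs have
lower predicted viability"). Confidence intervals on AUC are not computed.

## Synthetic screens (`simulate`)

The generator emulates the joint structure the pipeline consumes, not the
L1000 assay itself. Unique (cell line, drug, dose) conditions are drawn
without replacement from the design grid, assigned one perturbation time,
and replicated across batches. Expression is standard normal per gene
(the marginal distribution of real level-5 signatures is not specified
anywhere; standard-normal is an assumption, stated as such); the
informative genes additionally share a latent per-condition state with
within-condition correlation ρ = 0.7, so batch replicates are correlated
the way biological replicates are while every gene stays N(0, 1)
marginally. Viability follows a bounded saturating link — a weighted sum
of the informative genes through tanh — because the motivation for fusing
a tree ensemble with a linear selector is precisely a nonlinear
gene→viability relationship:

```
cv = baseline + amplitude · tanh(w·x/√m) + dose_effect · log₁₀(dose) + N(0, noise_sd)
```

Compound mode uses baseline 0.5, amplitude 0.35 (a [0, 1]-like viability
scale); shRNA mode uses baseline 0, amplitude 1 (a signed log-fold effect
scale) and no dose. Defaults — 600 instances, 978 genes, 15 informative
genes with weights ±U(0.75, 1.5), 6 cell lines × 25 drugs × 5 log-spaced
doses (0.12–10 µM), times {3, 6, 24} h, 2 batches, noise SD 0.05, dose
effect −0.04 per log₁₀ µM (viability falls mildly with dose) — are the
benchmark conditions used throughout the tests. One global seed fans out
to independent substreams (design, link, expression, noise) so stages can
be regenerated in isolation.

The sensitivity table derives intended labels from each drug's mean
noise-free viability: a viability deficit > 0.1 below baseline means
intended-effective, in which case the GI50 is placed strictly below the
maximum tested concentration (monotone in the deficit); otherwise the
GI50 is recorded at the highest tested concentration. The active area is
4 × deficit, so low viability maps to a large active area.

What the generator does **not** model: inference from the 978 landmarks
to the full genome, batch effects beyond replicate noise, cell-line
covariance structure, compound structure, or assay-specific error models.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and recovers planted structure at realistic dimensions — not that
the published real-data accuracies transfer.

## Pipeline choices (`pipeline`)

Rows split 60/20/20 into train/validation/test with a seeded shuffle
(split sizing is otherwise unspecified; a grouped-by-cell-line split can
be emulated by subsetting upstream). WRFEN runs on the training
partition; the swarm's fitness fits on train and scores on validation;
once hyperparameters are frozen the final model is refit on
train + validation and evaluated once on test. The untuned comparison
model (library-default hyperparameters, 100 rounds) is fit on train and
scored on validation, mirroring the tuned/default comparison. If the
elastic net retains no gene at any grid point — the expected outcome on a
signal-free target — the pipeline falls back to the RF ranking alone with
a warning rather than aborting, so null-control experiments run.

The benchmark configuration trims the boosting-round bounds to
iteration_times ∈ [50, 400] and uses a 15-particle, 10-iteration swarm:
at 600 × 978 with ~30 selected genes these sizes keep a full run around
ten seconds while leaving the optimizer a meaningful landscape (the full
[100, 6000] bounds remain the default space and are used when tuning from
the CLI). The swarm default elsewhere follows the published
configuration: 25 particles, T = 50 for compound-series and T = 20 for
shRNA-series models.

## Numerical notes and limitations

- Exact determinism: every stochastic stage takes a `numpy` Generator
  seeded from the experiment seed; reruns are bit-identical.
- Degenerate inputs: constant targets raise (Pearson undefined); constant
  predictions map to fitness −1; zero active-area spread excludes all
  records with a warning; empty time subsets and fully unmatched inputs
  return empty datasets with warnings rather than raising.
- The end-to-end test Pearson at the benchmark scale varies by a few
  hundredths across generator seeds (120-row test split, per-seed planted
  weights); the planted-signal benchmark sits near 0.8 with the null
  control near 0.
- Real-data formats (GCTX archives, portal release files) are out of
  scope; readers cover CSV/TSV and a matrix-only GCT 1.2 export.
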