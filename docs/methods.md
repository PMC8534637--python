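# Methods

This note documents the models and procedures specfresh implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic data can and cannot establish.

## Outlier clipping (MD-IC)

The detector assumes that, within one freshness class, the Mahalanobis
statistics of genuine spectra are approximately unimodal so that a 3σ rule
(PauTa criterion) isolates instrument faults. The statistic is the
quadratic form D = (x−x̄)Σ⁻¹(x−x̄)ᵀ **without** a square root; the
classical rooted distance is available via `squared=False`. The clip uses
the population standard deviation (1/m inside the root) and excludes
samples *at* the threshold (|D−μ| ≥ 3σ). Since |D−μ|/σ can never exceed
√(m−1), the rule is structurally unable to fire for very small groups
(m ≤ 9) — a property of the criterion itself, not a defect of the
implementation; the relevant unit test documents it.

Design choices:

- **Per-class clipping** (default): a global fit would let a strong class
  difference masquerade as outlyingness.
- **PCA refit every iteration**: scores depend on the sample set, so after
  an exclusion the projection itself changes; refitting is the faithful
  reading of "recompute and repeat". Components retained: smallest k
  reaching 99.99% cumulative variance, capped at 20 and at m−2 (so the
  score covariance stays invertible).
- **σ = 0 (all distances equal)**: the pass is flagged degenerate and
  stops; nothing is excluded.
- **max_iterations = 20** bounds pathological oscillation; hitting the
  bound sets `converged=False` in the report instead of raising.
- A singular score covariance raises with instructions to lower k;
  a Moore–Penrose fallback exists but only behind an explicit flag,
  because silently switching estimators changes the statistic.

## Network

Input is a raw spectrum, 1 channel × n points (default n = 125). The
method fixes the block structure (stem; eight SE-recalibrated residual
modules; GAP; flatten; dense softmax head) but not the numeric shape, so
all widths/kernels/strides are configuration with these defaults:

| parameter | default | rationale |
|---|---|---|
| stem | kernel 7, 16 ch, stride 1, max-pool 2 | classic wide first receptive field |
| stage widths | 16,16,32,32,64,64,128,128 | ResNet-style doubling, stride 2 at each increase |
| stage kernel | 3 | standard residual-block kernel |
| SE reduction r | 8 | SENet convention scaled to narrow channels; hidden width floor 1 |
| activation | ELU (α = 1) | the ablation's best performer; sigmoid/ReLU selectable |
| optimizer | Adam, lr 1e-3, batch 16 | defaults appropriate for ~10² samples |

Further conventions: post-addition activation (original ResNet ordering);
conv→BN→activation inside the stacked path; the SE gate sits directly
after the second BN, before the addition; shortcut is identity when shapes
match, else a strided 1×1 conv + BN; the excitation hidden nonlinearity
follows the model's configured activation; BN keeps running statistics
(momentum 0.1, biased variance) for inference. Class order is
(non-fresh, fresh) with fresh positive; probability ties resolve to fresh.
Disabling the SE gate (`se_enabled=False`) yields the plain 1D-ResNet used
as the attention ablation; `build_shallow_cnn` (one conv block + two dense
layers) is the low-capacity reference.

Everything is NumPy float64 with hand-derived backpropagation, verified
end-to-end against central finite differences in the test suite. All
randomness (init, shuffling) flows from one `numpy` Generator, so training
is bit-reproducible given the seed; there is deliberately no
framework dependency.

A `compact` preset (stem 8 ch; widths 8,8,16,16,24,24,32,32; r = 4) is the
package's standard scale for experiments and tests: on the synthetic task
it reaches the same accuracy as the full preset at a fraction of the cost.

## Baselines and preprocessing

SVM (RBF), random forest and PLS-DA are delegated to scikit-learn behind
the package's interfaces. PLS-DA codes the label as a single {0,1} column
(equivalent to two-column coding for a binary task) and thresholds the
predicted response at 0.5, ties toward fresh. "Smoothing" is a centered
moving average whose window truncates at the spectrum edges — the simplest
method consistent with a single window-size hyperparameter; Savitzky–Golay
(order 2) is available as an option. Standardization maps zero-variance
columns to 0. Every preprocessing statistic is a function of training rows
only; fitted chains refuse to transform before `fit`, and a sentinel test
corrupts held-out data to prove the fitted parameters cannot see it.

Default grids (the method prescribes the tuned hyperparameters but not
their ranges): C ∈ {0.1, 1, 10, 100}, γ ∈ 10^{−4..0} (5 log-spaced);
trees ∈ {50, 100, 200, 500}; PLS components ∈ {1..15}.

## Nested cross-validation

Groups are purchase days. With G groups: G outer folds (each group tested
exactly once); within an outer fold the G−1 training groups rotate as the
validation group of G−1 inner folds. Selection maximizes mean inner
validation accuracy; ties break to the first configuration in grid order
(deterministic and documented). The chosen configuration is refit on the
full outer training set with a seed derived from the global seed and the
fold index. With a single-configuration grid the inner evaluation is
short-circuited: the selection is forced, and the result is by definition
identical to plain grouped CV of that configuration.

Headline metrics are arithmetic means of the per-fold metrics; pooled
metrics over all test predictions are reported alongside (the two differ
once folds are imbalanced). A metric whose denominator is zero is flagged
undefined and dropped from the average with a warning. A fold whose
training side holds a single class aborts the run with diagnostics.

## Synthetic data

Each spectrum is a sum of six Gaussian absorbance bands at fixed positions
in 908–1676 nm (mimicking overtone/combination band structure without
claiming chemical realism), plus a per-day additive offset (batch effect),
a meat-type offset, smooth correlated noise (Gaussian-filtered white
noise, 30 nm correlation length) and white noise scaled by 1/√5 to emulate
five-scan averaging. The freshness signal multiplies two of the six bands
by (1 + class_shift) in the non-fresh state, so the classes remain
visually similar. Each "piece" is scanned in both states with shared
amplitude jitter, reproducing the paired structure of re-measuring the
same physical sample. Defaults (8 days × 15 pieces × 2 states, 125
points) mirror the target study design. Fault injection adds a narrow
spike, a baseline step, or a gain error of recorded magnitude to chosen
samples and returns the ground truth.

What this does *not* model: Beer–Lambert chemistry, scattering, actual
spoilage kinetics (TVB-N), wavelength-dependent detector noise. Passing
tests therefore demonstrate correctness of the algorithms and harness
under a controlled, realistic-looking generative model — not field
performance on real meat.

The generator's random stream is independent of `class_shift`, so a
difficulty sweep changes only the signal amplitude, holding every other
draw fixed — useful for isolating separability effects.

## Study scales used by the automated checks

The acceptance checks and script run at the package's standard reduced
scale: the compact architecture preset; 40 epochs per fold with a size-1
grid for the end-to-end learnability run; 6 epochs per fold for the
null-calibration run (chance-level behavior needs no convergence); and the
three-way model comparison on 8 days × 6 pieces per class per day at
class_shift 0.08 with 15 epochs over 5 seeds. At that scale the SE gate's
benefit over the plain ResNet is within seed noise, so the three-way
ordering is reported rather than asserted. MD-IC checks use the full
240-sample design with 6 injected faults of magnitude 2.0 absorbance
units, averaged over 10 seeds.

## Known limitations

- The PauTa rule's small-sample blindness (above) means tiny classes are
  never clipped.
- BN uses biased batch variance in running statistics; other conventions
  exist and give slightly different inference outputs.
- PLS-DA's rank guard uses the numerical rank of the centered training
  matrix; near-rank-deficient data may still be ill-conditioned.
- The nested-CV driver assumes group = acquisition batch; it does not
  support overlapping or hierarchical grouping.
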