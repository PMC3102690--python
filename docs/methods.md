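# Methods

## Model

A probe's measured binding intensity is treated as multiplicative in the
contributions of the K-mers its double-stranded sequence contains, i.e.
additive on the log scale:

```
p_i = Σ_j H_ij α_j + intercept + ε_i,        H_ij ∈ {0, 1}
```

`H_ij = 1` iff feature *j* occurs anywhere in probe *i*'s full sequence —
flank included — on the forward strand (strand-specific mode) or on either
strand (strand-tied mode). Multiple occurrences still give 1; binary
entries keep the matrix compact and count-valued entries were not found to
help. Intensities are log-transformed (base 2 by default) and
mean-subtracted before fitting; the subtracted mean is stored in the model
and added back to predictions. Mean subtraction prevents K-mers inside the
probe-invariant flank from absorbing the constant background intensity.
Affinities are not constrained to be non-negative: a K-mer may genuinely
inhibit binding, and an unconstrained solve is also much cheaper.

`α` has no physical-units interpretation (it is not a dissociation
constant); it is a relative, additive log-intensity contribution.

### Feature set and regularization

Including all 4–8-mers would give ~90,000 unknowns — underdetermined on a
40K-probe array. The default regularized set is

* all 4-, 5- and 6-mers (5,376 features), plus
* the 2,000 7-mers and 1,000 8-mers with the highest median log intensity
  over the probes containing them (ties broken by higher support, then
  pattern order; selection is deterministic),

for 8,376 K-mers plus an intercept. The high-median criterion assumes the
most informative K-mers are those carried by bright probes. Gapped 8-mers
(8 informative bases with one ignored base, default after the 4th) can be
added through the same median ranking. The counts are parameters: the
right budget scales with the array — the system should stay
overdetermined, so a 5,000-probe design gets ~2,000 features (all 4–5-mers
plus top 6-mers), not 8,376.

### Solver

The normal equations `HᵀHα = Hᵀp` are solved with conjugate gradients from
a zero start. The default of **10 iterations** is deliberate: truncated CG
is an implicit regularizer for the highly collinear K-mer columns (a
K-mer column is nearly the sum of its four left-extension columns). An
optional residual-tolerance stopping rule (`cg_tol`) runs CG to
convergence for oracle-style analyses; at convergence CG reproduces the
minimum-norm least-squares solution (verified against dense `lstsq` in the
tests). No preconditioning is used.

Feature columns that are constant across the training probes — every
K-mer inside the shared flank appears in *every* probe — are excluded from
the solve and reported with affinity zero. Such columns are exactly
collinear with the intercept; leaving them in lets the minimum-norm
solution smear the intercept over them, which on a *different* probe
design (where those K-mers occur only sporadically) injects diffuse
prediction noise. With the guard, cross-platform recovery on noiseless
synthetic data is essentially exact.

α is not unique under collinearity, but fitted values are; tests assert
that permuting the feature order leaves converged predictions unchanged to
1e-8.

### Variants

* **Stepwise residual**: fit the 4-mer block, then the 5-mer block on the
  residual, and so on. Gives unique per-block solutions; its training
  residual is never smaller than the joint fit's (asserted), matching the
  joint model's empirical advantage.
* **Strand-tied**: reverse-complement column pairs are merged by logical
  OR onto the lexicographically smaller pattern (palindromes map to
  themselves; 256 4-mers collapse to 136 = 120 pairs + 16 palindromes).
  Tied-model predictions are invariant under reverse-complementing the
  inputs.
* **Weighted least squares**: with an affine noise model the rows of
  (H, p) are scaled by 1/σ(p_i + mean) before the OLS path, so constant σ
  reduces *exactly* to OLS (an exactly constant σ skips the scaling
  entirely, making the equivalence structural rather than numerical).

### Probe noise model

With technical replicates, per-probe means μ̂ and standard deviations s of
the log intensities give an affine noise curve σ(μ) = σ₀ + β·μ. Two
corrections keep the fit consistent at realistic replicate counts:

* E[s] = c4(n)·σ for normal noise (c4(3) ≈ 0.886), so s is divided by c4;
  a naive fit would underestimate β by ~11% with 3 replicates.
* μ̂ is the mean of n noisy replicates; regressing on it attenuates the
  slope by Var(μ)/(Var(μ) + σ²/n). The slope is disattenuated using
  mean(s²)/n as the error-variance estimate, followed by one GLS pass with
  weights 1/σ̂² (bright probes have noisier s).

σ values are floored at 1e-6 when inverted. Recovering σ₀ (the intercept
at μ = 0, far below any observed intensity) is only well-posed when the
sample spans a wide intensity range; the synthetic noise-study profile
(below) spans ~8 log2 units for this reason.

## Preprocessing

All steps operate on log-scale intensities; zero raw intensities are set
missing before the transform, negative ones are an error.

* **Low-intensity filter**: a 100-bin histogram of the log intensities is
  scanned from its mode toward lower bins; the cutoff is the upper edge of
  the first bin whose count falls below 5% of the mode count (both
  parameters configurable — the descent constant is a package choice).
  Probes below the cutoff become missing but keep their grid position.
  The modal population itself can never be removed.
* **Spatial detrending**: each spot is rescaled by global median / local
  median in a 7×7 window, truncated at borders, ignoring missing cells;
  an all-missing window leaves the spot unchanged. The default applies
  the ratio to the log values (the literal reading for log-scale data);
  `mode="additive"` (= multiplicative on raw intensities) is available
  since the convention is ambiguous. Detrending is an *estimator*: on an
  artifact-free random array the local median has sampling variance and
  perturbs intensities by ~1%, so detrend only arrays that show spatial
  artifacts. Planted multiplicative blotches are corrected to within 5%
  relative error on ≥95% of spots (test-asserted).
* **Quantile normalization**: within each sample the i-th ranked
  non-missing value is replaced by the i-th quantile of the reference —
  by default the mean of the samples' sorted vectors interpolated onto a
  common quantile grid, so different missing-value masks combine cleanly.
  Ties get the mean of the reference quantiles they span, making rank
  preservation exact (Spearman 1 with the normalized self). Because
  saturated probes retain a faint ordering under the clamp ceiling,
  normalization against an unsaturated reference redistributes them into
  the reference's high tail, partially undoing saturation (asserted on
  synthetic clamped samples). Training and reference sample groups should
  be normalized separately. Equal-count samples share identical sorted
  vectors after normalization *when values are tie-free*; with ties, the
  tie-averaging convention can make the sorted vectors differ slightly —
  a deliberate trade for deterministic rank preservation.

## Synthetic study conditions

The generator mirrors the fitted model family: probe = 25-base shared
flank + 36 i.i.d. uniform random bases, laid row-major on a near-square
grid; clean log2 intensity = background mean (default 8.0, ~a 16-bit
scanner's mid-range) + planted affinities of contained K-mers. Artifacts:
Gaussian or affine intensity-dependent noise, a multiplicative circular
blotch on the log grid, and clamping above a saturation quantile with an
infinitesimal rank-preserving jitter. Everything is deterministic under
the seed.

Default planted profile: 20 distinct K-mers of lengths 4–6, affinities
drawn per length (4-mers 0.1–0.4, 5-mers 0.2–0.6, 6-mers 0.5–1.0 log2
units) — binding energy is roughly additive per matched position, so
longer matches contribute more. Two deliberate identifiability
constraints:

* Planted patterns never occur inside either flank: a flank motif appears
  in every probe and is confounded with the background — unrecoverable by
  any method.
* Default lengths stop at 6 because a few-thousand-probe *random* design
  covers 6-mer space (~70 occurrences each at 5,000 probes) but not 8-mer
  space (~4 occurrences each); real arrays use de Bruijn designs and
  40K probes precisely to cover longer K-mers. Experiments that need
  8-mer-driven signal (the K-length and regularization sweeps) use
  15,000-probe training designs with 16 planted 8-mers (affinities
  1.5–3.0) and noise sd 0.2.

What the simulator does **not** model: scanner optics, probe secondary
structure, position-within-probe effects, de Bruijn coverage designs, and
strand-specific artifacts. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
performance on real arrays.

Problem sizes used by the test suite and `scripts/acceptance.py`:
5,000 + 5,000-probe benchmarks for recovery and preprocessing checks,
10,000 probes × 3 replicates for the noise model, 15,000 + 4,000 for the
sweeps — sizes at which each measured quantity is statistically stable.

## Numerical and design choices

* Median over an even support count = mean of the two middle values.
* CG start vector 0; `dᵀAd ≤ 0` terminates the iteration (exact
  convergence or a null direction).
* Missing intensities are dropped from fits, never imputed; prediction
  accepts any sequences of the training length (a differing length only
  warns).
* Quantile grids use linear interpolation; single-sample normalization is
  the identity.
* Grid coordinates are 1-based in files; model files carry a format
  version tag; floats are serialized with 17 significant digits and read
  back with round-trip parsing.
* Exit codes: 0 success, 2 input/validation error, 3 numerical failure.

## Known limitations

* Affinities of K-mers longer than the design's coverage limit are not
  identifiable; the package does not warn about low-support features
  beyond excluding constant columns.
* The low-intensity cutoff constant (5% of mode) and histogram binning are
  conventions, not fitted quantities.
* Quantile normalization assumes samples share a distribution shape; a
  shape-preserving variant trained on unsaturated samples only is out of
  scope.
* No PWM conversion or visualization of the K-mer model, and no motif
  database comparison.
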