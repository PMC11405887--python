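# Methods

## The statistical model

blotkit's central analysis is a linear mixed model for replicated
densitometry. One observation is the target-protein band density of subject
*i* on technical replicate gel *j*:

y_ij = β0 + β_g(i) + γ·x_ij + u_i + v_j + ε_ij,

with group fixed effects β (treatment contrasts against the alphabetically
first group), the same-lane loading-control density x as a covariate with
slope γ, and three variance components: subject intercepts u_i (biological
variation), replicate-gel intercepts v_j (the shared shift of one gel run),
and lane noise ε_ij. All densities are in arbitrary fluorescence units, so
every coefficient is too; the standardized effect size divides the group
coefficient by the outcome SD to make results comparable across experiments.

**Crossed, not nested, replication.** Workflows that describe replication as
"nested within subject" cannot be fit literally here: with one observation
per subject × replicate cell, a per-cell intercept is indistinguishable from
the residual. The variance that replication actually contributes is the
gel-run batch effect, shared by every subject on the same replicate run, so
v_j is modelled as a crossed factor with (typically) as many levels as
technical replicates. The strictly nested parameterization is available via
`fit_lmm(..., nested=True)` and warns about its identifiability.

**Estimation.** The REML criterion is profiled: β and the residual variance
are solved in closed form at each value of the two variance *ratios*
(σ²_subject/σ²_residual, σ²_replicate/σ²_residual), and the remaining
2-parameter criterion is minimized by L-BFGS-B on the log ratios from three
fixed starts, bounds log-ratio ∈ [−14, 10]. Problems here are small (tens to
a few hundred rows), so the dense Cholesky per evaluation is cheap and the
multi-start guards against boundary basins. A ratio driven to the lower
bound is reported as a variance of exactly 0 with `boundary=True` — a
legitimate outcome, not an error. Agreement with an independent
implementation (statsmodels MixedLM with variance-component formulas) and
with a dense GLS solve at the estimated variances is enforced in the test
suite at 1e-4 and 1e-6 respectively.

**Inference.** The group p-value is a likelihood-ratio χ² between ML refits
with and without the group factor (REML log-likelihoods are not comparable
across fixed-effect structures). A Wald χ² on the group contrasts is
reported alongside. The LR test with ~10 subjects per group is known to be
mildly anticonservative (empirical size ≈ 6% at a nominal 5% in the
package's own calibration); Satterthwaite or Kenward–Roger corrections are
deliberately out of scope. OLS strategies use the sequential F-test of the
group factor after the covariate.

**Strategy grid.** The benchmark crosses four replicate treatments
(first-only, independent, mean, random-effect) with two loading-control
treatments (ratio, covariate). For mean+ratio the ratio is computed per lane
and then averaged (mean of ratios), matching how per-row ratio columns are
usually tabulated; `ratio_of_means=True` flips the order. "First-only" keeps
the lowest replicate index. Ratio outcomes are multiplicative and distort
variance; they are provided for comparison, not recommended, and
gamma-family semiparametric models for ratios are out of scope.

## Gel-design algorithm

`plan_gels` uses the minimum number of gels that fits all samples
(⌈n/usable lanes⌉), splits each group across gels with quotas differing by
at most one, and orients the remainders so per-gel lane totals are as even
as possible (verified against a brute-force enumeration of orientations in
the tests). `order_lanes` arranges one gel's group labels by greedy
most-remaining-first with seeded tie-breaks plus a swap-repair pass; on all
multisets of up to 8 samples it achieves the exhaustive-enumeration minimum
of adjacent same-group pairs, and zero whenever the largest group is at most
half the gel (rounded up). Loaded lanes are centered among the usable lanes
with the odd spare lane on the high-numbered end (an arbitrary but fixed
choice); the ladder occupies lane 1. Each technical replicate re-randomizes
both the subject-to-gel partition and the lane order by default, so lane
position and gel membership decorrelate across runs; a
`same_layout_across_replicates` flag freezes the first layout instead.
Adjacency is counted over consecutive loaded lanes, skipping but not
resetting at empty lanes, because the within-gel gradients being guarded
against are spatially smooth.

## Observed power

`monte_carlo_power` is a parametric bootstrap: simulate y from the fitted
fixed effects plus fresh random-effect and residual draws (unconditional
simulation — not conditioned on the estimated per-subject/per-gel BLUPs),
refit the identical strategy, and count p < α over n_sim = 1000 draws by
default. Refits that error or fail to converge are excluded from the
denominator and counted (excluding rather than calling them non-significant
avoids biasing power downward by optimizer artifacts); above 20% failures
the result carries a reliability warning. Inside repeated-simulation studies
(`simulation_study`) power is instead measured directly as the rejection
rate across simulated experiments, avoiding a nested Monte Carlo loop.

## The synthetic-data generator

`simulate_dataset` draws data from exactly the generative model above:
group effects on a baseline β0, subject and gel-run intercepts, lane noise,
and a loading-control covariate from a positive-truncated normal entering
*centered* (γ·(x−μ_x)) so β0 remains the reference-group mean regardless of
γ. Defaults describe a typical rodent-tissue experiment: 2 groups × 10
subjects × 3 technical replicates, β0 = 10, unit subject/gel/residual SDs
(no magnitudes are published for real variance components; 1.0 each is a
convention that makes the three sources comparably important), loading mean
10 with SD 1 (10% CV, pipetting-scale error) and slope 1. An optional
hyperbolic saturation d = d_max·a/(k+a) emulates out-of-linear-range signal
compression, and `simulate_dilution_series` produces serial 1:2 ladders
through the same response for the linear-range detector.

What the generator does *not* emulate: within-gel spatial gradients by lane
position, heteroscedastic or multiplicative noise, non-normal outliers,
image-level artifacts (blot background, band overlap), and missing lanes.
Calibration results obtained on simulated data therefore show that the
estimators and tests behave correctly *when the model's assumptions hold*;
they do not certify performance on real blots where those assumptions are
strained — that is precisely why counterbalanced design and linear-range
checks matter.

## Linear-range criterion

No formula for "linear enough" is standard; the detector's definition is a
dual criterion over every contiguous window of ≥ min_points (default 4)
dilutions: window r² ≥ 0.99 and every point within 10% relative deviation of
the window's least-squares line. The per-point bound exists because r² is
nearly blind to a single saturated point at a window edge. The longest
qualifying window wins, ties broken by higher r²; all three thresholds are
arguments. The fit is density against concentration on the natural scale.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` seeds; every
  artifact records the seed used, and the CLI draws and logs one when the
  user gives none.
- QC never throws: `validate_unique_groups` reports subjects found in two or
  more groups (failure) and repeated rows within one group (warning only,
  since two biological samples can share an ID by accident of labelling).
- Missing density cells in a template are dropped with a count, so partially
  filled templates can be analysed mid-experiment; a zero or negative
  loading-control density is an error since it serves as divisor and
  covariate.
- Group labels are whitespace-trimmed but case-sensitive; silent
  case-folding would mask the data-entry errors QC exists to surface.
- Calibration scale in the test suite: 1000 simulated null experiments for
  the size checks, 500 for parameter recovery and power calibration — sizes
  chosen to put Monte Carlo error well below the tolerances being asserted.

## Known limitations

- Degrees-of-freedom corrections (Satterthwaite/Kenward–Roger) are absent;
  at very small n the LR test runs slightly liberal.
- The lane-position balance of a given group across gels is randomized, not
  optimized: a group avoids systematic positions only in expectation.
- One target protein at a time; multiplexed joint models are not attempted.
- `estimate_linear_range` assumes a single contiguous linear window.
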