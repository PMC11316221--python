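# Methods

## Model and assumptions

Observed depth-normalized log-counts of variant *i* at timepoint *t* of assay
*α* are modeled as

    logC_it^α = f_i^α t + c_i^α + u_i (λ^α t + γ_t^α) + noise,

i.e. an exponential-growth (log-linear) trajectory plus a single rank-one bias
mode. Assumptions inherited from this model:

- **Exponential change.** Relative abundances change exponentially over an
  assay (variants are a small fraction of the culture relative to a reference,
  or growth is otherwise balanced). No saturating or lagged growth models.
- **Rank-one bias.** All systematic barcode-processing effects share one
  coherent pattern: a per-variant susceptibility times a per-sample
  prevalence. Additional systematic modes are not modeled.
- **Shared library.** The same barcoded library appears in every assay, so
  susceptibilities are common across assays; assays may be replicates or
  different conditions.
- **Control set.** At least one subset of variants shares (near-)equal true
  fitness. Only this subset informs the trend stage.

Natural logarithms are used throughout, so fitness is per assay-time unit in
whatever units the metadata supplies.

## Depth normalization

`logC[i,s] = log((C[i,s] + pseudocount) / depth_s × D̄)` with D̄ the geometric
mean depth. Depths default to column sums; a metadata `depth` column overrides
them (spike-in-style normalization). The geometric mean keeps the overall
scale of the data while making columns comparable; the default pseudocount of
0.5 keeps zero counts finite. Variant-assay blocks with all-zero counts are
excluded from fits (NaN) and logged, not dropped globally.

## Stage 1: residual factorization

Let P⊥_α be the residual projector of assay α (orthogonal complement of
span{1, t}); it is materialized once per assay and shared with the line
fitting, since OLS residuals are exactly P⊥ applied to the trajectory.
Because P⊥ annihilates anything linear in time, only the deviation part γ of
the prevalence is identifiable from residuals; the trend belongs to stage 2.

Both updates are exact conditional minimizers of the joint penalized objective

    J(u, γ) = Σ_{i,α} ‖P⊥_α(logC_i^α − u_i γ^α)‖² + ρ(‖u‖² + Σ_α‖γ^α‖²):

- susceptibilities: `û_i = Σ_α ⟨P⊥ logC_i^α, P⊥ v^α⟩ / (Σ_α ‖P⊥ v^α‖² + ρ)`
- deviations (per assay, constrained to the range of P⊥):
  `γ̂^α = P⊥ [Σ_i û_i logC_i^α] / (Σ_i û_i² + ρ)`

û starts at small Gaussian values (scale `init_scale`, default 0.01, from the
config seed) and γ̂ at zero, so each sweep updates γ̂ first (with γ̂ = 0 a
leading û-update would collapse to zero). J never increases: each half-step is
an exact minimizer, and the once-per-sweep rescale uses the penalty-optimal
balance s² = ‖û‖/‖γ̂‖ (which cannot increase J) rather than forcing a fixed
normalization mid-run. Iteration stops when the relative drop of J over a
sweep falls below `tol` (default 1e-8) or after `max_iter` (default 500)
sweeps. This alternating scheme is power iteration on the block-projected data
matrix, so on well-conditioned data the fixed point — and therefore the
invariant object, the effect matrix û⊗v̂ — is independent of the random
initialization.

Identifiability conventions, applied once at convergence:

- γ̂ lies in the range of P⊥ by construction (translation symmetry: offsets
  and trends belong to the intercept and λ);
- û is scaled to unit root-mean-square, with the compensating scale on γ̂
  (scale symmetry);
- the sign pair is flipped so the largest-|û| entry is positive.

The ridge ρ defaults to 1e-3 × n_samples: enough to keep degenerate updates
finite without measurably shrinking well-identified components. Exactness
properties (noiseless recovery to 1e-6) hold at ρ = 0, where the tiny rank-one
shrinkage the ridge introduces vanishes.

## Stage 2: trend anchoring

For control variants G, fitness errors are approximated by centering raw
fitness estimates on the per-assay group mean. Under the model these satisfy
δf_i = (u_i − ū_G)λ — group-centered on both sides — so the trend is
estimated by regressing δf on *group-centered* û:

    λ̂^α = Σ_G (û_i − ū̂_G) δf_i^α / Σ_G (û_i − ū̂_G)².

Because Σ_G δf = 0, the numerator equals the through-origin numerator; only
the denominator differs. Centering makes the estimator exact on noiseless data
(a pure through-origin fit against raw û is shrunk by the factor
1 − ū̂²_G/mean(û²_G), which vanishes only for balanced control sets). A
through-origin option (`fit_intercept_trend=False`) is retained. The
regression standard error of λ̂ is reported; no further uncertainty
quantification is attempted.

Corrected fitnesses are reported from refitting logA = logC − û⊗v̂; since γ̂ ⊥
{1, t}, these must equal f̄ − û λ̂ exactly, and the implementation asserts the
two routes agree as an internal consistency check.

## Validation oracles

- **SVD route.** For an equal-fitness group the error matrix δf is rank one
  (u λᵀ), so its first left/right singular vectors estimate u and λ with no
  iterative inference. Columns are group-mean-centered first; scaling and sign
  follow the same conventions as stage 1. Only correlation magnitude is
  meaningful (the sign convention of each route is arbitrary).
- **Replicate agreement.** Per-variant fitness discrepancy between replicate
  assays; under the model pre-correction discrepancies are u(λ₂ − λ₁) plus
  noise, so they correlate with û before correction and shrink after.
- **Equal variance.** Brown–Forsythe (median-centered Levene) test via
  scipy, used to judge whether correction tightened an equal-fitness group's
  fitness spread; degenerate all-constant input returns W = 0, p = 1 by
  convention.

## Synthetic data

The generator draws, per dataset: true fitnesses f ~ N(0, σ_f = 0.1) per
variant (shared across assays), susceptibilities u ~ N(0, σ_u = 1), trends
λ ~ N(0, σ_λ = 0.05) per assay, deviations γ ~ N(0, σ_γ = 0.05) per sample
projected orthogonal to {1, t}, and initial log-abundances ~ N(0, σ_m0 = 0.5)
(a realistic library-evenness spread). The control set is the first m = 40
variants with fitness drawn around the neutral mean with sd σ_c (default 0;
σ_c = σ_f is a degenerate control set). Defaults: 500 variants, 5 assays,
timepoints 0–3, depth 10⁶ reads/sample (configurable upward; 10⁶ keeps a
replicate under ~20 ms so grids of hundreds of replicates run at a desk).

Counts are Poisson draws around depth-D per-sample frequencies. The
compositional normalizer Z_s = Σ_i exp(log m_i + bias) is recorded as the
per-sample *effective depth* D·gmean(Z)/Z_s — the quantity spike-in
normalization measures in a real assay — so that depth-normalized expected
log-counts are exactly log-linear plus the rank-one bias, matching the
reference-dominated regime the model assumes. Without this (i.e. normalizing
by library column sums when no dominant reference exists), the drift of
log Z_s adds a common-mode fitness error — including a bias-dependent v²/2
term — that is constant across variants, hence *not* rank one and not
removable by this method or any rank-one correction; on real data without
spike-ins or a dominant reference this residual common-mode error remains and
is a known limitation.

The Poisson-only noise floor MAE_noise is measured on a *paired bias-off
twin*: the identical truth draw with u ≡ 0 and a fresh noise stream (a third
child of the dataset's seed sequence, so twin and dataset never share
randomness). ε = (MAE_post − MAE_noise)/(MAE_pre − MAE_noise) is undefined
when MAE_pre ≤ MAE_noise and is then reported as a "no bias-induced error"
flag rather than a number.

What passing these simulations does *not* show about real data: no serial
transfer bottlenecks or growth-cycle stochasticity, no batch effects beyond
the rank-one mode, no PCR jackpots (UMI-style stochastic amplification noise),
no deviations from exponential growth, and exactly one bias mode. Seeds:
every public entry point takes one seed; grid/replicate seeds are derived via
`numpy.random.SeedSequence([master, cell_i, cell_j, rep])`.

## Numerical choices and degenerate inputs

- Assays need ≥3 timepoints (line fit plus one residual degree of freedom);
  timepoints must be strictly increasing.
- All-zero û: prevalence deviations are unidentifiable; γ̂ = 0 with a warning
  (the regularized limit). Prevalence entirely inside span{1, t} with ρ = 0:
  the susceptibility update is degenerate and raises with instructions to set
  ρ > 0.
- Control sets need ≥2 members; control variant-assay fits that are missing
  are excluded from the group mean with a warning; if Σ(û − ū̂)² falls below
  1e-12, λ̂ = 0 with a warning (trend unidentifiable).
- Convergence uses relative objective change; an absolute floor (1e-30) stops
  exactly-solved noiseless problems where the relative test is 0/0.
- Unweighted OLS throughout: the closed-form updates assume the unweighted
  residual projector. (Inverse-variance weighting of timepoints would change
  the projector and is not implemented.)

## Problem sizes used in tests

The acceptance-style checks use 20 replicates of the 500 × 5 × 4 protocol at
depth 10⁶ for the headline error-removal figure, and a 3×3 grid
(m ∈ {10, 40, 160}, σ_c ∈ {0, 0.05, 0.1}) with 20 replicates per cell for the
control-set sensitivity trends; both are the package's own desk-scale
renderings of a 50-replicate protocol and complete in seconds.

## Known limitations

- Single bias mode (rank one); residual systematic structure beyond it is
  untouched.
- No stochastic amplification (UMI) handling.
- Common-mode (variant-independent) systematic errors are invisible to the
  decomposition (see the compositional-closure note above).
- The trend stage inherits any real fitness variance in the control set as
  noise on λ̂; quality and size of the control set trade off as the
  sensitivity grid shows.
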