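# Methods

`trajgsa` computes variance-based (Sobol') sensitivity indices for models
whose output is an entire trajectory — or an ensemble of trajectories across
agents and communities — rather than a scalar snapshot. Snapshot-based
indices oscillate when the output itself oscillates, so the package instead
summarizes each whole trajectory in a handful of diffusion coordinates and
attributes *their* variance to the input parameters.

## The pipeline

Given an experimental design `X ∈ R^{N×k}` with independent marginals and
one model-output record per row, reshaped to a matrix `Y_i ∈ R^{n×m}`:

1. **Grassmann projection.** Each `Y_i` is reduced to the pair of subspaces
   spanned by its `p` leading left/right singular vectors (thin SVD
   `Y_i = U_i Σ_i V_i^T`), i.e. points on `G(p, n)` and `G(p, m)`. Only the
   spans matter downstream; singular values are kept for reconstruction
   diagnostics. `p` is either user-fixed or chosen from the ensemble's
   numerical-rank profile (modal rank by default; an optional
   cumulative-frequency threshold scans ranks in descending occurrence
   order and takes the smallest rank included).
2. **Grassmannian kernel.** Pairwise similarity is the projection kernel
   `k_pr(A, B) = ||A^T B||_F^2 = Σ cos² φ_l` over principal angles — bounded
   by `p`, attained iff the spans coincide, and invariant to the basis
   chosen for either span. Left and right kernel matrices are composed
   entrywise (Hadamard product by default, sum optionally).
3. **Diffusion maps.** The composed kernel is degree-normalized
   (`κ = K / sqrt(DD^T)`) and row-normalized into a Markov matrix `P`; its
   spectrum is computed through the symmetric similarity transform, so the
   returned eigenpairs satisfy `||Pξ − λξ||_∞ ≤ 1e-8` by contract.
   Single-step diffusion coordinates are `θ_j = λ_j ξ_j`, the trivial
   `λ_0 = 1` pair excluded.
4. **Coordinate retention.** Either the top-`g` eigenpairs, or the
   *parsimonious* rule: scanning candidates in eigenvalue order, each
   eigenvector is regressed on all previous ones with a Gaussian-weighted
   leave-one-out local linear fit; low residuals flag "repeated
   eigendirections" (higher harmonics of earlier coordinates) and the `g`
   largest-residual eigenvectors are kept. The first candidate always
   scores 1.
5. **Surrogate.** A polynomial chaos expansion maps inputs to the retained
   coordinates, using polynomials orthonormal to the declared marginals
   (shifted/scaled Legendre for uniform, normalized probabilists' Hermite
   for Gaussian) on a total-degree basis of size `(k+s_max)!/(k! s_max!)`.
   Fitting is OLS on the full basis (all `g` columns at once) or hybrid
   least-angle regression per column: LAR yields a nested active-set
   sequence, each prefix is re-fit by OLS and scored by the closed-form
   leave-one-out error, and the minimizer wins, with an early stop at
   `ε_target` and a stop after three consecutive steps above the best error.
6. **Indices.** Squared coefficients of an orthonormal basis are partial
   variances, so `S_i` (multi-indices active in parameter i alone) and
   `S_Ti` (any multi-index touching i) follow exactly from the fitted
   coefficients, per retained coordinate. By construction
   `0 ≤ S_i ≤ S_Ti ≤ 1` and `Σ_i S_i ≤ 1`.

A conventional Saltelli Monte-Carlo estimator (base block, resample block,
and `d` pick-freeze blocks; `N(d+2)` evaluations) with percentile-bootstrap
confidence intervals is included as the baseline; its product-form
estimators follow the classical mean-of-products-minus-squared-mean
construction, with Jansen difference estimators behind a flag. Negative
small-sample estimates are reported unclipped (clipping would bias the
bootstrap intervals).

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `p` | Grassmann subspace dimension | `"auto"` (modal rank) | rank profile mirrors how practitioners pick it; a user value always wins |
| rank tolerance | relative σ cutoff for numerical rank | `1e-10` | conventional; configurable |
| `g` | retained diffusion coordinates | 3 | spectra of smooth ensembles decay fast; three coordinates cover the studies shipped here |
| `s_max` | max total polynomial degree | 6 | the bundled oscillator study's setting; purely config |
| `ε_target` | LAR early-stop LOO error | `1e-8` | effectively "run to the LOO minimum"; values near 1 risk overfitting |
| test fraction | held-out share for `ε_val`, MAE | 1/3 | deterministic tail split by default; seeded random split optional |
| bandwidth scale | local-linear-regression kernel width (× median pairwise distance) | 3 | smooth enough to flag harmonics without oversmoothing |

The leave-one-out error is the plain hat-matrix form
`E[(Δ_i/(1−h_i))²]/V[Y]` with no small-sample correction factor. Uniform
marginals on arbitrary `[a, b]` are mapped affinely to `[−1, 1]` so the
Legendre family is orthonormal under the *declared* bounds.

## Bundled generators and what a green test establishes

* **Lotka–Volterra** (`du/dt = αu − βuv`, `dv/dt = δuv − γv`): α ~ U(0.90,
  1.05), β ~ U(0.10, 0.18), γ = 1.5, δ = 0.75, u(0) = 10, v(0) = 5, T = 25
  on 512 points; both solutions concatenated and wrapped 32×32. Solved
  adaptively (rtol 1e-9); the first integral `δu − γ ln u + βv − α ln v`
  bounds solver drift in tests.
* **Toy epidemic**: per-contact transmission `P = 1 − exp(−λ)` with
  `λ = R S_a A_s B_n / Ī · ∫_{t−1}^t f_Γ(u; μΓ_F, σ²Γ_F) du` — the
  published base tables (nine age-susceptibility scalars, eleven
  stage-infectiousness scalars, network scalars 2/1/0.25, gamma profile
  μ = 5.5, σ² = 2.14) each multiplied by an uncertain general scale factor
  (R ~ U(1.9, 6.5), S_F, A_F ~ U(0.5, 1.5), B_F, Γ_F ~ U(0.7, 1.3)). The
  desk-scale simulator runs ≤10⁴ agents on three seeded random-regular
  networks (default degrees 3/8/2, so Ī = 13) with a reduced six-stage
  course (susceptible → presymptomatic → symptomatic → [hospitalized →]
  recovered/dead) and Poisson-plus-one stage durations; severity, outcome
  and durations are drawn at infection time; index cases are seeded mild so
  a zero-hazard run has no deaths. It preserves the hazard structure and
  the five tracked daily counts (susceptible, hospitalized, dead,
  recovered, active), *not* census initialization, interventions, or the
  full eleven-stage course — green tests establish hazard correctness,
  bookkeeping identities and stochastic ordering in R, nothing about
  real-world epidemic realism.
* **Multi-level wealth generator**: a *synthetic* stand-in producing
  micro/meso/macro trajectory structure with planted, analytically known
  sensitivities. The six named inputs act through one linear score
  `L = Σ_j sqrt(v_j) ψ_1(z_j)` that modulates the wealth decay rate and the
  frequency of an oscillatory component; both modulations rotate the
  subspaces of the wrapped matrices (a purely additive planted effect would
  leave all spans — and hence the Grassmannian kernel — unchanged, which is
  itself a useful negative result about what trajectory-subspace methods
  can see). Because every trajectory is a deterministic function of `L`,
  the first-order shares of the leading diffusion coordinate equal
  `v / Σv` up to the mild nonlinearity of the embedding's monotone warp of
  `L`; the end-to-end test checks recovery within 0.1. It does not simulate
  any economic mechanism.

## Numerical choices

* SVD/eigenvector sign fixed by making the largest-magnitude entry of each
  column positive (spans unaffected; stored bases reproducible).
* Eigenvalue ties keep original index order (stable sort).
* Matrices of numerical rank below the ensemble's fixed `p` are projected
  with `p` columns anyway, with a warning — one `p` per ensemble.
* Degenerate inputs fail loudly: zero kernel degrees, constant responses,
  zero test variance and `N < P` raise specific exceptions rather than
  returning NaNs; leverage values at 1 are excluded from the LOO sum with
  a warning.
* The transition matrix row-normalizes the *normalized* kernel κ (the
  standard construction); a literal-form alternative is behind
  `numerator="raw"`. The degree distribution `π = D/ΣD` is reported as
  metadata; it is stationary for the unnormalized walk `D⁻¹K`, not
  asserted for `P`.
* Trajectory records flatten row-major, responses in declared order with
  time fastest; results depend on this only through the induced subspaces,
  but one convention is fixed for reproducibility.
* Every stochastic stage consumes a seed derived by hashing the config
  seed with the stage name, making a run a pure function of its config.

## Known limitations

* The embedding is transductive: no out-of-sample extension, and the
  surrogate's test split reuses coordinates computed on the full ensemble.
* Subspace representations are blind to output variation that does not
  rotate subspaces (pure amplitude scaling, additive shifts within a fixed
  span). Relatedly, on the bundled oscillator study the leading diffusion
  coordinate is dominated by the frequency-controlling parameter α —
  perturbing α across its range moves the trajectory and its subspaces
  several times further than perturbing β — so the two parameters' indices
  on that coordinate are *not* similar here; see the worked example.
* Saltelli estimates at small `N` can be negative; they are reported
  unclipped.
* Parsimonious selection is O(N²) per candidate eigenvector and is the
  slowest stage for ensembles beyond a few thousand members.
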