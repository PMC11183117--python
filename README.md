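# trajgsa

Trajectory-based global sensitivity analysis for dynamical models and
agent-based simulations.

## The problem

Variance-based (Sobol') sensitivity analysis asks how much of a model
output's variance each uncertain input is responsible for — alone
(first-order index `S_i`) and together with its interactions (total-order
index `S_Ti`). For models whose output is a whole trajectory, the standard
practice of computing indices at one time snapshot is fragile: when the
output oscillates or shifts regime, the indices oscillate with it, and two
analysts looking at different snapshots can rank the same parameters
differently.

`trajgsa` instead treats the *entire trajectory* as the quantity of
interest. Each output record, reshaped to an `n×m` matrix `Y_i`, is reduced
to the subspaces spanned by its leading singular vectors — points on the
Grassmann manifolds `G(p, n)` and `G(p, m)` — and the ensemble of subspaces
is embedded with diffusion maps on the composed projection kernel
`k_pr(U_i, U_j) = ‖U_iᵀU_j‖_F²`. A sparse polynomial chaos expansion (PCE)
is then fit from the input parameters to the retained diffusion coordinates
`θ_j = λ_j ξ_j`, and Sobol' indices follow analytically from the squared
PCE coefficients:

```
S_i  = Σ_{s∈Λ_i}  c_s² / Σ_{s∈Λ∖0} c_s² ,   Λ_i  = {s : s_i ≠ 0, s_l = 0 ∀ l ≠ i}
S_Ti = Σ_{s∈Λ_Ti} c_s² / Σ_{s∈Λ∖0} c_s² ,   Λ_Ti = {s : s_i ≠ 0}
```

Sparsity comes from hybrid least-angle regression: LAR proposes a nested
sequence of active basis sets, each is re-fit by ordinary least squares, and
the closed-form leave-one-out error picks the winner. A conventional
Saltelli Monte-Carlo estimator (`N(d+2)` model runs, bootstrap confidence
intervals) is included as the baseline, along with three desk-scale data
generators: a Lotka–Volterra predator–prey ODE, a toy network epidemic with
a gamma-profile transmission hazard, and a synthetic multi-level (agent /
community / population) wealth-trajectory generator with planted,
analytically known sensitivities.

See `docs/methods.md` for the full method description, defaults, and
limitations.

## Worked example

The bundled predator–prey study: prey growth rate `α ~ U(0.90, 1.05)` and
predation rate `β ~ U(0.10, 0.18)` drive `du/dt = αu − βuv`,
`dv/dt = δuv − γv` (γ = 1.5, δ = 0.75, u₀ = 10, v₀ = 5). Each of N = 600
sampled parameter pairs yields both solutions on 512 time points,
concatenated and wrapped into a 32×32 matrix; the pipeline projects onto
`G(10, 32)`, keeps g = 3 parsimoniously selected diffusion coordinates, and
fits degree-6 sparse surrogates:

```python
from trajgsa import GSAConfig, run_gsa
from trajgsa.models import LOTKA_VOLTERRA_MARGINALS, get_model

model, _ = get_model("lotka_volterra")
config = GSAConfig(marginals=LOTKA_VOLTERRA_MARGINALS, N=600, p=10, g=3,
                   s_max=6, fit_method="lar", selection_mode="parsimonious",
                   seed=1)
result = run_gsa(config, model)
print(result.sensitivity.to_frame())
```

which prints (seed 1):

```
method parameter  output_dim       S1       ST
   pce     alpha           0 0.960919 0.979701
   pce     alpha           1 0.626405 1.000000
   pce     alpha           2 0.234177 0.919611
   pce      beta           0 0.020299 0.039081
   pce      beta           1 0.000000 0.373595
   pce      beta           2 0.080389 0.765823
retained diffusion coordinates: (1, 5, 6)
validation error per coordinate: [0.0048, 0.7279, 0.5290]
```

Reading the output: `output_dim` 0 is the first retained diffusion
coordinate — the slowest mode of the trajectory family, accurately
surrogated (validation error 0.005). Its variance is almost entirely
attributed to α (`S1 ≈ 0.96`), the parameter that sets the oscillation
frequency `ω ≈ √(αγ)`: over the declared ranges, an α perturbation rotates
the trajectory subspaces several times further than a β perturbation, which
mainly rescales amplitude. Parsimonious selection retained eigenvectors
{1, 5, 6}, skipping indices 2–4 as harmonics of the first coordinate. The
later coordinates mix shorter-timescale dynamics and are dominated by
interaction effects (`ST ≫ S1` for both parameters); their surrogates are
correspondingly rougher, so conclusions rest on the first coordinate.

The same `run_gsa` call drives the epidemic and wealth generators; the
`trajgsa` CLI exposes the stages individually (`sample`, `simulate`,
`embed`, `fit`, `indices`, `run`, `mc-sobol`).

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
— the full Lotka–Volterra pipeline above at its stated defaults — printing
the sensitivity table and writing the result manifest:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
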