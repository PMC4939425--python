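# Methods

## Model and conventions

The package samples Gibbs targets π(x) ∝ e^{−βV(x)} with the
nonreversible overdamped dynamics

    dX_t = (∇log π(X_t) + α γ(X_t)) dt + √2 dW_t,

where γ is divergence-free with respect to π. For the constant-matrix
construction we define γ **β-free** as γ(x) = −J∇V(x) (J = −Jᵀ), so the
full drift is −(βI + αJ)∇V and α measures the perturbation strength
relative to the raw potential gradient. With β = 1 this coincides with
γ = J∇log π up to the sign of J, and since every variance formula
depends on J only through JᵀJ and orthogonal conjugation, flipping the
sign of J changes nothing observable. The smoothed construction
γ = J∇V·ψ(V) (bounded when ψ is compactly supported) and the matrix
field γ = −J(x)∇V + ∇·J are also provided; all three are validated
numerically by `divergence_check`, which evaluates
∇·γ + γ·∇log π = ∇·(γπ)/π by central differences.

Torus targets use the minimum-image convention for all distances; this
limits representable pair separations to L/2, so the box must be large
enough for the states of interest (the dimer helpers enforce
spacing > r0 at initialisation).

## Gaussian theory

For dX = −(I+αJ)X dt + √2 dW (stationary N(0, I) for every α, J) and
f = x·Mx + l·x + k, the Poisson equation −ℒφ = f − π(f) has the
quadratic solution φ = x·Cx + D·x − Tr C with

    AC + CAᵀ = M,   AD = l,   A = (I + αJ)ᵀ = I − αJ,

solved with SciPy's Bartels–Stewart Lyapunov solver (residuals at
1e−12 relative; Tr C = Tr M/2 follows by tracing the equation). The
asymptotic variance is

    σ²_f(α) = 2⟨φ, f − π(f)⟩_π = 4 Tr(C Mᵀ) + 2 l·A⁻¹l,
    l·A⁻¹l = l·(I + α²JᵀJ)⁻¹l.

This normalisation is the one validated by three independent routes:
the directly solved 2-D rotation example (σ² = 4(1+1/(1+α²)) for
f = 2x₁²), the 1-D Green–Kubo value (σ² = 2 for f = x²−1), and
Monte-Carlo arbitration against the samplers in the test suite.

A second normalisation circulates in which the Lyapunov solution
carries an extra factor ½, making the quadratic contribution at α = 0
equal to ‖M‖²_F instead of 2‖M‖²_F. Several reference numbers for the
4-D two-block example (30 at α = 0, limit 25 under the eigen-pairing
matrix, lower bound 20) are quoted on that scale, so the expression is
exposed verbatim as `half_quadratic_variance`; the linear terms of the two
normalisations are identical and their quadratic terms differ by
exactly a factor 2 for every (J, M, α) — a relation the tests
regression-lock rather than silently "correcting" either way.

Large-α limits are evaluated numerically at α = 10⁶ with a consistency
probe at 10⁷ (warning on disagreement beyond 1e−5 relative) plus the
exact kernel contribution 2|l_N|², with Ker J detected by SVD at a
relative threshold of 1e−10. `pairing_J` sorts eigenvalues ascending,
fixes each eigenvector's first significantly nonzero component
positive (deterministic output), pairs the k-th lowest with the k-th
highest eigenvalue, and in odd dimension leaves the middle eigenvector
unperturbed. `optimal_linear_J` picks its default ω by Gram–Schmidt of
the basis vector least aligned with l — no RNG anywhere in the
constructions.

## Samplers

* **Euler–Maruyama**: X' = X + Δt(∇log π + αγ) + √(2Δt)ξ; one gradient
  per step. The scheme's invariant measure carries an O((1+α²)Δt) bias
  (for the OU case the stationary covariance is inflated by
  1/(1 − Δt(1+α²)/2)), which is why large α demands small Δt.
* **MALA**: Euler proposal with covariance 2Δt·I — consistent with the
  √2 diffusion; a Δt-covariance variant would not converge to the
  continuous dynamics — and the standard Metropolis–Hastings ratio
  π(X̃)q(X̃→X)/(π(X)q(X→X̃)). The reversible variant is exactly
  π-invariant at any Δt; the nonreversible-proposal variant uses drift
  ∇log π + αγ in the proposal only. One new gradient per step
  (the current-state gradient is cached). On torus targets MALA runs in
  unwrapped coordinates; the potential and observables are periodic, so
  time averages are unaffected.
* **Strang splitting**: Ψ_Δt = Φ_{r,Δt/2} ∘ Φ_{n,Δt} ∘ Φ_{r,Δt/2}, with
  Φ_r a single MALA step at Δt/2 and Φ_n classical RK4 for ż = αγ(z)
  (local error O(Δt⁵); exactly conserves V only up to that error, the
  continuous flow conserves it exactly). Six gradient evaluations per
  step after reuse — the number used for budget equalisation. At α = 0
  the flow map is the identity and the scheme reproduces, draw for
  draw, the MALA chain at stepsize Δt/2.

Blow-up handling: a step producing a non-finite state, or ‖X‖ or |V|
beyond `blowup_norm` (default 1e8), sets a divergence flag, truncates
the recorded series and returns partial data instead of raising; the
dimer target additionally raises a domain error on exactly coincident
particles, which the samplers convert into the same flag. All runs are
bit-reproducible from their seed; ensembles derive child seeds
deterministically from a master seed via `SeedSequence` spawn keys.

## Estimators

`ensemble_sigma2` is T·Var over independent replica time-averages;
`batch_means_sigma2` is T_b·Var over contiguous equal-length batch
means from one trajectory, with the trailing remainder discarded and a
default of 30 batches (the batch-means literature gives no canonical
tie-break; batch length must exceed the correlation time by a
comfortable factor). Both report an approximate standard error
σ̂²·√(2/(n−1)) from the χ² sampling distribution of a variance.
Confidence intervals use the normal quantile (CLT), not Student-t.
MSE across replicas excludes diverged runs and reports the excluded
fraction separately.

## Experiment scales

Defaults are desk-scale: the published-style figures behind these
drivers used T = 10⁵ with 10³ replicas (and 10¹⁰ steps for the dimer),
which is out of reach for a test suite. The suite instead uses, e.g.,
T = 100 with 400 replicas for the Gaussian arbitration, T = 500 with 60
replicas for the warped Gaussian (where an ~80× variance reduction from
α = 0 to α = 10 is already visible), and 10⁴–10⁵-step dimer
trajectories. Consequences: warped-Gaussian runs shorter than a few
multiples of the slow coordinate's relaxation time (≈ 50) are **not**
in the asymptotic regime and their σ̂² ordering can even invert —
tests assert orderings only at horizons where the regime is reached;
dimer results at desk scale establish machinery and stability
(Δt ≈ 10⁻⁵ is needed for stability at α = 10, matching the original
study's stepsize), not converged reaction-coordinate averages.

## Known limitations

- No user-facing symbolic differentiation: custom targets must supply
  their own gradient (checked via `check_gradient`).
- The MH ratio on torus targets treats the Gaussian proposal in
  unwrapped coordinates (exact only up to wrapped-normal image terms,
  negligible for √(2Δt) ≪ L).
- No search over the admissible-drift class: only the constructive
  optimal-J recipes for Gaussian targets are implemented.
- The dimer model is 2-D with a single dimer pair; the WCA pair loop is
  O(N²) per step.
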