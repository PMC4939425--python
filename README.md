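# nrlangevin

Nonreversible overdamped Langevin samplers, asymptotic-variance
estimation, and exact variance theory for Gaussian targets.

## The problem

To compute an expectation π(f) = ∫ f dπ for a Gibbs target
π(x) ∝ e^{−βV(x)}, one simulates the overdamped Langevin diffusion

    dX_t = ∇log π(X_t) dt + √2 dW_t

and uses the time average π_T(f) = (1/T)∫₀^T f(X_t) dt. The error of
this estimator is governed by the asymptotic variance σ²_f in the CLT
√T(π_T(f) − π(f)) → N(0, σ²_f). Adding a drift αγ that is
divergence-free with respect to π (∇·(γπ) = 0, e.g. γ = −J∇V with
J = −Jᵀ) leaves π invariant but breaks detailed balance, and σ²_f(α) is
then **never larger** than the reversible σ²_f(0) — often dramatically
smaller, because the antisymmetric flow sweeps the sampler along level
sets of V that the reversible dynamics crosses only diffusively.

This package provides, for researchers in sampling and molecular
simulation:

- **targets** — built-in Gibbs targets (standard Gaussian, 2-D warped
  Gaussian, periodic potential on the torus, a dimer in a WCA solvent in
  a periodic box) with analytic gradients and finite-difference checks;
- **drifts** — divergence-free perturbation fields (constant-J,
  smoothed γ = J∇V ψ(V), matrix fields γ = −J(x)∇V + ∇·J) plus the
  optimal antisymmetric matrices for linear and quadratic observables of
  Gaussian targets, and a numerical divergence validator;
- **samplers** — Euler–Maruyama for the nonreversible SDE, MALA
  (reversible and nonreversible-proposal), and a Strang splitting
  (MALA half-steps around an RK4 integration of ż = αγ(z)), with
  blow-up detection and gradient-evaluation accounting;
- **estimators** — ensemble and batch-means estimators of σ²_f, MSE
  across replicas, normal-theory confidence intervals;
- **gaussian_theory** — for the Ornstein–Uhlenbeck case
  dX = −(I+αJ)X dt + √2 dW with quadratic observables
  f = x·Mx + l·x + k: the exact Poisson solution via a Lyapunov solve
  (AC + CAᵀ = M, AD = l, A = I − αJ), exact σ²_f(α), its large-α
  limits, and the eigenvalue-pairing lower bound;
- **experiments** — α-sweeps, EM-vs-MH comparisons, MSE-vs-Δt sweeps at
  a fixed gradient-evaluation budget, and the solvated-dimer
  reaction-coordinate study; all emit fixed-schema CSV tables.

## Worked example

The 2-D standard Gaussian with the planar rotation J and the observable
f(x) = 2x₁² has the closed-form variance σ²_f(α) = 4(1 + 1/(1+α²)).
The exact machinery and a Monte-Carlo ensemble agree:

```python
import numpy as np
from nrlangevin import (LinearModel, SamplerConfig, asymptotic_variance,
                        constant_J_drift, ensemble_sigma2,
                        euler_maruyama_ensemble, make_gaussian,
                        make_observable_quadratic)

J = np.array([[0.0, -1.0], [1.0, 0.0]])      # planar rotation
M = np.diag([2.0, 0.0])                      # f(x) = 2 x1^2

model = LinearModel(J=J, alpha=3.0, M=M)
print(asymptotic_variance(model.with_alpha(0.0)))   # 8.0
print(asymptotic_variance(model))                   # 4.4

target = make_gaussian(2)
field = constant_J_drift(J, target)                 # gamma(x) = (x2, -x1)
obs = make_observable_quadratic(M, k=0.0)           # mean 2 under N(0, I)
cfg = SamplerConfig(dt=0.002, n_steps=60_000, alpha=3.0, seed=7,
                    burn_in=10_000)
res = euler_maruyama_ensemble(target, field, cfg, obs, n_replicas=400)
ve = ensemble_sigma2(res["estimates"], res["T"])
print(f"{ve.estimate:.3f}  [{ve.ci_low:.3f}, {ve.ci_high:.3f}]")
print(f"{ve.sigma2:.2f} +/- {ve.sigma2_se:.2f}")
```

Output:

```
8.0
4.4
2.019  [1.998, 2.039]
4.36 +/- 0.31
```

The ensemble of 400 replicas of length T = 100 estimates π(f) = 2 with
a 95% confidence interval of about ±0.02, and its variance estimate
σ̂² = 4.36 ± 0.31 matches the exact σ²_f(3) = 4.4; at α = 0 the same
run gives σ̂² ≈ 8, so the perturbation roughly halves the statistical
error budget at identical cost. See `docs/methods.md` for conventions,
defaults and limitations.

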