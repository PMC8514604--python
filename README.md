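# latentlangevin

Non-parametric maximum-likelihood inference of **latent, non-stationary
Langevin dynamics from Poisson spike trains**.

Many computations in the brain — perceptual decision making in
particular — are naturally described by a one-dimensional stochastic
process

```
dx/dt = D F(x) + sqrt(2 D) xi(t),        F(x) = -dPhi/dx,   x in [-1, 1],
```

where the potential Phi(x) encodes the deterministic forces (a tilted
slope for *ramping* drift-diffusion decisions, a double-barrier well for
*stepping* decisions), D is the noise magnitude, and the trajectory
x(t) is never observed directly: it only drives an inhomogeneous Poisson
process whose spikes occur with rate f(x(t)).  This package infers
Phi(x), D, and the initial-state density p0(x) from such spike trains,
for users (computational neuroscientists, biophysicists) who want an
interpretable dynamical model rather than a black-box fit.

The central difficulty is that trial-based data are **non-stationary**:
every trial starts from a specific state drawn from p0(x), and in
reaction-time designs it ends the moment the trajectory first hits a
decision boundary x = +-1.  The likelihood of one trial
`Y = {t0, t1..tN, tE}` marginalizes the latent path through a chain of
operators,

```
L[Y] = ∫ dx  [ A ]  e^{-H (tE - tN)}  f(x) ... f(x)  e^{-H (t1 - t0)}  p0 ,
```

where `H = H0 + f(x)` is the Fokker–Planck operator of the Langevin
dynamics plus the spike "sink" accounting for intervals without spikes,
H carries reflecting boundary conditions for fixed-duration designs or
absorbing conditions for reaction-time designs, and the absorption
operator `A = H0` (applied only in the reaction-time case) restricts
the likelihood to trajectories that terminate on a boundary at tE.
Omitting any of these non-stationary ingredients biases the inferred
potential with spurious features; the package exposes each of them as an
explicit ablation switch so that this can be demonstrated directly.

Fitting is gradient descent on the log-likelihood in the unconstrained
variables F(x), F0(x) = p0'/p0, and D, with exact adjoint (reverse-mode)
gradients through the discretized operator chain.  Because flexible
models eventually overfit, the optimal iterate is chosen by **feature
consistency**: models fitted to two independent data halves are compared
at matched *feature complexity* (the negative entropy of their latent
trajectories) via the time-integrated Jensen–Shannon divergence between
their latent densities, and the highest complexity at which the halves
still agree is selected.  Bootstrap refits give pointwise confidence
bands for the potential.

Everything runs on a Gauss–Lobatto–Legendre spectral grid (quadrature,
differentiation, and operator assembly are spectrally accurate), and a
built-in Euler–Maruyama / time-rescaling simulator generates synthetic
spike data from named ground-truth fixtures (`ramping`, `stepping`,
`fixed-duration`).

## Worked example

Recover the ramping potential from 200 simulated reaction-time trials:

```python
import numpy as np
from latentlangevin import (
    FitConfig, LatentModel, SimConfig, dataset_loglik, fit,
    fixture_model, simulate_dataset,
)
from latentlangevin.diagnostics import potential_rmse

# ground truth: tilted linear potential, reaction-time design
gt = fixture_model("ramping", 32)
data = simulate_dataset(gt, SimConfig(n_trials=200, rng_seed=0))
print(f"simulated {len(data)} trials, "
      f"mean duration {np.mean([t.duration for t in data]):.2f} s, "
      f"mean spikes/trial {np.mean([t.n_spikes for t in data]):.1f}")

# start from an unspecific flat potential; D and f(x) given as known
init = LatentModel.from_functions(
    gt.grid, lambda x: 0 * x, gt.noise, gt.p0, gt.rate_fn, "absorbing"
)
trace = fit(data, FitConfig(init_model=init, max_iterations=150))
idx = trace.plateau_index(n_trials=len(data))
ll_gt = dataset_loglik(gt, data) / len(data)
ll_fit = trace.logliks[idx] / len(data)
rmse = potential_rmse(trace.models[idx].potential, gt.potential, gt.grid.nodes)
print(f"plateau at iteration {idx}")
print(f"per-trial log-likelihood: fitted {ll_fit:.3f} vs ground truth {ll_gt:.3f}")
print(f"potential RMSE over the central 80% of the domain: {rmse:.3f}")
```

Output:

```
simulated 200 trials, mean duration 0.58 s, mean spikes/trial 26.9
plateau at iteration 149
per-trial log-likelihood: fitted 76.587 vs ground truth 76.573
potential RMSE over the central 80% of the domain: 0.207
```

The fitted model reaches the ground-truth likelihood (gap well below 1%)
and recovers the potential shape to ~0.2 in dimensionless potential
units over the central 80% of the domain.  (Log-likelihoods are spike-
time *densities*, so positive values are normal.)

The same pipeline is available from the shell:

```
latentlangevin simulate --fixture ramping --n-trials 200 --out data.txt --model-out gt.json
latentlangevin fit --data data.txt --init init.json --iterations 150 --out trace.npz
latentlangevin select --trace1 t1.npz --trace2 t2.npz --out report.json
latentlangevin loglik --data data.txt --model gt.json --no-absorption-op
```

The spike-data file format is plain text, one trial per line (see
`docs/example_spikes.txt`).

## Limitations

The method assumes a one-dimensional latent space, a known firing-rate
function f(x), Poisson spike emission, and trial-homogeneous dynamics;
see `docs/methods.md` for the model details, numerical choices, and the
known behavior of the consistency threshold on limited data.
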