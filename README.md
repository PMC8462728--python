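# purefrag

Simulation and inverse-problem toolkit for the **pure fragmentation
equation** — the population-balance model of protein filaments (amyloid
fibrils, prion aggregates and similar pseudo-linear polymers) that divide
without growing, for example once free monomers are depleted. It is aimed at
experimentalists and modellers who measure **time-point samples of fibril
lengths** (AFM / nano-imaging) and want the division law behind them.

## The model

The number density `u(t, x)` of filaments of length `x` obeys

```
∂u/∂t = −α x^γ u(t, x) + α ∫_x^∞ κ(x/y) y^{γ−1} u(t, y) dy
```

* `B(x) = α x^γ` — division rate; `γ > 0` means longer filaments break
  faster, `α` sets the clock (time is unitless, seconds / 1 s).
* `κ(z)` — fragmentation kernel: the distribution of relative daughter
  length `z = x/y`, with `∫κ = 2` (binary fission) and `∫zκ = 1` (mass
  conservation). Class A kernels vanish at `z = 0, 1` (interior breakage);
  class B kernels do not (end breakage).

Two structural results drive everything:

1. **Moment decay law.** The rescaled solution
   `t^{2/γ} u(t, t^{1/γ}·)` converges to a steady profile `g`, so every
   moment of the measured distribution `f = u/∫u` decays as
   `log M_q(t) = −(q/γ) log t + C(q)` — a straight line in log-log, whose
   slope gives `γ` without knowing `α`, `κ`, or the initial condition.
2. **Mellin identity.** With `G(s) = ∫x^{s−1} g dx` and `K(s) = ∫z^{s−1}κ dz`,
   `(2−s) G(s) = αγ (K(s)−1) G(s+γ)`. At `s = 1` (where `K(1) = 2`) this
   inverts to `α = 1/(γ Ĝ(1+γ))` for the unit-mass profile; solving for
   `K(s)` and inverting the Mellin transform along a contour `Re s = s0 > 2`
   recovers `κ` (an ill-posed step, regularized by an explicit low-pass
   filter that is recorded in every output).

The package provides: a conservative implicit solver on a logarithmic grid
(plus an explicit variant and a monomer-resolved discrete model for
cross-validation), the classical closed-form solutions as validation
oracles, the `(γ, α, κ)` estimators, two-sample Kolmogorov–Smirnov
machinery for kernel discrimination, a synthetic-experiment generator with
seeded length sampling and KDE reconstruction, and a CLI.

## Worked example

Simulate the headline configuration — `γ = 1.3`, `α = 1`, a symmetric
two-peaked Gaussian kernel, exponential initial lengths — observe noiseless
length distributions at `t = 5, 10, 20, 30, 40`, and invert them:

```python
import purefrag as pf

params = pf.FragmentationParameters(gamma=1.3, alpha=1.0)
kernel = pf.make_kernel("two_peaked_gaussian")          # offset 0.25, sd 0.05
data = pf.simulate_experiment(params, kernel, "exponential",
                              times=[5, 10, 20, 30, 40], n=0,
                              grid=pf.LogGrid.from_bounds(1e-4, 50, 600))
result = pf.analyze_experiment(data)
print(f"gamma_e = {result.gamma_e:.3f}  alpha_e = {result.alpha_e:.3f}  "
      f"T_e = {result.t_e:.2f}  class = {result.kernel_class}")
```

```
gamma_e = 1.356  alpha_e = 1.135  T_e = 5.20  class = A
```

`gamma_e` slightly overestimates the true 1.3 — the log-log moment curve is
concave, so any finite observation horizon biases the fitted slope upward;
`T_e` is the fitted onset of the asymptotic line, and the recommended
experiment length is `5 × T_e ≈ 26`. The profile is correctly classified as
class A (interior breakage). The same pipeline accepts measured lengths as
a `(time, length)` CSV:

```bash
purefrag synth --gamma 1.3 --kernel two_peaked_gaussian \
    --times 5,10,20,30,40 --n 200 --seed 1 --out lengths.csv
purefrag estimate --input lengths.csv --out report.json --plot diag
purefrag design --gamma 1.3 --kernel two_peaked_gaussian --times 5,10,20,30,40
```

There is also an sklearn-style front end:

```python
est = pf.FragmentationEstimator(estimate_kernel=True).fit(data)
est.gamma_, est.alpha_, est.t_e_, est.kernel_class_
```

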