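# shsize

Stochastic hybrid system (SHS) models of single-cell size homeostasis:
exact lineage simulation, closed-form stationary size moments, and
moment-matching parameter estimation from observed cell-size distributions.

Intended for quantitative cell biologists and modelers studying how
microbes (and some mammalian cells) keep their size distribution stationary
across growth–division cycles, and for anyone who needs an exact,
discretization-free simulator of piecewise-deterministic growth–division
dynamics.

## The model

A cell of size `s(t)` grows exponentially, `ds/dt = μs`, and divides with a
size-dependent hazard `k·s^α`. At division the tracked daughter inherits a
random fraction `β ∈ (0,1)` of the mother's size (beta-distributed with
mean `⟨β⟩` and noise `CV²_β`; `β = 1/2` exactly for perfectly precise
halving), and the sibling is discarded, so the model follows a single
lineage. Key regimes:

* **α = 0** (size-independent timing): no homeostasis — even with the
  division rate balanced so the mean stays flat (`k = μ/(1−⟨β⟩)`), the
  variance of size grows without bound. Active size sensing is necessary.
* **α = 1** (the *adder*): a cell adds an exponentially distributed size
  increment with mean `μ/k` per cycle, independent of its birth size. All
  stationary moments are exact:

  ```
  ⟨s⟩ = −μ/(k⟨log β⟩),     ⟨s^{p+1}⟩ = pμ⟨s^p⟩ / (k(1−⟨β^p⟩)),
  CV²_s = −1 + ⟨log β⟩/(⟨β⟩−1)      (= log 4 − 1 ≈ 0.39 at β = 1/2),
  ```

  with skewness ≈ 1.68, independent of μ and k.
* **α > 1** (sizer-like): `y = s^α` is itself an adder, giving exact
  moments of `y`; mean and CV² of `s` follow from a derivative-matching
  (log-normal) moment closure, `CV²_s ≈ −1 + (⟨log β⟩/(⟨β⟩−1))^{1/α}`,
  which decreases with α.
* **Multi-stage cell cycle**: the cycle traverses `M` stages, each left at
  a size-proportional hazard `k_i·s`; added size becomes Erlang with
  `CV²_Δ = 1/M`. Mean and second moment are exact for arbitrary rates; for
  equal rates `CV²_s = −1 + (1+M+⟨β⟩(M−1))/(2M) · ⟨log β⟩/(⟨β⟩−1)`,
  decreasing from ≈ 0.39 (M = 1) to the floor ≈ 0.04 (M → ∞) at `β = 1/2`.

The simulator samples event times exactly by inverting the integrated
hazard along the exponential ramp (no thinning, no time step), and the
estimation layer inverts the moment formulas — sample CV² → `CV²_β`
(one-dimensional root finding on the digamma expression for `⟨log β⟩`),
sample mean → `μ/k`, and the added-size or newborn-size noise → the stage
count `M` (exhaustive integer search).

## Worked example

```python
import shsize as sh

halving = sh.make_partition_law(0.5, 0.0)          # beta = 1/2 exactly
params = sh.SingleStepParams(mu=1.0, k=1.0, alpha=1.0)

exact = sh.adder_moments(params, halving, max_order=3)
print(f"exact mean size      : {exact.mean_size:.4f}")
print(f"exact size noise CV2 : {exact.cv2:.4f}")
print(f"exact skewness       : {exact.skewness:.4f}")

cfg = sh.SimConfig(model=params, partition=halving, n_cycles=100_000, seed=42)
est = sh.stationary_estimate(cfg)
print(f"simulated CV2        : {est.cv2:.4f} +/- {est.cv2_se:.4f}")

for M in (1, 10, 100):
    print(f"M = {M:>3d} stages       : CV2 = {sh.multistep_equal_rates(1, 1, M, halving).cv2:.4f}")
print(f"M -> infinity        : CV2 = {sh.multistep_cv2_limit(halving):.4f}")
```

prints

```
exact mean size      : 1.4427
exact size noise CV2 : 0.3863
exact skewness       : 1.6807
simulated CV2        : 0.3892 +/- 0.0025
M =   1 stages       : CV2 = 0.3863
M =  10 stages       : CV2 = 0.0744
M = 100 stages       : CV2 = 0.0432
M -> infinity        : CV2 = 0.0397
```

The mean size is `1/log 2` of the adder increment scale `μ/k`; the
simulated noise (a time-weighted average over 10⁵ division cycles, with a
batch-means standard error) agrees with the exact `log 4 − 1`; and
subdividing the cell cycle into more stages drives the noise toward its
ten-fold-lower floor `(3/2)·log 2 − 1`.

The same functionality is exposed on the command line:

```sh
shsize moments --mu 1 --k 1                    # adder moments as JSON
shsize sweep --m-values 1,2,5,10,50 --beta-cv2-values 0,0.02,0.05
shsize simulate --cycles 100000 --seed 1 --out run
shsize fit --sizes sizes.csv --added added.csv --model multistep
shsize diverge-demo --t-max 6                  # alpha = 0 variance blow-up
shsize fixtures --seed 0 --out-dir fixtures    # seeded synthetic datasets
```

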