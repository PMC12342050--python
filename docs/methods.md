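# Methods

## Model

The package implements a stochastic hybrid system (equivalently, a
piecewise-deterministic Markov process) for the size `s(t)` of a single
tracked cell. Between events the size grows deterministically and
exponentially, `ds/dt = μs`; discrete events fire as an inhomogeneous
Poisson process whose hazard depends on the current size. Two event
structures are supported:

* **single-step**: one event type, division, with hazard `k·s^α`;
* **multi-stage**: the cell cycle passes through stages `1..M`; stage `i`
  is left at hazard `k_i·s` (a size-proportional hazard per stage), and
  leaving stage `M` is division.

At division the size jumps to `β·s` with `β` drawn independently per
division from the partition law, and exactly one daughter is followed —
the model is a lineage process, not a population tree.

Modeling assumptions worth keeping in mind: growth is exactly exponential
with a fixed rate (no growth-rate fluctuations, no nutrient shifts); the
division hazard depends only on current size, not on age or birth size;
and partitioning noise is beta-distributed (or a point mass). These are
the standard idealizations under which the closed-form moments below are
exact.

## Parameters

| parameter | meaning | units | default / notes |
|---|---|---|---|
| `μ` | fractional growth rate | 1/time | 1 (sets the time unit) |
| `k` | division-rate constant | size`^-α`/time | 1 (with μ sets the size unit μ/k) |
| `α` | hazard exponent | — | 1 = adder; 0 = no size control; large = sizer |
| `M`, `k_i` | stage count and per-stage rates | 1/(size·time) | equal-rate case uses `k_i = kM` so the added-size mean stays `μ/k` for every M |
| `⟨β⟩` | mean inherited fraction | — | 1/2 (unbiased daughter choice) |
| `CV²_β` | partitioning noise | — | 0–0.1 is the physiological range explored; must be `< (1−⟨β⟩)/⟨β⟩` |

All noise measures (CV², skewness) are invariant under `(μ,k) → (cμ,ck)`;
only the mean carries the scale `(μ/k)^{1/α}`.

## Analytic layer

* Beta-law expectations are computed exactly: `⟨log β⟩ = ψ(a) − ψ(a+b)`
  (digamma), fractional moments `⟨β^p⟩` via log-gamma differences. The
  shape parametrization is `a = z`, `b = z(1/⟨β⟩−1)` with
  `z = (1−⟨β⟩(1+CV²_β))/CV²_β`. The degenerate `CV²_β = 0` case is a
  separate point-mass branch rather than a limiting beta, avoiding
  digammas of diverging shapes.
* Adder moments follow the exact recursion
  `⟨s^{p+1}⟩ = pμ⟨s^p⟩/(k(1−⟨β^p⟩))` seeded by
  `⟨s⟩ = −μ/(k⟨log β⟩)`; an equivalent closed product form is kept as an
  independent code path and cross-checked in tests.
* Skewness is the standard third standardized central moment
  `(⟨s³⟩ − 3⟨s⟩Var − ⟨s⟩³)/Var^{3/2}`; with precise halving it evaluates
  to ≈ 1.6807 and is nearly flat in `CV²_β` below ≈ 0.1.
* For general `α > 0` the transform `y = s^α` is an adder with growth rate
  `αμ` and fraction `β^α`, so all `y`-moments are exact; `α = 1/q`
  recovers exact `s`-moments as the `q`-th and `2q`-th `y`-moments. For
  `α ≥ 1` the derivative-matching closure approximates `⟨s^α⟩` and
  `⟨s^{α+1}⟩` by the log-normal-consistent monomials of the first two
  moments, giving `CV²_s ≈ −1 + (⟨log β⟩/(⟨β⟩−1))^{1/α}`. The closure is
  exact at `α = 1` (results carry an `exact` flag) and sits slightly below
  the simulated noise for larger α — a known one-sided bias of the
  log-normal closure for these right-skewed stationary laws.
* Multi-stage second moments use the per-stage flux-balance recursion
  (`⟨g_i s⟩` and `⟨g_i s²⟩`, where `g_i` indicates occupancy of stage i)
  as the primitive; the equivalent pair-sum closed form is retained only
  as a cross-check. The recursion reproduces the equal-rate closed form to
  1e-12 and collapses onto the single-step formulas when the later stages
  become infinitely fast.
* The small-noise expansion of `⟨log β⟩` (and the resulting CV²
  approximations) is a convenience; a warning fires when `CV²_β > 0.2`,
  where the expansion visibly degrades. The threshold is a package choice —
  the expansion itself is only claimed for `CV²_β ≪ 1`.

## Simulation

Event times are sampled exactly: for hazard `k s^α` along an exponential
ramp the integrated hazard inverts in closed form, so with a
standard-exponential variate `E` the size at the event satisfies
`s_end^α = s_start^α + αμE/k` (`s_end = s_start·e^{μE/k}` at `α = 0`) and
the waiting time is `log(s_end/s_start)/μ`. The implementation applies
this per-event closed form directly (vectorizing within and across
cycles), which is algebraically identical to sampling the waiting time by
hazard inversion and then growing the cell — there is no discretization
error anywhere, so simulation-vs-formula discrepancies are pure
Monte-Carlo noise.

Stationary statistics are estimated two ways:

* **Ergodic time averages** (default): one long lineage; `∫ s(t)^p dt` is
  evaluated exactly per growth segment as `(s_end^p − s_start^p)/(pμ)`,
  normalized by elapsed time after discarding a burn-in (default 100
  cycles). Standard errors come from 50 contiguous equal-duration batches
  (batch means). Time-weighting matters: sampling sizes only at event
  times would bias the stationary law.
* **Ensemble snapshots**: many independent lineages (one deterministically
  spawned RNG stream each, so results are order-independent) evaluated at
  a common time. Because all lineages start from a common initial
  condition, cell-cycle synchrony decays only gradually — very slowly for
  low-noise models such as Erlang-M cycles with large M — so snapshot
  moments oscillate around their stationary values for many generations.
  Snapshots are therefore used where the ensemble view is the point (the
  α = 0 divergence demonstration); stationary samples for estimation use
  `sample_stationary_sizes`, which evaluates `s(t)` at uniform random
  times along one long lineage and hence draws from the time-weighted
  stationary law by construction.

Default problem sizes (10⁴–10⁵ cycles per lineage, 2×10⁴ stationary
draws, 2×10⁴ lineages for ensemble checks) were chosen so that Monte-Carlo
standard errors resolve the analytic differences under test at the 3-sigma
level while a full run of the suite stays interactive.

## Estimation

The estimation layer is method-of-moments, inverting the package's own
closed-form formulas (the formulas, not a likelihood, are the model's
tractable handle):

1. sample CV² of sizes → `CV²_β` by Brent root finding on the exact
   (digamma) noise formula for the candidate stage count; the model CV² is
   strictly increasing in `CV²_β`, so the root is unique;
2. sample mean → `μ/k = −⟨s⟩·⟨log β⟩`;
3. stage count `M` by exhaustive integer search (default 1–200), scored by
   the auxiliary moment: `CV²_Δ = 1/M` when added sizes are available, or
   the newborn-noise formula when birth sizes are.

Sample CV² uses the unbiased variance estimator; the diagnostics report
whether the biased estimator would change the selected `M`. With sizes
alone `(M, CV²_β)` trade off along a one-parameter ridge (larger M is
compensated by larger partitioning noise); the fitter returns that ridge
explicitly, with a warning, instead of picking a point. Sample noise below
the `CV²_β = 0` floor of the requested model class is flagged infeasible
and reported at the boundary. `⟨β⟩` is fixed at 1/2 — asymmetric-mean
partitioning is not identifiable from these moments alone and is out of
scope for the fitter.

## Synthetic data

The fixture generator produces seeded datasets from the simulator itself:
adder cycles with and without partitioning noise, equal-rate 5-stage
cycles, and an `α = 2` ensemble snapshot, each with a JSON manifest of the
generating parameters. They emulate idealized lineage data — exact
exponential growth, perfectly observed sizes, no measurement error, no
lineage selection bias. Passing recovery tests on them demonstrates that
the inversion machinery is correct and well-conditioned at realistic
parameter values; it does not demonstrate robustness to measurement noise,
non-exponential growth, or population-snapshot sampling bias in real
microscopy data.

## Numerical choices and edge cases

* Partition-law feasibility (`CV²_β < (1−⟨β⟩)/⟨β⟩`) is enforced at
  construction; impossible moment pairs fail fast with the violated bound
  named.
* Fractional beta moments use `gammaln` differences, accurate for the
  irrational orders `αp` that the power-law transform needs.
* Root finding uses `brentq` with `xtol = 1e-12` on a bracketing interval
  grown geometrically toward the feasibility ceiling.
* Ties in the integer-M search resolve to the smaller M (parsimony).
* Batch-means standard errors are reported as NaN when fewer than two
  batches are requested.
* `MomentSummary` validates `⟨s²⟩ ≥ ⟨s⟩²` and the stored-vs-implied CV²
  at construction, so inconsistent summaries cannot propagate.

## Known limitations

* Transient (time-dependent) moments are provided only for `α = 0`, where
  the moment hierarchy closes at every order; for `α ≥ 1` only stationary
  quantities are computed.
* The closure for `α > 1` is a point approximation with a one-sided bias;
  no error bound is attached.
* The multi-stage model assumes size-proportional stage hazards
  (exponent 1 per stage); mixed per-stage exponents are not supported.
* Population-level (tree) statistics, growth-rate variability, and
  measurement-error deconvolution are out of scope.
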