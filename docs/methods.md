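# Methods

## Model and assumptions

`genedose` treats a gene as a two-state (telegraph) transcript source: the
promoter switches OFF→ON at rate *f* and ON→OFF at rate *h*; transcripts are
synthesized at rate *k* only while ON and degrade first-order at rate ρ.
All four rates are in 1/hour.  The model is intentionally minimal: it ignores
protein-level dynamics, extrinsic noise, multi-state promoters and any
feedback of the product on its own promoter.  Its value is exact solvability:
every simulated statistic can be checked against closed forms or brute-force
integration of the master equation.

Treatment enters through time-dependent rates.  A drug is described by the
rate it targets, the baseline value r₀ of that rate, the value r₁ reached by
one maximum-tolerated dose, and the exponential decay rate λ of its effect.
A dose carries a fraction ξ ∈ (0, 1] of the maximum effect; the mapping from
a physical dose (µM) to ξ is deliberately outside the model (it would require
drug- and cell-line-specific experiments), so ξ is the interface.

Doses superpose: immediately after the j-th dose the targeted rate is
r_s(τⱼ) = r₁ · Σ_{i≤j} ξᵢ e^{−λ(τⱼ−τᵢ)}, and between doses
r(t) = r₀ + (r_s(τⱼ) − r₀) e^{−λ(t−τⱼ)}.  This published superposition has a
quirk we reproduce deliberately: the reset discards the r₀-proportional part
of the pre-dose value, so a *small* fraction can momentarily pull the rate
below baseline.  A `continuity_mode` option instead adds (r₁−r₀)ξⱼ on top of
the left limit, which is jump-consistent; the default reproduces the
published behaviour, and the tests pin down both.

## Moment dynamics

Taking first- and second-moment sums of the master equation closes on five
quantities: x = (A, ⟨n⟩, ⟨n·1₍ON₎⟩, ⟨n²⟩, ⟨n²·1₍ON₎⟩), with dx/dt = Mx + b
linear at constant rates.  The eigenvalues of M are
−{ε, 1, 1+ε, 2, 2+ε}·ρ with ε = (f+h)/ρ, which reproduces the exponential
structure of the closed-form mean/variance transients.  We propagate
x(t) = x_s + e^{Mt}(x₀ − x_s) rather than evaluating literal coefficient
formulas: partial-fraction coefficients diverge when exponents collide
(ε = 1 makes e^{−ερt} and e^{−ρt} degenerate), whereas the matrix exponential
is well defined there.

One numerical subtlety: M is non-normal, and near the ε = 1 degeneracy
double-precision Padé scaling-and-squaring loses ~8 significant digits in the
squaring phase (verified against 50-digit arithmetic).  `expm_moments`
therefore runs plain scaling-and-squaring Taylor in 80-bit long doubles,
which restores ~1e−15 relative accuracy for all ε at negligible cost for a
5×5 matrix.  The closed-form/ODE-integration agreement tests run at 1e−8
relative, including |ε − 1| < 1e−6.

## Stationary law

With a = f/ρ, b = h/ρ, N = k/ρ, the stationary copy-number law is
P(n) = Nⁿ/n! · (a)ₙ/(a+b)ₙ · M(a+n, a+b+n, −N) (Kummer's confluent
hypergeometric function).  We evaluate it through the Kummer transformation
M(a+n, a+b+n, −N) = e^{−N} M(b, a+b+n, N), whose series has all-positive
terms, summed in log space (log-sum-exp) so N ~ 1000 burst regimes do not
underflow.  An arbitrary-precision (mpmath) fallback covers extreme bursting
corners (N > 500 with a ≪ 1).  Truncation starts at
⌈N + 10√N + 50⌉ and doubles until the omitted tail is below `tail_tol`; a
tail that cannot be met below a configurable cap raises — the law is never
silently renormalized.

## Piecewise-constant rate approximation

Between consecutive dose times the exact rate is a single exponential, so the
integrated absolute deviation of a constant from it has a closed form (the
integrand changes sign exactly once, at the midpoint).  Each inter-dose
interval is refined by recursive bisection until every segment's integrated
deviation is ≤ `abs_err` (default 1e−4, the published working tolerance);
each segment carries the exact rate at its midpoint (second-order accurate;
recorded in output metadata as `segment_rule: midpoint`).  Bisection makes
refinement monotone: halving `abs_err` can only split further.  Segments
never straddle a dose time.  With several drugs the propagation grid is the
union of all drugs' breakpoints, so every segment has all rates constant —
the constant-rate solution forces this choice.  Trajectory output is sampled
on a 0.05 h grid plus all segment boundaries; halving the output step changes
reported metrics by < 0.1%.

## Readout conventions

The default success threshold is 80 transcripts and the default target mean
100 (a Poisson-regime gene averaging 100 has 80 = ⟨n⟩ − 2σ); the
time-averaged readouts ⟨n⟩−σ and 2σ use the unweighted trapezoidal average
over a 60–80 h window after the first dose.  Threshold crossings are located
by linear interpolation between output grid points.  All three conventions
are scenario fields, overridable in config.

The degradation-rate convention deserves a note: the motivating study prints
ρ = 0.17 h⁻¹, but its printed switching-speed ladder (notably ε₁ = 91 from
f₁ = 13.65, h = 1.52) is consistent only with ρ = 1/6 h⁻¹.  Fixtures default
to 1/6; `--rho-convention printed` selects 0.17.  Derived parameters are
checked against printed values at 2.5%, or ±0.05 for values ≤ 1 printed to
one decimal.

## Oracles

The stochastic oracle runs the exact (Gillespie) algorithm per cell on the
same piecewise-constant rate grid (at a stricter default tolerance, 1e−6, so
oracle disagreement cannot be blamed on approximation mismatch).  Each cell
draws its initial (promoter state, copy number) from the joint stationary law
— obtained by a direct sparse solve of the truncated master-equation
generator with a normalization row — and owns an independent random stream
derived from (seed, cell index), making ensembles reproducible and
order-independent.  The inner loop is numba-compiled.

The master-equation oracle truncates the state space at n_max (ON and OFF
blocks), advances the resulting linear system per segment by the action of
the sparse matrix exponential, and reports the probability mass leaking past
the truncation; leakage above 1e−6 raises with an instruction to enlarge
n_max.  The two oracles are cross-checked against each other (chi-square on a
small-N dosed scenario) and against the analytic engine.

## Regime classification

The qualitative regime label is a documented heuristic, not a sharp boundary:
bimodal if the stationary law has ≥ 2 local maxima (counting a boundary mode
at n = 0); else burst if A < 0.05 and N ≥ 10/A; else quasi-Poissonian if
ε ≥ 5 and the Fano factor is < 2; else table-shaped.  It is validated only on
the packaged regime fixtures.

## Dose-fraction scan and enhanced design

The grid scan re-simulates the full agenda for each (ξ_a, ξ_b) pair on a
regular grid including 0 and 1 (fraction 0 drops that drug's doses, since a
zero-fraction dose is outside the dose model), recording both windowed
readouts.  Cumulative dose reduction is 100·(1 − Σξᵢ/J) — linear in each
fraction and order-invariant.

The enhanced design inverts the stationary noise formula
σ₁² = N₁A₁(1 + N₁(1−A₁)/(1+ε₁)): given a target mean and ε₁ (default 91, the
most effective single-drug value) it sets N₁ = max(target, 1 + ε₁) and
A₁ = target/N₁, placing the design on the low-noise side of the variance
maximum at A* = (1 + (1+ε₁)/N₁)/2, and returns the realizing rates
f₁ = A₁ε₁ρ₁, h₁ = (1−A₁)ε₁ρ₁, k₁ = N₁ρ₁.  The problem is under-determined
(four rates, two constraints); this is one documented resolution and
alternatives can be plugged in.  Default effect-decay rates for the
four-drug enhancement cocktail are (λ_k, λ_ρ, λ_f, λ_h) =
(0.25, 6, 0.05, 0.053) h⁻¹.

## Problem sizes and known limitations

Validation runs use small maximal copy numbers (N ≤ 50 for
stationary/oracle grids, N ≤ 30-ish for ensemble comparisons, 10⁴ cells for
the stochastic bracket at 20 probe times) — sizes at which the brute-force
references are exact and fast; the analytic engine itself is insensitive to
N.  The generator of random parameter sets spans ε ∈ [10⁻1.2, 10^1.5],
A ∈ [0.02, 0.98], which covers all five qualitative regimes.

What passing tests do *not* show: anything about real dose–response
pharmacology (the ξ interface is abstract), protein-level outcomes,
interactions between the targeted gene and the rest of its network, or
extrinsic (cell-size, cell-cycle) variability — the model attributes all
heterogeneity to intrinsic promoter/birth–death noise.  Known limitations:
the published dose superposition is discontinuity-inconsistent for small
fractions (kept for fidelity; see above); the multi-dose crossing time of the
synthesis-rate design recomputes to ≈ 12.4 h where the source text reads
"~10 h" from a graph; and the regime classifier is heuristic.
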