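# Methods

## Model

Two gene products *X* and *Y* mutually activate each other's synthesis and
decay linearly:

    dX/dt = k_xy · H(Y; K_xy, n) − μ_x · X + ξ_x(t)
    dY/dt = k_yx · H(X; K_yx, n) − μ_y · Y + ξ_y(t)

with the activating Hill function H(v; K, n) = vⁿ/(Kⁿ+vⁿ). The Hill form
follows from a quasi-steady-state treatment of TF–DNA binding
(X + D ⇌ XD, bound fraction X/(K+X) with K = k_off/k_on); cooperativity
n > 1 stands in for multimeric binding. ξ_x, ξ_y are independent zero-mean
white noises. Everything is expressed in molecule copy numbers (no explicit
volume; copy number and concentration are used interchangeably), time in
minutes.

Parameters, units, defaults:

| symbol | meaning | unit | default (basal operating point) |
|---|---|---|---|
| k_xy, k_yx | maximal synthesis rates | copies/min | 5 |
| K_xy, K_yx | half-maximal activation thresholds | copies | tied to the mean (see sweep) |
| n | Hill coefficient | — | 1 |
| μ_x, μ_y | degradation rates | 1/min | 0.5 |

The basal operating point (k = 5, μ = 0.5, n = 1, K = ⟨X⟩ = 5 copies) is the
package-wide default because it is the canonical low-copy regime where noise
effects are strongest; sweeps start there and scale k upward.

Positive autoregulation (a single self-activating gene) is the restriction
of the symmetric loop to its diagonal X = Y and is exposed as a constructor
(`FeedbackLoopParams.autoregulatory`), not a separate code path.

## Deterministic analysis

Fixed points solve the coupled nullcline equations. Substituting the
Y-nullcline y(x) = (k_yx/μ_y)·H(x; K_yx, n) into the X-nullcline leaves one
scalar equation f(x) = (k_xy/μ_x)·H(y(x); K_xy, n) − x = 0, which is scanned
on 2048 uniform grid points over [0, k_xy/μ_x·(1+10⁻⁶)] and refined by
bisection to |f| ≤ 10⁻¹⁰; roots closer than 10⁻⁶ of the box width are
merged. This 1-D reduction is robust because both nullclines are monotone
for activating Hill kinetics — which also implies every fixed point of a
symmetric loop lies on the diagonal (an increasing map composed with itself
admits no 2-cycles). The origin is always a fixed point (H(0) = 0) and is
always reported. Each root carries the analytic Jacobian

    J = [[−μ_x, k_xy·H′(Y)], [k_yx·H′(X), −μ_y]],  H′(v) = (n/v)·H·(1−H),

its eigenvalues, and a stability label: *stable* if both real parts are
below −10⁻⁹/min, *saddle* if the real parts have opposite signs beyond that
tolerance, *unstable* otherwise (marginal spectra are logged). The explicit
tolerance keeps classification deterministic under round-off.

A consequence worth stating plainly: with n = 1 and K tied to the mean, the
origin's eigenvalues are −μ ± k/K = {+μ, −3μ}, i.e. the OFF state is a
saddle and the deterministic circuit is **monostable at the active state,
not bistable**. The package reports what the mathematics gives. Genuine
ON/OFF bistability needs cooperativity: e.g. k = 20, K = 8, μ = 1, n = 2
yields stable states (0,0) and (16,16) with a saddle at (4,4) (the
diagonal condition 20x²/(64+x²) = x factors to x² − 20x + 64 = 0, roots 4
and 16).

## Linear-noise approximation

Around a stable fixed point the linearized fluctuations obey
d(δx)/dt = J δx + ξ, so the stationary covariance Σ solves the Lyapunov
equation JΣ + ΣJᵀ + D = 0 (solved with `scipy.linalg.solve_continuous_lyapunov`;
residual required ≤ 10⁻¹⁰·‖D‖; refusing non-Hurwitz J, where no stationary
distribution exists).

**Noise matrix.** The white-noise intensities are not free parameters: the
default "poissonian" mode sets D = diag(birth flux + death flux) at the
fixed point — the diffusion approximation of the underlying birth–death
process — which equals 2μ·mean per species there. This makes the LNA
directly comparable to the exact simulator with no tunable knob. An
"explicit" mode accepts user amplitudes for what-if analyses. Off-diagonals
are zero because the two noises are independent.

**Mutual information.** For the stationary Gaussian,
I(X;Y) = −½log₂(1−ρ²) = ½log₂[Σ(X)/Σ(X|Y)] with
Σ(X|Y) = Σ(X) − Σ(X,Y)²/Σ(Y); the two algebraic forms agree to 10⁻¹²
relative and the conditional-variance form is the one under which MI is
symmetric, non-negative, and zero exactly when the covariance vanishes.
Logarithms are base 2 throughout (bits). The **normalized MI** is defined as
2I/(H(X)+H(Y)) with Gaussian differential entropies H = ½log₂(2πe·var);
differential entropies can be non-positive (var < 1/2πe ≈ 0.059 copies²),
in which case the normalization is meaningless and the value is withheld
(flagged `None`). This normalization is a design choice of this package:
along the self-consistent sweep the raw MI is exactly constant
(ρ = ½ at every level), so any decline in relative coordination is carried
entirely by the entropy growth in the denominator.

**Symmetric closed form (oracle).** For the symmetric loop at its
self-consistent point the Jacobian is [[−μ, μ/2], [μ/2, −μ]] and D = 2μm·I;
with a = μ, b = μ/2, d = 2μm the Lyapunov solution is
var = d·a/(2(a²−b²)) = 4m/3 and cov = var·b/a = 2m/3 — a constant Fano
factor 4/3 and correlation ½, hence MI = ½log₂(4/3) ≈ 0.2075 bits at every
expression level. This closed form is derived independently of the solver
and serves as its test oracle (agreement required to 10⁻¹⁰ absolute over
means 5–100).

## Exact stochastic simulation

The discrete counterpart is the four-channel jump process with propensities
k_xy·H(y), μ_x·x, k_yx·H(x), μ_y·y and ±1 stoichiometries, simulated by the
Gillespie direct method (exponential waiting time at the total propensity,
channel chosen proportionally). Hill propensities are evaluated at integer
copy numbers directly — no volume scaling, consistent with the copy-number
convention. The inner loop is JIT-compiled (numba); a fixed seed gives a
bit-identical trajectory. **The origin is absorbing**: H(0) = 0 silences
both birth channels, so extinction of both products is irreversible. Runs
report this via an `absorbed` flag rather than an error.

Stationary moments are **time-weighted** (each state weighted by its holding
time) over the window (burn-in, t_end], where t_end is the horizon or the
absorption time, whichever came first — in the latter case the estimate
describes the dynamics conditioned on survival and is flagged. Mean standard
errors come from batch means over 32 equal-time batches. Empirical MI is the
Gaussian plug-in of the sampled covariance, with the empirical correlation
clipped to |ρ| ≤ 1−10⁻¹² against round-off. Exactness is checked against the
unregulated gene (constant birth k, death μ·x), whose stationary law is
exactly Poisson(k/μ): decorrelated samples (every 10 relaxation times) must
pass a chi-square goodness-of-fit test at p > 0.01 and show a Fano factor of
1 within 3 standard errors.

**Memory persistence** is the fraction of independent replicates, started
at the ON state, that after a time horizon are neither absorbed nor below
the memory threshold in either species. The threshold is the interior
saddle when one separates OFF from ON (the basin boundary on the diagonal),
else half the ON mean — a surrogate that stays well defined in monostable
regimes. Replicate seeds derive from one master seed via `SeedSequence`, so
a persistence fraction is exactly reproducible.

## The expression sweep

"Expression level" is realized by sweeping k with the Hill constants tied to
the stationary mean (K = ⟨X⟩). Because H(m; m, n) = ½ identically, the tied
fixed point is m = k/2μ for every n, and the reported x-axis variable is
that mean. Default grid: means 5–50 in steps of 5 (k = 5–50 copies/min at
μ = 0.5/min), spanning upward from the basal point. Per level the pipeline
computes the LNA covariance and (normalized) MI at the stable active fixed
point and pairs them with one long SSA run started there
(t_total = 10⁵ min, burn-in 10³ min — long relative to the ~4 min relaxation
time while keeping the full sweep around a minute of wall time). Per-row
seeds are master seed + row index. The comparison report lists per-row
relative deviations for var(X), var(Y), cov and MI against a 15% band and
an overall pass flag; rows without empirical data appear as explicit gaps
and preclude an overall pass.

## What the simulations do and do not show

The sweep's analytic columns behave exactly as the theory says: variances
and covariance grow linearly (Fano 4/3), raw MI is constant, normalized MI
decays. The empirical columns match within 15% at means ≥ 20. At low means
the discrete model departs from the LNA picture qualitatively, not just
quantitatively: since the origin is absorbing, the active state is only
*quasi*-stationary. Measured median extinction times from the ON state are
roughly 34 min at mean 5, 9.7×10² min at mean 10 and 6.7×10³ min at mean 15
— at means 5 and 10 the run dies before the burn-in ends, so those rows
carry no empirical statistics, and at means 15–20 the surviving-window
estimates are biased by survival conditioning (covariance and MI inflated
by up to ~20–35% in pilot measurements with an ensemble restart estimator).
This is reported as-is: it is the sharpest form of the package's own
message, that low-copy noise destroys the memory state outright. Passing
tests therefore certify the analytic machinery everywhere but certify
LNA–SSA agreement only in the regime where a metastable active state exists
on the observation timescale.

Other limitations: the LNA is a second-moment theory and says nothing about
switching kinetics; the Gaussian plug-in MI ignores the discreteness of low
copy numbers; no extrinsic noise, cell division/dilution, delays, or
tau-leaping acceleration; the network is strictly two-node.

## Numerical choices, briefly

Hill evaluation switches to 1/(1+(K/v)ⁿ) for v > K so large inputs cannot
overflow; H′ uses the (n/v)·H(1−H) form with the v → 0 limit handled
separately (1/K for n = 1, zero for n > 1). Fixed-point classification,
root refinement and deduplication tolerances are stated above. Covariance
containers enforce Cauchy–Schwarz with 10⁻⁹ relative slack; Lyapunov
solutions are symmetrized and variances clamped at zero against round-off.
Trajectory buffers grow in 2²⁰-event chunks; the RNG is seeded once per run
so chunked continuation preserves the stream.
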