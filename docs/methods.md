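# Methods

## Model and observation process

Each taxon's relative abundance follows the stochastic logistic model
(SLM), an Itô SDE with logistic self-limiting growth and multiplicative
environmental noise:

    dx/dt = (x/τ)(1 − x/K) + sqrt(σ/τ) · x · η(t),   ⟨η(t)η(t′)⟩ = δ(t − t′).

Parameters: τ (days) is the growth timescale (inverse of the maximum
growth rate), K the carrying capacity on the relative-abundance scale,
and σ the environmental noise strength.  For 0 < σ < 2 the stationary
distribution is gamma with shape 2/σ − 1 and scale Kσ/2 (mean K(1 − σ/2),
CV² = σ/(2 − σ)); at σ ≥ 2 no stationary distribution exists and the
parameter container rejects the value.  σ = 0 is accepted as the
deterministic logistic limit, used by tests.

Sequencing is modelled as multinomial read sampling: on each retained
collection day a depth is drawn as Poisson(depth_mean) truncated at ≥ 1
(library-size variation without extra parameters), and reads are drawn
from the community composition.  Taxa are independent in the dynamics, so
the composition is closed by a passive residual slot: abundances are
mapped to x/(1 + Σx), with 1/(1 + Σx) absorbing "everything else".  This
keeps the multinomial well defined while preserving each taxon's marginal
dynamics up to a slowly varying factor; tests that compare fitted to
generating moments use the realized composition as the oracle, since the
composition factor (a few percent to ~15% depending on total community
mass) is what sequencing actually observes.  Scheduled days are dropped
independently with probability missing_fraction.

For inference the latent abundance is integrated out analytically:
gamma abundance + Poisson reads gives a negative-binomial marginal with
mean N_t·x̄ and shape β = 1/CV².  This is the assumed sequencing-noise
model (the standard gamma–Poisson convention in the macroecology
literature); a binomial read layer would be indistinguishable at the
depths and abundances considered here.

## Numerical integration

Euler–Maruyama under the Itô convention with default step
dt = min(τ, δt)/100.  A coarser step (τ/50) leaves a visible stationary
bias at σ = 1.5 (Kolmogorov–Smirnov distance ≈ 0.04 from the exact gamma
at n = 5000, against a pure-sampling floor of ≈ 0.012); at τ/100 the bias
is below that floor for all σ ≤ 1.5, which is why /100 is the default.
Steps that land at or below zero are reflected to a floor of 1e-12·K (the
true process is strictly positive; such events are rare at the σ values
used).  Gaussian increments are pre-generated in fixed-size numpy blocks
and consumed by either a numba kernel or a pure-numpy loop — the two
paths perform identical arithmetic in identical order, so results are
bit-identical with and without numba.  Ensembles are seeded through
`numpy.random.SeedSequence` spawning, one child stream per taxon, so
individual taxa are reproducible in isolation.

## Sampling-aware fitting

The NB log-likelihood is maximised in (log x̄, log β) with L-BFGS-B from
a 3×3 multiplicative grid of starts centred on the plug-in moments, with
the CV boxed to [0.01, 50]; fits pinned at the box are flagged censored
(constant counts drive the CV to the lower bound).  Observations are
sorted into a canonical order before summation so the fit is exactly
invariant to permuting the series.  The plug-in comparator uses
population (divide-by-n) moments, making it the exact infinite-depth
limit of the MLE.

## Sojourn statistics

Series are rescaled as y(t) = ln(x(t)/x̄) on days with non-zero counts;
the steady-state reference is the time average ȳ (mean of log, not log
of mean — for a gamma the two differ, and deviations are defined as
y − ȳ).  A sojourn trajectory is a maximal run of constant sign of
y − ȳ bounded on both sides by an observed crossing; runs touching
either end of the series are discarded, which also removes the
length-biased runs "in progress" at the boundaries and leaves interior
run lengths unbiased (for i.i.d. symmetric signs the interior run-length
law is exactly geometric 2^−T, one of the test oracles).

Gap rules for near-daily data: a sampling gap of up to max_gap_days
(default 2) is bridged when the sign matches on both sides; a sign change
across any gap longer than a day is an unobserved crossing and discards
the runs on both sides; a day dropped for a zero count always breaks the
series (the taxon's log-abundance there is unknown).  T counts
observations, not calendar days.  Exact ties y = ȳ terminate runs and
start none (measure-zero under continuous abundances).  Height is
H = max|y − ȳ| within the run; the integrated deviation (area) is
recorded alongside but not used by the headline analyses.  Above- and
below-mean trajectories are folded (multiplied by their sign) before
profiles are averaged.

Residence and return times are the presence/absence analogues — interior
runs of non-zero and zero counts — computed on all taxa, not only the
high-occupancy ones used for sojourns.

The scaling exponent α is the least-squares slope of ln(mean over
positions of the T-profile) against ln T, with a stratified bootstrap
over trajectories within each T class for the confidence interval.

## Null models and divergence

The gamma-i.i.d. null redraws abundances independently from the fitted
stationary gamma and pushes them through the same Poisson read sampling,
rescaling and run extraction as the data, so it differs from the data
only in temporal ordering.  The permutation null shuffles observed y
values over observed days (missing days stay missing), preserving the
marginal exactly.  Distributions are compared by KL(empirical ‖ null)
(Jensen–Shannon available by option) on the union support, after pooling
the null's upper 1% tail into one bin and placing pseudo-mass 1e-6 in
bins where the null is empty — so identical distributions give exactly
zero.  A calibration band is built by resampling the null against itself
at the empirical sample size; "exceeds band" means divergence >
null mean + 3 null sd.

## SLM predictions

Predictions are simulation-based: long SLM trajectories observed at δt
are pushed through the identical run-extraction machinery, which
guarantees internal consistency between prediction and measurement.  Two
closed forms anchor the simulations analytically: (i) τ ≪ δt gives the
geometric law p(T) → 2^−T, ⟨T⟩ → 2; (ii) σ → 0 gives a Gaussian AR(1)
in y with lag correlation e^(−δt/τ), whose sign-persistence is
P = 1/2 + arcsin(ρ)/π and mean run length 1/(1 − P) (matched by the
simulations within ~2% for σ ≤ 0.1).  The timescale fit is a grid search
minimising KL(target ‖ predicted); ties break toward smaller τ.
Candidate simulations use the same per-path observation span as the
target: shorter paths have noisier per-path baselines ȳ, which shortens
apparent runs and biases the fitted timescale upward (with mismatched
spans the criterion-scale recovery dropped from 20/20 to 14/20).
ASV-specific predictions evaluate the σ-curves at each taxon's fitted CV
through σ = 2CV²/(1 + CV²); the pooled-p(T) fit uses the
abundance-weighted median σ of the host's taxa.

## What the synthetic generator does and does not emulate

It reproduces: gamma-stationary single-taxon dynamics with heterogeneous
(K, σ) and shared τ, daily observation at finite depth with library-size
variation, compositional closure, and optional missing days.  It omits:
species interactions, demographic noise, within-day dynamics, read-level
artefacts (chimeras, contamination), and any non-stationarity
(perturbations, diet shifts).  Passing tests therefore demonstrate that
the measurement and inference machinery recovers known structure under
the SLM's assumptions — not that real gut communities satisfy those
assumptions.

## Regime caveats found during validation

Two expectations about the τ = δt, σ = 1 regime turn out not to hold for
the latent SLM, and are worth stating plainly because they shape what
the test suite asserts:

* **H–T coupling.**  The peak deviation H of an excursion is strongly
  rank-correlated with its duration (ρ ≈ 0.8 at τ = δt, σ = 1; ρ ≈ 0.4
  even in the τ ≪ δt limit, where H is the maximum of T exchangeable
  draws and necessarily grows with T).  The model's genuine scale-free
  prediction concerns the *mean* within-sojourn deviation, not the peak.
* **α at τ = δt.**  The mean-deviation exponent is α ≈ 0 only when
  within-sojourn observations are effectively exchangeable (τ ≪ δt,
  where simulations give |α| < 0.01 for Gaussian noise and ≈ −0.06 for
  the skewed log-gamma case).  At τ = δt, σ = 1 the log-abundance lag-1
  correlation is ≈ 0.75 — the effective log-space relaxation rate is
  (1 − σ/2)/τ, half the naive 1/τ, and deep below-mean excursions mix
  slower still — and the latent SLM gives α ≈ 0.39.  Adding the
  finite-depth observation layer attenuates but does not remove this
  (α ≈ 0.09–0.39 for mean counts 3–1000).

At finite depth, read noise also couples observed sojourn statistics to
abundance: rarer taxa have noisier y, hence more noise-driven crossings
and shorter apparent ⟨T⟩.  In communities whose retained taxa span mean
counts of ~10–100 this induces a positive ⟨T⟩–abundance rank correlation
(~0.7 at high precision) that is purely a measurement effect; analyses of
⟨T⟩ against abundance on real count data should be read with this in
mind, or restricted to taxa whose expected counts make read noise
subdominant.

## Problem sizes

Default analysis and test scales were chosen for single-CPU desk runs:
stationarity checks use 5000 thinned samples; MLE recovery uses 100
replicate series of 300 time points at depth 10⁴; α pools ~10⁵ sojourns
from 100 series of 5000 days; timescale recovery uses a ~4.5·10⁵-day
target (~5.6·10⁴ sojourns) and 1.35·10⁵ days per grid candidate;
divergence calibration uses 100 ten-taxon hosts of 150 days.

## Known limitations

Single-host, single-taxon inference only (no hierarchical pooling, no
compositional covariance corrections); the timescale fit assumes one τ
per host; divergence p-values are raw (no multiple-testing correction
across hosts); the analytic time-dependent sojourn theory of the SLM is
not implemented — predictions are Monte Carlo with the two closed-form
limits above as anchors.
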