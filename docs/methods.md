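# Methods

## The circuit and its mean-field theory

`ffgain` models a strictly feedforward two-population circuit inspired by
the electrosensory lateral-line lobe (ELL) of the weakly electric fish
*Apteronotus leptorhynchus*.  A population of `N` deep-pyramidal (DP)
leaky integrate-and-fire neurons receives a sensory bias `mu` plus
independent white noise of intensity `sigma`:

    tau_m dV_i/dt = -V_i + mu(t) + noise,        (spike at V_th, reset V_r,
                                                  refractory tau_r)

Their pooled spike train, filtered by a synaptic kernel `s` (a delayed
alpha function by default, a pure delay Dirac kernel for the
delay-linearization studies) and scaled by `tau_m G / N`, forms the
feedforward signal `f(t)` added to the drive of a superficial-pyramidal
(SP) LIF cell that receives the same sensory bias.  `G <= 0` is the net
(inhibitory) pathway strength; there is no recurrence and no feedback to
the DP population ("open-loop feedback").

Because the DP dynamics never depend on `f`, the stationary theory closes
in one step.  The single-neuron rate function is

* noise-free: `r(mu) = [tau_r + tau_m ln((V_r - mu)/(V_th - mu))]^{-1}`
  for `mu > V_th`, else 0 (strict onset: at `mu = V_th` the crossing time
  diverges);
* with noise: the Siegert/Tuckwell integral
  `r(mu) = [tau_r + tau_m * I]^{-1}`,
  `I = \int_{z_r}^{z_th} sqrt(pi) e^{z^2}(1 + erf z) dz`,
  `z_x = (V_x - mu)/sigma`.

The SP cell then fires at the single-neuron rate evaluated at the
*effective bias* `mu_eff = mu + tau_m G r_D(mu)` — the entire gain-control
phenomenology follows from the shape of `mu_eff(mu)`:

* `sigma = 0` (**subtractive**): the SP onset solves `mu_eff(mu) = V_th`
  and sits right of the DP onset; at large bias the horizontal shift
  approaches `tau_m |G| / tau_r`.
* `sigma > 0`, moderate `|G|` (**divisive**): noise linearizes the DP
  curve near onset, `r_D ~ C1 mu + C2`, so `mu_eff` is approximately
  linear with slope `1 + C1 tau_m G` and the SP gain is divisively scaled
  by that factor.
* `sigma > 0`, strong `|G|` (**non-monotonic**): `mu_eff` develops a
  maximum and a minimum where `r_D'(mu) = -1/(tau_m G)`.  Since `r_D'` is
  a single bell of height `gamma` (the maximum DP slope), the pair of
  extrema exists exactly when `gamma > 1/(tau_m |G|)`; the critical line
  of the phase diagram is `|G|_c = 1/(tau_m gamma)`.

A closed-loop comparison model (a single population inhibiting itself,
`nu = F(nu)` with `F` the Siegert rate at `mu + tau_m G nu`) is provided
as a foil: self-limiting feedback suppresses rates less than the open-loop
pathway, so the open-loop circuit is the stronger divisive controller.

## Default parameters

Unless stated otherwise (all times ms, voltages in resting-to-threshold
units): `tau_m = 10`, `tau_r = 1`, `V_th = 1`, `V_r = 0`, `tau_s = 5`,
`tau_d = 10`, `N = 500`.  Rates are carried internally in ms^-1 so that
`tau_m G r` is a dimensionless bias; serialized tables report Hz.  The ELL
module uses its own constants (below).

## Numerics

* **Siegert quadrature.**  The integrand is evaluated through the
  identity `e^{z^2}(1 + erf z) = erfcx(-z)` (scaled complementary error
  function), which never overflows for the `z` ranges of interest; naive
  `e^{z^2}` overflows already for `sigma ~ 0.1`.  Adaptive quadrature
  (`scipy.integrate.quad`) runs at `epsabs = 1e-12`, `epsrel = 1e-10`,
  and raises if the reported error is not small.  For
  `sigma < 1e-4` the quadrature is ill-conditioned and the code delegates
  to the noise-free formula, which is the exact limit.  For
  `z_th >= 26` (bias ~26 sigma below threshold) the rate underflows and 0
  is returned.
* **Rate derivative.**  Differentiating the rate integral gives the
  closed form `r'(mu) = sqrt(pi) tau_m r^2 / sigma * [erfcx(-z_th) -
  erfcx(-z_r)]`, used everywhere a slope is needed (gamma, extrema); it
  agrees with central finite differences to 1e-6 relative.
* **Scan range for the gradient bell.**  Extrema and gamma searches use a
  bias interval grown from `[V_r - 5 sigma, V_th + 5 sigma + 2]` until the
  gradient at both ends is below 1% of the interior peak.  The left tail
  decays like a Gaussian; the right tail only algebraically (~1/mu^2), so
  the interval grows geometrically on the right.
* **Extrema.**  Rather than blind grid bracketing — which can miss the
  closely spaced root pair just above the critical line — the solver uses
  the bell structure: if `1 + tau_m G gamma >= 0` there are no roots;
  otherwise exactly one root lies on each flank of the bell, each
  bracketed between a scan-range end and the bell's argmax and polished by
  Brent's method.  Classification (maximum first, then minimum) follows
  from the sign pattern of `d mu_eff / d mu`.
* **Closed-loop fixed point.**  Damped iteration
  `nu <- 0.5 nu + 0.5 F(nu)` from the `G = 0` rate, residual tolerance
  1e-12 ms^-1, at most 10^4 iterations.  `F` is monotone decreasing in
  `nu` for `G < 0`, and the damping makes the iteration contract in
  practice.
* **Onset linearization window.**  "Near onset" is operationalized as the
  bias interval where the DP rate lies between 2% and 40% of the
  saturation rate `1/tau_r`; `average_gain` fits its line where the rate
  lies between 10% and 60% of `1/tau_r` (the visually linear mid-range of
  the noisy f-I curves).  Both windows are exposed as arguments.

## The simulator

Euler–Maruyama with update
`V <- V + (dt/tau_m)(mu_t - V) + sigma sqrt(dt/tau_m) N(0,1)`; this noise
scaling makes the free-membrane stationary variance equal the
Ornstein–Uhlenbeck value `sigma^2 / 2`, which is pinned by a unit test and
fixes the convention relating `sigma` to the rate formulas.  Spikes are
registered at the end of the crossing step (no interpolation); the voltage
is clamped at `V_r` with input ignored for `tau_r`.  Initial potentials
are drawn uniformly on `[V_r, V_th)` so a noise-free population starts
desynchronized — otherwise all DP neurons would fire in lockstep and
`f(t)` would be a pulse train instead of a near-constant drive; with
`sigma = 0` random phases persist indefinitely, which is exactly what is
needed.

Because the circuit is feedforward, the run proceeds in two passes: the DP
population is integrated and its spikes binned on the `dt` grid; `f(t)` is
then the FFT convolution of the binned population spike train with the
discretized kernel, scaled by `tau_m G / N` (identical to depositing each
spike's kernel, at `O(n log n)` cost); finally the SP cell(s) integrate
`mu + zeta + f`.  The alpha kernel is sampled at bin centers, truncated at
`tau_d + 20 tau_s`, and renormalized to exactly unit mass, so every DP
spike delivers total charge `tau_m G / N` into `f`.

Noise is pre-generated in fixed 8192-step chunks by numpy's PCG64
generator (float32) and consumed by a numba-compiled stepper; the chunk
size is a constant of the implementation, so every run is bit-reproducible
from a single seed, from which per-population streams, initial conditions,
the stimulus realization, and per-grid-point sub-seeds are all derived
(`numpy.random.SeedSequence` mixing of `(seed, index)`).

**Step size.**  `dt = 0.05 ms` by default.  Euler integration of a
threshold system carries an `O(sqrt(dt))` crossing bias equivalent to a
small threshold shift `~ sigma sqrt(dt/tau_m)`; it is amplified by
`tau_m |G|` when it enters through the DP rate.  The acceptance-scale
theory/simulation comparisons therefore integrate noisy fixtures at
`dt = 0.0125 ms`, chosen by the step-halving rule (halve `dt` until rates
move by less than one standard error); noise-free fixtures keep 0.05 ms,
where the only discretization effect is `O(dt)` quantization.

**Rate errors.**  Empirical rates use post-transient spike counts; the
standard error is the across-neuron SEM where several neurons are
available and the Poisson error `sqrt(count)/T` for a single train.  When
a simulated rate is compared against a predicted one, the comparison width
is the larger of the empirical error and the Poisson error implied by the
*predicted* rate — on near-silent grid points the empirical error
collapses to zero on zero counts, and the theory-implied width is the
statistically meaningful one.

## Time-varying stimuli and delays

The fluctuating stimulus is `mu_hat(t) = mu + zeta(t)` with `zeta` white
Gaussian noise passed once (causally) through a 4th-order Butterworth
low-pass (default cutoff 100 Hz), mean-subtracted, and rescaled so its
empirical standard deviation equals `sigma_c` exactly.  Causal filtering
is the physically sensible choice; the rescaling pins `sigma_c` as
defined.  Within a run the same `zeta` drives every DP neuron and the SP
cell (common sensory input); intrinsic noises stay independent.

With a pure transmission delay (`s(t) = delta(t - tau_d)`), the inhibition
tracks `-zeta` late.  At `tau_d = 0` it cancels part of the common slow
fluctuation — the covariance `cov(f, zeta)` is negative and the
membrane-filtered variance of `mu_eff` is *below* that of `mu_hat`; with
growing delay the two decorrelate, `cov(f, zeta)` rises toward zero (with
a minor oscillatory component), and the effective drive fluctuates more
than the stimulus itself.  The extra variance lifts the SP rate around the
firing onset — delay-induced linearization of the f-I curve.  The
covariance is estimated empirically from one DP spike realization per scan
(the DP dynamics are independent of `tau_d`, so shifting the binned spike
train reproduces every delay from the same realization, removing
seed-to-seed scatter from the delay dependence); a transient of
`10 * max(tau_m, tau_d, 1/f_cutoff)` is discarded first.  No closed-form
covariance is implemented.

"Near onset" for the delay studies is the bias at which the mean effective
drive reaches threshold, `mu_eff(mu) = V_th` — the parameter-free location
of the fluctuation-driven firing regime.  Past that point the f-I curve
turns locally concave and extra variance no longer raises (and can
slightly lower) the rate, so operationalizations based on a fixed fraction
of the saturation rate land on the wrong side of the onset.

## The ELL application

The electric-fish application uses its standard constants throughout:
LIF constants `tau_m = 6 ms`, `tau_r = 0.8 ms`, `sigma = 0.01`;
afferent map `mu(E_AM) = mu_0 + A/(1 + e^{-k(E_AM - h)})` with
`mu_0 = -0.16`, `A = 2.31` (the lumped gain `tau_m G_aff r_max`; the
factors are never needed separately), `k = 3 cm/mV`, `h = 0`; decibel
scale `20 log10(E_AM / 2 mV/cm)`.  Three feedforward conventions generate
predicted SP curves: lesion (`G = 0`, parallel fibers removed), constant
control (`G = -0.65`, matching the large-amplitude behavior), and the ad
hoc sigmoid `G(E_AM) = 0.75 - 1.4/(1 + e^{-5 E_AM})`, which is net
excitatory below ~0.03 mV/cm and saturates to -0.65.  The default AM grid
is log-spaced over 0.01–20 mV/cm; the lower end sits below the sign change
of `G(E_AM)` so the lesion/control crossing is on-grid.  Baseline-rate
offsets of the experimental data are *not* added by default (they belong
to the recordings, not to the model); an optional argument can add one.
No experimental data points are fitted — the module is a forward model
evaluated at fixed reference constants.

## What the synthetic conditions do and do not show

All tests run on model-generated data at the circuit's own stated
conditions (`N = 500`, 20 s windows per grid point for simulation-backed
checks).  They validate the internal consistency of the theory and the
simulator — rate formulas against Monte-Carlo, regime boundaries against
bracketing scans, delay effects against their variance mechanism — under
homogeneous populations, white intrinsic noise, and a common scalar
stimulus.  They do not probe heterogeneous biases or noise intensities
across populations, conductance effects, frequency-dependent pathway
strength, or receptive-field structure, all of which shape real ELL
responses.

## Known limitations and edge behavior

* The non-monotonic machinery assumes the gradient bell is unimodal
  (true for the Siegert rate of this LIF); exotic parameter sets violating
  this would need the grid-scan fallback.
* Near the critical line the extremum pair collapses toward the bell's
  argmax; peak positions there are well-defined but no longer follow the
  deep-regime monotonicity trends (e.g. at `G = -2` the `sigma = 2` peak
  sits slightly right of the `sigma = 1` peak, while at `G = -3` the
  ordering is the expected one).
* `rate_stochastic` is exact only for white noise; colored intrinsic noise
  is out of scope (the *stimulus* may be colored — that is the point of
  the delay module — but it enters as a common signal, not as intrinsic
  noise).
* Euler integration has no threshold interpolation by design; very coarse
  `dt` biases rates low (see Step size above), and the `dt`-halving rule
  is the guard.
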