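# Methods

## Model

The subthreshold dynamics is the two-variable generalized integrate-and-fire
(GIF) resonator

```
tau_V dV/dt = -V - g w + I(t)
tau_w dw/dt =  V - w
```

with membrane time constant `tau_V` (ms), intrinsic-current time constant
`tau_w` (ms) and relative conductance `g` (dimensionless; `g > 0`
hyperpolarizing, `g < 0` depolarizing, `g <= -1` unstable).  Spikes are
upward crossings of a hard threshold `theta` (default 1) and the voltage is
**not** reset — the Gauss–Rice idealization.  The input is split into a
deterministic mean channel (weak sinusoid or step) and a zero-mean
Ornstein–Uhlenbeck (OU) noise channel with standard deviation `sigma_I` and
correlation time `tau_I`; the mean input offset is fixed at 0
(fluctuation-driven regime).  All internal times are in ms, angular
frequencies in rad/ms; the CLI reports ordinary frequencies in Hz and rates
in spikes/s.

Because the subthreshold system is linear and the drive Gaussian, the
stationary voltage is a Gaussian process and the population firing rate is
the upward level-crossing rate of the threshold:

```
nu_0 = (sigma_Vdot / sigma_V) exp(-theta^2 / (2 sigma_V^2)) / (2 pi),
```

equivalently `nu_0 tau_s = exp(-1/(2 sigma^2)) / (2 pi)` with
`sigma = sigma_V/theta` and the differential correlation time
`tau_s = sigma_V/sigma_Vdot`.  The linear rate response to a weak mean-channel
modulation is a cascade: the current-to-voltage filter (first-order zero at
`1/tau_w` over a second-order low pass with center `omega_L` and quality
`Q_L`) followed by a first-order spiking high pass `(1 + i omega tau_c)` with
`tau_c = sqrt(pi/2) sigma tau_s`:

```
nu_1(omega)/nu_0 = (1/(sigma^2 theta)) (1 + i omega tau_c) chi(omega),
chi(omega) = (1 + i omega tau_w) / (g + (1 + i omega tau_w)(1 + i omega tau_V)).
```

The *normative definition* of the dynamic gain in this package is
operational: the modulation depth of the population rate, relative to `nu_0`,
per unit amplitude of a cosine drive.  Every constant prefactor is pinned by
this definition and cross-validated against the ensemble simulator (vector
strength of spike phases), not taken from transcribed formula constants.

### Closed forms and their derivation route

* **Voltage spectrum.**  `S_V = |chi|^2 * 2 D/(1 + omega^2 tau_I^2)` with
  `D = tau_I sigma_I^2` and the convention
  `C(tau) = int (domega/2pi) S(omega) e^{i omega tau}`.  This compositional
  identity is treated as definitional.
* **Correlation function.**  Derived at run time by residues of the spectrum
  (three simple poles: `1/tau_I` and the eigenvalue pair `lambda_pm`), giving
  one component decaying with `tau_I` and one with the relaxation time
  `tau_r`, ringing at the intrinsic frequency `Omega = Im(lambda_+)` when it
  exists.  Proven in the tests against an FFT inverse of the spectrum to
  `1e-6 sigma_V^2`.
* **Variances.**  Explicit closed forms built from
  `alpha_w = (1 + tau_w/tau_eff)/(1 + tau_w/tau_V)` and
  `alpha_I = (1 + tau_I/tau_eff)/(1 + tau_I/tau_V)`, validated to `1e-8`
  against numerical quadrature of the spectrum.  Note `sigma_Vddot` does not
  exist: the spectrum decays as `omega^-4`, so `C` has an odd `|tau|^3` term
  at zero delay.  This is why second-derivative checks use one-sided stencils
  and why empirical derivative variances are compared against
  `(C(0) - C(2 dt))/(2 dt^2)` rather than the continuum limit.
* **Critical rate.**  The low/high-pass boundary `nu_inf = 1` (i.e.
  `tau_c = tau_eff`) is root-found by bisection; the rederived closed form
  `nu_crit = exp(-(pi/4) tau_s^2/tau_eff^2)/(2 pi tau_s)` is kept as an
  independent cross-check (agreement 1e-10).
* **Step response.**  Partial fractions of `G(s)/s`:
  `r(t) = A (c0 + sum_j c_j (e^{lambda_j t} - 1)/lambda_j)` for `t > 0`, with
  the exact identities `r(0+) = A theta tau_c/(sigma_V^2 tau_V)` and
  `r(inf) = A G(0)`.  The test oracle inverts
  `nu_1(omega) * (pi delta(omega) + 1/(i omega))` numerically, carrying the
  principal-value part and the slowly decaying `1/omega` tail in analytic
  bridge filters so the FFT only handles an absolutely integrable remainder.
* **EIF validity cut-off.**  `f_limit` is the numerical intersection of the
  flat Gauss–Rice high-frequency gain with the exponential
  integrate-and-fire `1/f` decay `nu_0/(Delta_T 2 pi f tau_V)`; it scales
  exactly as `1/Delta_T`.

### Degenerate parameters

Closed forms divide by `lambda_+ - lambda_-` and by pole differences such as
`lambda_pm + 1/tau_I`.  Eigenvalues within `1e-12` (relative) of critical
damping, or within `1e-9` of the input rate, are resolved by a relative
parameter perturbation of `1e-7` (in `g`, respectively `tau_I`); the
perturbation is flagged in the returned statistics.  `tau_w = tau_I` needs no
guard: the filter zero cancels the input pole and the residue vanishes
identically.  White noise (`tau_I = 0`) is rejected at construction — the
level-crossing rate is undefined for non-differentiable voltage correlation.

### Quality factor and relaxation time

`Q_L = omega_L tau_bar / 2` uses `tau_bar = 2 tau_V tau_w/(tau_V + tau_w)`,
which equals the relaxation time `-1/Re(lambda_pm)` whenever the eigenvalues
are complex (`Q_L > 1/2`); for real eigenvalues the no-reset validity monitor
uses the slow root `-1/lambda_+` instead.  Stability in shape coordinates is
`Q_L < omega_L tau_w`.  Voltage resonance is defined by the center-frequency
criterion (`|chi(omega_L)| > V_low`, i.e. `Q_L^2 (1 + (omega_L tau_w)^2) > 1`);
the interior-maximum search of `|chi|` is exposed separately
(`voltage_resonance_frequency`) and converges to `Omega` for
`omega_L tau_w >> 1`, `Omega tau_r >> 1`.

### Filter taxonomy

With gain normalized by its zero-frequency value, the response shape is fixed
by `(nu_inf, nu_omegaL, Q_L)` where `nu_inf = tau_c/tau_eff` and
`nu_omegaL = Q_L sqrt((1 + nu_inf xi)(1 + nu_inf/xi))`, `xi = tau_w/tau_c`.
The sign pattern of `(nu_omegaL - 1, nu_inf - 1, nu_omegaL - nu_inf)` yields
six feasible classes (two of the eight patterns are arithmetically
impossible); spiking resonance is `nu_omegaL > max(1, nu_inf)`.  Stability
maps to `Q_L^2 < xi nu_inf` and accessible shapes obey the arithmetic–
geometric-mean bound `nu_omegaL >= Q_L (1 + nu_inf)` with equality iff
`tau_w = tau_c`.  Region labels are exported as the sign triple plus a
descriptive string, since a purely numeric labeling is convention-dependent.

One refinement found during implementation: for any hyperpolarizing `g` the
slope of `tau_s^2` in `tau_w` at `tau_w = 0` is `-g tau_I/tau_V < 0`, so a
small initial dip always precedes the sigmoidal rise; the dip is negligible
(<1%) for `tau_eff/tau_I >> 1` and pronounced (>5%) for `tau_eff/tau_I < 1`.
The taxonomy statements above are unaffected.

## Simulator

The ensemble simulator draws one independent random stream per neuron from
`SeedSequence(seed).spawn(i)`, so results are bit-exact reproducible and
independent of how the ensemble is chunked.  The OU input uses its exact
one-step discretization (stationary start).  The default deterministic stage
propagates the linear `(V, w)` system with the exact matrix exponential over
each step, treating the noise as piecewise linear within the step; because
this update is a linear recurrence, it is evaluated as a second-order
recursive filter over the whole input sequence (`scipy.signal.lfilter`),
which integrates thousands of neuron-seconds per second on one core.  A
classical RK4 stage (`scheme="rk4"`) is retained and agrees pathwise with the
exact scheme to `<1e-6 sigma_V`; dt-robustness is additionally verified
through the discrete-time transfer function, whose stationary variance
matches the continuum to 3e-5 (relative) at the default step
`dt = min(tau_I, tau_eff, tau_w)/50`.

Spikes are linearly interpolated upward crossings of the sampled voltage; the
dynamics continues through threshold (no reset).  The exponential
integrate-and-fire (EIF) variant adds `Delta_T exp((V - V_T)/Delta_T)` inside
the `tau_V dV/dt` equation (exponent clipped at 30, with an immediate-spike
guard), registers spikes at a high numerical threshold `V_thr` and resets the
voltage to `V_reset` (0 by default; `w` is left unchanged, both exposed as
options because the reduction does not prescribe them).

Estimators: population rate and per-neuron voltage moments with
across-neuron standard errors; PSTHs in spikes/s with per-bin Poisson errors;
and the dynamic gain from the spike-phase resultant
`R = |<e^{-i omega t_m}>_m|`, which for a cosine drive of amplitude `A`
estimates the relative gain as `2R/A`.  The resultant is debiased for its
finite-sample floor (`R^2 -> R^2 - (1-R^2)/n`) and its standard error comes
from a seeded bootstrap over neurons (200 resamples).

Validity monitors (machine-parsable `VALIDITY:` lines) flag the regimes where
the no-reset idealization degrades: `nu_0 tau_s > 0.1` (spiking not sparse),
`tau_s/tau_I` outside `[0.3, 3]` (input correlation too far from the voltage
correlation) and `nu_0 tau_r > 0.1` (relaxation slow relative to the
inter-spike interval).

### What the simulations do and do not show

The simulator generates exactly the stochastic process the theory assumes —
linear subthreshold dynamics, additive OU noise, hard threshold.  Agreement
between the two therefore validates the derivations and the estimators, not
the biological realism of the reduction; the EIF comparison probes one step
of that realism (finite action-potential rise speed), bounding the usable
frequency range by `f_limit ∝ 1/Delta_T`.  Conductance noise, synaptic shot
noise, reset dynamics and network feedback are out of scope.

## Problem sizes used in the shipped checks

The default test suite and validation commands use the running resonator
example (`tau_V = 10 ms`, `tau_w = 20 ms`, `g = 3`, `tau_I = 1 ms`,
`theta = 1`) with the noise calibrated to `nu_0 tau_s = 0.01` (≈3.88
spikes/s).  Ensemble sizes were chosen to give standard errors a few times
smaller than the effects being tested while keeping the whole suite in the
minutes range on one core: 300 neurons × 10 s (dt = 5 µs·10³) for moments,
16 × 10 s for autocorrelation traces, 250 neurons × 12 s per probe frequency
for vector-strength gain (≈12,000 spikes each, amplitude 0.05), 12,000
neurons × 0.4 s for the step PSTH (step height 0.1), and 1200 neurons × 1.7 s
per EIF run (amplitude 0.2, probes at 10 and 150 Hz straddling the
`Delta_T = 0.35` cut-off of ≈54 Hz but not the `Delta_T = 0.035` one at
≈540 Hz).  The EIF numerical threshold is `V_thr = 3` for `Delta_T = 0.35`
and `1.15` for `0.035` — the slower action potential needs the higher
threshold for its rise speed to dominate the registered crossing — and `V_T`
is calibrated by a short secant iteration so both variants fire at the 2
spikes/s operating point.  Statistical comparisons use 3 standard errors
pointwise; the
40-bin PSTH comparison allows the single >3 SE excursion expected under the
model and requires all bins within 5 SE.

## Known limitations

* The mean channel is linear-response only; amplitudes above `0.2 theta`
  trigger a warning, and the rate's non-negativity is not enforced by the
  analytic prediction.
* Variance-channel (noise-amplitude) modulation is not implemented.
* The vector-strength phase is reported but its small-sample bias is not
  corrected (only the gain is debiased).
* The no-reset model is meaningful only inside the validity region flagged by
  the monitors; outside it the analytic rate and gain can deviate strongly
  from any reset model.
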