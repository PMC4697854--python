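# gifgain

Analytic dynamic gain of **Gauss–Rice generalized integrate-and-fire (GIF)
resonator neurons**, with a seeded stochastic ensemble simulator that
estimates every predicted quantity empirically.

## The problem

Many neurons are *resonators*: a slow intrinsic current (adaptation,
h-current, M-current …) couples to the membrane voltage and gives the cell a
frequency preference.  How that subthreshold preference shapes the
*population* response — the amplification or attenuation of each input
frequency in the ensemble firing rate, called the **dynamic gain** — is hard
to compute for two-variable models: the Fokker–Planck route is intractable.
This package implements the level-crossing (Gauss–Rice) route: drop the
after-spike voltage reset, so the voltage stays a Gaussian process, and
count spikes as upward threshold crossings.  The entire linear-response
theory then comes out in closed form, valid for all intrinsic time constants
and all input frequencies, and every formula can be checked against direct
simulation.

## The model and its response

```
tau_V dV/dt = -V - g w + I(t)        (membrane voltage)
tau_w dw/dt =  V - w                 (intrinsic current)
```

Spikes occur at upward crossings of a threshold `theta` (no reset).  The
input is a zero-mean Ornstein–Uhlenbeck noise (SD `sigma_I`, correlation
time `tau_I`) plus a weak deterministic signal.  Core results, all
implemented and cross-validated:

* stationary rate `nu_0 = (sigma_Vdot/sigma_V) e^{-theta^2/2 sigma_V^2}/(2 pi)`
  (Rice's crossing rate), bounded by `1/(2 pi tau_s)` with
  `tau_s = sigma_V/sigma_Vdot`;
* linear response as a filter cascade
  `nu_1(omega)/nu_0 = (1/(sigma^2 theta)) (1 + i omega tau_c) chi(omega)` —
  the current-to-voltage filter `chi` (zero at `1/tau_w`, second-order low
  pass with center `omega_L`, quality `Q_L`) followed by a spiking high pass
  with `tau_c = sqrt(pi/2) sigma tau_s`;
* the closed-form voltage autocorrelation (exponential component at `tau_I`
  plus a component ringing at the intrinsic frequency `Omega` inside an
  `e^{-|tau|/tau_r}` envelope), variances, step response, and the
  high/low-pass critical rate;
* the six-class taxonomy of gain shapes in `(nu_inf, nu_omegaL)` coordinates,
  with the accessibility bound `nu_omegaL >= Q_L (1 + nu_inf)`, and the
  double dissociation of voltage vs spiking resonance;
* the validity cut-off `f_limit ∝ 1/Delta_T` from comparison with an
  exponential integrate-and-fire (EIF) spike generator.

Units: times in ms, angular frequencies in rad/ms inside the library; the
CLI speaks Hz and spikes/s.

## Worked example

The running resonator example: `tau_V = 10 ms`, `tau_w = 20 ms`, `g = 3`
(hyperpolarizing, intrinsic frequency ≈ 19 Hz), OU input with
`tau_I = 1 ms`, noise calibrated to fire at 3.88 spikes/s:

```bash
gifgain gain --tau-v 10 --tau-w 20 --g 3 --tau-i 1 --rate 3.8836 --out gain.csv
```

prints

```
wrote gain.csv (200 frequencies), region: resonant low pass
```

and the JSON sidecar `gain.csv.json` contains the shape descriptors:

```
"nu_low": 1.3836,  "nu_inf": 0.5487,  "nu_omegaL": 2.8812,
"Q_L": 0.9428,     "omega_L_rad_per_ms": 0.14142,
"tau_c_ms": 1.3718, "tau_s_ms": 2.5750, "nu0_hz": 3.8836,
"region_label": "resonant low pass",
"spiking_resonant": true, "voltage_resonant": true,
"has_intrinsic_frequency": true
```

Reading: the zero-frequency gain is 1.38 per unit input amplitude; the
high-frequency plateau is a factor `nu_inf = 0.55` below it (overall low
pass), but the response at the center frequency (`omega_L/2pi ≈ 22.5 Hz`)
is `nu_omegaL = 2.88` times the low-frequency response — a spiking
resonance, here riding on a genuine voltage resonance and an intrinsic
frequency.  `gifgain simulate --amp 0.05 --freq-hz 20 --seed 1 ...` produces
a spike ensemble whose vector-strength gain reproduces the curve in
`gain.csv` within its standard error (this is exactly what
`gifgain validate gain --seed 1` and the test suite check).

Other entry points: `gifgain atlas` (machine-readable phase diagrams over
any 2-D parameter grid), `gifgain classify`, `gifgain step` (analytic step
response), `gifgain validate {corr,moments,gain,step,limits}`.

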