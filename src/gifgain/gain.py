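"""Spiking-side response theory of the Gauss-Rice GIF neuron.

With Gaussian voltage statistics and no reset, the stationary firing rate is
the upward level-crossing rate of the threshold (Rice's formula)::

    nu_0 = (1 / 2 pi) * (sigma_Vdot / sigma_V) * exp(-theta**2 / (2 sigma_V**2))

and the linear response of the population rate to a weak modulation of the
mean input is a first-order high-pass filter applied to the mean voltage
response::

    nu_1(omega) / nu_0 = (1 / (sigma**2 * theta)) * (1 + i omega tau_c) * transfer(omega)

with ``sigma = sigma_V / theta`` and the spiking characteristic time
``tau_c = sqrt(pi/2) * sigma * tau_s``.  The *dynamic gain* is the modulus of
this response: the measurable modulation depth of the population rate,
relative to the stationary rate, per unit input amplitude.  That operational
definition is normative here; every constant factor is fixed by it (and
cross-validated against ensemble simulations), not by transcribed prefactors.

Internally rates are in 1/ms (multiply by 1e3 for spikes/s) and angular
frequencies in rad/ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .params import NeuronParameters, classify_regime, eigenvalues, require_stable, to_filter_shape
from .subthreshold import InputModel, VoltageStatistics, is_voltage_resonant, tau_s as _tau_s, voltage_moments, voltage_transfer

__all__ = [
    "GainDescriptors",
    "ResponseCurve",
    "ShapeClassification",
    "stationary_rate",
    "max_rate",
    "sigma_I_for_rate",
    "tau_c",
    "linear_response",
    "linear_response_biquad",
    "dynamic_gain",
    "critical_rate",
    "critical_rate_closed_form",
    "classify_shape",
    "step_response",
    "eif_high_frequency_gain",
    "f_limit",
]


@dataclass(frozen=True)
class GainDescriptors:
    """Shape descriptors of a spiking response curve.

    ``nu_low``/``nu_high`` are the zero- and infinite-frequency limits of the
    relative gain (per unit input amplitude, 1/voltage); ``nu_inf`` and
    ``nu_omegaL`` are the high-frequency and center-frequency responses
    relative to the low-frequency one; ``xi = tau_w / tau_c``.
    """

    nu_low: float
    nu_high: float
    nu_inf: float
    nu_omegaL: float
    xi: float
    tau_c: float
    tau_s: float
    sigma: float
    nu0: float
    Q_L: float
    omega_L: float


@dataclass(frozen=True)
class ResponseCurve:
    """Complex linear rate response sampled on a frequency grid.

    ``response`` is ``nu_1(omega)/nu_0`` per unit input amplitude; ``gain``
    its modulus and ``phase`` its argument in ``(-pi, pi]`` (positive phase =
    response leads the input).
    """

    freq_hz: np.ndarray
    response: np.ndarray
    descriptors: GainDescriptors

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.response)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.response)


@dataclass(frozen=True)
class ShapeClassification:
    """One of the six feasible filter classes plus resonance flags.

    ``region`` is the sign triple ``(sign(nu_omegaL - 1), sign(nu_inf - 1),
    sign(nu_omegaL - nu_inf))``; exactly six of the eight patterns are
    arithmetically feasible.
    """

    region: tuple[int, int, int]
    label: str
    spiking_resonant: bool
    pass_type: str
    accessible: bool
    voltage_resonant: bool
    has_intrinsic_frequency: bool


_REGION_LABELS = {
    (1, 1, 1): "resonant high pass",
    (1, -1, 1): "resonant low pass",
    (1, 1, -1): "high pass with shoulder",
    (-1, 1, -1): "high pass with dip",
    (-1, -1, -1): "low pass with dip",
    (-1, -1, 1): "low pass with shoulder",
}


def stationary_rate(p: NeuronParameters, inp: InputModel) -> float:
    """Stationary population firing rate (1/ms) from Rice's crossing formula.

    ``nu_0 = (sigma_Vdot / sigma_V) exp(-theta**2/(2 sigma_V**2)) / (2 pi)``
    with zero mean input.  Monotone increasing in ``sigma_I`` and bounded by
    ``1/(2 pi tau_s)``; zero noise gives rate zero.
    """
    require_stable(p)
    if inp.sigma_I == 0:
        return 0.0
    st = voltage_moments(p, inp)
    return (
        st.sigma_Vdot / st.sigma_V / (2.0 * math.pi)
        * math.exp(-p.theta**2 / (2.0 * st.sigma_V**2))
    )


def max_rate(p: NeuronParameters, inp_or_tau_I) -> float:
    """Supremum ``1/(2 pi tau_s)`` of achievable stationary rates (1/ms)."""
    tau_I = inp_or_tau_I.tau_I if isinstance(inp_or_tau_I, InputModel) else float(inp_or_tau_I)
    ts = _tau_s(p, InputModel(tau_I=tau_I, sigma_I=1.0))
    return 1.0 / (2.0 * math.pi * ts)


def sigma_I_for_rate(p: NeuronParameters, tau_I: float, nu_target: float) -> float:
    """Input noise amplitude that yields the stationary rate ``nu_target`` (1/ms).

    Inverts the Rice rate for the relative fluctuation ``sigma`` and rescales
    through the linear map ``sigma_V proportional to sigma_I``.  Rates at or
    above the Gauss-neuron bound ``1/(2 pi tau_s)`` are forbidden.
    """
    ts = _tau_s(p, InputModel(tau_I=tau_I, sigma_I=1.0))
    bound = 1.0 / (2.0 * math.pi * ts)
    if not (0.0 < nu_target < bound):
        raise ValueError(
            f"forbidden rate: nu_target={nu_target} /ms outside (0, 1/(2 pi tau_s)) "
            f"= (0, {bound:.6g}) /ms"
        )
    # nu0 * tau_s = exp(-1/(2 sigma^2)) / (2 pi)  =>  sigma
    sigma = math.sqrt(-0.5 / math.log(2.0 * math.pi * nu_target * ts))
    unit = voltage_moments(p, InputModel(tau_I=tau_I, sigma_I=1.0)).sigma_V
    return sigma * p.theta / unit


def tau_c(p: NeuronParameters, inp: InputModel) -> float:
    """Characteristic time of the voltage-to-rate high-pass filter (ms).

    ``tau_c = sqrt(pi/2) * sigma * tau_s`` with ``sigma = sigma_V/theta``;
    equivalently ``sigma**-2 = (pi/2) tau_s**2 / tau_c**2``.  Grows with the
    noise level and hence with the stationary rate.
    """
    st = voltage_moments(p, inp)
    return math.sqrt(math.pi / 2.0) * st.sigma_rel * st.tau_s


def linear_response(p: NeuronParameters, inp: InputModel, omega) -> np.ndarray:
    """Relative complex linear response ``nu_1(omega)/nu_0`` per unit amplitude.

    The analytic prediction for the population rate under a weak mean-channel
    oscillation ``A cos(omega t)``::

        nu(t) ~= nu_0 * (1 + A * Re[G(omega) e^{i omega t}])

    where ``G`` is the returned value: modulation depth ``A |G|`` and phase
    lead ``arg G``.  Units 1/voltage.
    """
    st = voltage_moments(p, inp)
    tc = math.sqrt(math.pi / 2.0) * st.sigma_rel * st.tau_s
    w = np.asarray(omega, dtype=float)
    return (
        (1.0 / st.sigma_rel**2)
        * (1.0 + 1j * w * tc)
        * voltage_transfer(p, w)
        / p.theta
    )


def linear_response_biquad(p: NeuronParameters, inp: InputModel, omega) -> np.ndarray:
    """Shape-parameter (biquad cascade) form of the relative linear response.

    ``nu_low * (1 + i nu_inf xi w/wL)(1 + i w tau_w) / (1 - w^2/wL^2 +
    i w/(Q_L wL))`` rewritten via ``(nu_inf/xi) = (omega_L tau_c)**2``;
    algebraically identical to :func:`linear_response`.
    """
    d = descriptors(p, inp)
    f = to_filter_shape(p)
    w = np.asarray(omega, dtype=float)
    wn = w / f.omega_L
    num = (1.0 + 1j * wn * math.sqrt(d.nu_inf * d.xi)) * (
        1.0 + 1j * wn * math.sqrt(d.nu_inf / d.xi)
    )
    den = 1.0 - wn**2 + 1j * wn / f.Q_L
    return d.nu_low * num / den


def descriptors(p: NeuronParameters, inp: InputModel) -> GainDescriptors:
    """Shape descriptors of the relative linear response for this drive."""
    st = voltage_moments(p, inp)
    f = to_filter_shape(p)
    tc = math.sqrt(math.pi / 2.0) * st.sigma_rel * st.tau_s
    nu0 = stationary_rate(p, inp)
    nu_low = (1.0 / st.sigma_rel**2) * f.V_low / p.theta
    nu_high = (1.0 / st.sigma_rel**2) * (tc / p.tau_V) / p.theta
    nu_inf = tc / f.tau_eff
    xi = p.tau_w / tc
    nu_omegaL = f.Q_L * math.sqrt((1.0 + nu_inf * xi) * (1.0 + nu_inf / xi))
    return GainDescriptors(
        nu_low=nu_low,
        nu_high=nu_high,
        nu_inf=nu_inf,
        nu_omegaL=nu_omegaL,
        xi=xi,
        tau_c=tc,
        tau_s=st.tau_s,
        sigma=st.sigma_rel,
        nu0=nu0,
        Q_L=f.Q_L,
        omega_L=f.omega_L,
    )


def dynamic_gain(p: NeuronParameters, inp: InputModel, freq_grid_hz) -> ResponseCurve:
    """Dynamic gain and phase on a grid of ordinary frequencies (Hz)."""
    freq = np.asarray(freq_grid_hz, dtype=float)
    if freq.ndim != 1 or np.any(freq < 0) or np.any(np.diff(freq) <= 0):
        raise ValueError("frequency grid must be 1-D, non-negative and strictly increasing")
    omega = 2.0 * math.pi * freq / 1000.0  # Hz -> rad/ms
    resp = linear_response(p, inp, omega)
    return ResponseCurve(freq_hz=freq, response=resp, descriptors=descriptors(p, inp))


def critical_rate_closed_form(p: NeuronParameters, tau_I: float) -> float:
    """Closed-form critical rate (1/ms) separating low- from high-pass gain.

    ``tau_c = tau_eff`` gives ``sigma_crit**-2 = (pi/2) tau_s**2/tau_eff**2``,
    hence ``nu_crit = exp(-(pi/4) tau_s**2/tau_eff**2) / (2 pi tau_s)``.
    """
    ts = _tau_s(p, InputModel(tau_I=tau_I, sigma_I=1.0))
    return math.exp(-(math.pi / 4.0) * ts**2 / p.tau_eff**2) / (2.0 * math.pi * ts)


def critical_rate(p: NeuronParameters, tau_I: float) -> float:
    """Stationary rate (1/ms) at which ``nu_inf = 1`` (``tau_c = tau_eff``).

    Found by bisection of ``tau_c(nu_0) - tau_eff`` on the admissible rate
    interval; the gain is high pass above and low pass below.  ``tau_c`` is
    increasing in ``nu_0`` and spans ``(0, inf)`` over the admissible rates,
    so the root always exists for stable parameters.
    """
    require_stable(p)
    ts = _tau_s(p, InputModel(tau_I=tau_I, sigma_I=1.0))
    bound = 1.0 / (2.0 * math.pi * ts)

    def h(nu0: float) -> float:
        # tau_c as a function of rate: sigma from the Rice relation
        sigma = math.sqrt(-0.5 / math.log(2.0 * math.pi * nu0 * ts))
        return math.sqrt(math.pi / 2.0) * sigma * ts - p.tau_eff

    lo, hi = bound * 1e-300, bound * (1.0 - 1e-15)
    root = optimize.brentq(h, lo, hi, xtol=1e-300, rtol=1e-14)
    return float(root)


def classify_shape(
    desc: GainDescriptors, p: NeuronParameters
) -> ShapeClassification:
    """Classify the filter shape from its descriptors.

    The region is the sign pattern of ``(nu_omegaL - 1, nu_inf - 1,
    nu_omegaL - nu_inf)``; spiking resonance means an elevated center response
    that also exceeds the high-frequency plateau.  Accessibility encodes the
    stability constraint ``Q_L**2 < xi * nu_inf`` (equivalent to
    ``Q_L < omega_L tau_w``) together with the lower bound
    ``nu_omegaL >= Q_L (1 + nu_inf)``.
    """
    s1 = 1 if desc.nu_omegaL > 1.0 else -1
    s2 = 1 if desc.nu_inf > 1.0 else -1
    s3 = 1 if desc.nu_omegaL > desc.nu_inf else -1
    region = (s1, s2, s3)
    if region not in _REGION_LABELS:
        raise RuntimeError(f"infeasible filter sign pattern {region}; internal inconsistency")
    regime = classify_regime(p)
    return ShapeClassification(
        region=region,
        label=_REGION_LABELS[region],
        spiking_resonant=(s1 == 1 and s3 == 1),
        pass_type="high" if s2 == 1 else "low",
        accessible=(
            desc.Q_L**2 < desc.xi * desc.nu_inf
            and desc.nu_omegaL >= desc.Q_L * (1.0 + desc.nu_inf) * (1.0 - 1e-12)
        ),
        voltage_resonant=is_voltage_resonant(p),
        has_intrinsic_frequency=regime.has_intrinsic_frequency,
    )


def step_response(p: NeuronParameters, inp: InputModel, A: float, t_grid) -> np.ndarray:
    """Relative rate deviation ``(nu(t) - nu_0)/nu_0`` after a mean-input step.

    The step of height ``A`` switches on at ``t = 0``.  The closed form is the
    partial-fraction inverse transform of ``G(omega)/(i omega)``: writing
    ``G(s=i omega) = c0 + sum_j c_j/(s - lambda_j)``,

    ``r(t) = A * (c0 + sum_j c_j (exp(lambda_j t) - 1)/lambda_j)`` for t > 0.

    The instantaneous jump at ``0+`` is ``A*c0 = A theta tau_c/(sigma_V**2
    tau_V)`` and the asymptote is the zero-frequency gain times ``A`` (an
    exact identity).  When an intrinsic frequency exists the relaxation rings
    at ``Omega`` inside the envelope ``exp(-t/tau_r)``.
    """
    st = voltage_moments(p, inp)
    tc = math.sqrt(math.pi / 2.0) * st.sigma_rel * st.tau_s
    lam_p, lam_m = eigenvalues(p)
    pref = p.theta / (st.sigma_V**2 * p.tau_V * p.tau_w)
    c0 = p.theta * tc / (st.sigma_V**2 * p.tau_V)
    t = np.asarray(t_grid, dtype=float)
    out = np.zeros(t.shape, dtype=complex)
    pos = t > 0
    tp = t[pos]
    acc = np.full(tp.shape, c0, dtype=complex)
    for lam, other in ((lam_p, lam_m), (lam_m, lam_p)):
        c_j = pref * (1.0 + lam * tc) * (1.0 + lam * p.tau_w) / (lam - other)
        acc = acc + c_j * (np.exp(lam * tp) - 1.0) / lam
    out[pos] = acc
    return A * np.real(out)


def eif_high_frequency_gain(p: NeuronParameters, Delta_T: float, freq_hz) -> np.ndarray:
    """High-frequency relative gain of the exponential integrate-and-fire model.

    ``|nu_1|/nu_0 ~ 1/(Delta_T * 2 pi f tau_V)`` per unit input amplitude:
    the finite rise speed of the action potential turns the flat hard-
    threshold plateau into a ``1/f`` decay.
    """
    f_per_ms = np.asarray(freq_hz, dtype=float) / 1000.0
    return 1.0 / (Delta_T * 2.0 * math.pi * f_per_ms * p.tau_V)


def f_limit(p: NeuronParameters, inp: InputModel, Delta_T: float) -> float:
    """Validity cut-off (Hz) of the hard-threshold response.

    The frequency where the flat Gauss-Rice high-frequency gain intersects the
    EIF ``1/f`` decay, solved numerically from the two implemented limits;
    scales as ``1/Delta_T``.  Warns when the cut-off falls below the center
    frequency, i.e. when the resonant structure itself is not protected.
    """
    if not (Delta_T > 0):
        raise ValueError(f"spike slope factor must be positive, got Delta_T={Delta_T}")
    d = descriptors(p, inp)

    def h(log_f: float) -> float:
        f = math.exp(log_f)
        return math.log(d.nu_high) - math.log(eif_high_frequency_gain(p, Delta_T, f))

    root = optimize.brentq(h, math.log(1e-9), math.log(1e12), rtol=1e-14)
    f_hz = math.exp(root)
    f_center_hz = d.omega_L / (2.0 * math.pi) * 1000.0
    if f_hz < f_center_hz:
        warnings.warn(
            f"resonance not protected: f_limit={f_hz:.3g} Hz lies below the "
            f"center frequency {f_center_hz:.3g} Hz",
            stacklevel=2,
        )
    return f_hz
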