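"""Subthreshold voltage statistics of the GIF resonator driven by colored noise.

The input is split into a deterministic mean channel (a weak sinusoid or a
step) and a zero-mean Ornstein-Uhlenbeck (OU) noise channel with standard
deviation ``sigma_I`` and correlation time ``tau_I``.  This module provides

* the current-to-voltage transfer function in all three parameter
  representations,
* the voltage resonance criterion and resonance-frequency search,
* the two-sided voltage power spectrum and its closed-form inverse transform,
  the voltage autocorrelation function,
* the voltage variance, the variance of the voltage derivative, and the
  differential correlation time ``tau_s = sigma_V / sigma_Vdot``.

Fourier convention: ``V(omega) = int V(t) exp(-i omega t) dt`` with two-sided
spectra and ``C(tau) = int (domega/2pi) S(omega) exp(i omega tau)``.  All
constant factors are fixed by the compositional identity
``S_V = |transfer|**2 * S_I`` together with ``int (domega/2pi) S_I = sigma_I**2``.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Union

import numpy as np
from scipy import optimize

from .params import (
    DEGENERACY_PERTURBATION,
    NeuronParameters,
    eigenvalues,
    require_stable,
    to_filter_shape,
    to_implicit,
)

__all__ = [
    "Sinusoid",
    "Step",
    "InputModel",
    "VoltageStatistics",
    "voltage_transfer",
    "center_gain_ratio",
    "gamma_factor",
    "is_voltage_resonant",
    "voltage_resonance_frequency",
    "ou_spectrum",
    "voltage_spectrum",
    "correlation_function",
    "voltage_moments",
    "tau_s",
    "tau_s_implicit",
]

#: linear-response use of the mean channel warns above this amplitude/theta
LINEAR_AMPLITUDE_WARN = 0.2


@dataclass(frozen=True)
class Sinusoid:
    """Mean-channel oscillation ``A * cos(omega * t)`` (``omega`` in rad/ms)."""

    amplitude: float
    omega: float


@dataclass(frozen=True)
class Step:
    """Mean-channel step of the given height switched on at ``onset`` (ms)."""

    height: float
    onset: float = 0.0


@dataclass(frozen=True)
class InputModel:
    """OU noise channel plus an optional deterministic mean-channel signal.

    Parameters
    ----------
    tau_I : float
        OU correlation time in ms.  Must be strictly positive: white noise
        makes the voltage correlation non-differentiable at zero delay, and
        the level-crossing construction of the firing rate is then undefined.
    sigma_I : float
        OU standard deviation in voltage units (>= 0).
    signal : Sinusoid | Step | None
        Deterministic mean-channel signal; the mean input offset is fixed to 0
        (fluctuation-driven regime).
    """

    tau_I: float
    sigma_I: float
    signal: Optional[Union[Sinusoid, Step]] = None

    def __post_init__(self) -> None:
        if not (self.tau_I > 0):
            raise ValueError(
                f"white-noise input rejected: OU correlation time must satisfy "
                f"tau_I > 0, got tau_I={self.tau_I}"
            )
        if self.sigma_I < 0:
            raise ValueError(f"noise amplitude must be non-negative, got {self.sigma_I}")

    @property
    def D(self) -> float:
        """Noise strength ``D = tau_I * sigma_I**2``."""
        return self.tau_I * self.sigma_I**2

    def check_linear(self, theta: float) -> None:
        """Warn when the mean-channel amplitude is too large for linear response."""
        amp = None
        if isinstance(self.signal, Sinusoid):
            amp = abs(self.signal.amplitude)
        elif isinstance(self.signal, Step):
            amp = abs(self.signal.height)
        if amp is not None and amp / theta > LINEAR_AMPLITUDE_WARN:
            warnings.warn(
                f"signal amplitude {amp} exceeds {LINEAR_AMPLITUDE_WARN}*theta; "
                "linear-response predictions may be inaccurate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class VoltageStatistics:
    """Stationary Gaussian statistics of the subthreshold voltage.

    ``correlation`` is the closed-form autocorrelation ``C_V(tau)`` (tau in
    ms), even in its argument, with ``C_V(0) = sigma_V**2`` and
    ``-C_V''(0) = sigma_Vdot**2``.  ``alpha_w`` and ``alpha_I`` are the
    auxiliary conductance ratios entering the variance closed forms.
    """

    sigma_V: float
    sigma_Vdot: float
    tau_s: float
    sigma_rel: float
    correlation: Callable[[np.ndarray], np.ndarray]
    alpha_w: float
    alpha_I: float
    perturbed: bool = False

    @property
    def sigma_V2(self) -> float:
        return self.sigma_V**2

    @property
    def sigma_Vdot2(self) -> float:
        return self.sigma_Vdot**2


# ---------------------------------------------------------------------------
# Transfer function


def voltage_transfer(p: NeuronParameters, omega, form: str = "explicit"):
    """Complex current-to-voltage transfer function (dimensionless).

    ``(1 + i omega tau_w) / (g + (1 + i omega tau_w)(1 + i omega tau_V))``
    evaluated in the requested representation (``explicit``, ``implicit`` or
    ``shape``); all three agree to rounding.  Hermitian in ``omega``: the
    value at ``-omega`` is the complex conjugate.
    """
    require_stable(p)
    w = np.asarray(omega, dtype=float)
    iw = 1j * w
    if form == "explicit":
        return (1.0 + iw * p.tau_w) / (p.g + (1.0 + iw * p.tau_w) * (1.0 + iw * p.tau_V))
    if form == "implicit":
        # denominator (i w - lambda_+)(i w - lambda_-); for a complex pair this
        # is Omega**2 + (r - i w)**2 with r = -1/tau_r
        lam_p, lam_m = eigenvalues(p)
        return (1.0 + iw * p.tau_w) / (
            p.tau_V * p.tau_w * (iw - lam_p) * (iw - lam_m)
        )
    if form == "shape":
        f = to_filter_shape(p)
        return f.V_low * (1.0 + iw * p.tau_w) / (
            1.0 - w**2 / f.omega_L**2 + iw / (f.Q_L * f.omega_L)
        )
    raise ValueError(f"unknown transfer form {form!r}")


def center_gain_ratio(Q_L: float, omega_L_tau_w: float) -> float:
    """Voltage gain at the center frequency relative to the zero-frequency gain.

    Evaluated directly from the shape-form transfer at ``omega = omega_L``;
    this formula is meaningful for any positive ``(Q_L, omega_L*tau_w)``,
    including shapes with no stable explicit realization.  The ratio exceeds 1
    exactly when the filter is voltage resonant at its center frequency.
    """
    if not (Q_L > 0 and omega_L_tau_w > 0):
        raise ValueError("Q_L and omega_L*tau_w must be positive")
    # shape form at omega = omega_L: (1 + i x) / (1 - 1 + i/Q_L)
    return abs((1.0 + 1j * omega_L_tau_w) / (1j / Q_L))


def gamma_factor(Q_L: float) -> float:
    """Splitting factor of an overdamped second-order low pass.

    For ``Q_L <= 1/2`` the low-pass gain factors into two first-order poles at
    ``omega_L/gamma`` and ``gamma*omega_L`` where ``gamma >= 1`` solves
    ``Q_L = gamma / (gamma**2 + 1)``.
    """
    if not (0 < Q_L <= 0.5):
        raise ValueError(
            f"low pass does not factorize: gamma is defined for 0 < Q_L <= 1/2, got {Q_L}"
        )
    return (1.0 + math.sqrt(1.0 - 4.0 * Q_L**2)) / (2.0 * Q_L)


def is_voltage_resonant(p: NeuronParameters) -> bool:
    """True iff the voltage gain at ``omega_L`` exceeds the zero-frequency gain.

    Equivalent to ``Q_L**2 * (1 + (omega_L tau_w)**2) > 1``.
    """
    f = to_filter_shape(p)
    return center_gain_ratio(f.Q_L, f.omega_L * f.tau_w) > 1.0


def voltage_resonance_frequency(p: NeuronParameters) -> Optional[float]:
    """Location (rad/ms) of the interior maximum of the voltage gain, if any.

    A log-spaced bracket over ``[1e-3/tau_V, 1e3/tau_V]`` locates the maximum
    of ``|transfer|``, which is then refined to ~1e-10 relative accuracy.
    Returns ``None`` when the gain is maximal at zero frequency (no
    resonance).  Ties are broken toward the lower frequency by the bracketing
    scan.
    """
    require_stable(p)
    grid = np.logspace(-3, 3, 400) / p.tau_V
    gain = np.abs(voltage_transfer(p, grid))
    g0 = abs(voltage_transfer(p, 0.0))
    k = int(np.argmax(gain))
    if gain[k] <= g0 or k == 0 or k == len(grid) - 1:
        return None
    lo, hi = grid[k - 1], grid[k + 1]
    res = optimize.minimize_scalar(
        lambda w: -abs(voltage_transfer(p, w)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * grid[k]},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Spectrum and correlation function


def ou_spectrum(inp: InputModel, omega) -> np.ndarray:
    """Two-sided OU power spectral density ``2 D / (1 + omega**2 tau_I**2)``."""
    w = np.asarray(omega, dtype=float)
    return 2.0 * inp.D / (1.0 + (w * inp.tau_I) ** 2)


def voltage_spectrum(p: NeuronParameters, inp: InputModel, omega) -> np.ndarray:
    """Two-sided voltage power spectrum ``|transfer|**2 * S_I`` (voltage^2 * ms).

    Integrating ``d omega / (2 pi)`` over the real line recovers
    ``sigma_V**2``.  Decays as ``omega**-4`` at high frequency.
    """
    return np.abs(voltage_transfer(p, omega)) ** 2 * ou_spectrum(inp, omega)


def _safe_parameters(
    p: NeuronParameters, inp: InputModel
) -> tuple[NeuronParameters, InputModel, bool]:
    """Perturb parameters away from removable pole collisions.

    The partial-fraction expansion of the voltage spectrum has simple poles at
    ``1/tau_I`` and ``-lambda_pm``; if a model eigenvalue (numerically)
    coincides with the input rate ``-1/tau_I`` the input correlation time is
    perturbed by a relative :data:`DEGENERACY_PERTURBATION`.  Coincident
    eigenvalues themselves are already resolved inside ``eigenvalues``.
    """
    lam_p, lam_m = eigenvalues(p)
    perturbed = False
    tau_I = inp.tau_I
    for _ in range(4):
        rate = -1.0 / tau_I
        if (
            abs(lam_p - rate) > 1e-9 * abs(rate)
            and abs(lam_m - rate) > 1e-9 * abs(rate)
        ):
            break
        tau_I *= 1.0 + DEGENERACY_PERTURBATION
        perturbed = True
    if perturbed:
        inp = replace(inp, tau_I=tau_I)
    return p, inp, perturbed


def _correlation_components(
    p: NeuronParameters, inp: InputModel
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Residue expansion of the voltage autocorrelation.

    Returns ``(amplitudes, rates, perturbed)`` such that for ``tau >= 0``
    ``C_V(tau) = Re sum_k amplitudes[k] * exp(rates[k] * tau)`` with rates
    ``{-1/tau_I, lambda_+, lambda_-}``.  Obtained by closing the inverse
    Fourier integral of the spectrum in the upper half plane; every pole is
    simple after the degeneracy guard.
    """
    p, inp, perturbed = _safe_parameters(p, inp)
    lam_p, lam_m = eigenvalues(p)
    tau_I, tau_V, tau_w = inp.tau_I, p.tau_V, p.tau_w
    K = 2.0 * tau_I * inp.sigma_I**2 / (tau_V**2 * tau_w**2)

    def numerator(w: complex) -> complex:
        return 1.0 + (w * tau_w) ** 2

    def factors(w: complex) -> list[complex]:
        return [
            1.0 + 1j * w * tau_I,
            1.0 - 1j * w * tau_I,
            1j * w - lam_p,
            1j * w - lam_m,
            -1j * w - lam_p,
            -1j * w - lam_m,
        ]

    derivs = [1j * tau_I, -1j * tau_I, 1j, 1j, -1j, -1j]
    poles = [1j / tau_I, -1j * lam_p, -1j * lam_m]  # upper half plane
    pole_factor = [0, 2, 3]  # which factor vanishes at each pole

    amps, rates = [], []
    for w0, j in zip(poles, pole_factor):
        fs = factors(w0)
        denom = derivs[j]
        for k, f in enumerate(fs):
            if k != j:
                denom *= f
        residue = K * numerator(w0) / denom
        amps.append(1j * residue)  # C = i * sum(residues * e^{i w0 tau})
        rates.append(1j * w0)  # e^{i w0 tau} = e^{rate * tau}
    return np.array(amps, dtype=complex), np.array(rates, dtype=complex), perturbed


def correlation_function(
    p: NeuronParameters, inp: InputModel
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form voltage autocorrelation ``C_V(tau)`` (voltage^2), tau in ms.

    One exponential component decays with the input correlation time
    ``tau_I``; the other carries the envelope ``exp(-|tau|/tau_r)`` and, when
    an intrinsic frequency exists, rings at ``Omega``.  The returned callable
    is even in ``tau`` and vectorized; its residue components are exposed as
    the attributes ``amplitudes`` and ``rates``.
    """
    amps, rates, perturbed = _correlation_components(p, inp)

    def corr(tau):
        t = np.abs(np.asarray(tau, dtype=float))
        return np.real(np.exp(np.multiply.outer(t, rates)) @ amps)

    corr.amplitudes = amps  # type: ignore[attr-defined]
    corr.rates = rates  # type: ignore[attr-defined]
    corr.perturbed = perturbed  # type: ignore[attr-defined]
    return corr


# ---------------------------------------------------------------------------
# Variances, tau_s


def _alphas(p: NeuronParameters, inp: InputModel) -> tuple[float, float]:
    tau_eff = p.tau_eff
    alpha_w = (1.0 + p.tau_w / tau_eff) / (1.0 + p.tau_w / p.tau_V)
    alpha_I = (1.0 + inp.tau_I / tau_eff) / (1.0 + inp.tau_I / p.tau_V)
    return alpha_w, alpha_I


def voltage_moments(p: NeuronParameters, inp: InputModel) -> VoltageStatistics:
    """Stationary voltage statistics from the closed-form variances.

    ``sigma_V**2`` and ``sigma_Vdot**2`` are the explicit-representation
    closed forms built from the ratios ``alpha_w = (1 + tau_w/tau_eff)/(1 +
    tau_w/tau_V)`` and ``alpha_I = (1 + tau_I/tau_eff)/(1 + tau_I/tau_V)``;
    they equal the quadrature of the voltage spectrum and of
    ``omega**2`` times the spectrum, respectively.
    """
    require_stable(p)
    alpha_w, alpha_I = _alphas(p, inp)
    tau_eff = p.tau_eff
    r_wI = p.tau_w / inp.tau_I
    base = inp.sigma_I**2 / (p.tau_V / inp.tau_I + 1.0)
    sigma_V2 = (tau_eff / p.tau_V) * base * (1.0 + alpha_w * r_wI) / (alpha_I + r_wI)
    sigma_Vdot2 = (
        base / (inp.tau_I * p.tau_V) * (1.0 + alpha_w / r_wI) / (1.0 + alpha_I / r_wI)
    )
    corr = correlation_function(p, inp) if inp.sigma_I > 0 else (lambda tau: np.zeros_like(np.asarray(tau, dtype=float)))
    sigma_V = math.sqrt(sigma_V2)
    sigma_Vdot = math.sqrt(sigma_Vdot2)
    return VoltageStatistics(
        sigma_V=sigma_V,
        sigma_Vdot=sigma_Vdot,
        tau_s=sigma_V / sigma_Vdot if sigma_Vdot > 0 else math.nan,
        sigma_rel=sigma_V / p.theta,
        correlation=corr,
        alpha_w=alpha_w,
        alpha_I=alpha_I,
        perturbed=getattr(corr, "perturbed", False),
    )


def tau_s(p: NeuronParameters, inp: InputModel) -> float:
    """Differential correlation time ``sigma_V / sigma_Vdot`` in ms.

    Closed form ``sqrt(tau_eff tau_I (1 + alpha_w tau_w/tau_I) /
    (alpha_w + tau_w/tau_I))``; independent of ``sigma_I``.  Limits:
    ``sqrt(tau_I tau_eff)`` for ``tau_w -> 0`` and ``sqrt(tau_I tau_V)`` for
    ``tau_w -> inf`` (their ratio is ``sqrt(1+g)``).
    """
    require_stable(p)
    alpha_w, _ = _alphas(p, inp)
    r_wI = p.tau_w / inp.tau_I
    return math.sqrt(p.tau_eff * inp.tau_I * (1.0 + alpha_w * r_wI) / (alpha_w + r_wI))


def tau_s_implicit(p: NeuronParameters, inp: InputModel) -> float:
    """Eigenvalue-representation form of the differential correlation time.

    ``(omega_L tau_s)**2 = (1 + (omega_L tau_w)**2 + 2 tau_I/tau_r) /
    (1 + (omega_L tau_w)**2 + 2 tau_w**2/(tau_r tau_I))`` with
    ``tau_r = tau_bar``.  Agrees with :func:`tau_s` wherever both are defined.
    """
    require_stable(p)
    omega_L = p.omega_L
    tau_r = p.tau_bar
    x2 = (omega_L * p.tau_w) ** 2
    num = 1.0 + x2 + 2.0 * inp.tau_I / tau_r
    den = 1.0 + x2 + 2.0 * p.tau_w**2 / (tau_r * inp.tau_I)
    return math.sqrt(num / den) / omega_L
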