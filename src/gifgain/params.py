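"""Parameter space of the generalized integrate-and-fire (GIF) resonator neuron.

The subthreshold model couples the membrane voltage ``V`` to a single
intrinsic activity variable ``w``::

    tau_V dV/dt = -V - g*w + I(t)
    tau_w dw/dt =  V - w

with spikes emitted at upward crossings of a hard threshold ``theta`` and no
voltage reset.  ``g`` is the conductance of the intrinsic current relative to
the leak: ``g > 0`` makes ``w`` hyperpolarizing (resonator-like), ``g < 0``
depolarizing, and ``g <= -1`` destabilizes the dynamics.

The linear subthreshold dynamics admits three equivalent parametrizations:

explicit
    ``(tau_V, g, tau_w)`` -- the time constants and relative conductance of
    the differential equations themselves.
implicit
    ``(tau_r, Omega, tau_w)`` -- the relaxation time and intrinsic angular
    frequency given by the eigenvalues ``lambda_pm = -1/tau_r +- i*Omega`` of
    the 2x2 evolution operator.
filter shape
    ``(omega_L, Q_L, tau_w)`` -- the center frequency and quality factor of
    the second-order low-pass component of the current-to-voltage filter.

All times are in milliseconds and angular frequencies in rad/ms.  The voltage
is dimensionless with the threshold defaulting to ``theta = 1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuronParameters",
    "ImplicitRepresentation",
    "FilterShapeRepresentation",
    "Regime",
    "eigenvalues",
    "evolution_matrix",
    "g_crit",
    "g_min",
    "g_for_intrinsic_frequency",
    "neuron_from_intrinsic_frequency",
    "to_implicit",
    "to_filter_shape",
    "from_filter_shape",
    "classify_regime",
    "neuron_to_json",
    "neuron_from_json",
]

#: eigenvalues closer (in relative terms) to the critically damped branch than
#: this are treated as degenerate and resolved by a small parameter perturbation
DEGENERACY_RTOL = 1e-12

#: relative size of the perturbation applied to resolve degenerate parameters
DEGENERACY_PERTURBATION = 1e-7


@dataclass(frozen=True)
class NeuronParameters:
    """Explicit representation ``(tau_V, g, tau_w)`` plus the spike threshold.

    Parameters
    ----------
    tau_V : float
        Membrane time constant in ms (> 0).
    g : float
        Relative conductance of the intrinsic current (dimensionless).  The
        dynamics is stable only for ``g > -1``; unstable values may be stored
        (so they can be classified) but are rejected by every operation that
        requires stability.
    tau_w : float
        Time constant of the intrinsic current in ms (> 0).
    theta : float
        Spike threshold in voltage units (> 0), default 1.
    """

    tau_V: float
    g: float
    tau_w: float
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_V > 0):
            raise ValueError(f"membrane time constant must be positive, got tau_V={self.tau_V}")
        if not (self.tau_w > 0):
            raise ValueError(f"intrinsic time constant must be positive, got tau_w={self.tau_w}")
        if not (self.theta > 0):
            raise ValueError(f"spike threshold must be positive, got theta={self.theta}")

    @property
    def stable(self) -> bool:
        """True iff the subthreshold fixed point is stable (``g > -1``)."""
        return self.g > -1.0 and self.tau_V > 0

    @property
    def tau_eff(self) -> float:
        """Effective membrane time constant ``tau_V / (1 + g)`` in ms."""
        require_stable(self)
        return self.tau_V / (1.0 + self.g)

    @property
    def tau_bar(self) -> float:
        """Twice the harmonic mean rate: ``2 tau_V tau_w / (tau_V + tau_w)``.

        This is the relaxation time ``tau_r = -1/Re(lambda_pm)`` whenever the
        eigenvalues form a complex pair.
        """
        return 2.0 * self.tau_V * self.tau_w / (self.tau_V + self.tau_w)

    @property
    def omega_L(self) -> float:
        """Center frequency ``sqrt((1+g)/(tau_V tau_w))`` of the low pass (rad/ms)."""
        require_stable(self)
        return math.sqrt((1.0 + self.g) / (self.tau_V * self.tau_w))

    @property
    def Q_L(self) -> float:
        """Quality factor ``omega_L * tau_bar / 2`` of the low-pass component."""
        return self.omega_L * self.tau_bar / 2.0


@dataclass(frozen=True)
class ImplicitRepresentation:
    """Eigenvalue-based representation ``(tau_r, Omega, tau_w)``.

    ``tau_r`` is the relaxation time ``-1/Re(lambda_pm)`` and ``Omega`` the
    intrinsic angular frequency ``Im(lambda_+)`` (0 when the eigenvalues are
    real).  ``lambda_plus`` carries the root with the larger real part (real
    case) or positive imaginary part (complex case).
    """

    tau_r: float
    Omega: float
    tau_w: float
    lambda_plus: complex
    lambda_minus: complex
    theta: float = 1.0


@dataclass(frozen=True)
class FilterShapeRepresentation:
    """Filter-shape representation ``(omega_L, Q_L, tau_w)``.

    ``V_low = 1/(1+g)`` is the zero-frequency voltage response and
    ``tau_eff = tau_V/(1+g)`` the effective membrane time constant; both are
    derived quantities kept for convenience.  Stability requires
    ``Q_L < omega_L * tau_w``.
    """

    omega_L: float
    Q_L: float
    tau_w: float
    V_low: float
    tau_eff: float
    theta: float = 1.0


@dataclass(frozen=True)
class Regime:
    """Qualitative classification of the intrinsic dynamics."""

    unstable: bool
    depolarizing: bool
    hyperpolarizing: bool
    has_intrinsic_frequency: bool


def require_stable(p: NeuronParameters) -> None:
    """Raise ``ValueError`` naming the violated bound if ``p`` is unstable."""
    if not (p.g > -1.0):
        raise ValueError(
            f"unstable parameters: relative conductance g={p.g} violates g > -1"
        )
    if not (p.tau_V > 0):
        raise ValueError(f"unstable parameters: tau_V={p.tau_V} violates tau_V > 0")


def evolution_matrix(p: NeuronParameters) -> np.ndarray:
    """2x2 linear evolution operator of the subthreshold dynamics.

    ``d/dt (V, w) = B (V, w)`` with ``B = [[-1/tau_V, -g/tau_V],
    [1/tau_w, -1/tau_w]]``.
    """
    return np.array(
        [
            [-1.0 / p.tau_V, -p.g / p.tau_V],
            [1.0 / p.tau_w, -1.0 / p.tau_w],
        ]
    )


def _resolve_degeneracy(p: NeuronParameters) -> NeuronParameters:
    """Perturb ``g`` off the critically damped branch if needed.

    Downstream closed forms divide by ``lambda_+ - lambda_-``; exactly (or
    numerically) coincident eigenvalues are therefore nudged apart by a
    relative perturbation of :data:`DEGENERACY_PERTURBATION` in ``g``.
    """
    x = p.omega_L * p.tau_bar  # = 1 exactly at critical damping
    disc = 1.0 - x * x
    if abs(disc) > DEGENERACY_RTOL:
        return p
    g_new = p.g + DEGENERACY_PERTURBATION * (1.0 + abs(p.g))
    return replace(p, g=g_new)


def eigenvalues(p: NeuronParameters) -> tuple[complex, complex]:
    """Eigenvalues ``lambda_pm`` of the subthreshold evolution operator (1/ms).

    For stable parameters both roots have negative real part.  They form a
    complex-conjugate pair exactly when ``omega_L * tau_bar > 1``, i.e. when
    ``Q_L > 1/2``; otherwise both are real with ``lambda_+ >= lambda_-``.
    """
    require_stable(p)
    p = _resolve_degeneracy(p)
    tau_r = p.tau_bar
    x = p.omega_L * tau_r
    disc = 1.0 - x * x
    if disc > 0:
        s = math.sqrt(disc)
        lam_p = (-1.0 + s) / tau_r
        lam_m = (-1.0 - s) / tau_r
        return complex(lam_p), complex(lam_m)
    omega = math.sqrt(-disc) / tau_r
    return complex(-1.0 / tau_r, omega), complex(-1.0 / tau_r, -omega)


def g_crit(tau_V: float, tau_w: float) -> float:
    """Critical conductance above which an intrinsic frequency exists.

    ``g_crit = (tau_w - tau_V)**2 / (4 tau_w tau_V)``; the eigenvalues are
    complex iff ``g > g_crit``.
    """
    if not (tau_V > 0 and tau_w > 0):
        raise ValueError(f"time constants must be positive, got tau_V={tau_V}, tau_w={tau_w}")
    return (tau_w - tau_V) ** 2 / (4.0 * tau_w * tau_V)


def g_min(Omega_tau_V: float) -> float:
    """Smallest conductance achieving intrinsic frequency ``Omega`` (any tau_w).

    ``Omega_tau_V`` is the intrinsic frequency in units of ``1/tau_V``.  Over
    all ``tau_w > 0`` the conductance required by
    ``tau_V tau_w Omega**2 = g - g_crit`` is minimized at
    ``g_min = (-1 + sqrt(1 + 4 Omega**2 tau_V**2)) / 2``.
    """
    if Omega_tau_V < 0:
        raise ValueError(f"intrinsic frequency must be non-negative, got {Omega_tau_V}")
    return 0.5 * (-1.0 + math.sqrt(1.0 + 4.0 * Omega_tau_V**2))


def g_for_intrinsic_frequency(tau_V: float, tau_w: float, Omega: float) -> float:
    """Conductance giving intrinsic angular frequency ``Omega`` (rad/ms).

    Inverts ``tau_V tau_w Omega**2 = g - g_crit``.
    """
    if Omega < 0:
        raise ValueError(f"intrinsic frequency must be non-negative, got {Omega}")
    return tau_V * tau_w * Omega**2 + g_crit(tau_V, tau_w)


def neuron_from_intrinsic_frequency(
    tau_V: float, tau_w: float, f_int_hz: float, theta: float = 1.0
) -> NeuronParameters:
    """Build a neuron with intrinsic (damped-oscillation) frequency ``f_int_hz``.

    The conductance is derived from the eigenvalue relation, never taken from a
    rounded printed value; ``Omega = 2*pi*f_int_hz / 1000`` rad/ms.
    """
    Omega = 2.0 * math.pi * f_int_hz / 1000.0
    return NeuronParameters(
        tau_V=tau_V, g=g_for_intrinsic_frequency(tau_V, tau_w, Omega), tau_w=tau_w, theta=theta
    )


def to_implicit(p: NeuronParameters) -> ImplicitRepresentation:
    """Convert the explicit representation to the eigenvalue representation."""
    lam_p, lam_m = eigenvalues(p)
    if lam_p.imag != 0.0:
        tau_r = -1.0 / lam_p.real
        Omega = lam_p.imag
    else:
        # real eigenvalues: the relaxation is governed by the slow root
        tau_r = -1.0 / lam_p.real
        Omega = 0.0
    return ImplicitRepresentation(
        tau_r=tau_r,
        Omega=Omega,
        tau_w=p.tau_w,
        lambda_plus=lam_p,
        lambda_minus=lam_m,
        theta=p.theta,
    )


def to_filter_shape(p: NeuronParameters) -> FilterShapeRepresentation:
    """Convert the explicit representation to the filter-shape representation."""
    require_stable(p)
    return FilterShapeRepresentation(
        omega_L=p.omega_L,
        Q_L=p.Q_L,
        tau_w=p.tau_w,
        V_low=1.0 / (1.0 + p.g),
        tau_eff=p.tau_eff,
        theta=p.theta,
    )


def from_filter_shape(f: FilterShapeRepresentation) -> NeuronParameters:
    """Recover the explicit parameters from ``(omega_L, Q_L, tau_w)``.

    Uses ``omega_L tau_V = omega_L tau_w Q_L / (omega_L tau_w - Q_L)`` and
    ``g = omega_L**2 tau_V tau_w - 1``; defined only on the stable domain
    ``Q_L < omega_L * tau_w``.
    """
    if not (f.omega_L > 0 and f.Q_L > 0 and f.tau_w > 0):
        raise ValueError("omega_L, Q_L and tau_w must all be positive")
    x = f.omega_L * f.tau_w
    if not (f.Q_L < x):
        raise ValueError(
            f"unstable shape: Q_L={f.Q_L} violates Q_L < omega_L*tau_w={x}"
        )
    tau_V = f.tau_w * f.Q_L / (x - f.Q_L)
    g = f.omega_L**2 * tau_V * f.tau_w - 1.0
    return NeuronParameters(tau_V=tau_V, g=g, tau_w=f.tau_w, theta=f.theta)


def classify_regime(p: NeuronParameters) -> Regime:
    """Classify the intrinsic dynamics of ``p``.

    Reports instability (``g <= -1``), the sign of the intrinsic current
    (depolarizing ``g < 0`` / hyperpolarizing ``g > 0``) and whether an
    intrinsic frequency exists (``g > g_crit``, equivalently ``Q_L > 1/2``).
    """
    unstable = not p.stable
    has_omega = (not unstable) and p.g > g_crit(p.tau_V, p.tau_w)
    return Regime(
        unstable=unstable,
        depolarizing=p.g < 0,
        hyperpolarizing=p.g > 0,
        has_intrinsic_frequency=has_omega,
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization; representation is auto-detected from the key names.

def neuron_to_json(p: NeuronParameters, representation: str = "explicit") -> str:
    if representation == "explicit":
        payload = {"tau_V_ms": p.tau_V, "tau_w_ms": p.tau_w, "g": p.g, "theta": p.theta}
    elif representation == "shape":
        f = to_filter_shape(p)
        payload = {
            "omega_L_rad_per_ms": f.omega_L,
            "Q_L": f.Q_L,
            "tau_w_ms": f.tau_w,
            "theta": f.theta,
        }
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return json.dumps(payload)


def neuron_from_json(text: str) -> NeuronParameters:
    data = json.loads(text)
    theta = float(data.get("theta", 1.0))
    if "tau_V_ms" in data and "g" in data:
        return NeuronParameters(
            tau_V=float(data["tau_V_ms"]), g=float(data["g"]),
            tau_w=float(data["tau_w_ms"]), theta=theta,
        )
    if "omega_L_rad_per_ms" in data and "Q_L" in data:
        shape = FilterShapeRepresentation(
            omega_L=float(data["omega_L_rad_per_ms"]),
            Q_L=float(data["Q_L"]),
            tau_w=float(data["tau_w_ms"]),
            V_low=math.nan,
            tau_eff=math.nan,
            theta=theta,
        )
        return from_filter_shape(shape)
    raise ValueError("unrecognized parameter keys; expected explicit or shape representation")
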