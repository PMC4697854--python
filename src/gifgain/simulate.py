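"""Stochastic ensemble simulation of Gauss-Rice GIF and EIF neurons.

Every neuron receives an independent Ornstein-Uhlenbeck (OU) noise realization
plus a common deterministic mean-channel signal.  Spikes are upward crossings
of the hard threshold (no reset) for the GIF, or crossings of a high numerical
threshold followed by a voltage reset for the exponential integrate-and-fire
(EIF) variant with spike slope factor ``Delta_T``.

Integration schemes
-------------------
``exact`` (default)
    The OU input is advanced with its exact discretization and the linear
    (V, w) system is propagated with the exact matrix exponential over each
    step, treating the noise as piecewise linear within the step.  The update
    reduces to a second-order recursive filter on the input sequence, so whole
    ensembles integrate as vectorized array operations.
``rk4``
    Classical 4th-order deterministic stage for (V, w) with the same exact OU
    update and piecewise-linear noise interpolation; slower, used to
    cross-validate the default scheme.

Each neuron owns an independent random stream spawned from ``(seed, index)``,
so results are bit-exact reproducible and independent of ensemble chunking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, signal as sps

from .params import NeuronParameters, eigenvalues, evolution_matrix, require_stable, to_implicit
from .subthreshold import InputModel, Sinusoid, Step, tau_s as _tau_s
from .gain import stationary_rate

__all__ = [
    "SimConfig",
    "SpikeEnsemble",
    "SimResult",
    "VectorStrengthEstimate",
    "default_dt",
    "ou_step",
    "integrate_gif",
    "integrate_eif",
    "detect_spikes",
    "vector_strength_gain",
    "psth",
    "validity_warnings",
]

_BLOCK = 64          # neurons integrated per vectorized block
_CHUNK = 100_000     # time steps per chunk (bounds memory)
_EIF_BLOCK = 2048    # the EIF loop is per-step, so wide blocks amortize it


def default_dt(p: NeuronParameters, inp: InputModel) -> float:
    """Default integration step ``min(tau_I, tau_eff, tau_w)/50`` (ms)."""
    return min(inp.tau_I, p.tau_eff, p.tau_w) / 50.0


@dataclass(frozen=True)
class SimConfig:
    """Ensemble simulation settings (times in ms)."""

    dt: float
    duration: float
    n_neurons: int
    seed: int
    burn_in: float = 200.0
    scheme: str = "exact"

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.duration > 0 and self.n_neurons > 0):
            raise ValueError("dt, duration and n_neurons must be positive")
        if self.scheme not in ("exact", "rk4"):
            raise ValueError(f"unknown integration scheme {self.scheme!r}")

    def check(self, p: NeuronParameters, inp: InputModel) -> None:
        limit = min(inp.tau_I, p.tau_eff, p.tau_w) / 20.0
        if self.dt > limit:
            warnings.warn(
                f"dt={self.dt} ms exceeds min(tau_I, tau_eff, tau_w)/20={limit:.4g} ms",
                stacklevel=2,
            )
        need = 5.0 * max(p.tau_V, p.tau_w, inp.tau_I)
        if self.burn_in < need:
            warnings.warn(
                f"burn_in={self.burn_in} ms is below 5*max(tau_V, tau_w, tau_I)={need:.4g} ms",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SpikeEnsemble:
    """Per-neuron ordered spike times (ms) with the generating configuration."""

    spike_times: list  # list of 1-D float arrays, one per neuron
    config: SimConfig
    input: InputModel
    neuron: NeuronParameters

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))

    def pooled(self) -> np.ndarray:
        if not self.spike_times:
            return np.empty(0)
        return np.concatenate([np.asarray(s) for s in self.spike_times])

    def rates(self) -> np.ndarray:
        """Per-neuron firing rate in 1/ms over the recorded duration."""
        T = self.config.duration
        return np.array([len(s) / T for s in self.spike_times])


@dataclass
class SimResult:
    """Output of an ensemble integration."""

    ensemble: SpikeEnsemble
    mean_V: np.ndarray        # per-neuron time-averaged voltage
    var_V: np.ndarray         # per-neuron voltage variance
    var_Vdot: np.ndarray      # per-neuron central-difference derivative variance
    traces: Optional[np.ndarray] = None   # (n_recorded, n_samples) voltage traces
    trace_times: Optional[np.ndarray] = None
    w_traces: Optional[np.ndarray] = None


def ou_step(x, dt: float, tau_I: float, sigma_I: float, normal_draw):
    """Exact OU update ``x e^{-dt/tau_I} + sigma_I sqrt(1 - e^{-2dt/tau_I}) n``."""
    if not (dt > 0):
        raise ValueError("dt must be positive")
    a = math.exp(-dt / tau_I)
    b = sigma_I * math.sqrt(1.0 - a * a)
    return np.asarray(x) * a + b * np.asarray(normal_draw)


def _neuron_rngs(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n)]


def _discrete_propagator(p: NeuronParameters, dt: float):
    """Exact one-step propagator of the linear system with piecewise-linear input.

    Returns ``(M, J0, J1)`` with ``x_{k+1} = M x_k + J0 I_k + J1 I_{k+1}``
    where ``x = (V, w)`` and the input enters as ``(I/tau_V, 0)``.
    """
    B = evolution_matrix(p)
    F = linalg.expm(B * dt)
    Binv = np.linalg.inv(B)
    I2 = np.eye(2)
    int_e = Binv @ (F - I2)                         # int_0^dt e^{Bu} du
    int_ue = Binv @ (dt * F) - Binv @ Binv @ (F - I2)  # int_0^dt u e^{Bu} du
    b_vec = np.array([1.0 / p.tau_V, 0.0])
    # I(s) = I_k (1 - s/dt) + I_{k+1} s/dt, contribution int e^{B(dt-s)} b I(s) ds
    J0 = (int_ue / dt) @ b_vec
    J1 = (int_e - int_ue / dt) @ b_vec
    return F, J0, J1


def _filter_coefficients(F: np.ndarray, J0: np.ndarray, J1: np.ndarray, component: int = 0):
    """Second-order recursive-filter form of the propagator for one component."""
    trF = F[0, 0] + F[1, 1]
    detF = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
    i, j = component, 1 - component
    b0 = J1[i]
    b1 = J0[i] - F[j, j] * J1[i] + F[i, j] * J1[j]
    b2 = -F[j, j] * J0[i] + F[i, j] * J0[j]
    return np.array([b0, b1, b2]), np.array([1.0, -trF, detF])


def _mean_signal(inp: InputModel, t: np.ndarray) -> np.ndarray:
    if inp.signal is None:
        return np.zeros_like(t)
    if isinstance(inp.signal, Sinusoid):
        return inp.signal.amplitude * np.cos(inp.signal.omega * t)
    if isinstance(inp.signal, Step):
        return np.where(t >= inp.signal.onset, inp.signal.height, 0.0)
    raise TypeError(f"unsupported signal {inp.signal!r}")


def _crossings(V: np.ndarray, theta: float, t0: float, dt: float):
    """Upward threshold crossings of a (neurons, samples) voltage array."""
    below = V[:, :-1] < theta
    above = V[:, 1:] >= theta
    n, k = np.nonzero(below & above)
    frac = (theta - V[n, k]) / (V[n, k + 1] - V[n, k])
    return n, t0 + (k + frac) * dt


def integrate_gif(
    p: NeuronParameters,
    inp: InputModel,
    config: SimConfig,
    record_traces: int = 0,
) -> SimResult:
    """Integrate an ensemble of hard-threshold no-reset GIF neurons.

    Spikes are recorded at linearly interpolated upward crossings of
    ``p.theta``; the dynamics continues through the threshold.  Per-neuron
    voltage mean, variance and central-difference derivative variance are
    accumulated over the recorded window (after ``burn_in``), and full voltage
    traces of the first ``record_traces`` neurons are returned.
    """
    require_stable(p)
    config.check(p, inp)
    if config.scheme == "rk4":
        return _integrate_rk4(p, inp, config, record_traces)

    dt = config.dt
    n_burn = int(round(config.burn_in / dt))
    n_rec = int(round(config.duration / dt))
    n_total = n_burn + n_rec + 1
    a_ou = math.exp(-dt / inp.tau_I)
    b_ou = inp.sigma_I * math.sqrt(1.0 - a_ou * a_ou)
    F, J0, J1 = _discrete_propagator(p, dt)
    b_coef, a_coef = _filter_coefficients(F, J0, J1, component=0)

    rngs = _neuron_rngs(config.seed, config.n_neurons)
    spike_lists: list[list[np.ndarray]] = [[] for _ in range(config.n_neurons)]
    s1 = np.zeros(config.n_neurons)
    s2 = np.zeros(config.n_neurons)
    sd2 = np.zeros(config.n_neurons)
    count = 0
    dcount = 0
    traces = [] if record_traces > 0 else None

    for start in range(0, config.n_neurons, _BLOCK):
        stop = min(start + _BLOCK, config.n_neurons)
        nb = stop - start
        zi_ou = np.zeros((nb, 1))
        zi_v = np.zeros((nb, 2))
        carry_V = None  # last voltage sample of the previous chunk
        block_traces = [] if (traces is not None and start < record_traces) else None
        for c0 in range(0, n_total, _CHUNK):
            c1 = min(c0 + _CHUNK, n_total)
            m = c1 - c0
            noise = np.empty((nb, m))
            for j in range(nb):
                noise[j] = rngs[start + j].standard_normal(m)
            if c0 == 0 and b_ou > 0:
                noise[:, 0] *= inp.sigma_I / b_ou  # stationary OU start
            ou, zi_ou = sps.lfilter([b_ou], [1.0, -a_ou], noise, axis=1, zi=zi_ou)
            t_chunk = (np.arange(c0, c1) - n_burn) * dt
            drive = ou
            drive += _mean_signal(inp, t_chunk)[None, :]
            V, zi_v = sps.lfilter(b_coef, a_coef, drive, axis=1, zi=zi_v)
            if not np.all(np.isfinite(V[:, -1])):
                raise FloatingPointError(
                    f"non-finite state encountered near t={t_chunk[-1]:.3f} ms"
                )
            # prepend carried sample so chunk-boundary crossings are kept
            if carry_V is not None:
                Vx = np.concatenate([carry_V, V], axis=1)
                tx0 = t_chunk[0] - dt
            else:
                Vx = V
                tx0 = t_chunk[0]
            rec_mask = t_chunk >= 0
            if np.any(rec_mask):
                k_first = int(np.argmax(rec_mask))
                Vr = V[:, k_first:]
                s1[start:stop] += Vr.sum(axis=1)
                s2[start:stop] += (Vr**2).sum(axis=1)
                count += Vr.shape[1] if start == 0 else 0
                vd = (Vr[:, 2:] - Vr[:, :-2]) / (2.0 * dt)
                sd2[start:stop] += (vd**2).sum(axis=1)
                dcount += vd.shape[1] if start == 0 else 0
                if block_traces is not None:
                    block_traces.append(Vr[: max(0, record_traces - start)])
            idx, times = _crossings(Vx, p.theta, tx0, dt)
            keep = times >= 0
            idx, times = idx[keep], times[keep]
            order = np.argsort(idx, kind="stable")
            idx, times = idx[order], times[order]
            bounds = np.searchsorted(idx, np.arange(nb + 1))
            for j in range(nb):
                if bounds[j + 1] > bounds[j]:
                    spike_lists[start + j].append(times[bounds[j] : bounds[j + 1]])
            carry_V = V[:, -1:].copy()
        if block_traces is not None:
            traces.append(np.concatenate(block_traces, axis=1))

    spikes = [
        np.sort(np.concatenate(sl)) if sl else np.empty(0) for sl in spike_lists
    ]
    ens = SpikeEnsemble(spike_times=spikes, config=config, input=inp, neuron=p)
    mean_V = s1 / count
    var_V = s2 / count - mean_V**2
    out_traces = np.concatenate(traces, axis=0)[:record_traces] if traces else None
    trace_times = np.arange(count) * dt if traces else None
    return SimResult(
        ensemble=ens,
        mean_V=mean_V,
        var_V=var_V,
        var_Vdot=sd2 / dcount,
        traces=out_traces,
        trace_times=trace_times,
    )


def _integrate_rk4(
    p: NeuronParameters, inp: InputModel, config: SimConfig, record_traces: int
) -> SimResult:
    # reference scheme: explicit time loop, identical noise path to "exact"
    dt = config.dt
    n_burn = int(round(config.burn_in / dt))
    n_rec = int(round(config.duration / dt))
    n_total = n_burn + n_rec + 1
    n = config.n_neurons
    a_ou = math.exp(-dt / inp.tau_I)
    b_ou = inp.sigma_I * math.sqrt(1.0 - a_ou * a_ou)
    rngs = _neuron_rngs(config.seed, n)
    noise = np.empty((n_total, n))
    for j in range(n):
        noise[:, j] = rngs[j].standard_normal(n_total)
    if b_ou > 0:
        noise[0] *= inp.sigma_I / b_ou
    ou = sps.lfilter([b_ou], [1.0, -a_ou], noise, axis=0)
    t = (np.arange(n_total) - n_burn) * dt
    drive = ou + _mean_signal(inp, t)[:, None]

    V = np.zeros(n)
    w = np.zeros(n)
    Vs = np.empty((n_total, n))
    Vs[0] = V
    inv_tV, inv_tw = 1.0 / p.tau_V, 1.0 / p.tau_w

    def deriv(V, w, I):
        return (-V - p.g * w + I) * inv_tV, (V - w) * inv_tw

    for k in range(n_total - 1):
        I0, I1 = drive[k], drive[k + 1]
        Ih = 0.5 * (I0 + I1)
        k1V, k1w = deriv(V, w, I0)
        k2V, k2w = deriv(V + 0.5 * dt * k1V, w + 0.5 * dt * k1w, Ih)
        k3V, k3w = deriv(V + 0.5 * dt * k2V, w + 0.5 * dt * k2w, Ih)
        k4V, k4w = deriv(V + dt * k3V, w + dt * k3w, I1)
        V = V + dt / 6.0 * (k1V + 2 * k2V + 2 * k3V + k4V)
        w = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        Vs[k + 1] = V
    if not np.all(np.isfinite(Vs[-1])):
        raise FloatingPointError("non-finite state in rk4 integration")

    idx, times = _crossings(Vs.T, p.theta, t[0], dt)
    keep = times >= 0
    spikes = [np.sort(times[keep & (idx == j)]) for j in range(n)]
    Vr = Vs[n_burn:]
    mean_V = Vr.mean(axis=0)
    var_V = Vr.var(axis=0)
    vd = (Vr[2:] - Vr[:-2]) / (2.0 * dt)
    ens = SpikeEnsemble(spike_times=spikes, config=config, input=inp, neuron=p)
    return SimResult(
        ensemble=ens,
        mean_V=mean_V,
        var_V=var_V,
        var_Vdot=(vd**2).mean(axis=0),
        traces=Vr[:, :record_traces].T if record_traces else None,
        trace_times=np.arange(Vr.shape[0]) * dt if record_traces else None,
    )


def integrate_eif(
    p: NeuronParameters,
    inp: InputModel,
    config: SimConfig,
    Delta_T: float,
    V_T: float = 0.8,
    V_thr: float = 1.5,
    V_reset: float = 0.0,
    reset_w: bool = False,
) -> SpikeEnsemble:
    """Integrate the exponential integrate-and-fire variant of the model.

    Adds the spike-generating term ``Delta_T * exp((V - V_T)/Delta_T)`` inside
    the ``tau_V dV/dt`` equation; a spike is registered when ``V`` crosses the
    numerical threshold ``V_thr`` and the voltage is reset to ``V_reset``
    (``w`` unchanged unless ``reset_w``).  The linear part is propagated with
    the exact one-step map; the exponential term is added as a forward-Euler
    stage, with an overflow guard that registers an immediate spike once
    ``V - V_T > 30 Delta_T``.
    """
    require_stable(p)
    if not (Delta_T > 0):
        raise ValueError("Delta_T must be positive")
    if not (V_thr > V_T):
        raise ValueError("numerical threshold V_thr must exceed V_T")
    config.check(p, inp)
    dt = config.dt
    n_burn = int(round(config.burn_in / dt))
    n_rec = int(round(config.duration / dt))
    n_total = n_burn + n_rec + 1
    n = config.n_neurons
    a_ou = math.exp(-dt / inp.tau_I)
    b_ou = inp.sigma_I * math.sqrt(1.0 - a_ou * a_ou)
    F, J0, J1 = _discrete_propagator(p, dt)
    rngs = _neuron_rngs(config.seed, n)
    spike_lists: list[list[float]] = [[] for _ in range(n)]

    for start in range(0, n, _EIF_BLOCK):
        stop = min(start + _EIF_BLOCK, n)
        nb = stop - start
        V = np.zeros(nb)
        w = np.zeros(nb)
        I_cur = None
        zi_ou = np.zeros((1, nb))
        for c0 in range(0, n_total, _CHUNK):
            c1 = min(c0 + _CHUNK, n_total)
            m = c1 - c0
            noise = np.empty((m, nb))
            for j in range(nb):
                noise[:, j] = rngs[start + j].standard_normal(m)
            if c0 == 0 and b_ou > 0:
                noise[0] *= inp.sigma_I / b_ou
            ou, zi_ou = sps.lfilter([b_ou], [1.0, -a_ou], noise, axis=0, zi=zi_ou)
            t_chunk = (np.arange(c0, c1) - n_burn) * dt
            drive = ou + _mean_signal(inp, t_chunk)[:, None]
            k0 = 0
            if I_cur is None:
                I_cur = drive[0]
                k0 = 1
            for k in range(k0, m):
                I_next = drive[k]
                V_old = V
                Vw_V = F[0, 0] * V + F[0, 1] * w + J0[0] * I_cur + J1[0] * I_next
                Vw_w = F[1, 0] * V + F[1, 1] * w + J0[1] * I_cur + J1[1] * I_next
                expo = np.minimum((V - V_T) / Delta_T, 30.0)
                V = Vw_V + dt * (Delta_T / p.tau_V) * np.exp(expo)
                w = Vw_w
                I_cur = I_next
                fired = (V >= V_thr) | (V - V_T > 30.0 * Delta_T)
                if np.any(fired):
                    t_now = t_chunk[k]
                    jf = np.nonzero(fired)[0]
                    dv = V[jf] - V_old[jf]
                    frac = np.clip((V_thr - V_old[jf]) / np.where(dv != 0, dv, 1.0), 0.0, 1.0)
                    ts = t_now - dt + frac * dt
                    for jj, tsp in zip(jf, ts):
                        if tsp >= 0:
                            spike_lists[start + jj].append(float(tsp))
                    V[jf] = V_reset
                    if reset_w:
                        w[jf] = 0.0
    spikes = [np.sort(np.array(sl)) for sl in spike_lists]
    return SpikeEnsemble(spike_times=spikes, config=config, input=inp, neuron=p)


def detect_spikes(V_samples, theta: float, dt: float, t0: float = 0.0) -> np.ndarray:
    """Spike times from a uniformly sampled voltage trace.

    One spike per sign change of ``V - theta`` from negative to non-negative,
    linearly interpolated within the step; downward crossings are ignored.
    """
    V = np.asarray(V_samples, dtype=float)
    if V.ndim != 1:
        raise ValueError("expected a 1-D voltage trace")
    below = V[:-1] < theta
    above = V[1:] >= theta
    k = np.nonzero(below & above)[0]
    frac = (theta - V[k]) / (V[k + 1] - V[k])
    return t0 + (k + frac) * dt


@dataclass(frozen=True)
class VectorStrengthEstimate:
    """Relative dynamic gain estimated from spike phases.

    ``gain`` is the modulation depth of the population rate per unit input
    amplitude (same normalization as the analytic relative response); ``se``
    is a bootstrap standard error over neurons.
    """

    gain: float
    phase: float
    se: float
    n_spikes: int
    resultant: float


def vector_strength_gain(
    ens: SpikeEnsemble,
    omega: float,
    A: float,
    n_boot: int = 200,
    seed: int = 12345,
) -> VectorStrengthEstimate:
    """Estimate the relative dynamic gain at ``omega`` from spike times.

    For a drive ``A cos(omega t)`` the spike-phase resultant
    ``R = |<exp(-i omega t_m)>_m|`` satisfies ``R = A |nu_1/nu_0| / 2``, so
    the relative gain estimate is ``2 R / A`` (debiased for the finite-sample
    resultant-length floor) and the phase lead is the argument of the mean
    vector.  The standard error comes from a seeded bootstrap over neurons.
    """
    per_neuron = [np.asarray(s) for s in ens.spike_times if len(s) > 0]
    n_spikes = int(sum(len(s) for s in per_neuron))
    if n_spikes == 0:
        raise ValueError("undefined estimate: ensemble contains no spikes")
    if n_spikes < 100:
        warnings.warn(f"only {n_spikes} spikes; vector-strength estimate is unreliable")
    zs = [np.exp(-1j * omega * s) for s in per_neuron]
    sums = np.array([z.sum() for z in zs])
    counts = np.array([len(z) for z in zs])
    mean_vec = sums.sum() / counts.sum()
    R2 = abs(mean_vec) ** 2
    R_debiased = math.sqrt(max(R2 - (1.0 - R2) / n_spikes, 0.0))
    gain = 2.0 * R_debiased / A
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    m = len(per_neuron)
    for b in range(n_boot):
        pick = rng.integers(0, m, m)
        tot = counts[pick].sum()
        if tot == 0:
            boot[b] = np.nan
            continue
        mv = sums[pick].sum() / tot
        r2 = abs(mv) ** 2
        boot[b] = 2.0 * math.sqrt(max(r2 - (1.0 - r2) / tot, 0.0)) / A
    se = float(np.nanstd(boot, ddof=1))
    return VectorStrengthEstimate(
        gain=gain,
        phase=float(np.angle(mean_vec)),
        se=se,
        n_spikes=n_spikes,
        resultant=math.sqrt(R2),
    )


def psth(
    ens: SpikeEnsemble,
    bin_ms: float,
    t_start: float = 0.0,
    t_stop: Optional[float] = None,
):
    """Peri-stimulus time histogram in spikes/s with per-bin Poisson errors.

    Returns ``(bin_centers_ms, rate_hz, se_hz)``; the ensemble must share a
    common time-locked signal for the histogram to be meaningful.
    """
    if t_stop is None:
        t_stop = ens.config.duration
    edges = np.arange(t_start, t_stop + bin_ms / 2, bin_ms)
    pooled = ens.pooled()
    counts, _ = np.histogram(pooled, bins=edges)
    n = len(ens.spike_times)
    norm = n * bin_ms / 1000.0  # neuron-seconds per bin
    rate = counts / norm
    se = np.sqrt(np.maximum(counts, 1)) / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate, se


def validity_warnings(p: NeuronParameters, inp: InputModel) -> list[str]:
    """No-reset validity monitors, as machine-parsable strings.

    The Gauss-Rice construction approximates reset dynamics only for sparse
    spiking (``nu_0 tau_s <= 0.1``), input correlation near the voltage
    correlation (``tau_s/tau_I`` within [0.3, 3]) and relaxation fast relative
    to the inter-spike interval (``nu_0 tau_r <= 0.1``).
    """
    msgs = []
    ts = _tau_s(p, inp)
    nu0 = stationary_rate(p, inp)
    tau_r = -1.0 / to_implicit(p).lambda_plus.real
    if nu0 * ts > 0.1:
        msgs.append(f"VALIDITY: nu0*tau_s={nu0 * ts:.4g} > 0.1 (spiking not sparse)")
    ratio = ts / inp.tau_I
    if not (0.3 <= ratio <= 3.0):
        msgs.append(f"VALIDITY: tau_s/tau_I={ratio:.4g} outside [0.3, 3]")
    if nu0 * tau_r > 0.1:
        msgs.append(f"VALIDITY: nu0*tau_r={nu0 * tau_r:.4g} > 0.1 (slow relaxation)")
    return msgs
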