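"""Time integration of the coupled neuron-astrocyte system.

The external drive p(t) on the pyramidal population is either constant or
a piecewise-constant Gaussian process: a fresh Normal(p_bar, sigma^2)
draw held for each interval of length dt_noise.  The deterministic field
is advanced with classical fixed-step RK4 while the noise is frozen over
its refresh interval, which keeps deterministic experiments fourth-order
accurate and makes the stochastic drive a well-defined bounded process.

Experiment protocols are expressed as an :class:`EventSchedule`: boluses
are instantaneous increments of a state variable (e.g. +20 µM on GABA_e)
and switches replace a model parameter from their scheduled time onward
(e.g. the astrocytic uptake knockout Vgamma_ae -> 0).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.optimize import brentq, root

from . import bifurcation, model
from .bifurcation import FoldLossError
from .model import NSTATE, STATE_INDEX, STATE_VARS, NegativeConcentrationWarning, rhs, _sig
from .params import GlialParams, ModelParams

__all__ = [
    "InputSpec",
    "EventSchedule",
    "SimulationResult",
    "IntegrationBlowUp",
    "AstroFixedPoint",
    "make_input",
    "integrate",
    "steady_state_astro",
    "equilibrium_full_state",
]

DEFAULT_DT = 1e-3
DEFAULT_DT_NOISE = 0.1


class IntegrationBlowUp(RuntimeError):
    """Raised when the state leaves the finite range during integration."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"non-finite state encountered at t={t:.6g} s")


@dataclass(frozen=True)
class InputSpec:
    """External drive specification.

    kind : ``"constant"`` or ``"gaussian"``
    p_bar : mean drive (1/s)
    sigma : noise standard deviation (1/s); ignored for constant drive
    dt_noise : refresh interval of the piecewise-constant noise (s)
    seed : RNG seed for the Gaussian draws
    """

    kind: str = "constant"
    p_bar: float = 90.0
    sigma: float = 0.0
    dt_noise: float = DEFAULT_DT_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gaussian"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dt_noise <= 0:
            raise ValueError("dt_noise must be > 0")


class _PiecewiseGaussianDrive:
    """p(t) held constant on [k*dt_noise, (k+1)*dt_noise); draw k is the
    k-th variate of the seeded generator, so sample paths only depend on
    the seed, never on the evaluation order."""

    def __init__(self, spec: InputSpec):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)
        self._draws: list[float] = []

    def __call__(self, t: float) -> float:
        k = int(math.floor(t / self.spec.dt_noise + 1e-12))
        if k < 0:
            k = 0
        while len(self._draws) <= k:
            self._draws.append(
                float(self._rng.normal(self.spec.p_bar, self.spec.sigma))
            )
        return self._draws[k]


def make_input(spec: InputSpec) -> Callable[[float], float]:
    """Realize the drive as a callable p(t), reproducible from the seed."""
    if spec.kind == "constant" or spec.sigma == 0.0:
        p_bar = spec.p_bar
        return lambda t: p_bar
    return _PiecewiseGaussianDrive(spec)


@dataclass
class EventSchedule:
    """Protocol events: state boluses and parameter switches.

    boluses : list of (time s, state variable name, increment µM)
    switches : list of (time s, flat parameter name, new value)
    """

    boluses: list[tuple[float, str, float]] = field(default_factory=list)
    switches: list[tuple[float, str, float]] = field(default_factory=list)

    def validate(self, t_span: tuple[float, float]) -> None:
        for times, entries, what in (
            ([b[0] for b in self.boluses], self.boluses, "bolus"),
            ([s[0] for s in self.switches], self.switches, "switch"),
        ):
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"{what} times must be strictly increasing")
            for t in times:
                if not (t_span[0] <= t <= t_span[1]):
                    raise ValueError(
                        f"{what} time {t:g} s outside span {t_span}"
                    )
        for _, name, _ in self.boluses:
            if name not in STATE_INDEX:
                raise KeyError(f"unknown state variable {name!r} in bolus")


@dataclass
class SimulationResult:
    """A trajectory on a uniform grid plus provenance metadata.

    ``lfp`` is the local field potential y1 - y2 (mV); ``states`` has one
    row per time sample in :data:`~gliamass.model.STATE_VARS` order.
    """

    t: np.ndarray
    states: np.ndarray
    lfp: np.ndarray
    input_trace: np.ndarray
    metadata: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[name]]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def integrate(
    params: ModelParams,
    input_spec: InputSpec,
    events: EventSchedule | None = None,
    t_span: tuple[float, float] = (0.0, 10.0),
    dt: float = DEFAULT_DT,
    init=None,
    mode: str = "feedback",
    record_stride: int = 1,
    clamp_concentrations: bool = False,
) -> SimulationResult:
    """Fixed-step RK4 integration of the full 14-variable system.

    Boluses are applied as instantaneous state increments at their
    scheduled grid step; switches replace parameter values from their
    step onward.  ``init`` defaults to the full-system fixed point at the
    mean drive (see :func:`equilibrium_full_state`).
    """
    if mode not in model.MODES:
        raise ValueError(f"unknown coupling mode {mode!r}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if input_spec.kind == "gaussian" and dt > input_spec.dt_noise + 1e-15:
        raise ValueError("dt must not exceed dt_noise")
    events = events or EventSchedule()
    events.validate(t_span)

    t0, t1 = t_span
    n_steps = int(round((t1 - t0) / dt))
    if n_steps <= 0:
        raise ValueError("empty time span")

    if init is None:
        init = equilibrium_full_state(input_spec.p_bar, params, mode)
    y = [float(v) for v in np.asarray(init, dtype=float)]
    if len(y) != NSTATE or not all(math.isfinite(v) for v in y):
        raise ValueError("init must be a finite state of dimension 14")

    drive = make_input(input_spec)

    bolus_steps = {
        int(round((bt - t0) / dt)): (STATE_INDEX[name], amount)
        for bt, name, amount in events.boluses
    }
    switch_steps = {
        int(round((st - t0) / dt)): (name, value)
        for st, name, value in events.switches
    }

    n_rec = n_steps // record_stride + 1
    rec_t = np.empty(n_rec)
    rec_states = np.empty((n_rec, NSTATE))
    rec_input = np.empty(n_rec)

    conc_idx = [STATE_INDEX[n] for n in ("Glu_e", "Glu_a", "GABA_e", "GABA_a")]
    warned_negative = False

    half = dt / 2.0
    sixth = dt / 6.0
    i_rec = 0
    for step in range(n_steps + 1):
        if step in switch_steps:
            name, value = switch_steps[step]
            params = params.replace(**{name: value})
        if step in bolus_steps:
            idx, amount = bolus_steps[step]
            y[idx] += amount

        t = t0 + step * dt
        p = drive(t)

        if step % record_stride == 0:
            rec_t[i_rec] = t
            rec_states[i_rec] = y
            rec_input[i_rec] = p
            i_rec += 1

        if step == n_steps:
            break

        k1 = rhs(y, p, params, mode)
        y2 = [y[j] + half * k1[j] for j in range(NSTATE)]
        k2 = rhs(y2, p, params, mode)
        y3 = [y[j] + half * k2[j] for j in range(NSTATE)]
        k3 = rhs(y3, p, params, mode)
        y4 = [y[j] + dt * k3[j] for j in range(NSTATE)]
        k4 = rhs(y4, p, params, mode)
        y = [
            y[j] + sixth * (k1[j] + 2.0 * (k2[j] + k3[j]) + k4[j])
            for j in range(NSTATE)
        ]

        for j in conc_idx:
            if y[j] < 0.0:
                if clamp_concentrations:
                    y[j] = 0.0
                if not warned_negative:
                    warned_negative = True
                    warnings.warn(
                        f"{STATE_VARS[j]} went negative at t={t + dt:.4g} s"
                        + (" (clamped to 0)" if clamp_concentrations else ""),
                        NegativeConcentrationWarning,
                        stacklevel=2,
                    )

        if not math.isfinite(y[0]) or not math.isfinite(y[8]):
            if not all(math.isfinite(v) for v in y):
                raise IntegrationBlowUp(t + dt)

    rec_t = rec_t[:i_rec]
    rec_states = rec_states[:i_rec]
    rec_input = rec_input[:i_rec]
    lfp = rec_states[:, STATE_INDEX["y1"]] - rec_states[:, STATE_INDEX["y2"]]

    metadata = {
        "params": params.to_dict(),
        "input": {
            "kind": input_spec.kind,
            "p_bar": input_spec.p_bar,
            "sigma": input_spec.sigma,
            "dt_noise": input_spec.dt_noise,
            "seed": input_spec.seed,
        },
        "events": {"boluses": list(events.boluses), "switches": list(events.switches)},
        "t_span": (t0, t1),
        "dt": dt,
        "mode": mode,
        "record_stride": record_stride,
    }
    return SimulationResult(
        t=rec_t, states=rec_states, lfp=lfp, input_trace=rec_input, metadata=metadata
    )


class AstroFixedPoint(NamedTuple):
    """Fixed point of the glial subsystem at frozen neural firing rates."""

    J_G: float
    Glu_e: float
    Glu_a: float
    J_gamma: float
    GABA_e: float
    GABA_a: float


def steady_state_astro(
    neural_drive: tuple[float, float], gp: GlialParams
) -> AstroFixedPoint:
    """Unique stable fixed point of the astrocytic block.

    ``neural_drive`` is the pair (pyramidal firing rate, interneuron
    firing rate) in 1/s, i.e. the values of the sigmoids driving the
    release-flux kernels.  The glutamate balance requires
    0 < J_G < VG_ae + VG_ne; an unsolvable balance raises ValueError.
    """
    rate_p, rate_i = neural_drive
    if rate_p < 0 or rate_i < 0:
        raise ValueError("firing rates must be >= 0")

    j_g = gp.W * rate_p / gp.w2
    v_sum = gp.VG_ae + gp.VG_ne
    if not (0.0 < j_g < v_sum):
        raise ValueError(
            f"glutamate balance unsolvable: need 0 < J_G={j_g:g} < "
            f"VG_ae+VG_ne={v_sum:g}"
        )
    s = j_g / v_sum
    glu_e = gp.s_g - math.log(1.0 / s - 1.0) / gp.r_g
    glu_a = gp.VG_ae * s / gp.VG_c

    j_y = gp.Z * rate_i / gp.z2

    def gaba_balance(g: float) -> float:
        return (
            j_y
            - gp.Vgamma_ae * g / (g + gp.Kgamma_ae)
            - gp.Vgamma_ne * g / (g + gp.Kgamma_ne)
        )

    if j_y <= 0.0:
        gaba_e = 0.0
    else:
        if j_y >= gp.Vgamma_ae + gp.Vgamma_ne:
            raise ValueError(
                f"GABA balance unsolvable: J_gamma={j_y:g} exceeds the total "
                f"uptake capacity {gp.Vgamma_ae + gp.Vgamma_ne:g}"
            )
        hi = max(gp.Kgamma_ae, gp.Kgamma_ne)
        while gaba_balance(hi) > 0:
            hi *= 2.0
        gaba_e = brentq(gaba_balance, 0.0, hi, xtol=1e-13)
    gaba_a = gp.Vgamma_ae * (gaba_e / (gaba_e + gp.Kgamma_ae)) / gp.Vgamma_c if gaba_e > 0 else 0.0

    fp = AstroFixedPoint(j_g, glu_e, glu_a, j_y, gaba_e, gaba_a)
    eig = np.linalg.eigvals(_glial_jacobian(fp, gp))
    if np.any(eig.real >= 0):
        raise RuntimeError("astrocytic fixed point is not stable")  # pragma: no cover
    return fp


def _glial_jacobian(fp: AstroFixedPoint, gp: GlialParams) -> np.ndarray:
    """Jacobian of the 8-D glial block (J_G, dJ_G, Glu_e, Glu_a, J_gamma,
    dJ_gamma, GABA_e, GABA_a) at frozen neural drive."""
    J = np.zeros((8, 8))
    s = _sig(fp.Glu_e, gp.s_g, gp.r_g)
    ds = gp.r_g * s * (1 - s)
    dh_ae = gp.Kgamma_ae / (fp.GABA_e + gp.Kgamma_ae) ** 2
    dh_ne = gp.Kgamma_ne / (fp.GABA_e + gp.Kgamma_ne) ** 2
    J[0, 1] = 1.0
    J[1, 0] = -gp.w1 * gp.w2
    J[1, 1] = -(gp.w1 + gp.w2)
    J[2, 0] = 1.0
    J[2, 2] = -(gp.VG_ae + gp.VG_ne) * ds
    J[3, 2] = gp.VG_ae * ds
    J[3, 3] = -gp.VG_c
    J[4, 5] = 1.0
    J[5, 4] = -gp.z1 * gp.z2
    J[5, 5] = -(gp.z1 + gp.z2)
    J[6, 4] = 1.0
    J[6, 6] = -(gp.Vgamma_ae * dh_ae + gp.Vgamma_ne * dh_ne)
    J[7, 6] = gp.Vgamma_ae * dh_ae
    J[7, 7] = -gp.Vgamma_c
    return J


def _neural_equilibrium_y0(p: float, v1: float, v2: float, params: ModelParams) -> float:
    """Lower-branch (preferred) equilibrium y0 at drive p; falls back to
    the upper branch when p exceeds the SNIC value."""
    lo, hi = bifurcation._domain(params)
    (p_sn1, y_sn1), (p_sn2, y_sn2) = bifurcation.find_saddle_nodes(v1, v2, params)

    def res(y0: float) -> float:
        return bifurcation.equilibrium_input(y0, v1, v2, params) - p

    if p < p_sn1:
        return float(brentq(res, lo, y_sn1, xtol=1e-13))
    return float(brentq(res, y_sn2, hi, xtol=1e-13))


def equilibrium_full_state(
    p: float, params: ModelParams, mode: str = "feedback", polish: bool = True
) -> np.ndarray:
    """Fixed point of the full 14-variable system at constant drive p.

    Built by alternating the closed-form neural equilibrium (at the
    current feedback modulations) with the astrocytic fixed point at the
    implied firing rates, then polished by damped root-finding on the
    full vector field.  Above the activation threshold no full fixed
    point exists (sustained firing overwhelms the glutamate clearance
    capacity); the fallback is then the origin followed by a discarded
    5-second transient at constant drive.
    """
    try:
        return _equilibrium_full_state(p, params, mode, polish)
    except (ValueError, FoldLossError):
        res = integrate(
            params,
            InputSpec(kind="constant", p_bar=p),
            t_span=(0.0, 5.0),
            init=np.zeros(NSTATE),
            mode=mode,
            record_stride=1000,
        )
        return res.states[-1]


def _equilibrium_full_state(
    p: float, params: ModelParams, mode: str, polish: bool
) -> np.ndarray:
    n, fb = params.neural, params.feedback
    v1 = v2 = 0.0
    state = np.zeros(NSTATE)
    for _ in range(60):
        y0 = _neural_equilibrium_y0(p, v1, v2, params)
        neural = bifurcation.equilibrium_state(y0, v1, v2, params)
        rate_p = n.a * y0 / n.A  # from annihilating the y3 equation
        rate_i = 2 * n.e0 * _sig(n.C3 * y0, n.v0 - v1, n.r)
        astro = steady_state_astro((rate_p, rate_i), params.glial)
        state = np.array(
            [
                *neural,
                astro.J_G, 0.0, astro.Glu_e, astro.Glu_a,
                astro.J_gamma, 0.0, astro.GABA_e, astro.GABA_a,
            ]
        )
        if mode == "feedforward":
            break
        v1_new = fb.mG_I * _sig(astro.Glu_e, fb.v_G, fb.r_G)
        v2_new = fb.m_gamma * _sig(astro.GABA_e, fb.v_gamma, fb.r_gamma)
        if abs(v1_new - v1) < 1e-13 and abs(v2_new - v2) < 1e-13:
            v1, v2 = v1_new, v2_new
            break
        v1 = v1 + 0.5 * (v1_new - v1)
        v2 = v2 + 0.5 * (v2_new - v2)

    if polish:
        sol = root(
            lambda s: model.rhs(list(s), p, params, mode),
            state,
            method="hybr",
            tol=1e-12,
        )
        if sol.success and np.all(np.isfinite(sol.x)):
            state = sol.x
    return state
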