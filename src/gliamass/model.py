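"""Transfer functions, dynamic excitability thresholds and the vector field.

The coupled system has 14 state variables in the fixed order

    (y0, y1, y2, y3, y4, y5,
     J_G, dJ_G, Glu_e, Glu_a,
     J_gamma, dJ_gamma, GABA_e, GABA_a)

where y0..y2 are the population outputs/inputs (mV), y3..y5 their time
derivatives, J_G / J_gamma the glutamate / GABA release fluxes (µM/s)
with their derivatives, and Glu/GABA the extracellular ("_e") and
astrocytic ("_a") concentrations (µM).

Two coupling modes are supported.  In *feedforward* mode the neural
compartment drives the glial one but all excitability thresholds stay at
the constant v0, so concentrations never act back on the neurons.  In
*feedback* mode the pyramidal and interneuron thresholds v_P and v_I are
instantaneous functions of the extracellular glutamate and GABA
concentrations.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import FeedbackParams, GlialParams, ModelParams, NeuronMassParams

STATE_VARS: tuple[str, ...] = (
    "y0", "y1", "y2", "y3", "y4", "y5",
    "J_G", "dJ_G", "Glu_e", "Glu_a",
    "J_gamma", "dJ_gamma", "GABA_e", "GABA_a",
)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_VARS)}
NSTATE = len(STATE_VARS)

MODES = ("feedforward", "feedback")

# exp argument beyond which the sigmoid saturates to 0/1 within double precision
_EXP_CLIP = 700.0


class NegativeConcentrationWarning(UserWarning):
    """Emitted when an extracellular/astrocytic concentration drifts below 0."""


def sigmoid(x: float, x_th: float, r_sl: float):
    """Logistic activation 1/(1 + exp(r_sl * (x_th - x))).

    Strictly increasing in ``x`` with inflection at ``x_th``; evaluated
    branch-wise on the sign of the exponent so it never overflows.
    Accepts scalars or numpy arrays.
    """
    if r_sl <= 0:
        raise ValueError(f"sigmoid stiffness must be > 0, got {r_sl}")
    z = np.multiply(r_sl, np.subtract(x_th, x))
    if not np.all(np.isfinite(z)):
        raise ValueError("sigmoid received non-finite input")
    z = np.clip(z, -_EXP_CLIP, _EXP_CLIP)
    out = np.where(
        z >= 0,
        np.exp(-z) / (1.0 + np.exp(-z)),
        1.0 / (1.0 + np.exp(z)),
    )
    if np.isscalar(x) and np.isscalar(x_th):
        return float(out)
    return out


def _sig(x: float, x_th: float, r_sl: float) -> float:
    """Scalar fast path of :func:`sigmoid` (no validation)."""
    z = r_sl * (x_th - x)
    if z >= 0:
        if z > _EXP_CLIP:
            return 0.0
        ez = math.exp(-z)
        return ez / (1.0 + ez)
    if z < -_EXP_CLIP:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def firing_rate(x, v, params: NeuronMassParams):
    """Population discharge rate 2*e0*S(x, v, r), bounded in (0, 2*e0) (1/s)."""
    return 2.0 * params.e0 * sigmoid(x, v, params.r)


def hill(x, k: float):
    """Michaelis-Menten saturation x/(x+k) used for GABA uptake."""
    if k <= 0:
        raise ValueError(f"Michaelis constant must be > 0, got {k}")
    denom = np.add(x, k)
    if np.any(denom == 0):
        raise ZeroDivisionError("hill evaluated at x == -k")
    out = np.divide(x, denom)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class DerivedThresholds:
    """Instantaneous excitability thresholds and feedback modulations (mV).

    v1 = mG_I * S([Glu]_e, v_G, r_G) shifts both pyramidal and interneuron
    excitability (scaled by mG_P/mG_I for the pyramidal population);
    v2 = m_gamma * S([GABA]_e, v_gamma, r_gamma) raises the pyramidal
    threshold.  The secondary pyramidal population P' is nonlocal to the
    astrocyte and keeps the basic threshold v0.
    """

    vP: float
    vPprime: float
    vI: float
    v1: float
    v2: float


def feedback_thresholds(
    glu_e: float, gaba_e: float, fb: FeedbackParams, v0: float
) -> DerivedThresholds:
    """Map extracellular concentrations to the dynamic thresholds.

    vP  = v0 + v2 - (mG_P/mG_I) * v1
    vP' = v0
    vI  = v0 - v1
    """
    s_glu = _sig(glu_e, fb.v_G, fb.r_G)
    v1 = fb.mG_I * s_glu
    v2 = fb.m_gamma * _sig(gaba_e, fb.v_gamma, fb.r_gamma)
    return DerivedThresholds(
        vP=v0 + v2 - fb.mG_P * s_glu,  # == v0 + v2 - (mG_P/mG_I) v1
        vPprime=v0,
        vI=v0 - v1,
        v1=v1,
        v2=v2,
    )


def rhs(state, p: float, params: ModelParams, mode: str) -> list[float]:
    """Time derivatives of the 14 state variables (plain-float fast path).

    ``state`` is any length-14 sequence in :data:`STATE_VARS` order,
    ``p`` the external drive on population P (1/s).  Used directly by the
    fixed-step integrator; :func:`vector_field` is the validating array
    wrapper.
    """
    npar, gpar, fb = params.neural, params.glial, params.feedback
    (y0, y1, y2, y3, y4, y5,
     jg, djg, glu_e, glu_a,
     jy, djy, gaba_e, gaba_a) = state

    if mode == "feedback":
        s_glu_fb = _sig(glu_e, fb.v_G, fb.r_G)
        v2 = fb.m_gamma * _sig(gaba_e, fb.v_gamma, fb.r_gamma)
        vP = npar.v0 + v2 - fb.mG_P * s_glu_fb
        vI = npar.v0 - fb.mG_I * s_glu_fb
    elif mode == "feedforward":
        vP = npar.v0
        vI = npar.v0
    else:
        raise ValueError(f"unknown coupling mode {mode!r}; expected one of {MODES}")

    two_e0 = 2.0 * npar.e0
    s_pyr = two_e0 * _sig(y1 - y2, vP, npar.r)       # pyramidal firing rate
    s_exc = two_e0 * _sig(npar.C1 * y0, npar.v0, npar.r)  # P' firing rate
    s_inh = two_e0 * _sig(npar.C3 * y0, vI, npar.r)  # interneuron firing rate

    A, a, B, b = npar.A, npar.a, npar.B, npar.b
    s_glu = _sig(glu_e, gpar.s_g, gpar.r_g)
    h_ae = gaba_e / (gaba_e + gpar.Kgamma_ae)
    h_ne = gaba_e / (gaba_e + gpar.Kgamma_ne)
    uptake_ae = gpar.Vgamma_ae * h_ae

    return [
        y3,
        y4,
        y5,
        A * a * s_pyr - 2.0 * a * y3 - a * a * y0,
        A * a * npar.C2 * s_exc + A * a * npar.G * s_pyr
        - 2.0 * a * y4 - a * a * y1 + A * a * p,
        B * b * npar.C4 * s_inh - 2.0 * b * y5 - b * b * y2,
        djg,
        gpar.W * gpar.w1 * s_pyr - (gpar.w1 + gpar.w2) * djg - gpar.w1 * gpar.w2 * jg,
        jg - (gpar.VG_ae + gpar.VG_ne) * s_glu,
        gpar.VG_ae * s_glu - gpar.VG_c * glu_a,
        djy,
        gpar.Z * gpar.z1 * s_inh - (gpar.z1 + gpar.z2) * djy - gpar.z1 * gpar.z2 * jy,
        jy - uptake_ae - gpar.Vgamma_ne * h_ne,
        uptake_ae - gpar.Vgamma_c * gaba_a,
    ]


def vector_field(
    state,
    p: float,
    neural: NeuronMassParams | ModelParams | None = None,
    glial: GlialParams | None = None,
    feedback: FeedbackParams | None = None,
    mode: str = "feedback",
) -> np.ndarray:
    """Full vector field as a numpy array.

    Accepts either a :class:`~gliamass.params.ModelParams` in place of the
    ``neural`` argument, or the three blocks separately.
    """
    if isinstance(neural, ModelParams):
        params = neural
    else:
        params = ModelParams(
            neural=neural or NeuronMassParams(),
            glial=glial or GlialParams(),
            feedback=feedback or FeedbackParams(),
        )
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE,):
        raise ValueError(f"state must have shape ({NSTATE},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    return np.array(rhs(state, p, params, mode), dtype=float)


def check_concentrations(state, clamp: bool = False):
    """Warn on (and optionally clamp) negative concentrations.

    The glutamate efflux sigmoid never vanishes, so Glu_e can drift below
    zero under prolonged zero drive when the equations are integrated as
    written.  Default policy keeps the published equations untouched and
    emits :class:`NegativeConcentrationWarning`; ``clamp=True`` floors the
    four concentration variables at 0.
    """
    conc_idx = [STATE_INDEX[n] for n in ("Glu_e", "Glu_a", "GABA_e", "GABA_a")]
    state = np.asarray(state, dtype=float)
    bad = [STATE_VARS[i] for i in conc_idx if state[i] < 0]
    if bad:
        warnings.warn(
            f"negative concentration(s): {', '.join(bad)}",
            NegativeConcentrationWarning,
            stacklevel=2,
        )
        if clamp:
            state = state.copy()
            for i in conc_idx:
                if state[i] < 0:
                    state[i] = 0.0
    return state
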