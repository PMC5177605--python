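"""Equilibrium curve and bifurcation structure of the neural compartment.

With the feedback modulations v1 (glutamate) and v2 (GABA) treated as
quasi-static parameters, the singular points of the 6-dimensional neural
subsystem form a graph over the pyramidal output y0: for every y0 in
(0, 2*A*e0/a) there is exactly one drive value

    p = f(y0, v1, v2)
      = (a/A) (v0 - (mG_P/mG_I) v1 + v2)
        - (a/(A r)) ln((2 A e0 - a y0) / (a y0))
        - (a G / A) y0
        - C2 * Shat(C1 y0, v0)
        + (a B / (b A)) C4 * Shat(C3 y0, v0 - v1)

whose relative extrema are the two saddle-node bifurcations.  The local
maximum SN1 coincides with a saddle-node on invariant circle (SNIC), so
p_SNIC = p_SN1 acts as the activation threshold of the population: below
it the system sits on the stable lower branch, above it a large-period
limit cycle produces LFP spikes.  Because df/dy0 does not depend on v2,
y_SNIC is v2-independent and p_SNIC is affine in v2 with slope a/A.

The upper branch loses its instability through a supercritical Hopf
bifurcation located here by bisection on the real part of the leading
complex eigenvalue pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import _sig
from .params import ModelParams

__all__ = [
    "FoldLossError",
    "EquilibriumCurve",
    "BifurcationSummary",
    "equilibrium_input",
    "equilibrium_input_grad",
    "equilibrium_state",
    "neural_jacobian",
    "stability_spectrum",
    "find_saddle_nodes",
    "find_hopf",
    "p_snic",
]

# dense-scan resolution for fold bracketing; folds are O(1e-2) wide in y0
_SCAN_POINTS = 4001
_EPS_FRAC = 1e-6


class FoldLossError(RuntimeError):
    """The equilibrium curve is not S-shaped (fold count != 2)."""

    def __init__(self, n_found: int, v1: float):
        self.n_found = n_found
        self.v1 = v1
        super().__init__(
            f"expected exactly 2 critical points of the equilibrium curve, "
            f"found {n_found} at v1={v1:g}; the S-shape (and hence the SNIC) "
            f"is lost in this regime"
        )


def _domain(params: ModelParams) -> tuple[float, float]:
    hi = params.neural.y0_max
    eps = _EPS_FRAC * hi
    return eps, hi - eps


def equilibrium_input(y0, v1: float, v2: float, params: ModelParams):
    """Drive p at which y0 is a singular point, for frozen (v1, v2) (1/s).

    Vectorized over ``y0``; the domain is the open interval (0, 2*A*e0/a).
    """
    n, fb = params.neural, params.feedback
    y0 = np.asarray(y0, dtype=float)
    hi = n.y0_max
    if np.any(y0 <= 0) or np.any(y0 >= hi):
        raise ValueError(f"y0 must lie in the open interval (0, {hi:g})")
    a, A, B, b = n.a, n.A, n.B, n.b
    two_e0 = 2.0 * n.e0
    shat_exc = two_e0 * _sigmoid_arr(n.C1 * y0, n.v0, n.r)
    shat_inh = two_e0 * _sigmoid_arr(n.C3 * y0, n.v0 - v1, n.r)
    pyr_shift = fb.ratio * v1 if v1 != 0.0 else 0.0  # avoid 0/0 at zero gains
    out = (
        (a / A) * (n.v0 - pyr_shift + v2)
        - (a / (A * n.r)) * np.log((two_e0 * A - a * y0) / (a * y0))
        - (a * n.G / A) * y0
        - n.C2 * shat_exc
        + (a * B / (b * A)) * n.C4 * shat_inh
    )
    return float(out) if out.ndim == 0 else out


def _sigmoid_arr(x, x_th, r_sl):
    z = np.clip(r_sl * (np.asarray(x_th) - np.asarray(x)), -700.0, 700.0)
    return np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))


def equilibrium_input_grad(y0, v1: float, params: ModelParams):
    """Analytic partial derivative of f with respect to y0 (v2-independent)."""
    n = params.neural
    y0 = np.asarray(y0, dtype=float)
    a, A, B, b = n.a, n.A, n.B, n.b
    two_e0 = 2.0 * n.e0
    s_exc = _sigmoid_arr(n.C1 * y0, n.v0, n.r)
    s_inh = _sigmoid_arr(n.C3 * y0, n.v0 - v1, n.r)
    # d/du Shat(u, v) = 2 e0 r S (1 - S)
    dshat_exc = two_e0 * n.r * s_exc * (1 - s_exc)
    dshat_inh = two_e0 * n.r * s_inh * (1 - s_inh)
    out = (
        (a / (A * n.r)) * (a / (two_e0 * A - a * y0) + 1.0 / y0)
        - a * n.G / A
        - n.C2 * n.C1 * dshat_exc
        + (a * B / (b * A)) * n.C4 * n.C3 * dshat_inh
    )
    return float(out) if out.ndim == 0 else out


def equilibrium_state(y0: float, v1: float, v2: float, params: ModelParams) -> np.ndarray:
    """Neural equilibrium (y0..y5) with the given y0 component.

    y2 annihilates the inhibitory second-order block, y1 - y2 inverts the
    pyramidal sigmoid at the dynamic threshold vP, and the derivative
    variables vanish.
    """
    n, fb = params.neural, params.feedback
    hi = n.y0_max
    if not (0.0 < y0 < hi):
        raise ValueError(f"y0 must lie in the open interval (0, {hi:g})")
    two_e0 = 2.0 * n.e0
    vP = n.v0 + v2 - (fb.ratio * v1 if v1 != 0.0 else 0.0)
    y2 = (n.B / n.b) * n.C4 * two_e0 * _sig(n.C3 * y0, n.v0 - v1, n.r)
    # invert Shat(u, vP) = a*y0/A  =>  u = vP - (1/r) ln(2Ae0/(a y0) - 1)
    y1 = y2 + vP - (1.0 / n.r) * math.log((two_e0 * n.A - n.a * y0) / (n.a * y0))
    return np.array([y0, y1, y2, 0.0, 0.0, 0.0])


def neural_jacobian(state6, v1: float, v2: float, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the 6-D neural subsystem at a given state."""
    n, fb = params.neural, params.feedback
    y0, y1, y2 = float(state6[0]), float(state6[1]), float(state6[2])
    A, a, B, b = n.A, n.a, n.B, n.b
    two_e0 = 2.0 * n.e0
    vP = n.v0 + v2 - (fb.ratio * v1 if v1 != 0.0 else 0.0)
    vI = n.v0 - v1

    s_p = _sig(y1 - y2, vP, n.r)
    s_e = _sig(n.C1 * y0, n.v0, n.r)
    s_i = _sig(n.C3 * y0, vI, n.r)
    d_p = two_e0 * n.r * s_p * (1 - s_p)
    d_e = two_e0 * n.r * s_e * (1 - s_e)
    d_i = two_e0 * n.r * s_i * (1 - s_i)

    J = np.zeros((6, 6))
    J[0, 3] = 1.0
    J[1, 4] = 1.0
    J[2, 5] = 1.0
    J[3, 0] = -a * a
    J[3, 1] = A * a * d_p
    J[3, 2] = -A * a * d_p
    J[3, 3] = -2.0 * a
    J[4, 0] = A * a * n.C2 * n.C1 * d_e
    J[4, 1] = A * a * n.G * d_p - a * a
    J[4, 2] = -A * a * n.G * d_p
    J[4, 4] = -2.0 * a
    J[5, 0] = B * b * n.C4 * n.C3 * d_i
    J[5, 2] = -b * b
    J[5, 5] = -2.0 * b
    return J


def stability_spectrum(y0: float, v1: float, v2: float, params: ModelParams) -> np.ndarray:
    """Eigenvalues (length 6) of the neural Jacobian at the equilibrium with
    output y0; the count of eigenvalues with positive real part labels the
    branch (0: stable, 1: saddle, 2: unstable focus)."""
    state = equilibrium_state(y0, v1, v2, params)
    return np.linalg.eigvals(neural_jacobian(state, v1, v2, params))


def n_unstable(y0: float, v1: float, v2: float, params: ModelParams, tol: float = 0.0) -> int:
    eig = stability_spectrum(y0, v1, v2, params)
    return int(np.sum(eig.real > tol))


@dataclass
class BifurcationSummary:
    """Located codim-1 bifurcation points for frozen (v1, v2).

    SN1 (the local maximum of f; coincides with the SNIC connection) and
    SN2 bound the middle branch; H1 is the supercritical Hopf on the upper
    branch, absent when the complex pair never crosses the imaginary axis.
    """

    p_SN1: float
    y_SN1: float
    p_SN2: float
    y_SN2: float
    v1: float
    v2: float
    p_H1: float | None = None
    y_H1: float | None = None

    @property
    def p_SNIC(self) -> float:
        return self.p_SN1

    @property
    def y_SNIC(self) -> float:
        return self.y_SN1


def find_saddle_nodes(
    v1: float, v2: float, params: ModelParams
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Locate the two saddle-node points as ((p_SN1, y_SN1), (p_SN2, y_SN2)).

    Critical points of f are bracketed by sign changes of the analytic
    df/dy0 on a dense grid and refined by Brent root-finding.  SN1 is the
    local maximum (d2f/dy02 < 0, smaller y0), SN2 the local minimum.
    Raises :class:`FoldLossError` when the fold count differs from 2.
    """
    lo, hi = _domain(params)
    grid = np.linspace(lo, hi, _SCAN_POINTS)
    dvals = equilibrium_input_grad(grid, v1, params)
    sign = np.sign(dvals)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) != 2:
        raise FoldLossError(len(crossings), v1)
    roots = []
    h = 1e-7 * params.neural.y0_max
    for i in crossings:
        root = brentq(
            lambda y: equilibrium_input_grad(y, v1, params),
            grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16,
        )
        # Newton polish on df/dy0 (second derivative by central difference)
        for _ in range(3):
            g = equilibrium_input_grad(root, v1, params)
            curv = (
                equilibrium_input_grad(root + h, v1, params)
                - equilibrium_input_grad(root - h, v1, params)
            ) / (2 * h)
            if curv == 0.0:
                break
            step = g / curv
            if abs(step) > h:  # stay inside the bracket scale
                break
            root -= step
        roots.append(float(root))
    # classify by curvature: SN1 is the local max of f
    h = 1e-7 * params.neural.y0_max
    curv = [
        (equilibrium_input_grad(y + h, v1, params) - equilibrium_input_grad(y - h, v1, params))
        / (2 * h)
        for y in roots
    ]
    pairs = [(float(equilibrium_input(y, v1, v2, params)), y) for y in roots]
    sn1 = pairs[0] if curv[0] < 0 else pairs[1]
    sn2 = pairs[1] if curv[0] < 0 else pairs[0]
    if not (sn1[1] < sn2[1]):
        raise FoldLossError(2, v1)  # orientation inconsistent with the S-shape
    return sn1, sn2


def p_snic(v1: float, v2: float, params: ModelParams) -> float:
    """Activation threshold p_SNIC = p_SN1 of the neural compartment (1/s)."""
    (p1, _y1), _ = find_saddle_nodes(v1, v2, params)
    return p1


def find_hopf(
    v1: float, v2: float, params: ModelParams
) -> tuple[float, float] | None:
    """Supercritical Hopf point (p_H1, y_H1) on the upper branch, or None.

    Bisects on y0 > y_SN2 for the zero crossing of the maximal real part
    of the complex-conjugate eigenvalue pair.
    """
    _, (_, y_sn2) = find_saddle_nodes(v1, v2, params)
    _, hi = _domain(params)

    def complex_re(y0: float) -> float:
        eig = stability_spectrum(y0, v1, v2, params)
        cplx = eig[np.abs(eig.imag) > 1e-9]
        if len(cplx) == 0:
            return -np.inf
        return float(np.max(cplx.real))

    ys = np.linspace(y_sn2 * 1.0001, hi, 400)
    vals = np.array([complex_re(y) for y in ys])
    finite = np.isfinite(vals)
    # the Hopf stabilizes the branch: real part crosses + -> - in y0
    idx = np.nonzero(finite[:-1] & finite[1:] & (vals[:-1] > 0) & (vals[1:] < 0))[0]
    if len(idx) == 0:
        return None
    sign_change = idx[0]
    y_h = brentq(complex_re, ys[sign_change], ys[sign_change + 1], xtol=1e-12)
    return float(equilibrium_input(y_h, v1, v2, params)), float(y_h)


def summarize(v1: float, v2: float, params: ModelParams, hopf: bool = True) -> BifurcationSummary:
    """Full bifurcation summary (saddle-nodes plus optional Hopf search)."""
    (p1, y1), (p2, y2) = find_saddle_nodes(v1, v2, params)
    out = BifurcationSummary(p_SN1=p1, y_SN1=y1, p_SN2=p2, y_SN2=y2, v1=v1, v2=v2)
    if hopf:
        h = find_hopf(v1, v2, params)
        if h is not None:
            out.p_H1, out.y_H1 = h
    return out


@dataclass
class EquilibriumCurve:
    """Sampled singular-point locus p = f(y0) with per-point stability.

    ``n_unstable`` counts eigenvalues with positive real part; the curve is
    a graph over y0, so each y0 carries exactly one p.
    """

    y0: np.ndarray
    p: np.ndarray
    n_unstable: np.ndarray
    eigenvalues: np.ndarray  # shape (n, 6), complex
    v1: float
    v2: float

    @classmethod
    def compute(
        cls, v1: float, v2: float, params: ModelParams, n: int = 400
    ) -> "EquilibriumCurve":
        lo, hi = _domain(params)
        y0 = np.linspace(lo, hi, n)
        p = equilibrium_input(y0, v1, v2, params)
        eig = np.empty((n, 6), dtype=complex)
        for i, y in enumerate(y0):
            eig[i] = stability_spectrum(float(y), v1, v2, params)
        nuns = (eig.real > 0).sum(axis=1)
        return cls(y0=y0, p=p, n_unstable=nuns, eigenvalues=eig, v1=v1, v2=v2)

    def stability_labels(self) -> list[str]:
        names = {0: "stable", 1: "saddle"}
        return [names.get(int(k), "unstable") for k in self.n_unstable]
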