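"""Regimes of astrocytic glutamate-uptake deficiency.

How the activation threshold p_SNIC responds to the glutamate modulation
v1 is governed by the feedback-gain ratio mG_P/mG_I relative to the
composite constant

    chi = B * e0 * r * C4 / (2 b).

Along the fold (d f/d y0 = 0) the v1-derivative of the threshold reduces
to (a/A) * (4 chi h(v1) - ratio) with h(v1) = S(1-S) evaluated at the
interneuron sigmoid on the fold, so stationary points of p_SNIC(v1)
solve ratio = 4 chi h(v1).  For ratio >= chi no solution exists.  For
0 < ratio < chi the quadratic in X = exp(r (v0 - v1 - C3 y0)) has roots
V+ and V- (with V+ V- = 1), giving the candidate extremum locations

    v1*  = v0 - C3 y0 - ln(V+)/r   (local minimum of p_SNIC, at the SN1 fold)
    v1** = v0 - C3 y0 - ln(V-)/r   (local maximum, at the SN2 fold).

The minimum lies inside the physical range [0, mG_I] exactly when the
ratio falls in [I1, I2], whose endpoints evaluate 4 chi h at the fold
for v1 = 0 and v1 = mG_I.  The resulting scenarios for an uptake
knockout are (a) reduced activity when ratio < I1, (b) sustained
hyperexcitability when ratio > I2, and (c) transient hyperexcitability
with recovery when I1 <= ratio <= I2.

All computations here freeze v2 = 0: the fold equation is v2-independent
and p_SNIC is affine in v2, so the extremum locations and the interval
[I1, I2] do not depend on that choice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .bifurcation import (
    FoldLossError,
    equilibrium_input_grad,
    find_saddle_nodes,
    p_snic,
)
from .model import _sig
from .params import ModelParams, NeuronMassParams

__all__ = [
    "RegimeReport",
    "V1Extremum",
    "chi",
    "v_pm",
    "dg_dv1",
    "find_v1_extrema",
    "ratio_interval",
    "classify_regime",
    "p_snic_surface",
    "regime_report",
]

SCENARIOS = {
    "a": "reduced-activity",
    "b": "sustained-hyperexcitability",
    "c": "transient-hyperexcitability",
    "none": "no-extremum",
}


def chi(np_: NeuronMassParams) -> float:
    """Composite threshold constant B*e0*r*C4/(2b) (dimensionless)."""
    return np_.B * np_.e0 * np_.r * np_.C4 / (2.0 * np_.b)


def v_pm(ratio: float, chi_val: float) -> tuple[float, float]:
    """Roots V+ >= V- of the stationarity quadratic
    ratio*X^2 + 2*(ratio - 2 chi)*X + ratio = 0, valid for 0 < ratio < chi.

    Both roots are positive and satisfy V+ * V- = 1.
    """
    if not (0.0 < ratio < chi_val):
        raise ValueError(
            f"feedback-gain ratio must satisfy 0 < ratio < chi "
            f"(got ratio={ratio:g}, chi={chi_val:g}): the stationarity "
            f"quadratic has no real roots otherwise"
        )
    q = chi_val / ratio
    disc = 2.0 * math.sqrt(q * (q - 1.0))
    return 2.0 * q - 1.0 + disc, 2.0 * q - 1.0 - disc


def dg_dv1(y0: float, v1: float, params: ModelParams) -> float:
    """Partial derivative of the equilibrium curve with respect to v1,
    (a/A) * (4 chi S(1-S) - ratio) with S the interneuron fold sigmoid."""
    n, fb = params.neural, params.feedback
    s = _sig(n.C3 * y0, n.v0 - v1, n.r)
    return (n.a / n.A) * (4.0 * chi(n) * s * (1.0 - s) - fb.ratio)


@dataclass
class V1Extremum:
    """A stationary point of p_SNIC(v1).

    kind : "min" (SN1 fold crossing) or "max" (SN2 fold crossing)
    in_range : whether v1 lies in the physical interval [0, mG_I]
    fold_valid : whether the stationary point lies inside the region where
        the S-shape (and hence the fold itself) exists; when False the
        reported v1 is the closed-form candidate evaluated at the
        fold-existence boundary and no extremum of p_SNIC is realized there
    """

    v1: float
    y0: float
    p: float
    kind: str
    in_range: bool
    fold_valid: bool = True


def _fold_boundary_v1(params: ModelParams, v2: float, v1_good: float, v1_bad: float) -> float:
    """Bisect for the largest v1 (between a fold-valid and a fold-lost
    value) at which the two saddle-nodes still exist."""
    for _ in range(60):
        mid = 0.5 * (v1_good + v1_bad)
        try:
            find_saddle_nodes(mid, v2, params)
            v1_good = mid
        except FoldLossError:
            v1_bad = mid
        if abs(v1_bad - v1_good) < 1e-10:
            break
    return v1_good


def _iterate_extremum(
    params: ModelParams,
    v2: float,
    branch: str,
    log_root: float,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[float, float, bool]:
    """Damped fixed-point iteration coupling the fold location with the
    closed-form update v1 = v0 - C3*y0 - ln(V)/r.

    If the candidate v1 leaves the fold-valid region, the fold is
    evaluated at the existence boundary and the result flagged (third
    return value False): the joint stationarity system then has no
    solution and no extremum of p_SNIC is realized.  Non-converged
    in-region iterations fall back to a direct 2-D root solve of
    (dg/dy0, dg/dv1).
    """
    n = params.neural
    v1 = 0.5 * params.feedback.mG_I
    y0 = math.nan
    fold_valid = True
    for _ in range(max_iter):
        v1_eval = v1
        try:
            sn1, sn2 = find_saddle_nodes(v1_eval, v2, params)
            fold_valid = True
        except FoldLossError:
            v1_eval = _fold_boundary_v1(params, v2, 0.0, v1)
            sn1, sn2 = find_saddle_nodes(v1_eval, v2, params)
            fold_valid = False
        y0 = sn1[1] if branch == "SN1" else sn2[1]
        v1_new = n.v0 - n.C3 * y0 - log_root / n.r
        if abs(v1_new - v1) < tol:
            if fold_valid:  # re-evaluate the fold at the converged v1
                try:
                    sn1, sn2 = find_saddle_nodes(v1_new, v2, params)
                    y0 = sn1[1] if branch == "SN1" else sn2[1]
                except FoldLossError:
                    pass
            return v1_new, y0, fold_valid
        v1 += 0.5 * (v1_new - v1)

    if fold_valid:
        sol = root(
            lambda x: [
                equilibrium_input_grad(x[0], x[1], params),
                dg_dv1(x[0], x[1], params),
            ],
            [y0, v1],
            method="hybr",
            tol=1e-13,
        )
        if sol.success:
            return float(sol.x[1]), float(sol.x[0]), True
    raise RuntimeError(
        f"extremum iteration did not converge on branch {branch}"
    )


def find_v1_extrema(
    params: ModelParams, v2: float = 0.0, confirm: bool = True
) -> tuple[V1Extremum, V1Extremum]:
    """Locate the local minimum (v1*) and maximum (v1**) of p_SNIC(v1).

    Requires ratio < chi.  Each extremum solves dg/dy0 = 0 jointly with
    dg/dv1 = 0; the minimum sits on the SN1 fold, the maximum on the SN2
    fold.  Extrema outside [0, mG_I] are returned flagged, not raised.
    With ``confirm=True`` the min/max character is checked on a local
    p_SNIC(v1) grid (only possible for in-range extrema with valid folds).
    """
    n, fb = params.neural, params.feedback
    chi_val = chi(n)
    v_plus, v_minus = v_pm(fb.ratio, chi_val)  # raises if ratio >= chi

    v1_star, y0_star, valid_star = _iterate_extremum(params, v2, "SN1", math.log(v_plus))
    v1_dstar, y0_dstar, valid_dstar = _iterate_extremum(params, v2, "SN2", math.log(v_minus))

    def _safe_p(v1: float, branch: str) -> float:
        try:
            return _fold_p(params, v1, v2, branch)
        except FoldLossError:
            return math.nan

    out = (
        V1Extremum(
            v1=v1_star,
            y0=y0_star,
            p=_safe_p(v1_star, "SN1"),
            kind="min",
            in_range=0.0 <= v1_star <= fb.mG_I,
            fold_valid=valid_star,
        ),
        V1Extremum(
            v1=v1_dstar,
            y0=y0_dstar,
            p=_safe_p(v1_dstar, "SN2"),
            kind="max",
            in_range=0.0 <= v1_dstar <= fb.mG_I,
            fold_valid=valid_dstar,
        ),
    )
    if confirm:
        for ext in out:
            if ext.fold_valid:
                _confirm_extremum(params, v2, ext)
    return out


def _fold_p(params: ModelParams, v1: float, v2: float, branch: str) -> float:
    sn1, sn2 = find_saddle_nodes(v1, v2, params)
    return sn1[0] if branch == "SN1" else sn2[0]


def _confirm_extremum(
    params: ModelParams, v2: float, ext: V1Extremum, delta: float = 1e-3
) -> None:
    """Numeric stand-in for the bordered-Hessian classification: check the
    sign pattern of the fold value on a local v1 grid around the candidate
    (SN1 fold for the minimum, SN2 fold for the maximum)."""
    branch = "SN1" if ext.kind == "min" else "SN2"
    try:
        center = _fold_p(params, ext.v1, v2, branch)
        left = _fold_p(params, ext.v1 - delta, v2, branch)
        right = _fold_p(params, ext.v1 + delta, v2, branch)
    except FoldLossError:
        return  # fold vanished in the neighbourhood; nothing to classify
    if ext.kind == "min" and not (left > center < right):
        raise RuntimeError(
            f"candidate v1*={ext.v1:g} is not a local minimum of p_SNIC"
        )
    if ext.kind == "max" and not (left < center > right):
        raise RuntimeError(
            f"candidate v1**={ext.v1:g} is not a local maximum of p_SNIC"
        )


def ratio_interval(params: ModelParams, v2: float = 0.0) -> tuple[float, float]:
    """Endpoints (I1, I2) of the admissible feedback-gain-ratio interval.

    I1 evaluates 4*chi*h at the SN1 fold for v1 = 0 (boundary case
    v1* = 0), I2 at the SN1 fold for v1 = mG_I (boundary case
    v1* = mG_I).  The interior minimum of p_SNIC(v1) exists in
    [0, mG_I] exactly for ratios in [I1, I2].
    """
    n, fb = params.neural, params.feedback
    chi_val = chi(n)
    out = []
    for v1 in (0.0, fb.mG_I):
        (_, y0_fold), _ = find_saddle_nodes(v1, v2, params)
        s = _sig(n.C3 * y0_fold, n.v0 - v1, n.r)
        out.append(4.0 * chi_val * s * (1.0 - s))
    i1, i2 = out
    return i1, i2


def classify_regime(
    ratio: float, chi_val: float, i1: float, i2: float
) -> str:
    """Scenario label for a given feedback-gain ratio.

    "a" (reduced activity, p_SNIC increasing in v1) for ratio < I1;
    "b" (sustained hyperexcitability, decreasing) for ratio > I2;
    "c" (transient hyperexcitability, interior minimum) in between;
    "none" when ratio >= chi (no stationary point at all).
    """
    if ratio >= chi_val:
        return "none"
    if ratio < i1:
        return "a"
    if ratio > i2:
        return "b"
    return "c"


def p_snic_surface(
    v1_grid, v2_grid, params: ModelParams
) -> np.ndarray:
    """Matrix of p_SNIC over a (v1, v2) grid, rows indexed by v1.

    Cells where the fold is lost are NaN.  Every row is affine in v2
    with slope a/A (the fold equation does not involve v2).
    """
    v1_grid = np.asarray(v1_grid, dtype=float)
    v2_grid = np.asarray(v2_grid, dtype=float)
    out = np.full((len(v1_grid), len(v2_grid)), np.nan)
    for i, v1 in enumerate(v1_grid):
        for j, v2 in enumerate(v2_grid):
            try:
                out[i, j] = p_snic(float(v1), float(v2), params)
            except FoldLossError:
                pass
    return out


@dataclass
class RegimeReport:
    """Summary of the glutamate-uptake-deficiency analysis for one ratio."""

    chi: float
    ratio: float
    I1: float
    I2: float
    scenario: str
    scenario_name: str
    V_plus: float | None = None
    V_minus: float | None = None
    v1_star: float | None = None
    y0_star: float | None = None
    v1_dstar: float | None = None
    y0_dstar: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def regime_report(params: ModelParams, v2: float = 0.0) -> RegimeReport:
    """Full :class:`RegimeReport` for the model's feedback-gain ratio."""
    n, fb = params.neural, params.feedback
    chi_val = chi(n)
    i1, i2 = ratio_interval(params, v2)
    scenario = classify_regime(fb.ratio, chi_val, i1, i2)
    report = RegimeReport(
        chi=chi_val,
        ratio=fb.ratio,
        I1=i1,
        I2=i2,
        scenario=scenario,
        scenario_name=SCENARIOS[scenario],
    )
    if scenario != "none":
        report.V_plus, report.V_minus = v_pm(fb.ratio, chi_val)
        ext_min, ext_max = find_v1_extrema(params, v2, confirm=False)
        report.v1_star, report.y0_star = ext_min.v1, ext_min.y0
        report.v1_dstar, report.y0_dstar = ext_max.v1, ext_max.y0
    return report
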