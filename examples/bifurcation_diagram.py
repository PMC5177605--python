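"""Locate the bifurcation structure of the neural compartment.

Computes the S-shaped equilibrium curve p = f(y0) for the uncoupled
thresholds (v1 = v2 = 0), the two saddle-node points, and the
supercritical Hopf on the upper branch.  p_SN1 is the SNIC value: the
activation threshold separating quiescence from large-amplitude LFP
oscillation.
"""
from gliamass import EquilibriumCurve, default_params
from gliamass.bifurcation import summarize

params = default_params()
summary = summarize(0.0, 0.0, params)

print(f"SN1 (= SNIC): p = {summary.p_SN1:8.3f} 1/s at y0 = {summary.y_SN1:.5f} mV")
print(f"SN2         : p = {summary.p_SN2:8.3f} 1/s at y0 = {summary.y_SN2:.5f} mV")
print(f"Hopf H1     : p = {summary.p_H1:8.3f} 1/s at y0 = {summary.y_H1:.5f} mV")

curve = EquilibriumCurve.compute(0.0, 0.0, params, n=200)
n_stable = int((curve.n_unstable == 0).sum())
print(f"\nequilibrium curve: {len(curve.y0)} points, {n_stable} stable")
print(
    "interpretation: for drives below p_SN1 the population rests on the\n"
    "stable lower branch; above it a large-period limit cycle produces\n"
    "isolated LFP spikes, so p_SN1 acts as the activation threshold."
)
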