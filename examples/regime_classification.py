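"""Classify glutamate-uptake-deficiency regimes by the feedback-gain ratio.

The response of the activation threshold p_SNIC to the glutamate
modulation v1 is governed by the ratio mG_P/mG_I relative to
chi = B e0 r C4 / (2 b) and the interval [I1, I2]: below I1 the
threshold rises with v1 (reduced activity), above I2 it falls
(sustained hyperexcitability), in between it has an interior minimum
(transient hyperexcitability with recovery).
"""
from gliamass import default_params
from gliamass.regimes import regime_report

params = default_params()

for ratio in (1.7, 2.43, 3.2):
    rep = regime_report(params.replace(mG_P=ratio))
    line = (f"ratio {ratio:4.2f}: scenario {rep.scenario} "
            f"({rep.scenario_name})")
    if rep.v1_star is not None:
        line += f", v1* = {rep.v1_star:+.3f} mV"
    print(line)

rep = regime_report(params)
print(f"\nchi = {rep.chi:.3f}, I1 = {rep.I1:.3f}, I2 = {rep.I2:.3f}")
print(
    "interpretation: only ratios inside [I1, I2] place the threshold\n"
    "minimum v1* within the physical range [0, mG_I], which is what\n"
    "lets the population recover after a transient of hyperactivity."
)
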