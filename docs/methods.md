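# Methods

## Model

The package implements a 14-variable ODE system: a three-population
neural mass (pyramidal *P* with direct self-feedback, secondary
pyramidal *P′*, interneurons *I*; state y0..y5) coupled bilaterally to a
glial compartment (release fluxes J_G, J_γ with their derivatives, and
the extracellular/astrocytic glutamate and GABA pools). All transfer
steps are sigmoidal except GABA uptake, which is Michaelis–Menten. The
coupling back onto the neurons acts through the population excitability
thresholds: v_P = v0 + v2 − (mG_P/mG_I)·v1 and v_I = v0 − v1, with
v1 = mG_I·S([Glu]e, v_G, r_G) and v2 = m_γ·S([GABA]e, v_γ, r_γ); the
nonlocal population P′ keeps the basic threshold v0. A `feedforward`
mode freezes all thresholds at v0, exactly decoupling the neurons from
the glia (used as the control condition in every protocol).

Assumptions inherited from the mass approach: populations are
homogeneous, transmitter kinetics are lumped into second-order kernels,
and the astrocytic feedback is instantaneous in the concentrations
(quasi-static sigmoids, no receptor dynamics).

### Units

Concentrations are µM throughout; the "arbitrary units" of the bolus
protocol are identified with µM. The degradation constants V_G^c and
V_γ^c act as first-order rates (1/s) — they multiply a concentration in
the astrocytic balance equations — and the GABA feedback threshold
v_γ = 25 is a concentration (µM); both are stated here because their
printed units elsewhere are ambiguous.

## Parameters

The bundled defaults (`gliamass/data/default_params.yaml`, equal to
`ModelParams()`) are the published reference set that places the neural
compartment in the noise-induced-spiking regime. The parameters that
matter most for the analyses here:

* a/A (≈ 30.77 (mV·s)⁻¹) — the exact slope of p_SNIC in v2.
* χ = B·e0·r·C4/(2b) = 10.395 — upper bound on feedback-gain ratios
  admitting a threshold extremum in v1.
* mG_P/mG_I (default 2.5) — the feedback-gain ratio; the regime
  classification compares it with [I1, I2] = [1.831, 3.161].
* V_G^ae, V_γ^ae — the knockout handles; protocols set them to 0.

## Drive and integration

The external input p(t) is either constant or a piecewise-constant
Gaussian process: one Normal(p̄, σ²) draw held per interval dt_noise.
The deterministic field is advanced by fixed-step RK4 (default
dt = 1 ms) with the noise frozen across each step, so deterministic
runs are 4th order (verified by a self-convergence test) while the
stochastic drive remains a well-defined bounded process. No
Itô/Stratonovich machinery is needed because the drive is piecewise
constant by construction.

Defaults: p̄ = p_SNIC(0,0) − 5 = 84.96 s⁻¹ and σ = 10 s⁻¹, so the band
p̄ ± σ straddles the activation threshold — the NIS condition. The noise
correlation time is dt_noise = 0.1 s. This choice matters: the SNIC
passage takes of order 1 s near threshold, so a 10 ms refresh averages
out and produces essentially no spikes (~0.02 Hz), whereas a 0.1 s
correlation time yields the isolated ~0.4–0.9 Hz spiking that defines
the regime; 0.1 s is also commensurate with the slowest synaptic kernel
(1/b = 20 ms) rather than an arbitrary long correlation. Initial
conditions default to the full-system fixed point at p̄ (closed-form
neural equilibrium alternated with the astrocytic balance, polished by
root-finding); above threshold no full fixed point exists — sustained
firing exceeds the saturable glutamate clearance, so [Glu]e grows
without bound, which is a model feature, not a failure — and the
fallback is the origin plus a discarded 5-s transient.

Negative concentrations: the glutamate efflux sigmoid never vanishes, so
[Glu]e can drift below zero under prolonged quiescence. The equations
are integrated as written; a structured warning is emitted and an
optional `clamp_concentrations` switch floors the pools at zero.

## Bifurcation analysis

Equilibria of the neural block form a graph p = f(y0, v1, v2) over
y0 ∈ (0, 2Ae0/a). Saddle-nodes are located by a 4001-point scan of the
analytic ∂f/∂y0 (which is v2-independent), bracketing, Brent refinement
and a final Newton polish — fold residuals are ~1e-12. SN1 is the local
maximum of f (the SNIC, p_SNIC := p_SN1), SN2 the local minimum; any
fold count other than two raises a structured fold-loss error rather
than guessing, because the whole analysis presumes the S-shape. The
Hopf point is found by bisection on the real part of the leading complex
eigenvalue pair of the analytic 6×6 Jacobian along the upper branch,
selecting the stabilizing (+→−) crossing; the pair-formation crossing
just above SN2 is explicitly skipped. Limit-cycle extrema are measured
by direct simulation, not continuation.

With the reference parameters: p_SNIC(0,0) = 89.96 s⁻¹,
SN2 at −124.95 s⁻¹, Hopf at 354.0 s⁻¹.

## Threshold extrema in v1 and the regime interval

Stationary points of p_SNIC(v1) solve ∂g/∂v1 = 0 on the fold, which
reduces to ratio = 4χ·S(1−S) at the fold sigmoid. The quadratic in
X = exp(r(v0 − v1 − C3·y0)) has roots V± with V+·V− = 1; the minimum v1*
lives on the SN1 fold (root V+), the maximum v1** on the SN2 fold
(root V−). Both are found by a damped (factor 0.5) fixed-point
iteration coupling the fold location with the closed-form update
v1 = v0 − C3·y0 − ln(V±)/r, with a 2-D trust-region root solve as
fallback; extremum character is confirmed numerically on a local grid of
the branch-matched fold value rather than via the bordered-Hessian
argument (equivalent and directly testable).

A geometric fact worth recording: with the reference parameters the
S-shape is lost on the window v1 ≈ (3.4, 5.5) and re-emerges beyond it
(the interneuron sigmoid saturates and the excitatory fold structure
returns). The maximum v1** therefore exists but sits near 8.2 mV — far
outside the physical range [0, mG_I] = [0, 1] — and is returned flagged
`in_range=False`. If an iteration candidate lands inside the lost
window, the fold is evaluated at the existence boundary and the result
flagged `fold_valid=False`.

I1 and I2 evaluate 4χ·S(1−S) at the SN1 fold for v1 = 0 and v1 = mG_I
(the boundary cases v1* = 0 and v1* = mG_I). All Prop-style
computations freeze v2 = 0; this is without loss because the fold
equation does not involve v2.

## Protocols and readouts

* **Bolus**: +20 µM on [GABA]e at t = 0. The feedforward control is
  bitwise neutral for the neural trajectory (shared noise path); the
  feedback run is quiescent exactly while the quasi-static threshold
  trace p_SNIC(t) — recomputed from the stored concentrations at a
  configurable stride — exceeds the drive.
* **GABA-uptake knockout**: V_γ^ae → 0 at t = 40 s, run to 100 s.
  [GABA]e roughly doubles (≈1.0 → ≈2.2 µM), p_SNIC rises, spiking slows.
* **Glutamate-uptake knockout**: V_G^ae → 0 at t = 20 s. The scenario
  comparison uses 120-s runs with windows pre [5,20], transient [40,70]
  and post [90,120] s: the scenario-(a) decline and the scenario-(c)
  recovery develop over ~60–100 s of glutamate accumulation under this
  drive realization, so a 60-s record truncates them mid-transient.

Spike detection: upward crossings of median + 5·1.4826·MAD with a 0.2 s
refractory and a hysteresis re-arm at the midpoint between median and
threshold (prevents double counts on spike tails). For knockout records
the statistics are estimated on the pre-switch baseline window, since
MAD-based thresholds break when the late record is densely oscillatory.
Frequency is a sliding-window count (default 5 s window).

Settling: `settle_time` returns the first time after the switch from
which a series stays within 5% (relative) of its final-20% plateau.
Single stochastic runs fluctuate around the plateau by more than 5%, so
the ensemble readout (`ensemble_settle_time`) applies the same rule to
the across-seed mean trace; with 10 seeds this gives ≈52–54 s for the
GABA knockout — the relaxation rate is set by the linearized neuronal
uptake, τ = V_γ^ne·K_γ^ne/(G*+K_γ^ne)² ≈ 5.7 s at the plateau.

## What the synthetic fixture does and does not show

`make_fixture_lfp` builds Gaussian baseline noise plus stereotyped
Gaussian bumps at known times; it validates the detector's counting,
localization, refractory and threshold logic against a known ground
truth. It does not emulate the asymmetric spike shape, the
subthreshold oscillation preceding SNIC passages, or rate
nonstationarity, so detector performance on model LFP is additionally
exercised in the protocol tests themselves.

## Known limitations

* The SNIC is identified with the saddle-node SN1 plus the numerically
  observed large-period cycle; the global homoclinic connection itself
  is not verified.
* The quasi-static p_SNIC(t) trace assumes the concentrations move
  slowly relative to the neural dynamics; during the first ~100 ms
  after a bolus that separation is marginal.
* Above threshold the extracellular glutamate pool has no finite
  steady state (clearance saturates); long supra-threshold runs are
  physiologically meaningful only up to the point where [Glu]e leaves
  the plausible range.
* The stochastic readouts (spike rates, settling) depend on the noise
  correlation time, which real data would have to constrain; only the
  sign structure of the scenario comparisons is robust to that choice.
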