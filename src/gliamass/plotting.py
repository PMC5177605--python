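"""Minimal figure helpers for the CLI and examples (matplotlib, Agg-safe)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bifurcation import EquilibriumCurve
from .experiments import ExperimentOutcome


def plot_bifurcation_diagram(curve: EquilibriumCurve, path: str | Path) -> None:
    """Equilibrium curve in the (p, y0) plane colored by stability."""
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {0: "tab:blue", 1: "tab:cyan", 2: "tab:green"}
    for k in sorted(set(curve.n_unstable.tolist())):
        mask = curve.n_unstable == k
        label = {0: "stable", 1: "1 unstable", 2: "2 unstable"}.get(int(k), f"{k} unstable")
        ax.plot(curve.p[mask], curve.y0[mask], ".", ms=2,
                color=colors.get(int(k), "tab:red"), label=label)
    ax.set_xlabel("p (1/s)")
    ax.set_ylabel("y0 (mV)")
    ax.set_title(f"equilibria, v1={curve.v1:g}, v2={curve.v2:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_experiment(outcome: ExperimentOutcome, path: str | Path) -> None:
    """LFP, concentrations and threshold trace of a protocol run."""
    res = outcome.result
    fig, axes = plt.subplots(4, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(res.t, res.lfp, lw=0.5)
    axes[0].set_ylabel("LFP (mV)")
    axes[1].plot(res.t, res["GABA_e"], lw=0.8, label="[GABA]_e")
    axes[1].plot(res.t, res["Glu_e"], lw=0.8, label="[Glu]_e")
    axes[1].set_ylabel("µM")
    axes[1].legend(fontsize=8)
    axes[2].plot(outcome.p_snic_t, outcome.p_snic_trace, lw=1.0, label="p_SNIC(t)")
    axes[2].axhline(res.metadata["input"]["p_bar"], ls="--", c="gray", label="p̄")
    axes[2].set_ylabel("1/s")
    axes[2].legend(fontsize=8)
    axes[3].plot(outcome.freq_t, outcome.freq_trace, lw=1.0)
    axes[3].set_ylabel("spike rate (1/s)")
    axes[3].set_xlabel("t (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
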