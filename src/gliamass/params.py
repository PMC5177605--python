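"""Parameter containers for the neuron-astrocyte mass model.

Parameters are grouped in three blocks mirroring the model structure:
the neural mass (two pyramidal populations P, P' and an interneuron
population I), the glial compartment (neurotransmitter release fluxes,
extracellular and astrocytic glutamate/GABA pools), and the astrocytic
feedback (sigmoidal modulation of population excitability thresholds by
extracellular concentrations).

The defaults are the published reference set that places the neural
compartment in the noise-induced-spiking (NIS) regime.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping


def _require_positive(obj: Any, names: tuple[str, ...], allow_zero: tuple[str, ...] = ()) -> None:
    for name in names:
        value = getattr(obj, name)
        if not isinstance(value, (int, float)):
            raise TypeError(f"parameter {name!r} must be a number, got {type(value).__name__}")
        if name in allow_zero:
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        elif value <= 0:
            raise ValueError(f"parameter {name!r} must be > 0, got {value}")


@dataclass
class NeuronMassParams:
    """Constants of the neural compartment.

    A, B : average excitatory/inhibitory synaptic gains (mV)
    a, b : reciprocal time constants of the excitatory/inhibitory
        postsynaptic kernels (1/s)
    e0 : half the maximum population discharge rate (1/s)
    v0 : basic excitability threshold (mV)
    r : sigmoid stiffness at the inflection point (1/mV)
    C1..C4 : synaptic connectivity gains (dimensionless)
    G : gain of the direct excitatory feedback of P onto itself
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    G: float = 40.0

    def __post_init__(self) -> None:
        _require_positive(
            self, ("A", "B", "a", "b", "e0", "v0", "r", "C1", "C2", "C3", "C4", "G")
        )

    @property
    def y0_max(self) -> float:
        """Upper bound 2*A*e0/a of the pyramidal output at equilibrium (mV)."""
        return 2.0 * self.A * self.e0 / self.a


@dataclass
class GlialParams:
    """Constants of the glial (astrocyte) compartment.

    W, Z : peak amplitudes of the glutamate/GABA release-flux kernels (µM/s)
    w1, w2, z1, z2 : rise/decay rate constants of those kernels (1/s)
    VG_ne, VG_ae : maximal neuronal/astrocytic glutamate uptake rates (µM/s)
    s_g, r_g : threshold (µM) and stiffness (1/µM) of the sigmoidal
        glutamate uptake
    Vgamma_ae, Vgamma_ne : maximal astrocytic/neuronal GABA uptake
        rates (µM/s), Michaelis-Menten with constants Kgamma_ae,
        Kgamma_ne (µM)
    VG_c, Vgamma_c : first-order degradation rates of astrocytic
        glutamate/GABA (1/s)

    ``VG_ae`` and ``Vgamma_ae`` may be set to 0 by uptake-knockout
    protocols; all other constants must be strictly positive.
    """

    W: float = 53.6
    Z: float = 53.6
    w1: float = 90.0
    w2: float = 33.0
    z1: float = 90.0
    z2: float = 33.0
    VG_ne: float = 0.5
    VG_ae: float = 4.5
    s_g: float = 6.0
    r_g: float = 0.9
    Vgamma_ae: float = 2.0
    Kgamma_ae: float = 8.0
    Vgamma_ne: float = 5.0
    Kgamma_ne: float = 24.0
    VG_c: float = 9.0
    Vgamma_c: float = 9.0

    def __post_init__(self) -> None:
        _require_positive(
            self,
            (
                "W", "Z", "w1", "w2", "z1", "z2", "VG_ne", "VG_ae", "s_g", "r_g",
                "Vgamma_ae", "Kgamma_ae", "Vgamma_ne", "Kgamma_ne", "VG_c", "Vgamma_c",
            ),
            allow_zero=("VG_ae", "Vgamma_ae"),
        )


@dataclass
class FeedbackParams:
    """Constants of the astrocytic feedback onto neural excitability.

    v_G, r_G : threshold (µM) and stiffness (1/µM) of the glutamate
        feedback sigmoid
    mG_P, mG_I : maximal glutamate feedback gains on the pyramidal and
        interneuron populations (mV); their ratio mG_P/mG_I governs the
        uptake-deficiency regime
    v_gamma, r_gamma, m_gamma : threshold (µM), stiffness (1/µM) and
        maximal gain (mV) of the GABA feedback on pyramidal neurons
    """

    v_G: float = 30.0
    r_G: float = 0.15
    mG_P: float = 2.5
    mG_I: float = 1.0
    v_gamma: float = 25.0
    r_gamma: float = 0.12
    m_gamma: float = 1.0

    def __post_init__(self) -> None:
        # gains may be zeroed to decouple a feedback pathway entirely
        _require_positive(
            self,
            ("v_G", "r_G", "mG_P", "mG_I", "v_gamma", "r_gamma", "m_gamma"),
            allow_zero=("mG_P", "mG_I", "m_gamma"),
        )

    @property
    def ratio(self) -> float:
        """Feedback-gain ratio mG_P/mG_I."""
        return self.mG_P / self.mG_I


# flat key -> (block attribute, field name); keys follow the published symbols
_BLOCK_FIELDS: dict[str, tuple[str, str]] = {}
for _block, _cls in (("neural", NeuronMassParams), ("glial", GlialParams), ("feedback", FeedbackParams)):
    for _f in dataclasses.fields(_cls):
        _BLOCK_FIELDS[_f.name] = (_block, _f.name)


@dataclass
class ModelParams:
    """The full parameter set: neural + glial + feedback blocks."""

    neural: NeuronMassParams = field(default_factory=NeuronMassParams)
    glial: GlialParams = field(default_factory=GlialParams)
    feedback: FeedbackParams = field(default_factory=FeedbackParams)

    @classmethod
    def from_dict(cls, flat: Mapping[str, float]) -> "ModelParams":
        """Build from a flat {symbol: value} mapping; omitted symbols keep
        their defaults, unknown symbols raise ``KeyError``."""
        kwargs: dict[str, dict[str, float]] = {"neural": {}, "glial": {}, "feedback": {}}
        for key, value in flat.items():
            if key not in _BLOCK_FIELDS:
                raise KeyError(f"unknown model parameter {key!r}")
            block, name = _BLOCK_FIELDS[key]
            kwargs[block][name] = float(value)
        return cls(
            neural=NeuronMassParams(**kwargs["neural"]),
            glial=GlialParams(**kwargs["glial"]),
            feedback=FeedbackParams(**kwargs["feedback"]),
        )

    def to_dict(self) -> dict[str, float]:
        """Flat {symbol: value} mapping in declaration order."""
        out: dict[str, float] = {}
        for block_name in ("neural", "glial", "feedback"):
            block = getattr(self, block_name)
            for f in dataclasses.fields(block):
                out[f.name] = getattr(block, f.name)
        return out

    def replace(self, **flat: float) -> "ModelParams":
        """Return a copy with the given flat-symbol overrides applied."""
        merged = self.to_dict()
        for key, value in flat.items():
            if key not in merged:
                raise KeyError(f"unknown model parameter {key!r}")
            merged[key] = float(value)
        return ModelParams.from_dict(merged)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


def default_params() -> ModelParams:
    """The published reference parameter set (NIS regime)."""
    return ModelParams()


PARAM_NAMES: tuple[str, ...] = tuple(_BLOCK_FIELDS)
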