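"""Cell, synapse and network parameter sets.

Internal unit system: mV, ms, nS, pA, pF.  These are mutually consistent
(pA/nS = mV and pF/nS = ms) so the single-cell equations can be integrated
without conversion factors.  Population rates are expressed in Hz; the
transfer-function layer converts ms -> s explicitly where needed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import yaml

__all__ = [
    "CellParams",
    "NetworkConfig",
    "load_presets",
    "cell_preset",
    "network_defaults",
    "classification_defaults",
    "tf_normalization",
    "reference_coefficients",
    "mean_field_defaults",
]


@dataclass(frozen=True)
class CellParams:
    """AdEx + conductance-synapse parameters for one cell type in one state.

    The neuron obeys

        cm dv/dt = gL (EL - v) + gL Delta exp((v - Vt)/Delta) - w + I_syn + I_ext
        tau_w dw/dt = a (v - EL) - w

    with an increment ``w += b`` and reset ``v = V_reset`` whenever v crosses
    ``V_spike``, followed by ``t_refrac`` ms of clamping.  Synaptic
    conductances jump by ``Qe``/``Qi`` per presynaptic spike and decay with
    ``tau_e``/``tau_i``.
    """

    cm: float          # membrane capacitance, pF
    gL: float          # leak conductance, nS
    EL: float          # resting potential, mV
    Vt: float          # spike-onset threshold, mV
    Delta: float       # spike-onset sharpness, mV
    a: float           # subthreshold adaptation conductance, nS
    b: float           # spike-triggered adaptation increment, pA
    tau_w: float       # adaptation time constant, ms
    Qe: float          # excitatory quantal conductance increment, nS
    Qi: float          # inhibitory quantal conductance increment, nS
    tau_e: float       # excitatory synaptic decay, ms
    tau_i: float       # inhibitory synaptic decay, ms
    Ee: float          # excitatory reversal potential, mV
    Ei: float          # inhibitory reversal potential, mV
    V_spike: float = -20.0   # numerical spike-detection threshold, mV
    V_reset: float = -50.0   # post-spike reset potential, mV
    t_refrac: float = 5.0    # refractory period, ms
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("cm", "gL", "tau_w", "tau_e", "tau_i", "Delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        # EL may sit at or below Ei (the hyperpolarised sleep RE preset has
        # EL = -85 mV under Ei = -80 mV), but both must lie below Ee.
        if not (self.Ei < self.Ee and self.EL < self.Ee):
            raise ValueError(
                f"require Ei, EL < Ee, got Ei={self.Ei}, EL={self.EL}, Ee={self.Ee}"
            )
        if not self.V_reset < self.V_spike:
            raise ValueError("V_reset must lie below V_spike")

    def with_overrides(self, **kw) -> "CellParams":
        return replace(self, **kw)

    @property
    def tau_m(self) -> float:
        """Leak membrane time constant cm/gL in ms."""
        return self.cm / self.gL


@dataclass(frozen=True)
class NetworkConfig:
    """Erdos-Renyi TC-RE network layout with external P and S drives."""

    N_tc: int = 500
    N_re: int = 500
    N_P: int = 8000
    N_S: int = 500
    p: dict = field(default_factory=dict)   # keys TC_RE, RE_TC, RE_RE, P_TC, P_RE, S_TC
    Q_drive: dict = field(default_factory=dict)  # per-projection quantal overrides (nS)
    state: str = "awake"                    # awake | sleep | spindle
    seed: int = 0

    def __post_init__(self) -> None:
        for key, val in self.p.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"connection probability {key}={val} outside [0,1]")
        for name in ("N_tc", "N_re", "N_P", "N_S"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.state not in ("awake", "sleep", "spindle"):
            raise ValueError(f"unknown state {self.state!r}")

    def cell_params(self, population: str) -> CellParams:
        """Preset parameters for 'TC' or 'RE' in this config's state."""
        return cell_preset(f"{population}_{self.state}")


def _load_yaml() -> dict:
    with resources.files("thalmf.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


_PRESETS_CACHE: dict | None = None


def load_presets() -> dict:
    """Raw preset dictionary (cached) mirroring the shipped config file."""
    global _PRESETS_CACHE
    if _PRESETS_CACHE is None:
        _PRESETS_CACHE = _load_yaml()
    return copy.deepcopy(_PRESETS_CACHE)


def cell_preset(name: str) -> CellParams:
    """Named cell preset, e.g. 'TC_awake', 'RE_sleep', 'TC_spindle'.

    Sleep/spindle entries inherit every unlisted parameter from their parent
    preset (the dash convention of the parameter table).
    """
    presets = load_presets()["cells"]
    if name not in presets:
        raise KeyError(f"unknown cell preset {name!r}; have {sorted(presets)}")
    entry = dict(presets[name])
    chain = [entry]
    while "inherits" in chain[-1]:
        chain.append(dict(presets[chain[-1].pop("inherits")]))
    merged: dict = {}
    for level in reversed(chain):
        level.pop("inherits", None)
        merged.update(level)
    valid = {f.name for f in fields(CellParams)}
    merged = {k: v for k, v in merged.items() if k in valid}
    return CellParams(label=name, **merged)


def network_defaults(state: str = "awake", seed: int = 0, **overrides) -> NetworkConfig:
    net = load_presets()["network"]
    kw = dict(
        N_tc=net["N_tc"], N_re=net["N_re"], N_P=net["N_P"], N_S=net["N_S"],
        p=dict(net["p"]), Q_drive=dict(net.get("Q_drive", {})),
        state=state, seed=seed,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


def classification_defaults() -> dict:
    return load_presets()["classification"]


def tf_normalization() -> dict:
    return load_presets()["transfer_function"]["normalization"]


def reference_coefficients(cell: str) -> list[float]:
    """Reference effective-threshold amplitudes for 'TC' or 'RE' (mV)."""
    return list(load_presets()["transfer_function"]["coefficients"][cell])


def mean_field_defaults() -> dict:
    return load_presets()["mean_field"]
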