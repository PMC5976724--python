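"""Huber-Braun cold-thermoreceptor neuron model with a hyperpolarization-
activated cation current (HB + I_h).

The model is a conductance-based parabolic burster: fast spike-generating
currents (I_d depolarizing Na_V, I_r repolarizing K_dr) ride on a slow
subthreshold oscillation driven by a persistent depolarizing current I_sd
(Na_P/Ca_T), a calcium-activated repolarizing current I_sr (K_Ca) and the
hyperpolarization-activated current I_h.  Depending on the slow conductances
(g_sd, g_sr, g_h) the isolated cell fires tonically, in bursts, with cycle
skipping, or chaotically; removing I_h (g_h = 0) abolishes chaos entirely.

Units: time in ms, voltage in mV, conductance densities in mS/cm^2,
currents in uA/cm^2, capacitance in uF/cm^2, so that dV/dt is in mV/ms.

State per neuron: (V, a_r, a_sd, a_sr, a_h).  a_d is instantaneous
(a_d = a_d_inf(V)) and the leak activation is identically 1, so neither is
a state variable.  a_sr tracks intracellular calcium concentration.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = [
    "NeuronParameters",
    "NeuronState",
    "temperature_factors",
    "steady_state_activation",
    "ionic_currents",
    "derivatives",
    "resting_state",
    "params_to_matrix",
    "PARAM_COLUMNS",
]

# a_sr enters I_sr through a Hill-type term a_sr^2 / (a_sr^2 + 0.4^2)
CA_HALF = 0.4


def temperature_factors(T: float) -> tuple[float, float]:
    """Temperature scale factors (rho, phi) at temperature ``T`` (deg C).

    ``rho`` scales conductances (Q10 = 1.3), ``phi`` scales channel
    kinetics (Q10 = 3); both are 1 at the 25 deg C reference.
    """
    if not math.isfinite(T):
        raise ValueError("temperature must be finite")
    e = (T - 25.0) / 10.0
    return 1.3**e, 3.0**e


def steady_state_activation(V, s_i: float, V0_i: float):
    """Sigmoid steady-state open probability 1 / (1 + exp(-s_i (V - V0_i))).

    Monotone increasing in V for s_i > 0 and decreasing for s_i < 0
    (the h-current activates under hyperpolarization: s_h < 0).
    """
    with np.errstate(over="ignore"):  # exp overflow -> sigmoid saturates at 0
        return 1.0 / (1.0 + np.exp(-s_i * (np.asarray(V, dtype=float) - V0_i)))


@dataclass(frozen=True)
class NeuronParameters:
    """Full constant set of the HB + I_h neuron.

    Defaults are the published reference values; the study varies only
    g_sd, g_sr and g_h.
    """

    C_m: float = 1.0        # uF/cm^2
    T: float = 36.0         # deg C
    g_d: float = 2.5        # mS/cm^2
    g_r: float = 2.8
    g_sd: float = 0.21
    g_sr: float = 0.28
    g_l: float = 0.06
    g_h: float = 0.4
    V0_d: float = -25.0     # mV
    V0_r: float = -25.0
    V0_sd: float = -40.0
    V0_h: float = -85.0
    s_d: float = 0.25       # 1/mV
    s_r: float = 0.25
    s_sd: float = 0.11
    s_h: float = -0.14
    tau_r: float = 2.0      # ms
    tau_sd: float = 10.0
    tau_sr: float = 35.0
    tau_h: float = 125.0
    eta: float = 0.014      # cm^2/uA, current-to-calcium factor
    kappa: float = 0.18     # calcium removal rate (dimensionless)
    E_d: float = 50.0       # mV
    E_r: float = -90.0
    E_sd: float = 50.0
    E_sr: float = -90.0
    E_l: float = -80.0
    E_h: float = -30.0

    def __post_init__(self) -> None:
        for name in ("g_d", "g_r", "g_sd", "g_sr", "g_l", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("tau_r", "tau_sd", "tau_sr", "tau_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")

    def with_(self, **kwargs) -> "NeuronParameters":
        return replace(self, **kwargs)

    # -- flat key=value serialization ------------------------------------
    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "NeuronParameters":
        kv = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = float(val)
        return cls(**kv)

    @classmethod
    def from_packaged_defaults(cls) -> "NeuronParameters":
        text = (
            importlib.resources.files("chaosnet") / "data" / "hbih_defaults.txt"
        ).read_text()
        return cls.from_text(text)


@dataclass
class NeuronState:
    """Dynamical variables of one neuron."""

    V: float = -60.0
    a_r: float = 0.0
    a_sd: float = 0.0
    a_sr: float = 0.1
    a_h: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.a_r, self.a_sd, self.a_sr, self.a_h])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "NeuronState":
        return cls(*map(float, x))


def resting_state(p: NeuronParameters, V: float = -60.0, a_sr: float = 0.1) -> NeuronState:
    """Default initial condition: gating at steady state for ``V``."""
    return NeuronState(
        V=V,
        a_r=float(steady_state_activation(V, p.s_r, p.V0_r)),
        a_sd=float(steady_state_activation(V, p.s_sd, p.V0_sd)),
        a_sr=a_sr,
        a_h=float(steady_state_activation(V, p.s_h, p.V0_h)),
    )


def ionic_currents(state: NeuronState, p: NeuronParameters) -> dict[str, float]:
    """Membrane current densities (uA/cm^2) at the given state.

    I_i = rho(T) g_i a_i (V - E_i) with a_l = 1 and a_d instantaneous;
    I_sr uses the calcium Hill term a_sr^2 / (a_sr^2 + 0.4^2).
    """
    rho, _ = temperature_factors(p.T)
    V = state.V
    a_d = float(steady_state_activation(V, p.s_d, p.V0_d))
    ca_gate = state.a_sr**2 / (state.a_sr**2 + CA_HALF**2)
    return {
        "I_d": rho * p.g_d * a_d * (V - p.E_d),
        "I_r": rho * p.g_r * state.a_r * (V - p.E_r),
        "I_sd": rho * p.g_sd * state.a_sd * (V - p.E_sd),
        "I_sr": rho * p.g_sr * ca_gate * (V - p.E_sr),
        "I_h": rho * p.g_h * state.a_h * (V - p.E_h),
        "I_l": rho * p.g_l * (V - p.E_l),
    }


def derivatives(state: NeuronState, p: NeuronParameters, I_syn: float = 0.0) -> np.ndarray:
    """Time derivative of (V, a_r, a_sd, a_sr, a_h) in (mV/ms, 1/ms, ...).

    dV/dt = (-I_sd - I_sr - I_h - I_d - I_r - I_l + I_syn) / C_m; the slow
    calcium variable integrates the (inward, negative) I_sd current:
    da_sr/dt = phi (-eta I_sd - kappa a_sr) / tau_sr.
    """
    x = state.as_array()
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite neuron state (numerical blow-up)")
    _, phi = temperature_factors(p.T)
    cur = ionic_currents(state, p)
    V = state.V
    dV = (
        -cur["I_sd"] - cur["I_sr"] - cur["I_h"] - cur["I_d"] - cur["I_r"]
        - cur["I_l"] + I_syn
    ) / p.C_m
    da_r = phi * (float(steady_state_activation(V, p.s_r, p.V0_r)) - state.a_r) / p.tau_r
    da_sd = phi * (float(steady_state_activation(V, p.s_sd, p.V0_sd)) - state.a_sd) / p.tau_sd
    da_sr = phi * (-p.eta * cur["I_sd"] - p.kappa * state.a_sr) / p.tau_sr
    da_h = phi * (float(steady_state_activation(V, p.s_h, p.V0_h)) - state.a_h) / p.tau_h
    return np.array([dV, da_r, da_sd, da_sr, da_h])


# ---------------------------------------------------------------------------
# struct-of-arrays packing for the compiled integration kernels
# ---------------------------------------------------------------------------

# column order consumed by chaosnet._kernels; rho/phi are precomputed
PARAM_COLUMNS = (
    "C_m", "rho", "phi",
    "g_d", "g_r", "g_sd", "g_sr", "g_l", "g_h",
    "V0_d", "V0_r", "V0_sd", "V0_h",
    "s_d", "s_r", "s_sd", "s_h",
    "tau_r", "tau_sd", "tau_sr", "tau_h",
    "eta", "kappa",
    "E_d", "E_r", "E_sd", "E_sr", "E_l", "E_h",
)


def params_to_matrix(params: NeuronParameters | Iterable[NeuronParameters]) -> np.ndarray:
    """Pack one or many parameter sets into the (N, 29) kernel layout."""
    if isinstance(params, NeuronParameters):
        params = [params]
    rows = []
    for p in params:
        rho, phi = temperature_factors(p.T)
        d = {"rho": rho, "phi": phi}
        d.update({f.name: getattr(p, f.name) for f in fields(p)})
        rows.append([d[c] for c in PARAM_COLUMNS])
    return np.asarray(rows, dtype=np.float64)
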