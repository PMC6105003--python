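"""Membrane-potential compartment: Kir, Na⁺, leak, K⁺ and T-type Ca²⁺ currents.

Hodgkin–Huxley-style voltage dynamics for a near-passive glial membrane:
an inward-rectifying K⁺ current dominates the resting conductance, with
classical Na⁺/K⁺/leak kinetics and a low-threshold T-type Ca²⁺ current
whose flux couples into the calcium compartment via the scale ``p_s``.

All rate "constants" are taken per second rather than per millisecond, so
the membrane responds on the second timescale of the calcium dynamics
(voltage saturation over multi-second pulses); the membrane block is
therefore an effective, qualitative model, fully overridable through
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._symcompat import exp
from .params import CoreParams, MembraneParams, StimulusProtocol

#: order of the membrane variables in state vectors
MEMBRANE_VARS = ("V", "m", "h", "n", "mcaT", "hcaT")


@dataclass
class MembraneState:
    """Voltage (mV) and gating variables (fractions in [0, 1])."""

    V: float = -65.0
    m: float = 0.05
    h: float = 0.6
    n: float = 0.32
    mcaT: float = 0.29
    hcaT: float = 0.01

    def as_array(self):
        return [self.V, self.m, self.h, self.n, self.mcaT, self.hcaT]


# --- ionic currents ---------------------------------------------------------

def i_kir(V, params: MembraneParams):
    """Inward-rectifier K⁺ current.

    ``-g_kir * [K_0 / (1 + exp((V - V_ka - V_a2)/V_a3))] * (V - V_ka - V_a1)``
    — zero at ``V = V_ka + V_a1`` and shut off by the logistic factor at
    depolarised potentials.
    """
    g = params.g_kir * params.g_kir_scale
    gate = params.K_0 / (1.0 + exp((V - params.V_ka - params.V_a2)
                                   / params.V_a3))
    return -g * gate * (V - params.V_ka - params.V_a1)


def i_na(V, m, h, params: MembraneParams):
    return params.g_na * m ** 3 * h * (V - params.V_na)


def i_k(V, n, params: MembraneParams):
    return params.g_k * n ** 4 * (V - params.V_k)


def i_leak(V, params: MembraneParams):
    return params.g_l * (V - params.V_l)


def i_caT(V, mcaT, hcaT, params: MembraneParams):
    """T-type Ca²⁺ current ``g_caT * mcaT² * hcaT * (V - V_ca)``."""
    return params.g_caT * mcaT ** 2 * hcaT * (V - params.V_ca)


# --- gating kinetics --------------------------------------------------------
# Classical Hodgkin-Huxley alpha/beta functions (per second); the resting
# values at -65 mV are m=0.053, h=0.596, n=0.318.

def alpha_m(V):
    return 0.1 * (V + 40.0) / (1.0 - exp(-(V + 40.0) / 10.0))


def beta_m(V):
    return 4.0 * exp(-(V + 65.0) / 18.0)


def alpha_h(V):
    return 0.07 * exp(-(V + 65.0) / 20.0)


def beta_h(V):
    return 1.0 / (1.0 + exp(-(V + 35.0) / 10.0))


def alpha_n(V):
    return 0.01 * (V + 55.0) / (1.0 - exp(-(V + 55.0) / 10.0))


def beta_n(V):
    return 0.125 * exp(-(V + 65.0) / 80.0)


# Low-threshold T-type gating: smooth steady-state/time-constant forms with
# half-activation -57 mV and half-inactivation -81 mV; at rest (-65 mV) the
# channel is mostly deinactivated-activated (m≈0.22, h≈0.02).

def mcaT_inf(V):
    return 1.0 / (1.0 + exp(-(V + 57.0) / 6.2))


def tau_mcaT(V):
    return 0.612 + 1.0 / (exp(-(V + 132.0) / 16.7) + exp((V + 16.8) / 18.2))


def hcaT_inf(V):
    return 1.0 / (1.0 + exp((V + 81.0) / 4.0))


def tau_hcaT(V):
    return 8.2 + 25.0 / (1.0 + exp((V + 70.0) / 6.0))


def membrane_derivatives(state, t, params: MembraneParams,
                         stim: StimulusProtocol | None = None,
                         i_app: float | None = None):
    """Time derivatives of (V, m, h, n, mcaT, hcaT).

    ``C_m dV/dt = -I_kir - I_na - I_l - I_k - I_caT + I_app(t)``; every
    gating variable follows ``dx/dt = (x_inf(V) - x)/tau_x(V)`` (HH gates
    in alpha/beta form).  ``i_app`` overrides the protocol lookup so the
    symbolic assembly can keep the applied current as a free parameter.
    """
    if isinstance(state, MembraneState):
        V, m, h, n, mcaT, hcaT = state.as_array()
    else:
        V, m, h, n, mcaT, hcaT = state
    if i_app is None:
        i_app = stim.current(t) if stim is not None else 0.0
    total = i_kir(V, params) + i_na(V, m, h, params) + i_leak(V, params)
    if params.include_ik:
        total = total + i_k(V, n, params)
    total = total + i_caT(V, mcaT, hcaT, params)
    dV = (-total + i_app) / params.C_m
    dm = alpha_m(V) * (1.0 - m) - beta_m(V) * m
    dh = alpha_h(V) * (1.0 - h) - beta_h(V) * h
    dn = alpha_n(V) * (1.0 - n) - beta_n(V) * n
    dmcaT = (mcaT_inf(V) - mcaT) / tau_mcaT(V)
    dhcaT = (hcaT_inf(V) - hcaT) / tau_hcaT(V)
    return [dV, dm, dh, dn, dmcaT, dhcaT]


def j_vca(state, params: CoreParams, mparams: MembraneParams):
    """VGCC calcium flux ``-p_s * g_caT * mcaT² * hcaT * (V - V_ca)``.

    The ion-flux conversion factor 1/(2Fw) is absorbed into ``p_s``, the
    single calibration knob for membrane→Ca²⁺ coupling; positive (inward)
    for ``V < V_ca``, and identically zero when ``p_s = 0``.
    """
    if isinstance(state, MembraneState):
        V, mcaT, hcaT = state.V, state.mcaT, state.hcaT
    else:
        V, _, _, _, mcaT, hcaT = state
    return -params.p_s * i_caT(V, mcaT, hcaT, mparams)
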