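"""Pure flux terms of the calcium compartment.

Each function maps (concentrations, parameters) to a flux in µM s⁻¹ (or a
rate in s⁻¹ for :func:`ryr_rate_k3`) with no hidden state, so the same code
serves the ODE right-hand side, Jacobian differencing, and unit tests.
Fluxes into the cytosol are positive.
"""

from __future__ import annotations

from ._symcompat import _is_symbolic, clamp_nonneg
from .params import CoreParams


def _check_nonneg(value, name: str) -> None:
    if not _is_symbolic(value) and value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")


def j_in(p, a, params: CoreParams):
    """Membrane leak: basal + IP3-linear + Aβ-pore influx.

    ``a1 + a2*p + k_beta*a**m_pore``; strictly increasing in both ``p``
    and ``a``.  The Aβ term models plasma-membrane pores formed by the
    peptide with cooperativity ``m_pore``.
    """
    _check_nonneg(p, "p")
    _check_nonneg(a, "a")
    return params.a1 + params.a2 * p + params.k_beta * a ** params.m_pore


def j_pm(c, params: CoreParams):
    """Plasma-membrane pump: Hill extrusion with coefficient 2, bound V_pm."""
    _check_nonneg(c, "c")
    c = clamp_nonneg(c)
    return params.V_pm * c ** 2 / (params.K_pm ** 2 + c ** 2)


def j_serca(c, c_e, params: CoreParams):
    """Bidirectional SERCA pump (four-state Markov reduction).

    ``(c - K1*c_e) / (K2 + K3*c + K4*c_e + K5*c*c_e)`` — forward (cytosol
    to ER) when ``c > K1*c_e``, reversed below that point.
    """
    c = clamp_nonneg(c)
    c_e = clamp_nonneg(c_e)
    den = params.K2 + params.K3 * c + params.K4 * c_e + params.K5 * c * c_e
    if not _is_symbolic(den) and den <= 0:
        raise ValueError("SERCA denominator must be positive")
    return (c - params.K1 * c_e) / den


def ryr_rate_k3(c, a, params: CoreParams):
    """Ca²⁺-dependent RyR rate (CICR), with Aβ-shifted sensitivity.

    ``k1 + k2*c**n / ((k_d + k_alpha*a)**n + c**n)``: sigmoidal in ``c``
    between the zero-calcium leak ``k1`` and ``k1 + k2``.  Aβ increases
    the half-saturation point, i.e. the rate at fixed ``c > 0`` decreases
    with ``a`` (the sensitivity shift; the influx gain shows up through
    ``k_alpha`` scans).
    """
    _check_nonneg(c, "c")
    _check_nonneg(a, "a")
    c = clamp_nonneg(c)
    n = params.n_ryr
    kd_eff = params.k_d + params.k_alpha * a
    return params.k1 + params.k2 * c ** n / (kd_eff ** n + c ** n)


def j_ryr(c, c_e, a, params: CoreParams):
    """RyR flux: gradient-driven leak ``k3(c, a) * (c_e - c)``."""
    return ryr_rate_k3(c, a, params) * (c_e - c)


def j_ipr(c, c_e, P0, params: CoreParams):
    """IPR flux ``(k_f*P0 + J_er)*(c_e - c)`` with open probability P0.

    The default ``J_er = 0`` matches the assembled model, where the RyR
    leak ``k1`` plays the baseline-leak role.
    """
    if not _is_symbolic(P0) and not (0.0 <= P0 <= 1.0):
        raise ValueError(f"P0 must lie in [0, 1], got {P0}")
    return (params.k_f * P0 + params.J_er) * (c_e - c)
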