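"""Dynamic IP3 production and degradation with Aβ-modified PLC terms.

A hybrid PLC model: Ca²⁺ activates IP3 production with maximal rate
``V_PLC(a) = v_PLC + mu_PLC*a`` and sensitivity ``K_PLC(a) = k_PLC +
kappa_PLC*a``; degradation mixes Ca²⁺-dependent phosphorylation (fraction
``eta``) with Ca²⁺-independent dephosphorylation.  Aβ thus both boosts PLC
output and blunts its calcium sensitivity.
"""

from __future__ import annotations

from ._symcompat import _is_symbolic, clamp_nonneg
from .params import Ip3Params


def production(c, a, params: Ip3Params):
    """IP3 production term (µM s⁻¹, before the 1/tau_p scaling).

    ``squared_sensitivity`` selects ``K_PLC(a)**2`` (consistent with the
    uncoupled PLC model) versus ``K_PLC(a)`` in the denominator.
    """
    c = clamp_nonneg(c)
    v = params.v_PLC + params.mu_PLC * a
    k = params.k_PLC + params.kappa_PLC * a
    den = k ** 2 if params.squared_sensitivity else k
    return v * c ** 2 / (den + c ** 2)


def degradation_coefficient(c, params: Ip3Params):
    """Coefficient of p in the degradation term (dimensionless, in (0, 1])."""
    c = clamp_nonneg(c)
    eta = params.eta
    return eta * c ** 2 / (params.K_3K ** 2 + c ** 2) + (1.0 - eta)


def ip3_derivative(p, c, a, params: Ip3Params):
    """dp/dt = (production(c, a) - degradation_coefficient(c) * p) / tau_p."""
    for name, v in (("p", p), ("c", c), ("a", a)):
        if not _is_symbolic(v) and v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return (production(c, a, params)
            - degradation_coefficient(c, params) * p) / params.tau_p


def equilibrium_p(c: float, a: float, params: Ip3Params) -> float:
    """Fixed point of p at frozen c: production / degradation coefficient."""
    return production(c, a, params) / degradation_coefficient(c, params)
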