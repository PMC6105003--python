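"""Scalar math that works on floats and sympy expressions alike.

The flux and gating formulas are written once and evaluated either
numerically (simulation, unit tests) or symbolically (to build the exact
Jacobian used by the variational equations and as an independent check on
the finite-difference Jacobian).
"""

from __future__ import annotations

import math
from typing import Any


def _is_symbolic(x: Any) -> bool:
    return hasattr(x, "free_symbols")


def exp(x: Any) -> Any:
    if _is_symbolic(x):
        import sympy
        return sympy.exp(x)
    return math.exp(x)


def clamp_nonneg(x: Any) -> Any:
    """Clamp transient negatives to zero for numeric inputs only.

    Adaptive integrators may probe slightly negative concentrations inside
    a rejected step; clamping inside flux evaluation keeps powers such as
    c**n well behaved without hiding unphysical stored states.  Symbolic
    inputs pass through so the Jacobian stays smooth.
    """
    if _is_symbolic(x):
        return x
    return x if x > 0.0 else 0.0
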