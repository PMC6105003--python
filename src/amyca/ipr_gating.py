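"""Six-state IP3-receptor gating kinetics (Sneyd–Dufour 2002).

The receptor occupies one of six states — resting R, open O, active A,
shut S, and two inactivated states I1 and I2 — with transition rates that
saturate in cytosolic Ca²⁺ (c) and depend linearly on IP3 (p) for the
R→O binding step.  Calcium flows when all four identical subunits are open
or active, giving the open probability ``(alpha1*O + alpha2*A)**4``.

S is eliminated by conservation (the five ODEs below plus
``S = 1 - R - O - A - I1 - I2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CoreParams, IprParams

#: order of the five independent occupancies in state vectors
IPR_VARS = ("R", "O", "A", "I1", "I2")


@dataclass
class IprState:
    """Occupancies of the six receptor states (fractions summing to 1)."""

    R: float = 1.0
    O: float = 0.0
    A: float = 0.0
    I1: float = 0.0
    I2: float = 0.0

    @property
    def S(self) -> float:
        return 1.0 - (self.R + self.O + self.A + self.I1 + self.I2)

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.O, self.A, self.I1, self.I2])


# --- saturating-binding transition rates -----------------------------------
# phi1: R -> I1 (Ca-dependent inactivation); phi2*p: R -> O (IP3 binding);
# phi_2m: O -> R; phi3: O -> S; kr3m: S -> O; phi4: O -> A; phi_4m: A -> O;
# phi5: A -> I2; recovery I1/I2 -> R/A at rate kr1m + l2m.

def phi1(c, q: IprParams):
    return (q.kr1 * q.L1 + q.l2) * c / (q.L1 + c * (1.0 + q.L1 / q.L3))


def phi2(c, q: IprParams):
    return (q.kr2 * q.L3 + q.l4 * c) / (q.L3 + c * (1.0 + q.L3 / q.L1))


def phi_2m(c, q: IprParams):
    return (q.kr2m + q.l4m * c) / (1.0 + c / q.L5)


def phi3(c, q: IprParams):
    return q.kr3 * q.L5 / (q.L5 + c)


def phi4(c, q: IprParams):
    return (q.kr4 * q.L5 + q.l6) * c / (q.L5 + c)


def phi_4m(c, q: IprParams):
    return q.L1 * (q.kr4m + q.l6m) / (q.L1 + c)


def ipr_derivatives(state, c, p, q: IprParams):
    """Time derivatives of the five independent occupancies (R, O, A, I1, I2).

    ``state`` may be an :class:`IprState` or a length-5 sequence in
    :data:`IPR_VARS` order.  dS/dt is the negative of the returned sum.
    """
    if isinstance(state, IprState):
        R, O, A, I1, I2 = state.as_array()
    else:
        R, O, A, I1, I2 = state
    S = 1.0 - (R + O + A + I1 + I2)
    rec = q.kr1m + q.l2m
    dR = phi_2m(c, q) * O - phi2(c, q) * p * R + rec * I1 - phi1(c, q) * R
    dO = (phi2(c, q) * p * R - (phi_2m(c, q) + phi4(c, q) + phi3(c, q)) * O
          + phi_4m(c, q) * A + q.kr3m * S)
    dA = phi4(c, q) * O - phi_4m(c, q) * A - phi5(c, q) * A + rec * I2
    dI1 = phi1(c, q) * R - rec * I1
    dI2 = phi5(c, q) * A - rec * I2
    return [dR, dO, dA, dI1, dI2]


def phi5(c, q: IprParams):
    return (q.kr1 * q.L1 + q.l2) * c / (q.L1 + c)


def open_probability(state, params: CoreParams):
    """IPR open probability ``(alpha1*O + alpha2*A)**4``."""
    if isinstance(state, IprState):
        O, A = state.O, state.A
    else:
        O, A = state[1], state[2]
    return (params.alpha1 * O + params.alpha2 * A) ** 4


def rate_matrix(c: float, p: float, q: IprParams) -> np.ndarray:
    """Markov generator Q (6x6) over (R, O, A, S, I1, I2) at fixed (c, p).

    Column j holds the outflow/inflow rates of state j: occupancy dynamics
    are ``dx/dt = Q @ x`` for the full six-state vector.  Used for the
    algebraic stationary distribution, an independent oracle for the
    integrated kinetics.
    """
    rec = q.kr1m + q.l2m
    # off-diagonal entries Q[i, j] = rate j -> i
    Q = np.zeros((6, 6))
    iR, iO, iA, iS, iI1, iI2 = range(6)
    Q[iO, iR] = phi2(c, q) * p
    Q[iI1, iR] = phi1(c, q)
    Q[iR, iO] = phi_2m(c, q)
    Q[iA, iO] = phi4(c, q)
    Q[iS, iO] = phi3(c, q)
    Q[iO, iS] = q.kr3m
    Q[iO, iA] = phi_4m(c, q)
    Q[iI2, iA] = phi5(c, q)
    Q[iR, iI1] = rec
    Q[iA, iI2] = rec
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return Q


def stationary_distribution(c: float, p: float, q: IprParams) -> np.ndarray:
    """Unique stationary occupancy over (R, O, A, S, I1, I2) at fixed (c, p).

    Solved algebraically from the null space of the generator with the
    simplex constraint (replace one balance row by the normalisation).
    """
    Q = rate_matrix(c, p, q)
    M = Q.copy()
    M[-1, :] = 1.0
    b = np.zeros(6)
    b[-1] = 1.0
    pi = np.linalg.solve(M, b)
    return pi


def stationary_independent(c: float, p: float, q: IprParams) -> np.ndarray:
    """Stationary occupancies in (R, O, A, I1, I2) order (S dropped)."""
    pi = stationary_distribution(c, p, q)
    return np.array([pi[0], pi[1], pi[2], pi[4], pi[5]])
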