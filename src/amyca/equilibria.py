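"""Steady states, linear stability, and one-/two-parameter bifurcation scans.

Equilibria of the membrane-free variants have a semi-analytic structure
that the continuation exploits: summing the cytosolic and (volume-scaled)
ER balance equations cancels every ER-exchange flux, so at equilibrium the
membrane influx equals the pump efflux, ``J_in = J_pm``.  This pins the
equilibrium cytosolic calcium (in closed form for clamped IP3; via a
scalar root coupling in the IP3 fixed point for the dynamic variant); the
IPR occupancies follow algebraically from the gating stationary
distribution, and the ER concentration from a second scalar root.  A
Newton polish on the full right-hand side then drives the residual below
tolerance.

Hopf points are detected as changes of the unstable-eigenvalue count by
two through a complex pair and refined by bisection; branch termination
(fold / divergence of the equilibrium) is refined by bisection on
equilibrium existence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, root

from . import fluxes, ip3_dynamics, ipr_gating
from .model import CompiledModel, ModelConfig
from .params import ModelParams

HOPF_RE_TOL = 1e-6     # |Re| certificate at a refined Hopf point
HOPF_IM_MIN = 1e-3     # minimum |Im| to call a crossing pair complex
PARAM_REFINE_TOL = 1e-8


@dataclass
class BifurcationPoint:
    """A located bifurcation with its diagnostic data."""

    kind: str                     # hopf | fold | period_doubling
    parameter: str
    value: float
    state: np.ndarray | None = None
    eigenpair: complex | None = None       # critical eigenvalue (hopf/fold)
    multiplier: float | None = None        # critical Floquet multiplier (pd)
    diagnostics: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {"kind": self.kind, "parameter": self.parameter,
               "value": float(self.value)}
        if self.state is not None:
            rec["state"] = [float(v) for v in self.state]
        if self.eigenpair is not None:
            rec["eigenvalue"] = [float(self.eigenpair.real),
                                 float(self.eigenpair.imag)]
        if self.multiplier is not None:
            rec["multiplier"] = float(self.multiplier)
        rec.update(self.diagnostics)
        return rec


class ContinuationError(RuntimeError):
    pass


def _with_param(params: ModelParams, config: ModelConfig, name: str,
                value: float) -> tuple[ModelParams, ModelConfig]:
    """Rebind one scan parameter, which may live in params or in config."""
    if name in ("a", "p_fixed", "p_s"):
        kwargs = {"variant": config.variant, "p_fixed": config.p_fixed,
                  "a": config.a, "p_s": config.p_s,
                  "stimulus": config.stimulus, "t_end": config.t_end,
                  "output_dt": config.output_dt, "rtol": config.rtol,
                  "atol": config.atol, "method": config.method}
        kwargs[name] = value
        return params, ModelConfig(**kwargs)
    return params.with_overrides(**{name: value}), config


def semi_analytic_equilibrium(params: ModelParams,
                              config: ModelConfig) -> np.ndarray | None:
    """Equilibrium of a membrane-free variant by flux balance, or None.

    Returns None when no equilibrium exists (influx at or above the pump
    ceiling, or the coupled influx/efflux balance has lost its root) —
    the divergence of the steady-state branch.
    """
    if config.variant == "with_membrane":
        raise ValueError("semi-analytic construction requires p_s = 0")
    core, a = params.core, config.a

    if config.variant == "dynamic_ip3":
        def g(c):
            p = ip3_dynamics.equilibrium_p(c, a, params.ip3)
            return fluxes.j_in(p, a, core) - fluxes.j_pm(c, core)
        # influx exceeds efflux at c=0; find the first sign change
        grid = np.geomspace(1e-8, 1e4, 400)
        gv = g(grid[0])
        c = None
        for lo, hi in zip(grid[:-1], grid[1:]):
            gh = g(hi)
            if gv > 0 >= gh:
                c = brentq(g, lo, hi, xtol=1e-15, rtol=1e-15)
                break
            gv = gh
        if c is None:
            return None
        p = ip3_dynamics.equilibrium_p(c, a, params.ip3)
    else:
        p = config.p_fixed
        j_influx = fluxes.j_in(p, a, core)
        if j_influx >= core.V_pm:
            return None
        c = core.K_pm * np.sqrt(j_influx / (core.V_pm - j_influx))

    occ = ipr_gating.stationary_independent(c, p, params.ipr)
    P0 = ipr_gating.open_probability(occ, core)
    k3 = fluxes.ryr_rate_k3(c, a, core)
    leak = core.k_f * P0 + core.J_er + k3

    def h(ce):
        return leak * (ce - c) - fluxes.j_serca(c, ce, core)

    hi = max(10.0 * c, 1.0)
    while h(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            return None
    ce = brentq(h, c, hi, xtol=1e-14, rtol=1e-15)
    y = [c, ce, *occ]
    if config.variant == "dynamic_ip3":
        y.append(p)
    return np.array(y)


def find_steady_state(guess: Sequence[float], params: ModelParams,
                      config: ModelConfig, tol: float = 1e-10) -> np.ndarray:
    """Newton root of the autonomous right-hand side from ``guess``.

    Uses the exact (symbolically compiled) Jacobian; raises
    ``ContinuationError`` with the residual history on non-convergence.
    """
    cm = CompiledModel(params, config)
    history: list[float] = []

    def fun(y):
        r = cm.rhs_autonomous(y)
        history.append(float(np.max(np.abs(r))))
        return r

    sol = root(fun, np.asarray(guess, dtype=float),
               jac=lambda y: cm.jac_autonomous(y), method="hybr",
               options={"xtol": 1e-13})
    resid = np.max(np.abs(cm.rhs_autonomous(sol.x)))
    if resid > tol:
        raise ContinuationError(
            f"steady-state solve stalled at residual {resid:.3e} "
            f"(history tail {history[-5:]})")
    return sol.x


def equilibrium_at(params: ModelParams, config: ModelConfig,
                   guess: np.ndarray | None = None) -> np.ndarray | None:
    """Best-effort equilibrium: semi-analytic construction + Newton polish."""
    if config.variant == "with_membrane":
        if guess is None:
            raise ValueError("membrane-variant equilibria need a guess")
        return find_steady_state(guess, params, config)
    y = semi_analytic_equilibrium(params, config)
    if y is None:
        return None
    return find_steady_state(y, params, config)


def jacobian_fd(state: Sequence[float], params: ModelParams,
                config: ModelConfig, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-variable scaled steps."""
    cm = CompiledModel(params, config)
    y = np.asarray(state, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1e-3)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (cm.rhs_autonomous(yp) - cm.rhs_autonomous(ym)) / (2 * h)
    return J


def eigenvalues_at(state: Sequence[float], params: ModelParams,
                   config: ModelConfig, analytic: bool = False) -> np.ndarray:
    """Spectrum of the Jacobian at an equilibrium.

    ``analytic=True`` uses the symbolically compiled Jacobian (fast path
    for scans); the default is central finite differences.
    """
    if analytic:
        J = CompiledModel(params, config).jac_autonomous(
            np.asarray(state, dtype=float))
    else:
        J = jacobian_fd(state, params, config)
    return np.linalg.eigvals(J)


def _n_unstable(ev: np.ndarray) -> int:
    return int(np.sum(ev.real > 0.0))


def _critical_pair(ev: np.ndarray) -> complex:
    """Eigenvalue with the smallest |Re| among those with nonzero Im,
    falling back to the smallest-|Re| real eigenvalue."""
    cplx = ev[np.abs(ev.imag) > HOPF_IM_MIN]
    pool = cplx if cplx.size else ev
    return complex(pool[np.argmin(np.abs(pool.real))])


@dataclass
class Branch:
    """Equilibrium branch from a one-parameter scan."""

    parameter: str
    values: np.ndarray            # parameter values with an equilibrium
    states: np.ndarray            # equilibria, one row per value
    max_re: np.ndarray            # max Re over the spectrum
    n_unstable: np.ndarray
    points: list[BifurcationPoint]
    termination: dict | None      # {"reason", "value"} or None

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({self.parameter: self.values,
                           "c": self.states[:, 0],
                           "ce": self.states[:, 1],
                           "max_re": self.max_re,
                           "n_unstable": self.n_unstable})
        return df


def scan_branch(parameter: str, p_range: tuple[float, float], steps: int,
                params: ModelParams, config: ModelConfig,
                norm_bound: float = 1e6) -> Branch:
    """Natural-parameter equilibrium continuation with bifurcation detection.

    Walks ``parameter`` over a uniform grid, computing the equilibrium and
    its spectrum at each value.  A change of the unstable count by two
    through a complex pair marks a Hopf point; by one through a real
    eigenvalue, a fold.  Loss of equilibrium existence (or equilibrium
    norm beyond ``norm_bound``) terminates the branch; the boundary is
    refined by bisection and reported both as a fold-type point and in
    ``Branch.termination``.
    """
    lo, hi = p_range
    grid = np.linspace(lo, hi, steps)

    def solve(v):
        pa, cf = _with_param(params, config, parameter, v)
        y = equilibrium_at(pa, cf)
        if y is not None and np.linalg.norm(y) > norm_bound:
            return None, None
        if y is None:
            return None, None
        ev = eigenvalues_at(y, pa, cf, analytic=True)
        return y, ev

    values, states, max_res, n_us = [], [], [], []
    points: list[BifurcationPoint] = []
    termination = None
    prev: tuple[float, int] | None = None

    for v in grid:
        y, ev = solve(v)
        if y is None:
            if prev is not None:
                term_v = _bisect_existence(solve, prev[0], v)
                termination = {"reason": "equilibrium lost (fold/divergence)",
                               "value": term_v}
                points.append(BifurcationPoint(
                    kind="fold", parameter=parameter, value=term_v,
                    diagnostics={"reason": "branch termination"}))
            else:
                termination = {"reason": "no equilibrium at scan start",
                               "value": v}
            break
        nu = _n_unstable(ev)
        if prev is not None and nu != prev[1]:
            points.extend(_refine_crossings(solve, parameter,
                                            prev[0], v, prev[1], nu))
        values.append(v)
        states.append(y)
        max_res.append(float(ev.real.max()))
        n_us.append(nu)
        prev = (v, nu)

    return Branch(parameter=parameter, values=np.array(values),
                  states=np.array(states), max_re=np.array(max_res),
                  n_unstable=np.array(n_us), points=points,
                  termination=termination)


def _bisect_existence(solve: Callable, v_ok: float, v_bad: float) -> float:
    for _ in range(80):
        mid = 0.5 * (v_ok + v_bad)
        if mid == v_ok or mid == v_bad:
            break
        y, _ = solve(mid)
        if y is None:
            v_bad = mid
        else:
            v_ok = mid
        if abs(v_bad - v_ok) < PARAM_REFINE_TOL:
            break
    return 0.5 * (v_ok + v_bad)


def _refine_crossings(solve: Callable, parameter: str, v0: float, v1: float,
                      nu0: int, nu1: int) -> list[BifurcationPoint]:
    """Bisect a change of the unstable count into located points."""
    lo, hi = v0, v1
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        _, ev = solve(mid)
        if ev is None:
            break
        if _n_unstable(ev) == nu0:
            lo = mid
        else:
            hi = mid
        if hi - lo < PARAM_REFINE_TOL:
            break
    v_star = 0.5 * (lo + hi)
    y, ev = solve(v_star)
    crit = _critical_pair(ev)
    kind = ("hopf" if abs(nu1 - nu0) == 2 and abs(crit.imag) > HOPF_IM_MIN
            else "fold")
    return [BifurcationPoint(
        kind=kind, parameter=parameter, value=v_star, state=y,
        eigenpair=crit,
        diagnostics={"n_unstable_before": nu0, "n_unstable_after": nu1})]


def hopf_points(branch: Branch) -> list[BifurcationPoint]:
    return [pt for pt in branch.points if pt.kind == "hopf"]


def two_parameter_scan(param1: str, p1_range: tuple[float, float],
                       steps1: int, param2: str,
                       p2_values: Sequence[float], params: ModelParams,
                       config: ModelConfig) -> dict:
    """Hopf/fold loci over a grid: a ``scan_branch`` in param1 per param2.

    Returns ``{"slices": {v2: Branch}, "loci": [...], "failures": [...]}``;
    failed slices are flagged, never silently dropped.
    """
    slices, loci, failures = {}, [], []
    for v2 in p2_values:
        pa, cf = _with_param(params, config, param2, v2)
        try:
            br = scan_branch(param1, p1_range, steps1, pa, cf)
        except Exception as exc:     # noqa: BLE001 - report, don't drop
            failures.append({"value": float(v2), "error": str(exc)})
            continue
        slices[float(v2)] = br
        for pt in br.points:
            loci.append({param2: float(v2), param1: float(pt.value),
                         "kind": pt.kind})
    return {"slices": slices, "loci": loci, "failures": failures}
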