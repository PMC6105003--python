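"""Assembled whole-cell model: state layout, right-hand side, integration.

Three variants are studied:

``constant_ip3``
    IP3 clamped at ``p_fixed``; state (c, ce, R, O, A, I1, I2).
``dynamic_ip3``
    IP3 produced/degraded dynamically; state gains ``p``.
``with_membrane``
    Constant IP3 plus the membrane block (V, m, h, n, mcaT, hcaT) with
    VGCC→Ca²⁺ coupling ``p_s > 0``.

A single assembly function owns the variable ordering, so the bifurcation
and orbit machinery never hard-code state positions.  The right-hand side
is written once, in terms of the pure flux/gating functions, and evaluated
either numerically or symbolically; the symbolic route is compiled with
sympy into fast scalar callables for the trajectory, Jacobian, and
variational integrations.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import fluxes, ip3_dynamics, ipr_gating, membrane
from .ipr_gating import IPR_VARS
from .membrane import MEMBRANE_VARS
from .params import (CoreParams, Ip3Params, IprParams, MembraneParams,
                     ModelParams, StimulusProtocol)

TRACE_COLUMNS = ("t", "c", "ce", "p", "R", "O", "A", "I1", "I2", "S",
                 "V", "m", "n", "h", "mcaT", "hcaT")

VARIANTS = ("constant_ip3", "dynamic_ip3", "with_membrane")


class FluxError(RuntimeError):
    """A flux term evaluated to NaN/Inf; the message names the term."""


@dataclass
class ModelConfig:
    """Which model variant runs, under what stimulus, and how it is solved."""

    variant: str = "constant_ip3"
    p_fixed: float = 0.0          # µM, IP3 clamp (constant_ip3/with_membrane)
    a: float = 0.0                # Aβ level
    p_s: float | None = None      # VGCC coupling; None -> params.core.p_s
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    t_end: float = 300.0          # s
    output_dt: float = 0.05       # s, resampling step for traces
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"          # any solve_ivp method; LSODA = stiff fallback

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")

    def effective_ps(self, params: ModelParams) -> float:
        """VGCC coupling actually applied: zero unless the membrane runs.

        ``p_s = 0`` with the membrane variant is allowed — the membrane
        evolves but is decoupled from calcium, recovering the
        membrane-free traces exactly.
        """
        ps = self.p_s if self.p_s is not None else params.core.p_s
        if ps < 0:
            raise ValueError("p_s must be nonnegative")
        if self.variant != "with_membrane":
            ps = 0.0
        return ps


def state_variables(variant: str) -> tuple[str, ...]:
    """Ordered dynamic variables of a variant (the index map)."""
    names = ["c", "ce", *IPR_VARS]
    if variant == "dynamic_ip3":
        names.append("p")
    elif variant == "with_membrane":
        names.extend(MEMBRANE_VARS)
    return tuple(names)


def initial_state(params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Default initial conditions: c=0.05, ce=10, R=1, p=0.01, HH rest."""
    values = {"c": 0.05, "ce": 10.0, "R": 1.0, "O": 0.0, "A": 0.0,
              "I1": 0.0, "I2": 0.0, "p": 0.01}
    ms = membrane.MembraneState()
    values.update(dict(zip(MEMBRANE_VARS, ms.as_array())))
    return np.array([values[v] for v in state_variables(config.variant)])


# --- generic right-hand side (floats or sympy expressions) ------------------

def _rhs_terms(y: Sequence, params: ModelParams, config: ModelConfig,
               a, p_s, i_app):
    """Flux breakdown and state derivative, generic over scalar type.

    Returns (derivatives list, named flux dict).  ``a``/``p_s``/``i_app``
    are passed explicitly so they may be symbols.
    """
    names = state_variables(config.variant)
    sv = dict(zip(names, y))
    c, ce = sv["c"], sv["ce"]
    ipr_state = [sv[k] for k in IPR_VARS]
    p = sv["p"] if config.variant == "dynamic_ip3" else config.p_fixed

    P0 = ipr_gating.open_probability(ipr_state, params.core)
    terms = {
        "J_IPR": fluxes.j_ipr(c, ce, P0, params.core),
        "J_RyR": fluxes.j_ryr(c, ce, a, params.core),
        "J_SERCA": fluxes.j_serca(c, ce, params.core),
        "J_in": fluxes.j_in(p, a, params.core),
        "J_pm": fluxes.j_pm(c, params.core),
        "J_vca": 0.0,
    }
    if config.variant == "with_membrane":
        mem = [sv[k] for k in MEMBRANE_VARS]
        terms["J_vca"] = -p_s * membrane.i_caT(mem[0], mem[4], mem[5],
                                               params.membrane)
    er = terms["J_IPR"] + terms["J_RyR"] - terms["J_SERCA"]
    dc = er + terms["J_in"] - terms["J_pm"] + terms["J_vca"]
    dce = -params.core.gamma * er
    deriv = [dc, dce]
    deriv.extend(ipr_gating.ipr_derivatives(ipr_state, c, p, params.ipr))
    if config.variant == "dynamic_ip3":
        deriv.append(ip3_dynamics.ip3_derivative(p, c, a, params.ip3))
    elif config.variant == "with_membrane":
        deriv.extend(membrane.membrane_derivatives(
            mem, 0.0, params.membrane, i_app=i_app))
    return deriv, terms


def rhs(state: Sequence[float], t: float, params: ModelParams,
        config: ModelConfig) -> np.ndarray:
    """Numeric right-hand side with NaN/Inf diagnosis by flux term."""
    a = config.a
    p_s = config.effective_ps(params)
    i_app = config.stimulus.current(t)
    deriv, terms = _rhs_terms(state, params, config, a, p_s, i_app)
    for name, value in terms.items():
        if not np.isfinite(value):
            raise FluxError(f"flux term {name} is non-finite ({value}) "
                            f"at t={t}, state={list(state)}")
    deriv = np.asarray(deriv, dtype=float)
    if not np.all(np.isfinite(deriv)):
        bad = state_variables(config.variant)[int(np.argmax(
            ~np.isfinite(deriv)))]
        raise FluxError(f"derivative of {bad} is non-finite at t={t}")
    return deriv


def flux_breakdown(state: Sequence[float], t: float, params: ModelParams,
                   config: ModelConfig) -> dict[str, float]:
    """Named flux terms at a state, for diagnostics."""
    a = config.a
    p_s = config.effective_ps(params)
    _, terms = _rhs_terms(state, params, config, a, p_s,
                          config.stimulus.current(t))
    return {k: float(v) for k, v in terms.items()}


# --- symbolic compilation ---------------------------------------------------

def _param_entries(variant: str) -> tuple[tuple[str, str], ...]:
    out: list[tuple[str, str]] = [("core", f.name) for f in
                                  dc_fields(CoreParams)
                                  if f.name not in ("n_ryr", "m_pore", "p_s")]
    out += [("ipr", f.name) for f in dc_fields(IprParams)]
    if variant == "dynamic_ip3":
        out += [("ip3", f.name) for f in dc_fields(Ip3Params)
                if f.name != "squared_sensitivity"]
    if variant == "with_membrane":
        out += [("mem", f.name) for f in dc_fields(MembraneParams)
                if f.name != "include_ik"]
    out += [("run", "a"), ("run", "p_s"), ("run", "p_fixed")]
    return tuple(out)


@lru_cache(maxsize=32)
def _compile_variant(variant: str, squared_sensitivity: bool,
                     include_ik: bool, n_ryr: int, m_pore: int):
    """Lambdified rhs and Jacobian with every scalar parameter symbolic."""
    import sympy

    names = state_variables(variant)
    ysym = sympy.symbols([f"y_{n}" for n in names], real=True)
    entries = _param_entries(variant)
    psym = sympy.symbols([f"q_{b}_{n}" for b, n in entries], real=True)
    pmap = {(b, n): s for (b, n), s in zip(entries, psym)}
    iapp = sympy.Symbol("i_app", real=True)

    def blk(cls, block, **extra):
        kw = {n: pmap[(block, n)] for (b, n) in entries if b == block}
        kw.update(extra)
        obj = object.__new__(cls)          # bypass numeric validation
        for k, v in kw.items():
            object.__setattr__(obj, k, v)
        return obj

    core = blk(CoreParams, "core", n_ryr=n_ryr, m_pore=m_pore, p_s=0.0)
    ipr = blk(IprParams, "ipr")
    ip3 = blk(Ip3Params, "ip3",
              squared_sensitivity=squared_sensitivity) \
        if variant == "dynamic_ip3" else Ip3Params()
    mem = blk(MembraneParams, "mem", include_ik=include_ik) \
        if variant == "with_membrane" else MembraneParams()
    params = object.__new__(ModelParams)
    object.__setattr__(params, "core", core)
    object.__setattr__(params, "ipr", ipr)
    object.__setattr__(params, "ip3", ip3)
    object.__setattr__(params, "membrane", mem)

    config = ModelConfig(variant=variant, p_fixed=pmap[("run", "p_fixed")])
    deriv, _ = _rhs_terms(list(ysym), params, config,
                          a=pmap[("run", "a")], p_s=pmap[("run", "p_s")],
                          i_app=iapp)
    fvec = sympy.Matrix(deriv)
    jmat = fvec.jacobian(sympy.Matrix(ysym))
    args = (*ysym, *psym, iapp)
    f_fn = sympy.lambdify(args, list(fvec), modules="math", cse=True)
    j_fn = sympy.lambdify(args, jmat.tolist(), modules="math", cse=True)
    return entries, f_fn, j_fn


def _param_vector(entries, params: ModelParams, config: ModelConfig,
                  p_s: float) -> tuple[float, ...]:
    blocks = {"core": params.core, "ipr": params.ipr, "ip3": params.ip3,
              "mem": params.membrane}
    run = {"a": config.a, "p_s": p_s, "p_fixed": config.p_fixed}
    return tuple(run[n] if b == "run" else float(getattr(blocks[b], n))
                 for b, n in entries)


class CompiledModel:
    """Fast callable right-hand side and exact Jacobian for one run.

    Wraps the sympy-compiled variant system with this run's parameter
    vector frozen; the applied current remains a per-call argument so the
    stimulus boxcar never enters the symbolic expressions.
    """

    def __init__(self, params: ModelParams, config: ModelConfig):
        self.params = params
        self.config = config
        self.p_s = config.effective_ps(params)
        entries, f_fn, j_fn = _compile_variant(
            config.variant, params.ip3.squared_sensitivity,
            params.membrane.include_ik, params.core.n_ryr,
            params.core.m_pore)
        self._pv = _param_vector(entries, params, config, self.p_s)
        self._f = f_fn
        self._j = j_fn
        self.variables = state_variables(config.variant)
        self.n = len(self.variables)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        i_app = self.config.stimulus.current(t)
        return np.array(self._f(*y, *self._pv, i_app))

    def rhs_autonomous(self, y: np.ndarray, i_app: float = 0.0) -> np.ndarray:
        return np.array(self._f(*y, *self._pv, i_app))

    def rhs_unstimulated(self, t: float, y: np.ndarray) -> np.ndarray:
        """(t, y) signature with zero applied current, for autonomous flows."""
        return np.array(self._f(*y, *self._pv, 0.0))

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        i_app = self.config.stimulus.current(t)
        return np.array(self._j(*y, *self._pv, i_app), dtype=float)

    def jac_autonomous(self, y: np.ndarray,
                       i_app: float = 0.0) -> np.ndarray:
        return np.array(self._j(*y, *self._pv, i_app), dtype=float)


@dataclass
class Trace:
    """Time-indexed simulated trajectory plus solver metadata."""

    data: pd.DataFrame
    params: ModelParams
    config: ModelConfig
    stats: dict

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")


def _segments(t0: float, t1: float,
              stim: StimulusProtocol) -> list[tuple[float, float]]:
    """Split [t0, t1] at stimulus edges so the boxcar discontinuity never
    falls inside an adaptive step."""
    pts = sorted({t0, t1, *[e for e in stim.edges if t0 < e < t1]})
    return list(zip(pts[:-1], pts[1:]))


def simulate(config: ModelConfig, params: ModelParams | None = None,
             y0: np.ndarray | None = None) -> Trace:
    """Integrate the configured variant and resample at the output step.

    Adaptive integration (default explicit Runge–Kutta (4,5); stiff
    methods selectable via ``config.method``) with dense output.  Raises
    ``FluxError`` carrying the last good time/state on solver failure.
    """
    params = params or ModelParams()
    cm = CompiledModel(params, config)
    if y0 is None:
        y0 = initial_state(params, config)
    y0 = np.asarray(y0, dtype=float)

    t_eval_all: list[np.ndarray] = []
    y_all: list[np.ndarray] = []
    stats = {"nfev": 0, "njev": 0, "segments": 0}
    wall0 = time.perf_counter()
    y_cur = y0
    for (s0, s1) in _segments(0.0, config.t_end, config.stimulus):
        kwargs = dict(rtol=config.rtol, atol=config.atol, dense_output=True)
        if config.method in ("LSODA", "BDF", "Radau"):
            kwargs["jac"] = cm.jac
        sol = solve_ivp(cm.rhs, (s0, s1), y_cur, method=config.method,
                        **kwargs)
        stats["nfev"] += sol.nfev
        stats["njev"] += getattr(sol, "njev", 0) or 0
        stats["segments"] += 1
        if not sol.success:
            raise FluxError(
                f"solver failed at t={sol.t[-1]:.6g} "
                f"(last good state {sol.y[:, -1].tolist()}): {sol.message}")
        n_pts = max(int(round((s1 - s0) / config.output_dt)), 1)
        tt = s0 + config.output_dt * np.arange(n_pts)
        tt = tt[tt <= s1 + 1e-12]
        t_eval_all.append(tt)
        y_all.append(sol.sol(tt))
        y_cur = sol.y[:, -1]
    t_eval_all.append(np.array([config.t_end]))
    y_all.append(y_cur[:, None])
    stats["wall_s"] = time.perf_counter() - wall0

    t = np.concatenate(t_eval_all)
    y = np.concatenate(y_all, axis=1)
    names = cm.variables
    df = pd.DataFrame({"t": t})
    for col in TRACE_COLUMNS[1:]:
        if col in names:
            df[col] = y[names.index(col)]
        elif col == "p" and config.variant != "dynamic_ip3":
            df[col] = config.p_fixed
        elif col == "S":
            occ = sum(y[names.index(k)] for k in IPR_VARS)
            df[col] = 1.0 - occ
        else:
            df[col] = np.nan
    return Trace(data=df, params=params, config=config, stats=stats)
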