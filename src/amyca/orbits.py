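"""Periodic orbits: Poincaré shooting, Floquet multipliers, period doubling.

Orbits are located by single shooting anchored to a Poincaré section in
the cytosolic calcium variable (the largest-amplitude observable): the
section fixes ``c`` at a reference level with increasing crossing
orientation, and Newton iterates on the remaining state components plus
the period until the orbit closes in state norm.  The monodromy matrix is
accumulated alongside the trajectory by integrating the variational
equations with the exact (symbolically compiled) Jacobian; its eigenvalues
are the Floquet multipliers, whose trivial member must equal one — an
integration-accuracy certificate.  Period doubling is detected as a real
multiplier crossing −1 along an orbit branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import BifurcationPoint
from .model import CompiledModel, ModelConfig, state_variables
from .params import ModelParams


class OrbitError(RuntimeError):
    pass


@dataclass
class PeriodicOrbit:
    """A closed orbit: period, one-period samples, amplitude, multipliers."""

    period: float
    x0: np.ndarray                 # state on the section (c increasing)
    t_samples: np.ndarray
    y_samples: np.ndarray          # shape (n, len(t_samples))
    multipliers: np.ndarray
    residual: float
    converged: bool = True
    method: str = "shooting"       # or "simulation" for the fallback

    @property
    def amplitude(self) -> float:
        c = self.y_samples[0]
        return float(c.max() - c.min())

    @property
    def trivial_multiplier(self) -> complex:
        return complex(self.multipliers[np.argmin(
            np.abs(self.multipliers - 1.0))])

    @property
    def pd_multiplier(self) -> float:
        """Period-doubling indicator: the most negative real multiplier.

        It crosses −1 at a period doubling and then runs away towards
        large negative values, so the minimum (not the value nearest −1)
        is the quantity to track along a branch.
        """
        re, im = self.multipliers.real, self.multipliers.imag
        reals = re[np.abs(im) <= 1e-8 + 1e-6 * np.abs(re)]
        neg = reals[reals < 0.0]
        if neg.size:
            return float(neg.min())
        pool = reals if reals.size else re
        return float(pool[np.argmin(np.abs(pool + 1.0))])


def _flow_with_monodromy(cm: CompiledModel, x0: np.ndarray, T: float,
                         rtol: float = 1e-9, atol: float = 1e-11,
                         n_samples: int = 0):
    """Integrate state + variational equations over [0, T].

    Returns (x(T), monodromy M, samples).  The variational system
    dΦ/dt = J(x)Φ, Φ(0)=I rides along the trajectory.
    """
    n = x0.size

    def rhs(t, z):
        y = z[:n]
        Phi = z[n:].reshape(n, n)
        dy = cm.rhs_autonomous(y)
        dPhi = cm.jac_autonomous(y) @ Phi
        return np.concatenate([dy, dPhi.ravel()])

    z0 = np.concatenate([x0, np.eye(n).ravel()])
    t_eval = np.linspace(0.0, T, n_samples) if n_samples else None
    sol = solve_ivp(rhs, (0.0, T), z0, method="RK45", rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise OrbitError(f"variational integration failed: {sol.message}")
    zT = sol.y[:, -1]
    samples = (sol.t, sol.y[:n, :])
    return zT[:n], zT[n:].reshape(n, n), samples


def _flow_state(cm: CompiledModel, x0: np.ndarray, T: float,
                rtol: float = 1e-9, atol: float = 1e-11) -> np.ndarray:
    """State-only flow map (cheap residual evaluations for line search)."""
    sol = solve_ivp(cm.rhs_unstimulated, (0.0, T), x0, method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise OrbitError(f"flow integration failed: {sol.message}")
    return sol.y[:, -1]


def _oscillatory_segment(params: ModelParams, config: ModelConfig,
                         t_transient: float, t_window: float):
    """Simulate past the transient; return (t, y) on the analysis window."""
    from .model import simulate
    cfg = ModelConfig(variant=config.variant, p_fixed=config.p_fixed,
                      a=config.a, p_s=config.p_s, stimulus=config.stimulus,
                      t_end=t_transient + t_window, output_dt=0.01,
                      rtol=config.rtol, atol=config.atol,
                      method=config.method)
    tr = simulate(cfg, params)
    names = state_variables(config.variant)
    mask = tr.t >= t_transient
    y = np.array([tr[v][mask] for v in names])
    return tr.t[mask], y


def _section_guess(t: np.ndarray, y: np.ndarray):
    """Initial shooting guess from upward crossings of c through its mean."""
    c = y[0]
    c_sec = 0.5 * (c.max() + c.min())
    up = np.where((c[:-1] < c_sec) & (c[1:] >= c_sec))[0]
    if up.size < 2:
        raise OrbitError("trace has fewer than two section crossings; "
                         "system may not be oscillatory here")
    i0, i1 = up[-2], up[-1]
    # linear interpolation onto the section
    w = (c_sec - c[i0]) / (c[i0 + 1] - c[i0])
    x0 = y[:, i0] + w * (y[:, i0 + 1] - y[:, i0])
    x0[0] = c_sec
    T = t[i1] - t[i0]
    return x0, T, c_sec


def find_orbit(params: ModelParams, config: ModelConfig,
               initial_guess: tuple[np.ndarray, float] | None = None,
               t_transient: float = 300.0, t_window: float = 120.0,
               tol: float = 1e-9, max_iter: int = 30,
               n_samples: int = 400, var_rtol: float = 1e-8,
               var_atol: float = 1e-10,
               fallback: bool = True) -> PeriodicOrbit:
    """Locate a periodic orbit by Newton shooting from a converged trace.

    ``initial_guess`` is ``(x0, T)`` with ``x0`` near the section; when
    omitted, a transient integration supplies it.  On shooting failure the
    orbit is characterised from the simulation itself (peak statistics),
    flagged ``method="simulation"`` with ``converged=False``.
    """
    cm = CompiledModel(params, config)
    n = cm.n
    if initial_guess is None:
        t, y = _oscillatory_segment(params, config, t_transient, t_window)
        x0, T, _ = _section_guess(t, y)
    else:
        x0, T = np.asarray(initial_guess[0], dtype=float), initial_guess[1]

    c_sec = x0[0]
    free = np.arange(1, n)          # c is pinned to the section

    x, T_cur = x0.copy(), float(T)
    residual = np.inf
    for _ in range(max_iter):
        xT, M, _ = _flow_with_monodromy(cm, x, T_cur, rtol=var_rtol,
                                        atol=var_atol)
        r = xT - x
        residual = float(np.linalg.norm(r))
        if residual < tol:
            break
        f_end = cm.rhs_autonomous(xT)
        # Jacobian of the residual w.r.t. (free components of x0, T)
        J = np.empty((n, n))
        J[:, :n - 1] = M[:, free] - np.eye(n)[:, free]
        J[:, n - 1] = f_end
        try:
            delta = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise OrbitError(f"singular shooting Jacobian: {exc}") from exc
        # damped Newton: backtrack on flow blow-up or residual growth
        step = 1.0
        while step >= 1.0 / 64.0:
            x_try = x.copy()
            x_try[free] += step * delta[:n - 1]
            T_try = T_cur + step * delta[n - 1]
            if T_try <= 0:
                step *= 0.5
                continue
            try:
                r_try = _flow_state(cm, x_try, T_try) - x_try
            except OrbitError:
                step *= 0.5
                continue
            if np.linalg.norm(r_try) < residual or step <= 1.0 / 64.0:
                x, T_cur = x_try, T_try
                break
            step *= 0.5
        else:
            if not fallback:
                raise OrbitError('shooting line search stalled')
            return _simulation_fallback(params, config, t_transient,
                                        t_window)
    else:
        if not fallback:
            raise OrbitError('shooting did not converge')
        return _simulation_fallback(params, config, t_transient, t_window)

    xT, M, samples = _flow_with_monodromy(cm, x, T_cur, rtol=var_rtol,
                                          atol=var_atol,
                                          n_samples=n_samples)
    mults = np.linalg.eigvals(M)
    return PeriodicOrbit(period=T_cur, x0=x, t_samples=samples[0],
                         y_samples=samples[1], multipliers=mults,
                         residual=residual, converged=True)


def _simulation_fallback(params: ModelParams, config: ModelConfig,
                         t_transient: float, t_window: float) -> PeriodicOrbit:
    """Degraded characterisation when shooting does not converge."""
    t, y = _oscillatory_segment(params, config, t_transient, t_window)
    try:
        x0, T, _ = _section_guess(t, y)
    except OrbitError:
        T, x0 = np.nan, y[:, -1]
    return PeriodicOrbit(period=float(T), x0=x0, t_samples=t, y_samples=y,
                         multipliers=np.array([np.nan]), residual=np.inf,
                         converged=False, method="simulation")


def floquet_multipliers(orbit: PeriodicOrbit, params: ModelParams,
                        config: ModelConfig,
                        rtol: float = 1e-9) -> np.ndarray:
    """Floquet multipliers of a converged orbit via the monodromy matrix.

    Recomputes the variational flow over one period and verifies that the
    trivial multiplier sits within 1e-3 of +1; an ill-conditioned
    monodromy raises ``OrbitError``.
    """
    if not orbit.converged:
        raise OrbitError("Floquet analysis requires a converged orbit")
    cm = CompiledModel(params, config)
    _, M, _ = _flow_with_monodromy(cm, orbit.x0, orbit.period, rtol=rtol)
    if not np.all(np.isfinite(M)):
        raise OrbitError("non-finite monodromy matrix")
    if np.linalg.cond(M) > 1e14:
        # strongly contracting orbits give a large condition number by
        # nature; flag it but let the trivial-multiplier certificate decide
        import logging
        logging.getLogger("amyca").warning(
            "monodromy condition number %.2e; small multipliers are at "
            "the noise floor", np.linalg.cond(M))
    mults = np.linalg.eigvals(M)
    triv = mults[np.argmin(np.abs(mults - 1.0))]
    if abs(triv - 1.0) > 1e-3:
        raise OrbitError(f"trivial multiplier off unity: {triv}")
    return mults


def continue_orbit(parameter: str, values: np.ndarray, params: ModelParams,
                   config: ModelConfig,
                   first_guess: tuple[np.ndarray, float] | None = None,
                   t_transient: float = 300.0) -> list[dict]:
    """Warm-started orbit continuation along ``parameter``.

    Returns one record per parameter value: the orbit plus its PD
    indicator (real multiplier nearest −1).  Branch loss is recorded and
    continuation stops there.
    """
    from .equilibria import _with_param
    records: list[dict] = []
    guess = first_guess
    for v in values:
        pa, cf = _with_param(params, config, parameter, v)
        try:
            orb = find_orbit(pa, cf, initial_guess=guess,
                             t_transient=t_transient)
        except OrbitError:
            orb = None
        if (orb is None or not orb.converged) and guess is not None:
            # retry cold: re-derive the guess from a fresh transient
            try:
                orb = find_orbit(pa, cf, initial_guess=None,
                                 t_transient=t_transient)
            except OrbitError as exc:
                records.append({"value": float(v), "orbit": None,
                                "error": str(exc)})
                break
        if orb is None or not orb.converged:
            records.append({"value": float(v), "orbit": orb,
                            "error": "shooting did not converge"})
            break
        records.append({"value": float(v), "orbit": orb,
                        "pd_multiplier": orb.pd_multiplier})
        guess = (orb.x0, orb.period)
    return records


def find_period_doubling(parameter: str, p_range: tuple[float, float],
                         params: ModelParams, config: ModelConfig,
                         steps: int = 12, refine_tol: float = 1e-3,
                         t_transient: float = 300.0,
                         first_only: bool = True,
                         ) -> list[BifurcationPoint]:
    """Locate period-doubling points along a periodic-orbit branch.

    Adaptive warm-started continuation of the (possibly unstable)
    primary orbit over ``p_range``: the parameter step halves whenever
    shooting fails or the period jumps discontinuously (a sign the solver
    slipped onto the doubled attractor), and each crossing of the
    PD multiplier through −1 is bisected to ``refine_tol``.
    """
    from .equilibria import _with_param

    def orbit_at(v, guess):
        pa, cf = _with_param(params, config, parameter, v)
        try:
            # closure tolerance sits above the variational error floor so
            # Newton terminates promptly; still well inside the 1e-6
            # orbit-closure contract
            orb = find_orbit(pa, cf, initial_guess=guess,
                             t_transient=t_transient, tol=1e-7,
                             max_iter=10, fallback=False)
        except OrbitError:
            return None
        return orb if orb.converged else None

    lo, hi = p_range
    step0 = (hi - lo) / steps
    v = lo
    orb = orbit_at(v, None)
    if orb is None:
        raise OrbitError(f"no converged orbit at {parameter}={lo}")
    points: list[BifurcationPoint] = []
    step = step0
    while v < hi - 1e-12:
        v_next = min(v + step, hi)
        cand = orbit_at(v_next, (orb.x0, orb.period))
        same_branch = (cand is not None and
                       abs(cand.period - orb.period) < 0.25 * orb.period)
        if not same_branch:
            step *= 0.5
            if step < max(refine_tol / 4, 1e-6):
                break                       # branch lost
            continue
        m0, m1 = orb.pd_multiplier, cand.pd_multiplier
        if (m0 + 1.0) * (m1 + 1.0) < 0:
            v_star = _bisect_pd(orbit_at, v, orb, v_next, cand, refine_tol)
            points.append(BifurcationPoint(
                kind="period_doubling", parameter=parameter, value=v_star,
                multiplier=-1.0,
                diagnostics={"bracket_multipliers": [float(m0), float(m1)]}))
            if first_only:
                return points
        v, orb = v_next, cand
        step = min(step * 1.5, step0)
    return points


def _bisect_pd(orbit_at, v_lo, orb_lo, v_hi, orb_hi, tol) -> float:
    m_lo = orb_lo.pd_multiplier
    while v_hi - v_lo > tol:
        v_mid = 0.5 * (v_lo + v_hi)
        guess = (orb_lo.x0, orb_lo.period)
        orb = orbit_at(v_mid, guess)
        if orb is None or abs(orb.period - orb_lo.period) > 0.3 * orb_lo.period:
            guess = (orb_hi.x0, orb_hi.period)
            orb = orbit_at(v_mid, guess)
        if orb is None:
            # shooting only fails on the strongly unstable (post-PD) side;
            # shrink the bracket from above
            v_hi = v_mid
            continue
        if (orb.pd_multiplier + 1.0) * (m_lo + 1.0) > 0:
            v_lo, orb_lo, m_lo = v_mid, orb, orb.pd_multiplier
        else:
            v_hi, orb_hi = v_mid, orb
    return 0.5 * (v_lo + v_hi)
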