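"""Model parameters with literature defaults.

All concentrations are in µM, times in seconds, voltages in mV.  The
amyloid-beta level ``a`` is a dimensionless control parameter numerically
equal to the ambient Aβ concentration in µM; it is held constant over a
simulation because Aβ accumulates on a timescale of months to years while
the calcium dynamics of interest play out in seconds to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class CoreParams:
    """Rates and constants of the calcium compartment.

    The defaults are the baseline parameterisation of the whole-cell model:
    IPR density ``k_f``; RyR leak/maximal rates ``k1``/``k2`` with CICR
    sensitivity ``k_d`` (Hill exponent ``n_ryr``); bidirectional SERCA
    constants ``K1..K5``; membrane leak ``a1 + a2*p + k_beta*a**m_pore``;
    plasma-membrane pump ``V_pm``, ``K_pm`` (Hill coefficient 2);
    cytosol/ER volume ratio ``gamma``.  ``k_alpha`` couples Aβ to the RyR
    sensitivity; ``k_beta``/``m_pore`` model Aβ membrane pores.  ``p_s``
    scales the voltage-gated Ca²⁺ flux (0 decouples the membrane).
    """

    k_f: float = 0.98        # s^-1, IPR density rate
    J_er: float = 0.0        # s^-1, explicit ER leak (baseline role played by k1)
    alpha1: float = 0.1      # open-state weight in the IPR open probability
    alpha2: float = 0.9      # active-state weight
    k1: float = 0.013        # s^-1, RyR zero-calcium leak
    k2: float = 0.18         # s^-1, RyR maximal rate
    k_d: float = 0.13        # µM, RyR CICR sensitivity
    k_alpha: float = 0.75    # Aβ -> RyR sensitivity coupling
    n_ryr: int = 3           # RyR Hill exponent
    K1: float = 1e-4         # SERCA (dimensionless)
    K2: float = 0.007        # s
    K3: float = 0.06         # µM^-1 s
    K4: float = 0.0014       # µM^-1 s
    K5: float = 0.007        # µM^-2 s
    a1: float = 0.003        # µM s^-1, basal membrane leak
    a2: float = 0.02         # s^-1, IP3-dependent leak slope
    k_beta: float = 1.0      # s^-1, Aβ pore rate constant
    m_pore: int = 4          # Aβ pore cooperativity
    V_pm: float = 2.8        # µM s^-1, plasma-membrane pump maximal rate
    K_pm: float = 0.425      # µM, pump sensitivity
    gamma: float = 5.4       # cytosolic/ER volume ratio
    p_s: float = 0.0         # VGCC -> Ca²⁺ coupling scale (absorbs 1/(2Fw))

    def __post_init__(self) -> None:
        for name in ("k_f", "J_er", "k1", "k2", "k_d", "k_alpha", "K1", "K2",
                     "K3", "K4", "K5", "a1", "a2", "k_beta", "V_pm", "K_pm",
                     "p_s"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(self.gamma > 0, "gamma must be positive")
        _require(self.n_ryr >= 1, "n_ryr must be a positive integer")
        _require(self.m_pore >= 1, "m_pore must be a positive integer")


@dataclass
class IprParams:
    """Six-state IP3-receptor transition-rate constants (Sneyd–Dufour 2002).

    Rate constants k_i (µM^-1 s^-1 forward, s^-1 backward), saturating
    constants L1/L3/L5 (µM) and the auxiliary l-rates of the saturating
    binding scheme.  Every constant is exposed so an alternative receptor
    calibration can be dropped in via configuration.
    """

    kr1: float = 0.64     # µM^-1 s^-1
    kr1m: float = 0.04    # s^-1  (k_{-1})
    kr2: float = 37.4     # µM^-1 s^-1
    kr2m: float = 1.4     # s^-1
    kr3: float = 0.11     # µM^-1 s^-1
    kr3m: float = 29.8    # s^-1
    kr4: float = 4.0      # µM^-1 s^-1
    kr4m: float = 0.54    # s^-1
    L1: float = 0.12      # µM
    L3: float = 0.025     # µM
    L5: float = 54.7      # µM
    l2: float = 1.7       # s^-1
    l4: float = 1.7       # µM^-1 s^-1
    l6: float = 4707.0    # s^-1
    l2m: float = 0.8      # s^-1  (l_{-2})
    l4m: float = 2.5      # µM^-1 s^-1
    l6m: float = 11.4     # s^-1

    def __post_init__(self) -> None:
        for f_ in fields(self):
            _require(getattr(self, f_.name) > 0,
                     f"{f_.name} must be positive")


@dataclass
class Ip3Params:
    """Dynamic IP3 production/degradation (hybrid PLC model) with Aβ coupling.

    Production is ``(v_PLC + mu_PLC*a) * c^2 / (D(a) + c^2)`` where
    ``D(a) = (k_PLC + kappa_PLC*a)**2`` when ``squared_sensitivity`` is on
    (the form consistent with the uncoupled model) and the unsquared value
    otherwise.  Degradation mixes Ca²⁺-activated phosphorylation (rate
    ``k_3K``, half-saturation ``K_3K``) with dephosphorylation ``k_5P``.
    ``tau_p`` and ``eta`` are derived, never set independently.
    """

    v_PLC: float = 1.5       # µM s^-1
    mu_PLC: float = 1.0      # µM s^-1 per unit a
    k_PLC: float = 1.0       # µM
    kappa_PLC: float = 1.0   # µM per unit a
    K_3K: float = 0.4        # µM
    k_3K: float = 0.5        # s^-1
    k_5P: float = 0.25       # s^-1
    squared_sensitivity: bool = True

    def __post_init__(self) -> None:
        for name in ("v_PLC", "mu_PLC", "k_PLC", "kappa_PLC", "K_3K"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(self.k_3K + self.k_5P > 0, "k_3K + k_5P must be positive")

    @property
    def tau_p(self) -> float:
        return 1.0 / (self.k_3K + self.k_5P)

    @property
    def eta(self) -> float:
        return self.k_3K / (self.k_3K + self.k_5P)


@dataclass
class MembraneParams:
    """Membrane compartment: Kir, Hodgkin–Huxley Na⁺/K⁺/leak, T-type VGCC.

    The Kir and VGCC constants follow the calcium model's table.  The
    Na⁺/K⁺/leak kinetics use the classical Hodgkin–Huxley rate functions
    and conductances (the printed resting gating values m=0.05, n=0.32,
    h=0.6 at V=-65 mV are the classical HH resting state), with the
    delayed-rectifier K⁺ current switchable via ``include_ik``.  The Kir
    conductance is interpreted as an effective value on the same scale as
    the HH conductances (``g_kir_scale`` converts the tabulated 60).
    """

    C_m: float = 1.0          # µF cm^-2
    g_kir: float = 60.0       # tabulated Kir conductance
    g_kir_scale: float = 1e-3  # effective-units conversion for g_kir
    K_0: float = 2.0          # mM extracellular K+
    V_ka: float = -65.2       # mV, K+ Nernst potential
    V_a1: float = -14.83      # mV
    V_a2: float = 34.0        # mV
    V_a3: float = 19.23       # mV
    g_na: float = 120.0       # mS cm^-2
    V_na: float = 50.0        # mV
    g_k: float = 36.0         # mS cm^-2
    V_k: float = -77.0        # mV
    g_l: float = 0.3          # mS cm^-2
    V_l: float = -54.387      # mV
    g_caT: float = 0.45       # effective T-type conductance
    V_ca: float = 100.0       # mV, Ca²⁺ Nernst potential
    include_ik: bool = True   # delayed-rectifier K+ (implied by the n gate)

    def __post_init__(self) -> None:
        for name in ("C_m", "g_kir", "g_na", "g_k", "g_l", "g_caT"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")


@dataclass
class StimulusProtocol:
    """Boxcar applied-current pulse: ``amplitude`` on [t_on, t_on+duration)."""

    amplitude: float = 0.0   # nA
    t_on: float = 100.0      # s
    duration: float = 50.0   # s

    def __post_init__(self) -> None:
        _require(self.duration >= 0, "duration must be nonnegative")

    def current(self, t: float) -> float:
        if self.amplitude and self.t_on <= t < self.t_on + self.duration:
            return self.amplitude
        return 0.0

    @property
    def edges(self) -> tuple[float, ...]:
        if self.amplitude == 0 or self.duration == 0:
            return ()
        return (self.t_on, self.t_on + self.duration)


@dataclass
class ModelParams:
    """Full parameter set: calcium core, IPR gating, IP3, membrane."""

    core: CoreParams = field(default_factory=CoreParams)
    ipr: IprParams = field(default_factory=IprParams)
    ip3: Ip3Params = field(default_factory=Ip3Params)
    membrane: MembraneParams = field(default_factory=MembraneParams)

    def with_overrides(self, **named: float) -> "ModelParams":
        """Return a copy with flat ``name=value`` overrides applied.

        Names are looked up in core, then ipr, ip3, membrane; unknown names
        raise ``KeyError``.
        """
        blocks = {"core": dict(), "ipr": dict(), "ip3": dict(),
                  "membrane": dict()}  # type: dict[str, dict[str, Any]]
        for name, value in named.items():
            for block in ("core", "ipr", "ip3", "membrane"):
                if any(f_.name == name for f_ in fields(getattr(self, block))):
                    blocks[block][name] = value
                    break
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return ModelParams(
            core=replace(self.core, **blocks["core"]),
            ipr=replace(self.ipr, **blocks["ipr"]),
            ip3=replace(self.ip3, **blocks["ip3"]),
            membrane=replace(self.membrane, **blocks["membrane"]),
        )

    def get(self, name: str) -> float:
        for block in (self.core, self.ipr, self.ip3, self.membrane):
            if any(f_.name == name for f_ in fields(block)):
                return getattr(block, name)
        raise KeyError(f"unknown parameter {name!r}")
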