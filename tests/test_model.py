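"""Assembled model: compositionality, conservation identities, integration."""

import numpy as np
import pytest

from amyca import fluxes
from amyca.equilibria import semi_analytic_equilibrium
from amyca.model import (CompiledModel, FluxError, ModelConfig, flux_breakdown,
                         initial_state, rhs, simulate, state_variables)
from amyca.params import StimulusProtocol


def _random_states(variant, n, rng):
    """Plausible random states on the physical domain."""
    names = state_variables(variant)
    out = []
    for _ in range(n):
        sv = {"c": rng.uniform(0.01, 2.0), "ce": rng.uniform(0.5, 30.0),
              "p": rng.uniform(0.0, 20.0), "V": rng.uniform(-80.0, 20.0)}
        occ = rng.dirichlet(np.ones(6))
        for k, v in zip(("R", "O", "A", "I1", "I2"), occ[:5]):
            sv[k] = v
        for k in ("m", "h", "n", "mcaT", "hcaT"):
            sv[k] = rng.uniform(0.0, 1.0)
        out.append(np.array([sv[k] for k in names]))
    return out


@pytest.mark.parametrize("variant, kw", [
    ("constant_ip3", dict(p_fixed=5.0, a=0.2)),
    ("dynamic_ip3", dict(a=0.4)),
    ("with_membrane", dict(p_fixed=10.0, a=0.1, p_s=1.0)),
])
def test_symbolic_rhs_matches_reference(variant, kw, rng, params):
    """The compiled (symbolic) right-hand side agrees with the direct
    composition of the unit-tested flux/gating functions."""
    cfg = ModelConfig(variant=variant, **kw)
    cm = CompiledModel(params, cfg)
    for y in _random_states(variant, 5, rng):
        np.testing.assert_allclose(cm.rhs(0.0, y), rhs(y, 0.0, params, cfg),
                                   rtol=1e-12, atol=1e-12)


def test_rhs_is_sum_of_flux_terms(params):
    """dc/dt decomposes exactly into the named fluxes, and the ER equation
    is -gamma times the ER-exchange subset."""
    cfg = ModelConfig(variant="constant_ip3", p_fixed=5.0, a=0.3)
    y = initial_state(params, cfg)
    d = rhs(y, 0.0, params, cfg)
    fb = flux_breakdown(y, 0.0, params, cfg)
    er = fb["J_IPR"] + fb["J_RyR"] - fb["J_SERCA"]
    assert d[0] == pytest.approx(er + fb["J_in"] - fb["J_pm"] + fb["J_vca"])
    assert d[1] == pytest.approx(-params.core.gamma * er)


@pytest.mark.parametrize("variant, kw", [
    ("constant_ip3", dict(p_fixed=8.0, a=0.5)),
    ("dynamic_ip3", dict(a=0.8)),
    ("with_membrane", dict(p_fixed=8.0, a=0.5, p_s=1.3)),
])
def test_total_calcium_identity(variant, kw, rng, params):
    """Exact algebraic identity of the two-pool structure:
    d(c + ce/gamma)/dt = J_in - J_pm + J_vca at every state."""
    cfg = ModelConfig(variant=variant, **kw)
    for y in _random_states(variant, 8, rng):
        d = rhs(y, 0.0, params, cfg)
        fb = flux_breakdown(y, 0.0, params, cfg)
        lhs = d[0] + d[1] / params.core.gamma
        np.testing.assert_allclose(
            lhs, fb["J_in"] - fb["J_pm"] + fb["J_vca"], rtol=1e-9,
            atol=1e-12)


def test_rest_equilibrium_without_drivers(params):
    """With no amyloid, no IP3 and no membrane coupling the cell settles to
    a low physiological resting calcium."""
    cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0, a=0.0)
    y = semi_analytic_equilibrium(params, cfg)
    assert np.max(np.abs(rhs(y, 0.0, params, cfg))) < 1e-9
    assert 0.01 <= y[0] <= 0.2


def test_trace_columns_and_ipr_simplex(trace_p5, params):
    df = trace_p5.data
    for col in ("t", "c", "ce", "p", "R", "O", "A", "I1", "I2", "S"):
        assert col in df.columns
    assert df["V"].isna().all()          # membrane absent in this variant
    occ = df[["R", "O", "A", "I1", "I2", "S"]].to_numpy()
    np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
    assert occ.min() > -1e-6 and occ.max() < 1.0 + 1e-6


def test_oscillation_frequency_increases_with_ip3(trace_p5, trace_p10):
    """More IP3 drives faster calcium oscillations (p=5 vs p=10)."""
    from scipy.signal import find_peaks

    def n_peaks(tr):
        c = tr["c"][tr.t > 100.0]
        return find_peaks(c, prominence=0.1)[0].size

    assert n_peaks(trace_p10) > n_peaks(trace_p5) > 3


def test_tolerance_convergence(params):
    """Halving solver tolerances leaves the trace unchanged to ~1e-4."""
    base = dict(variant="constant_ip3", p_fixed=5.0, a=0.0, t_end=60.0,
                output_dt=0.5)
    tr1 = simulate(ModelConfig(**base), params)
    tr2 = simulate(ModelConfig(**base, rtol=5e-9, atol=5e-11), params)
    scale = np.max(np.abs(tr1["c"]))
    assert np.max(np.abs(tr1["c"] - tr2["c"])) / scale < 1e-4


def test_stimulus_splits_segments_and_is_reproducible(params):
    stim = StimulusProtocol(amplitude=300.0, t_on=10.0, duration=5.0)
    cfg = ModelConfig(variant="with_membrane", p_fixed=5.0, p_s=1.0,
                      stimulus=stim, t_end=30.0, output_dt=0.1)
    tr = simulate(cfg, params)
    assert tr.stats["segments"] == 3
    V = tr["V"]
    t = tr.t
    assert V[(t > 11) & (t < 15)].max() > V[t < 9].max() + 5.0


def test_nonfinite_flux_is_diagnosed(params):
    cfg = ModelConfig(variant="constant_ip3", p_fixed=5.0)
    y = initial_state(params, cfg)
    y[0] = np.nan
    with pytest.raises(FluxError):
        rhs(y, 0.0, params, cfg)


def test_trace_csv_roundtrip(tmp_path, trace_p5):
    import pandas as pd
    path = tmp_path / "trace.csv"
    trace_p5.to_csv(path)
    back = pd.read_csv(path)
    np.testing.assert_allclose(back["c"].to_numpy(), trace_p5["c"],
                               rtol=1e-12, atol=1e-16)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(variant="nonsense")
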