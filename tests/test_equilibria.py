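"""Steady states, stability, and equilibrium continuation."""

import numpy as np
import pytest

from amyca.equilibria import (eigenvalues_at, equilibrium_at,
                              find_steady_state, hopf_points, jacobian_fd,
                              scan_branch, two_parameter_scan)
from amyca.ipr_gating import stationary_independent
from amyca.model import CompiledModel, ModelConfig, simulate
REST_CFG = ModelConfig(variant="constant_ip3", p_fixed=0.0, a=0.0)


def test_steady_state_agrees_with_long_integration(params):
    y_eq = equilibrium_at(params, REST_CFG)
    cm = CompiledModel(params, REST_CFG)
    assert np.max(np.abs(cm.rhs_autonomous(y_eq))) < 1e-10
    # the rest state is approached on a ~1/|Re(lambda_slow)| ~ 400 s
    # timescale, so integrate well past it (stiff method: this leg is cheap)
    cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0, a=0.0,
                      t_end=4000.0, method="LSODA", output_dt=1.0)
    tr = simulate(cfg, params)
    final = np.array([tr[v][-1] for v in
                      ("c", "ce", "R", "O", "A", "I1", "I2")])
    np.testing.assert_allclose(final, y_eq, rtol=1e-3, atol=1e-6)


def test_equilibrium_gating_matches_null_space(params):
    """The IPR block of a full-model equilibrium equals the algebraic
    stationary distribution at the equilibrium (c, p)."""
    cfg = ModelConfig(variant="constant_ip3", p_fixed=5.0, a=0.0)
    y = equilibrium_at(params, cfg)
    pi = stationary_independent(y[0], 5.0, params.ipr)
    np.testing.assert_allclose(y[2:7], pi, atol=1e-9)


def test_newton_from_perturbed_guess(params):
    y = equilibrium_at(params, REST_CFG)
    rough = y * (1 + 1e-2) + 1e-4
    polished = find_steady_state(rough, params, REST_CFG)
    np.testing.assert_allclose(polished, y, rtol=1e-8, atol=1e-10)


def test_finite_difference_jacobian_matches_symbolic(params):
    """Independent differentiation oracle: central finite differences agree
    with the symbolically derived Jacobian."""
    cfg = ModelConfig(variant="dynamic_ip3", a=0.5)
    y = equilibrium_at(params, cfg)
    J_fd = jacobian_fd(y, params, cfg)
    J_sym = CompiledModel(params, cfg).jac_autonomous(y)
    np.testing.assert_allclose(J_fd, J_sym, rtol=2e-5,
                               atol=1e-6 * np.abs(J_sym).max())


def test_rest_state_is_stable(params):
    y = equilibrium_at(params, REST_CFG)
    ev = eigenvalues_at(y, params, REST_CFG)
    assert ev.real.max() < 0.0


@pytest.fixture(scope="module")
def branch_a_p0(params):
    cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0)
    return scan_branch("a", (0.0, 1.32), 67, params, cfg)


class TestBranchScan:
    def test_hopf_bubble_without_ip3(self, branch_a_p0):
        """Raising amyloid with no IP3 destabilises the rest state through
        a Hopf pair (an oscillatory window) before the branch diverges."""
        hbs = hopf_points(branch_a_p0)
        assert len(hbs) == 2
        hb1, hb2 = sorted(pt.value for pt in hbs)
        assert hb1 < 1.15 < hb2    # the window contains the oscillatory run
        for pt in hbs:
            assert abs(pt.eigenpair.imag) > 1e-3

    def test_divergence_matches_flux_balance_root(self, branch_a_p0, params):
        """The branch terminates where the amyloid-pore influx saturates the
        plasma-membrane pump: a1 + k_beta*a^4 = V_pm."""
        core = params.core
        a_star = (core.V_pm - core.a1) ** 0.25
        assert branch_a_p0.termination is not None
        assert branch_a_p0.termination["value"] == pytest.approx(a_star,
                                                                 abs=1e-3)

    def test_hopf_certificate(self, branch_a_p0, params):
        """Perturbing a Hopf point by ±1e-3 flips the sign of the critical
        pair's real part."""
        pt = hopf_points(branch_a_p0)[0]
        signs = []
        for da in (-1e-3, 1e-3):
            cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0,
                              a=pt.value + da)
            y = equilibrium_at(params, cfg)
            ev = eigenvalues_at(y, params, cfg, analytic=True)
            pair = ev[np.abs(ev.imag) > 1e-3]
            signs.append(np.sign(pair.real.max()))
        assert signs[0] != signs[1]

    def test_refinement_is_step_insensitive(self, branch_a_p0, params):
        """Halving the scan step moves the detected Hopf by < 1e-3."""
        cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0)
        fine = scan_branch("a", (0.0, 1.32), 133, params, cfg)
        coarse_vals = sorted(pt.value for pt in hopf_points(branch_a_p0))
        fine_vals = sorted(pt.value for pt in hopf_points(fine))
        assert len(coarse_vals) == len(fine_vals)
        for v1, v2 in zip(coarse_vals, fine_vals):
            assert abs(v1 - v2) < 1e-3


def test_two_parameter_single_slice_reduces_to_branch(params):
    cfg = ModelConfig(variant="constant_ip3", p_fixed=0.0)
    res = two_parameter_scan("a", (0.9, 1.32), 43, "p_fixed", [0.0],
                             params, cfg)
    assert not res["failures"]
    br = scan_branch("a", (0.9, 1.32), 43, params, cfg)
    got = sorted(x["a"] for x in res["loci"] if x["kind"] == "hopf")
    want = sorted(pt.value for pt in hopf_points(br))
    np.testing.assert_allclose(got, want, atol=1e-9)
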