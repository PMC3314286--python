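"""Integration, readouts and trajectory invariants."""

import numpy as np
import pytest

import smadtif as st
from smadtif.simulate import SolverOptions, Trajectory


def test_pre_equilibration_reaches_steady_state(integrated_system):
    basal = st.pre_equilibrate(integrated_system)
    assert np.max(np.abs(integrated_system.rhs(basal, 0.0, 0.0))) < 1e-10
    assert np.all(basal >= 0)


def test_no_stimulus_keeps_basal_state(integrated_system):
    traj = st.simulate(integrated_system, st.StimulusProtocol.none(),
                       np.linspace(0, 7200, 25))
    basal = st.pre_equilibrate(integrated_system)
    assert np.allclose(traj.y, basal[None, :], atol=1e-8)
    assert np.allclose(st.readout(traj, "pS24n"), 0.0, atol=1e-10)


def test_pS24n_zero_before_stimulation(integrated_traj):
    assert st.readout(integrated_traj, "pS24n")[0] == pytest.approx(0.0,
                                                                    abs=1e-10)


def test_conserved_totals_constant_along_trajectory(integrated_traj):
    system = integrated_traj.system
    ref = system.conserved_totals(integrated_traj.y[0])
    for k in range(0, len(integrated_traj.t), 40):
        now = system.conserved_totals(integrated_traj.y[k])
        for group, value in ref.items():
            if value > 0:
                assert abs(now[group] - value) / value < 1e-6, group


def test_protocol_edges_present_in_output_grid(integrated_system):
    protocol = st.StimulusProtocol.pulse_train(10.0, 600.0, 1800.0, 3)
    traj = st.simulate(integrated_system, protocol,
                       np.linspace(0, 7200, 33))
    for edge in protocol.edges(7200.0):
        assert edge in traj.t


def test_integrated_without_tif1g_matches_base_model(base_system):
    """Variant-reduction identity: TIF1γ-free integrated == base core."""
    tif0 = st.build_model("INTEGRATED", init={"TIF1g_n": 0.0})
    grid = np.linspace(0, 21600, 49)
    opts = SolverOptions(rtol=1e-11, atol=1e-14)
    prot = st.StimulusProtocol.sustained(10.0)
    a = st.simulate(base_system, prot, grid, opts)
    b = st.simulate(tif0, prot, grid, opts)
    for name in base_system.species_names:
        ya, yb = a.series(name), b.series(name)
        scale = max(ya.max(), yb.max(), 1e-12)
        assert np.max(np.abs(ya - yb)) / scale < 1e-8, name


def test_adaptive_solver_agrees_with_fixed_step_rk4(base_system):
    """Brute-force oracle: classic RK4 at a step far below the fastest
    timescale reproduces the adaptive solution."""
    opts = SolverOptions(rtol=1e-10, atol=1e-13)
    grid = np.linspace(0, 1800.0, 7)
    prot = st.StimulusProtocol.sustained(10.0)
    traj = st.simulate(base_system, prot, grid, opts)
    y = st.pre_equilibrate(base_system).copy()
    dt = 0.05
    out = [y.copy()]
    checkpoints = set(np.round(grid / dt).astype(int)[1:])
    n_steps = int(round(1800.0 / dt))
    for k in range(1, n_steps + 1):
        t = (k - 1) * dt
        k1 = base_system.rhs(y, t, 10.0)
        k2 = base_system.rhs(y + 0.5 * dt * k1, t + 0.5 * dt, 10.0)
        k3 = base_system.rhs(y + 0.5 * dt * k2, t + 0.5 * dt, 10.0)
        k4 = base_system.rhs(y + dt * k3, t + dt, 10.0)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if k in checkpoints:
            out.append(y.copy())
    oracle = np.vstack(out)
    scale = max(np.max(np.abs(oracle)), 1e-12)
    assert np.max(np.abs(traj.y - oracle)) / scale < 1e-6


def test_tolerance_refinement_converges(integrated_system):
    grid = np.linspace(0, 3600, 5)
    prot = st.StimulusProtocol.sustained(10.0)
    coarse = st.simulate(integrated_system, prot, grid,
                         SolverOptions(rtol=1e-6, atol=1e-9))
    fine = st.simulate(integrated_system, prot, grid,
                       SolverOptions(rtol=1e-9, atol=1e-12))
    rel = np.max(np.abs(coarse.y[-1] - fine.y[-1])) / max(
        np.max(np.abs(fine.y[-1])), 1e-12)
    assert rel < 10 * 1e-6


def test_peak_of_refined_grid_matches(integrated_system):
    prot = st.StimulusProtocol.sustained(10.0)
    coarse = st.simulate(integrated_system, prot, np.linspace(0, 21600, 121))
    fine = st.simulate(integrated_system, prot, np.linspace(0, 21600, 1201))
    pc, _ = st.peak_response(coarse, "pS24n")
    pf, _ = st.peak_response(fine, "pS24n")
    assert pc == pytest.approx(pf, rel=2e-3)


def test_readout_aliases_and_errors(integrated_traj):
    a = st.readout(integrated_traj, "pS2nTIF1g")
    b = st.readout(integrated_traj, "pS2nTIF1γ")
    assert np.array_equal(a, b)
    with pytest.raises(KeyError):
        st.readout(integrated_traj, "pS99n")


def test_pS2nTIF1g_identically_zero_without_tif1g():
    system = st.build_model("INTEGRATED", init={"TIF1g_n": 0.0})
    traj = st.simulate(system, st.StimulusProtocol.sustained(10.0),
                       np.linspace(0, 7200, 25))
    assert np.allclose(st.readout(traj, "pS2nTIF1g"), 0.0, atol=1e-12)


def _fake_traj(t, series):
    y = np.asarray(series, float)[:, None]
    return Trajectory(t=np.asarray(t, float), y=y, species=["pS24n"],
                      protocol=st.StimulusProtocol.none())


def test_peak_response_tie_breaks_and_trivial_cases():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    assert st.peak_response(_fake_traj(t, [0, 0, 0, 0]), "pS24n") == (0.0, 0.0)
    assert st.peak_response(_fake_traj(t, [0, 1, 2, 3]), "pS24n") == (3.0, 3.0)
    # ties broken by earliest attaining time
    assert st.peak_response(_fake_traj(t, [0, 5, 5, 1]), "pS24n") == (5.0, 1.0)


def test_simulate_rejects_bad_grids(integrated_system):
    prot = st.StimulusProtocol.sustained(10.0)
    with pytest.raises(ValueError):
        st.simulate(integrated_system, prot, np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        st.simulate(integrated_system, prot, np.array([0.0, 2.0, 2.0]))


def test_depletion_protocol_requires_depletion_model(integrated_system):
    prot = st.StimulusProtocol.sustained(10.0, depletion=True)
    with pytest.raises(ValueError):
        st.simulate(integrated_system, prot, np.linspace(0, 100, 3))
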