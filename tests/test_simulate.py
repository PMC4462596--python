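"""Integration: accuracy, determinism, invariants, core-model equivalence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import clocknad as cn
from clocknad.parameters import STATE_NAMES

from conftest import series_after


class TestBasics:
    def test_inert_system_stays_constant(self):
        params = cn.ModelParameters(nac=1.0)  # AC**nac = AC so OP relaxes to AC
        state = cn.ModelState(M=1.0, TF=0.5, CP=0.3, CP2=0.2, N=1.0, NP=1.0,
                              AC_NP=0.25, AC_CP=0.25, OP_CP=0.25, OP_NP=0.25,
                              NAD=2.0)
        traj = cn.integrate(state, params, t_end=100.0)
        assert np.abs(traj.states - state.as_array()).max() < 1e-8

    def test_determinism(self, current):
        a = cn.integrate(current.initial_state, current.parameters, t_end=100.0)
        b = cn.integrate(current.initial_state, current.parameters, t_end=100.0)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_grid_and_shape(self, current_traj):
        assert current_traj.states.shape == (len(current_traj.times),
                                             len(STATE_NAMES))
        steps = np.diff(current_traj.times)
        assert np.allclose(steps, 0.05)

    def test_invalid_inputs(self, current):
        with pytest.raises(ValueError):
            cn.integrate(current.initial_state, current.parameters, t_end=-1.0)
        with pytest.raises(ValueError):
            cn.SolverSettings(rtol=0.0)


class TestInvariantsAlongTrajectory:
    def test_non_negativity(self, current_traj):
        assert current_traj.states.min() >= -1e-9

    def test_acetylation_bounded(self, current_traj):
        for name in ("AC_NP", "AC_CP", "OP_CP", "OP_NP"):
            col = current_traj.series(name)
            assert col.min() >= -1e-9 and col.max() <= 1.0 + 1e-9

    def test_transcription_factor_conserved(self, current, current_traj):
        assert current_traj.series("TF").max() <= current.parameters.TFtot + 1e-9


class TestAccuracy:
    def test_tolerance_convergence_contract(self, current):
        """Halving rtol and atol changes the estimated period by < 0.01 h."""
        periods = []
        for factor in (1.0, 0.5):
            settings = cn.SolverSettings(rtol=1e-8 * factor, atol=1e-10 * factor)
            traj = cn.integrate(current.initial_state, current.parameters,
                                t_end=480.0, settings=settings)
            t, cp = series_after(traj, "CP")
            periods.append(cn.period(t, cp))
        assert abs(periods[0] - periods[1]) < 0.01

    def test_output_step_refinement_leaves_peaks_in_place(self, current):
        coarse = cn.integrate(current.initial_state, current.parameters,
                              t_end=240.0)
        fine = cn.integrate(current.initial_state, current.parameters,
                            t_end=240.0,
                            settings=cn.SolverSettings(step=0.025))
        pk_c = cn.find_peaks(*series_after(coarse, "CP"))
        pk_f = cn.find_peaks(*series_after(fine, "CP"))
        assert len(pk_c) == len(pk_f)
        assert np.abs(pk_c - pk_f).max() < 0.05

    def test_limit_cycle_convergence_after_transient(self, current_traj):
        """After the 5-day transient, consecutive CP cycle lengths agree to
        better than 0.05 h."""
        t, cp = series_after(current_traj, "CP")
        peaks = cn.find_peaks(t, cp)
        cycles = np.diff(peaks)
        assert np.abs(np.diff(cycles)).max() < 0.05


def _core_model_rhs(t, y, p):
    """Independent minimal implementation of the four-variable core
    oscillator, written directly from the reduced equations."""
    M, TF, CP, CP2 = y
    IC = p.TFtot - TF
    CPtot = CP + 2 * CP2 + 2 * IC
    hill = p.kms * TF ** p.n / (p.J ** p.n + TF ** p.n)
    dM = -p.kmd * M + p.Dex + hill
    dTF = (-p.kica * CP2 * TF + p.kp2 * IC / (p.Jp + CPtot)
           + p.kchk2c * IC + p.kcp2d * IC + p.kicd * IC)
    dCP = (-p.kchk2 * CP - p.kp1 * CP / (p.Jp + CPtot) + 2 * p.kd * CP2
           - 2 * p.ka * CP ** 2 - p.kcpd * CP + p.kcps * M)
    dCP2 = (-p.kica * CP2 * TF - p.kchk2 * CP2 - p.kp2 * CP2 / (p.Jp + CPtot)
            - p.kcp2d * CP2 + p.kicd * IC - p.kd * CP2 + p.ka * CP ** 2)
    return [dM, dTF, dCP, dCP2]


class TestCoreModelEquivalence:
    def test_full_model_reproduces_core_oscillator(self, hong2009):
        """With the legacy parameter set, the full 11-species integrator and
        an independent 4-variable implementation agree to < 1e-6 relative
        error over five days."""
        t_end = 120.0
        settings = cn.SolverSettings(rtol=1e-10, atol=1e-12)
        full = cn.integrate(hong2009.initial_state, hong2009.parameters,
                            t_end=t_end, settings=settings)
        y0 = hong2009.initial_state.as_array()[:4]
        oracle = solve_ivp(_core_model_rhs, (0.0, t_end), y0, method="LSODA",
                           t_eval=full.times, rtol=1e-10, atol=1e-12,
                           args=(hong2009.parameters,))
        assert oracle.success
        for k, name in enumerate(("M", "TF", "CP", "CP2")):
            ours = full.series(name)
            ref = oracle.y[k]
            err = np.abs(ours - ref).max() / np.abs(ref).max()
            assert err < 1e-6, f"{name}: relative error {err}"

    def test_core_oscillator_period_near_24h(self, hong2009):
        traj = cn.integrate(hong2009.initial_state, hong2009.parameters,
                            t_end=480.0)
        t, cp = series_after(traj, "CP")
        assert cn.period(t, cp) == pytest.approx(24.0, abs=0.2)


class TestForcingIntegration:
    def test_breakpoints_are_not_stepped_over(self, current):
        """A short strong pulse must take effect even though its edges fall
        between output grid points."""
        pulse = cn.Pulse("kPARP", 100.013, 2.0, 20.0)
        forced = cn.integrate(current.initial_state, current.parameters,
                              cn.ForcingSchedule([pulse]), t_end=110.0)
        free = cn.integrate(current.initial_state, current.parameters,
                            t_end=110.0)
        nad_drop = free.series("NAD")[-1] - forced.series("NAD")[-1]
        assert forced.solver_meta["n_segments"] == 3
        assert not np.allclose(forced.series("NAD"), free.series("NAD"))

    def test_exports_round_trip(self, current, tmp_path):
        traj = cn.integrate(current.initial_state, current.parameters,
                            t_end=10.0)
        csv = tmp_path / "traj.csv"
        traj.to_csv(csv)
        import pandas as pd

        frame = pd.read_csv(csv, index_col=0)
        assert list(frame.columns) == list(STATE_NAMES)
        np.testing.assert_allclose(frame.to_numpy(), traj.states, rtol=1e-12)
        traj.to_json(tmp_path / "traj.json")
        import json

        payload = json.loads((tmp_path / "traj.json").read_text())
        assert payload["species"] == list(STATE_NAMES)
        assert payload["params"]["TFtot"] == current.parameters.TFtot
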