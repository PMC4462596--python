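"""Rate laws, derived quantities, and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clocknad as cn
from clocknad.parameters import STATE_NAMES, StateError

nonneg = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


class TestSirt1Rate:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.0, 1.0, 3.0, 0.1, 0.1), 0.0),            # zero max rate
            ((1.0, 0.0, 3.0, 0.1, 0.1), 0.0),            # no substrate
            ((1.0, 1.0, 0.0, 0.1, 0.1), 0.0),            # no cosubstrate
            # hand evaluation of V*S*NAD/(ka*kb + kb*S + S*NAD) at the
            # shipped SIRT1 constants with the initial CP2 level
            ((0.094568, 0.046, 3.0, 0.10491, 0.098395), 0.08538100986576048),
        ],
    )
    def test_values(self, args, expected):
        assert cn.sirt1_rate(*args) == pytest.approx(expected, abs=1e-15)

    @given(V=nonneg, S=nonneg, NAD=nonneg, ka=positive, kb=positive)
    def test_bounded_by_vmax_and_nonnegative(self, V, S, NAD, ka, kb):
        rate = cn.sirt1_rate(V, S, NAD, ka, kb)
        assert 0.0 <= rate <= V + 1e-12

    def test_rejects_negative_arguments(self):
        with pytest.raises(ValueError):
            cn.sirt1_rate(1.0, -0.1, 3.0, 0.1, 0.1)


class TestPromoterAcetylationRate:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.0, 5.0, 0.02, 0.2), 0.0),   # no transcription factor
            ((1.0, 0.0, 0.0, 0.2), 1.0),    # saturated activator, no repressor
            ((0.0, 0.0, 0.0, 0.0), 0.0),    # 0/0 convention
            # hand evaluation at the CRY/PER-promoter constants and the
            # initial TF/CP2 levels
            ((0.13, 0.046, 0.020133, 0.20757), 0.7088166395474338),
        ],
    )
    def test_values(self, args, expected):
        assert cn.promoter_acetylation_rate(*args) == pytest.approx(expected, abs=1e-15)

    @given(TF=nonneg, CP2=nonneg, K_TF=nonneg, K_CP2=nonneg)
    def test_stays_in_unit_interval(self, TF, CP2, K_TF, K_CP2):
        assert 0.0 <= cn.promoter_acetylation_rate(TF, CP2, K_TF, K_CP2) <= 1.0


class TestDerived:
    def test_initial_state_arithmetic(self, current):
        d = cn.derived(current.initial_state, current.parameters)
        assert d.IC == pytest.approx(0.84792 - 0.13, abs=1e-12)      # 0.71792
        assert d.CPtot == pytest.approx(0.037 + 2 * 0.046 + 2 * 0.71792, abs=1e-12)

    def test_free_transcription_factor_means_no_complex(self, current):
        state = cn.ModelState(TF=current.parameters.TFtot)
        d = cn.derived(state, current.parameters)
        assert d.IC == 0.0
        assert d.CPtot == 0.0

    def test_conservation_violation_raises(self, current):
        state = cn.ModelState(TF=current.parameters.TFtot + 0.01)
        with pytest.raises(StateError):
            cn.derived(state, current.parameters)


def _printed_rhs(y, p):
    """Independent term-by-term evaluation of the printed rate equations
    (default sign resolution), written directly from the equations."""
    M, TF, CP, CP2, N, NP, AC_NP, AC_CP, OP_CP, OP_NP, NAD = y

    def mm(V, S):
        if V == 0 or S == 0 or NAD == 0:
            return 0.0
        return V * S * NAD / (p["kaCPSIRT1"] * p["kbCPSIRT1"]
                              + p["kbCPSIRT1"] * S + S * NAD)

    IC = p["TFtot"] - TF
    CPtot = CP + 2 * CP2 + 2 * IC
    hill = (p["kms"] * TF ** p["n"] / (p["J"] ** p["n"] + TF ** p["n"])
            if p["kms"] > 0 else 0.0)
    knpac = (TF / (TF + p["KTFNP"])) * (p["KCP2NP"] / (p["KCP2NP"] + CP2))
    kcpac = (TF / (TF + p["KTFCP"])) * (p["KCP2CP"] / (p["KCP2CP"] + CP2))
    return [
        p["VM"] * OP_CP - p["kmd"] * M + p["Dex"] + hill,
        (-p["kica"] * CP2 * TF + p["kp2"] * IC / (p["Jp"] + CPtot)
         + p["kchk2c"] * IC + p["kcp2d"] * IC + p["kicd"] * IC + mm(p["VSIRT1c"], IC)),
        (-mm(p["VSIRT1c"], CP) - p["kchk2"] * CP - p["kp1"] * CP / (p["Jp"] + CPtot)
         + 2 * p["kd"] * CP2 - 2 * p["ka"] * CP * CP - p["kcpd"] * CP + p["kcps"] * M),
        (-mm(p["VSIRT1c"], CP2) - p["kica"] * CP2 * TF - p["kchk2"] * CP2
         - p["kp2"] * CP2 / (p["Jp"] + CPtot) - p["kcp2d"] * CP2
         + p["kicd"] * IC - p["kd"] * CP2 + p["ka"] * CP * CP),
        p["VN"] * OP_NP - p["knd"] * N,
        -p["knpd"] * NP + p["knps"] * N,
        -mm(p["VSIRT1d"], AC_NP) + knpac * (1 - AC_NP) - p["knpdeac"] * AC_NP,
        -mm(p["VSIRT1d"], AC_CP) + kcpac * (1 - AC_CP) - p["kcpdeac"] * AC_CP,
        (AC_CP ** p["nac"] - OP_CP) / p["Tconst_cp"],
        (AC_NP ** p["nac"] - OP_NP) / p["Tconst_np"],
        (-mm(p["VSIRT1d"], AC_CP) - mm(p["VSIRT1d"], AC_NP) - mm(p["VSIRT1c"], IC)
         - mm(p["VSIRT1c"], CP2) - mm(p["VSIRT1c"], CP)
         - p["knadd"] * NAD + p["VNADc"] * NP - p["kPARP"] * NAD),
    ]


class TestRhs:
    def test_inert_system_has_zero_derivative(self):
        params = cn.ModelParameters()  # every rate constant zero
        state = cn.ModelState(M=1.0, TF=0.5, CP=0.3, CP2=0.2, N=1.0, NP=1.0,
                              AC_NP=0.5, AC_CP=0.5, OP_CP=0.0, OP_NP=0.0, NAD=2.0)
        d = cn.rhs(0.0, state, params)
        # the accessibility variables relax toward AC**nac = 0.5**0 = 1
        free = [i for i, n in enumerate(STATE_NAMES) if not n.startswith("OP")]
        assert np.allclose(d[free], 0.0)

    def test_matches_independent_equation_evaluation(self, current):
        y = current.initial_state.as_array()
        expected = _printed_rhs(y, current.parameters.to_dict())
        got = cn.rhs(0.0, current.initial_state, current.parameters)
        np.testing.assert_allclose(got, expected, rtol=1e-13, atol=1e-15)

    def test_matches_independent_evaluation_mid_cycle(self, current, current_traj):
        # a generic interior point of the limit cycle
        y = current_traj.states[4000]
        expected = _printed_rhs(y, current.parameters.to_dict())
        got = cn.rhs(0.0, y, current.parameters)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-14)

    def test_reduces_to_core_model_structure(self, hong2009):
        """With the legacy parameter set, the NAD/chromatin extension is
        structurally inert: dN/dt = -knd*N and dNAD/dt = 0."""
        state = cn.ModelState(M=0.7, TF=0.2, CP=0.1, CP2=0.05, N=1.5, NP=1.0,
                              AC_NP=0.01, AC_CP=0.01, OP_CP=0.4, OP_NP=0.4, NAD=3.0)
        d = cn.rhs(0.0, state, hong2009.parameters)
        p = hong2009.parameters
        assert d[STATE_NAMES.index("N")] == pytest.approx(-p.knd * state.N)
        assert d[STATE_NAMES.index("NAD")] == 0.0
        hill = p.kms * state.TF ** p.n / (p.J ** p.n + state.TF ** p.n)
        assert d[STATE_NAMES.index("M")] == pytest.approx(-p.kmd * state.M + hill)

    @given(st.data())
    def test_nad_bookkeeping_identity(self, current, data):
        """Every NAD molecule consumed by SIRT1 is debited once: the five
        SIRT1 terms in dNAD/dt equal the SIRT1 rates computed from the
        shared rate law at the same state."""
        p = current.parameters
        draw = lambda hi: data.draw(st.floats(min_value=0.0, max_value=hi,
                                              allow_nan=False))
        y = np.array([draw(3.0), draw(p.TFtot), draw(1.0), draw(1.0), draw(3.0),
                      draw(3.0), draw(1.0), draw(1.0), draw(1.0), draw(1.0),
                      draw(5.0)])
        d = cn.rhs(0.0, y, p)
        TF, CP, CP2 = y[1], y[2], y[3]
        AC_NP, AC_CP, NAD, NP = y[6], y[7], y[10], y[5]
        IC = p.TFtot - TF
        sirt1_total = sum(
            cn.sirt1_rate(V, S, NAD, p.kaCPSIRT1, p.kbCPSIRT1)
            for V, S in [(p.VSIRT1c, IC), (p.VSIRT1c, CP), (p.VSIRT1c, CP2),
                         (p.VSIRT1d, AC_CP), (p.VSIRT1d, AC_NP)])
        dnad = d[STATE_NAMES.index("NAD")]
        balance = -p.knadd * NAD + p.VNADc * NP - p.kPARP * NAD
        assert dnad - balance == pytest.approx(-sirt1_total, rel=1e-12, abs=1e-15)

    def test_variant_flags_flip_the_ambiguous_signs(self, current):
        y = current.initial_state.as_array()
        base = cn.rhs(0.0, y, current.parameters)
        drain = cn.rhs(0.0, y, current.parameters,
                       variant=cn.ModelVariant(tf_sirt1_release=False))
        loss = cn.rhs(0.0, y, current.parameters,
                      variant=cn.ModelVariant(nampt_acetylation_gain=False))
        i_tf = STATE_NAMES.index("TF")
        i_ac = STATE_NAMES.index("AC_NP")
        assert drain[i_tf] < base[i_tf]  # SIRT1 term now drains TF
        assert loss[i_ac] < base[i_ac]   # acetylation term now a loss
        assert np.allclose(np.delete(base, i_tf), np.delete(drain, i_tf))

    def test_negative_state_beyond_tolerance_raises(self, current):
        y = current.initial_state.as_array()
        y[2] = -1e-3
        with pytest.raises(Exception):
            cn.rhs(0.0, y, current.parameters)


class TestParametersAndState:
    def test_fixture_values_match_embedded_tables(self, current, hong2009):
        assert current.parameters.TFtot == 0.84792
        assert current.parameters.VNADc == 5.2479
        assert current.parameters.kPARP == 0.0
        assert hong2009.parameters.kms == 1.0
        assert hong2009.parameters.J == 0.3
        assert hong2009.parameters.Jp == 0.05
        assert hong2009.parameters.ka == 100.0
        assert current.initial_state.NAD == 3.0
        assert current.initial_state.M == 1.4

    def test_fixtures_are_value_copies(self):
        a = cn.load_fixture("current")
        b = cn.load_fixture("current")
        assert a.parameters == b.parameters
        assert a.parameters.replace(kmd=1.0) != b.parameters
        assert cn.load_fixture("current").parameters.kmd == 0.13857

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            cn.load_fixture("nonexistent")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(Exception):
            cn.ModelParameters(kmd=-0.1)
        with pytest.raises(Exception):
            cn.ModelParameters(TFtot=0.0)

    def test_parameter_roundtrip(self, current):
        p = current.parameters
        assert cn.ModelParameters.from_mapping(p.to_dict()) == p
        with pytest.raises(Exception):
            p.replace(not_a_parameter=1.0)
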