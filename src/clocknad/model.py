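"""Rate laws and the ODE right-hand side of the clock/NAD model.

The deterministic model has 11 species.  The core loop is the familiar
transcription-translation negative feedback: BMAL1/CLOCK (``TF``) drives
CRY/PER transcription, CRY/PER protein dimerizes and sequesters TF into an
inactive complex ``IC = TFtot - TF``.  The extension couples this loop to
metabolism: TF acetylates promoter histones (CLOCK is an acetyltransferase),
acetylation opens chromatin (``OP`` relaxes toward ``AC**nac``) and permits
transcription of both CRY/PER and NAMPT; NAMPT drives NAD production; and
NAD fuels SIRT1, which deacetylates histones (repressing transcription) and
clock proteins (destabilizing PER and releasing TF from the inactive
complex).  PARP1 competes with SIRT1 for NAD during DNA damage.

Every SIRT1 reaction uses the same two-substrate Michaelis-Menten law,
:func:`sirt1_rate`, and every NAD molecule consumed by SIRT1 is debited from
the NAD balance, so the five SIRT1 terms appear with matching magnitude in
the substrate equations and in dNAD/dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    FORCING_TARGETS,
    PARAM_NAMES,
    STATE_NAMES,
    ModelParameters,
    ModelState,
    StateError,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover
    def _jit(func):
        return func

#: Components more negative than this are treated as invariant violations;
#: smaller undershoots are solver noise and are clamped before power/quotient
#: terms are evaluated.
NEGATIVE_TOLERANCE = 1e-6

_I = {name: i for i, name in enumerate(PARAM_NAMES)}
_S = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class ModelVariant:
    """Resolution of the two structurally ambiguous signs in the rate
    equations.

    tf_sirT1_release is spelled ``tf_sirt1_release``: if True (default),
    SIRT1 action on the inactive complex releases free BMAL1/CLOCK
    (``+`` sign in dTF/dt); if False the term drains TF as printed in the
    source equations.  The drain variant pushes TF negative from the shipped
    initial conditions and does not oscillate.

    ``nampt_acetylation_gain``: if True (default), CLOCK-mediated histone
    acetylation at the NAMPT promoter is a gain term ``+knpac*(1-AC_NP)``,
    mirroring the CRY/PER promoter equation; if False the term is applied
    with a minus sign.  The minus variant immediately drives AC_NP negative.
    """

    tf_sirt1_release: bool = True
    nampt_acetylation_gain: bool = True

    def signs(self) -> tuple[float, float]:
        return (1.0 if self.tf_sirt1_release else -1.0,
                1.0 if self.nampt_acetylation_gain else -1.0)


DEFAULT_VARIANT = ModelVariant()


def sirt1_rate(V: float, S: float, NAD: float, ka: float, kb: float) -> float:
    """Two-substrate Michaelis-Menten SIRT1 deacetylation rate.

    ``V*S*NAD / (ka*kb + kb*S + S*NAD)`` with substrate ``S`` and cosubstrate
    NAD.  Returns 0 when the maximal rate, the substrate, or NAD is zero.
    """
    if min(V, S, NAD, ka, kb) < 0:
        raise ValueError("sirt1_rate arguments must be non-negative")
    if V == 0.0 or S == 0.0 or NAD == 0.0:
        return 0.0
    den = ka * kb + kb * S + S * NAD
    if den == 0.0:
        raise ZeroDivisionError("sirt1_rate denominator vanished with nonzero numerator")
    return V * S * NAD / den


def promoter_acetylation_rate(TF: float, CP2: float, K_TF: float, K_CP2: float) -> float:
    """Histone acetylation rate at a promoter: activation by BMAL1/CLOCK,
    inhibition by the PER dimer.

    ``[TF/(TF+K_TF)] * [K_CP2/(K_CP2+CP2)]``; indeterminate 0/0 quotients
    evaluate to 0, making the function total on non-negative inputs.
    """
    if min(TF, CP2, K_TF, K_CP2) < 0:
        raise ValueError("promoter_acetylation_rate arguments must be non-negative")
    act = TF / (TF + K_TF) if TF + K_TF > 0 else 0.0
    rep = K_CP2 / (K_CP2 + CP2) if K_CP2 + CP2 > 0 else 0.0
    return act * rep


@dataclass(frozen=True)
class DerivedQuantities:
    """Algebraic quantities implied by a state: inactive complex, total PER,
    and the two promoter acetylation rates."""

    IC: float
    CPtot: float
    knpac: float
    kcpac: float


def derived(state: ModelState, params: ModelParameters,
            tol: float = 1e-9) -> DerivedQuantities:
    """Inactive complex ``IC = TFtot - TF``, total PER
    ``CPtot = CP + 2*CP2 + 2*IC``, and promoter acetylation rates."""
    if state.TF > params.TFtot + tol:
        raise StateError(
            f"TF={state.TF} exceeds TFtot={params.TFtot}: the BMAL1/CLOCK pool is conserved")
    IC = max(params.TFtot - state.TF, 0.0)
    CPtot = state.CP + 2.0 * state.CP2 + 2.0 * IC
    knpac = promoter_acetylation_rate(state.TF, state.CP2, params.KTFNP, params.KCP2NP)
    kcpac = promoter_acetylation_rate(state.TF, state.CP2, params.KTFCP, params.KCP2CP)
    return DerivedQuantities(IC=IC, CPtot=CPtot, knpac=knpac, kcpac=kcpac)


@_jit
def _rhs_kernel(t, y, p, s_tf, s_ac):  # pragma: no cover - jitted
    Dex = p[0]; kms = p[1]; J = p[2]; kmd = p[3]; kcps = p[4]; kcpd = p[5]
    ka = p[6]; kd = p[7]; kp1 = p[8]; Jp = p[9]; kchk2 = p[10]; kicd = p[11]
    kcp2d = p[12]; kica = p[13]; kchk2c = p[14]; kp2 = p[15]; TFtot = p[16]
    KTFCP = p[17]; KCP2CP = p[18]; KTFNP = p[19]; KCP2NP = p[20]
    kcpdeac = p[21]; knpdeac = p[22]; VM = p[23]; VN = p[24]; n = p[25]
    nac = p[26]; Tconst_np = p[27]; Tconst_cp = p[28]; VSIRT1c = p[29]
    knadd = p[30]; knd = p[31]; knps = p[32]; knpd = p[33]; VNADc = p[34]
    kas = p[35]; kbs = p[36]; kPARP = p[37]; VSIRT1d = p[38]

    M = y[0]; TF = y[1]
    CP = y[2] if y[2] > 0.0 else 0.0
    CP2 = y[3] if y[3] > 0.0 else 0.0
    N = y[4]; NP = y[5]
    AC_NP = y[6] if y[6] > 0.0 else 0.0
    AC_CP = y[7] if y[7] > 0.0 else 0.0
    OP_CP = y[8]; OP_NP = y[9]
    NAD = y[10] if y[10] > 0.0 else 0.0

    IC = TFtot - TF
    if IC < 0.0:
        IC = 0.0
    CPtot = CP + 2.0 * CP2 + 2.0 * IC
    kab = kas * kbs

    # SIRT1 two-substrate Michaelis-Menten terms (clock proteins & histones)
    if VSIRT1c == 0.0 or IC == 0.0 or NAD == 0.0:
        s_ic = 0.0
    else:
        s_ic = VSIRT1c * IC * NAD / (kab + kbs * IC + IC * NAD)
    if VSIRT1c == 0.0 or CP == 0.0 or NAD == 0.0:
        s_cp = 0.0
    else:
        s_cp = VSIRT1c * CP * NAD / (kab + kbs * CP + CP * NAD)
    if VSIRT1c == 0.0 or CP2 == 0.0 or NAD == 0.0:
        s_cp2 = 0.0
    else:
        s_cp2 = VSIRT1c * CP2 * NAD / (kab + kbs * CP2 + CP2 * NAD)
    if VSIRT1d == 0.0 or AC_CP == 0.0 or NAD == 0.0:
        s_accp = 0.0
    else:
        s_accp = VSIRT1d * AC_CP * NAD / (kab + kbs * AC_CP + AC_CP * NAD)
    if VSIRT1d == 0.0 or AC_NP == 0.0 or NAD == 0.0:
        s_acnp = 0.0
    else:
        s_acnp = VSIRT1d * AC_NP * NAD / (kab + kbs * AC_NP + AC_NP * NAD)

    # Hill-type transcription (legacy core model; inactive when kms == 0)
    if kms > 0.0:
        hill = kms * TF ** n / (J ** n + TF ** n)
    else:
        hill = 0.0

    # promoter acetylation rates (0/0 quotients -> 0)
    act = TF / (TF + KTFNP) if TF + KTFNP > 0.0 else 0.0
    rep = KCP2NP / (KCP2NP + CP2) if KCP2NP + CP2 > 0.0 else 0.0
    knpac = act * rep
    act = TF / (TF + KTFCP) if TF + KTFCP > 0.0 else 0.0
    rep = KCP2CP / (KCP2CP + CP2) if KCP2CP + CP2 > 0.0 else 0.0
    kcpac = act * rep

    out = np.empty(11)
    out[0] = VM * OP_CP - kmd * M + Dex + hill
    out[1] = (-kica * CP2 * TF + kp2 * IC / (Jp + CPtot)
              + kchk2c * IC + kcp2d * IC + kicd * IC + s_tf * s_ic)
    out[2] = (-s_cp - kchk2 * CP - kp1 * CP / (Jp + CPtot)
              + 2.0 * kd * CP2 - 2.0 * ka * CP * CP - kcpd * CP + kcps * M)
    out[3] = (-s_cp2 - kica * CP2 * TF - kchk2 * CP2 - kp2 * CP2 / (Jp + CPtot)
              - kcp2d * CP2 + kicd * IC - kd * CP2 + ka * CP * CP)
    out[4] = VN * OP_NP - knd * N
    out[5] = -knpd * NP + knps * N
    out[6] = -s_acnp + s_ac * knpac * (1.0 - AC_NP) - knpdeac * AC_NP
    out[7] = -s_accp + kcpac * (1.0 - AC_CP) - kcpdeac * AC_CP
    out[8] = (AC_CP ** nac - OP_CP) / Tconst_cp
    out[9] = (AC_NP ** nac - OP_NP) / Tconst_np
    out[10] = (-s_accp - s_acnp - s_ic - s_cp2 - s_cp
               - knadd * NAD + VNADc * NP - kPARP * NAD)
    return out


def rhs(t: float, state: ModelState | np.ndarray, params: ModelParameters,
        forcing=None, variant: ModelVariant = DEFAULT_VARIANT) -> np.ndarray:
    """Time-derivative of the 11 species at time ``t``.

    ``forcing`` (a :class:`clocknad.forcing.ForcingSchedule` or None)
    overrides the four stress inputs Dex/kchk2/kchk2c/kPARP at time ``t``.
    Raises :class:`StateError` for state components below
    ``-NEGATIVE_TOLERANCE``; smaller undershoots (stiff-solver noise) are
    clamped.
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    if y.min() < -NEGATIVE_TOLERANCE:
        bad = STATE_NAMES[int(np.argmin(y))]
        raise StateError(f"state component {bad} = {y.min()} is negative beyond tolerance")
    p = params.as_array()
    if forcing is not None:
        effective = forcing.evaluate(params, t)
        for name in FORCING_TARGETS:
            p[_I[name]] = effective[name]
    s_tf, s_ac = variant.signs()
    return _rhs_kernel(float(t), y, p, s_tf, s_ac)
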