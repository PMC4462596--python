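"""Reaction-network view of the model: 45 labeled elementary processes.

Each reaction carries a symbolic rate expression over the species and
parameter names plus a stoichiometry map.  Summing ``stoichiometry * rate``
over all reactions reproduces the ODE right-hand side exactly (asserted in
the test suite), and the same expressions are serialized as kinetic laws in
the SBML export.

The algebraic shorthands are expanded inline:
``IC = TFtot - TF``, ``CPtot = CP + 2*CP2 + 2*(TFtot - TF)``,
``knpac``/``kcpac`` are the promoter acetylation rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import sympy

from .parameters import PARAM_NAMES, STATE_NAMES

_IC = "(TFtot - TF)"
_CPTOT = f"(CP + 2*CP2 + 2*{_IC})"
_KNPAC = "(TF/(TF + KTFNP)) * (KCP2NP/(KCP2NP + CP2))"
_KCPAC = "(TF/(TF + KTFCP)) * (KCP2CP/(KCP2CP + CP2))"


def _sirt1(V: str, S: str) -> str:
    return (f"{V}*{S}*NAD / (kaCPSIRT1*kbCPSIRT1 + kbCPSIRT1*{S} + {S}*NAD)")


@dataclass(frozen=True)
class Reaction:
    label: str
    description: str
    rate: str                      # sympy-parsable expression
    stoichiometry: Mapping[str, float]  # species -> net coefficient


#: Reactions grouped by the species balance they enter; the SIRT1 reactions
#: that consume NAD appear twice (substrate side and NAD side) to mirror the
#: printed per-equation bookkeeping, so the NAD debits can be cross-checked
#: against the substrate equations term by term.
REACTIONS: tuple[Reaction, ...] = (
    # CRY/PER mRNA (M)
    Reaction("A1", "CP mRNA synthesis (OP_CP)", "VM*OP_CP", {"M": +1}),
    Reaction("A2", "CP mRNA degradation", "kmd*M", {"M": -1}),
    Reaction("A3", "CP mRNA synthesis (Dex induction)", "Dex", {"M": +1}),
    Reaction("A4", "CP mRNA synthesis (TF)", "kms*TF**n/(J**n + TF**n)", {"M": +1}),
    # BMAL1/CLOCK (TF)
    Reaction("A5", "IC association", f"kica*CP2*TF", {"TF": -1}),
    Reaction("A6", "IC degradation (phosphorylation)", f"kp2*{_IC}/(Jp + {_CPTOT})", {"TF": +1}),
    Reaction("A7", "IC degradation (CHK2)", f"kchk2c*{_IC}", {"TF": +1}),
    Reaction("A8", "IC degradation", f"kcp2d*{_IC}", {"TF": +1}),
    Reaction("A9", "IC disassociation", f"kicd*{_IC}", {"TF": +1}),
    Reaction("A10", "IC degradation (NAD)", _sirt1("VSIRT1c", _IC), {"TF": +1}),
    # CRY/PER monomer (CP)
    Reaction("A11", "CP degradation (NAD)", _sirt1("VSIRT1c", "CP"), {"CP": -1}),
    Reaction("A12", "CP degradation (CHK2)", "kchk2*CP", {"CP": -1}),
    Reaction("A13", "CP degradation (phosphorylation)", f"kp1*CP/(Jp + {_CPTOT})", {"CP": -1}),
    Reaction("A14", "CP degradation", "kcpd*CP", {"CP": -1}),
    Reaction("A15", "CP synthesis", "kcps*M", {"CP": +1}),
    # CRY/PER dimer (CP2)
    Reaction("A16", "CP2 degradation (NAD)", _sirt1("VSIRT1c", "CP2"), {"CP2": -1}),
    Reaction("A17", "IC association", "kica*CP2*TF", {"CP2": -1}),
    Reaction("A18", "CP2 degradation (CHK2)", "kchk2*CP2", {"CP2": -1}),
    Reaction("A19", "CP2 degradation (phosphorylation)", f"kp2*CP2/(Jp + {_CPTOT})", {"CP2": -1}),
    Reaction("A20", "CP2 degradation", "kcp2d*CP2", {"CP2": -1}),
    Reaction("A21", "IC disassociation", f"kicd*{_IC}", {"CP2": +1}),
    Reaction("A22", "CP2 disassociation", "kd*CP2", {"CP2": -1}),
    Reaction("A23", "CP dimerization", "ka*CP**2", {"CP2": +1}),
    # NAMPT mRNA (N)
    Reaction("A24", "N mRNA synthesis (OP_NP)", "VN*OP_NP", {"N": +1}),
    Reaction("A25", "N degradation", "knd*N", {"N": -1}),
    # NAMPT protein (NP)
    Reaction("A26", "NP degradation", "knpd*NP", {"NP": -1}),
    Reaction("A27", "NP synthesis", "knps*N", {"NP": +1}),
    # NAMPT promoter histone acetylation (AC_NP)
    Reaction("A28", "NP acetylated histone deacetylation (NAD)", _sirt1("VSIRT1d", "AC_NP"), {"AC_NP": -1}),
    Reaction("A29", "AC_NP histone acetylation", f"({_KNPAC})*(1 - AC_NP)", {"AC_NP": +1}),
    Reaction("A30", "NP acetylated histone deacetylation", "knpdeac*AC_NP", {"AC_NP": -1}),
    # CRY/PER promoter histone acetylation (AC_CP)
    Reaction("A31", "CP acetylated histone deacetylation (NAD)", _sirt1("VSIRT1d", "AC_CP"), {"AC_CP": -1}),
    Reaction("A32", "AC_CP histone acetylation", f"({_KCPAC})*(1 - AC_CP)", {"AC_CP": +1}),
    Reaction("A33", "CP acetylated histone deacetylation", "kcpdeac*AC_CP", {"AC_CP": -1}),
    # promoter accessibility
    Reaction("A34", "OP_CP synthesis", "(AC_CP**nac - OP_CP)/Tconst_cp", {"OP_CP": +1}),
    Reaction("A35", "OP_NP synthesis", "(AC_NP**nac - OP_NP)/Tconst_np", {"OP_NP": +1}),
    # NAD balance (SIRT1 debits mirror A10/A11/A16/A28/A31)
    Reaction("A36", "CP acetylated histone deacetylation (NAD)", _sirt1("VSIRT1d", "AC_CP"), {"NAD": -1}),
    Reaction("A37", "NP acetylated histone deacetylation (NAD)", _sirt1("VSIRT1d", "AC_NP"), {"NAD": -1}),
    Reaction("A38", "IC degradation (NAD)", _sirt1("VSIRT1c", _IC), {"NAD": -1}),
    Reaction("A39", "CP2 degradation (NAD)", _sirt1("VSIRT1c", "CP2"), {"NAD": -1}),
    Reaction("A40", "CP degradation (NAD)", _sirt1("VSIRT1c", "CP"), {"NAD": -1}),
    Reaction("A41", "NAD degradation", "knadd*NAD", {"NAD": -1}),
    Reaction("A42", "NAD synthesis", "VNADc*NP", {"NAD": +1}),
    Reaction("A43", "NAD degradation (PARP1)", "kPARP*NAD", {"NAD": -1}),
    # dimer exchange terms of the monomer balance (2 CP <-> CP2)
    Reaction("A44", "CP2 disassociation", "kd*CP2", {"CP": +2}),
    Reaction("A45", "CP dimerization", "ka*CP**2", {"CP": -2}),
)


_SYMBOLS = {name: sympy.Symbol(name, nonnegative=True)
            for name in (*STATE_NAMES, *PARAM_NAMES)}


def rate_expression(reaction: Reaction) -> sympy.Expr:
    """The reaction's rate as a sympy expression over species/parameter
    symbols."""
    return sympy.sympify(reaction.rate, locals=dict(_SYMBOLS))


@lru_cache(maxsize=1)
def _rate_functions():
    import numpy as np

    order = (*STATE_NAMES, *PARAM_NAMES)
    syms = [_SYMBOLS[name] for name in order]
    return [sympy.lambdify(syms, rate_expression(r), "numpy") for r in REACTIONS]


def network_rhs(y, p):
    """Right-hand side assembled from the reaction network:
    ``sum_r stoichiometry_r * rate_r``.

    Independent of :func:`clocknad.model.rhs` (which hard-codes the summed
    equations); the test suite asserts the two agree.  Valid on the interior
    of the state space (no 0/0 guards).
    """
    import numpy as np

    args = (*y, *p)
    out = np.zeros(len(STATE_NAMES))
    for reaction, fn in zip(REACTIONS, _rate_functions()):
        rate = fn(*args)
        for species, coeff in reaction.stoichiometry.items():
            out[STATE_NAMES.index(species)] += coeff * rate
    return out
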