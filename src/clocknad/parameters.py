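"""Model parameters, state, and the two shipped parameter sets.

The model couples the mammalian core circadian transcription-translation
feedback loop (BMAL1/CLOCK activator ``TF``, merged CRY/PER repressor ``CP``)
to NAD salvage metabolism: NAMPT expression is clock-controlled, NAD is
produced from NAMPT protein, and NAD fuels SIRT1 deacetylation of clock
proteins and promoter histones.  PARP1 (``kPARP``) is a first-order NAD sink
activated during DNA damage; CHK2 (``kchk2``/``kchk2c``) phosphorylates PER
species and triggers their degradation.

All concentrations are in arbitrary units (AU); all rate constants in 1/h;
time in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

#: Canonical parameter order; also the layout of ``ModelParameters.as_array``.
PARAM_NAMES: tuple[str, ...] = (
    "Dex", "kms", "J", "kmd", "kcps", "kcpd", "ka", "kd", "kp1", "Jp",
    "kchk2", "kicd", "kcp2d", "kica", "kchk2c", "kp2", "TFtot",
    "KTFCP", "KCP2CP", "KTFNP", "KCP2NP", "kcpdeac", "knpdeac",
    "VM", "VN", "n", "nac", "Tconst_np", "Tconst_cp",
    "VSIRT1c", "knadd", "knd", "knps", "knpd", "VNADc",
    "kaCPSIRT1", "kbCPSIRT1", "kPARP", "VSIRT1d",
)

#: Dynamical species, in state-vector order.
STATE_NAMES: tuple[str, ...] = (
    "M", "TF", "CP", "CP2", "N", "NP",
    "AC_NP", "AC_CP", "OP_CP", "OP_NP", "NAD",
)

#: The four stress/entrainment inputs that a forcing schedule may override.
FORCING_TARGETS: tuple[str, ...] = ("Dex", "kchk2", "kchk2c", "kPARP")


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


class StateError(ValueError):
    """Raised when a model state violates its invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate and binding constants of the clock/NAD model.

    Parameters
    ----------
    Dex : baseline CRY/PER mRNA induction by dexamethasone (AU/h).
    kms, J, n : Hill-type CRY/PER transcription (legacy core-model term;
        inactive when ``kms`` is 0).
    kmd, kcps, kcpd : CRY/PER mRNA degradation, protein synthesis and
        monomer degradation rates (1/h).
    ka, kd : CRY/PER dimer association/dissociation rates.
    kp1, kp2, Jp : kinase-mediated phosphorylation-degradation of PER
        monomer/dimer with shared Michaelis constant ``Jp``.
    kchk2, kchk2c : CHK2 phosphorylation of free PER species and of PER in
        the inactive complex (DNA-damage inputs, baseline 0).
    kicd, kcp2d, kica : inactive-complex dissociation, dimer degradation,
        and complex association rates.
    TFtot : conserved total BMAL1/CLOCK pool (AU).
    KTFCP, KCP2CP, KTFNP, KCP2NP : promoter binding constants of the
        activator (TF) and of the repressing PER dimer at the CRY/PER and
        NAMPT promoters.
    kcpdeac, knpdeac : basal histone deacetylation rates.
    VM, VN : maximal transcription rates scaled by promoter accessibility.
    nac, Tconst_np, Tconst_cp : accessibility relaxes toward ``AC**nac``
        with the given time constants.
    VSIRT1c, VSIRT1d : SIRT1 maximal deacetylation rates for clock proteins
        and for histones.
    kaCPSIRT1, kbCPSIRT1 : constants of the two-substrate Michaelis-Menten
        SIRT1 rate law (shared by all SIRT1 reactions).
    knadd, VNADc, kPARP : basal NAD turnover, NAMPT-driven NAD production,
        and PARP1 NAD consumption (DNA-damage input, baseline 0).
    knd, knps, knpd : NAMPT mRNA degradation, protein synthesis/degradation.
    """

    Dex: float = 0.0
    kms: float = 0.0
    J: float = 0.0
    kmd: float = 0.0
    kcps: float = 0.0
    kcpd: float = 0.0
    ka: float = 0.0
    kd: float = 0.0
    kp1: float = 0.0
    Jp: float = 0.0
    kchk2: float = 0.0
    kicd: float = 0.0
    kcp2d: float = 0.0
    kica: float = 0.0
    kchk2c: float = 0.0
    kp2: float = 0.0
    TFtot: float = 1.0
    KTFCP: float = 0.0
    KCP2CP: float = 0.0
    KTFNP: float = 0.0
    KCP2NP: float = 0.0
    kcpdeac: float = 0.0
    knpdeac: float = 0.0
    VM: float = 0.0
    VN: float = 0.0
    n: float = 0.0
    nac: float = 0.0
    Tconst_np: float = 1.0
    Tconst_cp: float = 1.0
    VSIRT1c: float = 0.0
    knadd: float = 0.0
    knd: float = 0.0
    knps: float = 0.0
    knpd: float = 0.0
    VNADc: float = 0.0
    kaCPSIRT1: float = 0.0
    kbCPSIRT1: float = 0.0
    kPARP: float = 0.0
    VSIRT1d: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if self.TFtot <= 0:
            raise ParameterError("TFtot must be > 0 (conserved BMAL1/CLOCK pool)")
        if self.Tconst_np <= 0 or self.Tconst_cp <= 0:
            raise ParameterError("promoter relaxation time constants must be > 0")

    def as_array(self) -> np.ndarray:
        """Parameter vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def replace(self, **overrides: float) -> "ModelParameters":
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter names: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ModelState:
    """The 11 dynamical species (all AU except the dimensionless chromatin
    variables ``AC_*`` and ``OP_*``, which live in [0, 1])."""

    M: float = 0.0
    TF: float = 0.0
    CP: float = 0.0
    CP2: float = 0.0
    N: float = 0.0
    NP: float = 0.0
    AC_NP: float = 0.0
    AC_CP: float = 0.0
    OP_CP: float = 0.0
    OP_NP: float = 0.0
    NAD: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise StateError(f"species {name!r} must be finite and >= 0, got {value}")
        for name in ("AC_NP", "AC_CP", "OP_CP", "OP_NP"):
            if getattr(self, name) > 1.0 + 1e-9:
                raise StateError(f"chromatin variable {name!r} must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(STATE_NAMES),):
            raise StateError(f"state vector must have shape ({len(STATE_NAMES)},)")
        return cls(**dict(zip(STATE_NAMES, values)))

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in STATE_NAMES}


# --- shipped parameter sets -------------------------------------------------

_CURRENT_PARAMS: dict[str, float] = {
    "Dex": 0.0, "kms": 0.0, "J": 0.0, "kmd": 0.13857, "kcps": 0.40453,
    "kcpd": 0.48936, "ka": 49.9712, "kd": 0.36005, "kp1": 9.4531,
    "Jp": 77.9254, "kchk2": 0.0, "kicd": 0.0, "kcp2d": 0.0025,
    "kica": 28.178, "kchk2c": 0.0, "kp2": 0.36296, "TFtot": 0.84792,
    "KTFCP": 0.020133, "KCP2CP": 0.20757, "KTFNP": 0.040267,
    "KCP2NP": 0.21591, "kcpdeac": 0.099, "knpdeac": 0.098073,
    "VM": 0.40053, "VN": 0.56383, "n": 0.0, "nac": 1.6107,
    "Tconst_np": 0.26014, "Tconst_cp": 0.22107, "VSIRT1c": 0.094568,
    "knadd": 1.3309, "knd": 0.16337, "knps": 0.20238, "knpd": 0.16024,
    "VNADc": 5.2479, "kaCPSIRT1": 0.10491, "kbCPSIRT1": 0.098395,
    "kPARP": 0.0, "VSIRT1d": 0.070926,
}

_HONG2009_PARAMS: dict[str, float] = {
    "Dex": 0.0, "kms": 1.0, "J": 0.3, "kmd": 0.1, "kcps": 0.5,
    "kcpd": 0.525, "ka": 100.0, "kd": 0.01, "kp1": 10.0, "Jp": 0.05,
    "kchk2": 0.0, "kicd": 0.01, "kcp2d": 0.0525, "kica": 20.0,
    "kchk2c": 0.0, "kp2": 0.1, "TFtot": 0.5, "KTFCP": 0.0,
    "KCP2CP": 0.0, "KTFNP": 0.0, "KCP2NP": 0.0, "kcpdeac": 0.0,
    "knpdeac": 0.0, "VM": 0.0, "VN": 0.0, "n": 2.0, "nac": 0.0,
    "Tconst_np": 1.0, "Tconst_cp": 1.0, "VSIRT1c": 0.0, "knadd": 0.0,
    "knd": 0.0, "knps": 0.0, "knpd": 0.0, "VNADc": 0.0,
    "kaCPSIRT1": 0.0, "kbCPSIRT1": 0.0, "kPARP": 0.0, "VSIRT1d": 0.0,
}

_CURRENT_STATE: dict[str, float] = {
    "M": 1.4, "TF": 0.13, "CP": 0.037, "CP2": 0.046, "N": 1.5, "NP": 1.0,
    "AC_NP": 0.0, "AC_CP": 0.0, "OP_CP": 0.0, "OP_NP": 0.0, "NAD": 3.0,
}

# The legacy core model carries no acetylation dynamics; its AC entries are
# inert but shipped as printed.
_HONG2009_STATE: dict[str, float] = {
    "M": 1.4, "TF": 0.13, "CP": 0.037, "CP2": 0.046, "N": 1.5, "NP": 1.0,
    "AC_NP": 0.01, "AC_CP": 0.01, "OP_CP": 0.0, "OP_NP": 0.0, "NAD": 3.0,
}

FIXTURE_NAMES: tuple[str, ...] = ("current", "hong2009")


@dataclass(frozen=True)
class NamedFixture:
    """A named (parameters, initial state) pair."""

    name: str
    parameters: ModelParameters
    initial_state: ModelState


def load_fixture(name: str) -> NamedFixture:
    """Return a value-copy of one of the shipped model configurations.

    ``"current"`` is the full clock/NAD model; ``"hong2009"`` reconstitutes
    the four-variable core oscillator (all NAD/chromatin extension rates
    zero).
    """
    if name == "current":
        return NamedFixture("current",
                            ModelParameters.from_mapping(_CURRENT_PARAMS),
                            ModelState(**_CURRENT_STATE))
    if name == "hong2009":
        return NamedFixture("hong2009",
                            ModelParameters.from_mapping(_HONG2009_PARAMS),
                            ModelState(**_HONG2009_STATE))
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
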