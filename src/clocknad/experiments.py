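"""The three computational experiments: robustness sweep, NAD/SIRT1
inhibition scans, and the DNA-damage phase-response battery.

All experiments share the transient policy of the free-running analyses:
20 simulated days with the first 5 discarded, unless the protocol fixes its
own window (the PRC protocol evaluates at day 19).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forcing import Pulse
from .model import DEFAULT_VARIANT, ModelVariant
from .parameters import PARAM_NAMES, STATE_NAMES, ModelParameters, ModelState, load_fixture
from .rhythm import (
    NO_PERIOD,
    PRCResult,
    peak_to_peak_amplitude,
    period,
    prc,
)
from .simulate import DEFAULT_SETTINGS, SolverSettings, integrate

TRANSIENT_HOURS = 120.0
RUN_HOURS = 480.0

#: The (kchk2, kPARP) damage configurations of the published battery.
DAMAGE_CONFIGS: tuple[tuple[float, float], ...] = (
    (0.2, 0.0), (0.0, 10.0), (0.0, 20.0),
    (0.1, 10.0), (0.1, 20.0), (0.2, 10.0), (0.2, 20.0),
)


def robustness_sweep(params: ModelParameters,
                     initial: ModelState,
                     fraction: float = 0.2,
                     parameter_names: Sequence[str] = PARAM_NAMES,
                     settings: SolverSettings = DEFAULT_SETTINGS,
                     variant: ModelVariant = DEFAULT_VARIANT) -> pd.DataFrame:
    """Scale every parameter individually by (1 +/- fraction) and record the
    oscillation period (CP mean-crossing; -1 if lost) and the peak-to-peak
    CRY/PER mRNA amplitude.

    Individual failures are recorded per row (period NaN, error message)
    rather than aborting the sweep.
    """
    rows = []
    for name in parameter_names:
        for direction in (-fraction, +fraction):
            scaled = params.replace(**{name: getattr(params, name) * (1.0 + direction)})
            row = {"parameter": name, "direction": direction,
                   "value": getattr(scaled, name)}
            try:
                traj = integrate(initial, scaled, None, RUN_HOURS, settings, variant)
                t, s = traj.after(TRANSIENT_HOURS)
                cp = s[:, STATE_NAMES.index("CP")]
                m = s[:, STATE_NAMES.index("M")]
                row["period"] = period(t, cp)
                row["amplitude_M"] = peak_to_peak_amplitude(t, m)
                row["error"] = ""
            except Exception as exc:  # keep sweeping
                row["period"] = float("nan")
                row["amplitude_M"] = float("nan")
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def inhibition_scan(params: ModelParameters,
                    initial: ModelState,
                    target: str,
                    scale_factors: Sequence[float],
                    statistic: str = "max",
                    settings: SolverSettings = DEFAULT_SETTINGS,
                    variant: ModelVariant = DEFAULT_VARIANT) -> pd.DataFrame:
    """Percent change of the steady-state CRY/PER mRNA level when scaling
    one of the NAD/SIRT1 parameters (``VNADc``, ``VSIRT1c``, ``VSIRT1d``).

    ``statistic`` selects the level measure compared between runs: ``"max"``
    (maximal M over the final 5 days) or ``"mean"`` (time-averaged M).
    Rows where oscillations are lost are flagged, not dropped.
    """
    if target not in ("VNADc", "VSIRT1c", "VSIRT1d"):
        raise ValueError("inhibition target must be one of VNADc, VSIRT1c, VSIRT1d")
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")

    window = RUN_HOURS - TRANSIENT_HOURS  # final 5 days of a 20-day run

    def level(traj):
        t, s = traj.after(window)
        m = s[:, STATE_NAMES.index("M")]
        cp = s[:, STATE_NAMES.index("CP")]
        stat = m.max() if statistic == "max" else m.mean()
        return stat, period(t, cp)

    baseline = integrate(initial, params, None, RUN_HOURS, settings, variant)
    base_level, base_period = level(baseline)
    rows = []
    for factor in scale_factors:
        scaled = params.replace(**{target: getattr(params, target) * factor})
        row = {"target": target, "scale_factor": factor}
        try:
            traj = integrate(initial, scaled, None, RUN_HOURS, settings, variant)
            lvl, per = level(traj)
            row["level_M"] = lvl
            row["pct_change_M"] = (lvl - base_level) / base_level * 100.0
            row["period"] = per
            row["oscillating"] = per != NO_PERIOD
        except Exception as exc:
            row.update(level_M=float("nan"), pct_change_M=float("nan"),
                       period=float("nan"), oscillating=False, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def damage_battery(params: ModelParameters,
                   initial: ModelState,
                   configs: Sequence[tuple[float, float]] = DAMAGE_CONFIGS,
                   pulse_duration: float = 2.0,
                   settings: SolverSettings = DEFAULT_SETTINGS,
                   variant: ModelVariant = DEFAULT_VARIANT,
                   pairing: str = "bracket",
                   keep_curves: bool = False):
    """Phase-response battery over (kchk2, kPARP) damage configurations.

    For each configuration a full 24-start-hour PRC is computed with
    co-timed CHK2 and PARP1 pulses of ``pulse_duration`` hours, and the four
    summary statistics are tabulated in the published schema.

    Returns a DataFrame, or ``(DataFrame, {config: PRCResult})`` when
    ``keep_curves`` is set.
    """
    rows = []
    curves: dict[tuple[float, float], PRCResult] = {}
    for kchk2, kparp in configs:
        template = []
        if kchk2 > 0:
            template.append(Pulse("kchk2", 0.0, pulse_duration, kchk2))
        if kparp > 0:
            template.append(Pulse("kPARP", 0.0, pulse_duration, kparp))
        row = {"kchk2": kchk2, "kparp": kparp}
        try:
            if template:
                result = prc(params, initial, template, settings=settings,
                             variant=variant, pairing=pairing)
            else:  # null battery: no perturbation, flat PRC
                hours = np.arange(24.0)
                result = PRCResult(hours, np.zeros(24), 0.0, 0.0,
                                   float("inf"), float("nan"))
            curves[(kchk2, kparp)] = result
            row.update(max_delay=result.max_delay, max_advance=result.max_advance,
                       advance_delay_ratio=result.advance_delay_ratio,
                       positive_area_fraction=result.positive_area_fraction,
                       error="")
        except Exception as exc:
            row.update(max_delay=float("nan"), max_advance=float("nan"),
                       advance_delay_ratio=float("nan"),
                       positive_area_fraction=float("nan"), error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    return (table, curves) if keep_curves else table


def hong_reconstitution_prc(kchk2: float = 0.2,
                            pulse_duration: float = 2.0,
                            settings: SolverSettings = DEFAULT_SETTINGS,
                            pairing: str = "bracket") -> PRCResult:
    """PRC of the reconstituted four-variable core model under CHK2 pulses.

    Loads the ``hong2009`` parameter set (all NAD/chromatin extension rates
    zero) and runs the same protocol as :func:`damage_battery`.
    """
    fx = load_fixture("hong2009")
    if kchk2 == 0.0:
        hours = np.arange(24.0)
        return PRCResult(hours, np.zeros(24), 0.0, 0.0, float("inf"), float("nan"))
    template = [Pulse("kchk2", 0.0, pulse_duration, kchk2)]
    return prc(fx.parameters, fx.initial_state, template,
               settings=settings, pairing=pairing)


def dex_prc(amplitude: float,
            pulse_duration: float = 2.0,
            settings: SolverSettings = DEFAULT_SETTINGS,
            pairing: str = "bracket") -> PRCResult:
    """PRC of the full model under dexamethasone pulses (entrainment-type
    perturbation).  Low amplitudes give a continuous (Type 1) curve, high
    amplitudes a discontinuous (Type 0) one."""
    fx = load_fixture("current")
    template = [Pulse("Dex", 0.0, pulse_duration, amplitude)]
    return prc(fx.parameters, fx.initial_state, template,
               settings=settings, pairing=pairing)
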