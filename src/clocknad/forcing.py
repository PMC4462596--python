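"""Time-dependent overrides of the stress/entrainment inputs.

Four model inputs can be driven externally: ``Dex`` (dexamethasone induction
of CRY/PER transcription, the zeitgeber surrogate), ``kchk2``/``kchk2c``
(CHK2 phosphorylation-degradation of PER species, the DNA-damage checkpoint
input) and ``kPARP`` (PARP1 NAD consumption, the DNA-damage metabolic
input).  A schedule entry *replaces* the baseline parameter value while it
is active; pulse intervals are half-open ``[start, start+duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .parameters import FORCING_TARGETS, ModelParameters


class ScheduleError(ValueError):
    """Raised for ill-formed forcing schedules (bad target, overlap, ...)."""


@dataclass(frozen=True)
class Pulse:
    """Constant override of ``target`` on ``[start, start+duration)``."""

    target: str
    start: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.target not in FORCING_TARGETS:
            raise ScheduleError(
                f"unknown forcing target {self.target!r}; expected one of {FORCING_TARGETS}")
        if self.start < 0:
            raise ScheduleError("pulse start must be >= 0")
        if self.duration <= 0:
            raise ScheduleError("pulse duration must be > 0")
        if self.amplitude < 0:
            raise ScheduleError("pulse amplitude must be >= 0")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration

    def value(self, t: float, baseline: float) -> float:
        return self.amplitude if self.active(t) else baseline

    def intervals(self, t_end: float):
        if self.start < t_end:
            yield (self.start, min(self.start + self.duration, t_end))

    def breakpoints(self, t_end: float) -> list[float]:
        return [b for b in (self.start, self.start + self.duration) if 0.0 < b < t_end]


@dataclass(frozen=True)
class SquareWave:
    """Periodic override alternating ``high`` (for ``on_duration`` hours)
    and ``low`` (for ``off_duration`` hours), starting its on-phase at
    ``phase_offset``.  Runs for all t >= 0."""

    target: str
    high: float
    low: float
    on_duration: float
    off_duration: float
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in FORCING_TARGETS:
            raise ScheduleError(
                f"unknown forcing target {self.target!r}; expected one of {FORCING_TARGETS}")
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ScheduleError("square-wave on/off durations must be > 0")
        if self.high < 0 or self.low < 0:
            raise ScheduleError("square-wave levels must be >= 0")

    @property
    def period(self) -> float:
        return self.on_duration + self.off_duration

    def active(self, t: float) -> bool:
        return t >= 0

    def value(self, t: float, baseline: float) -> float:
        phase = (t - self.phase_offset) % self.period
        return self.high if phase < self.on_duration else self.low

    def intervals(self, t_end: float):
        yield (0.0, t_end)

    def breakpoints(self, t_end: float) -> list[float]:
        out = []
        t = self.phase_offset - (self.phase_offset // self.period + 1) * self.period
        while t < t_end:
            for b in (t, t + self.on_duration):
                if 0.0 < b < t_end:
                    out.append(b)
            t += self.period
        return out


@dataclass(frozen=True)
class ForcingSchedule:
    """An ordered collection of :class:`Pulse` / :class:`SquareWave`
    entries.  Entries targeting the same input must not overlap in time; an
    empty schedule means free-running."""

    entries: tuple = ()

    def __init__(self, entries: Iterable = ()):
        entries = tuple(entries)
        object.__setattr__(self, "entries", entries)
        self._check_overlap()

    def _check_overlap(self) -> None:
        horizon = 0.0
        for e in self.entries:
            if isinstance(e, Pulse):
                horizon = max(horizon, e.start + e.duration)
        horizon += 1.0
        by_target: dict[str, list[tuple[float, float]]] = {}
        for e in self.entries:
            by_target.setdefault(e.target, []).extend(e.intervals(horizon))
        for target, spans in by_target.items():
            spans.sort()
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:  # half-open intervals: touching is fine
                    raise ScheduleError(
                        f"overlapping schedule entries for target {target!r}: "
                        f"[{a0}, {a1}) and [{b0}, {b1})")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def evaluate(self, params: ModelParameters, t: float) -> dict[str, float]:
        """Effective values of the four stress inputs at time ``t``: the
        baseline parameter values, replaced by any active entry."""
        if t < 0:
            raise ScheduleError("forcing schedules are defined for t >= 0")
        out = {name: getattr(params, name) for name in FORCING_TARGETS}
        for e in self.entries:
            if e.active(t):
                out[e.target] = e.value(t, out[e.target])
        return out

    def breakpoints(self, t_end: float) -> list[float]:
        """Sorted interior discontinuity times in ``(0, t_end)``."""
        out: set[float] = set()
        for e in self.entries:
            out.update(e.breakpoints(t_end))
        return sorted(out)
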