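"""n-back block paradigm: session/series/trial timeline and per-sample labels.

The default schedule mirrors a standard multi-session working-memory
protocol: 3 sessions x 3 series per subject, each series being 2 s of
instructions, 40 s of task (20 trials) and 20 s of rest, i.e. 62 s per
series and 558 s (180 trials) per subject.  Within a session the series
always run in the fixed order 0-back, 2-back, 3-back.

Per-sample labels partition the timeline exactly: task samples carry the
class code of their series, rest samples a distinct rest code, and the
transient instruction seconds are marked unlabeled (they belong to no
class and are never epoched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Workload class names in fixed within-session order, and their codes.
CLASS_NAMES: tuple[str, ...] = ("0-back", "2-back", "3-back")
REST_NAME = "rest"
REST_CODE = 3
UNLABELED_CODE = -1  # instruction seconds

LABEL_NAMES: dict[int, str] = {0: "0-back", 1: "2-back", 2: "3-back", 3: REST_NAME}


@dataclass(frozen=True)
class SeriesSpec:
    """One n-back series: label plus its instruction/task/rest timing."""

    class_code: int  # 0, 1, 2 -> 0-/2-/3-back
    instruction_s: float
    task_s: float
    rest_s: float
    n_trials: int

    @property
    def duration_s(self) -> float:
        return self.instruction_s + self.task_s + self.rest_s


@dataclass(frozen=True)
class Segment:
    """A contiguous labeled span of samples within one series."""

    label: int  # class code or REST_CODE
    series_index: int
    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class BlockSchedule:
    """Full per-subject timeline: ordered series with derived sample labels."""

    sampling_rate: float
    sessions: int
    series_per_session: int
    series: tuple[SeriesSpec, ...]
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.series))

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.series)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate))

    def _boundaries(self) -> np.ndarray:
        """Sample index of every instruction/task/rest boundary, cumulative.

        Rounding is applied to cumulative times, not per-segment durations,
        so segment lengths always sum exactly to the total sample count.
        """
        times = [0.0]
        for s in self.series:
            t0 = times[-1]
            times += [t0 + s.instruction_s, t0 + s.instruction_s + s.task_s, t0 + s.duration_s]
        return np.round(np.asarray(times) * self.sampling_rate).astype(int)

    def label_track(self) -> np.ndarray:
        """Per-sample integer labels over the whole recording.

        Codes: 0/1/2 = 0-/2-/3-back task, 3 = rest, -1 = instruction.
        """
        if "track" not in self._cache:
            track = np.empty(self.n_samples, dtype=np.int8)
            b = self._boundaries()
            for i, s in enumerate(self.series):
                i0, i1, i2, i3 = b[3 * i : 3 * i + 4]
                track[i0:i1] = UNLABELED_CODE
                track[i1:i2] = s.class_code
                track[i2:i3] = REST_CODE
            self._cache["track"] = track
        return self._cache["track"]

    def segments(self, include_rest: bool = True) -> list[Segment]:
        """Contiguous labeled segments (task and, optionally, rest) in time order."""
        out: list[Segment] = []
        b = self._boundaries()
        for i, s in enumerate(self.series):
            _, i1, i2, i3 = b[3 * i : 3 * i + 4]
            out.append(Segment(s.class_code, i, int(i1), int(i2)))
            if include_rest:
                out.append(Segment(REST_CODE, i, int(i2), int(i3)))
        return out


def build_schedule(
    sessions: int = 3,
    series_per_session: int = 3,
    sampling_rate: float = 10.0,
    instruction_s: float = 2.0,
    task_s: float = 40.0,
    rest_s: float = 20.0,
    trials_per_series: int = 20,
) -> BlockSchedule:
    """Build the n-back block schedule.

    Each session runs one series per workload class in the fixed order
    0-back, 2-back, 3-back (``series_per_session`` > 3 cycles through the
    classes again).  Defaults give 9 series of 62 s (558 s, 180 trials).
    """
    if sessions < 1 or series_per_session < 1 or trials_per_series < 1:
        raise ValidationError("sessions, series_per_session and trials_per_series must be >= 1")
    if min(instruction_s, task_s, rest_s) <= 0 or sampling_rate <= 0:
        raise ValidationError("all durations and the sampling rate must be positive")
    series = tuple(
        SeriesSpec(
            class_code=j % len(CLASS_NAMES),
            instruction_s=float(instruction_s),
            task_s=float(task_s),
            rest_s=float(rest_s),
            n_trials=int(trials_per_series),
        )
        for _ in range(sessions)
        for j in range(series_per_session)
    )
    return BlockSchedule(
        sampling_rate=float(sampling_rate),
        sessions=int(sessions),
        series_per_session=int(series_per_session),
        series=series,
    )
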