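"""Stimulus construction for optogenetic auditory experiments.

Three stimulus classes are generated symbolically (event times and chord
levels — no audio is rendered, since every downstream analysis operates on
event times and level matrices):

* **Pure-tone tuning trains** — log-spaced tone frequencies presented in
  pseudo-random order, alternating trials paired with a laser pulse at a
  fixed onset relative to the tone.
* **Click trains** — repeated trains of broadband clicks, alternating trains
  paired with a long laser pulse that leads the train.
* **Dynamic random chords (DRC)** — a dense chord sequence whose per-band
  levels are drawn i.i.d. uniform, with periodic laser epochs; the regressor
  for spectro-temporal receptive-field (STRF) estimation.

Conventions (fixed for determinism):

* Time is in seconds from session start; all intervals are half-open
  ``[onset, onset + duration)``.
* "Alternating" laser pairing means presentation-order even indices
  (0-based) are laser ON.
* Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, ScheduleFormatError

__all__ = [
    "FrequencyGrid",
    "ToneEvent",
    "ClickTrainEvent",
    "StimulusSchedule",
    "DRCStimulus",
    "make_frequency_grid",
    "make_tone_schedule",
    "make_click_schedule",
    "make_drc",
    "write_schedule",
    "read_schedule",
    "write_drc",
    "read_drc",
]

_SQRT3 = math.sqrt(3.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrequencyGrid:
    """A strictly geometric (log-spaced) frequency grid, endpoints inclusive."""

    n_freqs: int
    f_lo: float
    f_hi: float
    values: np.ndarray

    @property
    def step_octaves(self) -> float:
        """Octave spacing between consecutive grid frequencies."""
        return math.log2(self.f_hi / self.f_lo) / (self.n_freqs - 1)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyGrid)
            and self.n_freqs == other.n_freqs
            and self.f_lo == other.f_lo
            and self.f_hi == other.f_hi
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ToneEvent:
    onset: float
    duration: float
    frequency: float
    level: float
    ramp: float = 0.005
    laser: bool = False
    laser_onset_rel: float | None = None  # laser start minus tone start; negative = laser leads
    laser_duration: float | None = None

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class ClickTrainEvent:
    onset: float
    n_clicks: int
    click_duration: float
    isi: float
    level: float
    laser: bool = False
    laser_onset_rel: float | None = None
    laser_duration: float | None = None

    @property
    def duration(self) -> float:
        """Train span: first click onset to last click offset."""
        return self.n_clicks * self.click_duration + (self.n_clicks - 1) * self.isi

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusSchedule:
    """An ordered, non-overlapping sequence of stimulus events."""

    events: list
    total_duration: float
    kind: str  # {"tone", "click"}
    seed: int | None = None

    def __post_init__(self):
        validate_events(self.events)

    def laser_events(self, laser: bool):
        return [e for e in self.events if e.laser == laser]

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])


@dataclass
class DRCStimulus:
    """Dynamic random chord stimulus: a chord × frequency level matrix.

    ``chord_levels`` holds absolute levels in dB SPL. Laser epochs of length
    ``laser_duration`` occur once per ``laser_period``, placed at the end of
    each cycle (onset ``k*laser_period + laser_onset_offset``) so that the
    equal-length window immediately preceding each laser onset lies inside
    the stimulus — the layout the ON/OFF chunking analysis assumes.
    """

    chord_levels: np.ndarray  # [n_chords, n_freqs], dB SPL
    chord_duration: float
    ramp: float
    freqs: FrequencyGrid
    mean_level: float
    level_sd: float
    laser_period: float
    laser_duration: float
    n_files: int
    file_duration: float
    seed: int | None = None
    laser_onset_offset: float | None = None  # laser onset within each cycle

    def __post_init__(self):
        if self.laser_onset_offset is None:
            self.laser_onset_offset = self.laser_period - self.laser_duration

    @property
    def n_chords(self) -> int:
        return self.chord_levels.shape[0]

    @property
    def total_duration(self) -> float:
        return self.n_chords * self.chord_duration

    def laser_onsets(self) -> np.ndarray:
        """Absolute onset times of every laser epoch."""
        n_cycles = int(round(self.total_duration / self.laser_period))
        return np.arange(n_cycles) * self.laser_period + self.laser_onset_offset

    def laser_epochs(self) -> np.ndarray:
        """[n_epochs, 2] array of (on, off) times, half-open."""
        on = self.laser_onsets()
        return np.column_stack([on, on + self.laser_duration])

    def file_starts(self) -> np.ndarray:
        return np.arange(self.n_files) * self.file_duration

    def level_deviations(self) -> np.ndarray:
        """Chord levels as deviation from the nominal mean level (dB)."""
        return self.chord_levels - self.mean_level


def validate_events(events: Sequence) -> None:
    """Enforce schedule invariants: sorted by onset, no temporal overlap."""
    prev_end = -math.inf
    prev_onset = -math.inf
    for i, e in enumerate(events):
        if e.onset < prev_onset:
            raise ScheduleFormatError("events not sorted by onset", line=i, field="onset_s")
        if e.onset < prev_end:
            raise ScheduleFormatError("overlapping events", line=i, field="onset_s")
        prev_onset = e.onset
        prev_end = e.offset


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_frequency_grid(n_freqs: int, f_lo: float, f_hi: float) -> FrequencyGrid:
    """Log-spaced inclusive frequency grid (e.g. 50 tones, 3–70 kHz)."""
    if n_freqs < 2:
        raise ParameterError(f"n_freqs must be >= 2, got {n_freqs}")
    if not (0 < f_lo < f_hi):
        raise ParameterError(f"need 0 < f_lo < f_hi, got f_lo={f_lo}, f_hi={f_hi}")
    values = np.geomspace(f_lo, f_hi, n_freqs)
    values[0], values[-1] = f_lo, f_hi  # pin endpoints exactly
    return FrequencyGrid(n_freqs=n_freqs, f_lo=float(f_lo), f_hi=float(f_hi), values=values)


def _balanced_laser_order(n_freqs: int, n_repeats: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random frequency-index order with per-frequency laser balance.

    Even presentation slots (laser ON) and odd slots (laser OFF) are each
    filled with an independently shuffled multiset containing every
    frequency ``n_repeats // 2`` times; for odd ``n_repeats`` the leftover
    occurrence of each frequency is randomly assigned a parity, subject to
    the slot counts. Guarantees that for even ``n_repeats`` every frequency
    appears equally often in both laser conditions.
    """
    n_events = n_freqs * n_repeats
    n_even = (n_events + 1) // 2  # slots 0, 2, 4, ... = laser ON
    base, extra = divmod(n_repeats, 2)
    counts_even = np.full(n_freqs, base)
    if extra:
        need = n_even - base * n_freqs
        pick = rng.choice(n_freqs, size=need, replace=False)
        counts_even[pick] += 1
    even_list = np.repeat(np.arange(n_freqs), counts_even)
    odd_list = np.repeat(np.arange(n_freqs), n_repeats - counts_even)
    rng.shuffle(even_list)
    rng.shuffle(odd_list)
    order = np.empty(n_events, dtype=int)
    order[0::2] = even_list
    order[1::2] = odd_list
    return order


def make_tone_schedule(
    grid: FrequencyGrid,
    n_repeats: int,
    tone_dur: float = 0.050,
    isi: float = 0.450,
    level: float = 70.0,
    laser_onset_rel: float = -0.100,
    laser_dur: float = 0.250,
    seed: int = 0,
    ramp: float = 0.005,
) -> StimulusSchedule:
    """Pseudo-random tone train with alternating laser pairing.

    Each grid frequency is presented ``n_repeats`` times; the inter-onset
    interval is ``tone_dur + isi``. Even presentation indices are laser ON,
    with the pulse starting at ``laser_onset_rel`` relative to tone onset
    (negative = laser leads the tone).
    """
    if n_repeats < 1:
        raise ParameterError(f"n_repeats must be >= 1, got {n_repeats}")
    if tone_dur <= 0 or isi < 0:
        raise ParameterError("tone_dur must be > 0 and isi >= 0")
    rng = np.random.default_rng(seed)
    order = _balanced_laser_order(grid.n_freqs, n_repeats, rng)
    period = tone_dur + isi
    events = []
    for i, fi in enumerate(order):
        on = i % 2 == 0
        events.append(
            ToneEvent(
                onset=i * period,
                duration=tone_dur,
                frequency=float(grid.values[fi]),
                level=level,
                ramp=ramp,
                laser=on,
                laser_onset_rel=laser_onset_rel if on else None,
                laser_duration=laser_dur if on else None,
            )
        )
    total = len(events) * period
    return StimulusSchedule(events=events, total_duration=total, kind="tone", seed=seed)


def make_click_schedule(
    n_trains: int = 120,
    n_clicks: int = 6,
    click_dur: float = 0.050,
    click_isi: float = 0.050,
    train_isi: float = 0.450,
    laser_lead: float = 0.250,
    laser_dur: float = 1.0,
    level: float = 70.0,
) -> StimulusSchedule:
    """Repeated click trains; alternating trains paired with a leading laser pulse."""
    if n_trains < 1 or n_clicks < 1:
        raise ParameterError("n_trains and n_clicks must be >= 1")
    if min(click_dur, click_isi, train_isi, laser_dur) <= 0:
        raise ParameterError("all durations must be > 0")
    span = n_clicks * click_dur + (n_clicks - 1) * click_isi
    period = span + train_isi
    events = []
    for i in range(n_trains):
        on = i % 2 == 0
        events.append(
            ClickTrainEvent(
                onset=i * period,
                n_clicks=n_clicks,
                click_duration=click_dur,
                isi=click_isi,
                level=level,
                laser=on,
                laser_onset_rel=-laser_lead if on else None,
                laser_duration=laser_dur if on else None,
            )
        )
    total = n_trains * period
    return StimulusSchedule(events=events, total_duration=total, kind="click", seed=None)


def make_drc(
    grid: FrequencyGrid,
    chord_dur: float = 0.020,
    total_dur: float = 2400.0,
    mean_level: float = 50.0,
    level_sd: float = 20.0,
    laser_period: float = 1.0,
    laser_dur: float = 0.250,
    n_files: int = 8,
    seed: int = 0,
    ramp: float = 0.001,
    level_range: tuple[float, float] | None = None,
) -> DRCStimulus:
    """Dynamic random chord stimulus with periodic laser epochs.

    Per-chord, per-frequency levels are drawn i.i.d. from a uniform
    distribution. With only a mean and SD given, the unique uniform with
    those moments is used: ``[mean - sqrt(3)*sd, mean + sqrt(3)*sd]``
    (override via ``level_range``).
    """
    def _divisible(a: float, b: float) -> bool:
        return abs(a / b - round(a / b)) < 1e-9

    if not _divisible(total_dur, chord_dur):
        raise ParameterError(f"total_dur {total_dur} not divisible by chord_dur {chord_dur}")
    if n_files < 1 or not _divisible(total_dur, n_files * chord_dur):
        raise ParameterError("total_dur must split into n_files whole-chord files")
    if laser_dur > laser_period:
        raise ParameterError("laser_dur must not exceed laser_period")
    if level_sd < 0:
        raise ParameterError("level_sd must be >= 0")

    n_chords = int(round(total_dur / chord_dur))
    rng = np.random.default_rng(seed)
    if level_range is None:
        half = _SQRT3 * level_sd
        lo, hi = mean_level - half, mean_level + half
    else:
        lo, hi = level_range
    if hi < lo:
        raise ParameterError("level_range upper bound below lower bound")
    levels = rng.uniform(lo, hi, size=(n_chords, grid.n_freqs))
    return DRCStimulus(
        chord_levels=levels,
        chord_duration=chord_dur,
        ramp=ramp,
        freqs=grid,
        mean_level=mean_level,
        level_sd=level_sd,
        laser_period=laser_period,
        laser_duration=laser_dur,
        n_files=n_files,
        file_duration=total_dur / n_files,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# schedule file I/O (tab-delimited text)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "onset_s",
    "kind",
    "frequency_hz",
    "level_db",
    "duration_s",
    "laser",
    "laser_onset_rel_s",
    "laser_duration_s",
    "n_clicks",
    "click_isi_s",
    "ramp_s",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, str):
        return x
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> Path:
    """Write a schedule as tab-delimited text (one event per row).

    ``#``-prefixed header lines carry schedule-level fields so that
    ``read_schedule(write_schedule(s)) == s`` field-for-field.
    """
    path = Path(path)
    lines = [
        f"# kind\t{schedule.kind}",
        f"# total_duration_s\t{_fmt(schedule.total_duration)}",
        f"# seed\t{_fmt(schedule.seed)}",
        "\t".join(_COLUMNS),
    ]
    for e in schedule.events:
        if isinstance(e, ToneEvent):
            row = [e.onset, "tone", e.frequency, e.level, e.duration,
                   e.laser, e.laser_onset_rel, e.laser_duration, None, None, e.ramp]
        elif isinstance(e, ClickTrainEvent):
            row = [e.onset, "click", None, e.level, e.click_duration,
                   e.laser, e.laser_onset_rel, e.laser_duration, e.n_clicks, e.isi, None]
        else:  # pragma: no cover - guarded by schedule construction
            raise ParameterError(f"unknown event type {type(e).__name__}")
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse(value: str, field_name: str, line_no: int, kind: type):
    if value == "":
        return None
    try:
        if kind is bool:
            return bool(int(value))
        return kind(value)
    except ValueError as exc:
        raise ScheduleFormatError(
            f"cannot parse {value!r} as {kind.__name__}", line=line_no, field=field_name
        ) from exc


def read_schedule(path: str | Path) -> StimulusSchedule:
    """Read a tab-delimited schedule, enforcing all schedule invariants."""
    path = Path(path)
    meta: dict[str, str] = {}
    events = []
    header: list[str] | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise ScheduleFormatError(
                        f"missing column(s) {missing}", line=line_no, field=missing[0]
                    )
                continue
            row = dict(zip(header, cells))
            ekind = row.get("kind", "")
            onset = _parse(row["onset_s"], "onset_s", line_no, float)
            if onset is None:
                raise ScheduleFormatError("empty onset", line=line_no, field="onset_s")
            laser = _parse(row["laser"], "laser", line_no, bool) or False
            common = dict(
                laser=laser,
                laser_onset_rel=_parse(row["laser_onset_rel_s"], "laser_onset_rel_s", line_no, float),
                laser_duration=_parse(row["laser_duration_s"], "laser_duration_s", line_no, float),
            )
            if ekind == "tone":
                events.append(
                    ToneEvent(
                        onset=onset,
                        duration=_parse(row["duration_s"], "duration_s", line_no, float),
                        frequency=_parse(row["frequency_hz"], "frequency_hz", line_no, float),
                        level=_parse(row["level_db"], "level_db", line_no, float),
                        ramp=_parse(row["ramp_s"], "ramp_s", line_no, float),
                        **common,
                    )
                )
            elif ekind == "click":
                events.append(
                    ClickTrainEvent(
                        onset=onset,
                        n_clicks=_parse(row["n_clicks"], "n_clicks", line_no, int),
                        click_duration=_parse(row["duration_s"], "duration_s", line_no, float),
                        isi=_parse(row["click_isi_s"], "click_isi_s", line_no, float),
                        level=_parse(row["level_db"], "level_db", line_no, float),
                        **common,
                    )
                )
            else:
                raise ScheduleFormatError(f"unknown event kind {ekind!r}", line=line_no, field="kind")
    if "kind" not in meta or "total_duration_s" not in meta:
        raise ScheduleFormatError("missing '# kind' or '# total_duration_s' header", line=1)
    seed = meta.get("seed", "")
    try:
        return StimulusSchedule(
            events=events,
            total_duration=float(meta["total_duration_s"]),
            kind=meta["kind"],
            seed=int(seed) if seed not in ("", "None") else None,
        )
    except ScheduleFormatError:
        raise
    except ValueError as exc:
        raise ScheduleFormatError(f"bad header metadata: {exc}", line=1) from exc


# ---------------------------------------------------------------------------
# DRC container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_drc(drc: DRCStimulus, path: str | Path) -> Path:
    """Write a DRC to a self-describing HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("chord_levels", data=drc.chord_levels)
        f.create_dataset("frequencies_hz", data=drc.freqs.values)
        for key in (
            "chord_duration", "ramp", "mean_level", "level_sd", "laser_period",
            "laser_duration", "n_files", "file_duration", "laser_onset_offset",
        ):
            f.attrs[key] = getattr(drc, key)
        f.attrs["seed"] = -1 if drc.seed is None else drc.seed
    return path


def read_drc(path: str | Path) -> DRCStimulus:
    import h5py

    with h5py.File(path, "r") as f:
        levels = f["chord_levels"][()]
        freqs = f["frequencies_hz"][()]
        attrs = dict(f.attrs)
    grid = FrequencyGrid(
        n_freqs=len(freqs), f_lo=float(freqs[0]), f_hi=float(freqs[-1]), values=freqs
    )
    seed = int(attrs["seed"])
    return DRCStimulus(
        chord_levels=levels,
        chord_duration=float(attrs["chord_duration"]),
        ramp=float(attrs["ramp"]),
        freqs=grid,
        mean_level=float(attrs["mean_level"]),
        level_sd=float(attrs["level_sd"]),
        laser_period=float(attrs["laser_period"]),
        laser_duration=float(attrs["laser_duration"]),
        n_files=int(attrs["n_files"]),
        file_duration=float(attrs["file_duration"]),
        seed=None if seed < 0 else seed,
        laser_onset_offset=float(attrs["laser_onset_offset"]),
    )
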