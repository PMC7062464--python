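"""Synthetic spike-train generator with known ground truth.

Units are linear–nonlinear–Poisson (LNP): a stimulus drive (Gaussian
log-frequency tuning for tone sessions, a planted STRF for chord sessions)
is added to a spontaneous rate, half-wave rectified, and spikes are drawn by
thinning an inhomogeneous Poisson process against the piecewise-constant
rate (1 ms resolution).

Optogenetic modulation is modelled separably, mirroring how feedback
effects are typically reported: while the laser effect window is active,

* the spontaneous rate receives an additive offset ``spont_delta`` (Hz), and
* the stimulus-driven rate component is multiplied by ``evoked_gain``.

The effect window is the laser pulse shifted by a small ``latency``; rates
are floored at zero after summation. Because the ground-truth parameters are
retained on each unit, the downstream metric and STRF modules can be tested
as estimators: they should recover ``spont_delta``, ``evoked_gain``, the
best frequency, and the planted STRF peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError
from .stimuli import DRCStimulus, StimulusSchedule

__all__ = [
    "ModulationModel",
    "GroundTruthUnit",
    "SpikeRecording",
    "LaserOnlySession",
    "gaussian_tuning",
    "make_gaussian_strf",
    "make_population",
    "simulate_tone_session",
    "simulate_drc_session",
    "simulate_laser_only",
    "write_recording",
    "read_recording",
]

DT = 0.001  # spike-generation rate resolution, s


@dataclass
class ModulationModel:
    """Laser effect on a unit: additive spontaneous offset + evoked gain.

    ``applies_to`` restricts the effect to units of one region label
    ({'all', 'DCIC', 'CNIC'}); units outside it are unmodulated.
    """

    spont_delta: float = 0.0   # Hz, added to spontaneous rate while ON
    evoked_gain: float = 1.0   # multiplier on stimulus-driven rate while ON
    latency: float = 0.005     # s, laser onset -> effect onset
    applies_to: str = "all"

    def __post_init__(self):
        if self.evoked_gain < 0:
            raise ParameterError(f"evoked_gain must be >= 0, got {self.evoked_gain}")
        if self.applies_to not in ("all", "DCIC", "CNIC"):
            raise ParameterError(f"unknown applies_to {self.applies_to!r}")

    def affects(self, region: str) -> bool:
        return self.applies_to == "all" or self.applies_to == region


@dataclass
class GroundTruthUnit:
    unit_id: str
    region: str = "DCIC"           # {"DCIC", "CNIC"} metadata label
    spont_rate: float = 4.0        # Hz
    bf: float = 15000.0            # best frequency, Hz
    bandwidth: float = 0.5         # tuning SD, octaves
    peak_evoked: float = 20.0      # Hz at BF
    onset_latency: float = 0.010   # s, tone onset -> response onset
    strf_true: np.ndarray | None = None   # [n_lags, n_freqs], Hz per dB
    strf_lag_bin: float = 0.005    # s, lag resolution of strf_true
    modulation: ModulationModel = field(default_factory=ModulationModel)
    single_unit: bool = False

    def __post_init__(self):
        if self.spont_rate < 0 or self.peak_evoked < 0:
            raise ParameterError("spont_rate and peak_evoked must be >= 0")

    def tuning(self, freqs: np.ndarray) -> np.ndarray:
        return gaussian_tuning(freqs, self.bf, self.bandwidth, self.peak_evoked)


@dataclass
class SpikeRecording:
    """Spike times per unit for one simulated session."""

    units: dict[str, np.ndarray]           # unit_id -> sorted spike times, s
    duration: float
    seed: int | None = None
    metadata: dict[str, dict] = field(default_factory=dict)  # unit_id -> labels/ground truth

    def __post_init__(self):
        for uid, t in self.units.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.duration):
                raise ParameterError(f"unit {uid}: spike times unsorted or out of range")
            self.units[uid] = t

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units)


@dataclass
class LaserOnlySession:
    """Laser-only sweeps (no sound): recording plus the sweep table."""

    recording: SpikeRecording
    sweeps: "pandas.DataFrame"  # columns: t_start, sweep_dur, laser, laser_onset, laser_dur


def gaussian_tuning(freqs: np.ndarray, bf: float, bandwidth: float, peak: float) -> np.ndarray:
    """Gaussian tuning over log2 frequency: peak * exp(-log2(f/bf)^2 / (2 bw^2))."""
    x = np.log2(np.asarray(freqs, dtype=float) / bf)
    return peak * np.exp(-0.5 * (x / bandwidth) ** 2)


def make_gaussian_strf(
    n_lags: int,
    n_freqs: int,
    peak_lag: int,
    peak_freq: int,
    sigma_lag: float = 2.5,
    sigma_freq: float = 2.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """A localized Gaussian-bump STRF (positive lobe) on the lag × freq grid."""
    li = np.arange(n_lags)[:, None]
    fi = np.arange(n_freqs)[None, :]
    g = np.exp(-0.5 * (((li - peak_lag) / sigma_lag) ** 2 + ((fi - peak_freq) / sigma_freq) ** 2))
    return amplitude * g


def _strf_amplitude_for_sd(
    shape: np.ndarray, level_sd: float, chord_bins: int, target_sd: float
) -> float:
    """Scale factor so the chord-driven rate SD roughly equals ``target_sd``.

    Adjacent lag bins within one chord see identical level deviations, so
    the effective variance is ~ level_sd^2 * chord_bins * sum(shape^2) for
    kernels smooth on the chord scale.
    """
    denom = level_sd * np.sqrt(chord_bins * np.sum(shape**2))
    if denom == 0:
        return 0.0
    return target_sd / denom


def make_population(
    n_units: int,
    rate_ranges: dict | None = None,
    modulation: ModulationModel | None = None,
    seed: int = 0,
    region: str = "DCIC",
    freq_range: tuple[float, float] = (3000.0, 70000.0),
    strf_shape: str | None = None,
    n_lags: int = 20,
    n_freqs: int = 50,
    strf_lag_bin: float = 0.005,
    level_sd: float = 20.0,
    evoked_sd: float = 10.0,
) -> list[GroundTruthUnit]:
    """Draw a population of ground-truth units.

    ``rate_ranges`` maps parameter names to (lo, hi) uniform ranges; defaults
    are typical for midbrain auditory units (spontaneous 2–8 Hz, peak evoked
    15–45 Hz, bandwidth 0.3–1.0 octaves, onset latency 5–15 ms). Best
    frequencies are log-uniform over the central 80% of ``freq_range`` so
    tuning curves peak inside the stimulus grid.

    With ``strf_shape='gaussian'`` each unit also gets a planted
    Gaussian-bump STRF at a random (lag, frequency) position, scaled so the
    chord-driven rate SD is ~``evoked_sd`` Hz under a DRC with level SD
    ``level_sd``.
    """
    if n_units < 1:
        raise ParameterError(f"n_units must be >= 1, got {n_units}")
    ranges = {
        "spont_rate": (2.0, 8.0),
        "peak_evoked": (15.0, 45.0),
        "bandwidth": (0.3, 1.0),
        "onset_latency": (0.005, 0.015),
    }
    if rate_ranges:
        for k, v in rate_ranges.items():
            if k not in ranges:
                raise ParameterError(f"unknown rate range {k!r}")
            if v[1] < v[0]:
                raise ParameterError(f"empty range for {k!r}: {v}")
            ranges[k] = (float(v[0]), float(v[1]))
    modulation = modulation or ModulationModel()
    rng = np.random.default_rng(seed)
    lo, hi = np.log2(freq_range[0]), np.log2(freq_range[1])
    span = hi - lo
    units = []
    for i in range(n_units):
        params = {k: rng.uniform(*ranges[k]) for k in ranges}
        bf = 2.0 ** rng.uniform(lo + 0.1 * span, hi - 0.1 * span)
        strf = None
        if strf_shape == "gaussian":
            peak_lag = int(rng.integers(3, max(4, n_lags - 5)))
            peak_freq = int(rng.integers(4, n_freqs - 4))
            shape = make_gaussian_strf(n_lags, n_freqs, peak_lag, peak_freq)
            chord_bins = 4  # 20 ms chords at 5 ms lag bins
            strf = shape * _strf_amplitude_for_sd(shape, level_sd, chord_bins, evoked_sd)
        elif strf_shape is not None:
            raise ParameterError(f"unknown strf_shape {strf_shape!r}")
        units.append(
            GroundTruthUnit(
                unit_id=f"u{i:03d}",
                region=region,
                bf=bf,
                strf_true=strf,
                strf_lag_bin=strf_lag_bin,
                modulation=modulation,
                **params,
            )
        )
    return units


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _thin_spikes(rate: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Thinning of a homogeneous Poisson proposal against a binned rate."""
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0:
        return np.empty(0)
    total = rate.size * dt
    n_prop = rng.poisson(rmax * total)
    t = np.sort(rng.uniform(0.0, total, size=n_prop))
    keep = rng.uniform(0.0, rmax, size=n_prop) < rate[np.minimum((t / dt).astype(int), rate.size - 1)]
    return t[keep]


def _add_window(vec: np.ndarray, t0: float, t1: float, value: float, dt: float) -> None:
    """Add ``value`` over the half-open window [t0, t1), clipped to the session."""
    b0 = max(int(np.ceil(t0 / dt - 1e-9)), 0)
    b1 = min(int(np.ceil(t1 / dt - 1e-9)), vec.size)
    if b1 > b0:
        vec[b0:b1] += value


def _unit_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_tone_session(
    units: Sequence[GroundTruthUnit],
    schedule: StimulusSchedule,
    seed: int = 0,
    dt: float = DT,
) -> SpikeRecording:
    """Simulate a pure-tone tuning session for a population of units."""
    if schedule.kind != "tone":
        raise ParameterError(f"expected a tone schedule, got kind={schedule.kind!r}")
    n_bins = int(round(schedule.total_duration / dt))
    onsets = np.array([e.onset for e in schedule.events])
    freqs = np.array([e.frequency for e in schedule.events])
    rngs = _unit_rngs(seed, len(units))
    spikes: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for unit, rng in zip(units, rngs):
        resp = gaussian_tuning(freqs, unit.bf, unit.bandwidth, unit.peak_evoked)
        evoked = np.zeros(n_bins)
        laser_ind = np.zeros(n_bins)
        for e, r in zip(schedule.events, resp):
            t0 = e.onset + unit.onset_latency
            _add_window(evoked, t0, t0 + e.duration, r, dt)
            if e.laser and unit.modulation.affects(unit.region):
                ton = e.onset + e.laser_onset_rel + unit.modulation.latency
                _add_window(laser_ind, ton, ton + e.laser_duration, 1.0, dt)
        laser_ind = np.minimum(laser_ind, 1.0)
        mod = unit.modulation
        spont_vec = unit.spont_rate + mod.spont_delta * laser_ind
        gain_vec = 1.0 + (mod.evoked_gain - 1.0) * laser_ind
        rate = np.maximum(spont_vec + gain_vec * evoked, 0.0)
        spikes[unit.unit_id] = _thin_spikes(rate, dt, rng)
        meta[unit.unit_id] = _unit_meta(unit)
    return SpikeRecording(units=spikes, duration=n_bins * dt, seed=seed, metadata=meta)


def simulate_drc_session(
    units: Sequence[GroundTruthUnit],
    drc: DRCStimulus,
    seed: int = 0,
    dt: float = DT,
) -> SpikeRecording:
    """Simulate a DRC session; every unit must carry a planted STRF.

    The stimulus drive is the planted STRF applied to the level deviations
    of the preceding chords: ``evoked(t) = sum_l sum_f strf[l, f] *
    dev(t - (l+1)*lag_bin, f)`` (lags strictly precede the spike bin, the
    same convention the estimator uses).
    """
    for u in units:
        if u.strf_true is None:
            raise ParameterError(f"unit {u.unit_id} has no strf_true")
        if u.strf_true.shape[0] * u.strf_lag_bin > drc.laser_period / 2:
            raise ParameterError(
                f"unit {u.unit_id}: STRF lag extent exceeds laser_period/2; "
                "history would cross ON/OFF chunk boundaries"
            )
        if u.strf_true.shape[1] != drc.freqs.n_freqs:
            raise ParameterError(f"unit {u.unit_id}: STRF frequency axis mismatch")

    lag_bin = units[0].strf_lag_bin
    rep = int(round(drc.chord_duration / lag_bin))
    if abs(rep * lag_bin - drc.chord_duration) > 1e-9 or rep < 1:
        raise ParameterError("chord_duration must be a multiple of the STRF lag bin")
    dev = np.repeat(drc.level_deviations(), rep, axis=0)  # [n_bins5, n_freqs]
    n_bins5 = dev.shape[0]
    expand = int(round(lag_bin / dt))

    laser5 = np.zeros(n_bins5)
    epochs = drc.laser_epochs()
    rngs = _unit_rngs(seed, len(units))
    spikes: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for unit, rng in zip(units, rngs):
        y = fftconvolve(dev, unit.strf_true, axes=0)[: n_bins5, :].sum(axis=1)
        evoked5 = np.empty(n_bins5)
        evoked5[0] = 0.0
        evoked5[1:] = y[:-1]  # drive at bin t uses chords up to bin t-1
        las = laser5.copy()
        if unit.modulation.affects(unit.region):
            for on, off in epochs:
                b0 = int(np.ceil((on + unit.modulation.latency) / lag_bin - 1e-9))
                b1 = int(np.ceil((off + unit.modulation.latency) / lag_bin - 1e-9))
                las[max(b0, 0): min(b1, n_bins5)] = 1.0
        mod = unit.modulation
        rate5 = np.maximum(
            unit.spont_rate + mod.spont_delta * las
            + (1.0 + (mod.evoked_gain - 1.0) * las) * evoked5,
            0.0,
        )
        rate = np.repeat(rate5, expand)
        spikes[unit.unit_id] = _thin_spikes(rate, dt, rng)
        meta[unit.unit_id] = _unit_meta(unit)
    return SpikeRecording(units=spikes, duration=n_bins5 * lag_bin, seed=seed, metadata=meta)


def simulate_laser_only(
    units: Sequence[GroundTruthUnit],
    durations: Sequence[float],
    n_sweeps: int = 50,
    seed: int = 0,
    sweep_period: float = 1.0,
    laser_offset: float = 0.250,
    dt: float = DT,
) -> LaserOnlySession:
    """Interleaved laser / no-laser sweeps with no sound.

    For each pulse duration in ``durations`` (e.g. 1, 5, 25, 250 ms),
    ``2*n_sweeps`` sweeps of length ``sweep_period`` are laid out
    back-to-back, even sweeps laser ON with the pulse starting
    ``laser_offset`` into the sweep.
    """
    import pandas as pd

    if not durations:
        raise ParameterError("durations must be non-empty")
    if n_sweeps < 1:
        raise ParameterError("n_sweeps must be >= 1")
    rows = []
    t = 0.0
    for d in durations:
        if d <= 0 or laser_offset + d > sweep_period:
            raise ParameterError(f"pulse duration {d} does not fit in the sweep")
        for i in range(2 * n_sweeps):
            on = i % 2 == 0
            rows.append(
                dict(
                    t_start=t,
                    sweep_dur=sweep_period,
                    laser=on,
                    laser_onset=t + laser_offset if on else np.nan,
                    laser_dur=d if on else np.nan,
                )
            )
            t += sweep_period
    sweeps = pd.DataFrame(rows)
    n_bins = int(round(t / dt))
    rngs = _unit_rngs(seed, len(units))
    spikes: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for unit, rng in zip(units, rngs):
        rate = np.full(n_bins, unit.spont_rate)
        if unit.modulation.affects(unit.region):
            for _, row in sweeps[sweeps.laser].iterrows():
                ton = row.laser_onset + unit.modulation.latency
                _add_window(rate, ton, ton + row.laser_dur, unit.modulation.spont_delta, dt)
        rate = np.maximum(rate, 0.0)
        spikes[unit.unit_id] = _thin_spikes(rate, dt, rng)
        meta[unit.unit_id] = _unit_meta(unit)
    rec = SpikeRecording(units=spikes, duration=n_bins * dt, seed=seed, metadata=meta)
    return LaserOnlySession(recording=rec, sweeps=sweeps)


def _unit_meta(unit: GroundTruthUnit) -> dict:
    d = {
        "region": unit.region,
        "single_unit": unit.single_unit,
        "ground_truth": {
            "spont_rate": unit.spont_rate,
            "bf": unit.bf,
            "bandwidth": unit.bandwidth,
            "peak_evoked": unit.peak_evoked,
            "onset_latency": unit.onset_latency,
            "spont_delta": unit.modulation.spont_delta,
            "evoked_gain": unit.modulation.evoked_gain,
            "mod_latency": unit.modulation.latency,
        },
    }
    return d


# ---------------------------------------------------------------------------
# recording I/O: TSV events + YAML sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: SpikeRecording, path: str | Path) -> Path:
    """Write spikes as TSV (unit_id, spike_time_s) with a YAML metadata sidecar."""
    import yaml

    path = Path(path)
    lines = ["unit_id\tspike_time_s"]
    for uid in rec.unit_ids:
        for t in rec.units[uid]:
            lines.append(f"{uid}\t{float(t)!r}")
    path.write_text("\n".join(lines) + "\n")
    side = path.with_suffix(path.suffix + ".meta.yaml")
    meta = {
        "duration": float(rec.duration),
        "seed": rec.seed,
        "unit_ids": rec.unit_ids,
        "units": rec.metadata,
    }
    side.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_recording(path: str | Path) -> SpikeRecording:
    import yaml

    from .errors import ScheduleFormatError

    path = Path(path)
    side = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(side.read_text())
    units: dict[str, list[float]] = {uid: [] for uid in meta.get("unit_ids", [])}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("unit_id"):
                continue
            try:
                uid, t = line.split("\t")
                units.setdefault(uid, []).append(float(t))
            except ValueError as exc:
                raise ScheduleFormatError(
                    "malformed spike row", line=line_no, field="spike_time_s"
                ) from exc
    return SpikeRecording(
        units={uid: np.sort(np.asarray(ts)) for uid, ts in units.items()},
        duration=float(meta["duration"]),
        seed=meta.get("seed"),
        metadata=meta.get("units", {}),
    )
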