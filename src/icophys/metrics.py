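"""Trial-aligned response metrics for interleaved laser/no-laser sessions.

Implements the unit-level measurements used throughout the analysis:

* multi-unit quality from inter-spike-interval (ISI) violations,
* peri-stimulus time histograms (PSTHs),
* tuning curves and the top-k preferred-frequency selection,
* responsiveness screening (evoked vs spontaneous + 2 SD),
* spontaneous rate and tone-evoked response magnitude per laser condition,
* sparseness of frequency tuning,
* best frequency,
* rank-matched linear fits of laser-ON vs laser-OFF tuning (gain analysis),
* subgroup stratification by >1 SD changes,
* laser-alone response windows.

All windows are half-open in seconds relative to tone onset; a spike exactly
at onset belongs to the evoked window. Tone-evoked firing rates used for
tuning curves, sparseness, best frequency and ranked fits are raw rates in
the evoked window (not spontaneous-subtracted), which keeps the sparseness
formula within its bounds; evoked response *magnitude* subtracts the
same-condition spontaneous rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import AnalysisError, ParameterError
from .simulate import LaserOnlySession, SpikeRecording
from .stimuli import FrequencyGrid, StimulusSchedule

__all__ = [
    "TuningCurve",
    "LinearFit",
    "isi_violation_rate",
    "trial_table",
    "psth",
    "tuning_curve",
    "top_frequencies",
    "select_responsive",
    "spontaneous_rate",
    "evoked_magnitude",
    "sparseness",
    "best_frequency",
    "ranked_linear_fit",
    "compute_unit_metrics",
    "stratify_units",
    "laser_only_response",
]

EVOKED_WINDOW = 0.075   # s after tone onset
SPONT_WINDOW_FEEDBACK = 0.020    # s before tone onset (feedback protocol)
SPONT_WINDOW_INTERNEURON = 0.050 # s before tone onset (interneuron protocol)
ISI_THRESHOLD = 0.001   # s
ISI_QUALITY_MAX = 0.01  # max violation fraction for a usable multi-unit


@dataclass
class TuningCurve:
    """Mean firing rate per stimulus frequency for one laser condition."""

    freqs: np.ndarray              # Hz, ascending
    fr: np.ndarray                 # Hz, same length
    condition: str                 # {"laser_on", "laser_off"}
    n_repeats_per_freq: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.fr = np.asarray(self.fr, dtype=float)
        if self.freqs.shape != self.fr.shape:
            raise ParameterError("freqs and fr must have equal length")
        if np.any(self.fr < 0):
            raise ParameterError("firing rates must be non-negative")

    @property
    def n(self) -> int:
        return self.fr.size


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    stderr: float
    degenerate: bool = False


def isi_violation_rate(spikes: np.ndarray, threshold: float = ISI_THRESHOLD) -> float:
    """Fraction of inter-spike intervals shorter than ``threshold``.

    Quality rule for multi-units: usable iff the rate is < 1%. With fewer
    than two spikes the rate is undefined; 0 is returned with a warning.
    """
    spikes = np.asarray(spikes)
    if spikes.size < 2:
        warnings.warn("isi_violation_rate undefined for <2 spikes; returning 0")
        return 0.0
    isis = np.diff(spikes)
    return float(np.mean(isis < threshold))


def trial_table(schedule: StimulusSchedule) -> pd.DataFrame:
    """One row per stimulus event: onset, frequency, laser fields."""
    rows = []
    for i, e in enumerate(schedule.events):
        rows.append(
            dict(
                trial=i,
                onset=e.onset,
                frequency=getattr(e, "frequency", np.nan),
                duration=e.duration,
                laser=e.laser,
                laser_onset_rel=e.laser_onset_rel if e.laser else np.nan,
                laser_duration=e.laser_duration if e.laser else np.nan,
            )
        )
    return pd.DataFrame(rows)


def _window_counts(spikes: np.ndarray, onsets: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Spike counts in [onset+t0, onset+t1) for each onset."""
    spikes = np.asarray(spikes)
    lo = np.searchsorted(spikes, onsets + t0, side="left")
    hi = np.searchsorted(spikes, onsets + t1, side="left")
    return (hi - lo).astype(float)


def window_rates(spikes: np.ndarray, onsets: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Per-trial firing rate (Hz) in the half-open window [t0, t1) rel. onset."""
    if t1 <= t0:
        raise ParameterError("window must have positive length")
    return _window_counts(spikes, np.asarray(onsets, dtype=float), t0, t1) / (t1 - t0)


def psth(
    spikes: np.ndarray,
    schedule: StimulusSchedule,
    window: tuple[float, float] = (-0.05, 0.15),
    binsize: float = 0.005,
    laser: bool | None = None,
    frequencies: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate around stimulus onset.

    Returns (rates_hz, bin_edges). ``laser``/``frequencies`` filter trials;
    an empty trial set raises, naming the filter.
    """
    if binsize <= 0:
        raise ParameterError("binsize must be > 0")
    tt = trial_table(schedule)
    if laser is not None:
        tt = tt[tt.laser == laser]
    if frequencies is not None:
        tt = tt[np.isin(tt.frequency, np.asarray(frequencies))]
    if tt.empty:
        raise AnalysisError(
            f"no trials match filter (laser={laser}, frequencies="
            f"{None if frequencies is None else len(frequencies)})"
        )
    t0, t1 = window
    edges = np.arange(t0, t1 + binsize * 0.5, binsize)
    counts = np.zeros(edges.size - 1)
    spikes = np.asarray(spikes)
    for onset in tt.onset.to_numpy():
        rel = spikes[(spikes >= onset + t0) & (spikes < onset + edges[-1])] - onset
        counts += np.histogram(rel, bins=edges)[0]
    return counts / (len(tt) * binsize), edges


def tuning_curve(
    spikes: np.ndarray,
    schedule: StimulusSchedule,
    laser: bool | None,
    window: tuple[float, float] = (0.0, EVOKED_WINDOW),
) -> TuningCurve:
    """Per-frequency mean evoked-window firing rate.

    ``laser`` selects one condition; ``laser=None`` pools both conditions
    (the curve used for preferred-frequency selection — pooling keeps the
    selection noise symmetric across conditions, so downstream ON vs OFF
    comparisons on the selected trials stay calibrated under a null laser
    effect).
    """
    tt = trial_table(schedule)
    if laser is not None:
        tt = tt[tt.laser == laser]
    if tt.empty:
        raise AnalysisError(f"no trials with laser={laser}")
    rates = window_rates(spikes, tt.onset.to_numpy(), *window)
    df = pd.DataFrame({"frequency": tt.frequency.to_numpy(), "rate": rates})
    agg = df.groupby("frequency", sort=True)["rate"].agg(["mean", "count"])
    condition = "pooled" if laser is None else ("laser_on" if laser else "laser_off")
    return TuningCurve(
        freqs=agg.index.to_numpy(),
        fr=agg["mean"].to_numpy(),
        condition=condition,
        n_repeats_per_freq=int(agg["count"].min()),
    )


def top_frequencies(tuning: TuningCurve, k: int = 7) -> np.ndarray:
    """Indices of the k frequencies with the largest response in ``tuning``.

    Ties broken toward the lower frequency; indices returned sorted
    ascending. The metric chain passes the pooled-condition curve here (see
    :func:`tuning_curve`); pass a laser-OFF curve to select on no-laser
    trials only.
    """
    if k > tuning.n:
        raise ParameterError(f"k={k} exceeds number of frequencies {tuning.n}")
    order = np.argsort(-tuning.fr, kind="stable")  # stable => lower freq wins ties
    return np.sort(order[:k])


def spontaneous_rate(
    spikes: np.ndarray,
    schedule: StimulusSchedule,
    laser: bool,
    window_len: float = SPONT_WINDOW_FEEDBACK,
    top_freqs: np.ndarray | None = None,
    k: int = 7,
) -> float:
    """Mean rate in the pre-onset window over top-k preferred-frequency trials.

    The preferred frequencies default to the top-k of the pooled-condition
    tuning curve (pass ``top_freqs`` as frequency values to reuse a
    selection).
    """
    return float(np.mean(_condition_trial_rates(
        spikes, schedule, laser, (-window_len, 0.0), top_freqs, k)))


def evoked_magnitude(
    spikes: np.ndarray,
    schedule: StimulusSchedule,
    laser: bool,
    spont_window_len: float = SPONT_WINDOW_FEEDBACK,
    top_freqs: np.ndarray | None = None,
    k: int = 7,
) -> float:
    """Tone-evoked response magnitude: mean evoked-window rate minus the
    same-condition spontaneous rate, over top-k preferred-frequency trials.

    May be negative when suppression dominates; no clipping.
    """
    ev = float(np.mean(_condition_trial_rates(
        spikes, schedule, laser, (0.0, EVOKED_WINDOW), top_freqs, k)))
    sp = spontaneous_rate(spikes, schedule, laser, spont_window_len, top_freqs, k)
    return ev - sp


def _condition_trial_rates(
    spikes: np.ndarray,
    schedule: StimulusSchedule,
    laser: bool,
    window: tuple[float, float],
    top_freqs: np.ndarray | None,
    k: int,
) -> np.ndarray:
    if top_freqs is None:
        tc_pool = tuning_curve(spikes, schedule, laser=None)
        top_freqs = tc_pool.freqs[top_frequencies(tc_pool, k)]
    tt = trial_table(schedule)
    tt = tt[(tt.laser == laser) & np.isin(tt.frequency, np.asarray(top_freqs))]
    if tt.empty:
        raise AnalysisError(f"no qualifying trials (laser={laser})")
    return window_rates(spikes, tt.onset.to_numpy(), *window)


def select_responsive(
    recording: SpikeRecording,
    schedule: StimulusSchedule,
    k: int = 7,
    evoked_window: float = EVOKED_WINDOW,
    spont_window: float = 0.050,
    threshold_sd: float = 2.0,
) -> pd.DataFrame:
    """Pure-tone responsiveness screen (laser-OFF trials only).

    A unit is retained iff its mean evoked rate over top-k-frequency
    laser-OFF trials is at least ``threshold_sd`` spontaneous SDs above the
    spontaneous mean (spontaneous measured per-trial in ``spont_window``
    before onset on the same trials). Returns one row per unit with the
    decision, the quality (ISI-violation) rate, and degenerate flags.
    """
    tt = trial_table(schedule)
    if not (~tt.laser).any():
        raise AnalysisError("no laser-OFF trials in schedule")
    rows = []
    for uid in recording.unit_ids:
        spikes = recording.units[uid]
        degenerate = False
        if spikes.size == 0:
            rows.append(dict(unit_id=uid, responsive=False, degenerate=True,
                             evoked_rate=0.0, spont_mean=0.0, spont_sd=0.0,
                             isi_violation_rate=0.0, quality_pass=True))
            continue
        tc_pool = tuning_curve(spikes, schedule, laser=None, window=(0.0, evoked_window))
        top = tc_pool.freqs[top_frequencies(tc_pool, k)]
        sub = tt[(~tt.laser) & np.isin(tt.frequency, top)]
        ev = window_rates(spikes, sub.onset.to_numpy(), 0.0, evoked_window)
        sp = window_rates(spikes, sub.onset.to_numpy(), -spont_window, 0.0)
        sp_mean, sp_sd = float(sp.mean()), float(sp.std(ddof=1))
        if sp_sd == 0 and float(ev.mean()) == sp_mean:
            degenerate = True
            responsive = False
        else:
            responsive = bool(ev.mean() >= sp_mean + threshold_sd * sp_sd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            viol = isi_violation_rate(spikes)
        rows.append(dict(
            unit_id=uid, responsive=responsive, degenerate=degenerate,
            evoked_rate=float(ev.mean()), spont_mean=sp_mean, spont_sd=sp_sd,
            isi_violation_rate=viol, quality_pass=bool(viol < ISI_QUALITY_MAX),
        ))
    return pd.DataFrame(rows).set_index("unit_id")


def sparseness(fr: np.ndarray | TuningCurve) -> float:
    """Sparseness of a tuning curve: 1 - (mean FR)^2 / mean(FR^2).

    0 for flat tuning, approaching 1 - 1/n for a one-hot curve. Undefined
    (NaN, with a warning) for an all-zero curve.
    """
    if isinstance(fr, TuningCurve):
        fr = fr.fr
    fr = np.asarray(fr, dtype=float)
    if np.any(fr < 0):
        raise ParameterError("sparseness requires non-negative rates")
    ms = np.mean(fr**2)
    if ms == 0:
        warnings.warn("sparseness undefined for all-zero tuning curve")
        return float("nan")
    return float(1.0 - np.mean(fr) ** 2 / ms)


def best_frequency(tuning: TuningCurve) -> float:
    """Frequency eliciting the maximum mean response (ties → lowest frequency)."""
    if tuning.n == 0:
        raise ParameterError("empty tuning curve")
    return float(tuning.freqs[int(np.argmax(tuning.fr))])


def ranked_linear_fit(
    tuning_off: TuningCurve,
    tuning_on: TuningCurve,
    ranked: bool = True,
) -> LinearFit:
    """OLS fit of laser-ON tuning on laser-OFF tuning (gain analysis).

    With ``ranked=True`` (default) each condition's per-frequency means are
    independently sorted ascending before regression — the rank-matched
    response-function construction, insulating the slope/intercept from
    best-frequency shifts. Slope < 1 indicates a divisive component,
    intercept > 0 an additive component.
    """
    if tuning_off.n != tuning_on.n:
        raise ParameterError("tuning curves must have equal length")
    x = np.sort(tuning_off.fr) if ranked else tuning_off.fr
    y = np.sort(tuning_on.fr) if ranked else tuning_on.fr
    if np.ptp(x) == 0:
        warnings.warn("zero variance in laser-OFF tuning; slope undefined")
        return LinearFit(np.nan, np.nan, np.nan, np.nan, np.nan, degenerate=True)
    res = sstats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), pvalue=float(res.pvalue),
        stderr=float(res.stderr), degenerate=False,
    )


def compute_unit_metrics(
    recording: SpikeRecording,
    schedule: StimulusSchedule,
    k: int = 7,
    spont_window: float = SPONT_WINDOW_FEEDBACK,
    threshold_sd: float = 1.0,
    responsive_spont_window: float = 0.050,
) -> pd.DataFrame:
    """Full per-unit metric table for one tone session (one laser-onset condition).

    Columns: spontaneous rate and evoked magnitude per condition, sparseness,
    best frequency, ranked-fit slope/intercept, responsiveness and quality,
    and the >``threshold_sd``-SD subgroup flags (computed against the SD of
    this session's laser-OFF per-trial values; pair with
    :func:`stratify_units` to apply flags from a reference-onset session).
    """
    tt = trial_table(schedule)
    rows = []
    for uid in recording.unit_ids:
        spikes = recording.units[uid]
        row: dict = dict(unit_id=uid)
        if spikes.size == 0:
            row.update(responsive=False, degenerate=True)
            rows.append(row)
            continue
        tc_off = tuning_curve(spikes, schedule, laser=False)
        tc_on = tuning_curve(spikes, schedule, laser=True)
        # preferred frequencies from the pooled curve: symmetric selection
        # noise keeps the ON vs OFF comparison unbiased under a null effect
        tc_pool = tuning_curve(spikes, schedule, laser=None)
        top = tc_pool.freqs[top_frequencies(tc_pool, k)]

        per_trial = {}
        for laser in (False, True):
            sub = tt[(tt.laser == laser) & np.isin(tt.frequency, top)]
            per_trial[laser] = dict(
                spont=window_rates(spikes, sub.onset.to_numpy(), -spont_window, 0.0),
                evoked=window_rates(spikes, sub.onset.to_numpy(), 0.0, EVOKED_WINDOW),
            )
        spont_off = float(per_trial[False]["spont"].mean())
        spont_on = float(per_trial[True]["spont"].mean())
        mag_off = float(per_trial[False]["evoked"].mean()) - spont_off
        mag_on = float(per_trial[True]["evoked"].mean()) - spont_on

        fit = ranked_linear_fit(tc_off, tc_on)
        resp = select_responsive(
            SpikeRecording(units={uid: spikes}, duration=recording.duration),
            schedule, k=k, spont_window=responsive_spont_window,
        ).loc[uid]

        # >N SD stratification against laser-OFF per-trial variability
        sd_spont = float(per_trial[False]["spont"].std(ddof=1))
        sd_mag = float((per_trial[False]["evoked"] - spont_off).std(ddof=1))
        d_spont = spont_on - spont_off
        d_mag = mag_on - mag_off
        row.update(
            spont_on=spont_on, spont_off=spont_off,
            evoked_mag_on=mag_on, evoked_mag_off=mag_off,
            sparseness_on=sparseness(tc_on), sparseness_off=sparseness(tc_off),
            bf_on=best_frequency(tc_on), bf_off=best_frequency(tc_off),
            fit_slope=fit.slope, fit_intercept=fit.intercept,
            fit_degenerate=fit.degenerate,
            responsive=bool(resp.responsive),
            degenerate=bool(resp.degenerate),
            isi_violation_rate=float(resp.isi_violation_rate),
            quality_pass=bool(resp.quality_pass),
            spont_increase=bool(sd_spont > 0 and d_spont > threshold_sd * sd_spont),
            spont_decrease=bool(sd_spont > 0 and -d_spont > threshold_sd * sd_spont),
            mag_increase=bool(sd_mag > 0 and d_mag > threshold_sd * sd_mag),
            mag_decrease=bool(sd_mag > 0 and -d_mag > threshold_sd * sd_mag),
            strat_degenerate=bool(sd_spont == 0 or sd_mag == 0),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


def stratify_units(metrics_ref: pd.DataFrame, metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply subgroup flags from a reference-onset session to another table.

    The convention is to derive the flags from the −100 ms laser-onset
    session and analyse the flagged subgroups at every onset. With
    ``metrics=None`` the reference table itself is returned with only the
    flag columns.
    """
    flags = metrics_ref[
        ["spont_increase", "spont_decrease", "mag_increase", "mag_decrease", "strat_degenerate"]
    ]
    if metrics is None:
        return flags.copy()
    out = metrics.drop(columns=flags.columns, errors="ignore")
    return out.join(flags, how="left")


def click_response(
    recording: SpikeRecording,
    schedule: StimulusSchedule,
    spont_window: float = 0.250,
) -> pd.DataFrame:
    """Per-unit click-train response per laser condition.

    Click-evoked rate is the mean rate over the train span (first click
    onset to last click offset). The spontaneous reference is a
    ``spont_window`` window ending at laser onset on laser trials, and the
    matched pre-train window on no-laser trials.
    """
    if schedule.kind != "click":
        raise ParameterError(f"expected a click schedule, got kind={schedule.kind!r}")
    laser_events = schedule.laser_events(True)
    lead = -laser_events[0].laser_onset_rel if laser_events else spont_window
    rows = []
    for uid in recording.unit_ids:
        spikes = recording.units[uid]
        for laser in (False, True):
            evs = schedule.laser_events(laser)
            if not evs:
                continue
            onsets = np.array([e.onset for e in evs])
            span = evs[0].duration
            ev = window_rates(spikes, onsets, 0.0, span)
            sp = window_rates(spikes, onsets, -lead - spont_window, -lead)
            rows.append(dict(
                unit_id=uid, condition="laser_on" if laser else "laser_off",
                evoked_rate=float(ev.mean()), spont_rate=float(sp.mean()),
                evoked_mag=float(ev.mean() - sp.mean()), n_trains=len(evs),
            ))
    return pd.DataFrame(rows)


def laser_only_response(
    session: LaserOnlySession,
    min_window: float = 0.025,
) -> pd.DataFrame:
    """Per-unit laser-alone effect for each pulse duration.

    The response window is [laser onset, onset + max(duration, 25 ms)) on ON
    sweeps and the matched window on interleaved OFF sweeps. The change is
    also expressed in units of the OFF-sweep SD: (ON − OFF) / SD_OFF.
    """
    sw = session.sweeps
    rows = []
    for d, grp in sw.groupby(sw.laser_dur.where(sw.laser), dropna=True):
        wlen = max(float(d), min_window)
        on_starts = grp.laser_onset.to_numpy()
        # matched window on the interleaved OFF sweeps of the same block
        block = sw[(sw.t_start >= grp.t_start.min() - 1e-9)
                   & (sw.t_start <= grp.t_start.max() + sw.sweep_dur.max())]
        off = block[~block.laser]
        offset = float((grp.laser_onset - grp.t_start).iloc[0])
        off_starts = off.t_start.to_numpy() + offset
        for uid in session.recording.unit_ids:
            spikes = session.recording.units[uid]
            r_on = window_rates(spikes, on_starts, 0.0, wlen)
            r_off = window_rates(spikes, off_starts, 0.0, wlen)
            sd_off = float(r_off.std(ddof=1))
            delta = float(r_on.mean() - r_off.mean())
            rows.append(dict(
                unit_id=uid, laser_dur=float(d),
                rate_on=float(r_on.mean()), rate_off=float(r_off.mean()),
                delta=delta,
                delta_sd_units=delta / sd_off if sd_off > 0 else np.nan,
            ))
    return pd.DataFrame(rows)
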