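"""Spectro-temporal receptive field (STRF) estimation from DRC sessions.

The estimator is a spike-triggered average of the chord-level deviations
preceding each spike, computed separately for laser ON and laser OFF
epochs:

1. Each 1 s laser cycle is split into the laser ON chunk and the
   equal-length OFF chunk immediately preceding laser onset; spikes are
   assigned to chunks by their times, and spikes whose lag history would
   cross a chunk boundary are discarded (ON/OFF stimulus history is never
   mixed).
2. The chord matrix is upsampled to the lag resolution by nearest-neighbour
   replication and expressed as deviation from the nominal mean level.
3. The STRF is the mean pre-spike spectrogram window minus the mean window
   over *all* valid time bins (bias correction), averaged across stimulus
   files with per-file spike-count weighting.

Significance uses a scrambled-spike permutation scheme: per repetition, an
ensemble of circularly-shifted spike trains yields a null STRF mean and SD
per pixel; the real STRF is z-scored against it and cluster-extent
corrected (pixelwise |z| threshold, minimum cluster size from the null
cluster-size distribution). The repetition is run ``n_reps`` times and only
pixels significant in more than ``persist_threshold`` repetitions enter the
final mask. Contiguous same-signed significant pixels form lobes, which are
matched across laser conditions by pixel overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AnalysisError, ParameterError
from .stimuli import DRCStimulus, FrequencyGrid

__all__ = [
    "STRFMatrix",
    "SignificanceMask",
    "Lobe",
    "LobeMatchResult",
    "ChunkSegmentation",
    "STRFDesign",
    "segment_laser_chunks",
    "upsample_drc",
    "estimate_strf",
    "scramble_spikes",
    "strf_significance",
    "extract_lobes",
    "match_lobes",
    "compare_lobe_parameters",
    "drc_rate_split",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class STRFMatrix:
    """Lag × frequency receptive-field estimate (spike-triggered deviation)."""

    values: np.ndarray        # [n_lags, n_freqs], dB deviation per spike
    lag_bin: float            # s
    lags: np.ndarray          # s, lag l covers stimulus (l+1) bins before the spike bin
    freqs: FrequencyGrid
    condition: str            # {"laser_on", "laser_off"}
    n_spikes: int
    low_spike_count: bool = False

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]


@dataclass
class SignificanceMask:
    persistence_counts: np.ndarray  # int [n_lags, n_freqs] in [0, n_reps]
    mask: np.ndarray                # bool, counts > persist_threshold
    n_reps: int
    persist_threshold: int

    def at_threshold(self, persist_threshold: int) -> np.ndarray:
        """Mask recomputed at a different persistence threshold."""
        return self.persistence_counts > persist_threshold


@dataclass
class Lobe:
    sign: str                      # {"positive", "negative"}
    pixels: frozenset              # of (lag index, freq index)
    peak_time: float               # s
    temporal_width: float          # s
    peak_frequency: float          # Hz
    frequency_width: float         # octaves
    size: int


@dataclass
class LobeMatchResult:
    pairs: list                    # of (off Lobe, on Lobe)
    persistence: dict              # sign -> matched-off / total-off fraction (NaN if none)
    unmatched_off: list
    unmatched_on: list


@dataclass
class ChunkSegmentation:
    """Spike-to-chunk assignment for one recording against one DRC."""

    on_chunks: np.ndarray          # [n, 2] (t0, t1) half-open, laser ON epochs
    off_chunks: np.ndarray         # [n, 2] equal-length windows before laser onset
    on_spikes: list                # spike-time arrays per ON chunk
    off_spikes: list
    n_on: int
    n_off: int
    n_discarded: int               # spikes in neither chunk class


def segment_laser_chunks(drc: DRCStimulus, spikes: np.ndarray) -> ChunkSegmentation:
    """Split the session into per-cycle ON / pre-onset OFF chunks.

    Every spike lands in exactly one of {ON chunk, OFF chunk, discarded};
    the three counts sum to the total spike count.
    """
    onsets = drc.laser_onsets()
    dur = drc.laser_duration
    if dur > drc.laser_period - dur and drc.laser_onset_offset < dur:
        raise ParameterError("OFF chunk before laser onset does not fit in the cycle")
    on_chunks = np.column_stack([onsets, onsets + dur])
    off_chunks = np.column_stack([onsets - dur, onsets])
    spikes = np.asarray(spikes, dtype=float)
    on_spk, off_spk = [], []
    n_on = n_off = 0
    for (a, b), (c, d) in zip(on_chunks, off_chunks):
        s_on = spikes[(spikes >= a) & (spikes < b)]
        s_off = spikes[(spikes >= c) & (spikes < d)]
        on_spk.append(s_on)
        off_spk.append(s_off)
        n_on += s_on.size
        n_off += s_off.size
    return ChunkSegmentation(
        on_chunks=on_chunks, off_chunks=off_chunks,
        on_spikes=on_spk, off_spikes=off_spk,
        n_on=n_on, n_off=n_off,
        n_discarded=spikes.size - n_on - n_off,
    )


def upsample_drc(drc: DRCStimulus, target_bin: float = 0.005) -> np.ndarray:
    """Nearest-neighbour upsample of the level-deviation matrix.

    Each chord row is replicated ``chord_duration / target_bin`` times;
    levels are expressed as deviation from the nominal mean level (dB).
    """
    rep = drc.chord_duration / target_bin
    if abs(rep - round(rep)) > 1e-9 or round(rep) < 1:
        raise ParameterError(
            f"chord_duration {drc.chord_duration} not divisible by target_bin {target_bin}"
        )
    return np.repeat(drc.level_deviations(), int(round(rep)), axis=0)


class STRFDesign:
    """Precomputed stimulus machinery shared by estimation and permutation.

    Caches the upsampled deviation matrix, the per-bin chunk labelling, the
    valid anchor bins per condition (anchors whose full lag history stays
    inside one chunk), and the per-file bias windows. Building one design
    and reusing it across units/scrambles is the supported fast path.
    """

    def __init__(self, drc: DRCStimulus, max_lag: float = 0.100, lag_bin: float = 0.005):
        n_lags = max_lag / lag_bin
        if abs(n_lags - round(n_lags)) > 1e-9 or round(n_lags) < 1:
            raise ParameterError("max_lag must be a positive multiple of lag_bin")
        self.n_lags = int(round(n_lags))
        self.max_lag = max_lag
        self.lag_bin = lag_bin
        self.drc = drc
        if max_lag > drc.laser_duration:
            raise ParameterError(
                f"max_lag {max_lag} exceeds the {drc.laser_duration} s chunk length"
            )
        self.dev = upsample_drc(drc, lag_bin)  # float64: the estimator is
        # required to match a per-spike reference loop to 1e-10
        self.n_bins = self.dev.shape[0]
        self.freqs = drc.freqs
        self.lags = (np.arange(self.n_lags) + 1) * lag_bin

        # per-bin labels: 0 outside chunks, 1 OFF chunk, 2 ON chunk
        self.label = np.zeros(self.n_bins, dtype=np.int8)
        anchor_ok = np.zeros(self.n_bins, dtype=bool)
        onsets = drc.laser_onsets()
        for q in (drc.laser_duration, drc.laser_onset_offset, drc.laser_period):
            if abs(q / lag_bin - round(q / lag_bin)) > 1e-9:
                raise ParameterError(
                    "laser timing must align to the lag bin for ON/OFF chunking"
                )
        dur_bins = int(round(drc.laser_duration / lag_bin))
        for on in onsets:
            ob = int(round(on / lag_bin))
            a0, a1 = ob - dur_bins, ob          # OFF chunk
            b0, b1 = ob, ob + dur_bins          # ON chunk
            if a0 < 0 or b1 > self.n_bins:
                continue
            self.label[a0:a1] = 1
            self.label[b0:b1] = 2
            anchor_ok[a0 + self.n_lags: a1] = True
            anchor_ok[b0 + self.n_lags: b1] = True
        self.anchor_ok = anchor_ok
        self.file_of_bin = np.minimum(
            (np.arange(self.n_bins) * lag_bin / drc.file_duration).astype(int),
            drc.n_files - 1,
        )
        self._bias: dict[tuple[str, int], np.ndarray] = {}
        self._anchors: dict[str, dict[int, np.ndarray]] = {}
        for cond, code in (("laser_off", 1), ("laser_on", 2)):
            anchors = np.nonzero(anchor_ok & (self.label == code))[0]
            per_file: dict[int, np.ndarray] = {}
            for f in range(drc.n_files):
                a = anchors[self.file_of_bin[anchors] == f]
                per_file[f] = a
                if a.size:
                    bias = np.empty((self.n_lags, self.freqs.n_freqs), dtype=np.float64)
                    for l in range(self.n_lags):
                        bias[l] = self.dev[a - 1 - l].mean(axis=0)
                else:
                    bias = np.zeros((self.n_lags, self.freqs.n_freqs))
                self._bias[(cond, f)] = bias
            self._anchors[cond] = per_file

    def _code(self, condition: str) -> int:
        if condition not in ("laser_on", "laser_off"):
            raise ParameterError(f"unknown condition {condition!r}")
        return 2 if condition == "laser_on" else 1

    def valid_spike_bins(self, spikes: np.ndarray, condition: str) -> np.ndarray:
        """Bin indices of spikes usable for this condition's STRF."""
        tb = (np.asarray(spikes, dtype=float) / self.lag_bin).astype(int)
        tb = tb[(tb >= 0) & (tb < self.n_bins)]
        code = self._code(condition)
        return tb[self.anchor_ok[tb] & (self.label[tb] == code)]


def estimate_strf(
    spikes: np.ndarray,
    design: STRFDesign | DRCStimulus,
    condition: str = "laser_off",
    max_lag: float = 0.100,
    lag_bin: float = 0.005,
    min_spikes: int = 100,
    weighted: bool = True,
) -> STRFMatrix:
    """Spike-triggered average STRF for one laser condition.

    For every valid spike (full lag history inside one chunk of the right
    condition) the mean pre-spike deviation window is accumulated; the mean
    window over all valid anchor bins is subtracted (bias correction), and
    files are combined with per-file spike-count weighting (``weighted=True``)
    or a plain mean over files containing spikes.
    """
    if isinstance(design, DRCStimulus):
        design = STRFDesign(design, max_lag=max_lag, lag_bin=lag_bin)
    L = design.n_lags
    tb = design.valid_spike_bins(spikes, condition)
    n = tb.size
    if n == 0:
        raise AnalysisError(f"no valid spikes for condition {condition}")
    low = n < min_spikes
    if low:
        warnings.warn(f"only {n} valid spikes (< {min_spikes}); STRF will be noisy")

    lag_off = np.arange(1, L + 1)
    files = design.file_of_bin[tb]
    shape = (L, design.freqs.n_freqs)
    if weighted:
        # pooled spike mean minus spike-count-weighted per-file bias
        win_sum = design.dev[(tb[:, None] - lag_off[None, :]).ravel()]
        win_sum = win_sum.reshape(n, L, -1).sum(axis=0, dtype=np.float64)
        bias = np.zeros(shape)
        for f, cnt in zip(*np.unique(files, return_counts=True)):
            bias += cnt * design._bias[(condition, int(f))]
        values = win_sum / n - bias / n
    else:
        per_file = []
        for f in np.unique(files):
            tbf = tb[files == f]
            w = design.dev[(tbf[:, None] - lag_off[None, :]).ravel()]
            w = w.reshape(tbf.size, L, -1).mean(axis=0, dtype=np.float64)
            per_file.append(w - design._bias[(condition, int(f))])
        values = np.mean(per_file, axis=0)
    return STRFMatrix(
        values=values, lag_bin=design.lag_bin, lags=design.lags,
        freqs=design.freqs, condition=condition, n_spikes=int(n),
        low_spike_count=low,
    )


def scramble_spikes(
    spikes: np.ndarray, drc: DRCStimulus, rng: np.random.Generator
) -> np.ndarray:
    """Per-file circular shift of the spike train (preserves count and ISIs).

    Each file's spikes are rotated by one uniform random offset within the
    file, breaking the spike–stimulus relationship while keeping the
    within-file spike-train statistics.
    """
    spikes = np.asarray(spikes, dtype=float)
    out = np.empty_like(spikes)
    fd = drc.file_duration
    fidx = np.minimum((spikes / fd).astype(int), drc.n_files - 1)
    for f in range(drc.n_files):
        sel = fidx == f
        if not np.any(sel):
            continue
        shift = rng.uniform(0.0, fd)
        out[sel] = f * fd + np.mod(spikes[sel] - f * fd + shift, fd)
    return np.sort(out)


def _signed_cluster_sizes(z: np.ndarray, z_thresh: float) -> list[int]:
    sizes = []
    for sup in (z >= z_thresh, z <= -z_thresh):
        lab, nlab = ndimage.label(sup, structure=_EIGHT)
        if nlab:
            sizes.extend(np.bincount(lab.ravel())[1:].tolist())
    return sizes


def _cluster_mask(z: np.ndarray, z_thresh: float, min_size: float) -> np.ndarray:
    """Pixels in same-signed suprathreshold clusters larger than ``min_size``."""
    out = np.zeros(z.shape, dtype=bool)
    for sup in (z >= z_thresh, z <= -z_thresh):
        lab, nlab = ndimage.label(sup, structure=_EIGHT)
        if not nlab:
            continue
        sizes = np.bincount(lab.ravel())
        keep = np.nonzero(sizes > min_size)[0]
        keep = keep[keep > 0]
        if keep.size:
            out |= np.isin(lab, keep)
    return out


def strf_significance(
    spikes: np.ndarray,
    design: STRFDesign,
    condition: str = "laser_off",
    n_reps: int = 100,
    persist_threshold: int | None = None,
    alpha: float = 0.05,
    z_thresh: float = 3.0,
    n_null: int = 20,
    min_spikes: int = 100,
    seed: int = 0,
) -> tuple[STRFMatrix, SignificanceMask]:
    """Scrambled-spike permutation significance with cluster correction.

    Per repetition: an ensemble of ``n_null`` circularly-shifted spike
    trains gives a null STRF mean/SD per pixel; the real STRF is z-scored
    against it, thresholded at ``|z| >= z_thresh``, and clusters smaller
    than the ``(1 - alpha)`` percentile of the null maximum-cluster-size
    distribution are rejected. The final mask keeps pixels significant in
    more than ``persist_threshold`` of ``n_reps`` repetitions (default
    ``round(0.9 * n_reps)``, mirroring >90 of 100).
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 20:
        raise AnalysisError(f"too few spikes ({spikes.size}) to scramble meaningfully")
    if n_reps < 1 or n_null < 2:
        raise ParameterError("need n_reps >= 1 and n_null >= 2")
    if persist_threshold is None:
        persist_threshold = int(round(0.9 * n_reps))
    real = estimate_strf(spikes, design, condition, min_spikes=min_spikes)
    rng = np.random.default_rng(seed)
    counts = np.zeros(real.values.shape, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            nulls = []
            for _ in range(n_null):
                scr = scramble_spikes(spikes, design.drc, rng)
                try:
                    nulls.append(estimate_strf(scr, design, condition,
                                               min_spikes=min_spikes).values)
                except AnalysisError:
                    continue
            if len(nulls) < 2:
                raise AnalysisError("scrambled trains produced no valid spikes")
            nulls = np.stack(nulls)
            mu = nulls.mean(axis=0)
            sd = nulls.std(axis=0, ddof=1)
            sd = np.maximum(sd, np.finfo(float).tiny)
            z = (real.values - mu) / sd
            null_max = [
                max(_signed_cluster_sizes((nv - mu) / sd, z_thresh), default=0)
                for nv in nulls
            ]
            min_size = float(np.percentile(null_max, 100 * (1 - alpha)))
            counts += _cluster_mask(z, z_thresh, min_size)
    mask = counts > persist_threshold
    return real, SignificanceMask(
        persistence_counts=counts, mask=mask,
        n_reps=n_reps, persist_threshold=persist_threshold,
    )


def extract_lobes(strf: STRFMatrix, mask: SignificanceMask | np.ndarray) -> list[Lobe]:
    """Connected components (8-connectivity) of significant pixels, by sign.

    Morphometrics per lobe: peak time/frequency from the extreme-valued
    pixel (ties → earliest lag, then lowest frequency), temporal width as
    the lag extent, frequency width as the octave extent, size in pixels.
    """
    m = mask.mask if isinstance(mask, SignificanceMask) else np.asarray(mask, dtype=bool)
    if m.shape != strf.values.shape:
        raise ParameterError("mask shape does not match STRF")
    step_oct = strf.freqs.step_octaves
    lobes: list[Lobe] = []
    for sign, sel in (("positive", strf.values > 0), ("negative", strf.values < 0)):
        lab, nlab = ndimage.label(m & sel, structure=_EIGHT)
        for li in range(1, nlab + 1):
            idx = np.argwhere(lab == li)
            vals = np.abs(strf.values[idx[:, 0], idx[:, 1]])
            # row-major argwhere order => first max is earliest lag / lowest freq
            peak = idx[int(np.argmax(vals))]
            lmin, lmax = idx[:, 0].min(), idx[:, 0].max()
            fmin, fmax = idx[:, 1].min(), idx[:, 1].max()
            lobes.append(Lobe(
                sign=sign,
                pixels=frozenset(map(tuple, idx.tolist())),
                peak_time=float(strf.lags[peak[0]]),
                temporal_width=float((lmax - lmin + 1) * strf.lag_bin),
                peak_frequency=float(strf.freqs.values[peak[1]]),
                frequency_width=float((fmax - fmin + 1) * step_oct),
                size=int(len(idx)),
            ))
    return lobes


def match_lobes(
    lobes_off: list[Lobe], lobes_on: list[Lobe], min_overlap: float = 0.5
) -> LobeMatchResult:
    """Greedy one-to-one matching of same-signed lobes by pixel overlap.

    A pair qualifies iff the shared pixel count is at least ``min_overlap``
    of the smaller lobe's size (boundary inclusive). Pairs are taken in
    descending overlap; persistence per sign is matched-OFF / total-OFF.
    """
    candidates = []
    for i, lo in enumerate(lobes_off):
        for j, ln in enumerate(lobes_on):
            if lo.sign != ln.sign:
                continue
            ov = len(lo.pixels & ln.pixels)
            if ov >= min_overlap * min(lo.size, ln.size) - 1e-12:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_off: set[int] = set()
    used_on: set[int] = set()
    pairs = []
    for ov, i, j in candidates:
        if i in used_off or j in used_on:
            continue
        used_off.add(i)
        used_on.add(j)
        pairs.append((lobes_off[i], lobes_on[j]))
    persistence = {}
    for sign in ("positive", "negative"):
        total = sum(1 for l in lobes_off if l.sign == sign)
        matched = sum(1 for lo, _ in pairs if lo.sign == sign)
        persistence[sign] = matched / total if total else float("nan")
    return LobeMatchResult(
        pairs=pairs,
        persistence=persistence,
        unmatched_off=[l for i, l in enumerate(lobes_off) if i not in used_off],
        unmatched_on=[l for j, l in enumerate(lobes_on) if j not in used_on],
    )


def compare_lobe_parameters(match: LobeMatchResult) -> pd.DataFrame:
    """Paired ON vs OFF morphometrics of matched (stable) lobes."""
    rows = []
    for lo, ln in match.pairs:
        rows.append(dict(
            sign=lo.sign,
            peak_time_off=lo.peak_time, peak_time_on=ln.peak_time,
            temporal_width_off=lo.temporal_width, temporal_width_on=ln.temporal_width,
            peak_frequency_off=lo.peak_frequency, peak_frequency_on=ln.peak_frequency,
            frequency_width_off=lo.frequency_width, frequency_width_on=ln.frequency_width,
            size_off=lo.size, size_on=ln.size,
        ))
    cols = ["sign",
            "peak_time_off", "peak_time_on",
            "temporal_width_off", "temporal_width_on",
            "peak_frequency_off", "peak_frequency_on",
            "frequency_width_off", "frequency_width_on",
            "size_off", "size_on"]
    return pd.DataFrame(rows, columns=cols)


def drc_rate_split(spikes: np.ndarray, drc: DRCStimulus, alpha: float = 0.05) -> dict:
    """Classify a unit's mean DRC-evoked rate change under laser.

    Per-cycle ON-chunk vs OFF-chunk rates are compared with a paired
    sign-rank test; the unit is 'increased'/'decreased' by the sign of the
    mean difference if p < alpha, else 'ns'.
    """
    from .stats import paired_signrank

    seg = segment_laser_chunks(drc, spikes)
    dur = drc.laser_duration
    r_on = np.array([s.size for s in seg.on_spikes]) / dur
    r_off = np.array([s.size for s in seg.off_spikes]) / dur
    res = paired_signrank(r_on, r_off)
    d = float(r_on.mean() - r_off.mean())
    label = "ns"
    if res.pvalue < alpha:
        label = "increased" if d > 0 else "decreased"
    return dict(rate_on=float(r_on.mean()), rate_off=float(r_off.mean()),
                delta=d, pvalue=res.pvalue, classification=label)
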