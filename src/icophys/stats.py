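"""Population statistics: noise correlations, paired tests, summary tables.

The paired Wilcoxon sign-rank test is implemented in-package with the exact
conventions the analysis relies on — zero differences dropped, midranks for
tied magnitudes, the exact permutation distribution (via a polynomial
convolution over rank sums) for n <= 25, and a normal approximation with
continuity and tie corrections above. ``scipy.stats.wilcoxon`` is used as an
independent cross-check in the test suite, never as the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import AnalysisError, ParameterError
from .metrics import EVOKED_WINDOW, SPONT_WINDOW_FEEDBACK, trial_table, window_rates
from .simulate import SpikeRecording
from .stimuli import StimulusSchedule

__all__ = [
    "TestResult",
    "noise_correlations",
    "paired_signrank",
    "normalized_ks",
    "population_summary",
    "significance_stars",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n: int
    direction: str = ""            # {"increase", "decrease", ""}
    mean_on: float = float("nan")
    mean_off: float = float("nan")
    median_on: float = float("nan")
    median_off: float = float("nan")
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ParameterError(f"p value {self.pvalue} outside [0, 1]")


def significance_stars(p: float) -> str:
    """Reporting convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# noise correlations
# ---------------------------------------------------------------------------

def noise_correlations(
    recording: SpikeRecording,
    schedule: StimulusSchedule,
    window_kind: str = "evoked",
    laser: bool | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-trial spike counts.

    Spikes are counted in a 20 ms pre-onset window (``window_kind='spont'``)
    or a 75 ms post-onset window (``'evoked'``), within a laser condition
    (both conditions when ``laser=None``). Pairs where either unit has
    zero count variance are flagged undefined (r = NaN).
    """
    if window_kind == "evoked":
        t0, t1 = 0.0, EVOKED_WINDOW
    elif window_kind == "spont":
        t0, t1 = -SPONT_WINDOW_FEEDBACK, 0.0
    else:
        raise ParameterError(f"unknown window_kind {window_kind!r}")
    uids = recording.unit_ids
    if len(uids) < 2:
        raise AnalysisError("need >= 2 simultaneously recorded units")
    tt = trial_table(schedule)
    conditions = [laser] if laser is not None else [False, True]
    rows = []
    for cond in conditions:
        onsets = tt[tt.laser == cond].onset.to_numpy()
        if onsets.size < 10:
            raise AnalysisError(f"need >= 10 trials, got {onsets.size} (laser={cond})")
        counts = {
            uid: window_rates(recording.units[uid], onsets, t0, t1) * (t1 - t0)
            for uid in uids
        }
        for a, b in combinations(uids, 2):
            xa, xb = counts[a], counts[b]
            undefined = xa.std() == 0 or xb.std() == 0
            r = float("nan") if undefined else float(np.corrcoef(xa, xb)[0, 1])
            rows.append(dict(
                unit_a=a, unit_b=b, condition="laser_on" if cond else "laser_off",
                r=r, n_trials=int(onsets.size), window_kind=window_kind,
                undefined=undefined,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired Wilcoxon sign-rank
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 25


def _signrank_exact_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ by polynomial convolution over sign flips.

    ``ranks2`` are the doubled midranks (integers). Returns the count of
    sign assignments achieving each value of 2*W+ (index = value).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def paired_signrank(x_on: np.ndarray, x_off: np.ndarray, name: str = "signrank") -> TestResult:
    """Two-sided paired Wilcoxon sign-rank test.

    Zero differences are dropped; tied magnitudes receive midranks. For
    n <= 25 effective pairs the exact permutation distribution of W+ is
    used; above that, a normal approximation with continuity correction and
    the standard tie correction. All pairs tied → degenerate, p = 1.
    """
    x_on = np.asarray(x_on, dtype=float)
    x_off = np.asarray(x_off, dtype=float)
    if x_on.shape != x_off.shape or x_on.ndim != 1:
        raise ParameterError("x_on and x_off must be equal-length vectors")
    d = x_on - x_off
    d = d[d != 0]
    m = d.size
    base = dict(
        n=int(m),
        mean_on=float(np.mean(x_on)), mean_off=float(np.mean(x_off)),
        median_on=float(np.median(x_on)), median_off=float(np.median(x_off)),
    )
    if m == 0:
        return TestResult(name=name, statistic=0.0, pvalue=1.0,
                          degenerate=True, **base)
    if m < 5:
        raise ParameterError(f"need >= 5 non-tied pairs, got {m}")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    direction = "increase" if np.median(d) > 0 else "decrease"
    if np.median(d) == 0:
        direction = "increase" if d.mean() > 0 else "decrease"

    if m <= _EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
        counts = _signrank_exact_cdf(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = m * (m + 1) / 4.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_corr = np.sum(t_counts**3 - t_counts) / 48.0
        var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_corr
        diff = w_plus - mu
        # continuity correction toward the mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))
    return TestResult(name=name, statistic=w_plus, pvalue=float(p),
                      direction=direction, **base)


# ---------------------------------------------------------------------------
# normalized KS test for laser-alone changes
# ---------------------------------------------------------------------------

def normalized_ks(deltas: np.ndarray, name: str = "normalized_ks") -> TestResult:
    """One-sample KS test of mean/SD-normalized per-unit changes vs N(0, 1).

    Used for laser-alone data: the per-unit ON−OFF changes are z-scored by
    their own mean and SD and compared against the standard normal. The
    mean and median in SD units are reported alongside.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n < 5:
        raise ParameterError(f"need n >= 5, got {n}")
    sd = deltas.std(ddof=1)
    if sd == 0:
        raise ParameterError("zero SD; cannot normalize")
    z = (deltas - deltas.mean()) / sd
    stat, p = sstats.kstest(z, "norm")
    return TestResult(
        name=name, statistic=float(stat), pvalue=float(p), n=int(n),
        extra=dict(
            mean_sd_units=float(deltas.mean() / sd),
            median_sd_units=float(np.median(deltas) / sd),
        ),
    )


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p values (optional; raw p values are reported by default)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_i, idx in enumerate(order[::-1]):
        i = n - rank_i  # 1-based rank from the top
        prev = min(prev, p[idx] * n / i)
        adj[idx] = prev
    return adj


def population_summary(
    table: pd.DataFrame,
    value_pairs: dict[str, tuple[str, str]] | None = None,
    groupby: str | list[str] | None = None,
) -> pd.DataFrame:
    """Per-group paired ON/OFF summary: mean ± SEM, median, n, sign-rank p, stars.

    ``value_pairs`` maps a measure name to its (ON column, OFF column) pair,
    defaulting to the standard metric-table pairs. Groups with a single unit
    get an undefined-SEM flag and no test.
    """
    if table.empty:
        raise ParameterError("empty metrics table")
    if value_pairs is None:
        value_pairs = {
            "spontaneous": ("spont_on", "spont_off"),
            "evoked_magnitude": ("evoked_mag_on", "evoked_mag_off"),
            "sparseness": ("sparseness_on", "sparseness_off"),
        }
        value_pairs = {k: v for k, v in value_pairs.items()
                       if v[0] in table.columns and v[1] in table.columns}
    groups = [("all", table)] if groupby is None else list(table.groupby(groupby))
    rows = []
    for gname, sub in groups:
        for measure, (con, coff) in value_pairs.items():
            vals = sub[[con, coff]].dropna()
            n = len(vals)
            row = dict(group=gname, measure=measure, n=n)
            if n == 0:
                rows.append(row)
                continue
            on, off = vals[con].to_numpy(), vals[coff].to_numpy()
            row.update(
                mean_on=float(on.mean()), mean_off=float(off.mean()),
                median_on=float(np.median(on)), median_off=float(np.median(off)),
            )
            if n < 2:
                row.update(sem_on=np.nan, sem_off=np.nan, pvalue=np.nan,
                           stars="", sem_undefined=True)
            else:
                row.update(
                    sem_on=float(on.std(ddof=1) / np.sqrt(n)),
                    sem_off=float(off.std(ddof=1) / np.sqrt(n)),
                    sem_undefined=False,
                )
                try:
                    res = paired_signrank(on, off, name=measure)
                    row.update(pvalue=res.pvalue, stars=significance_stars(res.pvalue),
                               direction=res.direction, test_degenerate=res.degenerate)
                except ParameterError:
                    row.update(pvalue=np.nan, stars="")
            rows.append(row)
    return pd.DataFrame(rows)
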