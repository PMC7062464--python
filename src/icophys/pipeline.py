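"""Configuration, orchestration and reporting for end-to-end runs.

A :class:`PipelineConfig` captures every parameter of a run (protocol,
stimulus settings, modulation ground truth, analysis windows, STRF
settings) plus one master seed; per-stage seeds are derived from the master
seed by stable hashing of the stage name, so stages are decoupled and every
run is bit-reproducible. ``run(config)`` executes
simulate → metrics → strf → stats for the configured protocol and writes a
report bundle (TSV tables, provenance JSON, a machine-parsable log) to the
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AnalysisError, ParameterError, ScheduleFormatError
from . import metrics as M
from . import simulate as S
from . import stats as ST
from . import stimuli as X
from . import strf as R

__all__ = ["PipelineConfig", "run", "validate_inputs", "derive_seed"]

PROTOCOLS = ("feedback_tone", "interneuron_tone", "click", "drc", "laser_only")

log = logging.getLogger("icophys.pipeline")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed by stable hashing (below 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    protocol: str = "feedback_tone"
    seed: int = 0
    out_dir: str = "icophys_out"

    # population / modulation ground truth
    n_units: int = 30
    region: str = "DCIC"
    spont_delta: float = 0.0
    evoked_gain: float = 1.0
    mod_latency: float = 0.005
    applies_to: str = "all"

    # tone stimulus
    n_freqs: int = 50
    f_lo: float = 3000.0
    f_hi: float = 70000.0
    n_repeats: int = 20
    tone_dur: float = 0.050
    isi: float = 0.450
    level: float = 70.0
    laser_onsets: list = field(default_factory=lambda: [-0.100])
    laser_dur: float = 0.250
    laser_enabled: bool = True

    # metrics
    k: int = 7
    spont_window: float | None = None  # None -> protocol default (20 / 50 ms)
    threshold_sd: float = 1.0

    # DRC / STRF
    drc_total_dur: float = 2400.0
    drc_chord_dur: float = 0.020
    drc_n_freqs: int = 50
    drc_f_lo: float = 5000.0
    drc_f_hi: float = 40000.0
    drc_mean_level: float = 50.0
    drc_level_sd: float = 20.0
    drc_laser_period: float = 1.0
    drc_laser_dur: float = 0.250
    drc_n_files: int = 8
    max_lag: float = 0.100
    lag_bin: float = 0.005
    strf_n_reps: int = 25
    strf_persist_threshold: int | None = None
    strf_alpha: float = 0.05
    strf_z_thresh: float = 3.0
    strf_n_null: int = 20
    evoked_sd: float = 10.0

    # laser-only
    laser_durations: list = field(default_factory=lambda: [0.001, 0.005, 0.025, 0.250])
    n_sweeps: int = 50

    # optional input files (runs on recorded data instead of simulating)
    input_spikes: str | None = None
    input_schedule: str | None = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ParameterError(f"unknown protocol {self.protocol!r}; one of {PROTOCOLS}")

    # -- config file round-trip ------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def effective_spont_window(self) -> float:
        if self.spont_window is not None:
            return self.spont_window
        return (M.SPONT_WINDOW_INTERNEURON if self.protocol == "interneuron_tone"
                else M.SPONT_WINDOW_FEEDBACK)

    def modulation(self) -> S.ModulationModel:
        return S.ModulationModel(
            spont_delta=self.spont_delta, evoked_gain=self.evoked_gain,
            latency=self.mod_latency, applies_to=self.applies_to,
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def _onset_tag(onset: float) -> str:
    ms = int(round(onset * 1000))
    return f"m{-ms}ms" if ms < 0 else f"p{ms}ms"


def _setup_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured protocol end-to-end; returns output paths.

    Deterministic given the master seed: running twice with the same config
    yields byte-identical tables. Every discarded spike/trial/unit is
    counted in the log and the provenance record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    outputs: dict[str, Path] = {}
    discards: dict[str, int] = {}
    stage_seeds: dict[str, int] = {}

    def seed_for(stage: str) -> int:
        s = derive_seed(config.seed, stage)
        stage_seeds[stage] = s
        return s

    try:
        log.info("stage=start protocol=%s seed=%d", config.protocol, config.seed)
        if config.protocol in ("feedback_tone", "interneuron_tone"):
            _run_tone(config, out, outputs, discards, seed_for)
        elif config.protocol == "drc":
            _run_drc(config, out, outputs, discards, seed_for)
        elif config.protocol == "laser_only":
            _run_laser_only(config, out, outputs, seed_for)
        elif config.protocol == "click":
            _run_click(config, out, outputs)
        prov = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "stage_seeds": stage_seeds,
            "discards": discards,
        }
        prov_path = out / "provenance.json"
        prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
        outputs["provenance"] = prov_path
        log.info("stage=done outputs=%d", len(outputs))
    except Exception as exc:
        log.error("stage=failed protocol=%s error=%s", config.protocol, exc)
        raise type(exc)(f"[pipeline:{config.protocol}] {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outputs


def _run_tone(config, out, outputs, discards, seed_for) -> None:
    grid = X.make_frequency_grid(config.n_freqs, config.f_lo, config.f_hi)
    units = S.make_population(
        config.n_units, modulation=config.modulation(),
        seed=seed_for("population"), region=config.region,
        freq_range=(config.f_lo, config.f_hi),
    )
    sw = config.effective_spont_window
    tables: dict[float, pd.DataFrame] = {}
    for onset in config.laser_onsets:
        tag = _onset_tag(onset)
        sched = X.make_tone_schedule(
            grid, config.n_repeats, tone_dur=config.tone_dur, isi=config.isi,
            level=config.level, laser_onset_rel=onset, laser_dur=config.laser_dur,
            seed=seed_for(f"schedule:{tag}"),
        )
        if not config.laser_enabled:
            for e in sched.events:
                e.laser = False
                e.laser_onset_rel = None
                e.laser_duration = None
        rec = S.simulate_tone_session(units, sched, seed=seed_for(f"simulate:{tag}"))
        outputs[f"schedule_{tag}"] = X.write_schedule(sched, out / f"schedule_{tag}.tsv")
        outputs[f"spikes_{tag}"] = S.write_recording(rec, out / f"spikes_{tag}.tsv")
        if config.laser_enabled:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mt = M.compute_unit_metrics(
                    rec, sched, k=config.k, spont_window=sw,
                    threshold_sd=config.threshold_sd,
                )
            tables[onset] = mt
        else:
            log.warning("stage=metrics no laser trials; OFF-only metrics, "
                        "laser comparisons skipped")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mt = _off_only_metrics(rec, sched, config.k, sw)
            tables[onset] = mt
        n_excl = int((~mt.get("responsive", pd.Series(dtype=bool))).sum())
        discards[f"units_nonresponsive_{tag}"] = n_excl
        log.info("stage=metrics onset=%s units=%d nonresponsive=%d",
                 tag, len(mt), n_excl)

    if config.laser_enabled and tables:
        ref_onset = -0.100 if -0.100 in tables else config.laser_onsets[0]
        ref = tables[ref_onset]
        summaries = []
        for onset, mt in tables.items():
            tag = _onset_tag(onset)
            mt = M.stratify_units(ref, mt)
            outputs[f"unit_table_{tag}"] = _write_table(mt, out / f"unit_table_{tag}.tsv")
            resp = mt[mt.responsive & mt.quality_pass]
            if not resp.empty:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    summ = ST.population_summary(resp)
                summ.insert(0, "laser_onset", onset)
                summaries.append(summ)
        if summaries:
            outputs["summary"] = _write_table(
                pd.concat(summaries, ignore_index=True), out / "summary.tsv", index=False
            )
    else:
        for onset, mt in tables.items():
            tag = _onset_tag(onset)
            outputs[f"unit_table_{tag}"] = _write_table(mt, out / f"unit_table_{tag}.tsv")


def _off_only_metrics(rec, sched, k, spont_window) -> pd.DataFrame:
    rows = []
    for uid in rec.unit_ids:
        spikes = rec.units[uid]
        if spikes.size == 0:
            rows.append(dict(unit_id=uid, responsive=False, degenerate=True))
            continue
        tc = M.tuning_curve(spikes, sched, laser=False)
        top = tc.freqs[M.top_frequencies(tc, k)]
        sp = M.spontaneous_rate(spikes, sched, laser=False,
                                window_len=spont_window, top_freqs=top)
        mag = M.evoked_magnitude(spikes, sched, laser=False,
                                 spont_window_len=spont_window, top_freqs=top)
        resp = M.select_responsive(
            S.SpikeRecording(units={uid: spikes}, duration=rec.duration), sched, k=k
        ).loc[uid]
        rows.append(dict(
            unit_id=uid, spont_off=sp, evoked_mag_off=mag,
            sparseness_off=M.sparseness(tc), bf_off=M.best_frequency(tc),
            responsive=bool(resp.responsive), degenerate=bool(resp.degenerate),
            quality_pass=bool(resp.quality_pass),
        ))
    return pd.DataFrame(rows).set_index("unit_id")


def _run_drc(config, out, outputs, discards, seed_for) -> None:
    import h5py

    grid = X.make_frequency_grid(config.drc_n_freqs, config.drc_f_lo, config.drc_f_hi)
    drc = X.make_drc(
        grid, chord_dur=config.drc_chord_dur, total_dur=config.drc_total_dur,
        mean_level=config.drc_mean_level, level_sd=config.drc_level_sd,
        laser_period=config.drc_laser_period, laser_dur=config.drc_laser_dur,
        n_files=config.drc_n_files, seed=seed_for("drc"),
    )
    n_lags = int(round(config.max_lag / config.lag_bin))
    units = S.make_population(
        config.n_units, modulation=config.modulation(), seed=seed_for("population"),
        region=config.region, strf_shape="gaussian", n_lags=n_lags,
        n_freqs=config.drc_n_freqs, strf_lag_bin=config.lag_bin,
        level_sd=config.drc_level_sd, evoked_sd=config.evoked_sd,
    )
    rec = S.simulate_drc_session(units, drc, seed=seed_for("simulate"))
    outputs["drc"] = X.write_drc(drc, out / "drc.h5")
    outputs["spikes"] = S.write_recording(rec, out / "spikes.tsv")

    design = R.STRFDesign(drc, max_lag=config.max_lag, lag_bin=config.lag_bin)
    lobe_rows, match_rows, pair_tables = [], [], []
    strf_h5 = out / "strf.h5"
    with h5py.File(strf_h5, "w") as f:
        f.attrs["lag_bin"] = config.lag_bin
        f.attrs["max_lag"] = config.max_lag
        f.create_dataset("frequencies_hz", data=grid.values)
        for uid in rec.unit_ids:
            spikes = rec.units[uid]
            seg = R.segment_laser_chunks(drc, spikes)
            discards[f"spikes_outside_chunks_{uid}"] = int(seg.n_discarded)
            lobes = {}
            for cond in ("laser_off", "laser_on"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est, sig = R.strf_significance(
                        spikes, design, condition=cond,
                        n_reps=config.strf_n_reps,
                        persist_threshold=config.strf_persist_threshold,
                        alpha=config.strf_alpha, z_thresh=config.strf_z_thresh,
                        n_null=config.strf_n_null,
                        seed=seed_for(f"strf:{uid}:{cond}"),
                    )
                g = f.create_group(f"{uid}/{cond}")
                g.create_dataset("values", data=est.values)
                g.create_dataset("persistence_counts", data=sig.persistence_counts)
                g.create_dataset("mask", data=sig.mask)
                g.attrs["n_spikes"] = est.n_spikes
                lobes[cond] = R.extract_lobes(est, sig)
                for lb in lobes[cond]:
                    lobe_rows.append(dict(
                        unit_id=uid, condition=cond, sign=lb.sign, size=lb.size,
                        peak_time=lb.peak_time, temporal_width=lb.temporal_width,
                        peak_frequency=lb.peak_frequency,
                        frequency_width=lb.frequency_width,
                    ))
            mres = R.match_lobes(lobes["laser_off"], lobes["laser_on"])
            match_rows.append(dict(
                unit_id=uid,
                persistence_positive=mres.persistence["positive"],
                persistence_negative=mres.persistence["negative"],
                n_pairs=len(mres.pairs),
            ))
            pairs = R.compare_lobe_parameters(mres)
            if not pairs.empty:
                pairs.insert(0, "unit_id", uid)
                pair_tables.append(pairs)
            log.info("stage=strf unit=%s lobes_off=%d lobes_on=%d",
                     uid, len(lobes["laser_off"]), len(lobes["laser_on"]))
    outputs["strf"] = strf_h5
    outputs["lobes"] = _write_table(pd.DataFrame(lobe_rows), out / "lobes.tsv", index=False)
    outputs["lobe_matches"] = _write_table(
        pd.DataFrame(match_rows), out / "lobe_matches.tsv", index=False)
    if pair_tables:
        outputs["lobe_pairs"] = _write_table(
            pd.concat(pair_tables, ignore_index=True), out / "lobe_pairs.tsv", index=False)


def _run_laser_only(config, out, outputs, seed_for) -> None:
    units = S.make_population(
        config.n_units, modulation=config.modulation(),
        seed=seed_for("population"), region=config.region,
    )
    sess = S.simulate_laser_only(
        units, config.laser_durations, n_sweeps=config.n_sweeps,
        seed=seed_for("simulate"),
    )
    outputs["spikes"] = S.write_recording(sess.recording, out / "spikes.tsv")
    outputs["sweeps"] = _write_table(sess.sweeps, out / "sweeps.tsv", index=False)
    resp = M.laser_only_response(sess)
    outputs["laser_response"] = _write_table(resp, out / "laser_response.tsv", index=False)
    rows = []
    for d, grp in resp.groupby("laser_dur"):
        deltas = grp.delta.to_numpy()
        try:
            res = ST.normalized_ks(deltas)
            rows.append(dict(laser_dur=d, n=res.n, statistic=res.statistic,
                             pvalue=res.pvalue, **res.extra))
        except ParameterError as exc:
            log.warning("stage=stats laser_dur=%s skipped: %s", d, exc)
    if rows:
        outputs["ks_summary"] = _write_table(
            pd.DataFrame(rows), out / "ks_summary.tsv", index=False)


def _run_click(config, out, outputs) -> None:
    if not (config.input_spikes and config.input_schedule):
        raise ParameterError(
            "click protocol runs on recorded data: set input_spikes and input_schedule"
        )
    rec = S.read_recording(config.input_spikes)
    sched = X.read_schedule(config.input_schedule)
    resp = M.click_response(rec, sched)
    outputs["click_response"] = _write_table(resp, out / "click_response.tsv", index=False)


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(
    spikes: str | Path | None = None,
    schedule: str | Path | None = None,
    drc: str | Path | None = None,
) -> pd.DataFrame:
    """Schema checks on interchange files; one diagnostic row per check."""
    rows: list[dict] = []

    def add(path, check, ok, detail=""):
        rows.append(dict(path=str(path), check=check, ok=bool(ok), detail=detail))

    sched_obj = rec_obj = None
    if schedule is not None:
        try:
            sched_obj = X.read_schedule(schedule)
            add(schedule, "readable", True,
                f"{len(sched_obj.events)} events, {sched_obj.total_duration} s")
        except (OSError, ScheduleFormatError) as exc:
            add(schedule, "readable", False, str(exc))
    if spikes is not None:
        try:
            rec_obj = S.read_recording(spikes)
            n = sum(t.size for t in rec_obj.units.values())
            add(spikes, "readable", True, f"{len(rec_obj.units)} units, {n} spikes")
            for uid, t in rec_obj.units.items():
                if t.size and t[0] < 0:
                    add(spikes, "spike_times_nonnegative", False, f"unit {uid}: t={t[0]}")
        except ParameterError as exc:
            add(spikes, "spike_times_valid", False, str(exc))
        except (OSError, ScheduleFormatError) as exc:
            add(spikes, "readable", False, str(exc))
    if drc is not None:
        try:
            drc_obj = X.read_drc(drc)
            add(drc, "readable", True,
                f"{drc_obj.n_chords} chords x {drc_obj.freqs.n_freqs} freqs")
            if sched_obj is not None and abs(
                drc_obj.total_duration - sched_obj.total_duration
            ) > 1e-6:
                add(drc, "duration_matches_schedule", False,
                    f"{drc_obj.total_duration} vs {sched_obj.total_duration}")
        except (OSError, KeyError) as exc:
            add(drc, "readable", False, str(exc))
    if rec_obj is not None and sched_obj is not None:
        if rec_obj.duration + 1e-6 < sched_obj.total_duration:
            add(spikes, "duration_covers_schedule", False,
                f"{rec_obj.duration} < {sched_obj.total_duration}")
        else:
            add(spikes, "duration_covers_schedule", True)
    return pd.DataFrame(rows, columns=["path", "check", "ok", "detail"])
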