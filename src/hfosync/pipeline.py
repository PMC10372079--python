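"""End-to-end orchestration of the analysis stages on a set of sessions.

``run_pipeline`` executes, per session: rhythmicity spectra -> HFO detection
-> phase synchrony -> spike entrainment -> rate modulation -> head-twitch
detection -> Granger causality, writing per-stage CSV tables, a prevalence
matrix over sessions, and a JSON run log with parameter provenance and
exclusion counts.  A stage failure is recorded and the remaining independent
stages still run.
"""
from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import granger as gc
from . import hfo as hfo_mod
from . import htr as htr_mod
from . import phase as phase_mod
from . import spikes as spike_mod
from .hfo import DetectionCriteria
from .irasa import average_spectrum, irasa
from .session import BASELINE_EPOCH, DRUG_EPOCH, Epoch, Session, make_bipolar, read_session, slice_epoch

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; stage parameters default to the study values."""

    sessions: list  # paths to containers or in-memory Session objects
    out_dir: str = "results/pipeline"
    baseline: Epoch = field(default_factory=lambda: BASELINE_EPOCH)
    drug: Epoch = field(default_factory=lambda: DRUG_EPOCH)
    window_s: float = 8.0
    overlap: float = 0.5
    fit_band: tuple = hfo_mod.DEFAULT_FIT_BAND
    criteria: DetectionCriteria = field(default_factory=DetectionCriteria)
    halfwidth: float = 5.0
    pair_r_min: float = 0.5
    reference_structure: str = "OB"
    bin_s: float = 10.0
    min_spikes: int = 50
    gc_window_s: float = 0.5
    gc_order: int = 5
    htr_params: htr_mod.HtrParams = field(default_factory=htr_mod.HtrParams)
    stages: tuple = ("spectra", "hfo", "phase", "entrain", "rates", "htr", "granger")
    seed: int = 0


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (Epoch,)):
        return dataclasses.asdict(obj)
    return obj


def _structure_frames(session: Session, config: RunConfig):
    """Per-structure, per-window spectra averaged over same-structure bipolar
    pairs, for structures with at least two channels."""
    frames = {}
    for struct in session.structures:
        pairs = make_bipolar(session, struct)
        if not pairs:
            continue
        per_pair = [irasa(bp.series, session.fs_lfp, config.window_s, config.overlap) for bp in pairs]
        n_win = min(len(fr) for fr in per_pair)
        struct_frames = []
        for w in range(n_win):
            struct_frames.append(average_spectrum([fr[w] for fr in per_pair]))
        frames[struct] = struct_frames
    return frames


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages on every session; returns the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {"params": _asdict(config) | {"sessions": [str(s) for s in config.sessions]},
           "stages": {}, "errors": [], "exclusions": {}}
    report = {"log": log}

    sessions = []
    for i, s in enumerate(config.sessions):
        sessions.append((f"session{i:02d}", s if isinstance(s, Session) else read_session(s)))

    rate_rows = []  # (session, structure, condition/epoch, rate)
    hfo_rows = []
    spectra_rows = []
    phase_rows = []
    lag_rows = []
    entrain_rows = []
    mod_rows = []
    htr_rows = []
    granger_rows = []
    median_freqs = {}

    for name, sess in sessions:
        inj = sess.injection_time if sess.injection_time is not None else 0.0
        t0 = time.time()
        struct_frames = {}
        if "spectra" in config.stages or "hfo" in config.stages:
            try:
                struct_frames = _structure_frames(sess, config)
                for struct, frames in struct_frames.items():
                    for ep in (config.baseline, config.drug):
                        try:
                            avg = average_spectrum(frames, ep, inj)
                        except ValueError:
                            continue
                        for f, s_db in zip(avg.freqs, avg.S_dB):
                            spectra_rows.append((name, struct, ep.name, f, s_db))
                log["stages"]["spectra"] = {"elapsed_s": round(time.time() - t0, 2)}
            except Exception as e:  # noqa: BLE001 - stage isolation
                log["errors"].append({"session": name, "stage": "spectra", "error": repr(e),
                                      "trace": traceback.format_exc(limit=3)})

        hfo_freq = None
        if "hfo" in config.stages and struct_frames:
            try:
                drug_fits = []
                for struct, frames in struct_frames.items():
                    for ep in (config.baseline, config.drug):
                        sel = [fr for fr in frames
                               if inj + ep.start <= fr.t_center < inj + ep.end]
                        if not sel:
                            continue
                        rate, fits = hfo_mod.detection_rate(sel, config.fit_band, config.criteria)
                        rate_rows.append((name, struct, ep.name, sess.drug_class, rate, len(sel)))
                        for fit in fits:
                            hfo_rows.append((name, struct, ep.name, *fit.params, fit.r2, fit.detected))
                        if ep.name == "drug":
                            drug_fits.extend(fits)
                try:
                    hfo_freq = hfo_mod.median_hfo_frequency(drug_fits)
                except ValueError:
                    hfo_freq = None
                median_freqs[name] = hfo_freq
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "hfo", "error": repr(e)})

        analytic_by_channel = {}
        if hfo_freq is not None and ("phase" in config.stages or "entrain" in config.stages):
            try:
                for ch in sess.channels:
                    x = slice_epoch(sess.lfp_channel(ch.channel_id), inj, config.drug, fs=sess.fs_lfp)
                    filt = phase_mod.narrowband(x, sess.fs_lfp, hfo_freq, config.halfwidth)
                    analytic_by_channel[ch.channel_id] = phase_mod.analytic(filt, hfo_freq, config.halfwidth)
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "phase-filter", "error": repr(e)})

        if "phase" in config.stages and analytic_by_channel:
            try:
                n_excluded = 0
                pair_stats = []
                chans = sess.channels
                for i in range(len(chans)):
                    for j in range(i + 1, len(chans)):
                        ai = analytic_by_channel[chans[i].channel_id]
                        aj = analytic_by_channel[chans[j].channel_id]
                        gate = (ai.amplitude > np.median(ai.amplitude)) & (aj.amplitude > np.median(aj.amplitude))
                        ps = phase_mod.phase_pair(
                            ai.phase, aj.phase, gate,
                            pair=(chans[i].channel_id, chans[j].channel_id),
                            structures=(chans[i].structure, chans[j].structure),
                        )
                        pair_stats.append(ps)
                        phase_rows.append((name, *ps.pair, *ps.structures, ps.dphi, ps.r, ps.kappa,
                                           ps.inverted, ps.n_samples))
                lag_map, _ = phase_mod.structure_phase_map(pair_stats, config.reference_structure,
                                                           config.pair_r_min)
                n_excluded = sum(1 for ps in pair_stats if ps.r < config.pair_r_min)
                for struct, row in lag_map.items():
                    lag_rows.append((name, struct, row["median_lag"], row["n_pairs"], row["p_wilcoxon"]))
                log["exclusions"].setdefault("phase_pairs_low_r", 0)
                log["exclusions"]["phase_pairs_low_r"] += n_excluded
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "phase", "error": repr(e)})

        if "entrain" in config.stages and analytic_by_channel:
            try:
                phase_by_channel = {cid: a.phase for cid, a in analytic_by_channel.items()}
                for u in sess.units:
                    same = [c.channel_id for c in sess.channels
                            if c.structure == u.structure and c.channel_id != u.electrode]
                    spk = slice_epoch(np.asarray(u.spike_times), inj, config.drug) - (inj + config.drug.start)
                    res = spike_mod.spike_entrainment(spk, phase_by_channel, sess.fs_lfp,
                                                      u.electrode, same, unit_id=u.unit_id,
                                                      min_spikes=config.min_spikes)
                    entrain_rows.append((name, u.unit_id, u.structure, res.mu, res.kappa,
                                         res.rayleigh_p, res.entrained, res.n_spikes, res.reason))
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "entrain", "error": repr(e)})

        if "rates" in config.stages:
            try:
                n_zero_sd = 0
                for u in sess.units:
                    rm = spike_mod.unit_modulation(u.spike_times, inj, config.baseline, config.drug,
                                                   config.bin_s)
                    n_zero_sd += int(rm.excluded)
                    mod_rows.append((name, u.unit_id, u.structure, u.cell_type, rm.mean_z_drug,
                                     rm.p_value, rm.mod_class, rm.excluded))
                log["exclusions"].setdefault("units_zero_baseline_sd", 0)
                log["exclusions"]["units_zero_baseline_sd"] += n_zero_sd
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "rates", "error": repr(e)})

        if "htr" in config.stages and sess.accel is not None:
            try:
                from .session import ACCEL_ML_AXIS

                times, index = htr_mod.htr_index(sess.accel[ACCEL_ML_AXIS], sess.fs_accel,
                                                 config.htr_params)
                events = htr_mod.detect_htr(times, index, config.htr_params)
                for ev in events:
                    htr_rows.append((name, ev.time, ev.index_value))
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "htr", "error": repr(e)})

        if "granger" in config.stages and hfo_freq is not None:
            try:
                firsts = {}
                for struct in sess.structures:
                    pairs = make_bipolar(sess, struct)
                    if pairs:
                        firsts[struct] = slice_epoch(pairs[0].series, inj, config.drug, fs=sess.fs_lfp)
                structs = list(firsts)
                pair_spectra = []
                for i in range(len(structs)):
                    for j in range(i + 1, len(structs)):
                        fit = gc.fit_var_windows(firsts[structs[i]], firsts[structs[j]],
                                                 sess.fs_lfp, config.gc_window_s, config.gc_order)
                        pair_spectra.append(((structs[i], structs[j]), gc.gc_spectrum(fit)))
                summary, _ = gc.band_summary(pair_spectra, hfo_freq)
                for direction, row in summary.items():
                    granger_rows.append((name, direction, row["median_peak"], row["n_qualifying"],
                                         row["mean_gc_hfo_band"], row["mean_gc_gamma_band"]))
            except Exception as e:  # noqa: BLE001
                log["errors"].append({"session": name, "stage": "granger", "error": repr(e)})

    tables = {
        "spectra": pd.DataFrame(spectra_rows, columns=["session", "structure", "epoch", "freq_hz", "s_db"]),
        "hfo_fits": pd.DataFrame(hfo_rows, columns=["session", "structure", "epoch", "a1", "a2", "a3",
                                                    "a4", "a5", "r2", "detected"]),
        "detection_rates": pd.DataFrame(rate_rows, columns=["session", "structure", "epoch",
                                                            "drug_class", "rate", "n_windows"]),
        "phase_pairs": pd.DataFrame(phase_rows, columns=["session", "ch_i", "ch_j", "struct_i",
                                                         "struct_j", "dphi", "r", "kappa", "inverted",
                                                         "n_samples"]),
        "structure_lags": pd.DataFrame(lag_rows, columns=["session", "structure", "median_lag",
                                                          "n_pairs", "p_wilcoxon"]),
        "entrainment": pd.DataFrame(entrain_rows, columns=["session", "unit", "structure", "mu",
                                                           "kappa", "rayleigh_p", "entrained",
                                                           "n_spikes", "reason"]),
        "rate_modulation": pd.DataFrame(mod_rows, columns=["session", "unit", "structure", "cell_type",
                                                           "mean_z_drug", "p_value", "mod_class",
                                                           "excluded"]),
        "htr_events": pd.DataFrame(htr_rows, columns=["session", "time_s", "index_g"]),
        "granger": pd.DataFrame(granger_rows, columns=["session", "direction", "median_peak",
                                                       "n_qualifying", "mean_gc_hfo_band",
                                                       "mean_gc_gamma_band"]),
    }

    # prevalence matrix: structures x (drug_class, epoch) over sessions
    prev_rows = []
    dr = tables["detection_rates"]
    if len(dr):
        for (struct, cls, ep), grp in dr.groupby(["structure", "drug_class", "epoch"]):
            prev_rows.append((struct, cls, ep, hfo_mod.prevalence_class(grp["rate"].to_numpy()),
                              len(grp)))
    tables["prevalence"] = pd.DataFrame(prev_rows, columns=["structure", "drug_class", "epoch",
                                                            "class", "n_sessions"])

    for key, df in tables.items():
        df.to_csv(out_dir / f"{key}.csv", index=False)
    log["median_hfo_freqs"] = median_freqs
    with open(out_dir / "run_log.json", "w") as f:
        json.dump(log, f, indent=2, default=str)
    report.update(tables)
    report["median_hfo_freqs"] = median_freqs
    return report
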