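"""End-to-end orchestration: recordings -> networks -> similarities -> stats.

The pipeline mirrors the analysis flow of a cross-over hypoxia study:
clean each breath-by-breath recording, estimate the surrogate-thresholded
TE network per participant x condition x phase, reduce to group median
networks and degree rankings, build the nine-column network-similarity
table, and run the cohort statistics (repeated-measures ANOVAs on the
similarity columns, symptom chi-square against control, McNemar for
headache, logistic regressions of total TE and SpO2/FiO2 ratio on
symptoms, and the total-TE correlation matrix).

Failures of single recordings are quarantined and listed in the summary
rather than aborting the run.  Everything is deterministic given the
config seed: each recording draws its surrogate permutations from a
substream keyed on (seed, participant, condition, phase).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as bstats
from .io import (PipelineConfig, read_manifest, read_recording,
                 write_diagram_json, write_network_csv, write_network_graphml,
                 write_network_json)
from .network import (COMPARISON_SCHEMA, TEMatrix, group_median_network,
                      participant_network, rank_nodes, total_te,
                      weighted_degrees, wjsi)
from .preprocessing import clean_recording
from .series import ParticipantRecording
from .synthetic import Cohort
from .te import TEConfig

__all__ = ["PipelineResult", "analyze_cohort", "run_pipeline",
           "similarity_table", "network_for_recording"]

log = logging.getLogger(__name__)


def _recording_seed(seed: int, pid: str, cond: str, phase: str) -> np.random.SeedSequence:
    tag = zlib.crc32(f"{pid}|{cond}|{phase}".encode())
    return np.random.SeedSequence((seed, tag))


def network_for_recording(recording: ParticipantRecording,
                          config: PipelineConfig) -> TEMatrix:
    """Clean one recording and estimate its significant-TE network."""
    cleaned = clean_recording(recording, config.hampel_window,
                              config.hampel_threshold)
    te_cfg = TEConfig(lag=config.lag, partition=config.partition,
                      n_bins=config.n_bins)
    seed = _recording_seed(config.seed, recording.participant_id,
                           recording.condition, recording.phase)
    return participant_network(cleaned, te_cfg, n_shuffles=config.n_shuffles,
                               percentile=config.percentile, seed=seed)


def similarity_table(networks: dict, participants: list[str]) -> pd.DataFrame:
    """Nine WJSI comparison columns per participant (table-style layout)."""
    rows = []
    for pid in participants:
        row: dict = {"participant_id": pid}
        for name, (cond_a, phase_a), (cond_b, phase_b) in COMPARISON_SCHEMA:
            a = networks.get((pid, cond_a, phase_a))
            b = networks.get((pid, cond_b, phase_b))
            row[name] = wjsi(a, b) if a is not None and b is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """In-memory bundle of everything an end-to-end run produces."""

    networks: dict                      # (pid, cond, phase) -> TEMatrix
    group_networks: dict                # (cond, phase) -> TEMatrix
    similarity: pd.DataFrame            # participant x 9 comparison columns
    total_te: pd.DataFrame              # participant x condition-phase columns
    rankings: dict                      # (cond, phase) -> {"ID": [...], "OD": [...]}
    stats: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def analyze_cohort(cohort: Cohort, config: PipelineConfig) -> PipelineResult:
    """Run the full network analysis on an in-memory cohort."""
    recs = {key: rec for key, rec in cohort.recordings.items()}
    return _analyze(recs, cohort.table, config)


def _analyze(recordings: dict, cohort_table: pd.DataFrame | None,
             config: PipelineConfig) -> PipelineResult:
    config.validate()
    networks: dict = {}
    failures: list = []
    for key in sorted(recordings):
        try:
            networks[key] = network_for_recording(recordings[key], config)
        except (ValueError, KeyError) as exc:
            log.warning("recording %s quarantined: %s", key, exc)
            failures.append({"recording": key, "error": str(exc)})

    participants = sorted({k[0] for k in networks})
    conditions = sorted({k[1] for k in networks})
    phases = sorted({k[2] for k in networks})

    group_networks = {}
    rankings = {}
    for cond in conditions:
        for phase in phases:
            members = [m for (pid, c, ph), m in networks.items()
                       if c == cond and ph == phase]
            if not members:
                continue
            g = group_median_network(members)
            group_networks[(cond, phase)] = g
            profile = weighted_degrees(g)
            rankings[(cond, phase)] = {"ID": rank_nodes(profile, "ID"),
                                       "OD": rank_nodes(profile, "OD")}

    sim = similarity_table(networks, participants)
    tt_rows = []
    for pid in participants:
        row: dict = {"participant_id": pid}
        for (p, cond, phase), m in networks.items():
            if p == pid:
                row[f"total_te_{cond}_{phase}"] = total_te(m)
        tt_rows.append(row)
    tt = pd.DataFrame(tt_rows)

    stats_report = _cohort_statistics(sim, tt, cohort_table, config)
    return PipelineResult(networks=networks, group_networks=group_networks,
                          similarity=sim, total_te=tt, rankings=rankings,
                          stats=stats_report, failures=failures)


def _cohort_statistics(sim: pd.DataFrame, tt: pd.DataFrame,
                       cohort_table: pd.DataFrame | None,
                       config: PipelineConfig) -> dict:
    report: dict = {}

    anova_sets = {
        "rest_exercise_wjsi": ["rest_ex_CTR", "rest_ex_HY1", "rest_ex_HY2"],
        "rest_phase_wjsi": ["CTR_HY1_rest", "CTR_HY2_rest", "HY1_HY2_rest"],
        "exercise_phase_wjsi": ["CTR_HY1_ex", "CTR_HY2_ex", "HY1_HY2_ex"],
    }
    report["rm_anova"] = {}
    for name, cols in anova_sets.items():
        block = sim[cols].dropna() if set(cols) <= set(sim.columns) else pd.DataFrame()
        if len(block) >= 3:
            res = bstats.rm_anova_gg(block, gg_threshold=config.gg_threshold)
            report["rm_anova"][name] = vars(res)

    te_cols = [c for c in tt.columns if c.startswith("total_te_")]
    if len(te_cols) >= 2 and len(tt) >= 3:
        try:
            corr = bstats.correlation_matrix(tt[te_cols])
            report["total_te_correlations"] = {
                k: v.round(6).to_dict() for k, v in corr.items()}
        except ValueError as exc:
            report["total_te_correlations"] = {"error": str(exc)}

    if cohort_table is None or cohort_table.empty:
        return report

    ctl = config.control_condition
    flags = cohort_table.drop_duplicates(["participant_id", "condition"])
    by_cond = {c: g.sort_values("participant_id")
               for c, g in flags.groupby("condition")}
    if ctl in by_cond:
        n = len(by_cond[ctl])
        ctl_yes = int(by_cond[ctl]["symptom"].sum())
        report["symptom_chi_square"] = {}
        for cond, g in by_cond.items():
            if cond == ctl:
                continue
            try:
                res = bstats.chi_square_vs_control(ctl_yes,
                                                   int(g["symptom"].sum()), n)
                report["symptom_chi_square"][cond] = vars(res)
            except ValueError as exc:
                report["symptom_chi_square"][cond] = {"error": str(exc)}
        report["headache_mcnemar"] = {}
        for cond, g in by_cond.items():
            if cond == ctl:
                continue
            paired = list(zip(by_cond[ctl]["headache"], g["headache"]))
            report["headache_mcnemar"][cond] = vars(bstats.mcnemar_test(paired))

    report["symptom_regressions"] = {}
    for cond in by_cond:
        rest_col = f"total_te_{cond}_rest"
        ex_col = f"total_te_{cond}_exercise"
        if rest_col not in tt.columns or ex_col not in tt.columns:
            continue
        merged = by_cond[cond].merge(tt, on="participant_id", how="inner")
        X = merged[[rest_col, ex_col]].rename(
            columns={rest_col: "rest_te", ex_col: "exercise_te"})
        y = merged["symptom"].astype(float)
        try:
            res = bstats.logistic_symptom_regression(X, y)
            report["symptom_regressions"][cond] = vars(res)
        except ValueError as exc:
            report["symptom_regressions"][cond] = {"error": str(exc)}

    if {"spo2", "fio2"} <= set(flags.columns):
        sf = flags.assign(sf=[bstats.sf_ratio(s, f) for s, f in
                              zip(flags["spo2"], flags["fio2"])])
        report["sf_ratio_by_condition"] = (
            sf.groupby("condition")["sf"].mean().round(2).to_dict())
        try:
            fit = bstats.spo2_fio2_regression(flags["fio2"] * 100, flags["spo2"])
            report["spo2_fio2_fit"] = vars(fit)
        except ValueError as exc:
            report["spo2_fio2_fit"] = {"error": str(exc)}
    return report


def run_pipeline(config: PipelineConfig, manifest_path=None,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Full run from a manifest (or in-memory cohort) to an output bundle.

    Writes, under ``config.output_dir``: per-recording and group adjacency
    CSVs (plus edge-list JSON / GraphML / diagram JSON for group
    networks), the similarity and total-TE tables, degree rankings, the
    statistics report, the resolved config, and a run summary listing any
    quarantined recordings.
    """
    config.validate()
    if (manifest_path is None) == (cohort is None):
        raise ValueError("provide exactly one of manifest_path or cohort")

    if cohort is not None:
        recordings = dict(cohort.recordings)
        cohort_table = cohort.table
    else:
        manifest_path = Path(manifest_path)
        base = manifest_path.parent
        recordings = {}
        rows = []
        failures = []
        for entry in read_manifest(manifest_path):
            key = (entry["participant_id"], entry["condition"], entry["phase"])
            try:
                recordings[key] = read_recording(
                    base / entry["file"], participant_id=key[0],
                    condition=key[1], phase=key[2],
                    column_map=config.column_map or None)
            except (FileNotFoundError, ValueError) as exc:
                failures.append({"recording": key, "error": str(exc)})
                continue
            rows.append({k: entry.get(k) for k in
                         ("participant_id", "sex", "condition", "symptom",
                          "headache", "spo2", "fio2")})
        cohort_table = pd.DataFrame(rows) if rows else None
        result_failures = failures

    result = _analyze(recordings, cohort_table, config)
    if cohort is None:
        result.failures = result_failures + result.failures

    out = Path(config.output_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "group").mkdir(exist_ok=True)
    for (pid, cond, phase), m in result.networks.items():
        write_network_csv(m, out / "networks" / f"{pid}_{cond}_{phase}.csv")
    for (cond, phase), m in result.group_networks.items():
        stem = out / "group" / f"{cond}_{phase}"
        write_network_csv(m, stem.with_suffix(".csv"))
        write_network_json(m, stem.with_suffix(".json"))
        write_network_graphml(m, stem.with_suffix(".graphml"))
        write_diagram_json(m, Path(str(stem) + "_diagram.json"))
    result.similarity.to_csv(out / "similarity.csv", index=False)
    result.total_te.to_csv(out / "total_te.csv", index=False)
    (out / "rankings.json").write_text(json.dumps(
        {f"{c}_{p}": v for (c, p), v in result.rankings.items()}, indent=1))
    (out / "stats.json").write_text(json.dumps(result.stats, indent=1,
                                               default=_jsonable))
    config.to_yaml(out / "config.yaml")
    summary = {"n_recordings": len(result.networks),
               "n_group_networks": len(result.group_networks),
               "failures": [{"recording": list(f["recording"])
                             if isinstance(f["recording"], tuple)
                             else f["recording"],
                             "error": f["error"]} for f in result.failures]}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return result


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
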