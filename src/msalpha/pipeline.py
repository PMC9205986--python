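"""End-to-end analysis: gaze preprocessing, microsaccade classification,
alpha lateralization per trial class, and permutation statistics.

``run_study_analysis`` reproduces the full analysis graph on a synthetic
study (or a study loaded from HDF5): trials are preprocessed and classified
as toward / away / no-microsaccade by the first detected gaze shift in the
200-600 ms selection window, behaviour is trimmed and compared across
classes, alpha-band (8-12 Hz) lateralization timecourses are computed per
class and tested with cluster-based permutation tests, and the early/late
microsaccade median split feeds the half-peak latency permutation test.
Ground truth from the generator is never consulted during analysis.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import StudyConfig
from .detect import (
    classify_trial,
    compute_velocity,
    detect_shifts,
    label_direction,
    shift_rate_timecourse,
    split_by_latency,
)
from .lateralization import alpha_timecourse_by_participant
from .preprocess import build_calibration_reference, mark_usable, preprocess_trial
from .stats import (
    ClusterTestResult,
    LatencyTestResult,
    behaviour_class_stats,
    cluster_permutation_test,
    latency_permutation_test,
    trim_behaviour,
)
from .synth import SyntheticStudy, generate_study

__all__ = ["AnalysisReport", "run_study_analysis", "compare_conditions", "StageError"]

CLASSES = ("toward", "none", "away")


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class AnalysisReport:
    """Structured output of the full analysis."""

    class_counts: dict
    class_proportions: dict  # over usable trials; sums to 1
    n_usable: int
    n_trials: int
    behaviour: dict
    times_ms: list
    class_timecourses: dict  # class -> mean timecourse (list)
    class_cluster_tests: dict  # class -> ClusterTestResult.to_dict()
    comparisons: dict  # pair -> cluster test dict
    latency_split: dict
    latency_test: dict | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_counts": self.class_counts,
            "class_proportions": self.class_proportions,
            "n_usable": self.n_usable,
            "n_trials": self.n_trials,
            "behaviour": self.behaviour,
            "times_ms": self.times_ms,
            "class_timecourses": self.class_timecourses,
            "class_cluster_tests": self.class_cluster_tests,
            "comparisons": self.comparisons,
            "latency_split": self.latency_split,
            "latency_test": self.latency_test,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _classify_study(
    study: SyntheticStudy,
    extended_window: bool = False,
    dismiss_subfloor: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Preprocess, detect and classify every trial.

    Returns a per-trial table (participant, trial, class, latency, usable)
    and, per participant, the labelled event lists of usable trials (for
    rate timecourses).
    """
    from .detect import DetectionDiagnostics

    rows = []
    events_by_participant: dict[int, list] = {}
    for p in study.participants:
        try:
            ref = build_calibration_reference(p.calibration)
        except Exception as err:  # noqa: BLE001
            raise StageError(f"calibration (participant {p.participant}): {err}") from err
        ev_lists = []
        for t_idx, trial in enumerate(p.gaze):
            meta = p.trials.iloc[t_idx]
            epoch = preprocess_trial(trial, ref, str(meta["cued_side"]))
            usable = mark_usable(epoch)
            events = []
            diag = DetectionDiagnostics()
            if np.isfinite(epoch.position_pct).any():
                velocity = compute_velocity(epoch)
                events = label_direction(
                    detect_shifts(velocity, epoch, diagnostics=diag), epoch.cued_side
                )
            cls = classify_trial(
                events, usable, dismiss=dismiss_subfloor and diag.n_subfloor > 0
            )
            if extended_window and cls.label == "none":
                if any(0.0 <= e.onset_ms <= 600.0 for e in events):
                    cls = classify_trial([], False)  # excluded: early shift present
            rows.append(
                {
                    "participant": p.participant,
                    "trial": t_idx,
                    "trial_class": cls.label,
                    "first_shift_latency_ms": cls.first_shift_latency_ms,
                    "usable": usable,
                    "n_events": len(events),
                }
            )
            if usable:
                ev_lists.append(events)
        events_by_participant[p.participant] = ev_lists
    return pd.DataFrame(rows), events_by_participant


def _class_eeg(
    study: SyntheticStudy, classified: pd.DataFrame, label: str
) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Per-participant contra/ipsi trial stacks for one detected class."""
    contra, ipsi, pids = [], [], []
    for p in study.participants:
        sel = classified[
            (classified["participant"] == p.participant)
            & (classified["trial_class"] == label)
        ]["trial"].to_numpy()
        if sel.size == 0:
            warnings.warn(f"participant {p.participant} has no '{label}' trials; dropped")
            continue
        contra.append(p.eeg_contra[sel])
        ipsi.append(p.eeg_ipsi[sel])
        pids.append(p.participant)
    return contra, ipsi, pids


def run_study_analysis(
    config_or_study: StudyConfig | SyntheticStudy | str | Path,
    n_permutations: int = 2000,
    latency_n_permutations: int | None = None,
    step_ms: float = 50.0,
    latency_step_ms: float = 1.0,
    search_window: tuple[float, float] = (0.0, 1000.0),
    average: str = "power",
    extended_window: bool = False,
    dismiss_subfloor: bool = False,
    stats_seed: int = 0,
) -> AnalysisReport:
    """Run the complete analysis and return an :class:`AnalysisReport`.

    Accepts a :class:`StudyConfig` (a study is generated), an in-memory
    :class:`SyntheticStudy`, or a path to a saved study. Fully deterministic
    given the study seed and ``stats_seed``.
    """
    if isinstance(config_or_study, (str, Path)):
        from .synth import load_study

        study = load_study(config_or_study)
    elif isinstance(config_or_study, StudyConfig):
        study = generate_study(config_or_study)
    else:
        study = config_or_study
    cfg = study.config

    classified, _events = _classify_study(
        study, extended_window=extended_window, dismiss_subfloor=dismiss_subfloor
    )
    usable = classified[classified["trial_class"] != "unusable"]
    n_usable = int(usable.shape[0])
    counts = {c: int((usable["trial_class"] == c).sum()) for c in CLASSES}
    proportions = {c: counts[c] / n_usable if n_usable else np.nan for c in CLASSES}

    # behaviour: detected class merged into trial metadata, trimmed, compared
    try:
        beh = study.trial_info.merge(
            classified[["participant", "trial", "trial_class"]],
            on=["participant", "trial"],
        )
        beh = trim_behaviour(beh)
        behaviour = {
            m: behaviour_class_stats(beh, measure=m) for m in ("error_deg", "rt_ms")
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(f"behaviour: {err}") from err

    # per-class alpha lateralization + cluster tests vs zero
    time_ms = study.participants[0].eeg_time_ms
    rng = np.random.default_rng(stats_seed)
    timecourses: dict[str, np.ndarray] = {}
    pid_sets: dict[str, list[int]] = {}
    class_tests = {}
    times = None
    for label in CLASSES:
        contra, ipsi, pids = _class_eeg(study, classified, label)
        if len(contra) < 2:
            raise StageError(f"lateralization: <2 participants with '{label}' trials")
        times, tc = alpha_timecourse_by_participant(
            contra, ipsi, time_ms, step_ms=step_ms, sampling_rate=cfg.sampling_rate,
            average=average,
        )
        timecourses[label] = tc
        pid_sets[label] = pids
        post = times >= 0  # test the post-cue interval
        res = cluster_permutation_test(
            tc[:, post], n_permutations=n_permutations, seed=rng
        )
        class_tests[label] = res.to_dict()

    comparisons = {}
    for a, b in (("toward", "none"), ("toward", "away")):
        comparisons[f"{a}_vs_{b}"] = compare_conditions(
            {a: (pid_sets[a], timecourses[a]), b: (pid_sets[b], timecourses[b])},
            (a, b),
            times=times,
            n_permutations=n_permutations,
            seed=rng,
        ).to_dict()

    # early/late toward-microsaccade split and latency test
    lat_rows = usable[usable["trial_class"] == "toward"]
    lat_by_p = {
        int(pid): list(
            zip(g["trial"].astype(int), g["first_shift_latency_ms"].astype(float))
        )
        for pid, g in lat_rows.groupby("participant")
    }
    split = split_by_latency(lat_by_p)
    latency_test = None
    split_summary = {"n_participants": len(split)}
    if len(split) >= 2:
        early_tc, late_tc = [], []
        for p in study.participants:
            if p.participant not in split:
                continue
            early_ids, late_ids = split[p.participant]
            if not early_ids or not late_ids:
                continue
            _, tc_e = alpha_timecourse_by_participant(
                [p.eeg_contra[np.asarray(early_ids)]],
                [p.eeg_ipsi[np.asarray(early_ids)]],
                time_ms, step_ms=latency_step_ms, sampling_rate=cfg.sampling_rate,
                average=average,
            )
            lat_times, tc_l = alpha_timecourse_by_participant(
                [p.eeg_contra[np.asarray(late_ids)]],
                [p.eeg_ipsi[np.asarray(late_ids)]],
                time_ms, step_ms=latency_step_ms, sampling_rate=cfg.sampling_rate,
                average=average,
            )
            early_tc.append(tc_e[0])
            late_tc.append(tc_l[0])
        if len(early_tc) >= 2:
            lat_B = latency_n_permutations or n_permutations
            res = latency_permutation_test(
                np.asarray(early_tc), np.asarray(late_tc), lat_times,
                n_permutations=lat_B, search_window=search_window, seed=rng,
            )
            latency_test = res.to_dict()
            split_summary["n_participants"] = len(early_tc)

    mean_latencies = {}
    for which, idx in (("early", 0), ("late", 1)):
        vals = [
            lat
            for pid, (e, l) in split.items()
            for tid, lat in lat_by_p[pid]
            if tid in ((e, l)[idx])
        ]
        mean_latencies[which] = float(np.mean(vals)) if vals else np.nan
    split_summary["mean_latency_ms"] = mean_latencies

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    report = AnalysisReport(
        class_counts=counts,
        class_proportions=proportions,
        n_usable=n_usable,
        n_trials=int(classified.shape[0]),
        behaviour=behaviour,
        times_ms=[float(x) for x in times],
        class_timecourses={c: timecourses[c].mean(axis=0).tolist() for c in CLASSES},
        class_cluster_tests=class_tests,
        comparisons=comparisons,
        latency_split=split_summary,
        latency_test=latency_test,
        provenance={
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "stats_seed": stats_seed,
            "n_permutations": n_permutations,
            "version": _version,
        },
    )
    return report


def compare_conditions(
    condition_data: dict[str, tuple[list[int], np.ndarray]],
    pair: tuple[str, str],
    times: np.ndarray,
    n_permutations: int = 2000,
    seed=0,
) -> ClusterTestResult:
    """Paired cluster permutation test between two conditions' timecourses.

    ``condition_data`` maps condition name to (participant ids, participants
    x times array). Participants present in only one condition are dropped
    with a warning; the paired difference over the post-cue interval is
    tested against zero via participant-level sign flips (equivalent to
    condition-label swaps).
    """
    a, b = pair
    pids_a, tc_a = condition_data[a]
    pids_b, tc_b = condition_data[b]
    common = sorted(set(pids_a) & set(pids_b))
    dropped = sorted(set(pids_a) ^ set(pids_b))
    if dropped:
        warnings.warn(f"unpaired participants dropped from {a} vs {b}: {dropped}")
    if len(common) < 2:
        raise StageError(f"comparison {a} vs {b}: <2 paired participants")
    ia = [pids_a.index(p) for p in common]
    ib = [pids_b.index(p) for p in common]
    post = np.asarray(times) >= 0
    return cluster_permutation_test(
        np.asarray(tc_a)[ia][:, post],
        np.asarray(tc_b)[ib][:, post],
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed),
    )
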