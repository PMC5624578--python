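"""Study drivers: simulation sweeps with detection counts, and cohort analysis.

``run_simulation_study`` reproduces the validation design for the resampling
schemes: for each configuration in a grid, many independent realizations are
simulated, fitted and resampled; between consecutive grid configurations the
single-recording difference test is applied to per-run pairs and the number of
significant outcomes (detections out of ``runs``) is recorded. With no true
parameter change between configurations these detections are false positives,
whose count should stay within the binomial ceiling at the test level.

``run_cohort_analysis`` applies the same machinery to a cohort of recorded
R-R series (subjects x tasks): per-recording order selection (AIC), fit,
indexes, confidence limits, within-subject task-pair tests, and a group
summary combining a Wilcoxon signed-rank test with the tally of individually
significant increases/decreases.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .ar import ARFit, fit_ar, select_order
from .errors import ArciError
from .resampling import (
    PERCENTILES,
    ConfidenceSummary,
    DifferenceTestResult,
    ReplicateSet,
    bs_replicates,
    confidence_summary,
    difference_test,
    mc_replicates,
)
from .series import TimeSeries
from .simulate import SimulationConfig
from .spectral import IndexSet, compute_indexes

__all__ = [
    "StudyRow",
    "CohortRow",
    "CohortResult",
    "run_simulation_study",
    "run_cohort_analysis",
    "binomial_false_positive_bound",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("f_lf", "p_lfhf", "s_x")


def _child_seed(master: int, *labels) -> int:
    key = zlib.crc32("/".join(str(x) for x in labels).encode())
    return int(np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0] & 0x7FFFFFFF)


def binomial_false_positive_bound(n_trials: int, p: float, conf: float) -> int:
    """Smallest k with Binomial(n_trials, p) CDF(k) >= conf.

    The expected ceiling on false positives: at a 5% test level over 100
    independent trials, up to 9 detections are compatible with pure chance
    (95% confidence).
    """
    if not (0 < p < 1 and 0 < conf < 1):
        raise ValueError("p and conf must be in (0, 1)")
    return int(scipy.stats.binom.ppf(conf, n_trials, p))


@dataclass
class StudyRow:
    """Per-configuration summary of a simulation sweep."""

    label: str
    n_runs: int
    n_failed: int
    #: method -> index -> {percentile: mean over runs of that replicate percentile}
    mean_percentiles: dict[str, dict[str, dict[int, float]]]
    #: index -> percentiles of the per-run point estimates (the gold standard)
    gold_percentiles: dict[str, dict[int, float]]
    #: index -> true value from the generating parameters (None when undefined)
    true_values: dict[str, float | None]
    #: method -> index -> significant detections vs the PREVIOUS configuration
    detection_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    flagged: bool = False  # > 10% of runs failed


def _summarize_runs(values_per_run: dict[str, list[np.ndarray]]) -> dict:
    out = {}
    for name in INDEX_NAMES:
        per_pct: dict[int, list[float]] = {q: [] for q in PERCENTILES}
        for arr in values_per_run[name]:
            finite = arr[np.isfinite(arr)]
            if finite.size == 0:
                continue
            for q, v in zip(PERCENTILES, np.percentile(finite, PERCENTILES)):
                per_pct[q].append(float(v))
        out[name] = {
            q: (float(np.mean(v)) if v else float("nan")) for q, v in per_pct.items()
        }
    return out


def run_simulation_study(
    grid: list[SimulationConfig],
    runs: int = 100,
    m: int = 1000,
    alpha: float = 0.05,
    method: str = "mc",
    seed: int = 0,
) -> list[StudyRow]:
    """Simulate / fit / resample each grid configuration and count detections.

    Parameters
    ----------
    grid
        Ordered configurations; difference tests compare each configuration
        with its predecessor, pairing run i with run i (independent series).
    runs
        Realizations per configuration.
    m
        Replicates per realization.
    method
        "mc", "bs", or "both".
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    if method not in ("mc", "bs", "both"):
        raise ValueError("method must be 'mc', 'bs' or 'both'")
    methods = ("mc", "bs") if method == "both" else (method,)

    rows: list[StudyRow] = []
    prev_replicates: dict[str, dict[str, list[np.ndarray]]] | None = None
    for ci, config in enumerate(grid):
        # replicate index arrays per method per index, one entry per run
        reps: dict[str, dict[str, list[np.ndarray]]] = {
            meth: {name: [] for name in INDEX_NAMES} for meth in methods
        }
        points: dict[str, list[np.ndarray]] = {name: [] for name in INDEX_NAMES}
        n_failed = 0
        for r in range(runs):
            run_seed = _child_seed(seed, "study", config.label, ci, r)
            try:
                ts = config.simulate(run_seed)
                fit = fit_ar(ts, config.estimation_order)
                point = compute_indexes(fit.model)
                run_reps = {}
                for meth in methods:
                    run_reps[meth] = _replicates(meth, fit, ts, m, run_seed)
            except ArciError as exc:
                logger.warning("run %d of %r failed: %s", r, config.label, exc)
                n_failed += 1
                for meth in methods:
                    for name in INDEX_NAMES:
                        reps[meth][name].append(np.full(m, np.nan))
                for name in INDEX_NAMES:
                    points[name].append(np.array([np.nan]))
                continue
            for meth in methods:
                for name in INDEX_NAMES:
                    reps[meth][name].append(run_reps[meth].index_array(name))
            for name, v in zip(INDEX_NAMES, point.as_tuple()):
                points[name].append(np.array([v]))

        # true index values from the generating parameters (linear mode only)
        true_values: dict[str, float | None] = {n: None for n in INDEX_NAMES}
        if config.mode == "linear" and config.trend_amplitude_rel == 0:
            truth = compute_indexes(config.model())
            true_values = dict(zip(INDEX_NAMES, (truth.f_lf, truth.p_lfhf, truth.s_x)))

        gold = {}
        for name in INDEX_NAMES:
            flat = np.concatenate(points[name])
            finite = flat[np.isfinite(flat)]
            gold[name] = (
                dict(zip(PERCENTILES, map(float, np.percentile(finite, PERCENTILES))))
                if finite.size
                else {q: float("nan") for q in PERCENTILES}
            )

        detection: dict[str, dict[str, int]] = {}
        if prev_replicates is not None:
            for meth in methods:
                detection[meth] = {}
                for name in INDEX_NAMES:
                    count = 0
                    for r in range(runs):
                        t_seed = _child_seed(seed, "pair", ci, r, name, meth)
                        try:
                            res = difference_test(
                                prev_replicates[meth][name][r],
                                reps[meth][name][r],
                                alpha=alpha,
                                seed=t_seed,
                            )
                        except ArciError:
                            continue
                        count += int(res.significant)
                    detection[meth][name] = count

        rows.append(
            StudyRow(
                label=config.label,
                n_runs=runs,
                n_failed=n_failed,
                mean_percentiles={meth: _summarize_runs(reps[meth]) for meth in methods},
                gold_percentiles=gold,
                true_values=true_values,
                detection_counts=detection,
                flagged=n_failed > 0.1 * runs,
            )
        )
        prev_replicates = reps
    return rows


def _replicates(method: str, fit: ARFit, ts: TimeSeries, m: int, seed: int) -> ReplicateSet:
    if method == "mc":
        return mc_replicates(fit, m, seed)
    return bs_replicates(fit, ts, m, seed)


@dataclass
class CohortRow:
    """Per subject/task estimates with their confidence limits."""

    subject: str
    task: str
    order: int
    indexes: IndexSet
    summaries: dict[str, ConfidenceSummary]


@dataclass
class CohortResult:
    rows: list[CohortRow]
    #: (subject, task_a, task_b, index) -> DifferenceTestResult
    tests: dict[tuple[str, str, str, str], DifferenceTestResult]
    #: one row per (task pair, index): median/iqr of differences, Wilcoxon p,
    #: percentage of subjects with significant increase / ns / decrease
    group_summary: pd.DataFrame


def run_cohort_analysis(
    recordings: dict[str, dict[str, TimeSeries]],
    m: int = 1000,
    alpha: float = 0.05,
    order_range: tuple[int, int] = (5, 15),
    seed: int = 0,
    method: str = "mc",
) -> CohortResult:
    """Individual-by-individual index estimation and task comparison.

    Every retained subject must have every task; subjects with missing tasks
    are excluded with a warning. For each recording the AR order is chosen by
    AIC in ``order_range``; the default resampling scheme is Monte Carlo.
    """
    if method not in ("mc", "bs"):
        raise ValueError("method must be 'mc' or 'bs'")
    tasks: list[str] = []
    for task_map in recordings.values():
        for t in task_map:
            if t not in tasks:
                tasks.append(t)
    subjects = []
    for subj, task_map in recordings.items():
        if all(t in task_map for t in tasks):
            subjects.append(subj)
        else:
            logger.warning("subject %r missing tasks, excluded", subj)
    if not subjects:
        raise ValueError("no subject has every task")

    rows: list[CohortRow] = []
    rep_arrays: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    point_values: dict[tuple[str, str], IndexSet] = {}
    for subj in subjects:
        for task in tasks:
            ts = recordings[subj][task]
            order = select_order(ts, *order_range)
            fit = fit_ar(ts, order)
            point = compute_indexes(fit.model)
            rset = _replicates(method, fit, ts, m, _child_seed(seed, "cohort", subj, task))
            summaries = {
                name: confidence_summary(rset.index_array(name), point.as_tuple()[i])
                for i, name in enumerate(INDEX_NAMES)
                if np.isfinite(rset.index_array(name)).any()
            }
            rows.append(CohortRow(subj, task, order, point, summaries))
            rep_arrays[(subj, task)] = {n: rset.index_array(n) for n in INDEX_NAMES}
            point_values[(subj, task)] = point

    tests: dict[tuple[str, str, str, str], DifferenceTestResult] = {}
    summary_records = []
    pairs = [(tasks[i], tasks[j]) for i in range(len(tasks)) for j in range(i + 1, len(tasks))]
    for task_a, task_b in pairs:
        for name in INDEX_NAMES:
            outcomes = []
            diffs = []
            for subj in subjects:
                pa = point_values[(subj, task_a)].as_tuple()[INDEX_NAMES.index(name)]
                pb = point_values[(subj, task_b)].as_tuple()[INDEX_NAMES.index(name)]
                if np.isfinite(pa) and np.isfinite(pb):
                    diffs.append(pb - pa)
                try:
                    res = difference_test(
                        rep_arrays[(subj, task_a)][name],
                        rep_arrays[(subj, task_b)][name],
                        alpha=alpha,
                        seed=_child_seed(seed, "cohort-test", subj, task_a, task_b, name),
                    )
                except ArciError:
                    continue
                tests[(subj, task_a, task_b, name)] = res
                outcomes.append(res.direction)
            n = len(outcomes)
            diffs_arr = np.array(diffs)
            if diffs_arr.size >= 5 and np.any(diffs_arr != 0):
                wilcoxon_p = float(scipy.stats.wilcoxon(diffs_arr).pvalue)
            else:
                wilcoxon_p = float("nan")
            q75, q25 = (
                np.percentile(diffs_arr, [75, 25]) if diffs_arr.size else (np.nan, np.nan)
            )
            summary_records.append(
                {
                    "pair": f"{task_a}->{task_b}",
                    "index": name,
                    "median_difference": float(np.median(diffs_arr)) if diffs_arr.size else np.nan,
                    "iqr_difference": float(q75 - q25),
                    "wilcoxon_p": wilcoxon_p,
                    "pct_increase": 100.0 * outcomes.count("increase") / n if n else np.nan,
                    "pct_ns": 100.0 * outcomes.count("none") / n if n else np.nan,
                    "pct_decrease": 100.0 * outcomes.count("decrease") / n if n else np.nan,
                    "n_subjects": n,
                }
            )
    return CohortResult(rows=rows, tests=tests, group_summary=pd.DataFrame(summary_records))
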