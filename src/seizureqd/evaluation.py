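"""Baseline detectors, TP/FP/FN scoring, and the gamma sensitivity sweep.

Baselines:

* BE — the classic Bayesian estimator: first stage with ``pi_k > 0.5`` per
  run segment, with the same terminate-and-restart and refractory machinery
  as the quickest-detection policy.
* HT — a heuristic threshold on the raw statistic: first stage with
  ``z_k > h_bar`` where ``h_bar = mean + 3 SD`` of the nonictal training
  data (sample SD, n-1 denominator).

Scoring follows the clinical protocol: a detection is a true positive if an
annotated onset lies within the matching tolerance (20 s, symmetric) and has
not already been claimed; matching is greedy in detection-time order and
one-to-one.  Unmatched detections are false positives, unmatched onsets false
negatives.  Delays are signed (negative = anticipation); the combined delay
summary is the mean of absolute values.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm_glm import HmmGlmModel
from .information_state import InformationTrajectory
from .qd_policy import (CostSpec, DetectionEvent, ThresholdPolicy,
                        DEFAULT_REFRACTORY_S, run_qd, synthesize_policy)

MATCH_TOLERANCE_S = 20.0
BE_THRESHOLD = 0.5


@dataclass
class DetectionReport:
    """Scored detections against annotated onsets."""

    detections: list[float]
    tp: int
    fp: int
    fn: int
    delays: list[float]             # signed seconds, one per matched onset
    analyzed_hours: float | None = None

    @property
    def sensitivity(self) -> float:
        n_onsets = self.tp + self.fn
        return self.tp / n_onsets if n_onsets else float("nan")

    @property
    def fpr(self) -> float:
        """False positives per analyzed hour."""
        if not self.analyzed_hours:
            return float("nan")
        return self.fp / self.analyzed_hours

    @property
    def mean_abs_delay(self) -> float:
        return float(np.mean(np.abs(self.delays))) if self.delays \
            else float("nan")

    def summary(self) -> dict:
        return {
            "n_detections": len(self.detections), "tp": self.tp,
            "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "fpr_per_h": self.fpr,
            "mean_abs_delay_s": self.mean_abs_delay,
            "delays_s": list(self.delays),
        }


# ---------------------------------------------------------------------------
# Baseline detectors
# ---------------------------------------------------------------------------

class _ConstantThresholdPolicy:
    """Fixed-threshold stand-in with the run_qd stage interface."""

    M = 2**31

    def __init__(self, threshold: float, policy_id: str):
        self.threshold = threshold
        self.policy_id = policy_id

    def threshold_at(self, k_in_segment: int) -> float:
        return self.threshold


def bayes_detector(model: HmmGlmModel, observations: Sequence[float],
                   threshold: float = BE_THRESHOLD,
                   refractory_s: float = DEFAULT_REFRACTORY_S,
                   ) -> tuple[list[float], InformationTrajectory]:
    """First crossing of ``pi_k > 0.5`` per run segment.

    Returns detection times (s) and the filtered trajectory (whose restart
    points are the detections themselves).
    """
    policy = _ConstantThresholdPolicy(threshold, policy_id="be")
    events, traj = run_qd(model, policy, observations,
                          refractory_s=refractory_s)
    return [float(e.stage) for e in events], traj


def heuristic_threshold(training_z: Sequence[float]) -> float:
    """``h_bar = mean + 3 * sample SD`` of the nonictal training statistic."""
    training_z = np.asarray(training_z, dtype=float)
    if len(training_z) == 0:
        raise ValueError("training sequence is empty")
    sd = float(np.std(training_z, ddof=1)) if len(training_z) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("zero-variance training data: degenerate HT threshold",
                      stacklevel=2)
    return float(np.mean(training_z)) + 3.0 * sd


def heuristic_detector(z: Sequence[float], training_z: Sequence[float],
                       refractory_s: float = DEFAULT_REFRACTORY_S,
                       ) -> list[float]:
    """Detection at the first ``z_k > h_bar`` per run segment."""
    h_bar = heuristic_threshold(training_z)
    z = np.asarray(z, dtype=float)
    detections: list[float] = []
    refractory_until = -1.0
    for k in range(len(z)):
        if z[k] > h_bar and k > refractory_until:
            detections.append(float(k))
            refractory_until = k + refractory_s
    return detections


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_detections(detections: Sequence[float], onsets: Sequence[float],
                     tolerance_s: float = MATCH_TOLERANCE_S,
                     analyzed_hours: float | None = None) -> DetectionReport:
    """Greedy one-to-one TP/FP/FN matching with a symmetric tolerance window.

    Detections are processed in time order; each claims the nearest unmatched
    onset within ``tolerance_s`` (ties to the earlier onset).  The signed
    delay of a match is ``detection - onset`` (negative = anticipation).
    """
    detections = list(detections)
    onsets = list(onsets)
    if any(b < a for a, b in zip(detections, detections[1:])):
        raise ValueError("detections must be sorted in time")
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onsets must be sorted in time")

    matched = [False] * len(onsets)
    tp = fp = 0
    delays: list[float] = []
    for det in detections:
        best_i, best_d = None, np.inf
        for i, onset in enumerate(onsets):
            if matched[i]:
                continue
            d = abs(det - onset)
            if d <= tolerance_s and d < best_d:
                best_i, best_d = i, d
        if best_i is None:
            fp += 1
        else:
            matched[best_i] = True
            tp += 1
            delays.append(det - onsets[best_i])
    fn = len(onsets) - tp
    return DetectionReport(detections=detections, tp=tp, fp=fp, fn=fn,
                           delays=delays, analyzed_hours=analyzed_hours)


def pool_reports(reports: Sequence[DetectionReport]) -> DetectionReport:
    """Pool per-run reports into one corpus-level report."""
    hours = [r.analyzed_hours for r in reports]
    total_hours = (sum(h for h in hours if h is not None)
                   if any(h is not None for h in hours) else None)
    return DetectionReport(
        detections=[t for r in reports for t in r.detections],
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        delays=[d for r in reports for d in r.delays],
        analyzed_hours=total_hours)


def analyzed_hours(duration_s: float,
                   ictal_spans: Sequence[tuple[float, float]] = (),
                   n_detections: int = 0,
                   refractory_s: float = 0.0) -> float:
    """Nonictal hours entering the FPR denominator.

    Annotated ictal spans and (approximately) post-detection refractory spans
    are excluded from the analyzed duration.
    """
    ictal = sum(b - a for a, b in ictal_spans)
    return max(duration_s - ictal - n_detections * refractory_s, 0.0) / 3600.0


# ---------------------------------------------------------------------------
# Corpus evaluation and gamma sweep
# ---------------------------------------------------------------------------

def evaluate_runs(detection_lists: Sequence[Sequence[float]],
                  onset_lists: Sequence[Sequence[float]],
                  run_length_s: float, ictal_s: float = 0.0,
                  tolerance_s: float = MATCH_TOLERANCE_S,
                  refractory_s: float = 0.0) -> DetectionReport:
    """Score each run and pool the counts."""
    reports = []
    for dets, onsets in zip(detection_lists, onset_lists, strict=True):
        hours = analyzed_hours(run_length_s,
                               [(o, o + ictal_s) for o in onsets],
                               n_detections=len(dets),
                               refractory_s=refractory_s)
        reports.append(score_detections(dets, onsets, tolerance_s,
                                        analyzed_hours=hours))
    return pool_reports(reports)


def gamma_sweep(model: HmmGlmModel, cost_template: CostSpec,
                observation_runs: Sequence[Sequence[float]],
                onset_runs: Sequence[Sequence[float]],
                gamma_grid: Sequence[float],
                run_length_s: float, ictal_s: float = 0.0,
                training_codes: Sequence[int] | None = None,
                refractory_s: float = DEFAULT_REFRACTORY_S,
                pi_grid_size: int = 1001,
                ) -> list[tuple[float, DetectionReport]]:
    """Delay-vs-false-positive trade-off curve over the gamma grid.

    The policy is re-synthesized for every gamma and scored on the runs.
    """
    if any(not 0.0 <= g <= 1.0 for g in gamma_grid):
        raise ValueError("gamma grid must lie within [0, 1]")
    results = []
    for g in gamma_grid:
        cost = dataclasses.replace(cost_template, gamma=g)
        policy = synthesize_policy(model, cost, pi_grid_size=pi_grid_size,
                                   training_codes=training_codes,
                                   policy_id=f"qd-gamma-{g:g}")
        det_lists = []
        for z in observation_runs:
            events, _ = run_qd(model, policy, z, refractory_s=refractory_s)
            det_lists.append([float(e.stage) for e in events])
        report = evaluate_runs(det_lists, onset_runs, run_length_s,
                               ictal_s=ictal_s, refractory_s=refractory_s)
        results.append((float(g), report))
    return results
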