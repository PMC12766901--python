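"""Reliable change and clinically significant improvement criteria.

A follow-up gain on a cognitive scale counts as a real, clinically meaningful
improvement only if it clears two bars at once:

* the reliable change index RC = 1.96 * SD1 * sqrt(2 (1 - alpha)), the
  smallest change exceeding what measurement error alone produces (SD1 =
  baseline SD of the scale, alpha = its Cronbach reliability), and
* a clinically significant cutoff CS = (M_clin * SD_norm + M_norm * SD_clin)
  / (SD_norm + SD_clin), the score at which membership of the clinical and
  the normative population is equally likely.

The three-part rule: a subject improves at a visit iff the change from
baseline is positive, *strictly* exceeds RC, and the follow-up score
*strictly* exceeds CS ("exceeding" / "surpassing"; boundary ties do not
count). Confusion-matrix metrics for the improver/non-improver distinction
live here too so every classifier report can be recomputed from its counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import SubjectRecord


@dataclass(frozen=True)
class ChangeCriteria:
    """Reliable-change index + clinical cutoff pair defining improvement."""

    rc_index: float
    cutoff: float
    alpha_reliability: float
    sd_baseline: float


@dataclass(frozen=True)
class ImprovementCall:
    subject_id: str
    visit: str
    improved: bool
    change_score: float
    followup_score: float


def reliable_change_index(sd_baseline: float, alpha: float) -> float:
    """RC = 1.96 * SD1 * sqrt(2 (1 - alpha)); zero only at perfect reliability."""
    if sd_baseline <= 0:
        raise ValueError("sd_baseline must be positive")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return 1.96 * sd_baseline * float(np.sqrt(2.0 * (1.0 - alpha)))


def back_solve_alpha(rc_index: float, sd_baseline: float) -> float:
    """Reliability implied by a published RC index (audit helper).

    Inverts RC = 1.96 * SD1 * sqrt(2 (1 - alpha)).
    """
    if rc_index < 0 or sd_baseline <= 0:
        raise ValueError("rc_index must be >= 0 and sd_baseline > 0")
    alpha = 1.0 - (rc_index / (1.96 * sd_baseline)) ** 2 / 2.0
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"implied alpha {alpha:.4f} outside (0, 1]")
    return float(alpha)


def clinical_cutoff(mean_clin: float, sd_clin: float, mean_norm: float, sd_norm: float) -> float:
    """CS = (M_clin SD_norm + M_norm SD_clin) / (SD_norm + SD_clin).

    A convex combination of the two means (weights are the *opposite* group's
    SD), so the cutoff always lies between them.
    """
    if sd_clin <= 0 or sd_norm <= 0:
        raise ValueError("standard deviations must be positive")
    return (mean_clin * sd_norm + mean_norm * sd_clin) / (sd_norm + sd_clin)


def make_criteria(
    sd_baseline: float, alpha: float,
    mean_clin: float, sd_clin: float, mean_norm: float, sd_norm: float,
) -> ChangeCriteria:
    return ChangeCriteria(
        rc_index=reliable_change_index(sd_baseline, alpha),
        cutoff=clinical_cutoff(mean_clin, sd_clin, mean_norm, sd_norm),
        alpha_reliability=alpha,
        sd_baseline=sd_baseline,
    )


def classify_improvement(
    records: list[SubjectRecord],
    score_name: str,
    criteria: ChangeCriteria,
    visit: str,
) -> tuple[list[ImprovementCall], int]:
    """Apply the three-part rule at one visit.

    improved <=> change > 0 AND change > rc_index AND followup > cutoff,
    all strict. Records missing the visit score are excluded; the count of
    exclusions is returned alongside the calls.
    """
    calls: list[ImprovementCall] = []
    n_excluded = 0
    for rec in records:
        baseline = rec.score_at(score_name, "baseline")
        followup = rec.score_at(score_name, visit)
        if baseline is None or followup is None:
            n_excluded += 1
            continue
        change = followup - baseline
        improved = (change > 0) and (change > criteria.rc_index) and (followup > criteria.cutoff)
        calls.append(
            ImprovementCall(
                subject_id=rec.subject_id, visit=visit, improved=improved,
                change_score=change, followup_score=followup,
            )
        )
    return calls, n_excluded


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent from confusion counts."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if tp + fn == 0:
        raise ValueError("no positive-class subjects (tp + fn == 0)")
    if tn + fp == 0:
        raise ValueError("no negative-class subjects (tn + fp == 0)")
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    accuracy = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    return sensitivity, specificity, accuracy
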