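"""Leave-pair-out SVM classification of improvers vs non-improvers.

Features are per-subject means of a metric map (ReHo or DC) over the voxels
of a significant cluster. Classification uses a support vector machine
(radial-basis kernel by default) evaluated by leave-pair-out cross-validation:
every (improver, non-improver) pair is held out in turn, the classifier is
trained on the remaining subjects with features standardised by *training*
statistics only, and the pair is classified. A subject's final call is the
majority vote over all pairs containing it (ties break towards the positive
class and are logged). Hyperparameters are grid-searched on a log2 lattice
over (C, gamma); the best cell maximises accuracy, ties resolved towards the
smallest regularisation (then smallest width).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .clinical_change import confusion_metrics
from .group_inference import ClusterResult
from .imaging_io import MetricMap

logger = logging.getLogger(__name__)

#: Default log2 search lattice: C in 2^-5..2^15, gamma in 2^-15..2^3, exponent
#: step 4 (the conventional coarse grid). A step-1 lattice can be passed in.
DEFAULT_GRID = {
    "C": [2.0**e for e in range(-5, 16, 4)],
    "gamma": [2.0**e for e in range(-15, 4, 4)],
}


@dataclass
class FeatureTable:
    """Per-subject named features plus a binary improvement label."""

    features: pd.DataFrame       # index: subject_id, columns: feature names
    labels: pd.Series            # aligned to features.index; values in {0, 1}

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(set(self.features.columns)) != len(self.features.columns):
            raise ValueError("feature names must be unique")
        self.labels = self.labels.loc[self.features.index]
        classes = set(self.labels.unique().tolist())
        if not classes <= {0, 1} or len(classes) != 2:
            raise ValueError("labels must contain both classes 0 and 1")


@dataclass
class LpoCvReport:
    calls: pd.Series                      # final per-subject prediction (0/1)
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    best_params: dict
    grid: pd.DataFrame = field(default_factory=pd.DataFrame)  # C, gamma, accuracy
    n_vote_ties: int = 0


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_cluster_features(
    maps_by_kind: dict[str, list[MetricMap]],
    clusters_by_kind: dict[str, ClusterResult],
    subject_ids: list[str],
    labels: pd.Series | dict[str, int] | None = None,
) -> FeatureTable | pd.DataFrame:
    """One feature per (map kind, cluster): the mean of in-cluster voxel values.

    ``maps_by_kind`` maps a metric name (e.g. "reho", "dc") to that metric's
    per-subject maps, ordered like ``subject_ids``; ``clusters_by_kind`` gives
    the cluster set whose voxels define each feature. Returns a plain
    DataFrame when no labels are supplied.
    """
    columns: dict[str, np.ndarray] = {}
    for kind, maps in maps_by_kind.items():
        if len(maps) != len(subject_ids):
            raise ValueError(f"{kind}: {len(maps)} maps for {len(subject_ids)} subjects")
        result = clusters_by_kind[kind]
        for c_idx, cluster in enumerate(result.clusters):
            if cluster.voxels is None or len(cluster.voxels) == 0:
                raise ValueError(f"{kind} cluster {c_idx} has no member voxels")
            voxels = np.asarray(cluster.voxels)
            columns[f"{kind}_cluster{c_idx}"] = np.array(
                [float(m.data[tuple(voxels.T)].mean()) for m in maps]
            )
    df = pd.DataFrame(columns, index=pd.Index(subject_ids, name="subject_id"))
    if labels is None:
        return df
    labels = pd.Series(labels)
    return FeatureTable(features=df, labels=labels)


def features_from_masks(
    maps_by_kind: dict[str, list[MetricMap]],
    voxel_masks_by_kind: dict[str, list[np.ndarray]],
    subject_ids: list[str],
    labels: pd.Series | dict[str, int],
) -> FeatureTable:
    """Feature table from explicit boolean voxel masks (one list per map kind)."""
    columns: dict[str, np.ndarray] = {}
    for kind, maps in maps_by_kind.items():
        for c_idx, vmask in enumerate(voxel_masks_by_kind[kind]):
            if not vmask.any():
                raise ValueError(f"{kind} mask {c_idx} selects no voxels")
            columns[f"{kind}_cluster{c_idx}"] = np.array(
                [float(m.data[vmask].mean()) for m in maps]
            )
    df = pd.DataFrame(columns, index=pd.Index(subject_ids, name="subject_id"))
    return FeatureTable(features=df, labels=pd.Series(labels))


# ---------------------------------------------------------------------------
# Leave-pair-out cross-validation
# ---------------------------------------------------------------------------

def _lpo_votes(X: np.ndarray, y: np.ndarray, C: float, gamma: float, kernel: str) -> np.ndarray:
    """Mean held-out decision per subject over all (positive, negative) pairs.

    Returns the per-subject average predicted label in [0, 1]; > 0.5 is a
    positive majority. Standardisation uses training-fold statistics only.
    """
    n = len(y)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    votes = np.zeros(n)
    counts = np.zeros(n)
    for p in pos_idx:
        for q in neg_idx:
            train = np.ones(n, dtype=bool)
            train[[p, q]] = False
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(C=C, gamma=gamma, kernel=kernel)
            clf.fit((X[train] - mu) / sd, y[train])
            pred = clf.predict((X[[p, q]] - mu) / sd)
            votes[p] += pred[0]
            votes[q] += pred[1]
            counts[p] += 1
            counts[q] += 1
    return votes / counts


def leave_pair_out_cv(
    table: FeatureTable,
    params_grid: dict | None = None,
    kernel: str = "rbf",
    rng: np.random.Generator | None = None,
) -> LpoCvReport:
    """Grid-searched leave-pair-out SVM with per-subject majority voting.

    Every grid cell (C, gamma) is evaluated by full leave-pair-out CV; the
    report uses the cell maximising accuracy (ties: smallest C, then smallest
    gamma). Metrics are always recomputable from the counts via
    :func:`limbiccog.clinical_change.confusion_metrics`.
    """
    grid = params_grid or DEFAULT_GRID
    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("each class needs n >= 2")

    rows = []
    best = None
    for C in sorted(grid["C"]):
        for gamma in sorted(grid["gamma"]):
            mean_votes = _lpo_votes(X, y, C, gamma, kernel)
            calls = (mean_votes >= 0.5).astype(int)     # ties -> positive
            acc = float(np.mean(calls == y))
            rows.append({"C": C, "gamma": gamma, "accuracy": 100.0 * acc})
            # strictly-greater keeps the smallest (C, gamma) on ties because
            # of the sorted iteration order
            if best is None or acc > best[0]:
                best = (acc, C, gamma, calls, mean_votes)
    _, C_best, gamma_best, calls, mean_votes = best
    n_ties = int(np.sum(mean_votes == 0.5))
    if n_ties:
        logger.info("leave_pair_out_cv: %d subjects with tied votes called positive", n_ties)

    tp = int(np.sum((calls == 1) & (y == 1)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    sens, spec, acc = confusion_metrics(tp, fn, tn, fp)
    return LpoCvReport(
        calls=pd.Series(calls, index=table.features.index),
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        best_params={"C": C_best, "gamma": gamma_best, "kernel": kernel},
        grid=pd.DataFrame(rows),
        n_vote_ties=n_ties,
    )


def grid_search_surface(report: LpoCvReport) -> pd.DataFrame:
    """The full (C, gamma, accuracy) lattice for external surface plotting."""
    return report.grid.copy()
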