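"""Connectome-based predictive modeling (CPM).

Pipeline: parcel the BOLD volume into regions, average voxel time series per
region, build a Fisher-transformed (artanh r) region-by-region connectivity
matrix per subject; across subjects, correlate every edge with the behaviour
score and keep edges significant at a fixed threshold (default p < 0.001),
split by correlation sign into a positive and a negative network; summarise
each subject by network strength (sum of edge values over the selected set);
fit a linear model of behaviour on strength and evaluate it by leave-one-out
cross-validation, with edge selection redone inside every training fold so
the held-out subject never influences its own fold's edge mask. Significance
of the cross-validated prediction comes from permuting the behaviour labels
and repeating the whole procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging_io import BoldSeries, Parcellation

logger = logging.getLogger(__name__)

ARTANH_CLIP = 1.0 - 1e-7

MODELS = ("negative", "positive", "combined")


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region matrix of Fisher-transformed correlations."""

    values: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} regions")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v[~np.eye(n, dtype=bool)])):
            raise ValueError("off-diagonal entries must be finite")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def edge(self, region_i: int, region_j: int) -> float:
        a = self.region_ids.index(region_i)
        b = self.region_ids.index(region_j)
        return float(self.values[a, b])


@dataclass
class EdgeMask:
    """Behaviour-correlated edges split by correlation sign."""

    positive_edges: frozenset[tuple[int, int]]
    negative_edges: frozenset[tuple[int, int]]
    selection_p: float

    def __post_init__(self) -> None:
        self.positive_edges = frozenset(tuple(sorted(e)) for e in self.positive_edges)
        self.negative_edges = frozenset(tuple(sorted(e)) for e in self.negative_edges)
        if self.positive_edges & self.negative_edges:
            raise ValueError("positive and negative edge sets must be disjoint")
        for i, j in self.positive_edges | self.negative_edges:
            if i == j:
                raise ValueError("self-pairs are not valid edges")


@dataclass
class CpmResult:
    predicted: np.ndarray
    observed: np.ndarray
    r_pred_obs: float
    model: str
    p_perm: float | None = None
    fold_masks: list[EdgeMask] = field(default_factory=list)
    fold_coefficients: list[np.ndarray] = field(default_factory=list)
    n_empty_folds: int = 0


# ---------------------------------------------------------------------------
# Connectivity construction
# ---------------------------------------------------------------------------

def build_connectivity(bold: BoldSeries, parc: Parcellation) -> ConnectivityMatrix:
    """Mean region series -> artanh(Pearson r) matrix, diagonal zero.

    Perfect correlations are clipped to artanh(1 - 1e-7) and flagged;
    zero-variance region series get zero edges and are flagged; regions with
    no voxels are an error listing the offending ids.
    """
    labels = parc.labels
    if tuple(labels.shape) != tuple(bold.spatial_shape):
        raise ValueError("parcellation does not match BOLD spatial shape")
    region_ids = parc.region_ids
    empty = [rid for rid in region_ids if not np.any(labels == rid)]
    if empty:
        raise ValueError(f"regions with no voxels: {empty}")
    series = np.stack([bold.data[labels == rid].mean(axis=0) for rid in region_ids]).astype(np.float64)
    sd = series.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("build_connectivity: %d zero-variance region series; edges set to 0",
                       int(flat.sum()))
    centered = series - series.mean(axis=1, keepdims=True)
    norm = np.where(flat, 1.0, np.linalg.norm(centered, axis=1))
    z = centered / norm[:, None]
    z[flat] = 0.0
    raw = z @ z.T
    off_diag = ~np.eye(len(series), dtype=bool)
    n_clipped = int(np.sum(off_diag & (np.abs(raw) > ARTANH_CLIP))) // 2
    if n_clipped:
        logger.warning("build_connectivity: %d edge(s) at |r| ~ 1 clipped before artanh", n_clipped)
    values = np.arctanh(np.clip(raw, -ARTANH_CLIP, ARTANH_CLIP))
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, region_ids=list(region_ids))


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Plain-text square matrix with a region-id header row."""
    import pandas as pd

    pd.DataFrame(matrix.values, columns=matrix.region_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path) -> ConnectivityMatrix:
    """Inverse of :func:`write_matrix`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ids = [int(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    # symmetrise away text round-off before validation
    values = (values + values.T) / 2.0
    return ConnectivityMatrix(values=values, region_ids=ids)


def _edge_index(matrices: list[ConnectivityMatrix]):
    ids = matrices[0].region_ids
    for m in matrices[1:]:
        if m.region_ids != ids:
            raise ValueError("all matrices must share one region list")
    iu = np.triu_indices(len(ids), k=1)
    pairs = [(ids[a], ids[b]) for a, b in zip(*iu)]
    X = np.stack([m.values[iu] for m in matrices])      # (n_subjects, n_edges)
    return X, pairs


# ---------------------------------------------------------------------------
# Edge selection and network strength
# ---------------------------------------------------------------------------

def select_edges(
    matrices: list[ConnectivityMatrix],
    behavior,
    p_threshold: float = 0.001,
) -> EdgeMask:
    """Edges whose across-subject correlation with behaviour beats p_threshold."""
    y = np.asarray(behavior, dtype=float)
    if len(matrices) < 4:
        raise ValueError("edge selection needs at least 4 subjects")
    if len(matrices) != len(y) or not np.all(np.isfinite(y)):
        raise ValueError("behavior must be finite and match the number of matrices")
    X, pairs = _edge_index(matrices)
    n = len(y)
    xs = X.std(axis=0)
    usable = xs > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.info("select_edges: %d zero-variance edges excluded", n_dropped)
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    if y_norm == 0:
        raise ValueError("behavior has zero variance")
    Xc = X - X.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (np.linalg.norm(Xc, axis=0) * y_norm)
    r = np.where(usable, r, 0.0)
    r_abs = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = r_abs * np.sqrt((n - 2) / (1.0 - r_abs**2))
    p = 2.0 * stats.t.sf(t, n - 2)
    sig = usable & (p < p_threshold)
    pos = frozenset(pairs[k] for k in np.flatnonzero(sig & (r > 0)))
    neg = frozenset(pairs[k] for k in np.flatnonzero(sig & (r < 0)))
    return EdgeMask(positive_edges=pos, negative_edges=neg, selection_p=p_threshold)


def network_strength(matrix: ConnectivityMatrix, mask: EdgeMask) -> tuple[float, float]:
    """(positive, negative) network strength: sum of edge values per selected set."""
    pos = sum(matrix.edge(i, j) for i, j in mask.positive_edges)
    neg = sum(matrix.edge(i, j) for i, j in mask.negative_edges)
    return float(pos), float(neg)


def _features(strengths: tuple[float, float], model: str) -> np.ndarray:
    pos, neg = strengths
    if model == "positive":
        return np.array([pos])
    if model == "negative":
        return np.array([neg])
    return np.array([pos, neg])


# ---------------------------------------------------------------------------
# Leave-one-out prediction
# ---------------------------------------------------------------------------

def loocv_predict(
    matrices: list[ConnectivityMatrix],
    behavior,
    p_threshold: float = 0.001,
    model: str = "negative",
) -> CpmResult:
    """Leave-one-out CPM: per fold, select edges and fit the strength model on
    the training subjects only, then predict the held-out subject.

    A fold whose selected-edge set (for the requested model) is empty predicts
    the training-mean behaviour and is counted in ``n_empty_folds``. If *every*
    fold is empty there is no connectome model at all; the prediction carries
    no edge information and ``r_pred_obs`` is reported as 0 (leave-one-out
    training means otherwise correlate with the observed values at exactly -1
    by construction, which would mistake a null for a strong signal).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    y = np.asarray(behavior, dtype=float)
    n = len(matrices)
    if n < 8:
        raise ValueError("leave-one-out CPM needs at least 8 subjects")
    predicted = np.empty(n)
    fold_masks: list[EdgeMask] = []
    fold_coefs: list[np.ndarray] = []
    n_empty = 0
    for s in range(n):
        train_idx = [i for i in range(n) if i != s]
        train_m = [matrices[i] for i in train_idx]
        train_y = y[train_idx]
        mask = select_edges(train_m, train_y, p_threshold)
        fold_masks.append(mask)
        relevant = (
            mask.negative_edges if model == "negative"
            else mask.positive_edges if model == "positive"
            else mask.positive_edges | mask.negative_edges
        )
        if not relevant:
            n_empty += 1
            predicted[s] = train_y.mean()
            fold_coefs.append(np.array([train_y.mean()]))
            continue
        F = np.stack([_features(network_strength(m, mask), model) for m in train_m])
        design = np.column_stack([np.ones(len(train_idx)), F])
        coef = np.linalg.lstsq(design, train_y, rcond=None)[0]
        fold_coefs.append(coef)
        f_test = _features(network_strength(matrices[s], mask), model)
        predicted[s] = coef[0] + f_test @ coef[1:]
    if n_empty:
        logger.debug("loocv_predict: %d/%d folds had no selected edges (predicted training mean)",
                     n_empty, n)
    if n_empty == n or np.std(predicted) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(predicted, y)[0, 1])
    return CpmResult(
        predicted=predicted, observed=y.copy(), r_pred_obs=r, model=model,
        fold_masks=fold_masks, fold_coefficients=fold_coefs, n_empty_folds=n_empty,
    )


def permutation_p(
    matrices: list[ConnectivityMatrix],
    behavior,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    p_threshold: float = 0.001,
    model: str = "negative",
) -> tuple[float, CpmResult]:
    """One-tailed permutation p for the LOOCV prediction correlation.

    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm); the full leave-one-out
    procedure is repeated for every permuted behaviour vector.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = rng or np.random.default_rng()
    y = np.asarray(behavior, dtype=float)
    result = loocv_predict(matrices, y, p_threshold, model)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        r_perm = loocv_predict(matrices, y[perm], p_threshold, model).r_pred_obs
        if r_perm >= result.r_pred_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    result.p_perm = p
    return p, result
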