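"""Voxel-wise resting-state metrics: regional homogeneity and degree centrality.

Regional homogeneity (ReHo) is Kendall's coefficient of concordance W between
a voxel's time series and its spatial neighbours (default: the centre voxel
plus its nearest 26 neighbours). Maps are then normalised by the whole-brain
mean and smoothed with a Gaussian kernel (default 4 mm FWHM) — in that order:
W is computed on unsmoothed data.

Degree centrality (DC) sums, for every in-mask voxel, its supra-threshold
positive Pearson correlations with all other in-mask voxels (default
threshold r > 0.25); negative correlations never contribute. The raw sums
are then standardised, by default as an in-mask z-score (the usual reading
of "Fisher-Z transformation" for DC maps, since artanh of a sum of
correlations is undefined past 1); an artanh-of-mean-r variant is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .imaging_io import BoldSeries, BrainMask, MetricMap

logger = logging.getLogger(__name__)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RehoParams:
    """Neighbourhood size for Kendall's W: 7 (faces), 19 (faces+edges) or 27 (full cube)."""

    neighborhood: int = 27

    def __post_init__(self) -> None:
        if self.neighborhood not in (7, 19, 27):
            raise ValueError("neighborhood must be 7, 19 or 27")


@dataclass(frozen=True)
class DcParams:
    r_threshold: float = 0.25
    weighting: str = "weighted_sum"           # or "binary_count"
    standardization: str = "zscore"           # or "fisher_artanh_mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie strictly between 0 and 1")
        if self.weighting not in ("weighted_sum", "binary_count"):
            raise ValueError("weighting must be 'weighted_sum' or 'binary_count'")
        if self.standardization not in ("zscore", "fisher_artanh_mean"):
            raise ValueError("standardization must be 'zscore' or 'fisher_artanh_mean'")


def neighborhood_offsets(neighborhood: int) -> list[tuple[int, int, int]]:
    """Voxel offsets of the cubic neighbourhood, centre included."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                nz = sum(1 for d in (dx, dy, dz) if d != 0)
                if neighborhood == 7 and nz > 1:
                    continue
                if neighborhood == 19 and nz > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def _tie_correction(series: np.ndarray) -> float:
    """Kendall's tie term sum(t^3 - t) over groups of tied values in one series."""
    vals, counts = np.unique(series, return_counts=True)
    tied = counts[counts > 1].astype(float)
    return float(np.sum(tied**3 - tied))


# ---------------------------------------------------------------------------
# ReHo
# ---------------------------------------------------------------------------

def compute_reho(bold: BoldSeries, mask: BrainMask, params: RehoParams | None = None) -> MetricMap:
    """Kendall's W of each in-mask voxel with its in-mask cubic neighbours.

    With K neighbouring series of length n ranked independently (mean ranks
    for ties), the rank sums R_t across the neighbourhood give

        W = 12 * sum_t (R_t - K(n+1)/2)^2 / (K^2 (n^3 - n) - K * sum T_j)

    where T_j is series j's tie correction. Neighbours outside the mask are
    dropped (K shrinks at mask edges). A voxel with K = 1, or an all-tied
    neighbourhood (zero denominator), gets W = 0.
    """
    params = params or RehoParams()
    mask.check_congruent(bold.spatial_shape)
    n = bold.n_timepoints
    if n < 3:
        raise ValueError("ReHo needs at least 3 timepoints")
    m = mask.data
    shape = m.shape

    # Rank every voxel's series along time (mean ranks at ties); zero outside mask.
    ranks = np.zeros(bold.data.shape, dtype=np.float64)
    ranks[m] = rankdata(bold.data[m], axis=-1)

    ties = np.zeros(shape, dtype=np.float64)
    idx = np.argwhere(m)
    for x, y, z in idx:
        ties[x, y, z] = _tie_correction(bold.data[x, y, z])

    offsets = neighborhood_offsets(params.neighborhood)
    pad_ranks = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pad_mask = np.pad(m.astype(np.float64), 1)
    pad_ties = np.pad(ties, 1)

    sx, sy, sz = shape
    K = np.zeros(shape, dtype=np.float64)
    T = np.zeros(shape, dtype=np.float64)
    sum_sq = np.zeros(shape, dtype=np.float64)   # sum_t R_t^2 accumulated below
    r_sum = np.zeros((*shape, n), dtype=np.float64)
    for dx, dy, dz in offsets:
        K += pad_mask[1 + dx : 1 + dx + sx, 1 + dy : 1 + dy + sy, 1 + dz : 1 + dz + sz]
        T += pad_ties[1 + dx : 1 + dx + sx, 1 + dy : 1 + dy + sy, 1 + dz : 1 + dz + sz]
        r_sum += pad_ranks[1 + dx : 1 + dx + sx, 1 + dy : 1 + dy + sy, 1 + dz : 1 + dz + sz, :]
    r_bar = K * (n + 1) / 2.0
    sum_sq = np.sum((r_sum - r_bar[..., None]) ** 2, axis=-1)

    denom = K**2 * (n**3 - n) - K * T
    w = np.zeros(shape, dtype=np.float64)
    valid = m & (K > 1) & (denom > 0)
    w[valid] = 12.0 * sum_sq[valid] / denom[valid]
    w = np.clip(w, 0.0, 1.0)
    return MetricMap(
        data=w,
        metric_kind="reho",
        mask=mask,
        affine=bold.affine,
        provenance={"operation": "compute_reho", "neighborhood": params.neighborhood},
    )


def normalize_map(metric: MetricMap, mask: BrainMask | None = None) -> MetricMap:
    """Divide by the whole-brain (in-mask) mean, so the in-mask mean becomes 1."""
    mask = mask or metric.mask
    mask.check_congruent(metric.data.shape)
    values = metric.data[mask.data]
    mean = float(values.mean())
    if mean == 0.0:
        raise ValueError("cannot normalize: in-mask mean is zero")
    out = np.zeros_like(metric.data, dtype=np.float64)
    out[mask.data] = metric.data[mask.data] / mean
    kind = "reho_normalized" if metric.metric_kind == "reho" else metric.metric_kind
    return MetricMap(
        data=out,
        metric_kind=kind,
        mask=mask,
        affine=metric.affine,
        provenance={**metric.provenance, "normalized_by_mean": mean},
    )


def smooth_map(metric: MetricMap, fwhm_mm: float = 4.0, voxel_size_mm=(3.0, 3.0, 3.0)) -> MetricMap:
    """Mask-restricted Gaussian smoothing with edge renormalisation.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) / voxel size. Kernel weight
    falling outside the mask is redistributed by dividing by the smoothed
    mask, so a constant in-mask map is left unchanged and fwhm 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return metric
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    sigma = fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / voxel_size
    m = metric.mask.data.astype(np.float64)
    num = ndimage.gaussian_filter(metric.data * m, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    out = np.zeros_like(num)
    inside = metric.mask.data
    out[inside] = num[inside] / den[inside]
    return MetricMap(
        data=out,
        metric_kind=metric.metric_kind,
        mask=metric.mask,
        affine=metric.affine,
        provenance={**metric.provenance, "smoothed_fwhm_mm": fwhm_mm},
    )


# ---------------------------------------------------------------------------
# Degree centrality
# ---------------------------------------------------------------------------

def compute_dc(
    bold: BoldSeries,
    mask: BrainMask,
    params: DcParams | None = None,
    standardize: bool = True,
) -> MetricMap:
    """Degree centrality: per-voxel sum (or count) of supra-threshold positive correlations.

    Zero-variance series are flagged and contribute zero correlations.
    ``standardize=False`` returns the raw non-negative sums (used by the
    brute-force equivalence tests).
    """
    params = params or DcParams()
    mask.check_congruent(bold.spatial_shape)
    if bold.n_timepoints < 3:
        raise ValueError("DC needs at least 3 timepoints")
    m = mask.data
    series = bold.data[m].astype(np.float64)           # (V, t)
    n_vox = series.shape[0]
    if n_vox < 2:
        raise ValueError("DC needs at least 2 in-mask voxels")

    sd = series.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("compute_dc: %d zero-variance voxel series; their correlations set to 0", int(flat.sum()))
    centered = series - series.mean(axis=1, keepdims=True)
    norm = np.where(sd > 0, np.linalg.norm(centered, axis=1), 1.0)
    z = centered / norm[:, None]
    z[flat] = 0.0
    corr = z @ z.T
    np.fill_diagonal(corr, 0.0)                         # self-correlation excluded

    supra = corr > params.r_threshold
    if params.weighting == "weighted_sum":
        dc = np.sum(corr * supra, axis=1)
    else:
        dc = np.sum(supra, axis=1).astype(np.float64)

    if standardize:
        if params.standardization == "zscore":
            mu, s = dc.mean(), dc.std(ddof=1)
            dc = (dc - mu) / s if s > 0 else np.zeros_like(dc)
        else:  # artanh of the mean supra-threshold correlation per voxel
            counts = np.maximum(np.sum(supra, axis=1), 1)
            mean_r = np.sum(corr * supra, axis=1) / counts
            dc = np.arctanh(np.clip(mean_r, 0.0, 1.0 - 1e-7))

    out = np.zeros(m.shape, dtype=np.float64)
    out[m] = dc
    return MetricMap(
        data=out,
        metric_kind="dc",
        mask=mask,
        affine=bold.affine,
        provenance={
            "operation": "compute_dc",
            "r_threshold": params.r_threshold,
            "weighting": params.weighting,
            "standardization": params.standardization if standardize else "none",
        },
    )
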