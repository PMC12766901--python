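"""Scalar and voxel-wise group statistics.

Scalar tests mirror a standard clinical baseline table: pooled-variance
Student t (from raw samples or from printed summary statistics), Pearson
chi-square on 2x2 counts, partial correlation with nuisance covariates and
Bonferroni adjustment.

Voxel-wise inference runs an ordinary least squares GLM per voxel (group
indicators plus age / gender / education / framewise-displacement
covariates), with contrasts giving t maps, a nested-model F map for
three-group comparisons, and multiple-comparison control by permutation
max-cluster-extent inference: supra-threshold clusters of the observed map
are compared against the distribution of the largest cluster obtained when
subject maps are permuted relative to the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .imaging_io import BrainMask, MetricMap


@dataclass
class TTestResult:
    t: float
    dof: float
    p: float


@dataclass
class Cluster:
    peak_voxel: tuple[int, int, int]
    peak_world: tuple[float, float, float]
    extent: int
    peak_stat: float
    corrected_p: float
    voxels: np.ndarray | None = None      # (extent, 3) member voxel coordinates


@dataclass
class ClusterResult:
    """Supra-threshold clusters with permutation-corrected p-values."""

    clusters: list[Cluster] = field(default_factory=list)
    voxel_threshold: float = np.nan
    n_permutations: int = 0

    def significant(self, cluster_p: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p < cluster_p]


# ---------------------------------------------------------------------------
# Scalar tests
# ---------------------------------------------------------------------------

def two_sample_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance Student t from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / dof
    if sp2 == 0:
        if mean1 == mean2:
            return TTestResult(t=0.0, dof=dof, p=1.0)
        raise ValueError("zero pooled variance with unequal means is degenerate")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return TTestResult(t=float(t), dof=dof, p=float(p))


def two_sample_t(sample1, sample2) -> TTestResult:
    """Pooled-variance Student t from raw samples."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    return two_sample_t_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def chi_square_2x2(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after residualising both on the covariates.

    p-value from t = r * sqrt((n - k - 2) / (1 - r^2)) with dof = n - k - 2,
    k = number of covariates. With no covariates this is the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, k={k})")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    design = np.column_stack([np.ones(n), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the covariates has no residual variation
    # left to correlate: its partial correlation is 0 by convention
    if rx.std() <= 1e-12 * x.std() or ry.std() <= 1e-12 * y.std():
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_clipped = min(abs(r), 1.0 - 1e-15)
    t = r_clipped * np.sqrt(dof / (1.0 - r_clipped**2))
    p = 2.0 * stats.t.sf(t, dof)
    return r, float(p)


def bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: adjusted = min(1, p * m); reject where adjusted < alpha."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="bonferroni")
    return adjusted, adjusted < alpha


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def design_matrix(
    groups: list[str],
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one indicator per non-reference group + covariate columns.

    Groups are dummy-coded against the alphabetically first group. Raises on
    rank deficiency, naming the collinear columns.
    """
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    cols = [np.ones(len(groups))]
    names = ["intercept"]
    for level in levels[1:]:
        cols.append(np.array([1.0 if g == level else 0.0 for g in groups]))
        names.append(f"group[{level}]")
    if covariates is not None:
        for col in covariates.columns:
            cols.append(covariates[col].to_numpy(dtype=float))
            names.append(str(col))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def group_contrast(names: list[str], group_a: str, group_b: str) -> np.ndarray:
    """Contrast vector testing mean(group_a) - mean(group_b)."""
    c = np.zeros(len(names))
    found = False
    for label, sign in ((group_a, 1.0), (group_b, -1.0)):
        col = f"group[{label}]"
        if col in names:
            c[names.index(col)] = sign
            found = True
        # the reference group has no column: its coefficient is absorbed in
        # the intercept, so its entry stays 0
    if not found:
        raise ValueError(f"neither {group_a!r} nor {group_b!r} has a design column")
    return c


# ---------------------------------------------------------------------------
# Voxel-wise GLM
# ---------------------------------------------------------------------------

def _stack_maps(maps: list[MetricMap]) -> tuple[np.ndarray, BrainMask]:
    mask = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask.data, mask.data):
            raise ValueError("all maps must share one mask")
    Y = np.stack([m.in_mask_values().astype(np.float64) for m in maps])
    return Y, mask


def _glm_t(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistics per voxel for contrast c; Y is (n_subjects, n_voxels)."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    denom = np.sqrt(np.maximum(c @ xtx_inv @ c, 0.0) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (c @ beta) / denom, 0.0)
    return t, dof


def voxelwise_glm(
    maps: list[MetricMap],
    X: np.ndarray,
    contrast: np.ndarray,
    names: list[str] | None = None,
) -> tuple[MetricMap, int]:
    """Per-voxel OLS t map for the given contrast; returns (t map, dof)."""
    Y, mask = _stack_maps(maps)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design rows must match number of maps")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    t, dof = _glm_t(Y, np.asarray(X, dtype=float), np.asarray(contrast, dtype=float))
    out = np.zeros(mask.data.shape)
    out[mask.data] = t
    tmap = MetricMap(data=out, metric_kind="tstat", mask=mask, affine=maps[0].affine,
                     provenance={"operation": "voxelwise_glm", "dof": dof})
    return tmap, dof


def anova_oneway_map(
    maps: list[MetricMap],
    groups: list[str],
    covariates: pd.DataFrame | None = None,
) -> tuple[MetricMap, dict[tuple[str, str], MetricMap]]:
    """Nested-model one-way ANOVA F map plus pairwise post hoc t maps.

    F compares the covariate-only model against covariates + group factor.
    Post hoc t maps come from the full-model pairwise group contrasts
    (unrestricted: not masked to ANOVA-significant voxels).
    """
    levels = sorted(set(groups))
    if len(levels) != 3:
        raise ValueError("one-way ANOVA map expects exactly 3 groups")
    for level in levels:
        if groups.count(level) < 2:
            raise ValueError(f"group {level!r} needs n >= 2")
    Y, mask = _stack_maps(maps)
    n = Y.shape[0]

    X_full, names = design_matrix(groups, covariates)
    X_red = np.delete(
        X_full, [names.index(f"group[{lv}]") for lv in levels[1:]], axis=1
    )

    def rss(X):
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        r = Y - X @ beta
        return np.sum(r**2, axis=0)

    rss_full, rss_red = rss(X_full), rss(X_red)
    q = len(levels) - 1
    dof_full = n - X_full.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(rss_full > 0, ((rss_red - rss_full) / q) / (rss_full / dof_full), 0.0)
    f = np.maximum(f, 0.0)
    fout = np.zeros(mask.data.shape)
    fout[mask.data] = f
    fmap = MetricMap(data=fout, metric_kind="fstat", mask=mask, affine=maps[0].affine,
                     provenance={"operation": "anova_oneway_map", "dof": (q, dof_full)})

    posthoc: dict[tuple[str, str], MetricMap] = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = group_contrast(names, levels[i], levels[j])
            tmap, _ = voxelwise_glm(maps, X_full, c, names)
            posthoc[(levels[i], levels[j])] = tmap
    return fmap, posthoc


# ---------------------------------------------------------------------------
# Permutation cluster-extent correction
# ---------------------------------------------------------------------------

def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        s = np.ones((3, 3, 3), dtype=bool)
        for corner in np.ndindex(3, 3, 3):
            if all(c != 1 for c in corner):
                s[corner] = False
        return s
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def _max_cluster_extent(supra: np.ndarray, structure: np.ndarray) -> int:
    labeled, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))))


def cluster_correct(
    maps: list[MetricMap],
    X: np.ndarray,
    contrast: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    connectivity: int = 26,
) -> tuple[MetricMap, ClusterResult]:
    """Permutation max-cluster-extent correction of a voxel-wise contrast map.

    The observed t map is thresholded two-tailed at the ``voxel_p`` Student-t
    quantile and its 26-connected supra-threshold clusters are measured. The
    null distribution of the maximum cluster extent is built by permuting the
    subject maps relative to the design (full-exchangeability null) and
    re-running the identical GLM + thresholding; each observed cluster gets

        corrected_p = (1 + #{perm max extent >= observed extent}) / (1 + n_perm).

    Returns (observed t map, cluster result with all supra-threshold clusters;
    use ``.significant(cluster_p)`` for the reported set).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng or np.random.default_rng()
    Y, mask = _stack_maps(maps)
    X = np.asarray(X, dtype=float)
    c = np.asarray(contrast, dtype=float)
    t_obs, dof = _glm_t(Y, X, c)
    t_crit = stats.t.isf(voxel_p / 2.0, dof)
    structure = _connectivity_structure(connectivity)

    def supra_volume(t_flat):
        vol = np.zeros(mask.data.shape)
        vol[mask.data] = t_flat
        return vol

    vol_obs = supra_volume(t_obs)
    clusters: list[tuple[tuple[int, int, int], int, float, np.ndarray]] = []
    for sign in (1.0, -1.0):
        supra = (sign * vol_obs > t_crit) & mask.data
        labeled, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            where = labeled == lab
            extent = int(where.sum())
            coords = np.argwhere(where)
            stats_vals = vol_obs[tuple(coords.T)]
            peak_flat = int(np.argmax(np.abs(stats_vals)))
            peak = tuple(int(v) for v in coords[peak_flat])
            clusters.append((peak, extent, float(stats_vals[peak_flat]), coords))

    n_sub = Y.shape[0]
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_sub)
        t_perm, _ = _glm_t(Y[perm], X, c)
        vol = supra_volume(t_perm)
        null_max[i] = _max_cluster_extent((np.abs(vol) > t_crit) & mask.data, structure)

    affine = maps[0].affine
    result = ClusterResult(voxel_threshold=float(t_crit), n_permutations=n_perm)
    for peak, extent, peak_stat, coords in sorted(clusters, key=lambda c: -c[1]):
        corrected = (1.0 + np.sum(null_max >= extent)) / (1.0 + n_perm)
        world = tuple(float(v) for v in (affine @ np.array([*peak, 1.0]))[:3])
        result.clusters.append(
            Cluster(peak_voxel=peak, peak_world=world, extent=extent,
                    peak_stat=peak_stat, corrected_p=float(corrected), voxels=coords)
        )

    tmap = MetricMap(data=vol_obs, metric_kind="tstat", mask=mask, affine=affine,
                     provenance={"operation": "cluster_correct", "dof": dof,
                                 "voxel_p": voxel_p, "n_perm": n_perm})
    return tmap, result


def cluster_table(result: ClusterResult, cluster_p: float = 0.05) -> pd.DataFrame:
    """Cluster report as a DataFrame (peak world coords, extent, peak stat, corrected p)."""
    rows = [
        {
            "peak_x": c.peak_world[0], "peak_y": c.peak_world[1], "peak_z": c.peak_world[2],
            "n_voxels": c.extent, "peak_stat": c.peak_stat, "corrected_p": c.corrected_p,
            "significant": c.corrected_p < cluster_p,
        }
        for c in result.clusters
    ]
    return pd.DataFrame(rows)
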