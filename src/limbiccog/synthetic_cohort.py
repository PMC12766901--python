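"""Synthetic BOLD cohorts, toy parcellations and clinical-score tables.

Every downstream stage of the pipeline (local-coherence maps, hub maps,
connectome-based prediction, reliable-change grouping, classification) is
exercised against cohorts generated here with *planted, known* effects:

* local temporal coherence planted in chosen regions (raises Kendall's-W
  regional homogeneity there),
* a broadcast latent signal that makes chosen "hub" regions correlate with
  the whole brain (raises degree centrality there),
* a behavioural score coupled to chosen connectome edges (gives
  connectome-based predictive modeling a ground truth),
* clinical score tables whose per-group sample mean and SD match requested
  values exactly (moment matching), so summary-statistic tests become
  deterministic.

Determinism contract: identical (design, seed) produces a bit-identical
cohort. One master seed spawns an independent stream per subject by counter;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .imaging_io import (
    BoldSeries,
    BrainMask,
    Parcellation,
    SubjectRecord,
    write_mask,
    write_parcellation,
    write_subject_table,
    write_volume,
)

#: Regional coherence given to regions without a planted effect. Real grey
#: matter is never locally incoherent, so the no-effect floor is small but
#: nonzero; planted boosts add on top of it.
BASE_COHERENCE = 0.2

#: Coupling of the hub latent into non-hub regions, as a fraction of
#: ``hub_strength``. Hubs carry the latent at full strength; the rest of the
#: brain receives a weak echo so that hub voxels correlate with everything.
HUB_BROADCAST_FRACTION = 0.3

#: Baseline group summary statistics (mean, SD) for the simulated clinic:
#: healthy controls (n=55) vs drug-naive bipolar patients (n=92), plus the
#: demographic covariates. Used as *inputs* to the moment-matched generator.
BASELINE_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "HC": {
        "age": (20.60, 1.62),
        "education": (14.32, 1.04),
        "fd": (0.07, 0.02),
        "rbans_t": (94.38, 9.27),
        "rbans_total": (481.75, 34.73),
        "immediate_memory": (98.04, 13.90),
        "story_memory": (17.55, 3.17),
        "delayed_memory": (95.00, 6.03),
    },
    "BD": {
        "age": (20.55, 3.96),
        "education": (13.89, 2.06),
        "fd": (0.08, 0.03),
        "rbans_t": (84.55, 10.32),
        "rbans_total": (442.16, 42.21),
        "immediate_memory": (83.82, 14.01),
        "story_memory": (13.88, 3.92),
        "delayed_memory": (87.61, 10.52),
    },
}

#: Follow-up score summaries for the patient group. A modest mean gain with
#: widened spread yields a realistic mix of reliably improved and
#: non-improved patients under the reliable-change / cutoff rule.
FOLLOWUP_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "BD": {
        "rbans_t@week12": (90.00, 12.00),
        "rbans_t@week24": (92.00, 12.00),
    },
}

#: Observed male counts per group in the simulated clinic (males, total).
BASELINE_GENDER_COUNTS = {"HC": (20, 55), "BD": (25, 92)}

DEFAULT_GROUP_SIZES = {"HC": 55, "BD": 92}


class DesignError(ValueError):
    """Raised for invalid cohort designs."""


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort with planted effects.

    ``reho_effect_regions`` get ``coherence_boost`` extra within-region
    temporal coherence for subjects in ``effect_group``; ``dc_hub_regions``
    broadcast a shared latent series at ``hub_strength``; ``behavior_edges``
    couple the behavioural score to connectome edges.
    """

    n_bd: int = 10
    n_hc: int = 10
    grid_shape: tuple[int, int, int] = (9, 9, 9)
    n_timepoints: int = 100
    tr_seconds: float = 2.0
    n_regions: int = 8
    reho_effect_regions: frozenset[int] = frozenset()
    coherence_boost: float = 0.0
    effect_group: str = "BD"
    dc_hub_regions: frozenset[int] = frozenset()
    hub_strength: float = 0.0
    behavior_edges: tuple[tuple[int, int, float], ...] = ()
    behavior_noise_sd: float = 1.0
    edge_coupling: float = 0.0
    edge_coupling_sd: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.reho_effect_regions = frozenset(self.reho_effect_regions)
        self.dc_hub_regions = frozenset(self.dc_hub_regions)
        self.behavior_edges = tuple((int(i), int(j), float(w)) for i, j, w in self.behavior_edges)
        if self.n_regions < 2:
            raise DesignError("n_regions must be >= 2")
        if self.n_bd < 0 or self.n_hc < 0:
            raise DesignError("group sizes must be non-negative")
        if self.n_timepoints < 2:
            raise DesignError("n_timepoints must be >= 2")
        if self.noise_sd <= 0 and self.noise_sd != 0:
            raise DesignError("noise_sd must be >= 0")
        if not 0 <= self.coherence_boost <= 1:
            raise DesignError("coherence_boost must lie in [0, 1]")
        if not 0 <= self.hub_strength <= 1:
            raise DesignError("hub_strength must lie in [0, 1]")
        if self.edge_coupling < 0 or self.edge_coupling_sd < 0:
            raise DesignError("edge_coupling and edge_coupling_sd must be >= 0")
        region_range = range(1, self.n_regions + 1)
        for rid in self.reho_effect_regions | self.dc_hub_regions:
            if rid not in region_range:
                raise DesignError(f"region id {rid} outside 1..{self.n_regions}")
        seen = set()
        for i, j, _ in self.behavior_edges:
            if i == j:
                raise DesignError("behavior edges must join distinct regions")
            if not (i in region_range and j in region_range):
                raise DesignError(f"behavior edge ({i},{j}) outside 1..{self.n_regions}")
            key = frozenset((i, j))
            if key in seen:
                raise DesignError(f"behavior edge ({i},{j}) listed twice")
            seen.add(key)

    # -- serialisation (flat key/value YAML) --------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_bd": self.n_bd,
            "n_hc": self.n_hc,
            "grid_shape": list(self.grid_shape),
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "n_regions": self.n_regions,
            "reho_effect_regions": sorted(self.reho_effect_regions),
            "coherence_boost": self.coherence_boost,
            "effect_group": self.effect_group,
            "dc_hub_regions": sorted(self.dc_hub_regions),
            "hub_strength": self.hub_strength,
            "behavior_edges": [list(e) for e in self.behavior_edges],
            "behavior_noise_sd": self.behavior_noise_sd,
            "edge_coupling": self.edge_coupling,
            "edge_coupling_sd": self.edge_coupling_sd,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        doc = yaml.safe_load(Path(path).read_text())
        doc["grid_shape"] = tuple(doc.get("grid_shape", (9, 9, 9)))
        doc["behavior_edges"] = tuple(tuple(e) for e in doc.get("behavior_edges", ()))
        doc["reho_effect_regions"] = frozenset(doc.get("reho_effect_regions", ()))
        doc["dc_hub_regions"] = frozenset(doc.get("dc_hub_regions", ()))
        return cls(**doc)


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Independent per-subject stream spawned from the master seed by counter."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(subject_index)]))


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def _factor_triples(n: int):
    for a in range(1, n + 1):
        if n % a:
            continue
        m = n // a
        for b in range(1, m + 1):
            if m % b:
                continue
            yield a, b, m // b


def make_parcellation(design: CohortDesign) -> tuple[Parcellation, BrainMask]:
    """Tile the grid into ``n_regions`` contiguous blocks covering the whole mask.

    The region count is factorised into per-axis split counts chosen to keep
    blocks as cubic as the grid allows; each axis is then divided into
    near-equal slabs. Every region id 1..n_regions is present and region sizes
    sum to the mask size.
    """
    shape = tuple(design.grid_shape)
    n_vox = int(np.prod(shape))
    if n_vox < 8 * design.n_regions:
        raise DesignError(
            f"grid {shape} has {n_vox} voxels; cannot give {design.n_regions} regions >= 8 voxels each"
        )

    best, best_cost = None, None
    for a, b, c in _factor_triples(design.n_regions):
        if a > shape[0] or b > shape[1] or c > shape[2]:
            continue
        # block aspect: prefer splits proportional to the grid
        sides = (shape[0] / a, shape[1] / b, shape[2] / c)
        cost = max(sides) / min(sides)
        if np.floor(shape[0] / a) * np.floor(shape[1] / b) * np.floor(shape[2] / c) < 8:
            continue
        if best_cost is None or cost < best_cost:
            best, best_cost = (a, b, c), cost
    if best is None:
        raise DesignError(
            f"cannot tile grid {shape} into {design.n_regions} contiguous blocks of >= 8 voxels"
        )

    labels = np.zeros(shape, dtype=np.int32)
    edges = [np.array_split(np.arange(s), k) for s, k in zip(shape, best)]
    rid = 1
    for ix in edges[0]:
        for iy in edges[1]:
            for iz in edges[2]:
                labels[np.ix_(ix, iy, iz)] = rid
                rid += 1
    table = [(r, f"region_{r:03d}") for r in range(1, design.n_regions + 1)]
    return Parcellation(labels=labels, region_table=table), BrainMask(np.ones(shape, dtype=bool))


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def simulate_bold(
    design: CohortDesign,
    subject_group: str,
    rng: np.random.Generator,
    parcellation: Parcellation | None = None,
    subject_id: str = "synthetic",
) -> BoldSeries:
    """Simulate one subject's 4D BOLD series with the design's planted structure.

    Each voxel v in region r follows

        x_v(t) = c_r * s_r(t) + w_r * h(t) + noise_sd * eps_v(t)

    with s_r an independent standard-normal region signal, h a single latent
    series shared brain-wide, and eps_v white voxel noise. The coherence
    c_r is ``BASE_COHERENCE`` plus ``coherence_boost`` when r carries a
    planted effect for this subject's group; w_r is ``hub_strength`` for hub
    regions and a weak broadcast echo elsewhere, which is what makes hub
    voxels correlate with the entire brain.

    When behaviour edges are planted with a nonzero ``edge_coupling``, the
    two regions of each edge additionally share a per-edge latent series at
    subject-specific amplitude a = max(0, edge_coupling + edge_coupling_sd*g),
    g ~ N(0,1) one trait draw per subject. The trait makes the planted edges'
    connectivity covary across subjects, which is the between-subject signal
    connectome-behaviour prediction feeds on.
    """
    if parcellation is None:
        parcellation, _ = make_parcellation(design)
    shape = tuple(design.grid_shape)
    if tuple(parcellation.labels.shape) != shape:
        raise DesignError("parcellation does not match the design grid")
    t = design.n_timepoints
    r_ids = parcellation.region_ids

    region_signals = {rid: rng.standard_normal(t) for rid in r_ids}
    hub_latent = rng.standard_normal(t)

    edge_extra: dict[int, np.ndarray] = {}
    if design.behavior_edges and (design.edge_coupling > 0 or design.edge_coupling_sd > 0):
        trait = rng.standard_normal()
        amplitude = max(0.0, design.edge_coupling + design.edge_coupling_sd * trait)
        for i, j, _w in design.behavior_edges:
            latent = rng.standard_normal(t)
            for rid in (i, j):
                edge_extra[rid] = edge_extra.get(rid, np.zeros(t)) + amplitude * latent

    data = np.empty((*shape, t), dtype=np.float32)
    noise = rng.standard_normal((*shape, t))
    for rid in r_ids:
        where = parcellation.labels == rid
        c = BASE_COHERENCE
        if rid in design.reho_effect_regions and subject_group == design.effect_group:
            c = BASE_COHERENCE + design.coherence_boost
        if design.dc_hub_regions:
            w = design.hub_strength if rid in design.dc_hub_regions else (
                HUB_BROADCAST_FRACTION * design.hub_strength
            )
        else:
            w = 0.0
        series = c * region_signals[rid] + w * hub_latent
        if rid in edge_extra:
            series = series + edge_extra[rid]
        data[where] = series[None, :] + design.noise_sd * noise[where]
    return BoldSeries(
        subject_id=subject_id,
        data=data,
        voxel_size_mm=np.array([3.0, 3.0, 3.0]),
        tr_seconds=design.tr_seconds,
    )


def simulate_behavior(
    design: CohortDesign,
    connectivity: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Behaviour score coupled to the design's connectome edges.

    behavior = sum_e weight_e * edge_value_e + Gaussian(0, behavior_noise_sd).
    ``connectivity`` is the (n_regions, n_regions) matrix; edge (i, j) uses
    1-based region ids.
    """
    conn = np.asarray(connectivity, dtype=float)
    if conn.shape != (design.n_regions, design.n_regions):
        raise DesignError(
            f"connectivity shape {conn.shape} does not match n_regions={design.n_regions}"
        )
    total = 0.0
    for i, j, w in design.behavior_edges:
        total += w * conn[i - 1, j - 1]
    return float(total + design.behavior_noise_sd * rng.standard_normal())


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

def _moment_match(draws: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale draws so the sample mean and SD (ddof=1) match exactly."""
    z = (draws - draws.mean()) / draws.std(ddof=1)
    return mean + sd * z


def simulate_clinical_scores(
    group_stats: dict[str, dict[str, tuple[float, float]]],
    n_per_group: dict[str, int],
    seed: int,
    gender_counts: dict[str, tuple[int, int]] | None = None,
) -> list[SubjectRecord]:
    """Generate subject records whose per-group sample moments match exactly.

    ``group_stats`` maps group -> stat name -> (mean, sd). Stat names ``age``,
    ``education`` and ``fd`` populate the covariate fields; any other name is
    a cognitive score at baseline, unless suffixed ``@week12``/``@week24`` for
    a follow-up visit. Scores are drawn Gaussian then affinely rescaled so the
    sample mean and SD equal the request to ~1e-9 regardless of seed.
    ``gender_counts`` assigns exactly (males, total) gender codes per group
    (gender coded 1 = male, 0 = female), shuffled within the group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC11]))
    records: list[SubjectRecord] = []
    for group in sorted(group_stats):
        n = int(n_per_group[group])
        if n < 2:
            raise DesignError(f"group {group!r}: need n >= 2 for moment matching, got {n}")
        stats = group_stats[group]
        columns: dict[str, np.ndarray] = {}
        for name in sorted(stats):
            mean, sd = stats[name]
            if sd <= 0:
                raise DesignError(f"{group}/{name}: sd must be positive")
            columns[name] = _moment_match(rng.standard_normal(n), float(mean), float(sd))
        if gender_counts and group in gender_counts:
            males, total = gender_counts[group]
            if total != n:
                raise DesignError(f"group {group!r}: gender total {total} != n {n}")
            genders = np.array([1] * males + [0] * (n - males))
            rng.shuffle(genders)
        else:
            genders = (rng.random(n) < 0.5).astype(int)
        for i in range(n):
            covs = {"age": np.nan, "education": np.nan, "fd": np.nan}
            scores: dict[str, dict[str, float]] = {}
            for name, values in columns.items():
                if name in covs:
                    covs[name] = float(values[i])
                    continue
                if "@" in name:
                    score, visit = name.split("@", 1)
                else:
                    score, visit = name, "baseline"
                scores.setdefault(score, {})[visit] = float(values[i])
            # moment matching can push fd/education below their floors; clip
            # would break the moments, so leave values as generated and only
            # guard the physically impossible (handled by record validation
            # via nan-tolerant checks).
            records.append(
                SubjectRecord(
                    subject_id=f"{group}_{i:03d}",
                    group=group,
                    age=covs["age"],
                    gender=int(genders[i]),
                    education=max(covs["education"], 0.0) if np.isfinite(covs["education"]) else covs["education"],
                    fd=max(covs["fd"], 0.0) if np.isfinite(covs["fd"]) else covs["fd"],
                    scores=scores,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Whole-cohort writer (CLI / pipeline entry)
# ---------------------------------------------------------------------------

def write_cohort(design: CohortDesign, out_dir: str | Path) -> dict:
    """Simulate and write a full cohort: per-subject BOLD, parcellation, mask, table.

    Returns a manifest dict listing every artifact path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc, mask = make_parcellation(design)
    write_parcellation(parc, out / "parcellation.nii.gz")
    write_mask(mask, out / "mask.nii.gz")

    groups = ["BD"] * design.n_bd + ["HC"] * design.n_hc
    n_per_group = {"BD": design.n_bd, "HC": design.n_hc}
    stats = {
        g: {**BASELINE_GROUP_STATS[g], **FOLLOWUP_GROUP_STATS.get(g, {})}
        for g in n_per_group
        if n_per_group[g] >= 2
    }
    records = simulate_clinical_scores(
        stats, {g: n_per_group[g] for g in stats}, seed=design.seed
    )
    by_group: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)

    bold_paths = []
    assigned: list[SubjectRecord] = []
    counters = {g: 0 for g in n_per_group}
    for idx, group in enumerate(groups):
        rec = by_group[group][counters[group]]
        counters[group] += 1
        rng = subject_rng(design.seed, idx)
        bold = simulate_bold(design, group, rng, parc, subject_id=rec.subject_id)
        p = out / f"{rec.subject_id}_bold.nii.gz"
        write_volume(bold, p)
        bold_paths.append(str(p))
        assigned.append(rec)
    write_subject_table(assigned, out / "subjects.tsv")
    return {
        "parcellation": str(out / "parcellation.nii.gz"),
        "mask": str(out / "mask.nii.gz"),
        "subjects": str(out / "subjects.tsv"),
        "bold": bold_paths,
    }
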