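"""Volume and table I/O with the geometric conventions used throughout the package.

All volumes are NIfTI-1; scalar maps are stored as float32, label volumes as
int32. Voxels are addressed 0-based in (x, y, z) order everywhere; world (MNI)
coordinates appear only in reports and are obtained from the affine stored at
load time. Each :class:`MetricMap` written to disk gets a JSON sidecar that
records its ``metric_kind`` and provenance (operation name, parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Recognised group labels. Extending the vocabulary is a deliberate act:
#: append here (or via config) rather than passing arbitrary strings through.
GROUP_LABELS = ("BD", "HC", "Improved", "NonImproved")

#: Metric kinds a 3D map may carry.
METRIC_KINDS = ("reho", "reho_normalized", "dc", "tstat", "fstat")

VISITS = ("baseline", "week12", "week24")


class VolumeError(ValueError):
    """Raised for malformed or unreadable volumetric inputs."""


class TableError(ValueError):
    """Raised for malformed subject tables."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _default_affine(voxel_size_mm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BoldSeries:
    """One subject's preprocessed 4D BOLD lattice plus acquisition geometry."""

    subject_id: str
    data: np.ndarray                      # (x, y, z, t) float32
    voxel_size_mm: np.ndarray             # (3,) strictly positive
    tr_seconds: float
    affine: np.ndarray | None = None      # 4x4 voxel->world; identity-scaled default

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise VolumeError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise VolumeError("BOLD series needs at least 2 timepoints")
        if min(self.data.shape[:3]) < 1:
            raise VolumeError("all spatial dimensions must be >= 1")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise VolumeError("voxel_size_mm must be 3 strictly positive values")
        if self.tr_seconds <= 0:
            raise VolumeError("tr_seconds must be positive")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise VolumeError(f"BOLD series contains {n_bad} non-finite voxels")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """3D boolean in-brain mask; congruence with a paired volume is checked at pairing."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise VolumeError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise VolumeError("mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, spatial_shape: tuple[int, ...]) -> None:
        if tuple(self.data.shape) != tuple(spatial_shape):
            raise VolumeError(
                f"mask shape {self.data.shape} does not match volume shape {tuple(spatial_shape)}"
            )


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus a region lookup table."""

    labels: np.ndarray
    region_table: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 3:
            raise VolumeError("parcellation labels must be 3D")
        if np.any(self.labels < 0):
            raise VolumeError("parcellation labels must be non-negative")
        ids = [rid for rid, _ in self.region_table]
        if len(ids) != len(set(ids)):
            raise VolumeError("region ids must be unique")
        if any(rid <= 0 for rid in ids):
            raise VolumeError("region ids must be positive integers")
        present = set(np.unique(self.labels[self.labels > 0]).tolist())
        missing = present - set(ids)
        if missing:
            raise VolumeError(f"labels present in volume but absent from region_table: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        return [rid for rid, _ in self.region_table]

    @property
    def n_regions(self) -> int:
        return len(self.region_table)


@dataclass
class MetricMap:
    """One 3D scalar map (ReHo, DC or a test statistic) tied to a brain mask.

    Invariants: values outside the mask are exactly 0 and values inside are
    finite. Enforced at construction.
    """

    data: np.ndarray
    metric_kind: str
    mask: BrainMask
    affine: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise VolumeError(f"unknown metric_kind {self.metric_kind!r}; expected one of {METRIC_KINDS}")
        self.data = np.asarray(self.data, dtype=np.float32)
        self.mask.check_congruent(self.data.shape)
        m = self.mask.data
        n_bad = int(np.count_nonzero(~np.isfinite(self.data[m])))
        if n_bad:
            raise VolumeError(f"metric map contains {n_bad} non-finite voxels inside the mask")
        out = self.data.copy()
        out[~m] = 0.0
        self.data = out
        if self.affine is None:
            self.affine = np.eye(4)

    def in_mask_values(self) -> np.ndarray:
        return self.data[self.mask.data]


@dataclass
class SubjectRecord:
    """Identifiers, group, nuisance covariates and per-visit cognitive scores.

    ``scores`` maps score name -> {visit -> value}; a score present at a
    follow-up visit must also be present at baseline.
    """

    subject_id: str
    group: str
    age: float = np.nan
    gender: int = 0                       # 0/1 coding for covariate regression
    education: float = np.nan
    fd: float = np.nan                    # mean framewise displacement, mm
    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise TableError(f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}")
        if np.isfinite(self.fd) and self.fd < 0:
            raise TableError("fd must be >= 0")
        if np.isfinite(self.education) and self.education < 0:
            raise TableError("education must be >= 0")
        for name, visits in self.scores.items():
            for visit in visits:
                if visit not in VISITS:
                    raise TableError(f"unknown visit {visit!r} for score {name!r}")
            if ("week12" in visits or "week24" in visits) and "baseline" not in visits:
                raise TableError(f"score {name!r} has follow-up values but no baseline")

    def score_at(self, name: str, visit: str) -> float | None:
        return self.scores.get(name, {}).get(visit)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(
    path: str | Path,
    *,
    subject_id: str | None = None,
    metric_kind: str | None = None,
    mask: BrainMask | None = None,
) -> BoldSeries | MetricMap:
    """Read a NIfTI-1 image: 4D becomes a :class:`BoldSeries`, 3D a :class:`MetricMap`.

    For 3D images ``metric_kind`` is taken from the caller or from the sidecar
    JSON written by :func:`write_volume`. Without an explicit mask, the map's
    mask covers every voxel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise VolumeError(f"{path} is not a readable NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise VolumeError(f"{path} contains {n_bad} non-finite voxels")
    zooms = img.header.get_zooms()
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return BoldSeries(
            subject_id=subject_id or path.name.split(".")[0],
            data=data,
            voxel_size_mm=np.asarray(zooms[:3], dtype=float),
            tr_seconds=tr if tr > 0 else 1.0,
            affine=np.asarray(img.affine, dtype=float),
        )
    if data.ndim == 3:
        provenance: dict = {}
        sidecar = _sidecar_path(path)
        if metric_kind is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            metric_kind = meta.get("metric_kind")
            provenance = meta.get("provenance", {})
        if metric_kind is None:
            raise VolumeError(
                f"{path} is 3D but metric_kind is neither given nor recorded in a sidecar"
            )
        if mask is None:
            mask = BrainMask(np.ones(data.shape, dtype=bool))
        return MetricMap(
            data=data,
            metric_kind=metric_kind,
            mask=mask,
            affine=np.asarray(img.affine, dtype=float),
            provenance=provenance,
        )
    raise VolumeError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")


def write_volume(obj: BoldSeries | MetricMap, path: str | Path) -> None:
    """Write a volume as NIfTI-1; maps get a JSON sidecar with kind and provenance."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, BoldSeries):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        img.header.set_zooms((*obj.voxel_size_mm, obj.tr_seconds))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))
    elif isinstance(obj, MetricMap):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        nib.save(img, str(path))
        meta = {"metric_kind": obj.metric_kind, "provenance": obj.provenance}
        _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def write_mask(mask: BrainMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.int32), affine if affine is not None else np.eye(4))
    nib.save(img, str(Path(path)))


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(Path(path)))
    return BrainMask(np.asanyarray(img.dataobj) > 0)


def write_parcellation(parc: Parcellation, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), affine if affine is not None else np.eye(4))
    nib.save(img, str(Path(path)))
    table = {"regions": [{"id": rid, "name": name} for rid, name in parc.region_table]}
    _sidecar_path(Path(path)).write_text(json.dumps(table, indent=2))


def read_parcellation(path: str | Path) -> Parcellation:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        table = [(int(r["id"]), str(r["name"])) for r in json.loads(sidecar.read_text())["regions"]]
    else:
        table = [(int(rid), f"region_{int(rid)}") for rid in np.unique(labels[labels > 0])]
    return Parcellation(labels=labels, region_table=table)


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------

_COVARIATE_COLUMNS = ("age", "gender", "education", "fd")


def _score_columns(columns) -> list[tuple[str, str, str]]:
    """Columns named <score>_<visit> -> (column, score, visit)."""
    out = []
    for col in columns:
        for visit in VISITS:
            suffix = "_" + visit
            if col.endswith(suffix) and len(col) > len(suffix):
                out.append((col, col[: -len(suffix)], visit))
    return out


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a TSV with header into typed subject records.

    Required columns: ``subject_id``, ``group``. Optional covariates
    (age, gender, education, fd) and score columns named ``<score>_<visit>``
    with visit in {baseline, week12, week24}. Blank cells are missing values;
    non-numeric cells in numeric columns are reported with row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for required in ("subject_id", "group"):
        if required not in df.columns:
            raise TableError(f"{path}: missing required column {required!r}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise TableError(f"{path}: duplicate subject_id {sorted(set(dupes))}")

    numeric_cols = [c for c in df.columns if c in _COVARIATE_COLUMNS]
    score_cols = _score_columns(df.columns)
    numeric_cols += [c for c, _, _ in score_cols]

    parsed: dict[str, pd.Series] = {}
    for col in numeric_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].str.strip() != "") & values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableError(
                f"{path}: unparseable numeric cell at row {row + 2} column {col!r}: {df[col].iloc[row]!r}"
            )
        parsed[col] = values

    records = []
    for i in range(len(df)):
        scores: dict[str, dict[str, float]] = {}
        for col, score, visit in score_cols:
            v = parsed[col].iloc[i]
            if pd.notna(v):
                scores.setdefault(score, {})[visit] = float(v)
        def cov(name, default=np.nan):
            if name in parsed and pd.notna(parsed[name].iloc[i]):
                return float(parsed[name].iloc[i])
            return default
        records.append(
            SubjectRecord(
                subject_id=str(df["subject_id"].iloc[i]),
                group=str(df["group"].iloc[i]),
                age=cov("age"),
                gender=int(cov("gender", 0)),
                education=cov("education"),
                fd=cov("fd"),
                scores=scores,
            )
        )
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    """Write subject records to TSV (inverse of :func:`read_subject_table`)."""
    score_visit_pairs: list[tuple[str, str]] = []
    for rec in records:
        for score, visits in rec.scores.items():
            for visit in visits:
                if (score, visit) not in score_visit_pairs:
                    score_visit_pairs.append((score, visit))
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "gender": rec.gender,
            "education": rec.education,
            "fd": rec.fd,
        }
        for score, visit in score_visit_pairs:
            v = rec.score_at(score, visit)
            row[f"{score}_{visit}"] = v if v is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
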