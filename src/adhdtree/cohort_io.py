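"""Cohort I/O: phenotypic tables, per-subject ROI timecourses, and the AAL atlas.

The on-disk layout mirrors how ROI-averaged resting-state fMRI data are
commonly distributed: one comma-separated phenotypic table per cohort
(``subject_id,age,gender,iq,handedness,dx``) plus one whitespace-delimited
timecourse file per subject (T timepoints x 116 AAL regions, columns in
atlas order 1..116, named ``<subject_id>_rois_aal.tsv``).

Subjects with missing or malformed fields are rejected at read time rather
than imputed; errors name the offending row and column.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENDERS = ("F", "M")
DIAGNOSES = ("TD", "ADHD")
N_AAL_ROIS = 116

PHENOTYPE_COLUMNS = ("subject_id", "age", "gender", "iq", "handedness", "dx")


class CohortError(ValueError):
    """Raised for malformed phenotypic tables, timecourse files or cohorts."""


@dataclass(frozen=True)
class Subject:
    """One participant: phenotypics plus the clinical diagnosis label.

    age is in years, iq is a Wechsler-scale full IQ, handedness is an
    Edinburgh-style laterality score in [-1, 1] (not thresholded anywhere
    in this package).
    """

    subject_id: str
    age: float
    gender: str
    iq: float
    handedness: float
    dx: str

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise CohortError("subject_id must be a non-empty string")
        if not (self.age > 0 and np.isfinite(self.age)):
            raise CohortError(f"subject {self.subject_id}: age must be > 0, got {self.age}")
        if not (self.iq > 0 and np.isfinite(self.iq)):
            raise CohortError(f"subject {self.subject_id}: iq must be > 0, got {self.iq}")
        if not np.isfinite(self.handedness):
            raise CohortError(f"subject {self.subject_id}: handedness must be finite")
        if self.gender not in GENDERS:
            raise CohortError(f"subject {self.subject_id}: gender must be one of {GENDERS}, got {self.gender!r}")
        if self.dx not in DIAGNOSES:
            raise CohortError(f"subject {self.subject_id}: dx must be one of {DIAGNOSES}, got {self.dx!r}")


@dataclass
class RoiTimeseries:
    """One subject's ROI-averaged BOLD timecourses (T timepoints x R regions)."""

    matrix: np.ndarray
    tr_seconds: float
    roi_ids: tuple = tuple(range(1, N_AAL_ROIS + 1))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.roi_ids = tuple(int(r) for r in self.roi_ids)
        if self.matrix.ndim != 2:
            raise CohortError("timeseries matrix must be 2-D (timepoints x regions)")
        if self.matrix.shape[0] < 2:
            raise CohortError(f"timeseries needs at least 2 timepoints, got {self.matrix.shape[0]}")
        if self.matrix.shape[1] != len(self.roi_ids):
            raise CohortError(
                f"matrix has {self.matrix.shape[1]} columns but {len(self.roi_ids)} roi ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise CohortError("timeseries contains non-finite values")
        if not (self.tr_seconds > 0):
            raise CohortError("tr_seconds must be positive")
        ids = np.asarray(self.roi_ids)
        if np.any(np.diff(ids) <= 0) or ids[0] < 1 or ids[-1] > N_AAL_ROIS:
            raise CohortError("roi_ids must be strictly increasing within 1..116")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, roi_id: int) -> np.ndarray:
        """Return the timecourse of one ROI by atlas id."""
        try:
            j = self.roi_ids.index(int(roi_id))
        except ValueError:
            raise CohortError(f"roi id {roi_id} not present in this timeseries") from None
        return self.matrix[:, j]


@dataclass(frozen=True)
class AtlasEntry:
    roi_id: int
    name: str
    hemisphere: str


@dataclass
class RoiAtlas:
    """The AAL parcellation table: 116 regions, odd ids left / even ids right."""

    entries: tuple

    def __post_init__(self) -> None:
        if len(self.entries) != N_AAL_ROIS:
            raise CohortError(f"atlas must have exactly {N_AAL_ROIS} entries")
        for e in self.entries:
            expect = "R" if e.roi_id % 2 == 0 else "L"
            if e.hemisphere != expect:
                raise CohortError(f"roi {e.roi_id}: hemisphere {e.hemisphere} violates parity rule")

    def __getitem__(self, roi_id: int) -> AtlasEntry:
        return self.entries[int(roi_id) - 1]

    def label(self, roi_id: int) -> str:
        e = self[roi_id]
        return f"{e.name} ({e.hemisphere})"


@dataclass
class Cohort:
    """An ordered set of subjects with (optionally) their ROI timecourses."""

    subjects: list
    timeseries: dict = field(default_factory=dict)
    role: str = "training"

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject ids: {dup}")
        unknown = set(self.timeseries) - set(ids)
        if unknown:
            raise CohortError(f"timeseries for unknown subjects: {sorted(unknown)}")
        if self.role not in ("training", "test"):
            raise CohortError(f"role must be 'training' or 'test', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    @property
    def labels(self) -> list:
        return [s.dx for s in self.subjects]

    def counts(self) -> dict:
        return {dx: sum(s.dx == dx for s in self.subjects) for dx in DIAGNOSES}


def load_atlas() -> RoiAtlas:
    """Load the packaged AAL-116 atlas table."""
    text = importlib.resources.files("adhdtree.data").joinpath("aal116.tsv").read_text()
    entries = []
    for line in text.strip().splitlines()[1:]:
        rid, name, hemi = line.split("\t")
        entries.append(AtlasEntry(int(rid), name, hemi))
    return RoiAtlas(tuple(entries))


def limbic_roi_set() -> tuple:
    """The expert-selected limbic-system ROI ids (12 affective + 14 executive)."""
    text = importlib.resources.files("adhdtree.data").joinpath("limbic_rois.txt").read_text()
    ids = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        _, rid = line.split("\t")
        ids.append(int(rid))
    return tuple(sorted(ids))


def _parse_float(value, row: int, column: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        raise CohortError(f"row {row}: missing value in column '{column}'")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortError(f"row {row}: unparseable value {value!r} in column '{column}'") from None


def read_phenotypes(path, role: str = "training") -> Cohort:
    """Read a phenotypic CSV into a Cohort (without timeseries).

    Rejects files with missing columns, rows with missing/unparseable cells,
    invalid categories, or duplicate subject ids; errors carry the 1-based
    data-row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"phenotypic table {path}: missing columns {missing}")
    subjects = []
    seen = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        sid = str(rec["subject_id"]).strip()
        if not sid:
            raise CohortError(f"row {i}: missing value in column 'subject_id'")
        if sid in seen:
            raise CohortError(f"row {i}: duplicate subject id {sid!r}")
        seen.add(sid)
        gender = str(rec["gender"]).strip()
        dx = str(rec["dx"]).strip()
        if gender not in GENDERS:
            raise CohortError(f"row {i}: invalid gender {gender!r} (expected F or M)")
        if dx not in DIAGNOSES:
            raise CohortError(f"row {i}: invalid dx {dx!r} (expected TD or ADHD)")
        try:
            subjects.append(
                Subject(
                    subject_id=sid,
                    age=_parse_float(rec["age"], i, "age"),
                    gender=gender,
                    iq=_parse_float(rec["iq"], i, "iq"),
                    handedness=_parse_float(rec["handedness"], i, "handedness"),
                    dx=dx,
                )
            )
        except CohortError as err:
            if str(err).startswith("row"):
                raise
            raise CohortError(f"row {i}: {err}") from None
    return Cohort(subjects=subjects, role=role)


def write_phenotypes(cohort: Cohort, path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "gender": s.gender,
                "iq": s.iq,
                "handedness": s.handedness,
                "dx": s.dx,
            }
            for s in cohort.subjects
        ],
        columns=list(PHENOTYPE_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_roi_timeseries(path, tr_seconds: float = 2.0) -> RoiTimeseries:
    """Read one subject's whitespace-delimited T x 116 ROI timecourse file."""
    try:
        matrix = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as err:
        raise CohortError(f"timeseries file {path}: {err}") from None
    if matrix.shape[1] != N_AAL_ROIS:
        raise CohortError(
            f"timeseries file {path}: expected {N_AAL_ROIS} columns, got {matrix.shape[1]}"
        )
    if matrix.shape[0] < 2:
        raise CohortError(f"timeseries file {path}: needs at least 2 rows, got {matrix.shape[0]}")
    return RoiTimeseries(matrix=matrix, tr_seconds=tr_seconds)


def write_roi_timeseries(ts: RoiTimeseries, path) -> None:
    # %.17g preserves doubles exactly across a write/read cycle
    np.savetxt(path, ts.matrix, fmt="%.17g", delimiter="\t")


def timeseries_filename(subject_id: str) -> str:
    return f"{subject_id}_rois_aal.tsv"


def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort directory: phenotypes.csv plus one TSV per subject."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_phenotypes(cohort, directory / "phenotypes.csv")
    for sid, ts in cohort.timeseries.items():
        write_roi_timeseries(ts, directory / timeseries_filename(sid))


def read_cohort(directory, tr_seconds: float = 2.0, role: str = "training") -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    cohort = read_phenotypes(directory / "phenotypes.csv", role=role)
    for s in cohort.subjects:
        f = directory / timeseries_filename(s.subject_id)
        if f.exists():
            cohort.timeseries[s.subject_id] = read_roi_timeseries(f, tr_seconds=tr_seconds)
    return cohort
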