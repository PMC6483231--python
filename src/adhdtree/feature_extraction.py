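"""Build the classification feature table: phenotypics + per-ROI signal variances.

Each ROI contributes one feature, the unbiased (T-1 denominator) sample
variance of its BOLD timecourse — a proxy for the energy of resting-state
activity in that region.  With all four phenotypic attributes and all 116
AAL regions the table has 120 features.  Gender stays categorical so the
tree can perform a multiway split on it; it is only numerically encoded
where a Pearson correlation requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortError, N_AAL_ROIS

DEFAULT_PHENOTYPES = ("gender", "age", "iq", "handedness")


def roi_variance(series) -> float:
    """Unbiased sample variance of one ROI timecourse (length >= 2, finite)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise CohortError("roi_variance needs a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise CohortError("roi_variance: series contains non-finite values")
    return float(np.var(x, ddof=1))


def roi_feature_name(roi_id: int) -> str:
    return f"roi_{int(roi_id)}_var"


def parse_roi_feature(name: str):
    """Return the ROI id of a ``roi_<id>_var`` feature name, or None."""
    if name.startswith("roi_") and name.endswith("_var"):
        try:
            return int(name[4:-4])
        except ValueError:
            return None
    return None


@dataclass
class FeatureTable:
    """n subjects x features, with per-feature kinds and per-subject labels."""

    values: pd.DataFrame
    kinds: dict
    labels: pd.Series

    def __post_init__(self) -> None:
        names = list(self.values.columns)
        if len(set(names)) != len(names):
            raise CohortError("feature names must be unique")
        if set(self.kinds) != set(names):
            raise CohortError("kinds must cover exactly the feature columns")
        if not self.labels.index.equals(self.values.index):
            raise CohortError("labels index must match the value rows")
        bad = set(self.labels.unique()) - {"TD", "ADHD"}
        if bad:
            raise CohortError(f"invalid labels: {sorted(bad)}")

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return len(self.values)

    def subset_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(
            values=self.values[names].copy(),
            kinds={f: self.kinds[f] for f in names},
            labels=self.labels.copy(),
        )

    def subset_rows(self, positions) -> "FeatureTable":
        positions = list(positions)
        values = self.values.iloc[positions]
        return FeatureTable(values=values, kinds=dict(self.kinds), labels=self.labels.iloc[positions])

    def to_frame(self) -> pd.DataFrame:
        """Features plus a trailing ``dx`` label column (for CSV export)."""
        out = self.values.copy()
        out["dx"] = self.labels
        return out


def feature_table_from_frame(df: pd.DataFrame) -> FeatureTable:
    """Rebuild a FeatureTable from a CSV frame written by :meth:`to_frame`."""
    if "dx" not in df.columns:
        raise CohortError("feature CSV must contain a 'dx' column")
    labels = df["dx"].astype(str)
    values = df.drop(columns=["dx"])
    kinds = {c: ("categorical" if c == "gender" else "numeric") for c in values.columns}
    for c in values.columns:
        if kinds[c] == "numeric":
            values[c] = values[c].astype(float)
    return FeatureTable(values=values, kinds=kinds, labels=labels)


def build_feature_table(
    cohort: Cohort,
    roi_subset=None,
    phenotypes=DEFAULT_PHENOTYPES,
) -> FeatureTable:
    """Assemble the feature table for a cohort.

    Columns are the requested phenotypics (in the given order) followed by
    ``roi_<id>_var`` for the requested ROIs in ascending id.  ``roi_subset``
    of None means all 116 regions; an explicit empty list drops imaging
    features.  Every subject must have a timeseries covering the requested
    ROIs.
    """
    phenotypes = tuple(phenotypes)
    roi_ids = (
        tuple(range(1, N_AAL_ROIS + 1))
        if roi_subset is None
        else tuple(sorted(int(r) for r in roi_subset))
    )
    if not phenotypes and not roi_ids:
        raise CohortError("empty feature space: no phenotypes and no ROIs requested")
    unknown = set(phenotypes) - set(DEFAULT_PHENOTYPES)
    if unknown:
        raise CohortError(f"unknown phenotypic features: {sorted(unknown)}")
    rows = []
    for s in cohort.subjects:
        row = {}
        for p in phenotypes:
            row[p] = getattr(s, "gender" if p == "gender" else p)
        if roi_ids:
            ts = cohort.timeseries.get(s.subject_id)
            if ts is None:
                raise CohortError(f"subject {s.subject_id} has no timeseries")
            for rid in roi_ids:
                row[roi_feature_name(rid)] = roi_variance(ts.column(rid))
        rows.append(row)
    columns = list(phenotypes) + [roi_feature_name(r) for r in roi_ids]
    values = pd.DataFrame(rows, columns=columns, index=cohort.subject_ids)
    kinds = {c: ("categorical" if c == "gender" else "numeric") for c in columns}
    labels = pd.Series(cohort.labels, index=cohort.subject_ids, name="dx")
    return FeatureTable(values=values, kinds=kinds, labels=labels)
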