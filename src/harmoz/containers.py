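"""Core in-memory containers: subjects, volume tables, and Z-score tables.

Conventions follow the covariate coding used throughout the package:
sex 0 = female / 1 = male; field strength 0 = 3 T / 1 = 1.5 T; volumes in
mm^3; eTIV (estimated total intracranial volume) in mm^3.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "SubjectRecord",
    "VolumeTable",
    "ZScoreTable",
    "MASK_SCORED",
    "MASK_EXCLUDED",
    "MASK_MISSING",
]


class Group(str, enum.Enum):
    """Diagnostic group label. Labels are consumed as-is; clinical criteria
    for assignment are out of scope."""

    NC = "NC"
    SMCI = "sMCI"
    PMCI = "pMCI"
    AD = "AD"
    OTHER = "other"

    @classmethod
    def parse(cls, token: str) -> "Group":
        t = str(token).strip()
        for g in cls:
            if g.value.lower() == t.lower():
                return g
        raise ValueError(f"unknown diagnostic group label: {token!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's covariates and group label.

    Parameters
    ----------
    subject_id : opaque identifier, unique within a cohort.
    age : years, finite and > 0.
    sex : 0 = female, 1 = male.
    field_strength : 0 = 3 T, 1 = 1.5 T.
    etiv : estimated total intracranial volume, mm^3, finite and > 0.
    group : diagnostic label (defaults to ``other``).
    """

    subject_id: str
    age: float
    sex: int
    field_strength: int
    etiv: float
    group: Group = Group.OTHER

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: age must be finite and positive, got {self.age}"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id!r}: sex code must be 0 or 1, got {self.sex}")
        if self.field_strength not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: field_strength code must be 0 or 1, "
                f"got {self.field_strength}"
            )
        if not (math.isfinite(self.etiv) and self.etiv > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: eTIV must be finite and positive, got {self.etiv}"
            )
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group.parse(self.group))


def _check_unique_ids(subject_ids: list[str]) -> None:
    seen: set[str] = set()
    for sid in subject_ids:
        if sid in seen:
            raise ValueError(f"duplicate subject_id: {sid!r}")
        seen.add(sid)


@dataclass
class VolumeTable:
    """Subjects x ROIs matrix of structural volumes in mm^3.

    Cells must be strictly positive and finite (log10 must be defined), or
    NaN to mark a missing measurement. Missing cells are rejected by the
    reference fit and masked during scoring.
    """

    subject_ids: list[str]
    roi_names: list[str]
    volumes: np.ndarray  # shape (n_subjects, n_rois), float64

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 2:
            raise ValueError("volumes must be a 2-D matrix")
        n, r = self.volumes.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"row count {n} does not match number of subject ids {len(self.subject_ids)}"
            )
        if r != len(self.roi_names):
            raise ValueError(
                f"column count {r} does not match number of ROI names {len(self.roi_names)}"
            )
        _check_unique_ids(self.subject_ids)
        bad = ~(np.isnan(self.volumes) | (np.isfinite(self.volumes) & (self.volumes > 0)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid volume for subject {self.subject_ids[i]!r}, "
                f"ROI {self.roi_names[j]!r}: {self.volumes[i, j]} "
                "(volumes must be strictly positive and finite)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.volumes.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.volumes, index=pd.Index(self.subject_ids, name="subject_id"), columns=self.roi_names
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VolumeTable":
        return cls(
            subject_ids=[str(s) for s in df.index],
            roi_names=[str(c) for c in df.columns],
            volumes=df.to_numpy(dtype=float),
        )

    def row_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"subject {subject_id!r} not in volume table") from None

    def column_index(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(f"ROI {roi!r} not in volume table") from None


# Per-cell scoring status flags.
MASK_SCORED = "scored"
MASK_EXCLUDED = "excluded_outlier"
MASK_MISSING = "missing"


@dataclass
class ZScoreTable:
    """Subjects x ROIs matrix of harmonized Z values with a per-cell mask.

    ``mask`` holds one of :data:`MASK_SCORED`, :data:`MASK_EXCLUDED`
    (reference subject removed by outlier QC for that ROI; the Z under the
    refitted model is still reported) or :data:`MASK_MISSING` (no volume).
    Z is finite wherever the mask is ``scored``.
    """

    subject_ids: list[str]
    roi_names: list[str]
    z: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.mask is None:
            self.mask = np.where(np.isnan(self.z), MASK_MISSING, MASK_SCORED)
        self.mask = np.asarray(self.mask, dtype=object)
        if self.z.shape != (len(self.subject_ids), len(self.roi_names)):
            raise ValueError("z matrix shape does not match subject/ROI lists")
        if self.mask.shape != self.z.shape:
            raise ValueError("mask shape does not match z matrix")
        _check_unique_ids(self.subject_ids)
        valid = {MASK_SCORED, MASK_EXCLUDED, MASK_MISSING}
        if not set(np.unique(self.mask)) <= valid:
            raise ValueError(f"mask entries must be one of {sorted(valid)}")
        scored = self.mask == MASK_SCORED
        if not np.isfinite(self.z[scored]).all():
            raise ValueError("non-finite Z in a cell marked 'scored'")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z, index=pd.Index(self.subject_ids, name="subject_id"), columns=self.roi_names
        )

    def mask_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mask, index=pd.Index(self.subject_ids, name="subject_id"), columns=self.roi_names
        )

    def column(self, roi: str, *, scored_only: bool = True) -> np.ndarray:
        """Z values for one ROI, by default restricted to scored cells."""
        j = self.roi_names.index(roi)
        col = self.z[:, j]
        if scored_only:
            return col[self.mask[:, j] == MASK_SCORED]
        return col
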