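"""Core data containers shared across the analysis modules.

The package operates on per-subject node-by-time signal matrices (fMRI BOLD
time courses sampled every ``tr_seconds``), a per-subject behavioral table
(IRI empathy subscales and symptom ratings), and a stimulus rating curve
(median/MAD of continuous sadness ratings from an independent rater group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Group labels used throughout: patients and healthy controls.
GROUPS = ("pmdd", "control")

#: IRI subscale column names (questionnaire score units).
IRI_SUBSCALES = (
    "perspective_taking",
    "empathic_concern",
    "personal_distress",
    "fantasy",
)

#: Default symptom-rating column names (ordinal severity units).
SYMPTOMS = ("depression", "anxiety", "lability")


@dataclass
class SubjectTimeSeries:
    """One subject's unit-by-time signal matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Group label (e.g. ``"pmdd"`` or ``"control"``).
    data : ndarray, shape (n_units, n_tr)
        Signal matrix; rows are voxels/nodes, columns are TRs. Arbitrary
        signal units (all statistics used downstream are scale-free).
    tr_seconds : float
        Sampling interval in seconds.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id!r}: data must be 2-D "
                f"(units x TRs), got shape {self.data.shape}"
            )
        if self.data.shape[1] < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 2 TRs, "
                f"got {self.data.shape[1]}"
            )
        if self.data.shape[0] < 1:
            raise ValueError(f"subject {self.subject_id!r}: no units")
        if np.isnan(self.data).any():
            raise ValueError(
                f"subject {self.subject_id!r}: data contains missing values"
            )
        if self.tr_seconds <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: tr_seconds must be positive"
            )

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_tr(self) -> int:
        return self.data.shape[1]


def check_aligned(subjects: Sequence[SubjectTimeSeries]) -> tuple[int, int]:
    """Validate that all subjects share dimensions; return (n_units, n_tr).

    Raises ``ValueError`` listing every offending subject id.
    """
    if not subjects:
        raise ValueError("empty subject list")
    n_units, n_tr = subjects[0].n_units, subjects[0].n_tr
    bad = [
        s.subject_id
        for s in subjects
        if (s.n_units, s.n_tr) != (n_units, n_tr)
    ]
    if bad:
        raise ValueError(
            f"dimension mismatch across subjects: expected "
            f"{n_units} units x {n_tr} TRs, offending ids: {', '.join(bad)}"
        )
    return n_units, n_tr


@dataclass
class BehavioralTable:
    """Per-subject behavioral scores: IRI subscales plus symptom ratings.

    Wraps a tidy DataFrame with one row per subject. Required columns:
    ``subject_id``, ``group``; measure columns are free-form but by default
    comprise the four IRI subscales and the symptom ratings.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject_id", "group"):
            if col not in self.table.columns:
                raise ValueError(f"behavioral table missing column {col!r}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicated subject ids: {dupes}")
        self.table = self.table.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def measures(self) -> list[str]:
        """Names of all numeric measure columns."""
        skip = {"subject_id", "group"}
        return [
            c
            for c in self.table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.table[c])
        ]

    def subset(self, subject_ids: Sequence[str]) -> "BehavioralTable":
        keep = self.table["subject_id"].isin(list(subject_ids))
        return BehavioralTable(self.table[keep].reset_index(drop=True))


@dataclass
class RatingCurve:
    """Per-TR stimulus rating summary: median and MAD across raters."""

    median: np.ndarray
    mad: np.ndarray
    scale_max: float

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.mad = np.asarray(self.mad, dtype=float)
        if self.median.shape != self.mad.shape or self.median.ndim != 1:
            raise ValueError("median and mad must be 1-D and equal length")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")

    @property
    def n_tr(self) -> int:
        return self.median.size


@dataclass
class NetworkDefinition:
    """A named node set (brain network) over the dataset's unit axis.

    ``indices`` index into the unit axis of every ``SubjectTimeSeries``.
    ``labels`` and ``coords`` (Talairach mm) are optional pass-through
    metadata. ``pool`` optionally names the whole-brain node pool used for
    spatial-specificity nulls.
    """

    name: str
    indices: np.ndarray
    labels: list[str] | None = None
    coords: np.ndarray | None = None
    pool: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError(f"network {self.name!r}: indices must be 1-D")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError(f"network {self.name!r}: duplicate node indices")
        if self.labels is not None and len(self.labels) != self.indices.size:
            raise ValueError(f"network {self.name!r}: labels/indices mismatch")
        if self.pool is not None:
            self.pool = np.asarray(self.pool, dtype=int)

    @property
    def size(self) -> int:
        return self.indices.size
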