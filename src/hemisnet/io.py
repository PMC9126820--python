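"""Cohort data model and table input/output.

A cohort is a pair ``(ThicknessTable, list[Subject])``: a wide table of
regional mean cortical thickness (34 left + 34 right Desikan-Killiany
regions, in mm) and the per-subject covariates the case-control models
use (dataset, diagnosis, age, sex, plus optional clinical variables).

Files are tab-separated UTF-8 with a header row by default, matching
common FreeSurfer ``aparc`` table exports; comma-separated input is
accepted via the ``sep`` argument.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import DK_REGIONS, N_REGIONS, all_region_columns, hemisphere_columns

logger = logging.getLogger(__name__)

REQUIRED_COVARIATES = ("subject_id", "dataset_id", "diagnosis", "age", "sex")
OPTIONAL_COVARIATES = ("ados_total", "medication", "iq", "handedness")

RESULT_COLUMNS = (
    "tier",
    "metric",
    "node",
    "n_cases",
    "n_controls",
    "coefficient",
    "t",
    "cohens_d",
    "p_empirical",
    "p_adjusted",
    "significant",
)


class CohortFormatError(ValueError):
    """Malformed input table (missing columns, bad values, duplicates)."""


@dataclass
class Subject:
    """Covariates for one participant.

    ``diagnosis`` is ``"case"`` or ``"control"``; ``sex`` is ``"M"`` or
    ``"F"``. The clinical variables are optional and may be missing
    per-variable (``None``); they are only used in within-case models.
    """

    subject_id: str
    dataset_id: str
    diagnosis: str
    age: float
    sex: str
    ados_total: float | None = None
    medication: int | None = None
    iq: float | None = None
    handedness: str | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("case", "control"):
            raise CohortFormatError(
                f"subject {self.subject_id}: diagnosis must be 'case' or "
                f"'control', got {self.diagnosis!r}"
            )
        if self.sex is not None and self.sex not in ("M", "F"):
            raise CohortFormatError(
                f"subject {self.subject_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if self.handedness is not None and self.handedness not in ("L", "R"):
            raise CohortFormatError(
                f"subject {self.subject_id}: handedness must be 'L' or 'R', "
                f"got {self.handedness!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.diagnosis == "case"


class ThicknessTable:
    """Per-subject regional thickness, index-aligned by hemisphere.

    Wraps a DataFrame whose index is ``subject_id`` and whose columns are
    the 68 canonical region columns (34 ``*_L`` then 34 ``*_R``). Left
    column ``i`` and right column ``i`` are homotopic.
    """

    def __init__(self, data: pd.DataFrame):
        cols = all_region_columns()
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise CohortFormatError(f"missing region column(s): {', '.join(missing)}")
        data = data.loc[:, cols].astype(float)
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise CohortFormatError(f"duplicate subject_id(s): {dups}")
        values = data.to_numpy()
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortFormatError(
                f"non-positive or non-finite thickness at row {i} "
                f"(subject {data.index[i]!r}), column {cols[j]!r}: {values[i, j]!r}"
            )
        self.data = data

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def hemisphere(self, hemi: str) -> np.ndarray:
        """(n_subjects, 34) array of one hemisphere, canonical region order."""
        return self.data.loc[:, hemisphere_columns(hemi)].to_numpy()

    @property
    def left(self) -> np.ndarray:
        return self.hemisphere("L")

    @property
    def right(self) -> np.ndarray:
        return self.hemisphere("R")

    def global_mean(self) -> np.ndarray:
        """Mean thickness over all 68 regions, per subject."""
        return self.data.to_numpy().mean(axis=1)

    def swap_hemispheres(self) -> "ThicknessTable":
        """Return a table with left and right columns exchanged."""
        swapped = self.data.copy()
        lcols, rcols = hemisphere_columns("L"), hemisphere_columns("R")
        swapped[lcols] = self.data[rcols].to_numpy()
        swapped[rcols] = self.data[lcols].to_numpy()
        return ThicknessTable(swapped)


def _parse_optional(row: pd.Series, name: str):
    val = row.get(name)
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    return val


def subjects_from_frame(frame: pd.DataFrame) -> list[Subject]:
    """Build Subject records from a covariates DataFrame."""
    missing = [c for c in REQUIRED_COVARIATES if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"missing covariate column(s): {', '.join(missing)}")
    subjects = []
    for _, row in frame.iterrows():
        med = _parse_optional(row, "medication")
        age = _parse_optional(row, "age")
        sex = _parse_optional(row, "sex")
        iq = _parse_optional(row, "iq")
        ados = _parse_optional(row, "ados_total")
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                dataset_id=str(row["dataset_id"]),
                diagnosis=str(row["diagnosis"]),
                age=float(age) if age is not None else math.nan,
                sex=str(sex) if sex is not None else None,
                ados_total=float(ados) if ados is not None else None,
                medication=int(med) if med is not None else None,
                iq=float(iq) if iq is not None else None,
                handedness=_parse_optional(row, "handedness"),
            )
        )
    return subjects


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Inverse of :func:`subjects_from_frame`."""
    return pd.DataFrame([dataclasses.asdict(s) for s in subjects])


def read_cohort(
    thickness_path: str | Path,
    covariates_path: str | Path,
    sep: str = "\t",
) -> tuple[ThicknessTable, list[Subject]]:
    """Read a cohort from a thickness table and a covariates table.

    Subjects present in only one of the two files are dropped with a
    logged count. Raises :class:`CohortFormatError` on missing region
    columns, non-positive thickness, or duplicate subject ids.
    """
    thick = pd.read_csv(thickness_path, sep=sep, dtype={"subject_id": str})
    if "subject_id" not in thick.columns:
        raise CohortFormatError("thickness table must have a 'subject_id' column")
    thick = thick.set_index("subject_id")

    cov = pd.read_csv(covariates_path, sep=sep, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COVARIATES if c not in cov.columns]
    if missing:
        raise CohortFormatError(f"missing covariate column(s): {', '.join(missing)}")
    if cov["subject_id"].duplicated().any():
        dups = cov.loc[cov["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortFormatError(f"duplicate subject_id(s) in covariates: {dups}")

    shared = [sid for sid in thick.index if sid in set(cov["subject_id"])]
    n_dropped = (len(thick) - len(shared)) + (len(cov) - len(shared))
    if n_dropped:
        logger.warning(
            "dropping %d subject(s) present in only one input file", n_dropped
        )
    if not shared:
        raise CohortFormatError("no subjects shared between thickness and covariates")

    table = ThicknessTable(thick.loc[shared])
    cov = cov.set_index("subject_id").loc[shared].reset_index()
    subjects = subjects_from_frame(cov)
    return table, subjects


def write_cohort(
    table: ThicknessTable,
    subjects: list[Subject],
    thickness_path: str | Path,
    covariates_path: str | Path,
    sep: str = "\t",
) -> None:
    """Write a cohort in the format :func:`read_cohort` reads."""
    out = table.data.reset_index(names="subject_id")
    out.to_csv(thickness_path, sep=sep, index=False, float_format="%.17g")
    cov = subjects_to_frame(subjects)
    cov.to_csv(covariates_path, sep=sep, index=False, float_format="%.17g")


@dataclass
class TestResult:
    """One case-control (or within-case) test of a metric asymmetry.

    ``tier`` is the analysis family the multiplicity correction is scoped
    to: ``hemisphere`` (Bonferroni over 3), ``node`` (BH over 34 nodes per
    metric), ``edge`` (BH over 33 edges per seed), ``unilateral`` and
    ``within-case`` (uncorrected follow-ups).
    """

    __test__ = False  # not a pytest class, despite the name

    tier: str
    metric: str
    node: str  # region name, "hemisphere", or "seed->partner" for edges
    n_cases: int
    n_controls: int
    coefficient: float
    t: float
    cohens_d: float
    p_empirical: float
    p_adjusted: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.t != 0 and np.isfinite(self.t) and np.isfinite(self.cohens_d):
            if np.sign(self.cohens_d) != np.sign(self.t):
                raise ValueError("cohens_d and t must share a sign")


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])[list(RESULT_COLUMNS)]


def write_results(results: list[TestResult], path: str | Path, sep: str = "\t") -> None:
    """Write test results as a TSV that round-trips to full precision."""
    if not results:
        raise ValueError("results list is empty; refusing to write an empty table")
    frame = results_to_frame(results)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_results(path: str | Path, sep: str = "\t") -> list[TestResult]:
    """Read back a results table written by :func:`write_results`."""
    frame = pd.read_csv(path, sep=sep)
    out = []
    for _, row in frame.iterrows():
        padj = row["p_adjusted"]
        sig = row["significant"]
        out.append(
            TestResult(
                tier=row["tier"],
                metric=row["metric"],
                node=str(row["node"]),
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
                coefficient=float(row["coefficient"]),
                t=float(row["t"]),
                cohens_d=float(row["cohens_d"]),
                p_empirical=float(row["p_empirical"]),
                p_adjusted=None if pd.isna(padj) else float(padj),
                significant=None if pd.isna(sig) else bool(sig),
            )
        )
    return out
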