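"""Validated data model for long-format mixed-type longitudinal tables.

The canonical input layout is *long format*: one row per subject x visit,
with a subject-identifier column, a numeric time column, and one column per
observed variable. Variables are either continuous or categorical; the
declared category levels of a categorical variable are part of its spec.
Wide layouts (one column per variable x visit) are not reshaped here — the
time column makes the longitudinal structure explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CATEGORICAL_THRESHOLD = 9

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class ConfigurationError(ValueError):
    """Raised when inputs are wired up incorrectly (missing columns, bad specs)."""


class DatasetValidationError(ValueError):
    """Raised when a table violates the dataset invariants.

    Carries the individual findings in ``.findings``.
    """

    def __init__(self, findings: Sequence["Finding"]):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings[:10])
        extra = "" if len(self.findings) <= 10 else f" (+{len(self.findings) - 10} more)"
        super().__init__(f"dataset validation failed: {lines}{extra}")


@dataclass(frozen=True)
class VariableSpec:
    """Declared type of one observed variable.

    Parameters
    ----------
    name
        Column name, unique within a dataset.
    kind
        ``"continuous"`` or ``"categorical"``.
    levels
        Ordered category labels; required (>= 2) for categorical variables
        and forbidden for continuous ones.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ConfigurationError(
                f"variable {self.name!r}: kind must be 'continuous' or 'categorical', got {self.kind!r}"
            )
        if self.kind == CATEGORICAL:
            if self.levels is None or len(self.levels) < 2:
                raise ConfigurationError(
                    f"categorical variable {self.name!r} needs >= 2 declared levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ConfigurationError(f"variable {self.name!r}: duplicate levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        elif self.levels is not None:
            raise ConfigurationError(
                f"continuous variable {self.name!r} must not declare levels"
            )

    @property
    def is_continuous(self) -> bool:
        return self.kind == CONTINUOUS


@dataclass(frozen=True)
class Finding:
    """One validation finding with a machine-readable code and a location."""

    code: str
    message: str
    location: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.code}] {self.message} (at {self.location})"


@dataclass
class LongitudinalDataset:
    """Long-format table of mixed-type observations per subject x visit.

    ``data`` holds the id column, the time column, and one column per
    variable, in that order. ``groups`` optionally maps variable names to a
    named variable-grouping used for per-group dimension reduction.
    """

    data: pd.DataFrame
    id_col: str
    time_col: str
    variables: tuple[VariableSpec, ...]
    groups: dict[str, str] | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_col: str,
        time_col: str,
        spec: Sequence[VariableSpec] | str = "infer",
        *,
        groups: Mapping[str, str] | None = None,
        max_categorical_levels: int = DEFAULT_CATEGORICAL_THRESHOLD,
        validate: bool = True,
    ) -> "LongitudinalDataset":
        for col in (id_col, time_col):
            if col not in df.columns:
                hint = ""
                if col == time_col:
                    hint = (
                        " — the expected layout is long format (one row per"
                        " subject x visit with an explicit time column); wide"
                        " tables must be melted first"
                    )
                raise ConfigurationError(f"column {col!r} not found in table{hint}")
        value_cols = [c for c in df.columns if c not in (id_col, time_col)]
        if isinstance(spec, str):
            if spec != "infer":
                raise ConfigurationError(f"spec must be a list of VariableSpec or 'infer', got {spec!r}")
            variables = tuple(
                _infer_variable(df[c], max_categorical_levels) for c in value_cols
            )
        else:
            variables = tuple(spec)
            declared = {v.name for v in variables}
            missing = declared - set(value_cols)
            if missing:
                raise ConfigurationError(f"declared variables not in table: {sorted(missing)}")
            value_cols = [v.name for v in variables]
        frame = df[[id_col, time_col, *value_cols]].copy()
        for v in variables:
            if not v.is_continuous:
                frame[v.name] = frame[v.name].astype("string").astype(object)
        ds = cls(
            data=frame.reset_index(drop=True),
            id_col=id_col,
            time_col=time_col,
            variables=variables,
            groups=dict(groups) if groups is not None else None,
        )
        if validate:
            ds.require_valid()
        return ds

    # -- accessors ---------------------------------------------------------
    @property
    def subjects(self) -> list:
        """Subject ids in first-appearance order."""
        return list(pd.unique(self.data[self.id_col]))

    @property
    def n_subjects(self) -> int:
        return self.data[self.id_col].nunique()

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def continuous_variables(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.is_continuous]

    @property
    def categorical_variables(self) -> list[VariableSpec]:
        return [v for v in self.variables if not v.is_continuous]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data[self.time_col], dtype=float)

    def values(self) -> pd.DataFrame:
        """The observation columns only (no id/time)."""
        return self.data[self.variable_names]

    def subset_subjects(self, subject_ids: Iterable) -> "LongitudinalDataset":
        keep = set(subject_ids)
        mask = self.data[self.id_col].isin(keep)
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    # -- validation --------------------------------------------------------
    def require_valid(self) -> None:
        findings = validate_dataset(self)
        if findings:
            raise DatasetValidationError(findings)


def _infer_variable(col: pd.Series, max_categorical_levels: int) -> VariableSpec:
    """Infer a spec from a column: numeric -> continuous unless it looks like
    a small integer scale (<= threshold distinct integral values)."""
    values = col.dropna()
    if pd.api.types.is_numeric_dtype(values):
        distinct = pd.unique(values)
        integral = np.all(np.asarray(distinct, dtype=float) == np.floor(np.asarray(distinct, dtype=float)))
        if integral and len(distinct) <= max_categorical_levels:
            levels = tuple(str(int(v)) for v in sorted(distinct))
            logger.info(
                "inferred %r as categorical (%d distinct integral values <= %d)",
                col.name, len(distinct), max_categorical_levels,
            )
            return VariableSpec(str(col.name), CATEGORICAL, levels)
        logger.info("inferred %r as continuous", col.name)
        return VariableSpec(str(col.name), CONTINUOUS)
    levels = tuple(sorted({str(v) for v in pd.unique(values)}))
    if len(levels) < 2:
        levels = tuple(levels) + ("__other__",)
    logger.info("inferred %r as categorical (non-numeric, %d levels)", col.name, len(levels))
    return VariableSpec(str(col.name), CATEGORICAL, levels)


def validate_dataset(ds: LongitudinalDataset) -> list[Finding]:
    """Check all dataset invariants; return one finding per violation.

    The returned list is deterministic and order-stable for a fixed input:
    checks run in a fixed order and locations follow row order.
    """
    findings: list[Finding] = []
    df = ds.data

    names = [v.name for v in ds.variables]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            findings.append(Finding("duplicate-variable", f"variable name {n!r} declared twice", f"variable {n!r}"))
        seen.add(n)

    for col in (ds.id_col, ds.time_col, *names):
        if col not in df.columns:
            findings.append(Finding("missing-column", f"column {col!r} absent from table", f"column {col!r}"))
    present = [c for c in (ds.id_col, ds.time_col, *names) if c in df.columns]

    # missing cells (complete-data assumption)
    for col in present:
        isna = df[col].isna()
        for row in np.flatnonzero(isna.to_numpy()):
            findings.append(
                Finding("missing-value", f"missing value in column {col!r}", f"row {row}, column {col!r}")
            )

    if ds.time_col in df.columns:
        t = pd.to_numeric(df[ds.time_col], errors="coerce")
        bad = ~np.isfinite(t.to_numpy(dtype=float, na_value=np.nan))
        for row in np.flatnonzero(bad):
            findings.append(
                Finding("non-finite-time", f"time value {df[ds.time_col].iloc[row]!r} is not finite",
                        f"row {row}, column {ds.time_col!r}")
            )

    if ds.id_col in df.columns and ds.time_col in df.columns:
        dup = df.duplicated(subset=[ds.id_col, ds.time_col], keep="first")
        for row in np.flatnonzero(dup.to_numpy()):
            findings.append(
                Finding(
                    "duplicate-visit",
                    f"duplicate (subject, time) pair ({df[ds.id_col].iloc[row]!r}, {df[ds.time_col].iloc[row]!r})",
                    f"row {row}",
                )
            )

    for v in ds.variables:
        if v.name not in df.columns:
            continue
        if v.is_continuous:
            col = pd.to_numeric(df[v.name], errors="coerce")
            bad = col.isna() & ~df[v.name].isna()
            for row in np.flatnonzero(bad.to_numpy()):
                findings.append(
                    Finding("non-numeric", f"non-numeric value {df[v.name].iloc[row]!r} in continuous variable",
                            f"row {row}, column {v.name!r}")
                )
        else:
            allowed = set(v.levels or ())
            col = df[v.name]
            bad = ~col.isna() & ~col.astype(str).isin(allowed)
            for row in np.flatnonzero(bad.to_numpy()):
                findings.append(
                    Finding(
                        "unknown-level",
                        f"value {col.iloc[row]!r} not among declared levels {sorted(allowed)}",
                        f"row {row}, column {v.name!r}",
                    )
                )
    return findings


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    return ","


def read_long_table(
    path: str | Path,
    id_col: str,
    time_col: str,
    spec: Sequence[VariableSpec] | str = "infer",
    *,
    delimiter: str | None = None,
    groups: Mapping[str, str] | None = None,
    max_categorical_levels: int = DEFAULT_CATEGORICAL_THRESHOLD,
) -> LongitudinalDataset:
    """Read and validate a long-format CSV/TSV.

    The delimiter is sniffed from the extension (``.tsv``/``.tab``/``.txt``
    -> tab, otherwise comma) unless given explicitly. With ``spec="infer"``,
    numeric columns become continuous unless they take at most
    ``max_categorical_levels`` distinct integral values, in which case they
    are treated as categorical (questionnaire items are commonly small
    integer scales); explicit specs always win.

    Raises
    ------
    ConfigurationError
        If ``id_col``/``time_col`` are absent.
    DatasetValidationError
        On any missing cell, duplicate (subject, time) pair, or other
        invariant violation; findings name the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    return LongitudinalDataset.from_frame(
        df, id_col, time_col, spec,
        groups=groups, max_categorical_levels=max_categorical_levels,
    )


def write_long_table(ds: LongitudinalDataset, path: str | Path, *, delimiter: str | None = None) -> None:
    """Write the dataset back to CSV/TSV (value-level round trip with
    :func:`read_long_table`)."""
    path = Path(path)
    ds.data.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)
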