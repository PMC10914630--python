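"""Data containers and TSV I/O for postmortem brain proteomics cohorts.

The unit of analysis is a protein-by-sample log2 expression matrix together
with a per-sample metadata table describing diagnosis group, brain region,
preparation (bulk homogenate vs synaptosome), demographic/technical
covariates, and the clock time of death with sunrise/sunset on the day of
death.  Everything downstream (differential expression, rhythmicity,
co-expression networks) consumes the :class:`Dataset` built here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("unaffected", "OUD")
REGIONS = ("NAc", "DLPFC")
PREPARATIONS = ("homogenate", "synaptosome")
SEXES = ("M", "F")

#: exact column names required in a metadata TSV
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "region",
    "preparation",
    "sex",
    "age",
    "pmi",
    "plex",
    "tod",
    "sunrise",
    "sunset",
)


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def parse_clock(value) -> float:
    """Parse a clock time given as ``"HH:MM"`` or decimal hours into hours.

    The result must lie in ``[0, 24)``.
    """
    if isinstance(value, str) and ":" in value:
        m = re.fullmatch(r"\s*(\d{1,2}):(\d{2})\s*", value)
        if m is None:
            raise DataError(f"unparseable clock time {value!r}")
        hours = int(m.group(1)) + int(m.group(2)) / 60.0
    else:
        try:
            hours = float(value)
        except (TypeError, ValueError) as exc:
            raise DataError(f"unparseable clock time {value!r}") from exc
    if not (0.0 <= hours < 24.0):
        raise DataError(f"clock time {value!r} outside [0, 24)")
    return hours


@dataclass
class ExpressionMatrix:
    """Protein-by-sample matrix of log2 intensities.

    Parameters
    ----------
    protein_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        ``(n_proteins, n_samples)`` float array.  Missing values may be NaN
        until :meth:`drop_incomplete` is applied.
    is_log2
        Whether ``values`` are on the log2 scale.
    """

    protein_ids: list
    sample_ids: list
    values: np.ndarray
    is_log2: bool = True

    def __post_init__(self):
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_p = _duplicates(self.protein_ids)
        if dup_p:
            raise DataError(f"duplicate protein id(s): {sorted(dup_p)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise DataError(f"duplicate sample id(s): {sorted(dup_s)}")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_log2: bool = True) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), is_log2)

    def select_proteins(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [str(i) for i in ids]
        pos = {p: i for i, p in enumerate(self.protein_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"unknown protein id(s): {missing[:5]}")
        idx = [pos[i] for i in ids]
        return ExpressionMatrix(ids, list(self.sample_ids), self.values[idx], self.is_log2)

    def select_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [str(i) for i in ids]
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"unknown sample id(s): {missing[:5]}")
        idx = [pos[i] for i in ids]
        return ExpressionMatrix(list(self.protein_ids), ids, self.values[:, idx], self.is_log2)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-sample metadata for one preparation of one subject."""

    sample_id: str
    subject_id: str
    group: str
    region: str
    preparation: str
    sex: str
    age: float
    pmi: float
    plex: str
    tod_clock: float
    sunrise: float
    sunset: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DataError(f"group {self.group!r} not in {GROUPS}")
        if self.region not in REGIONS:
            raise DataError(f"region {self.region!r} not in {REGIONS}")
        if self.preparation not in PREPARATIONS:
            raise DataError(f"preparation {self.preparation!r} not in {PREPARATIONS}")
        if self.sex not in SEXES:
            raise DataError(f"sex {self.sex!r} not in {SEXES}")
        for name in ("tod_clock", "sunrise", "sunset"):
            v = getattr(self, name)
            if not (0.0 <= v < 24.0):
                raise DataError(f"{name}={v} outside [0, 24) for sample {self.sample_id}")


@dataclass
class Dataset:
    """An expression matrix aligned 1:1 with its sample metadata."""

    expr: ExpressionMatrix
    subjects: list

    def __post_init__(self):
        if [s.sample_id for s in self.subjects] != list(self.expr.sample_ids):
            raise DataError("subjects are not aligned with expression columns")
        per_key = {}
        for s in self.subjects:
            key = (s.subject_id, s.region, s.preparation)
            if key in per_key:
                raise DataError(
                    f"subject {s.subject_id} contributes more than one sample for "
                    f"({s.region}, {s.preparation})"
                )
            per_key[key] = s.sample_id

    # -- accessors ------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.expr.sample_ids)

    @property
    def protein_ids(self) -> list:
        return list(self.expr.protein_ids)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                dict(
                    sample_id=s.sample_id, subject_id=s.subject_id, group=s.group,
                    region=s.region, preparation=s.preparation, sex=s.sex,
                    age=s.age, pmi=s.pmi, plex=s.plex, tod=s.tod_clock,
                    sunrise=s.sunrise, sunset=s.sunset,
                )
            )
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))

    def select_group(self, group: str) -> "Dataset":
        if group not in GROUPS:
            raise DataError(f"group {group!r} not in {GROUPS}")
        keep = [s for s in self.subjects if s.group == group]
        if not keep:
            raise DataError(f"no samples in group {group!r}")
        expr = self.expr.select_samples([s.sample_id for s in keep])
        return Dataset(expr, keep)

    def select_proteins(self, ids: Iterable[str]) -> "Dataset":
        return Dataset(self.expr.select_proteins(ids), list(self.subjects))

    def drop_incomplete(self, max_missing_frac: float = 0.0) -> "Dataset":
        """Drop proteins exceeding ``max_missing_frac`` missing values in either group.

        Missingness handling is applied before analysis; all downstream stages
        assume complete rows.
        """
        groups = self.groups
        missing = np.isnan(self.expr.values)
        keep = np.ones(self.expr.n_proteins, dtype=bool)
        for g in np.unique(groups):
            cols = groups == g
            frac = missing[:, cols].mean(axis=1)
            keep &= frac <= max_missing_frac
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d protein(s) exceeding missingness threshold", n_drop)
        ids = [p for p, k in zip(self.expr.protein_ids, keep) if k]
        ds = self.select_proteins(ids)
        # residual missing values within tolerance are mean-imputed per group
        vals = ds.expr.values
        if np.isnan(vals).any():
            for g in np.unique(groups):
                cols = groups == g
                block = vals[:, cols]
                row_mean = np.nanmean(block, axis=1, keepdims=True)
                block = np.where(np.isnan(block), row_mean, block)
                vals[:, cols] = block
            ds.expr.values = vals
        return ds


def _duplicates(items: Sequence) -> set:
    seen, dups = set(), set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression(path, already_log2: bool = True, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Read an expression TSV (first column ``protein_id``, remaining columns samples).

    If ``already_log2`` is false, values are replaced by
    ``log2(value + pseudocount)``.  Empty cells become NaN (missing).
    Duplicate protein or sample ids, and non-numeric cells, are hard errors.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dup_s = _duplicates(sample_ids)
    if dup_s:
        raise DataError(f"duplicate sample id(s) in header of {path}: {sorted(dup_s)}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    protein_ids = df.iloc[:, 0].tolist()
    dup_p = _duplicates(protein_ids)
    if dup_p:
        raise DataError(f"duplicate protein id(s) in {path}: {sorted(dup_p)}")
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)   # exact (correctly rounded) parse
            except ValueError:
                raise DataError(
                    f"non-numeric cell {cell!r} at protein {protein_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    if not already_log2:
        logger.info("log2-transforming linear intensities with pseudocount %g", pseudocount)
        values = np.log2(values + pseudocount)
    return ExpressionMatrix(protein_ids, sample_ids, values, is_log2=True)


def write_expression(em: ExpressionMatrix, path) -> None:
    df = em.to_frame()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_metadata(path) -> list:
    """Read a metadata TSV into a list of :class:`SubjectRecord`.

    Required columns (exact names): sample_id, subject_id, group, region,
    preparation, sex, age, pmi, plex, tod, sunrise, sunset.  Clock fields
    accept ``"HH:MM"`` or decimal hours.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"metadata {path} missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                group=row["group"],
                region=row["region"],
                preparation=row["preparation"],
                sex=row["sex"],
                age=float(row["age"]),
                pmi=float(row["pmi"]),
                plex=row["plex"],
                tod_clock=parse_clock(row["tod"]),
                sunrise=parse_clock(row["sunrise"]),
                sunset=parse_clock(row["sunset"]),
            )
        )
    if not records:
        logger.warning("metadata %s contains a header but no rows", path)
    return records


def write_metadata(subjects: Iterable[SubjectRecord], path) -> None:
    rows = []
    for s in subjects:
        rows.append([
            s.sample_id, s.subject_id, s.group, s.region, s.preparation, s.sex,
            repr(s.age), repr(s.pmi), s.plex, repr(s.tod_clock), repr(s.sunrise),
            repr(s.sunset),
        ])
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def align_dataset(expr: ExpressionMatrix, subjects: Sequence[SubjectRecord]) -> Dataset:
    """Restrict both structures to the shared sample ids, in metadata order.

    Idempotent; the count of dropped samples is logged.  An empty
    intersection is a hard error.
    """
    expr_ids = set(expr.sample_ids)
    keep = [s for s in subjects if s.sample_id in expr_ids]
    n_drop = (len(subjects) - len(keep)) + (len(expr.sample_ids) - len(keep))
    if not keep:
        raise DataError("expression and metadata share no sample ids")
    if n_drop:
        logger.info("align_dataset dropped %d unmatched sample(s)", n_drop)
    aligned = expr.select_samples([s.sample_id for s in keep])
    return Dataset(aligned, list(keep))
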