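"""From per-admission diagnosis records to a per-patient transaction database.

The mining unit is the *patient*, not the admission: every ICD-10 category a
patient was ever coded with, across all hospitalizations, is merged into one
binary transaction. Patient-level selection mirrors the source cohort:

1. raw codes are normalized to three-character categories (malformed codes
   are skipped-with-count by default, or abort in strict mode);
2. excluded chapters and "other"-description codes are removed;
3. patients with a single distinct admission in the *raw* input are dropped
   (the hospitalization count is assessed before code-level exclusion);
4. duplicate categories collapse to one item per patient;
5. patients left with an empty category set are dropped.

Support denominators everywhere use ``n_transactions`` — the number of
retained patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .icd10 import ExclusionPolicy, Icd10ParseError, parse_code, _CATEGORY_RE

__all__ = [
    "DiagnosisRecord",
    "TransactionDB",
    "FrequencyTable",
    "RunLog",
    "EmptyCohortError",
    "build_transactions",
    "frequency_table",
    "to_binary_matrix",
    "from_binary_matrix",
    "read_records_csv",
    "write_records_csv",
    "write_transactions_long_csv",
]

RECORD_COLUMNS = ["patient_id", "admission_id", "icd10_code", "description"]


class EmptyCohortError(ValueError):
    """No eligible transactions remain after filtering."""


@dataclass(frozen=True)
class DiagnosisRecord:
    """One coded diagnosis within one admission of one patient."""

    patient_id: str
    admission_id: str
    code: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id or not self.admission_id:
            raise ValueError("patient_id and admission_id must be non-empty")


@dataclass
class RunLog:
    """Stage counts accumulated while building the transaction database."""

    n_raw_rows: int = 0
    n_malformed_dropped: int = 0
    n_excluded_codes: int = 0
    n_patients_raw: int = 0
    n_single_admission_dropped: int = 0
    n_empty_after_exclusion_dropped: int = 0
    n_transactions: int = 0
    n_codes_ingested: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class TransactionDB:
    """Patient-by-category binary incidence structure.

    ``items`` is the lexicographically sorted universe of distinct
    categories; ``transactions`` maps each retained patient to their
    deduplicated category set. ``code_occurrences`` keeps the retained
    per-row categories (with multiplicity) for frequency tables.
    """

    items: list[str]
    transactions: dict[str, frozenset[str]]
    n_codes_ingested: int
    code_occurrences: list[str] = field(default_factory=list, repr=False)
    log: RunLog = field(default_factory=RunLog, repr=False)

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def __post_init__(self) -> None:
        universe = set(self.items)
        for pid, cats in self.transactions.items():
            if not cats:
                raise ValueError(f"empty transaction for patient {pid!r}")
            if not cats <= universe:
                raise ValueError(
                    f"transaction for {pid!r} contains items outside the universe: "
                    f"{sorted(cats - universe)}"
                )


def _records_frame(records: Iterable[DiagnosisRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"records frame is missing columns {missing}")
        return records[RECORD_COLUMNS].copy()
    rows = [(r.patient_id, r.admission_id, r.code, r.description) for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def build_transactions(
    records: Iterable[DiagnosisRecord] | pd.DataFrame,
    policy: ExclusionPolicy | None = None,
    *,
    strict: bool = False,
) -> TransactionDB:
    """Build the per-patient binary transaction database.

    Parameters
    ----------
    records
        Diagnosis records, one per coded diagnosis per admission; either a
        sequence of :class:`DiagnosisRecord` or a DataFrame with columns
        ``patient_id, admission_id, icd10_code, description``.
    policy
        Code-level exclusion rules; defaults to the standard policy
        (chapters V/W/X/Y/Z, token "other").
    strict
        If True, a malformed ICD-10 code aborts the run; by default
        malformed rows are skipped and counted in the run log.

    Raises
    ------
    EmptyCohortError
        If no eligible transactions remain after all filters.
    """
    if policy is None:
        policy = ExclusionPolicy()
    df = _records_frame(records)
    log = RunLog(n_raw_rows=len(df))
    if len(df) == 0:
        raise EmptyCohortError("no input records")
    if df["patient_id"].astype(str).str.len().eq(0).any() or df[
        "admission_id"
    ].astype(str).str.len().eq(0).any():
        raise ValueError("patient_id and admission_id must be non-empty")

    df = df.astype({"patient_id": str, "admission_id": str, "icd10_code": str})
    df["description"] = df["description"].fillna("").astype(str)
    log.n_patients_raw = df["patient_id"].nunique()

    # Single-hospitalization filter on the RAW input, before any code filtering.
    adm_counts = df.groupby("patient_id")["admission_id"].nunique()
    multi = adm_counts.index[adm_counts >= 2]
    log.n_single_admission_dropped = log.n_patients_raw - len(multi)
    df = df[df["patient_id"].isin(set(multi))]

    # Vectorized category normalization; fall back on parse_code for messages.
    cleaned = df["icd10_code"].str.replace(r"\s+", "", regex=True).str.upper()
    category = cleaned.str[:3]
    valid = category.str.match(_CATEGORY_RE.pattern)
    if not valid.all():
        bad = df.loc[~valid, "icd10_code"]
        if strict:
            parse_code(bad.iloc[0])  # raises Icd10ParseError naming the value
            raise Icd10ParseError(f"malformed ICD-10 code {bad.iloc[0]!r}")
        log.n_malformed_dropped = int((~valid).sum())
        df = df[valid]
        category = category[valid]
    df = df.assign(category=category)

    # Code-level exclusion: chapter rule + standalone-word description rule.
    excl = df["category"].str[0].isin(policy.excluded_chapters)
    token_re = policy._token_re()
    if token_re is not None:
        excl |= df["description"].str.contains(token_re, regex=True)
    log.n_excluded_codes = int(excl.sum())
    df = df[~excl]

    # Patients whose retained set is empty vanish here (they have no rows).
    kept_patients = df["patient_id"].nunique()
    log.n_empty_after_exclusion_dropped = len(multi) - kept_patients
    if kept_patients == 0:
        raise EmptyCohortError("no eligible transactions after filtering")

    log.n_codes_ingested = len(df)
    log.n_transactions = kept_patients

    transactions = {
        pid: frozenset(cats)
        for pid, cats in df.groupby("patient_id")["category"].unique().items()
    }
    items = sorted(df["category"].unique())
    return TransactionDB(
        items=items,
        transactions=transactions,
        n_codes_ingested=len(df),
        code_occurrences=df["category"].tolist(),
        log=log,
    )


@dataclass(frozen=True)
class FrequencyTable:
    """Code-occurrence frequency distribution at chapter or category level."""

    level: str
    counts: dict[str, int]
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.counts, key=lambda k: (-self.counts[k], k))
        return pd.DataFrame(
            {
                self.level: keys,
                "count": [self.counts[k] for k in keys],
                "fraction": [self.fractions[k] for k in keys],
            }
        )


def frequency_table(records_retained: Sequence[str], level: str) -> FrequencyTable:
    """Frequency distribution of retained code occurrences.

    Counts every retained code occurrence (not deduplicated per patient),
    grouped by ``level``: ``"chapter"`` (first letter) or ``"category"``
    (the three-character code itself). Fractions are normalized by the
    total number of retained codes.
    """
    if level not in ("chapter", "category"):
        raise ValueError(f"unknown level {level!r}; expected 'chapter' or 'category'")
    if len(records_retained) == 0:
        raise ValueError("no retained codes to tabulate")
    keys = (
        [c[0] for c in records_retained] if level == "chapter" else list(records_retained)
    )
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    total = len(keys)
    fractions = {k: v / total for k, v in counts.items()}
    return FrequencyTable(level=level, counts=counts, fractions=fractions)


def to_binary_matrix(db: TransactionDB) -> pd.DataFrame:
    """Dense boolean incidence matrix: rows = patients (sorted by id),
    columns = the item universe (lexicographic). Cell True iff the patient
    ever carried the category."""
    pids = sorted(db.transactions)
    data = np.zeros((len(pids), len(db.items)), dtype=bool)
    col = {item: j for j, item in enumerate(db.items)}
    for i, pid in enumerate(pids):
        for cat in db.transactions[pid]:
            data[i, col[cat]] = True
    return pd.DataFrame(data, index=pd.Index(pids, name="patient_id"), columns=db.items)


def from_binary_matrix(matrix: pd.DataFrame) -> TransactionDB:
    """Inverse of :func:`to_binary_matrix` (lossless round trip)."""
    items = sorted(str(c) for c in matrix.columns)
    transactions = {}
    for pid, row in matrix.iterrows():
        cats = frozenset(str(c) for c in matrix.columns[row.astype(bool)])
        if cats:
            transactions[str(pid)] = cats
    if not transactions:
        raise EmptyCohortError("binary matrix has no non-empty rows")
    return TransactionDB(
        items=items,
        transactions=transactions,
        n_codes_ingested=int(matrix.to_numpy(dtype=bool).sum()),
    )


def read_records_csv(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a diagnosis-records file (UTF-8, header row) into a DataFrame
    with the canonical columns."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[RECORD_COLUMNS]


def write_records_csv(
    records: Iterable[DiagnosisRecord] | pd.DataFrame,
    path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    _records_frame(records).to_csv(path, sep=delimiter, index=False)


def write_transactions_long_csv(db: TransactionDB, path: str | Path) -> None:
    """Long format: one (patient_id, category) row per item per patient."""
    rows = [
        (pid, cat)
        for pid in sorted(db.transactions)
        for cat in sorted(db.transactions[pid])
    ]
    pd.DataFrame(rows, columns=["patient_id", "category"]).to_csv(path, index=False)
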