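"""Synthetic longitudinal diagnosis records with planted association structure.

The generator emulates the shape of a hospital discharge-diagnosis extract:
multiple admissions per patient, four-character ICD-10 codes, free-text
descriptions, a fraction of single-admission decoy patients, and injected
excluded codes (V/W/X/Y/Z chapters and "other"-description codes). Disease
co-occurrence is planted through :class:`PlantedRule` triples with
closed-form expected support/confidence/lift, so end-to-end parameter
recovery can be checked against known truth.

Per eligible patient, for each planted rule: the full antecedent is carried
with probability ``p_antecedent``; the consequent appears with probability
``p_conditional`` given the antecedent and ``p_background`` otherwise.
Noise items are independent Bernoulli draws at their marginal prevalence.
Items are scattered uniformly across the patient's admissions (with one
item re-coded in a second admission, as chronic conditions are at each
stay, so every eligible patient materializes at least two admissions).

All randomness flows through one named ``numpy`` generator; a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .icd10 import _CATEGORY_RE
from .transactions import RECORD_COLUMNS, DiagnosisRecord

__all__ = [
    "PlantedRule",
    "SyntheticCohortConfig",
    "expected_metrics",
    "generate_records",
    "generate_records_frame",
    "load_cohort_config",
]

# Generic filler category assigned to eligible patients whose stochastic
# draws produced no condition, so the transaction denominator equals
# n_patients (R69: unknown and unspecified causes of morbidity).
FILLER_CATEGORY = "R69"

_DESCRIPTIONS = {
    "I10": "Essential (primary) hypertension",
    "I63": "Cerebral infarction",
    "E11": "Type 2 diabetes mellitus",
    "C34": "Malignant neoplasm of bronchus and lung",
    "K29": "Gastritis and duodenitis",
    "J18": "Pneumonia, organism unspecified",
    "N18": "Chronic kidney disease",
    "I25": "Chronic ischaemic heart disease",
    FILLER_CATEGORY: "Unknown and unspecified causes of morbidity",
}

# Injected codes that the exclusion rules must remove: external-cause /
# health-status chapters, and residual categories described with "other".
_EXCLUDED_CHAPTER_POOL = [
    ("Z51", "Care involving chemotherapy"),
    ("Z38", "Liveborn infants according to place of birth"),
    ("V01", "Pedestrian injured in collision with pedal cycle"),
    ("W19", "Unspecified fall"),
    ("X59", "Exposure to unspecified factor"),
    ("Y83", "Surgical operation as the cause of abnormal reaction"),
]
_OTHER_DESC_POOL = [
    ("B99", "Other and unspecified infectious diseases"),
    ("L98", "Other disorders of skin and subcutaneous tissue"),
    ("T14", "Other injury of unspecified body region"),
]


def _valid_category(cat: str) -> bool:
    return bool(_CATEGORY_RE.match(cat))


@dataclass(frozen=True)
class PlantedRule:
    """A planted antecedent -> consequent dependency with known metrics."""

    antecedent: tuple[str, ...]
    consequent: str
    p_antecedent: float
    p_conditional: float
    p_background: float

    def __post_init__(self) -> None:
        ante = tuple(self.antecedent)
        object.__setattr__(self, "antecedent", ante)
        if not 1 <= len(ante) <= 2:
            raise ValueError("antecedent must contain one or two categories")
        cats = set(ante) | {self.consequent}
        if len(cats) != len(ante) + 1:
            raise ValueError("antecedent and consequent must be disjoint")
        for c in cats:
            if not _valid_category(c):
                raise ValueError(f"invalid ICD-10 category {c!r}")
        for name in ("p_antecedent", "p_conditional", "p_background"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self.antecedent) | {self.consequent}


def expected_metrics(rule: PlantedRule) -> tuple[float, float, float]:
    """Closed-form (support, confidence, lift) the planted rule induces.

    support = p_antecedent * p_conditional; confidence = p_conditional;
    lift = p_conditional / P(consequent) with
    P(consequent) = p_antecedent*p_conditional + (1-p_antecedent)*p_background.
    """
    support = rule.p_antecedent * rule.p_conditional
    confidence = rule.p_conditional
    marginal = support + (1 - rule.p_antecedent) * rule.p_background
    lift = confidence / marginal if marginal > 0 else float("nan")
    return support, confidence, lift


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults plant a single strong cerebrovascular dependency
    (I63 -> I10 with p_antecedent 0.3, p_conditional 0.8, p_background 0.1)
    over a background of common hospital diagnoses at realistic marginal
    prevalences, with 10% single-admission decoy patients and a 5%
    per-admission rate of injected excluded codes.
    """

    n_patients: int = 50_000
    seed: int = 0
    planted_rules: tuple[PlantedRule, ...] = (
        PlantedRule(("I63",), "I10", 0.3, 0.8, 0.1),
    )
    noise_items: Mapping[str, float] = field(
        default_factory=lambda: {
            "E11": 0.20,
            "C34": 0.10,
            "K29": 0.12,
            "J18": 0.08,
            "N18": 0.05,
        }
    )
    admissions_per_patient: tuple[int, int] = (2, 4)
    frac_single_admission: float = 0.10
    frac_excluded_codes: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        object.__setattr__(self, "noise_items", dict(self.noise_items))
        lo, hi = self.admissions_per_patient
        if lo < 2 or hi < lo:
            raise ValueError(
                "admissions_per_patient must be (lo, hi) with 2 <= lo <= hi"
            )
        if not (0 <= self.frac_single_admission <= 1):
            raise ValueError("frac_single_admission must be in [0, 1]")
        if not (0 <= self.frac_excluded_codes <= 1):
            raise ValueError("frac_excluded_codes must be in [0, 1]")
        planted = set()
        for rule in self.planted_rules:
            planted |= rule.categories
        noise = set(self.noise_items)
        for cat, prev in self.noise_items.items():
            if not _valid_category(cat):
                raise ValueError(f"invalid noise category {cat!r}")
            if not 0 <= prev <= 1:
                raise ValueError(f"noise prevalence for {cat} must be in [0, 1]")
        if planted & noise:
            raise ValueError(
                f"planted and noise categories overlap: {sorted(planted & noise)}"
            )
        if FILLER_CATEGORY in planted | noise:
            raise ValueError(f"{FILLER_CATEGORY} is reserved for the filler item")
        seen: set[str] = set()
        for rule in self.planted_rules:
            if seen & rule.categories:
                warnings.warn(
                    "planted rules share categories; closed-form expected "
                    "metrics assume independent rules",
                    stacklevel=2,
                )
            seen |= rule.categories

    @property
    def item_universe(self) -> list[str]:
        cats: set[str] = set()
        for rule in self.planted_rules:
            cats |= rule.categories
        cats |= set(self.noise_items)
        cats.add(FILLER_CATEGORY)
        return sorted(cats)


def _description(cat: str) -> str:
    return _DESCRIPTIONS.get(cat, f"Condition of category {cat}")


def generate_records_frame(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Generate the cohort as a records DataFrame (fast path).

    Columns are ``patient_id, admission_id, icd10_code, description`` — the
    same dialect the transactions module reads. Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cats = config.item_universe
    col = {c: j for j, c in enumerate(cats)}

    present = np.zeros((n, len(cats)), dtype=bool)
    for rule in config.planted_rules:
        ant = rng.random(n) < rule.p_antecedent
        p_cons = np.where(ant, rule.p_conditional, rule.p_background)
        cons = rng.random(n) < p_cons
        for a in rule.antecedent:
            present[:, col[a]] |= ant
        present[:, col[rule.consequent]] |= cons
    for cat, prev in config.noise_items.items():
        present[:, col[cat]] |= rng.random(n) < prev
    empty = ~present.any(axis=1)
    present[empty, col[FILLER_CATEGORY]] = True

    lo, hi = config.admissions_per_patient
    k = rng.integers(lo, hi + 1, size=n)

    row_idx, col_idx = np.nonzero(present)
    adm_idx = np.floor(rng.random(len(row_idx)) * k[row_idx]).astype(np.int64)

    # Re-code each patient's first item in a second, distinct admission so
    # every eligible patient materializes >= 2 admissions in the output.
    _, first_pos = np.unique(row_idx, return_index=True)
    extra_rows = row_idx[first_pos]
    extra_cols = col_idx[first_pos]
    extra_adm = (adm_idx[first_pos] + 1) % k[extra_rows]

    row_idx = np.concatenate([row_idx, extra_rows])
    col_idx = np.concatenate([col_idx, extra_cols])
    adm_idx = np.concatenate([adm_idx, extra_adm])

    cat_arr = np.asarray(cats, dtype=object)
    frames = [
        pd.DataFrame(
            {
                "_p": row_idx,
                "_a": adm_idx,
                "_cat": cat_arr[col_idx],
                "_desc_other": False,
            }
        )
    ]

    # Injected excluded codes, at a per-admission rate.
    if config.frac_excluded_codes > 0:
        total_adm = int(k.sum())
        adm_patient = np.repeat(np.arange(n), k)
        offsets = np.concatenate([[0], np.cumsum(k)[:-1]])
        adm_number = np.arange(total_adm) - np.repeat(offsets, k)
        hit = rng.random(total_adm) < config.frac_excluded_codes
        if hit.any():
            pool = _EXCLUDED_CHAPTER_POOL + _OTHER_DESC_POOL
            pick = rng.integers(0, len(pool), size=int(hit.sum()))
            frames.append(
                pd.DataFrame(
                    {
                        "_p": adm_patient[hit],
                        "_a": adm_number[hit],
                        "_cat": np.asarray([pool[i][0] for i in pick], dtype=object),
                        "_desc_other": True,
                    }
                ).assign(
                    _desc=np.asarray([pool[i][1] for i in pick], dtype=object)
                )
            )

    df = pd.concat(frames, ignore_index=True)
    if "_desc" not in df.columns:
        df["_desc"] = None

    # Single-admission decoy patients, dropped by the eligibility filter.
    m = int(round(config.frac_single_admission * n))
    if m > 0:
        decoy_cats = [c for c in cats if c != FILLER_CATEGORY] or cats
        pick = rng.integers(0, len(decoy_cats), size=m)
        decoys = pd.DataFrame(
            {
                "_p": np.arange(n, n + m),
                "_a": np.zeros(m, dtype=np.int64),
                "_cat": np.asarray([decoy_cats[i] for i in pick], dtype=object),
                "_desc_other": False,
                "_desc": None,
            }
        )
        df = pd.concat([df, decoys], ignore_index=True)

    fourth = rng.integers(0, 10, size=len(df))
    df["patient_id"] = "P" + pd.Series(df["_p"]).astype(str).str.zfill(7)
    df["admission_id"] = df["patient_id"] + "-A" + pd.Series(df["_a"]).astype(str)
    df["icd10_code"] = df["_cat"].astype(str) + "." + pd.Series(fourth).astype(str)
    df["description"] = df["_desc"].where(
        df["_desc"].notna(), df["_cat"].map(_description)
    )

    df = df[RECORD_COLUMNS]
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def generate_records(config: SyntheticCohortConfig) -> list[DiagnosisRecord]:
    """Generate the cohort as :class:`DiagnosisRecord` objects."""
    frame = generate_records_frame(config)
    return [
        DiagnosisRecord(
            patient_id=r.patient_id,
            admission_id=r.admission_id,
            code=r.icd10_code,
            description=r.description,
        )
        for r in frame.itertuples(index=False)
    ]


def load_cohort_config(source: str | Path | Mapping[str, Any]) -> SyntheticCohortConfig:
    """Build a config from a YAML/JSON document or an equivalent mapping."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ValueError("cohort config must be a mapping")
    kwargs: dict[str, Any] = dict(data)
    if "planted_rules" in kwargs:
        kwargs["planted_rules"] = tuple(
            r
            if isinstance(r, PlantedRule)
            else PlantedRule(
                antecedent=tuple(r["antecedent"]),
                consequent=r["consequent"],
                p_antecedent=float(r["p_antecedent"]),
                p_conditional=float(r["p_conditional"]),
                p_background=float(r["p_background"]),
            )
            for r in kwargs["planted_rules"]
        )
    if "admissions_per_patient" in kwargs:
        kwargs["admissions_per_patient"] = tuple(kwargs["admissions_per_patient"])
    return SyntheticCohortConfig(**kwargs)
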