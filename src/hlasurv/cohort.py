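"""Cohort assembly: clinical table + allele table -> analysis-ready cohort.

A cohort pairs one clinical record per patient (survival outcome plus
covariates) with a binary patient x superallele presence matrix built
by collapsing the typed four-digit alleles.  Carriage is scored
presence/absence only: a patient carrying two protein-level variants of
the same allele group (or the same allele on both haplotypes) is coded
1, never 2.

Patients lacking overall-survival time or vital status are dropped at
load with a logged count.  Missing clinical covariates propagate as NaN
and are deleted listwise inside each analysis that uses them, never
globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import (
    AlleleParseError,
    Superallele,
    parse_allele,
    superallele_sort_key,
    to_superallele,
)

__all__ = [
    "CohortLoadError",
    "Cohort",
    "read_clinical_table",
    "read_allele_table",
    "build_presence_matrix",
    "read_cohort",
    "encode_clinical_binary",
    "write_cohort",
]

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "stage",
    "tumor_status",
    "breslow_depth",
    "os_months",
    "event",
]

_NA_TOKENS = {"", "na", "nan", "none", "null", "missing", "[not available]", "[unknown]", "[discrepancy]"}

_STAGES = ("0", "I", "II", "III", "IV")


class CohortLoadError(ValueError):
    """Raised on malformed clinical or allele input."""


def _normalize_stage(value: object, row: object) -> str | float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s.lower() in _NA_TOKENS:
        return np.nan
    s = s.upper()
    if s.startswith("STAGE"):
        s = s[len("STAGE"):].strip()
    # substages (IIIA, IIB, ...) collapse to the roman group
    s = s.rstrip("ABC")
    if s in _STAGES:
        return s
    raise CohortLoadError(f"row {row}: unknown tumor stage {value!r}")


def _normalize_gender(value: object, row: object) -> str | float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    if s in _NA_TOKENS:
        return np.nan
    if s in {"male", "m"}:
        return "male"
    if s in {"female", "f"}:
        return "female"
    raise CohortLoadError(f"row {row}: unknown gender {value!r}")


def _normalize_tumor_status(value: object, row: object) -> str | float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower().replace("_", " ")
    if s in _NA_TOKENS:
        return np.nan
    if s in {"with tumor", "with-tumor"}:
        return "with_tumor"
    if s in {"tumor free", "tumor-free", "tumorfree"}:
        return "tumor_free"
    raise CohortLoadError(f"row {row}: unknown tumor status {value!r}")


def _normalize_event(value: object, row: object) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    if s in _NA_TOKENS:
        return np.nan
    if s in {"1", "1.0", "dead", "deceased"}:
        return 1.0
    if s in {"0", "0.0", "alive", "living", "censored"}:
        return 0.0
    raise CohortLoadError(f"row {row}: unknown vital status / event {value!r}")


def _detect_sep(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if line.count("\t") >= line.count(",") else ","
    return "\t"


@dataclass
class Cohort:
    """Aligned clinical records and binary superallele presence matrix.

    ``clinical`` is indexed by patient_id; ``presence`` shares that
    index, with canonical superallele strings as columns ordered by
    (gene, numeric field1).  ``candidates`` lists the columns whose
    carrier count reaches ``min_support`` — the screening-eligible set;
    rarer columns stay in the matrix and remain available on request.
    """

    clinical: pd.DataFrame
    presence: pd.DataFrame
    min_support: int = 10
    allele_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clinical.index.equals(self.presence.index):
            raise CohortLoadError("clinical and presence matrices are not aligned")

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def superalleles(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def support(self) -> pd.Series:
        return self.presence.sum(axis=0)

    @property
    def candidates(self) -> list[str]:
        sup = self.support
        return [c for c in self.presence.columns if sup[c] >= self.min_support]

    @property
    def os_months(self) -> pd.Series:
        return self.clinical["os_months"]

    @property
    def event(self) -> pd.Series:
        return self.clinical["event"]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-patient clinical table.

    Delimited text (TSV default, comma autodetected), '#' comments,
    header row with the canonical field names.  Categorical levels are
    normalized; unknown levels raise with a row reference.
    """
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype={"patient_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortLoadError(f"cannot parse clinical table {path}: {exc}") from exc
    missing = [c for c in ("patient_id", "os_months", "event") if c not in df.columns]
    if missing:
        raise CohortLoadError(f"clinical table {path} lacks required columns {missing}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise CohortLoadError(
            f"duplicate patient ids in {path}: {sorted(df.loc[dup, 'patient_id'].unique())}"
        )
    df["gender"] = [_normalize_gender(v, r) for r, v in zip(df["patient_id"], df["gender"])]
    df["stage"] = [_normalize_stage(v, r) for r, v in zip(df["patient_id"], df["stage"])]
    df["tumor_status"] = [
        _normalize_tumor_status(v, r) for r, v in zip(df["patient_id"], df["tumor_status"])
    ]
    df["event"] = [_normalize_event(v, r) for r, v in zip(df["patient_id"], df["event"])]
    for col in ("age", "breslow_depth", "os_months"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    neg = df["os_months"] < 0
    if neg.any():
        bad = df.loc[neg, "patient_id"].iloc[0]
        raise CohortLoadError(f"negative os_months for patient {bad!r} in {path}")
    neg_b = df["breslow_depth"] < 0
    if neg_b.any():
        bad = df.loc[neg_b, "patient_id"].iloc[0]
        raise CohortLoadError(f"negative breslow_depth for patient {bad!r} in {path}")
    return df[CLINICAL_COLUMNS].set_index("patient_id")


def read_allele_table(path: str | Path) -> pd.DataFrame:
    """Load a long-format (patient_id, allele) table; '#' comments."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if not {"patient_id", "allele"}.issubset(df.columns):
        raise CohortLoadError(f"allele table {path} must have columns (patient_id, allele)")
    return df[["patient_id", "allele"]].dropna()


def build_presence_matrix(
    allele_df: pd.DataFrame,
) -> tuple[pd.DataFrame, list[Superallele], dict[str, set[str]]]:
    """Collapse a long allele table into a binary presence matrix.

    Column order is deterministic: gene order A,B,C,DPB1,DQB1,DRB1 then
    numeric field1.  Returns (matrix, superallele list, map from
    superallele string to the distinct allele strings observed under it).
    Parse errors carry the patient id.
    """
    pairs: list[tuple[str, Superallele, str]] = []
    for pid, allele in zip(allele_df["patient_id"], allele_df["allele"]):
        try:
            name = parse_allele(allele)
        except AlleleParseError as exc:
            raise AlleleParseError(f"patient {pid!r}: {exc}") from exc
        pairs.append((pid, to_superallele(name), str(name)))
    patients = list(dict.fromkeys(allele_df["patient_id"]))
    supers = sorted({sa for _, sa, _ in pairs}, key=superallele_sort_key)
    columns = [str(sa) for sa in supers]
    mat = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"), columns=columns, dtype=np.int8)
    amap: dict[str, set[str]] = {c: set() for c in columns}
    for pid, sa, allele_str in pairs:
        mat.loc[pid, str(sa)] = 1
        amap[str(sa)].add(allele_str)
    return mat, supers, amap


def read_cohort(
    clinical_path: str | Path,
    allele_path: str | Path,
    min_support: int = 10,
) -> Cohort:
    """Assemble a cohort from clinical and allele files.

    Retains only patients with both OS time and event status; patients
    in the allele table but absent from the clinical table (or vice
    versa) are intersected out.  All exclusions are logged.
    """
    clinical = read_clinical_table(clinical_path)
    alleles = read_allele_table(allele_path)
    presence, _, amap = build_presence_matrix(alleles)

    unknown = set(presence.index) - set(clinical.index)
    if unknown:
        log.warning("dropping %d allele-table patients absent from clinical table", len(unknown))
    ids = [pid for pid in clinical.index if pid in set(presence.index)]
    dropped_no_alleles = len(clinical) - len(ids)
    if dropped_no_alleles:
        log.info("dropping %d clinical patients with no typed alleles", dropped_no_alleles)
    clinical = clinical.loc[ids]
    presence = presence.loc[ids]

    has_os = clinical["os_months"].notna() & clinical["event"].notna()
    n_drop = int((~has_os).sum())
    if n_drop:
        log.info("dropping %d patients lacking OS time or vital status", n_drop)
    clinical = clinical.loc[has_os]
    presence = presence.loc[has_os]

    carried = presence.sum(axis=0) > 0
    if (~carried).any():
        log.info("dropping %d superalleles carried by no retained patient", int((~carried).sum()))
    presence = presence.loc[:, carried]

    cohort = Cohort(clinical=clinical, presence=presence, min_support=min_support,
                    allele_map=amap)
    n_cand = len(cohort.candidates)
    log.info(
        "cohort: %d patients, %d superalleles (%d with support >= %d)",
        cohort.n, len(cohort.superalleles), n_cand, min_support,
    )
    return cohort


def encode_clinical_binary(clinical: pd.DataFrame | Cohort) -> pd.DataFrame:
    """Indicator covariates used by the published univariate/multivariate fits.

    Strict thresholds as printed: age > 60 years, Breslow depth > 3 mm;
    stage III+IV vs 0+I+II; tumor status "with tumor"; gender female.
    Missing inputs propagate as NaN (listwise-dropped per analysis).
    """
    if isinstance(clinical, Cohort):
        clinical = clinical.clinical
    out = pd.DataFrame(index=clinical.index)
    out["age_gt60"] = (clinical["age"] > 60).astype(float).where(clinical["age"].notna())
    out["female"] = (clinical["gender"] == "female").astype(float).where(clinical["gender"].notna())
    out["stage_3_4"] = clinical["stage"].isin(["III", "IV"]).astype(float).where(clinical["stage"].notna())
    out["with_tumor"] = (clinical["tumor_status"] == "with_tumor").astype(float).where(
        clinical["tumor_status"].notna()
    )
    out["breslow_gt3"] = (clinical["breslow_depth"] > 3).astype(float).where(
        clinical["breslow_depth"].notna()
    )
    return out


def write_cohort(cohort: Cohort, clinical_path: str | Path, presence_path: str | Path) -> None:
    """Export clinical table and presence matrix as TSV (bit-exact round trip)."""
    cohort.clinical.reset_index().to_csv(clinical_path, sep="\t", index=False)
    cohort.presence.to_csv(presence_path, sep="\t")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a presence-matrix TSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t", index_col="patient_id", comment="#")
    return df.astype(np.int8)
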