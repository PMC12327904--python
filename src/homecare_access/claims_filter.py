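"""Claims-based definitions of home-care provision and usage.

A hospital or clinic counts as *actually providing* home medical care if it
has at least one claim carrying a home medical care service fee code for a
patient aged >=75 in the study fiscal year. The per-municipality *usage
rate* divides the number of distinct such patients resident in the
municipality by its population aged >=75.

The default qualifying code set is the eight home medical care fee codes of
the Japanese national fee schedule used to define the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .geodata_model import Municipality, StudyRegion

logger = logging.getLogger(__name__)

#: Home medical care service fee codes (Japanese national fee schedule).
HOME_CARE_SERVICE_CODES: frozenset[str] = frozenset({
    "114001110", "114030310", "114042110", "114042210",
    "114042810", "114046310", "114027710", "114027810",
})

CLAIM_COLUMNS = ["patient_id", "patient_age", "patient_municipality_id",
                 "facility_id", "service_code", "fiscal_year"]


@dataclass(frozen=True)
class ClaimRecord:
    """One claim line — the unit filtered by code, age and fiscal year."""

    patient_id: str
    patient_age: int
    patient_municipality_id: str
    facility_id: str
    service_code: str
    fiscal_year: int

    def __post_init__(self) -> None:
        if self.patient_age < 0:
            raise ValueError("patient_age must be >= 0")
        if not self.service_code.isdigit():
            raise ValueError(f"service_code {self.service_code!r} is not a digit string")


@dataclass(frozen=True)
class QualifyingRule:
    """Which claims define home-care usage: code set, age floor, fiscal year."""

    code_set: frozenset[str] = HOME_CARE_SERVICE_CODES
    min_age: int = 75
    fiscal_year: int = 2019

    def __post_init__(self) -> None:
        if not self.code_set:
            raise ValueError("code_set must be non-empty")
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")


def is_qualifying(claim: ClaimRecord, rule: QualifyingRule = QualifyingRule()) -> bool:
    """True iff the claim's code is in the rule's set, the patient meets the
    age floor, and the fiscal year matches exactly."""
    return (claim.service_code in rule.code_set
            and claim.patient_age >= rule.min_age
            and claim.fiscal_year == rule.fiscal_year)


def _as_frame(claims: pd.DataFrame | Iterable[ClaimRecord]) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
        if missing:
            raise ValueError(f"claims table missing columns {missing}")
        return claims
    return pd.DataFrame(
        [(c.patient_id, c.patient_age, c.patient_municipality_id,
          c.facility_id, c.service_code, c.fiscal_year) for c in claims],
        columns=CLAIM_COLUMNS)


def qualifying_mask(claims: pd.DataFrame, rule: QualifyingRule = QualifyingRule()
                    ) -> pd.Series:
    """Boolean mask of qualifying claim lines (vectorised ``is_qualifying``)."""
    return (claims["service_code"].astype(str).isin(rule.code_set)
            & (claims["patient_age"].astype(int) >= rule.min_age)
            & (claims["fiscal_year"].astype(int) == rule.fiscal_year))


def read_claims(path: str | Path) -> pd.DataFrame:
    """Read a claims CSV, keeping ids and service codes as strings."""
    df = pd.read_csv(path, dtype={"patient_id": str, "patient_municipality_id": str,
                                  "facility_id": str, "service_code": str})
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def identify_providers(claims: pd.DataFrame | Iterable[ClaimRecord],
                       rule: QualifyingRule = QualifyingRule()) -> set[str]:
    """Facility ids with at least one qualifying claim.

    This is the operational definition of the "actual" provider set: a
    single qualifying claim line is sufficient.
    """
    df = _as_frame(claims)
    if df.empty:
        return set()
    return set(df.loc[qualifying_mask(df, rule), "facility_id"].astype(str))


def usage_summary(claims: pd.DataFrame | Iterable[ClaimRecord],
                  rule: QualifyingRule = QualifyingRule(),
                  municipalities: StudyRegion | Mapping[str, Municipality]
                  | Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-municipality claim counts, distinct-patient counts and usage rates.

    Returns a DataFrame indexed by municipality id with columns
    ``n_claims`` (qualifying claim lines), ``n_patients`` (distinct
    qualifying patients, attributed to their municipality of residence) and
    ``usage_rate`` (n_patients / pop_75plus; NaN when no population data is
    supplied).

    A patient whose qualifying claims disagree on municipality is counted
    once, in the municipality of their first qualifying claim in file
    order; the conflict is logged.
    """
    df = _as_frame(claims)
    q = df.loc[qualifying_mask(df, rule)].copy() if not df.empty else df
    pop75 = _pop75_map(municipalities)

    index_ids = sorted(pop75) if pop75 is not None else sorted(
        set(q["patient_municipality_id"].astype(str)) if not q.empty else set())
    out = pd.DataFrame(index=pd.Index(index_ids, name="municipality_id"))
    out["n_claims"] = 0
    out["n_patients"] = 0

    if not q.empty:
        q["patient_municipality_id"] = q["patient_municipality_id"].astype(str)
        claims_per_m = q.groupby("patient_municipality_id").size()
        # municipality of residence: first qualifying claim wins on conflict
        first = q.drop_duplicates("patient_id", keep="first")
        n_m = q.groupby("patient_id")["patient_municipality_id"].nunique()
        conflicted = n_m[n_m > 1]
        if len(conflicted):
            logger.warning(
                "%d patients have qualifying claims in multiple municipalities; "
                "first qualifying claim wins", len(conflicted))
        patients_per_m = first.groupby("patient_municipality_id").size()
        out["n_claims"] = claims_per_m.reindex(out.index, fill_value=0).astype(int)
        out["n_patients"] = patients_per_m.reindex(out.index, fill_value=0).astype(int)
        unknown = set(patients_per_m.index) - set(out.index)
        if unknown and pop75 is not None:
            raise ValueError(f"claims reference unknown municipalities: {sorted(unknown)}")

    if pop75 is None:
        out["usage_rate"] = float("nan")
    else:
        rates = []
        for mid in out.index:
            n, p = int(out.loc[mid, "n_patients"]), pop75[mid]
            if p == 0 and n > 0:
                raise ValueError(
                    f"municipality {mid!r}: {n} patients but pop_75plus is 0")
            rates.append(n / p if p else 0.0)
        out["usage_rate"] = rates
    return out


def _pop75_map(municipalities) -> dict[str, int] | None:
    if municipalities is None:
        return None
    if isinstance(municipalities, StudyRegion):
        return {mid: m.pop_75plus for mid, m in municipalities.municipalities.items()}
    out = {}
    for k, v in municipalities.items():
        out[str(k)] = v.pop_75plus if isinstance(v, Municipality) else int(v)
    return out
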