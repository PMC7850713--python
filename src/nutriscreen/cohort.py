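"""Survey ingest, inclusion rules and biologically-implausible-value flags.

Child-level records arrive as delimited text with one row per measured
child.  A child enters the analysis only if age, sex, weight, height and
MUAC are all present and age is in [6.0, 60.0) months.  Included children
are then screened against standard flagging limits for implausible
anthropometry — MUAC outside [70, 220] mm, WHZ beyond +/-5, HAZ beyond
+/-6, WAZ below -6 or above +5 — and a child failing any flag is dropped
entirely.  Flag bounds are strict: a child sitting exactly on a limit is
kept.  Countries contributing fewer than a minimum number of surveys
(default 5) are removed from all downstream strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_reference import compute_child_scores

__all__ = [
    "SURVEY_COLUMNS",
    "FlagLimits",
    "SurveyFormatError",
    "read_survey_file",
    "write_survey_file",
    "apply_inclusion",
    "apply_flags",
    "build_exclusion_report",
    "country_filter",
    "prepare_cohort",
]

SURVEY_COLUMNS = [
    "survey_id",
    "cluster_id",
    "country",
    "year",
    "age_months",
    "sex",
    "weight_kg",
    "height_cm",
    "position",
    "muac_mm",
    "oedema",
]

#: fields whose absence excludes a child (oedema and position are not here)
REQUIRED_FIELDS = ["age_months", "sex", "weight_kg", "height_cm", "muac_mm"]

AGE_MIN_MONTHS = 6.0
AGE_MAX_MONTHS = 60.0  # exclusive


class SurveyFormatError(ValueError):
    """Survey file does not match the documented layout."""


@dataclass(frozen=True)
class FlagLimits:
    """Implausible-value limits; all comparisons strict (on-limit kept).

    MUAC limits are in mm, z-score limits in SD units.
    """

    muac_low: float = 70.0
    muac_high: float = 220.0
    whz_abs: float = 5.0
    haz_abs: float = 6.0
    waz_low: float = -6.0
    waz_high: float = 5.0


def _detect_sep(path) -> str:
    if hasattr(path, "read"):
        header = path.readline()
        path.seek(0)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
    return "\t" if "\t" in header else ","


def read_survey_file(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a child-level survey file.

    Returns ``(records, surveys)``: per-child records with typed columns
    (unparseable numeric cells become missing, never zero), and per-survey
    metadata (survey_id, country, year, n_rows) derived from the rows.
    """
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in raw.columns]
    if missing:
        raise SurveyFormatError(f"survey file missing columns: {', '.join(missing)}")

    records = pd.DataFrame(index=raw.index)
    for col in ("survey_id", "cluster_id", "country"):
        records[col] = raw[col].replace("", pd.NA)
    for col in ("year", "age_months", "weight_kg", "height_cm", "muac_mm"):
        records[col] = pd.to_numeric(raw[col].replace("", pd.NA), errors="coerce")
    sex = raw["sex"].str.strip().str.lower().replace("", pd.NA)
    records["sex"] = sex.where(sex.isin(["f", "m"]) | sex.isna(), pd.NA)
    pos = raw["position"].str.strip().str.lower().replace("", "unknown")
    records["position"] = pos.where(pos.isin(["standing", "recumbent", "unknown"]), "unknown")
    oed = pd.to_numeric(raw["oedema"].replace("", pd.NA), errors="coerce")
    # missing oedema is treated as absent oedema: it is not an inclusion
    # field, but classification needs a definite value
    records["oedema"] = (oed == 1).fillna(False).astype(bool)

    surveys = (
        records.groupby("survey_id", dropna=False)
        .agg(country=("country", "first"), year=("year", "first"), n_rows=("country", "size"))
        .reset_index()
    )
    return records, surveys


def write_survey_file(records: pd.DataFrame, path) -> None:
    """Write records in the same delimited layout :func:`read_survey_file` reads."""
    out = records.loc[:, SURVEY_COLUMNS].copy()
    out["oedema"] = out["oedema"].astype(int)
    if hasattr(path, "write"):
        out.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, index=False)


def apply_inclusion(records: pd.DataFrame) -> pd.Series:
    """First-stage exclusion reason per child (``None`` if the child passes).

    Excluded iff any of age, sex, weight, height, MUAC is missing
    (``missing_field``) or age is outside [6.0, 60.0) months
    (``age_out_of_range``).  Missing oedema or position never excludes.
    """
    reason = pd.Series([None] * len(records), index=records.index, dtype=object)
    missing = records[REQUIRED_FIELDS].isna().any(axis=1)
    reason[missing] = "missing_field"
    age = records["age_months"]
    out_of_range = ~missing & ((age < AGE_MIN_MONTHS) | (age >= AGE_MAX_MONTHS))
    reason[out_of_range] = "age_out_of_range"
    return reason


def apply_flags(
    records: pd.DataFrame,
    scores: pd.DataFrame,
    limits: FlagLimits = FlagLimits(),
) -> pd.Series:
    """Flag reason per child that already passed inclusion (``None`` = keep).

    One reason per child, in order muac, whz, haz, waz; a child whose WHZ,
    HAZ or WAZ could not be computed (conditioning index outside the
    reference grid) gets ``score_unavailable``.  NaN scores never trip a
    numeric flag.
    """
    muac = records["muac_mm"]
    whz, haz, waz = scores["whz"], scores["haz"], scores["waz"]
    reason = pd.Series([None] * len(records), index=records.index, dtype=object)

    checks = [
        ("flag_muac", (muac < limits.muac_low) | (muac > limits.muac_high)),
        ("flag_whz", (whz < -limits.whz_abs) | (whz > limits.whz_abs)),
        ("flag_haz", (haz < -limits.haz_abs) | (haz > limits.haz_abs)),
        ("flag_waz", (waz < limits.waz_low) | (waz > limits.waz_high)),
        ("score_unavailable", whz.isna() | haz.isna() | waz.isna()),
    ]
    for code, mask in checks:
        hit = mask.fillna(False) & reason.isna()
        reason[hit] = code
    return reason


def build_exclusion_report(
    records: pd.DataFrame,
    scores: pd.DataFrame,
    limits: FlagLimits = FlagLimits(),
) -> pd.DataFrame:
    """Full per-child disposition: ``included`` flag and first failing reason.

    Precedence is missing-field, age-range, then the flags; every input
    child appears exactly once and excluded children carry exactly one
    reason.
    """
    reason = apply_inclusion(records)
    passed = reason.isna()
    flag_reason = apply_flags(records.loc[passed], scores.loc[passed], limits)
    reason.loc[passed] = flag_reason
    return pd.DataFrame(
        {"included": reason.isna(), "reason": reason}, index=records.index
    )


def country_filter(surveys: pd.DataFrame, min_surveys: int = 5) -> set[str]:
    """Countries retained: those with at least ``min_surveys`` surveys."""
    if len(surveys) == 0:
        return set()
    counts = surveys.groupby("country")["survey_id"].nunique()
    return set(counts.index[counts >= min_surveys])


def prepare_cohort(
    records: pd.DataFrame,
    refs,
    limits: FlagLimits = FlagLimits(),
    adjust_position: bool = True,
    min_surveys: int = 5,
    surveys: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Score, exclude and country-filter in one pass.

    Returns ``(children, report, retained_countries)`` where ``children``
    holds the included rows (from retained countries only) with ``whz``,
    ``haz`` and ``waz`` columns appended, and ``report`` is the
    per-child disposition over the full input.
    """
    scores = compute_child_scores(records, refs, adjust_position=adjust_position)
    report = build_exclusion_report(records, scores, limits)
    if surveys is None:
        surveys = (
            records.groupby("survey_id", dropna=False)
            .agg(country=("country", "first"))
            .reset_index()
        )
    retained = country_filter(surveys, min_surveys=min_surveys)
    children = pd.concat([records, scores], axis=1)
    keep = report["included"] & children["country"].isin(retained)
    return children.loc[keep].copy(), report, retained
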