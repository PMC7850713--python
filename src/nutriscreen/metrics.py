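"""Stratum-level counts and the program-evaluation metrics.

Every metric is computed from pooled raw counts — children are summed
survey -> country -> region -> overall and proportions taken on the
pooled numerators and denominators, never averaged across surveys.

For a screening strategy with eligible set T (the "target") and a case
condition C (e.g. SAM by any criterion):

* sensitivity of T to C      = 100 * |C and T| / |C|
* composition of T by C      = 100 * |C and T| / |T|   (specificity proxy)
* size ratio                  = |T| / |C|

Zero denominators yield an *undefined* marker (NaN, rendered blank) —
tiny strata can legitimately contain no SAM children, and reporting 0 or
100 there would fabricate an extreme value.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "PROGRAM_SETS",
    "SENSITIVITY_CONDITIONS",
    "COMPOSITION_CONDITIONS",
    "DEMOGRAPHIC_GROUPS",
    "UNDER2_MONTHS",
    "expand_profiles",
    "tabulate",
    "sensitivity",
    "composition",
    "size_ratio",
    "demographics",
    "prevalence",
    "stratum_metrics",
    "build_tables",
    "render_table",
    "format_percent",
    "format_ratio",
]

PROGRAM_SETS = ["target_mswaz", "suppl_mswaz", "target_expmuac", "suppl_expmuac"]
SENSITIVITY_CONDITIONS = ["sam_all", "mam_all", "wa_st"]
COMPOSITION_CONDITIONS = [
    "sam_all",
    "mam_all",
    "wa_st",
    "neither_sam_nor_mam",
    "neither_sam_nor_wast",
]
DEMOGRAPHIC_GROUPS = ["sam_all", "sam_muac", "target_mswaz"]

#: "younger children" = aged 6-23 months; a child at exactly 24.0 is not under 2
UNDER2_MONTHS = 24.0

_BASE_BOOLEANS = [
    "sam_muac",
    "mam_muac",
    "sam_all",
    "mam_all",
    "swaz",
    "wa_st",
    "target_mswaz",
    "suppl_mswaz",
    "target_expmuac",
    "suppl_expmuac",
]


def expand_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Add the derived indicator columns the count tables need.

    Adds ``neither_sam_nor_mam``, ``neither_sam_nor_wast``, ``female``,
    ``under24`` and every required intersection column
    ``<program_set>__<condition>`` / ``<group>__female`` /
    ``<group>__under24``.
    """
    out = profiles.copy()
    out["neither_sam_nor_mam"] = ~out["sam_all"] & ~out["mam_all"]
    out["neither_sam_nor_wast"] = ~out["sam_all"] & ~out["wa_st"]
    out["female"] = (out["sex"] == "f").fillna(False).astype(bool)
    out["under24"] = (out["age_months"] < UNDER2_MONTHS).astype(bool)
    for ps in PROGRAM_SETS:
        for cond in COMPOSITION_CONDITIONS:
            out[f"{ps}__{cond}"] = out[ps] & out[cond]
    for group in DEMOGRAPHIC_GROUPS:
        out[f"{group}__female"] = out[group] & out["female"]
        out[f"{group}__under24"] = out[group] & out["under24"]
    return out


_COUNT_COLUMNS = (
    _BASE_BOOLEANS
    + ["neither_sam_nor_mam", "neither_sam_nor_wast", "female", "under24"]
    + [f"{ps}__{cond}" for ps in PROGRAM_SETS for cond in COMPOSITION_CONDITIONS]
    + [f"{g}__{d}" for g in DEMOGRAPHIC_GROUPS for d in ("female", "under24")]
)


def _region_of(profiles: pd.DataFrame, region_map: dict[str, str]) -> pd.Series:
    unknown = sorted(set(profiles["country"].dropna()) - set(region_map))
    if unknown:
        raise KeyError(
            "countries missing from the region mapping: " + ", ".join(unknown)
        )
    return profiles["country"].map(region_map)


def tabulate(
    profiles: pd.DataFrame,
    stratifier: str = "overall",
    region_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pool child counts by stratum.

    ``stratifier`` is one of ``survey``, ``country``, ``region``,
    ``overall``.  Returns one row per stratum with ``n_children`` and a
    count column per indicator/intersection; strata partition the
    children, so counts pool exactly.
    """
    expanded = expand_profiles(profiles)
    if stratifier == "survey":
        key = expanded["survey_id"]
    elif stratifier == "country":
        key = expanded["country"]
    elif stratifier == "region":
        if region_map is None:
            raise ValueError("region stratification needs a country->region mapping")
        key = _region_of(expanded, region_map)
    elif stratifier == "overall":
        key = pd.Series("overall", index=expanded.index)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")

    grouped = expanded.groupby(key, sort=True)
    counts = grouped[_COUNT_COLUMNS].sum().astype(int)
    counts.insert(0, "n_children", grouped.size())
    counts.index.name = "stratum"
    return counts


# ---------------------------------------------------------------------------
# metrics from one stratum's counts
# ---------------------------------------------------------------------------


def _ratio_pct(num: float, den: float) -> float:
    if den == 0:
        return float("nan")
    return 100.0 * num / den


def prevalence(counts, case: str) -> float:
    """Percent of the stratum's children in ``case``."""
    return _ratio_pct(counts[case], counts["n_children"])


def sensitivity(counts, condition: str, program_set: str) -> float:
    """Percent of ``condition`` children captured by ``program_set``."""
    if condition not in SENSITIVITY_CONDITIONS:
        raise ValueError(f"unsupported sensitivity condition {condition!r}")
    return _ratio_pct(counts[f"{program_set}__{condition}"], counts[condition])


def composition(counts, program_set: str, condition: str) -> float:
    """Percent of ``program_set`` children that satisfy ``condition``."""
    if condition not in COMPOSITION_CONDITIONS:
        raise ValueError(f"unsupported composition condition {condition!r}")
    return _ratio_pct(counts[f"{program_set}__{condition}"], counts[program_set])


def size_ratio(counts, numerator_set: str, denominator_set: str) -> float:
    """|numerator_set| / |denominator_set| (NaN when the denominator is 0)."""
    den = counts[denominator_set]
    if den == 0:
        return float("nan")
    return counts[numerator_set] / den


def demographics(counts, group: str) -> tuple[float, float]:
    """(percent female, percent aged under 24 months) within ``group``."""
    if group not in DEMOGRAPHIC_GROUPS:
        raise ValueError(f"unsupported demographic group {group!r}")
    return (
        _ratio_pct(counts[f"{group}__female"], counts[group]),
        _ratio_pct(counts[f"{group}__under24"], counts[group]),
    )


def stratum_metrics(counts) -> dict[str, float]:
    """Every reported metric for one stratum's pooled counts."""
    row: dict[str, float] = {"n_children": int(counts["n_children"])}
    for case in _BASE_BOOLEANS:
        row[f"{case}_pct"] = prevalence(counts, case)
    for ps in PROGRAM_SETS:
        for cond in SENSITIVITY_CONDITIONS:
            row[f"{cond}_captured_by_{ps}_pct"] = sensitivity(counts, cond, ps)
        for cond in COMPOSITION_CONDITIONS:
            row[f"{ps}_{cond}_pct"] = composition(counts, ps, cond)
    row["ratio_target_mswaz_to_sam_all"] = size_ratio(counts, "target_mswaz", "sam_all")
    row["ratio_target_expmuac_to_sam_all"] = size_ratio(counts, "target_expmuac", "sam_all")
    row["ratio_suppl_mswaz_to_sam_muac"] = size_ratio(counts, "suppl_mswaz", "sam_muac")
    row["ratio_suppl_expmuac_to_sam_muac"] = size_ratio(counts, "suppl_expmuac", "sam_muac")
    for group in DEMOGRAPHIC_GROUPS:
        female, under2 = demographics(counts, group)
        row[f"{group}_female_pct"] = female
        row[f"{group}_under2_pct"] = under2
    return row


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = {
    "table1": [
        "n_surveys",
        "n_children",
        "sam_muac_pct",
        "sam_all_pct",
        "swaz_pct",
        "wa_st_pct",
        "target_mswaz_pct",
        "suppl_mswaz_pct",
        "wa_st_captured_by_target_mswaz_pct",
        "wa_st_captured_by_suppl_mswaz_pct",
        "target_mswaz_neither_sam_nor_wast_pct",
        "suppl_mswaz_neither_sam_nor_wast_pct",
    ],
    "table2": [
        "ratio_target_mswaz_to_sam_all",
        "sam_all_captured_by_target_mswaz_pct",
        "mam_all_captured_by_target_mswaz_pct",
        "target_mswaz_sam_all_pct",
        "target_mswaz_mam_all_pct",
        "target_mswaz_neither_sam_nor_mam_pct",
        "ratio_target_expmuac_to_sam_all",
        "sam_all_captured_by_target_expmuac_pct",
        "mam_all_captured_by_target_expmuac_pct",
        "target_expmuac_sam_all_pct",
        "target_expmuac_mam_all_pct",
    ],
    "table3": [
        "n_surveys",
        "n_children",
        "ratio_suppl_mswaz_to_sam_muac",
        "sam_all_captured_by_suppl_mswaz_pct",
        "mam_all_captured_by_suppl_mswaz_pct",
        "suppl_mswaz_sam_all_pct",
        "suppl_mswaz_mam_all_pct",
        "suppl_mswaz_neither_sam_nor_mam_pct",
        "ratio_suppl_expmuac_to_sam_muac",
        "sam_all_captured_by_suppl_expmuac_pct",
        "mam_all_captured_by_suppl_expmuac_pct",
        "suppl_expmuac_sam_all_pct",
        "suppl_expmuac_mam_all_pct",
    ],
    "table4": [
        "sam_all_female_pct",
        "sam_muac_female_pct",
        "target_mswaz_female_pct",
        "sam_all_under2_pct",
        "sam_muac_under2_pct",
        "target_mswaz_under2_pct",
    ],
}


def _survey_counts(surveys: pd.DataFrame, region_map: dict[str, str]) -> pd.Series:
    return surveys.groupby("country")["survey_id"].nunique()


def build_tables(
    profiles: pd.DataFrame,
    surveys: pd.DataFrame,
    region_map: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """The four report tables, strata ordered region -> country -> totals.

    Each table carries ``region`` and ``country`` columns ("Total" country
    rows are regional totals; the last row is the overall aggregate) plus
    the metric columns listed in :data:`TABLE_COLUMNS`.
    """
    country_counts = tabulate(profiles, "country")
    region_counts = tabulate(profiles, "region", region_map)
    overall_counts = tabulate(profiles, "overall")
    n_surveys = _survey_counts(surveys, region_map)

    rows: list[dict] = []

    def add_row(region: str, country: str, counts, n_sur: int) -> None:
        row = {"region": region, "country": country, "n_surveys": int(n_sur)}
        row.update(stratum_metrics(counts))
        rows.append(row)

    regions_present = sorted(
        {region_map[c] for c in country_counts.index if c in region_map}
    )
    for region in regions_present:
        members = sorted(c for c in country_counts.index if region_map.get(c) == region)
        for country in members:
            add_row(region, country, country_counts.loc[country], n_surveys.get(country, 0))
        if len(members) > 1:
            add_row(
                region,
                "Total",
                region_counts.loc[region],
                int(sum(n_surveys.get(c, 0) for c in members)),
            )
    add_row("Overall", "Total", overall_counts.loc["overall"], int(n_surveys.sum()))

    full = pd.DataFrame(rows)
    return {
        name: full[["region", "country"] + cols].copy()
        for name, cols in TABLE_COLUMNS.items()
    }


def format_percent(x) -> str:
    """Half-up to 1 decimal; blank for undefined."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_ratio(x) -> str:
    """Half-up to 2 decimals; blank for undefined."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_table(table: pd.DataFrame, path) -> None:
    """Write a report table as CSV at the published precision.

    Percent columns to 1 decimal, ratio columns to 2; undefined cells
    render blank.
    """
    out = table.copy()
    for col in out.columns:
        if col.endswith("_pct"):
            out[col] = out[col].map(format_percent)
        elif col.startswith("ratio_"):
            out[col] = out[col].map(format_ratio)
    if hasattr(path, "write"):
        out.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, index=False)
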