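"""Case definitions and program-eligibility profiles.

Definitions (defaults; every threshold is overridable through
:class:`Thresholds`):

* ``sam_muac``   — MUAC < 115 mm and/or oedema.
* ``mam_muac``   — 115 <= MUAC < 125 mm, no oedema.
* ``sam_all``    — MUAC < 115 mm and/or WHZ < -3 and/or oedema.
* ``mam_all``    — (115 <= MUAC < 125 mm and/or -3 <= WHZ < -2),
  excluding children already ``sam_all``.
* ``swaz``       — severe underweight, WAZ < -3.
* ``wa_st``      — concurrently wasted and stunted, WHZ < -2 and HAZ < -2.
* ``target_mswaz``  — MUAC+SWAZ program target: MUAC < 115 mm or
  WAZ < -3 or oedema.
* ``suppl_mswaz``   — the target minus the ``sam_muac`` children (set
  difference, so target = sam_muac + supplement exactly).
* ``target_expmuac`` — Expanded-MUAC program target: MUAC < 125 mm or oedema.
* ``suppl_expmuac``  — that target minus ``sam_muac``.

Supplements are defined by set difference rather than re-stating the
threshold arithmetic: it makes the disjoint-union identity
|target| = |sam_muac| + |supplement| exact by construction, including for
a child with MUAC exactly on the SAM cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Thresholds", "PROFILE_COLUMNS", "CARRIED_COLUMNS", "classify"]


@dataclass(frozen=True)
class Thresholds:
    """Case-definition cut-offs (MUAC in mm, z-scores in SD units)."""

    muac_sam_mm: float = 115.0
    muac_mam_mm: float = 125.0
    whz_severe: float = -3.0
    whz_moderate: float = -2.0
    waz_severe: float = -3.0
    haz_stunted: float = -2.0
    whz_wasted: float = -2.0


#: boolean columns produced by :func:`classify`, in output order
PROFILE_COLUMNS = [
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

#: covariates carried through for stratification and demographics
CARRIED_COLUMNS = ["survey_id", "cluster_id", "country", "year", "sex", "age_months", "oedema"]


def classify(children: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Assign every included child its full case/eligibility profile.

    ``children`` must carry ``muac_mm``, ``oedema`` and the scores
    ``whz``, ``haz``, ``waz`` (all present — excluded children never reach
    this point).  Returns one row per child: the ten profile booleans plus
    the carried covariates present in the input.
    """
    muac = children["muac_mm"]
    oedema = children["oedema"].astype(bool)
    whz, haz, waz = children["whz"], children["haz"], children["waz"]
    t = thresholds

    sam_muac = (muac < t.muac_sam_mm) | oedema
    mam_muac = (muac >= t.muac_sam_mm) & (muac < t.muac_mam_mm) & ~oedema
    sam_all = sam_muac | (whz < t.whz_severe)
    mam_all = (mam_muac | ((whz >= t.whz_severe) & (whz < t.whz_moderate))) & ~sam_all
    swaz = waz < t.waz_severe
    wa_st = (whz < t.whz_wasted) & (haz < t.haz_stunted)

    target_mswaz = (muac < t.muac_sam_mm) | swaz | oedema
    suppl_mswaz = target_mswaz & ~sam_muac
    target_expmuac = (muac < t.muac_mam_mm) | oedema
    suppl_expmuac = target_expmuac & ~sam_muac

    profile = pd.DataFrame(
        {
            "sam_muac": sam_muac,
            "mam_muac": mam_muac,
            "sam_all": sam_all,
            "mam_all": mam_all,
            "swaz": swaz,
            "wa_st": wa_st,
            "target_mswaz": target_mswaz,
            "suppl_mswaz": suppl_mswaz,
            "target_expmuac": target_expmuac,
            "suppl_expmuac": suppl_expmuac,
        },
        index=children.index,
    ).astype(bool)

    for col in CARRIED_COLUMNS:
        if col in children.columns:
            profile[col] = children[col]
    return profile
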