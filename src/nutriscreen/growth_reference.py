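"""LMS growth-reference tables and anthropometric z-scores.

The WHO child growth standards express the distribution of a body measure
(height for a given age, weight for a given age or height) with the LMS
parameterization: a Box-Cox power ``L``, a median ``M`` and a coefficient
of variation ``S`` tabulated on a grid of the conditioning index (age in
months, or length/height in cm).  The z-score of a measurement ``x`` is

    z = ((x / M)**L - 1) / (L * S)            (L != 0)
    z = ln(x / M) / S                          (L -> 0 limit)

For the weight-based indicators (weight-for-age, weight-for-length/height)
reference software restricts the z-score beyond +/-3 SD by extending the
scale linearly, using the spacing between the 2 SD and 3 SD points of the
reference distribution:

    z > 3:   z = 3 + (x - SD3) / (SD3 - SD2)
    z < -3:  z = -3 + (x - SD3neg) / (SD2neg - SD3neg)

where ``SDk`` is the measurement value at z = k.  Height-for-age is scored
with the plain LMS formula.  This module implements both forms, their
inverses, table loading with linear interpolation of (L, M, S) between
grid points, and per-child scoring of HAZ, WAZ and WHZ.

Indicator codes follow the WHO file convention: ``hfa`` (height-for-age),
``wfa`` (weight-for-age), ``wfl`` (weight-for-length, children measured
recumbent, used below 24 months), ``wfh`` (weight-for-height, standing,
24 months and above).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "SEXES",
    "GrowthReference",
    "ReferenceError",
    "load_reference",
    "write_reference",
    "interpolate_lms",
    "zscore_lms",
    "inverse_zscore",
    "zscore_restricted",
    "inverse_zscore_restricted",
    "compute_child_scores",
]

INDICATORS = ("hfa", "wfa", "wfl", "wfh")
SEXES = ("f", "m")

#: below this |L| the Box-Cox formula degenerates and the log limit is used
_L_EPS = 1e-8

#: age (months) below which weight-for-length is used and the recumbent
#: measurement position is the reference standard
LENGTH_AGE_CUTOFF = 24.0

#: cm added/subtracted when the measurement position does not match the
#: reference standard for the child's age
POSITION_ADJUST_CM = 0.7


class ReferenceError(ValueError):
    """Malformed or incomplete growth-reference table."""


@dataclass(frozen=True)
class GrowthReference:
    """LMS rows for one (indicator, sex), sorted by the conditioning index.

    ``index`` is age in months for hfa/wfa and length/height in cm for
    wfl/wfh.  Rows must be strictly increasing in ``index`` with no
    duplicates; ``M`` and ``S`` must be positive.
    """

    indicator: str
    sex: str
    index: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("index", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.indicator not in INDICATORS:
            raise ReferenceError(f"unknown indicator {self.indicator!r}")
        if self.sex not in SEXES:
            raise ReferenceError(f"unknown sex {self.sex!r}")
        if self.index.size < 2:
            raise ReferenceError(
                f"{self.indicator}/{self.sex}: need at least 2 rows, got {self.index.size}"
            )
        if not np.all(np.isfinite(self.index)):
            raise ReferenceError(f"{self.indicator}/{self.sex}: non-finite index value")
        if np.any(np.diff(self.index) <= 0):
            raise ReferenceError(
                f"{self.indicator}/{self.sex}: index not strictly increasing"
            )
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise ReferenceError(f"{self.indicator}/{self.sex}: M and S must be > 0")

    def __len__(self) -> int:
        return int(self.index.size)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.index[0]), float(self.index[-1])

    def lookup(self, x):
        """Interpolated (L, M, S) at index value(s) ``x``.

        Linear interpolation between the two bracketing rows; exact row
        values on the grid.  Outside [min, max] all three come back NaN —
        the "out of reference range" signal (the score is unavailable,
        never extrapolated).
        """
        x = np.asarray(x, dtype=float)
        L = np.interp(x, self.index, self.L)
        M = np.interp(x, self.index, self.M)
        S = np.interp(x, self.index, self.S)
        oob = ~np.isfinite(x) | (x < self.index[0]) | (x > self.index[-1])
        if np.ndim(L) == 0:
            if oob:
                return (np.nan, np.nan, np.nan)
            return (float(L), float(M), float(S))
        L = np.where(oob, np.nan, L)
        M = np.where(oob, np.nan, M)
        S = np.where(oob, np.nan, S)
        return L, M, S


def interpolate_lms(ref: GrowthReference, x):
    """Functional alias for :meth:`GrowthReference.lookup`."""
    return ref.lookup(x)


# ---------------------------------------------------------------------------
# reference-table file I/O
# ---------------------------------------------------------------------------

_REFERENCE_COLUMNS = ["indicator", "sex", "index", "L", "M", "S"]


def _detect_sep(path) -> str:
    if hasattr(path, "read"):
        header = path.readline()
        path.seek(0)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
    return "\t" if "\t" in header else ","


def load_reference(path) -> dict[tuple[str, str], GrowthReference]:
    """Read an LMS reference file into ``{(indicator, sex): GrowthReference}``.

    The file is comma- or tab-delimited (auto-detected from the header)
    with columns ``indicator, sex, index, L, M, S``; one file may hold all
    tables.  Malformed rows, duplicate or non-monotone indices raise
    :class:`ReferenceError` naming the offender.
    """
    sep = _detect_sep(path)
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in _REFERENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ReferenceError(f"reference file missing columns: {', '.join(missing)}")
    for col in ("index", "L", "M", "S"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any() or values.isna().any():
            line = int(table.index[values.isna()][0]) + 2  # header + 1-based
        else:
            line = None
        if line is not None:
            raise ReferenceError(f"non-numeric {col!r} at line {line}")
        table[col] = values

    refs: dict[tuple[str, str], GrowthReference] = {}
    for (indicator, sex), group in table.groupby(["indicator", "sex"], sort=False):
        group = group.sort_values("index")
        dup = group["index"].duplicated()
        if dup.any():
            value = group.loc[dup, "index"].iloc[0]
            raise ReferenceError(
                f"duplicate index {value} for ({indicator}, {sex})"
            )
        refs[(str(indicator), str(sex))] = GrowthReference(
            indicator=str(indicator),
            sex=str(sex),
            index=group["index"].to_numpy(),
            L=group["L"].to_numpy(),
            M=group["M"].to_numpy(),
            S=group["S"].to_numpy(),
        )
    if not refs:
        raise ReferenceError("reference file holds no rows")
    return refs


def write_reference(refs: dict[tuple[str, str], GrowthReference], path) -> None:
    """Write tables in the same delimited format :func:`load_reference` reads."""
    frames = []
    for (indicator, sex), ref in refs.items():
        frames.append(
            pd.DataFrame(
                {
                    "indicator": indicator,
                    "sex": sex,
                    "index": ref.index,
                    "L": ref.L,
                    "M": ref.M,
                    "S": ref.S,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if hasattr(path, "write"):
        out.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# LMS forward / inverse transforms
# ---------------------------------------------------------------------------


def zscore_lms(x, L, M, S):
    """Plain LMS z-score of measurement ``x`` under (L, M, S).

    Vectorized; non-positive ``x`` yields NaN (invalid measurement), and
    NaN in any parameter propagates (out-of-range index).
    """
    x, L, M, S = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(x > 0, x / M, np.nan)
        log_branch = np.log(ratio) / S
        L_safe = np.where(np.abs(L) < _L_EPS, 1.0, L)
        power_branch = (np.power(ratio, L_safe) - 1.0) / (L_safe * S)
        z = np.where(np.abs(L) < _L_EPS, log_branch, power_branch)
    if z.ndim == 0:
        return float(z)
    return z


def inverse_zscore(z, L, M, S):
    """Measurement value at z-score ``z``: x = M (1 + L S z)^(1/L).

    The Box-Cox domain requires ``1 + L S z > 0``; outside it the result
    is NaN (scalar input raises ValueError, mirroring a hard domain error).
    """
    z, L, M, S = np.broadcast_arrays(
        np.asarray(z, float), np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    )
    with np.errstate(invalid="ignore"):
        base = 1.0 + L * S * z
        L_safe = np.where(np.abs(L) < _L_EPS, 1.0, L)
        power_branch = M * np.power(np.where(base > 0, base, np.nan), 1.0 / L_safe)
        log_branch = M * np.exp(S * z)
        x = np.where(np.abs(L) < _L_EPS, log_branch, power_branch)
        bad = (np.abs(L) >= _L_EPS) & ~(base > 0)
    if x.ndim == 0:
        if bad:
            raise ValueError("inverse LMS domain error: 1 + L*S*z <= 0")
        return float(x)
    return x


def _sd_points(L, M, S):
    """Measurement values at z = -3, -2, +2, +3 (tail anchors)."""
    sd3neg = inverse_zscore(np.full_like(np.asarray(M, float), -3.0), L, M, S)
    sd2neg = inverse_zscore(np.full_like(np.asarray(M, float), -2.0), L, M, S)
    sd2 = inverse_zscore(np.full_like(np.asarray(M, float), 2.0), L, M, S)
    sd3 = inverse_zscore(np.full_like(np.asarray(M, float), 3.0), L, M, S)
    return sd3neg, sd2neg, sd2, sd3


def zscore_restricted(x, L, M, S):
    """LMS z-score with linear tail extension beyond +/-3 SD.

    Identical to :func:`zscore_lms` inside [-3, 3]; beyond, the scale is
    extended linearly with the SD2-SD3 spacing of the reference, which is
    how reference software scores the weight-based indicators.  Continuous
    and strictly increasing in ``x``.
    """
    x = np.asarray(x, float)
    z = np.asarray(zscore_lms(x, L, M, S))
    Lb, Mb, Sb = np.broadcast_arrays(
        np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    )
    sd3neg, sd2neg, sd2, sd3 = _sd_points(Lb, Mb, Sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        hi = 3.0 + (x - sd3) / (sd3 - sd2)
        lo = -3.0 + (x - sd3neg) / (sd2neg - sd3neg)
        out = np.where(z > 3.0, hi, np.where(z < -3.0, lo, z))
    if out.ndim == 0:
        return float(out)
    return out


def inverse_zscore_restricted(z, L, M, S):
    """Inverse of :func:`zscore_restricted` (plain inverse inside +/-3)."""
    z = np.asarray(z, float)
    Lb, Mb, Sb = np.broadcast_arrays(
        np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    )
    sd3neg, sd2neg, sd2, sd3 = _sd_points(Lb, Mb, Sb)
    inner = inverse_zscore(np.clip(z, -3.0, 3.0), Lb, Mb, Sb)
    hi = sd3 + (z - 3.0) * (sd3 - sd2)
    lo = sd3neg + (z + 3.0) * (sd2neg - sd3neg)
    out = np.where(z > 3.0, hi, np.where(z < -3.0, lo, inner))
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# per-child scoring
# ---------------------------------------------------------------------------


def adjusted_height(age_months, height_cm, position, enabled: bool = True):
    """Convert measured length/height to the reference standard position.

    Children under 24 months should be measured recumbent, older children
    standing.  A child measured in the other position gets +/-0.7 cm
    (standing under 24 months: +0.7; recumbent at 24 months or older:
    -0.7).  Position ``unknown`` is left unadjusted.
    """
    age = np.asarray(age_months, float)
    height = np.asarray(height_cm, float).copy()
    if not enabled:
        return height
    position = np.asarray(position, dtype=object)
    young = age < LENGTH_AGE_CUTOFF
    height = np.where(young & (position == "standing"), height + POSITION_ADJUST_CM, height)
    height = np.where(~young & (position == "recumbent"), height - POSITION_ADJUST_CM, height)
    return height


def compute_child_scores(
    records: pd.DataFrame,
    refs: dict[tuple[str, str], GrowthReference],
    adjust_position: bool = True,
) -> pd.DataFrame:
    """Score HAZ, WAZ and WHZ for every child row.

    ``records`` needs columns ``age_months, sex, weight_kg, height_cm,
    position`` (sex coded ``f``/``m``).  HAZ uses plain LMS on
    height-for-age; WAZ and WHZ use the restricted (tail-extended) score.
    WHZ is taken against weight-for-length under 24 months and
    weight-for-height from 24 months, after the measurement-position
    height conversion.  A score whose conditioning index falls outside
    the reference grid is NaN ("unavailable").

    Raises ``ReferenceError`` if a needed (indicator, sex) table is absent.
    """
    for sex in records["sex"].dropna().unique():
        if sex not in SEXES:
            continue
        for indicator in INDICATORS:
            if (indicator, sex) not in refs:
                raise ReferenceError(f"missing reference table ({indicator}, {sex})")

    n = len(records)
    haz = np.full(n, np.nan)
    waz = np.full(n, np.nan)
    whz = np.full(n, np.nan)

    age = records["age_months"].to_numpy(dtype=float)
    weight = records["weight_kg"].to_numpy(dtype=float)
    height = records["height_cm"].to_numpy(dtype=float)
    position = records["position"].to_numpy(dtype=object) if "position" in records else np.full(n, "unknown", dtype=object)
    h_adj = adjusted_height(age, height, position, enabled=adjust_position)

    sex_series = records["sex"]
    for sex in SEXES:
        m = (sex_series == sex).fillna(False).to_numpy(dtype=bool)
        if not m.any():
            continue
        L, M, S = refs[("hfa", sex)].lookup(age[m])
        haz[m] = zscore_lms(h_adj[m], L, M, S)

        L, M, S = refs[("wfa", sex)].lookup(age[m])
        waz[m] = zscore_restricted(weight[m], L, M, S)

        young = age[m] < LENGTH_AGE_CUTOFF
        for indicator, sel in (("wfl", young), ("wfh", ~young)):
            if not sel.any():
                continue
            idx = np.flatnonzero(m)[sel]
            L, M, S = refs[(indicator, sex)].lookup(h_adj[idx])
            whz[idx] = zscore_restricted(weight[idx], L, M, S)

    return pd.DataFrame({"whz": whz, "haz": haz, "waz": waz}, index=records.index)
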