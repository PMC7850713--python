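"""Synthetic two-stage cluster surveys with a self-consistent growth reference.

The generator produces child-level anthropometry with the statistical
structure the analysis assumes, so the whole pipeline is testable with
known ground truth and no external reference tables:

* a smooth parametric LMS reference (height-for-age, weight-for-age,
  weight-for-length/height, both sexes) in which the weight-for-age
  median is, by construction, the weight-for-height median evaluated at
  the height-for-age median — the three indices are mutually consistent;
* per cluster, a shared random shift of the HAZ and WHZ means
  (two-stage design: within-cluster correlation of deficits);
* per child, a correlated bivariate-normal (HAZ, WHZ) draw, converted to
  height via the inverse height-for-age LMS and to weight via the inverse
  (tail-extended) weight-for-length/height LMS at that height.  WAZ is
  never drawn: it emerges from the generated height and weight, which is
  what makes severe underweight overlap stunting;
* MUAC linear in age and WHZ with Gaussian noise, rare oedema, and
  instrument rounding (weight 0.1 kg, height 0.1 cm, MUAC 1 mm).

A draw whose inverse-LMS conversion leaves the reference grid (extreme
tail) is redrawn rather than clipped, and redraws are counted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth_reference as gr
from .classify import PROFILE_COLUMNS, Thresholds, classify
from .cohort import FlagLimits, build_exclusion_report

__all__ = [
    "MuacModel",
    "GeneratorConfig",
    "TruthSummary",
    "DEFAULT_COUNTRIES",
    "make_synthetic_reference",
    "simulate_survey",
    "simulate_dataset",
    "true_prevalence",
]


# ---------------------------------------------------------------------------
# synthetic growth reference
# ---------------------------------------------------------------------------

# Parametric forms (documented so the fixture is reproducible by hand):
#   height median   M_h(t)  = 45 * (1 + 0.01*[male]) + 35 * ln(1 + t/12)   cm
#   weight median   M_w(h)  = 6.26e-4 * h**2.19 * (1 + 0.03*[male])        kg
#   weight-for-age  M_wa(t) = M_w(M_h(t))
# with constant L and S per indicator.  The forms are synthetic: smooth,
# strictly increasing medians of realistic magnitude, not WHO values.
_HFA_L, _HFA_S = 1.0, 0.035
_WFH_L, _WFH_S = -0.35, 0.11
_WFA_L, _WFA_S = -0.25, 0.15

_AGE_GRID = np.arange(0.0, 61.0 + 0.5, 1.0)  # months, 0..61
_WFL_GRID = np.arange(45.0, 110.0 + 0.25, 0.5)  # cm (recumbent range)
_WFH_GRID = np.arange(65.0, 125.0 + 0.25, 0.5)  # cm (standing range)


def _median_height(age_months: np.ndarray, sex: str) -> np.ndarray:
    scale = 1.01 if sex == "m" else 1.0
    return scale * (45.0 + 35.0 * np.log1p(np.asarray(age_months, float) / 12.0))


def _median_weight_for_height(height_cm: np.ndarray, sex: str) -> np.ndarray:
    scale = 1.03 if sex == "m" else 1.0
    return scale * 6.26e-4 * np.power(np.asarray(height_cm, float), 2.19)


def make_synthetic_reference() -> dict[tuple[str, str], gr.GrowthReference]:
    """Build the synthetic LMS tables for all four indicators, both sexes."""
    refs: dict[tuple[str, str], gr.GrowthReference] = {}
    for sex in gr.SEXES:
        refs[("hfa", sex)] = gr.GrowthReference(
            "hfa", sex, _AGE_GRID,
            np.full_like(_AGE_GRID, _HFA_L),
            _median_height(_AGE_GRID, sex),
            np.full_like(_AGE_GRID, _HFA_S),
        )
        refs[("wfa", sex)] = gr.GrowthReference(
            "wfa", sex, _AGE_GRID,
            np.full_like(_AGE_GRID, _WFA_L),
            _median_weight_for_height(_median_height(_AGE_GRID, sex), sex),
            np.full_like(_AGE_GRID, _WFA_S),
        )
        for indicator, grid in (("wfl", _WFL_GRID), ("wfh", _WFH_GRID)):
            refs[(indicator, sex)] = gr.GrowthReference(
                indicator, sex, grid,
                np.full_like(grid, _WFH_L),
                _median_weight_for_height(grid, sex),
                np.full_like(grid, _WFH_S),
            )
    return refs


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

#: default countries and region grouping for multi-country runs (one
#: country per region keeps the default dataset small but exercises every
#: stratification level)
DEFAULT_COUNTRIES: dict[str, str] = {
    "Aland": "Region East",
    "Borica": "Region East",
    "Cadria": "Region South",
    "Dorsia": "Region South",
    "Ebran": "Region West",
    "Ferin": "Region West",
}


@dataclass(frozen=True)
class MuacModel:
    """MUAC (mm) = intercept + slope_age*age_months + slope_whz*WHZ + noise."""

    intercept_mm: float = 129.5
    slope_age: float = 0.4  # mm per month
    slope_whz: float = 5.0  # mm per WHZ unit
    resid_sd: float = 8.0  # mm


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic survey collection.

    The anthropometric defaults (HAZ mean -1.25 SD 1.1, WHZ mean -0.85
    SD 1.0, correlation 0.25, cluster shift SD 0.3, the MUAC model, rare
    oedema) describe a high-burden humanitarian setting: severe
    malnutrition by MUAC near 2%, by any criterion near 4%, severe
    underweight near 7-8% and largely stunting-driven — the regime in
    which MUAC- and WAZ-based screening strategies genuinely disagree.
    """

    seed: int = 0
    countries: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    n_surveys: int = 10  # per country
    clusters_per_survey: int = 25
    children_per_cluster: int = 20
    haz_mean: float = -1.25
    haz_sd: float = 1.1
    whz_mean: float = -0.85
    whz_sd: float = 1.0
    corr_haz_whz: float = 0.25
    cluster_effect_sd: float = 0.3  # added to both HAZ and WHZ cluster means
    muac: MuacModel = field(default_factory=MuacModel)
    oedema_prob: float = 0.005
    age_min: float = 6.0
    age_max: float = 60.0
    #: optional (lo, hi, weight) age bands; None = uniform on [age_min, age_max)
    age_bands: tuple[tuple[float, float, float], ...] | None = None
    round_weight_kg: float | None = 0.1
    round_height_cm: float | None = 0.1
    round_muac_mm: float | None = 1.0
    first_year: int = 2007
    last_year: int = 2018

    def __post_init__(self) -> None:
        if not (-1.0 < self.corr_haz_whz < 1.0):
            raise ValueError("corr_haz_whz must be in (-1, 1)")
        if not (0.0 <= self.oedema_prob <= 1.0):
            raise ValueError("oedema_prob must be in [0, 1]")
        if self.haz_sd < 0 or self.whz_sd < 0 or self.cluster_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TruthSummary:
    """Monte-Carlo case/target probabilities under a generator config."""

    probs: dict[str, float]
    se: dict[str, float]
    n_draws: int
    n_included: int
    n_redraws: int

    def as_dict(self) -> dict:
        return {
            "probs": dict(self.probs),
            "se": dict(self.se),
            "n_draws": self.n_draws,
            "n_included": self.n_included,
            "n_redraws": self.n_redraws,
        }


# ---------------------------------------------------------------------------
# child-level draws
# ---------------------------------------------------------------------------


def _draw_ages(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.age_bands is None:
        return rng.uniform(cfg.age_min, cfg.age_max, n)
    bands = np.asarray([(lo, hi) for lo, hi, _ in cfg.age_bands], float)
    weights = np.asarray([w for _, _, w in cfg.age_bands], float)
    weights = weights / weights.sum()
    which = rng.choice(len(bands), size=n, p=weights)
    return rng.uniform(bands[which, 0], bands[which, 1])


def _round_to(x: np.ndarray, precision: float | None) -> np.ndarray:
    if precision is None:
        return x
    return np.round(x / precision) * precision


def _draw_batch(rng, n, cfg, refs, shift_haz, shift_whz):
    """One vectorized draw of n children; returns columns plus validity mask.

    Draw order per child: age, sex, (HAZ, WHZ) pair, MUAC noise, oedema.
    """
    age = _draw_ages(rng, n, cfg)
    sex = np.where(rng.random(n) < 0.5, "f", "m").astype(object)
    eps = rng.standard_normal((n, 2))
    rho = cfg.corr_haz_whz
    z_haz = eps[:, 0]
    z_whz = rho * eps[:, 0] + np.sqrt(1.0 - rho * rho) * eps[:, 1]
    haz = cfg.haz_mean + shift_haz + cfg.haz_sd * z_haz
    whz = cfg.whz_mean + shift_whz + cfg.whz_sd * z_whz
    muac_noise = rng.standard_normal(n) * cfg.muac.resid_sd
    oedema = rng.random(n) < cfg.oedema_prob

    height = np.full(n, np.nan)
    weight = np.full(n, np.nan)
    young = age < gr.LENGTH_AGE_CUTOFF
    for s in gr.SEXES:
        m = sex == s
        if not m.any():
            continue
        L, M, S = refs[("hfa", s)].lookup(age[m])
        height[m] = gr.inverse_zscore(haz[m], L, M, S)
        for indicator, sel in (("wfl", young), ("wfh", ~young)):
            idx = np.flatnonzero(m & sel)
            if idx.size == 0:
                continue
            L, M, S = refs[(indicator, s)].lookup(height[idx])
            weight[idx] = gr.inverse_zscore_restricted(whz[idx], L, M, S)

    muac = (
        cfg.muac.intercept_mm
        + cfg.muac.slope_age * age
        + cfg.muac.slope_whz * whz
        + muac_noise
    )
    valid = (
        np.isfinite(height)
        & np.isfinite(weight)
        & (weight > 0)
        & (muac > 0)
    )
    cols = {
        "age_months": age,
        "sex": sex,
        "haz_true": haz,
        "whz_true": whz,
        "height_cm": height,
        "weight_kg": weight,
        "muac_mm": muac,
        "oedema": oedema,
    }
    return cols, valid


def _draw_children(rng, cfg, refs, shift_haz, shift_whz, max_rounds: int = 100):
    """Draw one child per shift entry, redrawing domain violations.

    Returns ``(DataFrame, n_redraws)``.  Redraw-not-clip keeps the tails
    honest — clipping would pile mass exactly where the implausible-value
    flags operate.
    """
    n = len(shift_haz)
    cols, valid = _draw_batch(rng, n, cfg, refs, shift_haz, shift_whz)
    redraws = 0
    rounds = 0
    while not valid.all():
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("generator failed to produce valid anthropometry")
        bad = np.flatnonzero(~valid)
        redraws += bad.size
        new_cols, new_valid = _draw_batch(
            rng, bad.size, cfg, refs, shift_haz[bad], shift_whz[bad]
        )
        for key, arr in cols.items():
            arr[bad] = new_cols[key]
        valid[bad] = new_valid

    frame = pd.DataFrame(cols)
    frame["position"] = np.where(
        frame["age_months"] < gr.LENGTH_AGE_CUTOFF, "recumbent", "standing"
    )
    frame["height_cm"] = _round_to(frame["height_cm"].to_numpy(), cfg.round_height_cm)
    frame["weight_kg"] = _round_to(frame["weight_kg"].to_numpy(), cfg.round_weight_kg)
    frame["muac_mm"] = _round_to(frame["muac_mm"].to_numpy(), cfg.round_muac_mm)
    return frame, redraws


# ---------------------------------------------------------------------------
# survey assembly
# ---------------------------------------------------------------------------


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in name)


def simulate_survey(
    cfg: GeneratorConfig,
    refs,
    rng: np.random.Generator,
    survey_id: str,
    country: str,
    year: int,
) -> pd.DataFrame:
    """Simulate one two-stage cluster survey as child-level records.

    Cluster effects are drawn first (one shared shift per cluster, added
    to both the HAZ and WHZ means), then children cluster by cluster in
    reading order.  Deterministic for a given generator state.
    """
    n_clusters = cfg.clusters_per_survey
    per_cluster = cfg.children_per_cluster
    cluster_shift = rng.standard_normal(n_clusters) * cfg.cluster_effect_sd
    shift = np.repeat(cluster_shift, per_cluster)
    children, redraws = _draw_children(rng, cfg, refs, shift, shift)
    children.insert(0, "survey_id", survey_id)
    children.insert(1, "cluster_id", np.repeat(np.arange(1, n_clusters + 1), per_cluster))
    children.insert(2, "country", country)
    children.insert(3, "year", year)
    children.attrs["n_redraws"] = redraws
    return children


def simulate_dataset(cfg: GeneratorConfig, refs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full multi-country survey collection.

    One independent seeded stream per survey (spawned from ``cfg.seed``
    in a fixed order), so any survey can be regenerated in isolation and
    the whole collection is reproducible across platforms.

    Returns ``(records, surveys)`` in the survey-file column layout.
    """
    if refs is None:
        refs = make_synthetic_reference()
    root = np.random.SeedSequence(cfg.seed)
    countries = list(cfg.countries)
    streams = root.spawn(len(countries) * cfg.n_surveys)
    frames = []
    meta = []
    k = 0
    for country in countries:
        for i in range(cfg.n_surveys):
            survey_id = f"{_slug(country)}-S{i + 1:03d}"
            year = cfg.first_year + i % (cfg.last_year - cfg.first_year + 1)
            rng = np.random.default_rng(streams[k])
            k += 1
            frames.append(simulate_survey(cfg, refs, rng, survey_id, country, year))
            meta.append({"survey_id": survey_id, "country": country, "year": year})
    records = pd.concat(frames, ignore_index=True)
    surveys = pd.DataFrame(meta)
    return records, surveys


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def true_prevalence(
    cfg: GeneratorConfig,
    refs=None,
    n_draws: int = 10**6,
    seed: int | None = None,
    thresholds: Thresholds = Thresholds(),
    limits: FlagLimits = FlagLimits(),
) -> TruthSummary:
    """Monte-Carlo probability of each case/target category under ``cfg``.

    Children are drawn down the same generative path as the surveys —
    including per-child cluster shifts, instrument rounding and the
    exclusion rules — but without assembly into surveys.  Probabilities
    are conditional on inclusion (matching pipeline prevalences) with
    binomial standard errors.
    """
    if refs is None:
        refs = make_synthetic_reference()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shift = rng.standard_normal(n_draws) * cfg.cluster_effect_sd
    children, redraws = _draw_children(rng, cfg, refs, shift, shift)
    children["survey_id"] = "mc"
    children["cluster_id"] = 0
    children["country"] = "mc"
    children["year"] = 0

    scores = gr.compute_child_scores(children, refs)
    report = build_exclusion_report(children, scores, limits)
    included = pd.concat([children, scores], axis=1).loc[report["included"]]
    profiles = classify(included, thresholds)

    n = len(profiles)
    probs = {}
    se = {}
    for col in PROFILE_COLUMNS:
        p = float(profiles[col].mean()) if n else float("nan")
        probs[col] = p
        se[col] = float(np.sqrt(p * (1.0 - p) / n)) if n else float("nan")
    return TruthSummary(probs=probs, se=se, n_draws=n_draws, n_included=n, n_redraws=redraws)
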