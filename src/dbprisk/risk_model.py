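"""Exposure and risk equations for the drinking-water ingestion route.

The model is the US EPA screening-level chronic ingestion model:

    ADD = (C × IR × EF × ED) / (BW × AT)          average daily dose
    CR  = SF × ADD × ADAF                          carcinogenic risk
    HQ  = ADD / RfD                                hazard quotient

with EF = 365 days/year, ED = 3 years per age group and AT = ED × 365 days,
so the full form reduces algebraically to ADD = C × IR / BW (the full form
is implemented; the reduction is asserted in tests).

Early-life susceptibility enters through age-dependent adjustment factors
(ADAFs): a factor of 3 applies through the 15th year of age and 1 for ages
16–17.  For the 15–17 age group the risk is the exposure-duration-weighted
average of one year at ADAF 3 and two years at ADAF 1, i.e. an effective
multiplier of (3·1 + 1·2)/3 = 5/3.

Exposure parameters (daily water intake IR, body weight BW) come from the
Exposure Factors Handbook of the Chinese Population, ages 6–17, stratified
by age group and gender.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    Analyte,
    AnalyteSpec,
    EmptyStratumError,
    ValidationError,
    WaterSample,
    samples_to_frame,
)

__all__ = [
    "AgeGroup",
    "Gender",
    "ExposureGroup",
    "builtin_exposure_groups",
    "average_daily_dose",
    "carcinogenic_risk",
    "hazard_quotient",
    "assess",
    "summarize_risks",
    "format_risk_report",
    "EXPOSURE_FREQUENCY_DAYS",
    "EXPOSURE_DURATION_YEARS",
]

EXPOSURE_FREQUENCY_DAYS = 365.0  # EF, days/year
EXPOSURE_DURATION_YEARS = 3.0  # ED, years per age group

#: ADAF weighting for the 15-17 group: 1 year at factor 3 (age 15),
#: 2 years at factor 1 (ages 16-17), over a 3-year exposure duration.
ADAF_YOUNG = 3.0
ADAF_OLD = 1.0
_ADAF_15_17 = (ADAF_YOUNG * 1.0 + ADAF_OLD * 2.0) / 3.0


class AgeGroup(str, enum.Enum):
    A6_8 = "6-8"
    A9_11 = "9-11"
    A12_14 = "12-14"
    A15_17 = "15-17"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    TOTAL = "total"


@dataclass(frozen=True)
class ExposureGroup:
    """Exposure parameters for one age-group × gender cell.

    ``adaf_effective`` is the multiplier applied to SF × ADD: 3 for the
    three younger groups, 5/3 for 15–17 (duration-weighted average).
    """

    age_group: AgeGroup
    gender: Gender
    ir: float  # daily drinking-water intake, L/day
    bw: float  # body weight, kg
    ef: float = EXPOSURE_FREQUENCY_DAYS
    ed: float = EXPOSURE_DURATION_YEARS
    adaf_effective: float = ADAF_YOUNG

    def __post_init__(self) -> None:
        if self.ir <= 0 or self.bw <= 0:
            raise ValidationError("IR and BW must be positive")

    @property
    def at_days(self) -> float:
        """Averaging time AT = ED × 365 days (cancels ED × EF in the dose)."""
        return self.ed * 365.0


# IR (L/day) and BW (kg) by (age group, gender).
_IR = {
    (AgeGroup.A6_8, Gender.MALE): 0.690,
    (AgeGroup.A6_8, Gender.FEMALE): 0.665,
    (AgeGroup.A6_8, Gender.TOTAL): 0.679,
    (AgeGroup.A9_11, Gender.MALE): 0.717,
    (AgeGroup.A9_11, Gender.FEMALE): 0.701,
    (AgeGroup.A9_11, Gender.TOTAL): 0.709,
    (AgeGroup.A12_14, Gender.MALE): 0.794,
    (AgeGroup.A12_14, Gender.FEMALE): 0.755,
    (AgeGroup.A12_14, Gender.TOTAL): 0.775,
    (AgeGroup.A15_17, Gender.MALE): 0.885,
    (AgeGroup.A15_17, Gender.FEMALE): 0.915,
    (AgeGroup.A15_17, Gender.TOTAL): 0.899,
}
_BW = {
    (AgeGroup.A6_8, Gender.MALE): 27.2,
    (AgeGroup.A6_8, Gender.FEMALE): 26.2,
    (AgeGroup.A6_8, Gender.TOTAL): 26.7,
    (AgeGroup.A9_11, Gender.MALE): 35.8,
    (AgeGroup.A9_11, Gender.FEMALE): 33.2,
    (AgeGroup.A9_11, Gender.TOTAL): 34.6,
    (AgeGroup.A12_14, Gender.MALE): 47.0,
    (AgeGroup.A12_14, Gender.FEMALE): 44.8,
    (AgeGroup.A12_14, Gender.TOTAL): 45.9,
    (AgeGroup.A15_17, Gender.MALE): 58.6,
    (AgeGroup.A15_17, Gender.FEMALE): 49.8,
    (AgeGroup.A15_17, Gender.TOTAL): 54.3,
}


def builtin_exposure_groups() -> list[ExposureGroup]:
    """The 12 exposure groups (4 age groups × male/female/combined)."""
    groups = []
    for age in AgeGroup:
        adaf = _ADAF_15_17 if age is AgeGroup.A15_17 else ADAF_YOUNG
        for gender in Gender:
            groups.append(
                ExposureGroup(
                    age_group=age,
                    gender=gender,
                    ir=_IR[(age, gender)],
                    bw=_BW[(age, gender)],
                    adaf_effective=adaf,
                )
            )
    return groups


def average_daily_dose(c: float, group: ExposureGroup) -> float:
    """ADD = (C × IR × EF × ED)/(BW × AT) in mg/kg·day, for C in mg/L.

    EF·ED/AT = 1 by construction, so this equals C × IR / BW; the full form
    is kept so that the parameterisation stays visible.
    """
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c}")
    return (c * group.ir * group.ef * group.ed) / (group.bw * group.at_days)


def carcinogenic_risk(add: float, spec: AnalyteSpec, group: ExposureGroup) -> float:
    """CR = SF × ADD × ADAF (dimensionless lifetime excess risk).

    For the 15–17 group ``group.adaf_effective`` is 5/3, which equals the
    duration-weighted average of CR at ADAF 3 for 1 year and ADAF 1 for 2
    years exactly.
    """
    if add < 0:
        raise ValidationError(f"dose must be >= 0, got {add}")
    return spec.sf * add * group.adaf_effective


def hazard_quotient(add: float, spec: AnalyteSpec) -> float:
    """HQ = ADD / RfD (dimensionless; values below 1 indicate low concern)."""
    if add < 0:
        raise ValidationError(f"dose must be >= 0, got {add}")
    if spec.rfd <= 0:
        raise ValidationError(f"{spec.analyte}: reference dose must be positive")
    return add / spec.rfd


# ---------------------------------------------------------------------------
# Per-sample assessment
# ---------------------------------------------------------------------------

def assess(
    samples: Sequence[WaterSample],
    registry: Mapping[Analyte, AnalyteSpec],
    groups: Sequence[ExposureGroup] | None = None,
) -> pd.DataFrame:
    """Apply the dose/risk equations to every sample × analyte × group.

    Returns a tidy DataFrame (one row per combination) with columns
    ``sample_id``, stratum labels, ``analyte``, ``age_group``, ``gender``,
    ``add``, ``cr``, ``hq``.  Samples must be imputed first; a censored
    value without a magnitude raises.
    """
    groups = list(groups) if groups is not None else builtin_exposure_groups()
    if len(samples) == 0:
        return pd.DataFrame(
            columns=[
                "sample_id", "season", "stage", "source", "disinfectant",
                "analyte", "age_group", "gender", "add", "cr", "hq",
            ]
        )
    df = samples_to_frame(samples)
    frames = []
    label_cols = ["sample_id", "season", "stage", "source", "disinfectant"]
    for a in Analyte:
        if a not in registry:
            raise ValidationError(f"analyte {a!r} not in registry")
        conc = df[a.value].to_numpy(dtype=float)
        if np.isnan(conc).any():
            raise ValidationError(
                f"{a.value}: censored values present without imputation; run impute_censored first"
            )
        spec = registry[a]
        for g in groups:
            add = conc * g.ir * g.ef * g.ed / (g.bw * g.at_days)
            sub = df[label_cols].copy()
            sub["analyte"] = a.value
            sub["age_group"] = g.age_group.value
            sub["gender"] = g.gender.value
            sub["add"] = add
            sub["cr"] = spec.sf * add * g.adaf_effective
            sub["hq"] = add / spec.rfd
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stratified summaries
# ---------------------------------------------------------------------------

def _median_qr(x: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(np.median(x)), float(q3 - q1)


def summarize_risks(records: pd.DataFrame, strata: Sequence[str]) -> pd.DataFrame:
    """Median and interquartile range of CR and HQ per analyte per stratum,
    plus one ``total`` row per stratum.

    The ``total`` row reports the sum of per-analyte medians (the
    convention used in multi-pollutant screening tables, where the total is
    tallied from the per-analyte summary column); the median of per-sample
    summed risks is also computed, under ``median_cr_samplesum`` /
    ``median_hq_samplesum``, since the two aggregates differ in general.

    ``strata`` are column names of ``records`` (e.g. ``["age_group",
    "gender"]`` or ``["season"]``).  When stratifying by a sample-level
    label, filter ``records`` to a single exposure group first so that
    exposure-parameter variation does not leak into the contrast.
    """
    if records.empty:
        raise EmptyStratumError("no risk records to summarize")
    for name in strata:
        if name not in records.columns:
            raise ValidationError(f"unknown stratum column {name!r}")
    strata = list(strata)
    rows = []
    for key, sub in records.groupby(strata, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = dict(zip(strata, key))
        medians_cr, medians_hq = [], []
        for analyte, asub in sub.groupby("analyte", sort=False, observed=True):
            m_cr, q_cr = _median_qr(asub["cr"].to_numpy())
            m_hq, q_hq = _median_qr(asub["hq"].to_numpy())
            medians_cr.append(m_cr)
            medians_hq.append(m_hq)
            rows.append(
                {
                    "analyte": analyte, **labels,
                    "median_cr": m_cr, "qr_cr": q_cr,
                    "median_hq": m_hq, "qr_hq": q_hq,
                    "n": len(asub),
                }
            )
        # per-sample totals within the stratum (sum over analytes first)
        per_sample = sub.groupby("sample_id", observed=True)[["cr", "hq"]].sum()
        m_cr_ss, q_cr_ss = _median_qr(per_sample["cr"].to_numpy())
        m_hq_ss, q_hq_ss = _median_qr(per_sample["hq"].to_numpy())
        rows.append(
            {
                "analyte": "total", **labels,
                "median_cr": float(np.sum(medians_cr)),
                "qr_cr": np.nan,
                "median_hq": float(np.sum(medians_hq)),
                "qr_hq": np.nan,
                "median_cr_samplesum": m_cr_ss,
                "qr_cr_samplesum": q_cr_ss,
                "median_hq_samplesum": m_hq_ss,
                "qr_hq_samplesum": q_hq_ss,
                "n": int(per_sample.shape[0]),
            }
        )
    return pd.DataFrame(rows)


def format_risk_report(summary: pd.DataFrame, strata: Sequence[str]) -> pd.DataFrame:
    """Report-precision risk table: CR on the ×10⁻⁶ scale and HQ on the
    ×10⁻² scale, three decimals, round-half-even.

    Totals rows are re-tallied from the *rounded* per-analyte entries, the
    way screening reports sum their printed columns, so the printed total
    equals the sum of the printed analyte rows.
    """
    strata = list(strata)
    out = summary.copy()
    out["median_cr_e6"] = (out["median_cr"] * 1e6).round(3)
    out["qr_cr_e6"] = (out["qr_cr"] * 1e6).round(3)
    out["median_hq_e2"] = (out["median_hq"] * 1e2).round(3)
    out["qr_hq_e2"] = (out["qr_hq"] * 1e2).round(3)
    is_total = out["analyte"] == "total"
    if is_total.any():
        analyte_rows = out[~is_total]
        tallies = analyte_rows.groupby(strata, sort=True, observed=True)[
            ["median_cr_e6", "median_hq_e2"]
        ].sum()
        for idx in out.index[is_total]:
            key = tuple(out.loc[idx, s] for s in strata)
            key = key if len(key) > 1 else key[0]
            out.loc[idx, "median_cr_e6"] = round(float(tallies.loc[key, "median_cr_e6"]), 3)
            out.loc[idx, "median_hq_e2"] = round(float(tallies.loc[key, "median_hq_e2"]), 3)
    cols = ["analyte", *strata, "median_cr_e6", "qr_cr_e6", "median_hq_e2", "qr_hq_e2", "n"]
    return out[cols]
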