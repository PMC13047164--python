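"""Seeded generator for a synthetic drinking-water DBP monitoring study.

The generator emulates the design of a two-season municipal monitoring
campaign: fixed numbers of samples per season, supply stage, source type
and disinfectant (matched exactly, by seeded shuffles of fixed-count label
vectors), and per-analyte concentration distributions calibrated so that
the post-imputation study margins — detection rate, overall median and
interquartile range — reproduce the published summary table of the
monitoring campaign being emulated.

Concentration model, per analyte:

* censoring is Bernoulli with probability 1 − detect_rate, independent of
  magnitude;
* detected values are log-normal, clipped to [LOD, observed maximum], with
  optional multiplicative season and supply-stage effects (log-centred so
  the overall marginal is approximately preserved);
* the log-normal parameters are solved by root finding so that the
  *post-imputation mixture* (a point mass of censored-then-imputed LOD/2
  values plus the detected distribution) has the target overall median and
  interquartile range.  For analytes whose overall median is itself the
  imputed LOD/2 (detection rate < 50%), the detected distribution is
  anchored instead by the overall Q3 (imputed value + IQR) and by treating
  the observed maximum as its 99.5th percentile.

Water-quality parameters are drawn from bounded normal (pH) and log-normal
(permanganate index, free chlorine) families matched to published medians
and IQRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .core_data import (
    Analyte,
    AnalyteSpec,
    ConcentrationValue,
    Disinfectant,
    Season,
    Source,
    Stage,
    ValidationError,
    WaterSample,
    builtin_registry,
)

__all__ = [
    "StudyDesign",
    "AnalyteCalibration",
    "WQPCalibration",
    "CalibrationError",
    "default_design",
    "scaled_design",
    "default_calibration",
    "default_wqp_calibration",
    "solve_lognormal",
    "solve_calibrated_lognormal",
    "generate",
]

_Z75 = norm.ppf(0.75)  # 0.6744897...


class CalibrationError(ValueError):
    """The requested calibration targets admit no valid distribution."""


@dataclass(frozen=True)
class StudyDesign:
    """Categorical margins of the monitoring campaign.  Every margin must
    sum to ``n_total``; the generator matches each margin exactly."""

    n_total: int
    season_counts: Mapping[Season, int]
    stage_counts: Mapping[Stage, int]
    source_counts: Mapping[Source, int]
    disinfectant_counts: Mapping[Disinfectant, int]
    n_waterworks: int

    def __post_init__(self) -> None:
        for name, margin in (
            ("season", self.season_counts),
            ("stage", self.stage_counts),
            ("source", self.source_counts),
            ("disinfectant", self.disinfectant_counts),
        ):
            total = sum(margin.values())
            if total != self.n_total:
                raise ValidationError(
                    f"{name} margin sums to {total}, expected n_total={self.n_total}"
                )
            if any(v < 0 for v in margin.values()):
                raise ValidationError(f"{name} margin has negative counts")
        if self.n_waterworks < 1:
            raise ValidationError("n_waterworks must be >= 1")


def default_design() -> StudyDesign:
    """The default two-season municipal campaign: 886 samples from 69
    waterworks with the margins 442/444 (dry/wet), 138/550/198
    (finished/terminal/secondary), 854/32 (surface/ground) and
    718/112/52/4 by disinfectant."""
    return StudyDesign(
        n_total=886,
        season_counts={Season.DRY: 442, Season.WET: 444},
        stage_counts={Stage.FINISHED: 138, Stage.TERMINAL: 550, Stage.SECONDARY: 198},
        source_counts={Source.SURFACE: 854, Source.GROUND: 32},
        disinfectant_counts={
            Disinfectant.SODIUM_HYPOCHLORITE: 718,
            Disinfectant.LIQUID_CHLORINE: 112,
            Disinfectant.COMPOSITE_CHLORINE_DIOXIDE: 52,
            Disinfectant.BLEACHING_POWDER: 4,
        },
        n_waterworks=69,
    )


def _scale_margin(margin: Mapping, n_new: int, n_old: int) -> dict:
    """Proportional rescale with largest-remainder rounding to an exact sum."""
    keys = list(margin)
    exact = {k: margin[k] * n_new / n_old for k in keys}
    out = {k: int(math.floor(exact[k])) for k in keys}
    short = n_new - sum(out.values())
    by_rem = sorted(keys, key=lambda k: exact[k] - out[k], reverse=True)
    for k in by_rem[:short]:
        out[k] += 1
    return out


def scaled_design(n_total: int, base: StudyDesign | None = None) -> StudyDesign:
    """A design with the same margin proportions at a different total size,
    e.g. for Monte-Carlo checks of the calibration at large n."""
    base = base or default_design()
    return StudyDesign(
        n_total=n_total,
        season_counts=_scale_margin(base.season_counts, n_total, base.n_total),
        stage_counts=_scale_margin(base.stage_counts, n_total, base.n_total),
        source_counts=_scale_margin(base.source_counts, n_total, base.n_total),
        disinfectant_counts=_scale_margin(base.disinfectant_counts, n_total, base.n_total),
        n_waterworks=base.n_waterworks,
    )


@dataclass(frozen=True)
class AnalyteCalibration:
    """Marginal targets for one analyte, on the post-imputation scale.

    ``median_overall`` / ``qr_overall`` are the overall (all samples,
    censored values imputed at LOD/2) median and interquartile range in
    mg/L; for analytes detected in fewer than half the samples the overall
    median equals the imputed value.  ``season_shift`` / ``stage_shift``
    are multiplicative, log-centred effects applied to detected values.
    """

    analyte: Analyte
    detect_rate: float
    median_overall: float
    qr_overall: float
    max_overall: float
    season_shift: Mapping[Season, float] = field(
        default_factory=lambda: {s: 1.0 for s in Season}
    )
    stage_shift: Mapping[Stage, float] = field(
        default_factory=lambda: {s: 1.0 for s in Stage}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_rate <= 1.0:
            raise ValidationError("detect_rate must be in [0, 1]")
        if self.median_overall <= 0 or self.qr_overall < 0:
            raise ValidationError("median_overall must be > 0 and qr_overall >= 0")
        if self.max_overall < self.median_overall:
            raise ValidationError("max_overall must be >= median_overall")


@dataclass(frozen=True)
class WQPCalibration:
    """Targets for the water-quality parameters: pH (bounded normal),
    permanganate index and free chlorine (bounded log-normal), in mg/L
    except pH."""

    ph_median: float = 7.20
    ph_qr: float = 0.40
    ph_bounds: tuple[float, float] = (6.50, 8.46)
    pi_median: float = 0.69
    pi_qr: float = 0.46
    pi_bounds: tuple[float, float] = (0.20, 2.49)
    fc_median: float = 0.26
    fc_qr: float = 0.30
    fc_bounds: tuple[float, float] = (0.01, 0.88)


# Stage-by-season medians (mg/L) for the analytes whose medians are
# detected values in both seasons and all stages; used to derive the
# default multiplicative season and stage effects.
_SHIFT_SOURCE_MEDIANS: dict[Analyte, dict[Season, tuple[float, float, float]]] = {
    # (finished, terminal, secondary)
    Analyte.TCM: {
        Season.DRY: (0.00570, 0.00941, 0.01100),
        Season.WET: (0.01095, 0.01437, 0.01700),
    },
    Analyte.DBCM: {
        Season.DRY: (0.00106, 0.00121, 0.00140),
        Season.WET: (0.00100, 0.00140, 0.00138),
    },
    Analyte.BDCM: {
        Season.DRY: (0.00348, 0.00440, 0.00480),
        Season.WET: (0.00445, 0.00521, 0.00562),
    },
}

# Default stage weights used for log-centring the stage effect (the
# finished/terminal/secondary proportions of the default design).
_STAGE_WEIGHTS = {Stage.FINISHED: 138 / 886, Stage.TERMINAL: 550 / 886, Stage.SECONDARY: 198 / 886}


def _default_shifts(analyte: Analyte) -> tuple[dict[Season, float], dict[Stage, float]]:
    src = _SHIFT_SOURCE_MEDIANS.get(analyte)
    if src is None:
        return {s: 1.0 for s in Season}, {s: 1.0 for s in Stage}
    dry = np.array(src[Season.DRY])
    wet = np.array(src[Season.WET])
    ratio = wet.mean() / dry.mean()
    season = {Season.DRY: ratio**-0.5, Season.WET: ratio**0.5}
    stage_med = {
        Stage.FINISHED: (dry[0] + wet[0]) / 2.0,
        Stage.TERMINAL: (dry[1] + wet[1]) / 2.0,
        Stage.SECONDARY: (dry[2] + wet[2]) / 2.0,
    }
    log_center = sum(_STAGE_WEIGHTS[s] * math.log(stage_med[s]) for s in Stage)
    stage = {s: math.exp(math.log(stage_med[s]) - log_center) for s in Stage}
    return season, stage


def default_calibration() -> dict[Analyte, AnalyteCalibration]:
    """Per-analyte targets matching the published campaign margins:
    detection rates, overall medians, interquartile ranges and maxima
    (mg/L; "overall" = all samples with non-detects imputed at LOD/2)."""
    registry = builtin_registry()
    raw = {
        # analyte: (detect_rate, median, qr, max) in mg/L; None -> LOD/2
        Analyte.TCM: (0.9898, 1.100e-2, 1.091e-2, 5.030e-2),
        Analyte.DBCM: (0.9142, 0.130e-2, 0.135e-2, 1.130e-2),
        Analyte.BDCM: (0.9763, 0.469e-2, 0.314e-2, 1.770e-2),
        Analyte.TBM: (0.3510, None, 0.008e-2, 1.100e-2),
        Analyte.DCAA: (0.5316, 0.44e-2, 1.00e-2, 4.75e-2),
        Analyte.TCAA: (0.3792, None, 0.65e-2, 4.40e-2),
    }
    out = {}
    for analyte, (dr, med, qr, mx) in raw.items():
        season, stage = _default_shifts(analyte)
        out[analyte] = AnalyteCalibration(
            analyte=analyte,
            detect_rate=dr,
            median_overall=med if med is not None else registry[analyte].half_lod_mg_l,
            qr_overall=qr,
            max_overall=mx,
            season_shift=season,
            stage_shift=stage,
        )
    return out


def default_wqp_calibration() -> WQPCalibration:
    return WQPCalibration()


# ---------------------------------------------------------------------------
# Log-normal calibration solvers
# ---------------------------------------------------------------------------

def solve_lognormal(median_target: float, iqr_target: float) -> tuple[float, float]:
    """Parameters (location µ, scale σ) of the log-normal with the given
    median and interquartile range, by one-dimensional root finding."""
    if median_target <= 0 or iqr_target <= 0:
        raise CalibrationError("median and IQR targets must be positive")
    mu = math.log(median_target)

    def gap(sigma: float) -> float:
        return median_target * (math.exp(_Z75 * sigma) - math.exp(-_Z75 * sigma)) - iqr_target

    hi = 1.0
    while gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if gap(hi) < 0:
        raise CalibrationError("no positive scale satisfies the IQR target")
    sigma = brentq(gap, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    return mu, float(sigma)


def solve_calibrated_lognormal(
    calib: AnalyteCalibration, spec: AnalyteSpec
) -> tuple[float, float]:
    """Log-normal parameters for the detected-value distribution such that
    the post-imputation mixture reproduces ``calib``'s overall targets.

    The mixture puts mass (1 − detect_rate) at the imputed LOD/2 and the
    rest on the detected log-normal, so the overall quantile at level p > q
    is the detected quantile at (p − q)/d.  Two regimes:

    * overall median above the imputed value (detection rate > 50% or
      median genuinely detected): µ is tied to the overall-median condition
      and σ solved so the mixture IQR matches;
    * overall median equal to the imputed value (majority censored): the
      detected distribution is anchored by the mixture Q3 and by treating
      the observed maximum as its 99.5th percentile (closed form).
    """
    d = calib.detect_rate
    q = 1.0 - d
    v0 = spec.half_lod_mg_l
    m = calib.median_overall
    if d <= 0.0:
        raise CalibrationError(f"{calib.analyte}: detect_rate must be positive to calibrate")
    if m < spec.lod_mg_l and d > 0.5:
        raise CalibrationError(
            f"{calib.analyte}: overall median {m} below LOD with detect_rate {d} > 0.5 "
            "is infeasible (the majority of values would be detected yet below LOD)"
        )

    if m <= v0 * (1.0 + 1e-12):  # ND-median regime (majority censored)
        p3 = (0.75 - q) / d
        if not 0.0 < p3 < 1.0:
            raise CalibrationError(f"{calib.analyte}: mixture Q3 not reachable (detect_rate {d})")
        x1 = v0 + calib.qr_overall  # mixture Q3 (Q1 is the imputed point mass)
        x2 = calib.max_overall  # treated as detected 99.5th percentile
        z1, z2 = norm.ppf(p3), norm.ppf(0.995)
        if x2 <= x1:
            raise CalibrationError(f"{calib.analyte}: maximum must exceed Q3 anchor")
        sigma = (math.log(x2) - math.log(x1)) / (z2 - z1)
        mu = math.log(x1) - sigma * z1
        return mu, float(sigma)

    pm = (0.5 - q) / d
    if not 0.0 < pm < 1.0:
        raise CalibrationError(f"{calib.analyte}: overall median not reachable at detect_rate {d}")
    zm = norm.ppf(pm)
    z3 = norm.ppf((0.75 - q) / d)

    def mixture_iqr(sigma: float) -> float:
        mu = math.log(m) - sigma * zm
        q3 = math.exp(mu + sigma * z3)
        if q >= 0.25:
            q1 = v0
        else:
            q1 = math.exp(mu + sigma * norm.ppf((0.25 - q) / d))
        return q3 - q1

    def gap(sigma: float) -> float:
        return mixture_iqr(sigma) - calib.qr_overall

    if gap(1e-9) > 0:
        raise CalibrationError(
            f"{calib.analyte}: IQR target {calib.qr_overall} below the minimum "
            f"achievable spread {mixture_iqr(1e-9):.3g}"
        )
    hi = 1.0
    while gap(hi) < 0 and hi < 64.0:
        hi *= 2.0
    if gap(hi) < 0:
        raise CalibrationError(f"{calib.analyte}: no scale satisfies the IQR target")
    sigma = brentq(gap, 1e-9, hi, xtol=1e-15, rtol=8.9e-16)
    mu = math.log(m) - sigma * zm
    return float(mu), float(sigma)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _shuffled_labels(rng: np.random.Generator, margin: Mapping) -> list:
    labels = [k for k, count in margin.items() for _ in range(count)]
    rng.shuffle(labels)
    return labels


def _bounded_normal(
    rng: np.random.Generator, n: int, median: float, qr: float, bounds: tuple[float, float]
) -> np.ndarray:
    sd = qr / (2.0 * _Z75)
    return np.clip(rng.normal(median, sd, size=n), bounds[0], bounds[1])


def _bounded_lognormal(
    rng: np.random.Generator, n: int, median: float, qr: float, bounds: tuple[float, float]
) -> np.ndarray:
    mu, sigma = solve_lognormal(median, qr)
    return np.clip(np.exp(mu + sigma * rng.standard_normal(n)), bounds[0], bounds[1])


def generate(
    design: StudyDesign | None = None,
    calibration: Mapping[Analyte, AnalyteCalibration] | None = None,
    seed: int | None = None,
    wqp: WQPCalibration | None = None,
    registry: Mapping[Analyte, AnalyteSpec] | None = None,
) -> list[WaterSample]:
    """Generate a fully synthetic monitoring study.

    Categorical margins are matched exactly for every seed (fixed-count
    label vectors, independently shuffled); waterworks ids are assigned
    round-robin.  Identical seed and configuration give identical output.
    Censored analytes carry no magnitude — run
    :func:`dbprisk.core_data.impute_censored` before assessment, exactly as
    for real data.
    """
    if seed is None:
        raise ValidationError("generate requires an explicit seed")
    design = design or default_design()
    calibration = calibration or default_calibration()
    wqp = wqp or default_wqp_calibration()
    registry = registry or builtin_registry()
    missing = [a for a in Analyte if a not in calibration]
    if missing:
        raise ValidationError(f"calibration missing analytes {missing}")

    rng = np.random.default_rng(seed)
    n = design.n_total
    seasons = _shuffled_labels(rng, design.season_counts)
    stages = _shuffled_labels(rng, design.stage_counts)
    sources = _shuffled_labels(rng, design.source_counts)
    disinfectants = _shuffled_labels(rng, design.disinfectant_counts)
    waterworks = [f"WW{(i % design.n_waterworks) + 1:02d}" for i in range(n)]

    conc_matrix: dict[Analyte, list[ConcentrationValue]] = {}
    for a in Analyte:
        calib = calibration[a]
        spec = registry[a]
        mu, sigma = solve_calibrated_lognormal(calib, spec)
        censored = rng.random(n) < (1.0 - calib.detect_rate)
        z = rng.standard_normal(n)
        log_shift = np.array(
            [
                math.log(calib.season_shift[seasons[i]]) + math.log(calib.stage_shift[stages[i]])
                for i in range(n)
            ]
        )
        values = np.exp(mu + sigma * z + log_shift)
        values = np.clip(values, spec.lod_mg_l, calib.max_overall)
        conc_matrix[a] = [
            ConcentrationValue(value=None, censored=True)
            if censored[i]
            else ConcentrationValue(value=float(values[i]), censored=False)
            for i in range(n)
        ]

    ph = _bounded_normal(rng, n, wqp.ph_median, wqp.ph_qr, wqp.ph_bounds)
    pi = _bounded_lognormal(rng, n, wqp.pi_median, wqp.pi_qr, wqp.pi_bounds)
    fc = _bounded_lognormal(rng, n, wqp.fc_median, wqp.fc_qr, wqp.fc_bounds)

    samples = []
    for i in range(n):
        samples.append(
            WaterSample(
                sample_id=f"S{i + 1:05d}",
                waterworks_id=waterworks[i],
                season=seasons[i],
                stage=stages[i],
                source=sources[i],
                disinfectant=disinfectants[i],
                conc={a: conc_matrix[a][i] for a in Analyte},
                ph=float(ph[i]),
                pi=float(pi[i]),
                fc=float(fc[i]),
            )
        )
    return samples
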