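"""Sample data model, CSV I/O, below-LOD imputation and concentration summaries.

Concentrations are stored internally in mg/L.  Analytical limits of
detection (LODs) are tabulated in µg/L, as analytical methods report them,
and are converted to mg/L at the imputation boundary.  A concentration
reported below the LOD ("ND", not detected) is a left-censored observation;
the substitution rule used throughout is LOD/2, the conventional simple
imputation for environmental monitoring data.  Detection status is carried
as an explicit flag so that detection rates remain computable after
imputation.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UG_PER_MG = 1000.0

__all__ = [
    "Analyte",
    "Season",
    "Stage",
    "Source",
    "Disinfectant",
    "AnalyteSpec",
    "ConcentrationValue",
    "WaterSample",
    "SummaryRow",
    "CsvDialect",
    "SchemaError",
    "RowParseError",
    "ValidationError",
    "EmptyStratumError",
    "builtin_registry",
    "read_samples",
    "write_samples",
    "impute_censored",
    "samples_to_frame",
    "summarize_concentrations",
    "summary_to_frame",
]


class SchemaError(ValueError):
    """The input table is structurally unusable (missing column, empty file)."""


class RowParseError(ValueError):
    """A row contains an unparseable value; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ValidationError(ValueError):
    """A value violates a domain invariant (unknown label, bad range)."""


class EmptyStratumError(ValueError):
    """A summary was requested for a stratum containing no samples."""


class Analyte(str, enum.Enum):
    """The six regulated disinfection by-products: four trihalomethanes and
    two haloacetic acids."""

    TCM = "tcm"  # trichloromethane (chloroform)
    DBCM = "dbcm"  # dibromochloromethane
    BDCM = "bdcm"  # bromodichloromethane
    TBM = "tbm"  # tribromomethane (bromoform)
    DCAA = "dcaa"  # dichloroacetic acid
    TCAA = "tcaa"  # trichloroacetic acid


class Season(str, enum.Enum):
    DRY = "dry"
    WET = "wet"


class Stage(str, enum.Enum):
    """Water supply stage: plant outlet, user tap, or building-level re-storage."""

    FINISHED = "finished"
    TERMINAL = "terminal"
    SECONDARY = "secondary"


class Source(str, enum.Enum):
    SURFACE = "surface"
    GROUND = "ground"


class Disinfectant(str, enum.Enum):
    SODIUM_HYPOCHLORITE = "sodium_hypochlorite"
    LIQUID_CHLORINE = "liquid_chlorine"
    COMPOSITE_CHLORINE_DIOXIDE = "composite_chlorine_dioxide"
    BLEACHING_POWDER = "bleaching_powder"


@dataclass(frozen=True)
class AnalyteSpec:
    """Toxicological constants for one analyte.

    Parameters
    ----------
    analyte
        Which DBP this spec describes.
    lod_ug_l
        Analytical limit of detection, µg/L.
    sf
        Carcinogenic slope factor, (mg/kg·day)^-1 (0 for non-carcinogens).
    rfd
        Oral reference dose, mg/kg·day.
    """

    analyte: Analyte
    lod_ug_l: float
    sf: float
    rfd: float

    def __post_init__(self) -> None:
        if self.lod_ug_l <= 0:
            raise ValidationError(f"{self.analyte}: LOD must be positive")
        if self.sf < 0:
            raise ValidationError(f"{self.analyte}: slope factor must be >= 0")
        if self.rfd <= 0:
            raise ValidationError(f"{self.analyte}: reference dose must be positive")

    @property
    def lod_mg_l(self) -> float:
        return self.lod_ug_l / UG_PER_MG

    @property
    def half_lod_mg_l(self) -> float:
        """The LOD/2 substitution value on the internal mg/L scale."""
        return self.lod_mg_l / 2.0


def builtin_registry() -> dict[Analyte, AnalyteSpec]:
    """Toxicology registry for the six DBPs (IRIS/RAIS oral values).

    LOD in µg/L, SF in (mg/kg·day)^-1, RfD in mg/kg·day.
    """
    specs = [
        AnalyteSpec(Analyte.TCM, 0.032, 0.031, 0.010),
        AnalyteSpec(Analyte.DBCM, 0.015, 0.084, 0.020),
        AnalyteSpec(Analyte.BDCM, 0.016, 0.062, 0.020),
        AnalyteSpec(Analyte.TBM, 0.041, 0.0079, 0.020),
        AnalyteSpec(Analyte.DCAA, 2.000, 0.050, 0.004),
        AnalyteSpec(Analyte.TCAA, 1.000, 0.070, 0.020),
    ]
    return {s.analyte: s for s in specs}


@dataclass(frozen=True)
class ConcentrationValue:
    """A single (possibly left-censored) concentration in mg/L.

    ``censored=True`` marks a non-detect; its ``value`` is absent until
    :func:`impute_censored` fills in LOD/2.  Detected values must be present
    and non-negative.
    """

    value: float | None
    censored: bool

    def __post_init__(self) -> None:
        if not self.censored:
            if self.value is None:
                raise ValidationError("detected concentration must carry a value")
            if self.value < 0 or not math.isfinite(self.value):
                raise ValidationError(f"concentration must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class WaterSample:
    """One monitoring sample with stratum labels, six DBP concentrations and
    water-quality parameters (pH, permanganate index, free chlorine)."""

    sample_id: str
    waterworks_id: str
    season: Season
    stage: Stage
    source: Source
    disinfectant: Disinfectant
    conc: Mapping[Analyte, ConcentrationValue]
    ph: float
    pi: float  # permanganate index, mg/L as O2
    fc: float  # free chlorine, mg/L

    def __post_init__(self) -> None:
        missing = [a for a in Analyte if a not in self.conc]
        if missing:
            raise ValidationError(f"sample {self.sample_id}: missing analytes {missing}")
        if not 0.0 <= self.ph <= 14.0:
            raise ValidationError(f"sample {self.sample_id}: pH {self.ph} outside [0, 14]")
        if self.pi < 0:
            raise ValidationError(f"sample {self.sample_id}: permanganate index < 0")
        if self.fc < 0:
            raise ValidationError(f"sample {self.sample_id}: free chlorine < 0")


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one analyte within one stratum.

    ``detection_rate`` uses the pre-imputation censoring flags; ``median``
    and ``qr`` (interquartile range, Q3 - Q1) are computed on imputed values.
    """

    analyte: Analyte
    labels: Mapping[str, str]
    n: int
    n_detected: int
    detection_rate: float
    minimum: float
    maximum: float
    median: float
    qr: float


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

STRATUM_COLUMNS = ("season", "stage", "source", "disinfectant")
WQP_COLUMNS = ("ph", "pi", "fc")

_ENUM_FOR_COLUMN = {
    "season": Season,
    "stage": Stage,
    "source": Source,
    "disinfectant": Disinfectant,
}


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and conventions for the flat sample table.

    ``nd_token`` is the sentinel for a censored (below-LOD) concentration.
    ``unit`` applies to the six concentration columns; internal storage is
    always mg/L.
    """

    nd_token: str = "ND"
    unit: str = "mg_per_L"  # or "ug_per_L"
    columns: Mapping[str, str] = field(default_factory=dict)  # logical -> file column

    def column(self, logical: str) -> str:
        return dict(self.columns).get(logical, logical)

    @property
    def concentration_factor(self) -> float:
        """Multiplier taking file units to mg/L."""
        if self.unit == "mg_per_L":
            return 1.0
        if self.unit == "ug_per_L":
            return 1.0 / UG_PER_MG
        raise ValidationError(f"unknown concentration unit {self.unit!r}")


def _parse_enum(enum_cls: type[enum.Enum], raw: str, column: str, row: int):
    try:
        return enum_cls(str(raw).strip().lower())
    except ValueError:
        raise ValidationError(
            f"row {row}: unknown {column} label {raw!r}; "
            f"expected one of {[e.value for e in enum_cls]}"
        ) from None


def _parse_float(raw, column: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowParseError(row, f"cannot parse {column}={raw!r} as a number") from None


def read_samples(path, dialect: CsvDialect | None = None) -> list[WaterSample]:
    """Read a flat CSV of monitoring samples into :class:`WaterSample` records.

    ND sentinels in concentration columns become censored values with no
    magnitude; an optional companion column ``<code>_censored`` (true/false)
    may mark censoring explicitly instead.
    """
    dialect = dialect or CsvDialect()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    required = ["sample_id", "waterworks_id", *STRATUM_COLUMNS]
    required += [a.value for a in Analyte]
    required += list(WQP_COLUMNS)
    for logical in required:
        if dialect.column(logical) not in df.columns:
            raise SchemaError(f"{path}: missing required column {dialect.column(logical)!r}")

    factor = dialect.concentration_factor
    samples: list[WaterSample] = []
    for i, rec in enumerate(df.to_dict("records")):
        conc: dict[Analyte, ConcentrationValue] = {}
        for a in Analyte:
            raw = str(rec[dialect.column(a.value)]).strip()
            cens_col = dialect.column(f"{a.value}_censored")
            explicit = str(rec.get(cens_col, "")).strip().lower() in ("true", "1", "yes")
            if raw == dialect.nd_token or explicit:
                conc[a] = ConcentrationValue(value=None, censored=True)
            else:
                conc[a] = ConcentrationValue(
                    value=_parse_float(raw, a.value, i) * factor, censored=False
                )
        samples.append(
            WaterSample(
                sample_id=str(rec[dialect.column("sample_id")]),
                waterworks_id=str(rec[dialect.column("waterworks_id")]),
                season=_parse_enum(Season, rec[dialect.column("season")], "season", i),
                stage=_parse_enum(Stage, rec[dialect.column("stage")], "stage", i),
                source=_parse_enum(Source, rec[dialect.column("source")], "source", i),
                disinfectant=_parse_enum(
                    Disinfectant, rec[dialect.column("disinfectant")], "disinfectant", i
                ),
                conc=conc,
                ph=_parse_float(rec[dialect.column("ph")], "ph", i),
                pi=_parse_float(rec[dialect.column("pi")], "pi", i),
                fc=_parse_float(rec[dialect.column("fc")], "fc", i),
            )
        )
    return samples


def write_samples(samples: Sequence[WaterSample], path_or_buf, dialect: CsvDialect | None = None) -> None:
    """Write samples to the flat CSV dialect (mg/L, ND sentinel for censored
    values that have not been imputed, ``<code>_censored`` flag columns)."""
    dialect = dialect or CsvDialect()
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "waterworks_id": s.waterworks_id,
            "season": s.season.value,
            "stage": s.stage.value,
            "source": s.source.value,
            "disinfectant": s.disinfectant.value,
        }
        for a in Analyte:
            cv = s.conc[a]
            row[a.value] = dialect.nd_token if cv.value is None else f"{cv.value:.10g}"
            row[f"{a.value}_censored"] = str(cv.censored).lower()
        row["ph"] = f"{s.ph:.6g}"
        row["pi"] = f"{s.pi:.6g}"
        row["fc"] = f"{s.fc:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_censored(
    samples: Iterable[WaterSample],
    registry: Mapping[Analyte, AnalyteSpec],
    rule: str = "half_lod",
) -> list[WaterSample]:
    """Fill censored concentrations with LOD/2 (converted µg/L -> mg/L).

    Detected values pass through unchanged; censoring flags are preserved so
    detection rates stay computable.  The operation is idempotent.
    """
    if rule != "half_lod":
        raise ValidationError(f"unknown imputation rule {rule!r}")
    out = []
    for s in samples:
        conc = {}
        for a, cv in s.conc.items():
            if a not in registry:
                raise ValidationError(f"analyte {a!r} not in registry")
            if cv.censored:
                conc[a] = ConcentrationValue(value=registry[a].half_lod_mg_l, censored=True)
            else:
                conc[a] = cv
        out.append(replace(s, conc=conc))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def samples_to_frame(samples: Sequence[WaterSample]) -> pd.DataFrame:
    """Tidy one-row-per-sample frame: stratum labels, per-analyte value and
    censored flag columns, WQPs.  Censored values that have not been imputed
    appear as NaN."""
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "waterworks_id": s.waterworks_id,
            "season": s.season.value,
            "stage": s.stage.value,
            "source": s.source.value,
            "disinfectant": s.disinfectant.value,
            "ph": s.ph,
            "pi": s.pi,
            "fc": s.fc,
        }
        for a in Analyte:
            cv = s.conc[a]
            row[a.value] = np.nan if cv.value is None else cv.value
            row[f"{a.value}_censored"] = cv.censored
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_from_frame(sub: pd.DataFrame, analyte: Analyte, labels: Mapping[str, str]) -> SummaryRow:
    values = sub[analyte.value].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(
            f"{analyte.value}: censored values present without imputation; run impute_censored first"
        )
    detected = ~sub[f"{analyte.value}_censored"].to_numpy(dtype=bool)
    n = len(values)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return SummaryRow(
        analyte=analyte,
        labels=dict(labels),
        n=n,
        n_detected=int(detected.sum()),
        detection_rate=float(detected.sum()) / n,
        minimum=float(values.min()),
        maximum=float(values.max()),
        median=float(np.median(values)),
        qr=float(q3 - q1),
    )


def summarize_concentrations(
    samples: Sequence[WaterSample],
    analyte: Analyte,
    strata: Sequence[str] | None = None,
) -> list[SummaryRow]:
    """Per-stratum descriptive statistics for one analyte.

    ``strata`` names sample-level label fields (``season``, ``stage``,
    ``source``, ``disinfectant``); ``None`` summarizes the whole collection.
    Samples must be imputed first (so every value is present); detection
    rates use the preserved censoring flags.
    """
    if len(samples) == 0:
        raise EmptyStratumError("no samples to summarize")
    df = samples_to_frame(samples)
    if not strata:
        return [_summary_from_frame(df, analyte, {})]
    for name in strata:
        if name not in STRATUM_COLUMNS:
            raise ValidationError(f"unknown stratum field {name!r}; expected one of {STRATUM_COLUMNS}")
    rows = []
    for key, sub in df.groupby(list(strata), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            raise EmptyStratumError(f"empty stratum {dict(zip(strata, key))}")
        rows.append(_summary_from_frame(sub, analyte, dict(zip(strata, key))))
    return rows


def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Flatten SummaryRows to a DataFrame mirroring the monitoring-report
    layout (range, median, interquartile range, detections, detection rate)."""
    out = []
    for r in rows:
        rec = {"analyte": r.analyte.value.upper(), **r.labels}
        rec.update(
            n=r.n,
            n_detected=r.n_detected,
            detection_rate_pct=round(100.0 * r.detection_rate, 2),
            min_mg_l=r.minimum,
            max_mg_l=r.maximum,
            median_mg_l=r.median,
            qr_mg_l=r.qr,
        )
        out.append(rec)
    return pd.DataFrame(out)
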