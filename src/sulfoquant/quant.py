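"""Internal-standard calibration, quantification and method validation.

The response of an analyte is its quantifier peak area divided by the
internal-standard area from the same injection; the ISD (a cerebroside
spiked at a constant 5 μg/mL) absorbs run-to-run drifts in ionization and
fragmentation efficiency.  Responses are regressed on nominal concentration
(ordinary or 1/x-weighted least squares); concentrations in unknowns are
back-calculated by inverting the line, converted to content per dry weight
through extract volume, dilution factor and sample mass, and expressed as
composition shares of the summed sulfolipid content.

Because only one SQDG standard is commercially available, all other species
are quantified against that single curve (surrogate calibration) — reported
concentrations for them are therefore relative to the standard's response
factor.

LOD/LOQ follow the ICH calibration-curve convention: 3.3·s/slope and
10·s/slope with s the residual standard deviation of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SingularFitError(ValueError):
    """Calibration design carries no usable slope information."""


def cv_percent(values: Iterable[float]) -> float:
    """Coefficient of variation in percent (sample SD, n−1 denominator)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


@dataclass(frozen=True)
class CalibrationLevel:
    nominal_concentration_ug_per_mL: float
    analyte_area: float
    isd_area: float

    def __post_init__(self) -> None:
        if self.isd_area <= 0:
            raise ValueError("ISD area must be positive")
        if self.analyte_area < 0:
            raise ValueError("analyte area must be non-negative")

    @property
    def response(self) -> float:
        return self.analyte_area / self.isd_area


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_levels: int
    lod_ug_per_mL: float
    loq_ug_per_mL: float
    weighting: str = "none"
    se_slope: float = float("nan")
    se_intercept: float = float("nan")

    def predict_response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def invert(self, response: float) -> float:
        """Back-calculated concentration; may be negative below the intercept."""
        return (response - self.intercept) / self.slope

    def summary(self) -> str:
        lines = [
            "Calibration curve (response = analyte area / ISD area)",
            f"  levels        : {self.n_levels}",
            f"  weighting     : {self.weighting}",
            f"  slope         : {self.slope:.4f} ± {self.se_slope:.4f} (SE)",
            f"  intercept     : {self.intercept:.4f} ± {self.se_intercept:.4f} (SE)",
            f"  R²            : {self.r_squared:.4f}",
            f"  residual SD   : {self.residual_sd:.4g}",
            f"  LOD (3.3·s/m) : {self.lod_ug_per_mL:.3g} µg/mL",
            f"  LOQ (10·s/m)  : {self.loq_ug_per_mL:.3g} µg/mL",
        ]
        return "\n".join(lines)


def fit_calibration(
    levels: Sequence[CalibrationLevel],
    weighting: str = "none",
) -> CalibrationCurve:
    """Least-squares fit of ISD-normalized response on nominal concentration.

    ``weighting`` is ``"none"`` (OLS) or ``"1/x"`` (WLS with weights equal to
    the reciprocal concentration, for strongly heteroscedastic data).
    Degenerate designs — all levels at one concentration, or a completely
    flat response — raise :class:`SingularFitError`.
    """
    if len(levels) < 3:
        raise ValueError("calibration requires at least 3 levels")
    conc = np.array([lv.nominal_concentration_ug_per_mL for lv in levels], dtype=float)
    resp = np.array([lv.response for lv in levels], dtype=float)
    if np.ptp(conc) == 0:
        raise SingularFitError("all calibration levels at the same concentration")
    if np.ptp(resp) == 0:
        raise SingularFitError("constant response carries no slope information")
    if weighting not in ("none", "1/x"):
        raise ValueError("weighting must be 'none' or '1/x'")

    X = sm.add_constant(conc)
    if weighting == "1/x":
        if np.any(conc <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        model = sm.WLS(resp, X, weights=1.0 / conc)
    else:
        model = sm.OLS(resp, X)
    res = model.fit()
    intercept, slope = res.params
    fitted = intercept + slope * conc
    dof = len(levels) - 2
    residual_sd = float(np.sqrt(np.sum((resp - fitted) ** 2) / dof)) if dof else 0.0
    lod, loq = lod_loq(residual_sd=residual_sd, slope=slope)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        residual_sd=residual_sd,
        n_levels=len(levels),
        lod_ug_per_mL=lod,
        loq_ug_per_mL=loq,
        weighting=weighting,
        se_slope=float(res.bse[1]),
        se_intercept=float(res.bse[0]),
    )


def lod_loq(
    curve: CalibrationCurve | None = None,
    *,
    residual_sd: float | None = None,
    slope: float | None = None,
) -> tuple[float, float]:
    """ICH calibration-curve limits: LOD = 3.3·s/slope, LOQ = 10·s/slope."""
    if curve is not None:
        residual_sd, slope = curve.residual_sd, curve.slope
    if residual_sd is None or slope is None:
        raise ValueError("need a curve or residual_sd and slope")
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if residual_sd < 0:
        raise ValueError("residual SD must be non-negative")
    return 3.3 * residual_sd / slope, 10.0 * residual_sd / slope


@dataclass(frozen=True)
class RecoveryInput:
    c_sample: float
    c_endogen: float
    c_spiked: float

    def __post_init__(self) -> None:
        if self.c_spiked <= 0:
            raise ValueError("spiked concentration must be positive")


def recovery(inp: RecoveryInput | float, c_endogen: float | None = None,
             c_spiked: float | None = None) -> float:
    """Spike recovery RE = (c_sample − c_endogen) · 100 / c_spiked, percent."""
    if not isinstance(inp, RecoveryInput):
        inp = RecoveryInput(float(inp), float(c_endogen), float(c_spiked))
    return (inp.c_sample - inp.c_endogen) * 100.0 / inp.c_spiked


# ---------------------------------------------------------------------------
# quantification

QUANT_COLUMNS = (
    "analyte", "area", "response", "conc_ug_mL", "content_mg_g", "share_pct", "flag",
)


@dataclass(frozen=True)
class QuantReport:
    table: pd.DataFrame
    total_content_mg_g: float
    dilution_factor: float
    extract_volume_mL: float
    sample_mass_g: float
    lod_ug_per_mL: float
    loq_ug_per_mL: float
    calibration_note: str = "surrogate calibration against the single SQDG standard"

    def summary(self) -> str:
        lines = [
            f"Quantification report ({self.calibration_note})",
            f"  extract {self.extract_volume_mL} mL, dilution x{self.dilution_factor}, "
            f"sample {self.sample_mass_g} g dry weight",
            f"  total sulfolipid content: {self.total_content_mg_g:.4g} mg/g",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "total_content_mg_g": self.total_content_mg_g,
            "dilution_factor": self.dilution_factor,
            "extract_volume_mL": self.extract_volume_mL,
            "sample_mass_g": self.sample_mass_g,
            "lod_ug_per_mL": self.lod_ug_per_mL,
            "loq_ug_per_mL": self.loq_ug_per_mL,
            "calibration_note": self.calibration_note,
            "analytes": self.table.to_dict(orient="records"),
        }


def quantify(
    areas: Mapping[str, float],
    curve: CalibrationCurve,
    isd_area: float,
    dilution_factor: float = 1.0,
    extract_volume_mL: float = 1.0,
    sample_mass_g: float = 1.0,
) -> QuantReport:
    """Back-calculate concentrations and dry-weight contents for one sample.

    ``areas`` maps analyte → quantifier peak area.  Responses below the
    calibration intercept are floored at zero concentration and flagged
    ``<LOD``.  Content per dry weight:
    concentration · extract volume · dilution / sample mass.  Composition
    shares are computed over analytes at or above the LOQ and sum to 100%.
    """
    if isd_area <= 0:
        raise ValueError("ISD area must be positive")
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    if dilution_factor <= 0 or extract_volume_mL <= 0:
        raise ValueError("dilution factor and extract volume must be positive")

    rows = []
    for analyte, area in areas.items():
        response = area / isd_area
        conc = curve.invert(response)
        flag = ""
        if conc < 0:
            conc, flag = 0.0, "<LOD"
        elif conc < curve.lod_ug_per_mL:
            flag = "<LOD"
        elif conc < curve.loq_ug_per_mL:
            flag = "<LOQ"
        content_mg_g = conc * extract_volume_mL * dilution_factor / sample_mass_g / 1000.0
        rows.append(dict(analyte=analyte, area=area, response=response,
                         conc_ug_mL=conc, content_mg_g=content_mg_g,
                         share_pct=np.nan, flag=flag))
    table = pd.DataFrame(rows, columns=QUANT_COLUMNS)

    quantifiable = table["flag"] == ""
    contents = dict(zip(table.loc[quantifiable, "analyte"],
                        table.loc[quantifiable, "content_mg_g"]))
    if contents and sum(contents.values()) > 0:
        shares = composition_shares(contents)
        table.loc[quantifiable, "share_pct"] = [
            shares[a] for a in table.loc[quantifiable, "analyte"]
        ]
    total = float(table.loc[quantifiable, "content_mg_g"].sum())
    return QuantReport(
        table=table,
        total_content_mg_g=total,
        dilution_factor=dilution_factor,
        extract_volume_mL=extract_volume_mL,
        sample_mass_g=sample_mass_g,
        lod_ug_per_mL=curve.lod_ug_per_mL,
        loq_ug_per_mL=curve.loq_ug_per_mL,
    )


def composition_shares(contents: Mapping[str, float]) -> dict[str, float]:
    """Each analyte's content as percent of the summed content (sums to 100)."""
    values = np.array(list(contents.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("contents must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("total content must be positive")
    return {k: float(v) / total * 100.0 for k, v in contents.items()}


# ---------------------------------------------------------------------------
# method validation

@dataclass(frozen=True)
class ValidationReport:
    qc_table: pd.DataFrame  # level, intra_day_cv, inter_day_cv, accuracy_pct, passes
    linearity_r2: tuple[float, ...]
    recoveries_pct: tuple[float, ...]
    cv_threshold: float
    n_days: int

    @property
    def passes(self) -> bool:
        return bool(self.qc_table["passes"].all())

    def summary(self) -> str:
        r2 = ", ".join(f"{v:.4f}" for v in self.linearity_r2)
        rec = ", ".join(f"{v:.1f}%" for v in self.recoveries_pct) or "n/a"
        verdict = "PASS" if self.passes else "FAIL"
        return "\n".join([
            f"Method validation ({self.n_days} day(s); CV threshold {self.cv_threshold}%)",
            f"  linearity R² per day : {r2}",
            f"  recoveries           : {rec}",
            "",
            self.qc_table.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            "",
            f"  overall precision    : {verdict}",
        ])


def validate_method(
    calibration_runs: Sequence[Sequence[CalibrationLevel]],
    qc_runs: pd.DataFrame | Iterable[Mapping],
    recovery_inputs: Sequence[RecoveryInput] = (),
    cv_threshold: float = 15.0,
    weighting: str = "none",
) -> ValidationReport:
    """FDA-style precision/accuracy assessment from replicate QC runs.

    ``calibration_runs`` holds one calibration series per day (used for the
    per-day linearity R² and for back-calculating that day's QC responses;
    days beyond the available curves fall back to the first day's curve).
    ``qc_runs`` needs columns ``nominal``, ``day``, ``replicate``,
    ``response``.  Per QC level: intra-day CV (mean of within-day CVs of the
    back-calculated concentrations), inter-day CV (pooled across days, only
    when ≥ 2 days), accuracy (mean back-calculated / nominal × 100), and the
    pass flag at the CV threshold (default 15%).
    """
    if not calibration_runs:
        raise ValueError("at least one calibration run is required")
    curves = [fit_calibration(run, weighting) for run in calibration_runs]
    qc = pd.DataFrame(qc_runs)
    required = {"nominal", "day", "response"}
    if missing := required - set(qc.columns):
        raise ValueError(f"QC runs missing columns: {sorted(missing)}")

    days = sorted(qc["day"].unique())
    day_curve = {day: curves[i] if i < len(curves) else curves[0]
                 for i, day in enumerate(days)}
    qc = qc.assign(conc=[
        day_curve[row.day].invert(row.response) for row in qc.itertuples()
    ])

    rows = []
    for nominal, level_grp in qc.groupby("nominal"):
        within_cvs = []
        for _, day_grp in level_grp.groupby("day"):
            if len(day_grp) < 2:
                raise ValueError(
                    f"QC level {nominal}: intra-day CV needs >= 2 replicates per day"
                )
            within_cvs.append(cv_percent(day_grp["conc"]))
        intra = float(np.mean(within_cvs))
        inter = cv_percent(level_grp["conc"]) if level_grp["day"].nunique() >= 2 else np.nan
        accuracy = float(level_grp["conc"].mean() / nominal * 100.0)
        passes = intra < cv_threshold and (np.isnan(inter) or inter < cv_threshold)
        rows.append(dict(level=nominal, intra_day_cv=intra, inter_day_cv=inter,
                         accuracy_pct=accuracy, passes=passes))

    return ValidationReport(
        qc_table=pd.DataFrame(rows).sort_values("level").reset_index(drop=True),
        linearity_r2=tuple(c.r_squared for c in curves),
        recoveries_pct=tuple(recovery(r) for r in recovery_inputs),
        cv_threshold=cv_threshold,
        n_days=len(days),
    )


# ---------------------------------------------------------------------------
# sample sheets

SAMPLE_SHEET_COLUMNS = (
    "sample_id", "type", "nominal_conc_ug_mL", "day", "replicate",
    "dilution_factor", "extract_volume_mL", "sample_mass_g",
)
SAMPLE_TYPES = ("calibrant", "qc", "blank", "sample")


def read_sample_sheet(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read and validate a sample sheet CSV (see :data:`SAMPLE_SHEET_COLUMNS`)."""
    sheet = pd.read_csv(source)
    if missing := set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["type"]) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"unknown sample types {sorted(bad)}; allowed: {SAMPLE_TYPES}")
    return sheet
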