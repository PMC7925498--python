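"""Seeded synthetic MRM data with known ground truth.

The generator emulates the acquisition this toolkit processes: one SRM
chromatogram per panel transition over a 52-minute run (the LC program:
2 min initial hold, 4 min ramp, 34 min at the final eluent, re-equilibration),
with a Gaussian peak at the panel retention time.  The quantifier peak area
is ``response_factor × concentration``; qualifier areas are fixed fractions
of the quantifier (0.4 and 0.2 by default — MRM qualifier ratios are
instrument-tuned constants, not modelled here).  Area noise is multiplicative
lognormal (CV-parameterized, the typical LC-MS heteroscedasticity);
baseline noise is additive Gaussian clipped at zero counts.

Default response factors are anchored so that the default calibration series
(10 equidistant levels, 1–10 μg/mL, ISD constant at 5 μg/mL) fits a slope of
0.330 — the reference method's mean calibration slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Trace, srm_channel_id
from .quant import CalibrationLevel
from .transitions import Role, TransitionPanel

#: default peak area per (µg/mL) for the internal standard channel
ISD_AREA_FACTOR = 1.0e5
#: analyte/ISD response-factor ratio chosen so that, with the ISD at
#: 5 µg/mL, the calibration slope is 1.65e5/(1e5·5) = 0.330
ANALYTE_AREA_FACTOR = 1.65e5
ISD_CONCENTRATION_UG_ML = 5.0
DEFAULT_RUN_LENGTH_MIN = 52.0

_ROLE_ORDER = (Role.QUANTIFIER, Role.QUALIFIER1, Role.QUALIFIER2)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the requested CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic MRM run."""

    panel: TransitionPanel
    true_concentrations_ug_mL: Mapping[str, float]
    response_factors: Mapping[str, float] = field(default_factory=dict)
    peak_sigma_min: float = 0.15
    rt_jitter_sd_min: float = 0.0
    area_noise_cv: float = 0.0
    baseline_noise_sd_counts: float = 0.0
    sampling_interval_min: float = 0.01
    run_length_min: float = DEFAULT_RUN_LENGTH_MIN
    qualifier_fractions: tuple[float, float] = (0.4, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_sigma_min <= 0 or self.sampling_interval_min <= 0:
            raise ValueError("peak sigma and sampling interval must be positive")
        if min(self.rt_jitter_sd_min, self.area_noise_cv,
               self.baseline_noise_sd_counts) < 0:
            raise ValueError("noise parameters must be non-negative")
        rts = [an.rt_min for an in self.panel if an.rt_min is not None]
        if rts and max(rts) >= self.run_length_min:
            raise ValueError(
                f"run length {self.run_length_min} min does not cover panel "
                f"retention times (max {max(rts)} min)"
            )

    def response_factor(self, analyte: str) -> float:
        if analyte in self.response_factors:
            return self.response_factors[analyte]
        return (ISD_AREA_FACTOR if self.panel[analyte].lipid_class == "ISD"
                else ANALYTE_AREA_FACTOR)


def default_concentrations(
    panel: TransitionPanel, analyte_conc_ug_mL: float = 5.0
) -> dict[str, float]:
    """All sulfolipids at one level, the ISD at its constant 5 µg/mL."""
    return {an.name: (ISD_CONCENTRATION_UG_ML if an.lipid_class == "ISD"
                      else analyte_conc_ug_mL)
            for an in panel}


def simulate_run(config: SimulationConfig) -> tuple[list[Trace], dict]:
    """Generate one run: a list of traces plus the ground truth.

    Analytes without a panel retention time are skipped with a warning entry
    in the ground truth (``skipped``).  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    time = np.arange(0.0, config.run_length_min + config.sampling_interval_min / 2,
                     config.sampling_interval_min)
    traces: list[Trace] = []
    truth: dict = {"seed": config.seed, "analytes": {}, "skipped": []}
    fractions = (1.0,) + tuple(config.qualifier_fractions)

    for an in config.panel:
        conc = float(config.true_concentrations_ug_mL.get(an.name, 0.0))
        if an.rt_min is None:
            truth["skipped"].append(an.name)
            continue
        rt = an.rt_min + (rng.normal(0.0, config.rt_jitter_sd_min)
                          if config.rt_jitter_sd_min > 0 else 0.0)
        rf = config.response_factor(an.name)
        entry = {"concentration_ug_mL": conc, "rt_min": rt, "areas": {}}
        by_role = {t.role: t for t in an.transitions}
        for role, fraction in zip(_ROLE_ORDER, fractions):
            t = by_role[role]
            area = rf * conc * fraction * float(_lognormal_factor(rng, config.area_noise_cv))
            sigma = config.peak_sigma_min
            y = (area / (sigma * math.sqrt(2 * math.pi))
                 * np.exp(-0.5 * ((time - rt) / sigma) ** 2)) if area > 0 else np.zeros_like(time)
            if config.baseline_noise_sd_counts > 0:
                y = y + rng.normal(0.0, config.baseline_noise_sd_counts, size=time.size)
            traces.append(Trace(
                channel_id=srm_channel_id(t.precursor_mz, t.product_mz),
                time_min=time,
                intensity=np.clip(y, 0.0, None),
            ))
            entry["areas"][role.value] = area
        truth["analytes"][an.name] = entry
    return traces, truth


def simulate_calibration(
    n_levels: int = 10,
    c_min: float = 1.0,
    c_max: float = 10.0,
    isd_conc_ug_mL: float = ISD_CONCENTRATION_UG_ML,
    response_factor: float = ANALYTE_AREA_FACTOR / (ISD_AREA_FACTOR * ISD_CONCENTRATION_UG_ML),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[list[CalibrationLevel], dict]:
    """Equidistant calibration series with the ISD held constant.

    Responses are ``response_factor · c · (1 + ε)`` with ε ~ Normal(0,
    noise_cv); ISD areas are constant up to the same relative noise.  The
    defaults reproduce the reference design: 10 points, 1–10 µg/mL, ISD at
    5 µg/mL, slope 0.330.
    """
    if n_levels < 3:
        raise ValueError("calibration needs at least 3 levels")
    if c_min >= c_max:
        raise ValueError("c_min must be below c_max")
    rng = np.random.default_rng(seed)
    concentrations = np.linspace(c_min, c_max, n_levels)
    levels = []
    for c in concentrations:
        isd_area = ISD_AREA_FACTOR * isd_conc_ug_mL * (1.0 + rng.normal(0, noise_cv) if noise_cv > 0 else 1.0)
        response = response_factor * c * (1.0 + (rng.normal(0, noise_cv) if noise_cv > 0 else 0.0))
        levels.append(CalibrationLevel(
            nominal_concentration_ug_per_mL=float(c),
            analyte_area=float(response * isd_area),
            isd_area=float(isd_area),
        ))
    truth = {"response_factor": response_factor, "noise_cv": noise_cv,
             "isd_conc_ug_mL": isd_conc_ug_mL, "seed": seed,
             "concentrations": concentrations.tolist()}
    return levels, truth


def simulate_validation_study(
    qc_levels_ug_mL: Sequence[float] = (2.0, 5.0, 8.0),
    replicates_per_day: int = 5,
    n_days: int = 3,
    noise_cv: float = 0.05,
    day_effect_cv: float = 0.0,
    response_factor: float = ANALYTE_AREA_FACTOR / (ISD_AREA_FACTOR * ISD_CONCENTRATION_UG_ML),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Replicate QC injections across days with known ground truth.

    Within-day noise is multiplicative (1 + ε), ε ~ Normal(0, noise_cv); a
    per-day multiplicative effect with CV ``day_effect_cv`` separates
    inter-day from intra-day variability.  Returns a long-format frame with
    columns ``nominal, day, replicate, response`` plus the truth record.
    """
    if replicates_per_day < 2:
        raise ValueError("need at least 2 replicates per day")
    if n_days < 1:
        raise ValueError("need at least 1 day")
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, n_days + 1):
        day_factor = 1.0 + (rng.normal(0, day_effect_cv) if day_effect_cv > 0 else 0.0)
        for nominal in qc_levels_ug_mL:
            for rep in range(1, replicates_per_day + 1):
                eps = rng.normal(0, noise_cv) if noise_cv > 0 else 0.0
                rows.append(dict(
                    nominal=float(nominal), day=day, replicate=rep,
                    response=response_factor * nominal * day_factor * (1.0 + eps),
                ))
    truth = {"response_factor": response_factor, "noise_cv": noise_cv,
             "day_effect_cv": day_effect_cv, "seed": seed,
             "qc_levels_ug_mL": list(map(float, qc_levels_ug_mL))}
    return pd.DataFrame(rows), truth
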