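"""Synthetic mother-infant lactation PK studies.

Emulates the paired plasma/breast-milk/infant sampling design of the
observational lamivudine cohort: 35 mothers (10 on 150 mg q12h, 25 on
300 mg q24h), two postpartum visits, morning-dosing mothers sampled
richly over 0-8 h (plasma 0, 1, 2, 4, 8 h; milk 0, 2, 4, 8 h) and
evening-dosing mothers sampled at 12, 16, 20 h after their self-reported
dose, infant spot samples, assay LLOQ censoring (5 ng/mL plasma,
16.6 ng/mL milk) and ~7% random sample loss.  All q12h mothers dose in
the morning; evening mothers are necessarily on the q24h regimen (their
sampling times exceed a 12-h interval).

Covariates are drawn to match the published cohort summaries: each is a
Beta(2,2) variate pushed through a piecewise-linear quantile map onto
[lo, median] / [median, hi], which reproduces the printed median and
range exactly (the printed medians are not range midpoints, so a plain
scaled Beta would not).  This is a documented stand-in for the unknown
joint covariate distribution.

Infant concentrations are simulated as a constant individual steady
state (the forward infant-exposure model) with 30% proportional noise,
reflecting the near-flat observed infant profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infant_exposure as ie
from .pk_model import (
    MGL_TO_NGML,
    DataError,
    DoseRegimen,
    PopulationModel,
    conc_mgl,
    individual_params,
)

#: (low, median, high) summaries the covariate sampler reproduces
COVARIATE_RANGES = {
    "WT": (50.0, 64.0, 89.0),        # maternal weight, kg
    "AGE": (19.0, 30.0, 40.0),       # maternal age, years
    "BMI": (20.0, 24.8, 30.5),       # kg/m^2
    "CRCL": (89.2, 134.6, 184.7),    # creatinine clearance, mL/min
    "VDAY1": (7.0, 13.0, 43.0),      # visit 1, days postpartum
    "VDAY2": (36.0, 73.5, 84.0),     # visit 2, days postpartum
    "IWT1": (2.40, 3.60, 5.58),      # infant weight at visit 1, kg
    "IWT2": (3.90, 5.17, 7.13),      # infant weight at visit 2, kg
}

LLOQ_PLASMA_NGML = 5.0
LLOQ_MILK_NGML = 16.6

#: columns of the canonical long-format observation table
TABLE_COLUMNS = [
    "ID", "ARM", "GROUP", "VISIT", "MATRIX", "TIME", "DV", "BLQ", "MDV",
    "DOSE", "TAU", "LLOQ", "WT", "AGE", "BMI", "CRCL", "VDAY", "IWT",
]


@dataclass(frozen=True)
class StudyDesign:
    """Arms, visit windows, sampling schedules and censoring limits."""

    n_q12: int = 10
    n_q24: int = 25
    n_morning: int = 14          # includes all q12h mothers
    dose_q12: float = 150.0
    dose_q24: float = 300.0
    plasma_times_morning: tuple = (0.0, 1.0, 2.0, 4.0, 8.0)
    milk_times_morning: tuple = (0.0, 2.0, 4.0, 8.0)
    times_evening: tuple = (12.0, 16.0, 20.0)   # both matrices
    infant_times_morning: tuple = (0.0, 4.0, 8.0)
    infant_times_evening: tuple = (12.0, 20.0)
    lloq_plasma: float = LLOQ_PLASMA_NGML
    lloq_milk: float = LLOQ_MILK_NGML
    missingness: float = 0.07    # per scheduled sample
    infant_sigma: float = 0.30   # proportional noise on infant levels
    dose_time_jitter_h: float = 0.0  # optional +/- jitter on evening dose times

    def __post_init__(self) -> None:
        if self.n_q12 < 0 or self.n_q24 < 0 or self.n_q12 + self.n_q24 < 1:
            raise DataError("need at least one mother")
        if not (self.n_q12 <= self.n_morning <= self.n_q12 + self.n_q24):
            raise DataError(
                "n_morning must cover all q12h mothers and not exceed the cohort"
            )
        if self.lloq_plasma <= 0 or self.lloq_milk <= 0:
            raise DataError("LLOQs must be > 0")
        if not 0 <= self.missingness < 1:
            raise DataError("missingness must be in [0, 1)")
        for t in self.times_evening:
            if t >= 24.0:
                raise DataError("evening sampling times must lie within 24 h")

    @property
    def n_mothers(self) -> int:
        return self.n_q12 + self.n_q24

    def regimen(self, arm: str) -> DoseRegimen:
        if arm == "q12":
            return DoseRegimen(self.dose_q12, 12.0)
        if arm == "q24":
            return DoseRegimen(self.dose_q24, 24.0)
        raise DataError(f"unknown arm {arm!r}")


def _beta_quantile_map(u: np.ndarray, lo: float, med: float, hi: float) -> np.ndarray:
    """Map Beta(2,2) draws onto [lo, hi] with the stated median."""
    lower = u <= 0.5
    return np.where(lower, lo + (med - lo) * 2 * u, med + (hi - med) * (2 * u - 1))


def generate_covariates(design: StudyDesign, seed) -> pd.DataFrame:
    """Per-mother covariates matching the published cohort summaries.

    Returns one row per mother with ID, ARM, GROUP and all covariates;
    infant weight and visit day are per-visit columns.  Reproducible
    under `seed` (an int or a numpy Generator).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = design.n_mothers
    out = {"ID": np.arange(1, n + 1)}
    for name, (lo, med, hi) in COVARIATE_RANGES.items():
        out[name] = _beta_quantile_map(rng.beta(2.0, 2.0, size=n), lo, med, hi)
    df = pd.DataFrame(out)
    # monotonicity across visits: second visit is later, infant has grown
    df["VDAY2"] = np.maximum(df["VDAY2"], df["VDAY1"] + 1.0)
    df["IWT2"] = np.maximum(df["IWT2"], df["IWT1"])
    # q12h mothers all dose in the morning; remaining morning slots are q24h
    arm = np.array(["q12"] * design.n_q12 + ["q24"] * design.n_q24)
    n_morning_q24 = design.n_morning - design.n_q12
    group = np.array(
        ["morning"] * design.n_q12
        + ["morning"] * n_morning_q24
        + ["evening"] * (design.n_q24 - n_morning_q24)
    )
    df["ARM"] = arm
    df["GROUP"] = group
    return df


def simulate_study(design: StudyDesign, model: PopulationModel, seed) -> pd.DataFrame:
    """Simulate a full study as a long-format observation table.

    Per mother: draw log-scale random effects from the model's IIV
    covariance, evaluate the steady-state plasma/milk closed forms at
    her group's schedule for both visits, apply proportional residual
    error, censor below the matrix LLOQ, and drop scheduled samples at
    the design missingness rate.  Infant records are a constant
    individual steady state plus proportional noise.  Byte-identical
    output under the same seed.
    """
    rng = np.random.default_rng(seed)
    cov = generate_covariates(design, rng)
    etas = model.draw_etas(design.n_mothers, rng)

    rows = []
    for i, sub in cov.iterrows():
        params = individual_params(model.theta, etas[i])
        regimen = design.regimen(sub["ARM"])
        if sub["GROUP"] == "morning":
            sched = [("plasma", design.plasma_times_morning),
                     ("milk", design.milk_times_morning),
                     ("infant", design.infant_times_morning)]
        else:
            sched = [("plasma", design.times_evening),
                     ("milk", design.times_evening),
                     ("infant", design.infant_times_evening)]
        # individual infant steady state (ng/mL) via the forward exposure chain
        conc_ave = ie.avg_plasma_conc(params, regimen)
        dose_ugkg = ie.infant_daily_dose(ie.avg_milk_conc(conc_ave, params.rcb))
        for visit in (1, 2):
            vday, iwt = sub[f"VDAY{visit}"], sub[f"IWT{visit}"]
            jit = (
                rng.uniform(-design.dose_time_jitter_h, design.dose_time_jitter_h)
                if design.dose_time_jitter_h > 0 and sub["GROUP"] == "evening"
                else 0.0
            )
            cl_inf = ie.infant_clearance(iwt, vday / 365.25)
            css_inf = ie.infant_css(dose_ugkg * iwt, cl_inf)
            for matrix, times in sched:
                for t in times:
                    if matrix == "infant":
                        pred = css_inf
                        sig = design.infant_sigma
                        tt = t
                    else:
                        tt = min(max(t + jit, 0.0), regimen.tau - 1e-9)
                        pred = MGL_TO_NGML * conc_mgl(
                            tt, regimen.dose, regimen.tau,
                            params.ka, params.cl, params.vc,
                            params.kcb, params.rcb, matrix == "milk",
                        )
                        sig = (
                            model.sigma_plasma if matrix == "plasma"
                            else model.sigma_milk
                        )
                    dv = float(pred) * (1.0 + sig * rng.standard_normal())
                    dv = max(dv, 0.0)
                    rows.append({
                        "ID": int(sub["ID"]), "ARM": sub["ARM"],
                        "GROUP": sub["GROUP"], "VISIT": visit,
                        "MATRIX": matrix, "TIME": float(t), "DV": dv,
                        "BLQ": 0, "MDV": 0,
                        "DOSE": regimen.dose, "TAU": regimen.tau,
                        "LLOQ": np.nan,
                        "WT": sub["WT"], "AGE": sub["AGE"],
                        "BMI": sub["BMI"], "CRCL": sub["CRCL"],
                        "VDAY": vday, "IWT": iwt,
                    })
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table = censor_blq(table, design.lloq_plasma, design.lloq_milk)
    if design.missingness > 0:
        keep = rng.random(len(table)) >= design.missingness
        table = table[keep].reset_index(drop=True)
    return table


def censor_blq(table: pd.DataFrame, lloq_plasma: float, lloq_milk: float) -> pd.DataFrame:
    """Flag records strictly below their matrix LLOQ as BLQ (and MDV).

    A record exactly at the LLOQ is quantifiable and is *not* flagged.
    Infant records use the plasma assay LLOQ.  The measured value is
    retained in DV; likelihood handling of BLQ rows is the estimation
    layer's concern, and summary statistics impute LLOQ/2 via
    :func:`blq_summary_values`.
    """
    if lloq_plasma < 0 or lloq_milk < 0:
        raise DataError("LLOQ must be >= 0")
    table = table.copy()
    lloq = np.where(table["MATRIX"] == "milk", lloq_milk, lloq_plasma)
    table["LLOQ"] = lloq
    blq = table["DV"].to_numpy() < lloq
    table["BLQ"] = blq.astype(int)
    table.loc[blq, "MDV"] = 1
    return table


def blq_summary_values(table: pd.DataFrame) -> pd.Series:
    """DV with BLQ records imputed at LLOQ/2 (for numeric summaries)."""
    return table["DV"].where(table["BLQ"] == 0, table["LLOQ"] / 2.0)
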