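"""Infant breast-milk exposure derived from the maternal model.

The chain is: average maternal plasma concentration over 24 h
(AUC0-24/24, which at steady state is daily dose / (CL * 24)), scaled by
the milk-to-plasma ratio Rcb to an average milk concentration,
multiplied by a standard milk intake of 0.15 L/kg/day to a weight-
normalised daily infant dose, and expressed (a) relative to the
weight-normalised maternal daily dose (RID%) and (b) relative to the
recommended therapeutic infant dose.  Infant steady-state concentration
follows from an allometry-plus-maturation apparent clearance:

    CL/F = 12.7 * (WT/7)^0.75 * Age^1.47 / (0.25^1.47 + Age^1.47)  [L/h]

with weight in kg and age in years, and Css = Dose / (CL * 24 h).

Cohort summaries are computed per mother-infant pair from empirical
Bayes parameter estimates and then summarised, never from typical
values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pk_model import (
    MGL_TO_NGML,
    DataError,
    DoseRegimen,
    ParameterError,
    StructuralParams,
)

VOL_MILK_L_PER_KG_DAY = 0.15
#: recommended therapeutic infant dose (4 mg/kg twice daily, age >= 4 weeks)
RECOMMENDED_INFANT_DOSE_MG_KG_DAY = 8.0
#: < 4-week recommendation (2 mg/kg twice daily), selectable reference
RECOMMENDED_NEONATAL_DOSE_MG_KG_DAY = 4.0

CL_INFANT_REF = 12.7    # L/h at the 7-kg reference weight, fully matured
WT_REF_KG = 7.0
ALLOMETRIC_EXP = 0.75
MATURATION_HILL = 1.47
MATURATION_TM50_YR = 0.25
DAYS_PER_YEAR = 365.25


def avg_plasma_conc(params: StructuralParams, regimen: DoseRegimen) -> float:
    """Average steady-state plasma concentration over 24 h (ng/mL).

    AUC0-24 at steady state equals (daily dose)/CL regardless of Ka and
    Vc, so ConcAve = daily dose / (CL * 24); the 24-h window spans two
    intervals for a q12h regimen.
    """
    if 24.0 % regimen.tau > 1e-9:
        raise DataError("dosing interval must divide the 24-h averaging window")
    auc24_mgl_h = regimen.daily_dose / params.cl
    return auc24_mgl_h / 24.0 * MGL_TO_NGML


def avg_milk_conc(conc_ave, rcb):
    """Average milk concentration (ng/mL): ConcMilk = Rcb * ConcAve."""
    conc_ave = np.asarray(conc_ave, dtype=float)
    if np.any(conc_ave < 0) or np.any(np.asarray(rcb) < 0):
        raise DataError("inputs must be >= 0")
    out = rcb * conc_ave
    return float(out) if np.ndim(out) == 0 else out


def infant_daily_dose(conc_milk_ngml, vol_milk=VOL_MILK_L_PER_KG_DAY):
    """Daily infant dose via milk, ug/kg/day.

    ConcMilk (ng/mL -> mg/L) times the per-kg daily milk intake, in ug.
    """
    conc_mgl = np.asarray(conc_milk_ngml, dtype=float) / MGL_TO_NGML
    dose_mg_kg_day = conc_mgl * vol_milk
    out = dose_mg_kg_day * 1000.0
    return float(out) if np.ndim(out) == 0 else out


def relative_infant_dose(dose_infant_ug_kg_day, maternal_dose_mg_day, maternal_wt_kg):
    """RID%: infant ug/kg/day as % of the maternal weight-normalised dose."""
    if np.any(np.asarray(maternal_wt_kg) <= 0):
        raise DataError("maternal weight must be > 0")
    maternal_mg_kg_day = np.asarray(maternal_dose_mg_day, dtype=float) / maternal_wt_kg
    out = 100.0 * (np.asarray(dose_infant_ug_kg_day, dtype=float) / 1000.0) / maternal_mg_kg_day
    return float(out) if np.ndim(out) == 0 else out


def infant_clearance(wt_kg, age_yr):
    """Infant apparent oral clearance (L/h) by allometry + maturation."""
    wt = np.asarray(wt_kg, dtype=float)
    age = np.asarray(age_yr, dtype=float)
    if np.any(wt <= 0) or np.any(age < 0):
        raise ParameterError("require WT > 0 and Age >= 0")
    mat = age**MATURATION_HILL / (MATURATION_TM50_YR**MATURATION_HILL + age**MATURATION_HILL)
    out = CL_INFANT_REF * (wt / WT_REF_KG) ** ALLOMETRIC_EXP * mat
    return float(out) if np.ndim(out) == 0 else out


def infant_css(dose_infant_ug_day, cl_infant_lh, tau_h: float = 24.0):
    """Infant steady-state concentration (ng/mL): Dose / (CL * tau)."""
    if np.any(np.asarray(cl_infant_lh) <= 0):
        raise ParameterError("infant clearance must be > 0")
    out = np.asarray(dose_infant_ug_day, dtype=float) / (np.asarray(cl_infant_lh) * tau_h)
    return float(out) if np.ndim(out) == 0 else out  # ug/L == ng/mL


def pct_recommended_dose(
    dose_infant_ug_kg_day, reference_mg_kg_day: float = RECOMMENDED_INFANT_DOSE_MG_KG_DAY
):
    """Infant milk dose as % of the recommended therapeutic infant dose."""
    out = 100.0 * np.asarray(dose_infant_ug_kg_day, dtype=float) / 1000.0 / reference_mg_kg_day
    return float(out) if np.ndim(out) == 0 else out


def exposure_table(fit, table: pd.DataFrame) -> pd.DataFrame:
    """Per mother-infant-visit exposure report from a fitted model.

    `fit` must expose ``subject_params()`` returning per (ID, VISIT)
    individual structural parameters (empirical Bayes scale).  Observed
    infant concentrations (median per visit, BLQ at LLOQ/2) are appended
    when present.
    """
    pars = fit.subject_params()
    meta = (
        table.groupby(["ID", "VISIT"])
        .agg({"DOSE": "first", "TAU": "first", "WT": "first", "VDAY": "first", "IWT": "first"})
        .reset_index()
    )
    df = pars.merge(meta, on=["ID", "VISIT"], how="inner")
    out = []
    for _, r in df.iterrows():
        params = StructuralParams(r["ka"], r["cl"], r["vc"], r["kcb"], r["rcb"])
        regimen = DoseRegimen(r["DOSE"], r["TAU"])
        conc_ave = avg_plasma_conc(params, regimen)
        conc_milk = avg_milk_conc(conc_ave, params.rcb)
        dose_ugkg = infant_daily_dose(conc_milk)
        rid = relative_infant_dose(dose_ugkg, regimen.daily_dose, r["WT"])
        cl_inf = infant_clearance(r["IWT"], r["VDAY"] / DAYS_PER_YEAR)
        css = infant_css(dose_ugkg * r["IWT"], cl_inf)
        out.append({
            "ID": int(r["ID"]), "VISIT": int(r["VISIT"]),
            "ConcAve": conc_ave, "ConcMilk": conc_milk,
            "DoseInfant": dose_ugkg, "RID": rid,
            "CLinfant": cl_inf, "Css": css,
            "PctRecommended": pct_recommended_dose(dose_ugkg),
        })
    rep = pd.DataFrame(out)
    inf = table[(table["MATRIX"] == "infant")]
    if len(inf):
        from .synthetic_study import blq_summary_values

        obs = (
            inf.assign(_dv=blq_summary_values(inf))
            .groupby(["ID", "VISIT"])["_dv"]
            .median()
            .rename("ObsInfantMedian")
            .reset_index()
        )
        rep = rep.merge(obs, on=["ID", "VISIT"], how="left")
    return rep
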