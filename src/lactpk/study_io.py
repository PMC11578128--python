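"""Dataset, configuration and result I/O.

Datasets travel as NONMEM-style CSV: one observation record per row with
ID, TIME (hours after the most recent dose), AMT, DV (ng/mL), EVID, MDV,
CMT (2 plasma, 3 breast milk, 4 infant blood), an explicit 0/1 BLQ
column (a deliberate divergence from DV-sentinel conventions), dose
metadata (DOSE mg, TAU h) and covariates.  Since all sampling is
expressed relative to the last dose at steady state, no dose-event rows
are emitted; the regimen lives in the DOSE/TAU columns.

Run configurations are YAML with four sections (design, model,
estimation, diagnostics); every CLI run writes the resolved
configuration next to its outputs so any artifact can be reproduced from
config + seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult, FitSettings
from .pk_model import DataError, PopulationModel, StructuralParams
from .synthetic_study import TABLE_COLUMNS, StudyDesign

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT", "BLQ"]
CMT_TO_MATRIX = {2: "plasma", 3: "milk", 4: "infant"}
MATRIX_TO_CMT = {v: k for k, v in CMT_TO_MATRIX.items()}


def write_dataset(table: pd.DataFrame, path) -> None:
    """Write an observation table as NONMEM-style CSV."""
    out = table.copy()
    out.insert(2, "AMT", 0.0)
    out.insert(3, "EVID", 0)
    out["CMT"] = out["MATRIX"].map(MATRIX_TO_CMT)
    cols = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT", "BLQ", "LLOQ",
            "DOSE", "TAU", "WT", "AGE", "BMI", "CRCL", "VISIT", "VDAY", "IWT",
            "ARM", "GROUP"]
    out[cols].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a NONMEM-style CSV back into the canonical observation table."""
    raw = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"dataset is missing required column(s): {missing}")
    obs = raw[raw["EVID"] == 0].copy()
    bad = obs[pd.to_numeric(obs["DV"], errors="coerce").isna() & (obs["MDV"] == 0)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # 1-based with header row
        raise DataError(f"non-numeric DV on observation row(s) at line(s) {lines}")
    obs["DV"] = pd.to_numeric(obs["DV"], errors="coerce")
    obs["MATRIX"] = obs["CMT"].map(CMT_TO_MATRIX)
    if obs["MATRIX"].isna().any():
        raise DataError("unknown CMT code; expected 2 (plasma), 3 (milk) or 4 (infant)")
    for col in TABLE_COLUMNS:
        if col not in obs.columns:
            obs[col] = np.nan
    return obs[TABLE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    design: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0

    _SECTIONS = ("design", "model", "estimation", "diagnostics")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise DataError(f"unknown config section(s): {sorted(unknown)}")
        cfg = cls(**{k: raw.get(k, {}) for k in cls._SECTIONS},
                  seed=int(raw.get("seed", 0)))
        cfg.study_design()   # validate eagerly so errors name the field
        cfg.population_model()
        cfg.fit_settings()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def study_design(self) -> StudyDesign:
        try:
            return StudyDesign(**self.design)
        except TypeError as exc:
            raise DataError(f"invalid design option: {exc}") from exc

    def population_model(self) -> PopulationModel:
        if not self.model:
            return PopulationModel.lamivudine_reference()
        m = dict(self.model)
        try:
            theta = StructuralParams(**m.pop("theta"))
            iiv = m.pop("iiv", {})
            sigma = m.pop("sigma", {})
        except (KeyError, TypeError) as exc:
            raise DataError(f"invalid model config: {exc}") from exc
        if m:
            raise DataError(f"unknown model option(s): {sorted(m)}")
        return PopulationModel.from_cv(
            theta,
            iiv.get("cl", 0.209), iiv.get("vc", 0.764), iiv.get("rcb", 0.159),
            iiv.get("corr_clvc", 0.42),
            sigma.get("plasma", 0.383), sigma.get("milk", 0.305),
        )

    def fit_settings(self) -> FitSettings:
        est = dict(self.estimation)
        if "iiv_on" in est:
            est["iiv_on"] = tuple(est["iiv_on"])
        if "fix_theta" in est:
            est["fix_theta"] = frozenset(est["fix_theta"])
        try:
            return FitSettings(**est)
        except TypeError as exc:
            raise DataError(f"invalid estimation option: {exc}") from exc


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def write_fit_json(fit: FitResult, table: pd.DataFrame, path) -> None:
    """Persist a fit: estimates, OFV, EBEs and per-subject parameters."""
    payload = {
        "estimates": {k: _f(v) for k, v in fit.estimates.items()},
        "theta": {n: _f(getattr(fit.model.theta, n)) for n in
                  ("ka", "cl", "vc", "kcb", "rcb")},
        "omega": np.asarray(fit.model.omega).tolist(),
        "sigma": {"plasma": _f(fit.model.sigma_plasma),
                  "milk": _f(fit.model.sigma_milk)},
        "ofv": _f(fit.ofv),
        "converged": bool(fit.converged),
        "message": fit.message,
        "shrinkage_pct": {k: _f(v) for k, v in fit.shrinkage.items()},
        "se": None if fit.se is None else {k: _f(v) for k, v in fit.se.items()},
        "rse_pct": None if fit.rse is None else {k: _f(v) for k, v in fit.rse.items()},
        "se_status": fit.se_status,
        "ebe": fit.ebe.to_dict(orient="records"),
        "subject_params": fit.subject_params().to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _f(v):
    v = float(v)
    return v if np.isfinite(v) else None


class FitSummary:
    """Reconstituted fit (from JSON) sufficient for downstream reports."""

    def __init__(self, payload: dict):
        self.payload = payload
        th = payload["theta"]
        self.model = PopulationModel(
            StructuralParams(th["ka"], th["cl"], th["vc"], th["kcb"], th["rcb"]),
            np.asarray(payload["omega"]),
            payload["sigma"]["plasma"], payload["sigma"]["milk"],
        )
        self.ofv = payload["ofv"]
        self.converged = payload["converged"]
        self.ebe = pd.DataFrame(payload["ebe"])
        self._subject_params = pd.DataFrame(payload["subject_params"])

    def subject_params(self) -> pd.DataFrame:
        return self._subject_params.copy()


def read_fit_json(path) -> FitSummary:
    with open(path) as fh:
        return FitSummary(json.load(fh))


def fit_report(fit: FitResult) -> str:
    """Human-readable parameter table (typical values, %CV, %RSE)."""
    lines = ["Parameter            Estimate      %RSE",
             "-" * 42]
    rse = fit.rse or {}
    rows = [
        ("CL (L/h)", fit.model.theta.cl, rse.get("CL")),
        ("Vc (L)", fit.model.theta.vc, rse.get("Vc")),
        ("Ka (1/h)", fit.model.theta.ka, rse.get("Ka")),
        ("Kcb (1/h)", fit.model.theta.kcb, rse.get("Kcb")),
        ("Rcb", fit.model.theta.rcb, rse.get("Rcb")),
        ("IIV CL (%CV)", fit.model.iiv_cv["CL"], rse.get("IIV_CL_CV")),
        ("IIV Vc (%CV)", fit.model.iiv_cv["Vc"], rse.get("IIV_Vc_CV")),
        ("IIV CL-Vc corr", fit.model.corr_clvc, rse.get("IIV_CLVc_corr")),
        ("IIV Rcb (%CV)", fit.model.iiv_cv["Rcb"], rse.get("IIV_Rcb_CV")),
        ("RUV plasma (%CV)", 100 * fit.model.sigma_plasma, rse.get("sigma_plasma_CV")),
        ("RUV milk (%CV)", 100 * fit.model.sigma_milk, rse.get("sigma_milk_CV")),
    ]
    for name, val, r in rows:
        rtxt = f"{r:8.1f}" if r is not None and np.isfinite(r) else "       -"
        lines.append(f"{name:<20s} {val:10.3f} {rtxt}")
    lines.append("-" * 42)
    lines.append(f"OFV {fit.ofv:.3f}   converged: {fit.converged}")
    for k, v in fit.shrinkage.items():
        lines.append(f"eta-shrinkage {k}: {v:.1f}%")
    return "\n".join(lines)
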