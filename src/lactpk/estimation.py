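"""Nonlinear mixed-effects estimation for the lactation PK model.

The marginal likelihood of the population model is approximated by the
Laplace method at each subject's conditional mode (with interaction:
the proportional residual variance depends on the subject-specific
prediction), optionally by its FOCE-style linearised variant.  The
objective reported is OFV = -2 log L including the full Gaussian
constant, so only differences between nested fits are meaningful.

Positivity and positive-semidefiniteness are enforced by transforms:
log for fixed effects and residual SDs, log-Cholesky for the CL-Vc
covariance block.  Standard errors come from a central finite-difference
Hessian of the objective with a delta-method map to the natural scale.

BLQ handling: the default "M1" excludes BLQ records from the likelihood
(they carry MDV=1); "M3" adds a censored normal-CDF contribution at the
record's LLOQ instead.

Model-building tools follow the pharmacometric workflow: likelihood
ratio test on OFV differences, greedy stepwise covariate modelling
(forward inclusion at dOFV >= 3.84, backward elimination retaining a
covariate only if its removal costs >= 6.63), and a nonparametric
bootstrap resampling whole subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pk_model import (
    MGL_TO_NGML,
    SD_FLOOR_MGL,
    DataError,
    NumericalError,
    ParameterError,
    PopulationModel,
    StructuralParams,
    conc_mgl,
)

THETA_NAMES = ("Ka", "CL", "Vc", "Kcb", "Rcb")
ETA_NAMES = ("CL", "Vc", "Rcb")
LOG2PI = np.log(2.0 * np.pi)
_FD_H = 1e-4

try:  # compiled steady-state kernel for the likelihood hot path
    from numba import njit as _njit

    @_njit(cache=True)
    def _accum_exp(lam, t, tau):
        # exp(-lam t) / (1 - exp(-lam tau)), with the lam*tau -> 0 limit
        # substituted when the denominator underflows (numba raises on /0)
        den = 1.0 - np.exp(-lam * tau)
        if den <= 0.0:
            den = lam * tau if lam * tau > 1e-300 else 1e-300
        return np.exp(-lam * t) / den

    @_njit(cache=True)
    def _conc_ss_rows(t, dose, tau, ka, cl, vc, kcb, rcb, milk):
        n = t.shape[0]
        out = np.empty(n)
        for i in range(n):
            ke = cl[i] / vc[i]
            kai = ka[i]
            if abs(kai - ke) <= 1e-8 * abs(ke):
                kai = ke * (1.0 + 1e-8)
            kcbi = kcb[i]
            if abs(kcbi - ke) <= 1e-8 * abs(ke):
                kcbi = ke * (1.0 + 1e-8)
            if abs(kcbi - kai) <= 1e-8 * abs(kai):
                kcbi = kai * (1.0 + 1e-8)
            amp = dose[i] * kai / (vc[i] * (kai - ke))
            a_ke = _accum_exp(ke, t[i], tau[i])
            a_ka = _accum_exp(kai, t[i], tau[i])
            if milk[i]:
                c1 = kcbi * rcb[i] * amp / (kcbi - ke)
                c2 = -kcbi * rcb[i] * amp / (kcbi - kai)
                a_kcb = _accum_exp(kcbi, t[i], tau[i])
                v = c1 * a_ke + c2 * a_ka - (c1 + c2) * a_kcb
            else:
                v = amp * (a_ke - a_ka)
            out[i] = v if v > 0.0 else 0.0
        return out

except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _conc_ss_rows = None

# dOFV thresholds quoted to the conventional 2 decimals so that a drop of
# exactly 3.84 (df=1) counts as significant at alpha=0.05
_DOFV_2DP = {1: {0.05: 3.84, 0.01: 6.63}}


def _dofv_threshold(alpha: float, df: int) -> float:
    try:
        return _DOFV_2DP[df][alpha]
    except KeyError:
        return float(np.round(stats.chi2.ppf(1.0 - alpha, df), 2))


# ---------------------------------------------------------------------------
# settings / covariate effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitSettings:
    """Estimation configuration.

    `iiv_on` lists the structural parameters carrying random effects (a
    subset of CL, Vc, Rcb in that canonical order); `corr_clvc` frees
    the CL-Vc covariance.  `fix_theta` names fixed effects held at their
    initial values.  `approximation` is "laplace" (default) or "foce".
    """

    approximation: str = "laplace"
    blq: str = "M1"
    iiv_on: tuple = ("CL", "Vc", "Rcb")
    corr_clvc: bool = True
    fix_theta: frozenset = frozenset()
    compute_se: bool = False
    maxiter: int = 300
    inner_tol: float = 1e-7
    inner_maxiter: int = 60
    rescue_rounds: int = 3  # direction-set escapes from quasi-Newton stalls

    def __post_init__(self) -> None:
        if self.approximation not in ("laplace", "foce"):
            raise ParameterError(f"unknown approximation {self.approximation!r}")
        if self.blq not in ("M1", "M3"):
            raise ParameterError(f"unknown BLQ mode {self.blq!r}")
        bad = set(self.iiv_on) - set(ETA_NAMES)
        if bad:
            raise ParameterError(f"iiv_on entries must be in {ETA_NAMES}, got {bad}")
        if set(self.fix_theta) - set(THETA_NAMES):
            raise ParameterError("fix_theta entries must be structural parameter names")
        # canonical order
        object.__setattr__(
            self, "iiv_on", tuple(n for n in ETA_NAMES if n in self.iiv_on)
        )
        object.__setattr__(self, "fix_theta", frozenset(self.fix_theta))


@dataclass(frozen=True)
class CovariateEffect:
    """A parameter-covariate relation (centered on the dataset median).

    form "linear":      P * (1 + beta*(cov - center))
    form "exponential": P * exp(beta*(cov - center))
    form "power":       P * (cov/center)^beta
    """

    parameter: str
    covariate: str
    form: str
    coefficient: float | None = None
    center: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ETA_NAMES:
            raise ParameterError(
                f"covariate effects are supported on {ETA_NAMES}, got {self.parameter!r}"
            )
        if self.form not in ("linear", "exponential", "power"):
            raise ParameterError(f"unknown form {self.form!r}")

    def factor(self, cov_values: np.ndarray, beta: float, center: float) -> np.ndarray:
        z = np.asarray(cov_values, dtype=float)
        if self.form == "linear":
            return np.maximum(1.0 + beta * (z - center), 1e-6)
        if self.form == "exponential":
            return np.exp(np.clip(beta * (z - center), -500, 500))
        return (z / center) ** beta


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, OFV, uncertainties and empirical Bayes estimates."""

    model: PopulationModel
    ofv: float
    converged: bool
    message: str
    n_obj_evals: int
    ebe: pd.DataFrame
    shrinkage: dict
    covariate_effects: tuple
    settings: FitSettings
    se: dict | None = None
    rse: dict | None = None
    cov_params: pd.DataFrame | None = None
    se_status: str = "not requested"
    engine: object = field(default=None, repr=False)

    @property
    def estimates(self) -> dict:
        """Natural-scale report: fixed effects, %CV IIV, %CV residual."""
        th = self.model.theta
        out = {
            "Ka": th.ka, "CL": th.cl, "Vc": th.vc, "Kcb": th.kcb, "Rcb": th.rcb,
            "IIV_CL_CV": self.model.iiv_cv["CL"],
            "IIV_Vc_CV": self.model.iiv_cv["Vc"],
            "IIV_Rcb_CV": self.model.iiv_cv["Rcb"],
            "IIV_CLVc_cov": self.model.omega[0, 1],
            "IIV_CLVc_corr": self.model.corr_clvc,
            "IIV_CLVc_CV": 100.0 * np.sqrt(abs(self.model.omega[0, 1])),
            "sigma_plasma_CV": 100.0 * self.model.sigma_plasma,
            "sigma_milk_CV": 100.0 * self.model.sigma_milk,
        }
        for e in self.covariate_effects:
            out[f"beta_{e.parameter}_{e.covariate}"] = e.coefficient
        return out

    def subject_params(self) -> pd.DataFrame:
        """Per (ID, VISIT) individual structural parameters (EBE scale)."""
        return self.engine.subject_params(self.ebe)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class _Prepared:
    """Row-level numpy views of the maternal observation records."""

    def __init__(self, table: pd.DataFrame, blq_mode: str):
        maternal = table[table["MATRIX"].isin(("plasma", "milk"))]
        obs = maternal[(maternal["MDV"] == 0)]
        if blq_mode == "M1":
            obs = obs[obs["BLQ"] == 0]
            cens = maternal.iloc[0:0]
        else:
            cens = maternal[maternal["BLQ"] == 1]
        if len(obs) == 0:
            raise DataError("no usable maternal observations")
        ids = np.sort(maternal["ID"].unique())
        counts = obs.groupby("ID").size().reindex(ids, fill_value=0)
        if (counts == 0).any():
            missing = list(counts[counts == 0].index)
            raise DataError(f"subjects with no usable observation: {missing}")
        self.ids = ids
        self.n_subj = len(ids)
        id_to_idx = {i: k for k, i in enumerate(ids)}
        # keep rows grouped by subject so per-subject sums can use reduceat
        obs = obs.sort_values("ID", kind="stable")
        cens = cens.sort_values("ID", kind="stable")

        def cols(df):
            return dict(
                subj=df["ID"].map(id_to_idx).to_numpy(int),
                t=df["TIME"].to_numpy(float),
                dose=df["DOSE"].to_numpy(float),
                tau=df["TAU"].to_numpy(float),
                milk=(df["MATRIX"] == "milk").to_numpy(),
                y=df["DV"].to_numpy(float) / MGL_TO_NGML,
                lloq=(
                    df["LLOQ"].to_numpy(float) / MGL_TO_NGML
                    if "LLOQ" in df
                    else np.full(len(df), np.nan)
                ),
                frame=df,
            )

        self.obs = cols(obs)
        self.cens = cols(cens)
        self.n_obs = len(obs)
        self.obs_starts = np.searchsorted(self.obs["subj"], np.arange(self.n_subj))
        # censored rows may not cover every subject: use a one-hot scatter
        self.cens_onehot = np.zeros((len(cens), self.n_subj))
        if len(cens):
            self.cens_onehot[np.arange(len(cens)), self.cens["subj"]] = 1.0
        self.has_milk = bool(self.obs["milk"].any())
        self.has_plasma = bool((~self.obs["milk"]).any())

    def covariate_rows(self, name: str, which: str = "obs") -> np.ndarray:
        d = getattr(self, which)["frame"]
        if name not in d.columns:
            raise DataError(f"covariate column {name!r} missing from the dataset")
        return d[name].to_numpy(float)


# ---------------------------------------------------------------------------
# finite differences (vectorised across subjects)
# ---------------------------------------------------------------------------


def _fd_grad_hess(fj, eta, f0, h=_FD_H):
    """Central-difference gradient and Hessian of a per-subject objective.

    All perturbed points are evaluated in one batched call to `fj`
    (which accepts a leading stack axis), so the cost is a handful of
    vectorised numpy passes rather than ~2q^2 separate evaluations.
    """
    n, q = eta.shape
    pts = []
    for k in range(q):
        e = np.zeros(q)
        e[k] = h
        pts += [eta + e, eta - e]
    for j in range(q):
        for k in range(j + 1, q):
            ej, ek = np.zeros(q), np.zeros(q)
            ej[j] = h
            ek[k] = h
            pts += [eta + ej + ek, eta + ej - ek, eta - ej + ek, eta - ej - ek]
    vals = fj(np.stack(pts))
    g = np.empty((n, q))
    H = np.empty((n, q, q))
    for k in range(q):
        fpk, fmk = vals[2 * k], vals[2 * k + 1]
        g[:, k] = (fpk - fmk) / (2 * h)
        H[:, k, k] = (fpk - 2 * f0 + fmk) / h**2
    pos = 2 * q
    for j in range(q):
        for k in range(j + 1, q):
            fpp, fpm, fmp, fmm = vals[pos:pos + 4]
            pos += 4
            H[:, j, k] = H[:, k, j] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    return g, H


def _sanitize_gh(g, H, huge=1e100):
    """Neutralise subjects whose FD derivatives overflowed (flat far tail)."""
    ok = (
        np.isfinite(g).all(axis=1)
        & np.isfinite(H).all(axis=(1, 2))
        & (np.abs(g) < huge).all(axis=1)
        & (np.abs(H) < huge).all(axis=(1, 2))
    )
    if not ok.all():
        g = g.copy()
        H = H.copy()
        g[~ok] = 0.0
        H[~ok] = np.eye(g.shape[1])
    return g, H


def _make_pd(H, floor=1e-8):
    """Per-subject ridge shifting the smallest eigenvalue above `floor`."""
    eig = np.linalg.eigvalsh(H)
    bump = np.maximum(0.0, floor - eig[..., 0])
    return H + bump[..., None, None] * np.eye(H.shape[-1])


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


class _Engine:
    """Holds prepared data, the parameter packing, and all likelihood code."""

    def __init__(self, table, init: PopulationModel, settings: FitSettings,
                 effects: tuple = ()):
        self.settings = settings
        self.prep = _Prepared(table, settings.blq)
        self.effects = tuple(effects)
        for e in self.effects:
            if e.parameter not in settings.iiv_on:
                raise ParameterError(
                    f"covariate on {e.parameter} requires IIV on that parameter"
                )
        self.q = len(settings.iiv_on)
        self.eta_cols = {name: k for k, name in enumerate(settings.iiv_on)}
        self.init = init
        # covariate row values and centers (dataset median)
        self._cov_obs = [self.prep.covariate_rows(e.covariate, "obs") for e in self.effects]
        self._cov_cens = [
            self.prep.covariate_rows(e.covariate, "cens") if len(self.prep.cens["frame"]) else None
            for e in self.effects
        ]
        self.centers = [
            e.center if e.center is not None else float(np.median(v))
            for e, v in zip(self.effects, self._cov_obs)
        ]
        self._build_packing()
        self.eta = np.zeros((self.prep.n_subj, self.q))
        self.n_obj_evals = 0
        self.inner_ok = True
        self._memo: dict = {}
        self._tile_cache: dict = {}

    # -- packing ------------------------------------------------------------

    def _build_packing(self):
        s = self.settings
        self.free_theta = [n for n in THETA_NAMES if n not in s.fix_theta]
        self.clvc_block = ("CL" in s.iiv_on and "Vc" in s.iiv_on and s.corr_clvc)
        self.free_sig_pl = self.prep.has_plasma
        self.free_sig_mk = self.prep.has_milk
        self.free_betas = [e for e in self.effects if e.coefficient is None]
        names = [f"log_{n}" for n in self.free_theta]
        if self.clvc_block:
            names += ["log_lCL", "l_CLVc", "log_lVc"]
            names += [f"log_w{n}" for n in s.iiv_on if n not in ("CL", "Vc")]
        else:
            names += [f"log_w{n}" for n in s.iiv_on]
        if self.free_sig_pl:
            names.append("log_sig_plasma")
        if self.free_sig_mk:
            names.append("log_sig_milk")
        names += [f"beta_{e.parameter}_{e.covariate}" for e in self.free_betas]
        self.x_names = names
        self.nx = len(names)

    def pack_init(self) -> np.ndarray:
        m = self.init
        th = {n: getattr(m.theta, n.lower()) for n in THETA_NAMES}
        x = [np.log(th[n]) for n in self.free_theta]
        om_full = m.omega  # 3x3 in ETA_NAMES order
        idx3 = {n: i for i, n in enumerate(ETA_NAMES)}

        def var(n):
            return max(om_full[idx3[n], idx3[n]], 1e-4)

        if self.clvc_block:
            v_cl, v_vc = var("CL"), var("Vc")
            cov = float(np.clip(om_full[0, 1], -0.99 * np.sqrt(v_cl * v_vc),
                                0.99 * np.sqrt(v_cl * v_vc)))
            l11 = np.sqrt(v_cl)
            l21 = cov / l11
            l22 = np.sqrt(max(v_vc - l21**2, 1e-6))
            x += [np.log(l11), l21, np.log(l22)]
            x += [0.5 * np.log(var(n)) for n in self.settings.iiv_on
                  if n not in ("CL", "Vc")]
        else:
            x += [0.5 * np.log(var(n)) for n in self.settings.iiv_on]
        if self.free_sig_pl:
            x.append(np.log(max(m.sigma_plasma, 1e-4)))
        if self.free_sig_mk:
            x.append(np.log(max(m.sigma_milk, 1e-4)))
        x += [0.0 if e.coefficient is None else e.coefficient for e in self.free_betas]
        return np.array(x[: self.nx], dtype=float)

    def bounds(self):
        b = []
        for name in self.x_names:
            if name.startswith("log_"):
                b.append((-12.0, 12.0))
            else:
                b.append((-50.0, 50.0))
        return b

    def unpack(self, x):
        x = np.asarray(x, dtype=float)
        pos = 0
        th = {n: getattr(self.init.theta, n.lower()) for n in THETA_NAMES}
        for n in self.free_theta:
            th[n] = np.exp(x[pos])
            pos += 1
        q = self.q
        Om = np.zeros((q, q))
        if self.clvc_block:
            l11, l21, l22 = np.exp(x[pos]), x[pos + 1], np.exp(x[pos + 2])
            pos += 3
            i_cl, i_vc = self.eta_cols["CL"], self.eta_cols["Vc"]
            Om[i_cl, i_cl] = l11**2
            Om[i_cl, i_vc] = Om[i_vc, i_cl] = l11 * l21
            Om[i_vc, i_vc] = l21**2 + l22**2
            for n in self.settings.iiv_on:
                if n not in ("CL", "Vc"):
                    Om[self.eta_cols[n], self.eta_cols[n]] = np.exp(2 * x[pos])
                    pos += 1
        else:
            for n in self.settings.iiv_on:
                Om[self.eta_cols[n], self.eta_cols[n]] = np.exp(2 * x[pos])
                pos += 1
        sig_pl = self.init.sigma_plasma
        sig_mk = self.init.sigma_milk
        if self.free_sig_pl:
            sig_pl = np.exp(x[pos])
            pos += 1
        if self.free_sig_mk:
            sig_mk = np.exp(x[pos])
            pos += 1
        betas = []
        k = 0
        for e in self.effects:
            if e.coefficient is None:
                betas.append(x[pos + k])
                k += 1
            else:
                betas.append(e.coefficient)
        return th, Om, float(sig_pl), float(sig_mk), betas

    # -- likelihood pieces ---------------------------------------------------

    def _typ_rows(self, th, betas, which="obs"):
        """Typical (covariate-adjusted, eta=0) parameter values per row."""
        d = getattr(self.prep, which)
        n = len(d["t"])
        out = {n_: np.full(n, th[n_]) for n_ in THETA_NAMES}
        covs = self._cov_obs if which == "obs" else self._cov_cens
        for e, beta, center, cv in zip(self.effects, betas, self.centers, covs):
            out[e.parameter] = out[e.parameter] * e.factor(cv, beta, center)
        return out

    def _static_tiled(self, which, B):
        key = (which, B)
        if key not in self._tile_cache:
            d = getattr(self.prep, which)
            self._tile_cache[key] = (
                np.tile(d["t"], B),
                np.tile(d["dose"], B),
                np.tile(d["tau"], B),
                np.tile(d["milk"], B),
            )
        return self._tile_cache[key]

    def _pred(self, typ, eta, which="obs"):
        """Model prediction (mg/L) per row; eta may carry leading batch axes.

        `eta` has shape (..., n_subj, q) (or None for the typical
        prediction); the result has shape (..., n_rows).  All dosing is
        at steady state, evaluated by the compiled closed-form kernel.
        """
        d = getattr(self.prep, which)
        subj = d["subj"]
        p = {k: v for k, v in typ.items()}
        if eta is not None:
            for name, col in self.eta_cols.items():
                p[name] = p[name] * np.exp(np.clip(eta[..., subj, col], -40.0, 40.0))
        if _conc_ss_rows is None:  # pragma: no cover - plain numpy fallback
            return conc_mgl(
                d["t"], d["dose"], d["tau"],
                p["Ka"], p["CL"], p["Vc"], p["Kcb"], p["Rcb"], d["milk"],
            )
        n_rows = len(d["t"])
        lead = None
        for v in p.values():
            if v.ndim > 1:
                lead = v.shape[:-1]
                break
        if lead is None:
            args = (d["t"], d["dose"], d["tau"], d["milk"])
            flat = {k: np.ascontiguousarray(v) for k, v in p.items()}
            return _conc_ss_rows(args[0], args[1], args[2],
                                 flat["Ka"], flat["CL"], flat["Vc"],
                                 flat["Kcb"], flat["Rcb"], args[3])
        B = int(np.prod(lead))
        t, dose, tau, milk = self._static_tiled(which, B)
        full = {
            k: np.ascontiguousarray(
                np.broadcast_to(v, lead + (n_rows,))
            ).reshape(-1)
            for k, v in p.items()
        }
        out = _conc_ss_rows(t, dose, tau, full["Ka"], full["CL"], full["Vc"],
                            full["Kcb"], full["Rcb"], milk)
        return out.reshape(lead + (n_rows,))

    def _by_subject(self, dev):
        """Sum a per-row quantity (..., n_rows) into (..., n_subj)."""
        return np.add.reduceat(dev, self.prep.obs_starts, axis=-1)

    def _data_neg2ll(self, typ_obs, typ_cens, sig_pl, sig_mk, eta):
        """Per-subject -2 log-likelihood of the observation records."""
        d = self.prep.obs
        f = self._pred(typ_obs, eta, "obs")
        sig = np.where(d["milk"], sig_mk, sig_pl)
        sd = np.maximum(f * sig, SD_FLOOR_MGL)
        dev = LOG2PI + 2.0 * np.log(sd) + ((d["y"] - f) / sd) ** 2
        tot = self._by_subject(dev)
        if len(self.prep.cens["t"]):
            dc = self.prep.cens
            fc = self._pred(typ_cens, eta, "cens")
            sdc = np.maximum(fc * np.where(dc["milk"], sig_mk, sig_pl), SD_FLOOR_MGL)
            p_cens = np.maximum(stats.norm.cdf((dc["lloq"] - fc) / sdc), 1e-300)
            tot = tot + (-2.0 * np.log(p_cens)) @ self.prep.cens_onehot
        return tot

    def joint_neg2ll(self, th, Om, sig_pl, sig_mk, betas, eta, _prior=None):
        """Per-subject -2 log joint density of data and random effects.

        `eta` may have leading batch axes: shape (..., n_subj, q) giving
        an output of shape (..., n_subj).  Batched evaluation keeps the
        finite-difference inner machinery inside a few vectorised numpy
        calls.  `_prior` optionally carries precomputed (Oinv, logdet)
        for the hot path.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            typ_obs = self._typ_rows(th, betas, "obs")
            typ_cens = self._typ_rows(th, betas, "cens") if len(self.prep.cens["t"]) else None
            out = self._data_neg2ll(typ_obs, typ_cens, sig_pl, sig_mk,
                                    eta if self.q else None)
            if self.q:
                if _prior is None:
                    L = np.linalg.cholesky(Om)
                    _prior = (np.linalg.inv(Om), 2.0 * np.sum(np.log(np.diag(L))))
                Oinv, logdet = _prior
                quad = np.einsum("...nq,qr,...nr->...n", eta, Oinv, eta)
                out = out + self.q * LOG2PI + logdet + quad
        return np.where(np.isfinite(out), out, np.inf)

    def _jac_eta(self, typ, eta, which="obs", h=_FD_H):
        """Prediction and d prediction / d eta per row, one batched call."""
        pts = [eta]
        for k in range(self.q):
            e = np.zeros(self.q)
            e[k] = h
            pts += [eta + e, eta - e]
        vals = self._pred(typ, np.stack(pts), which)
        J = np.empty((vals.shape[-1], self.q))
        for k in range(self.q):
            J[:, k] = (vals[2 * k + 1] - vals[2 * k + 2]) / (2 * h)
        return vals[0], J

    def _gn_grad_hess(self, th, betas, Oinv, sig_pl, sig_mk, eta):
        """Analytic gradient and Gauss-Newton Hessian of the joint -2LL.

        Uses the residual linearisation in eta (the FOCE-I information);
        the Hessian keeps only the PSD first-order terms plus the prior,
        so the Newton direction is always a descent direction.
        """
        d = self.prep.obs
        typ = self._typ_rows(th, betas, "obs")
        f, J = self._jac_eta(typ, eta, "obs")
        sig = np.where(d["milk"], sig_mk, sig_pl)
        raw_sd = f * sig
        floored = raw_sd < SD_FLOOR_MGL
        sd = np.maximum(raw_sd, SD_FLOOR_MGL)
        e = (d["y"] - f) / sd
        # d e / d f : -y/(sigma f^2) unless the SD floor is active
        dedf = np.where(floored, -1.0 / sd, -d["y"] / np.maximum(sig * f**2, 1e-300))
        # gradient rows: 2 J/f (log-variance term, off when floored) + 2 e de
        gl = np.where(floored, 0.0, 2.0 / np.maximum(f, 1e-300))
        grow = (gl + 2.0 * e * dedf)[:, None] * J
        u = dedf[:, None] * J  # de/deta rows
        g = np.stack([self._by_subject(grow[:, k]) for k in range(self.q)], axis=1)
        H = np.empty((self.prep.n_subj, self.q, self.q))
        for a in range(self.q):
            for b in range(a, self.q):
                Hab = self._by_subject(2.0 * u[:, a] * u[:, b])
                H[:, a, b] = H[:, b, a] = Hab
        if len(self.prep.cens["t"]):
            dc = self.prep.cens
            typc = self._typ_rows(th, betas, "cens")
            fc, Jc = self._jac_eta(typc, eta, "cens")
            sigc = np.where(dc["milk"], sig_mk, sig_pl)
            sdc = np.maximum(fc * sigc, SD_FLOOR_MGL)
            z = (dc["lloq"] - fc) / sdc
            # dz/df: (-sd - (lloq-f) sigma)/sd^2 = -(1 + z sigma)/sd (no floor)
            dzdf = np.where(fc * sigc < SD_FLOOR_MGL, -1.0 / sdc,
                            -(1.0 + z * sigc) / sdc)
            lam = stats.norm.pdf(z) / np.maximum(stats.norm.cdf(z), 1e-300)
            growc = (-2.0 * lam * dzdf)[:, None] * Jc
            w2 = 2.0 * (lam**2 + z * lam) * dzdf**2  # -2logPhi is convex in z
            g = g + (growc.T @ self.prep.cens_onehot).T
            uc = Jc * dzdf[:, None]
            for a in range(self.q):
                for b in range(a, self.q):
                    Hab = (np.maximum(w2, 0.0) * uc[:, a] * uc[:, b]) @ self.prep.cens_onehot
                    H[:, a, b] = H[:, b, a] = H[:, a, b] + Hab
        g = g + 2.0 * eta @ Oinv
        H = H + 2.0 * Oinv[None]
        return g, H

    # -- inner optimisation --------------------------------------------------

    def _inner(self, fj, gn, tol=None, maxiter=None):
        """Vectorised Gauss-Newton search for all subjects' eta modes.

        Every subject starts from the prior mean, so the profiled
        objective is a deterministic function of the outer parameters (a
        warm start across outer evaluations would make it depend on the
        evaluation history — the joint density is multimodal in eta for
        some subjects — and derail deterministic line searches).  `gn`
        supplies the analytic gradient and PSD Gauss-Newton Hessian; the
        line search evaluates the exact joint `fj`.
        """
        tol = tol or self.settings.inner_tol
        maxiter = maxiter or self.settings.inner_maxiter
        eta = np.zeros_like(self.eta)
        f0 = fj(eta).copy()
        n = len(eta)
        g = self._gn_descend(fj, gn, eta, f0, tol, maxiter)
        # basin check: the joint density can be multimodal in eta, and a
        # mode tracked from the prior mean may not be the deepest one.
        # Probe a fixed stencil of eta offsets; wherever a probe beats the
        # current mode, descend again from there.  This keeps the profiled
        # objective (approximately) the global-mode Laplace objective and,
        # crucially, free of spurious value cliffs.
        for _round in range(2):
            probes = []
            for k in range(self.q):
                for s in (-1.5, 1.5, -3.0, 3.0):
                    e = np.zeros(self.q)
                    e[k] = s
                    probes.append(eta + e)
            fp = fj(np.stack(probes))
            best = fp.min(axis=0)
            if not (best < f0 - 1e-8).any():
                break
            which = fp.argmin(axis=0)
            better = best < f0 - 1e-8
            eta[better] = np.stack(probes)[which[better], better]
            f0[better] = best[better]
            g = self._gn_descend(fj, gn, eta, f0, tol, maxiter)
        self.eta = eta
        self.inner_ok = bool(np.max(np.abs(g)) < max(tol * 1e3, 1e-3))
        return eta, f0

    def _gn_descend(self, fj, gn, eta, f0, tol, maxiter):
        """Damped Gauss-Newton sweep updating (eta, f0) in place."""
        n = len(eta)
        frozen = np.zeros(n, dtype=bool)  # line search exhausted: leave alone
        g = None
        for _ in range(maxiter):
            g, H = _sanitize_gh(*gn(eta))
            active = ~frozen & (np.abs(g).max(axis=1) >= tol)
            if not active.any():
                break
            Hpd = _make_pd(H, floor=1e-8)
            try:
                step = -np.linalg.solve(Hpd, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = -g
            # cap the step so a near-singular Hessian cannot fling a subject
            # into the flat far tail of the likelihood
            norm = np.linalg.norm(step, axis=1)
            step = step * np.minimum(1.0, 3.0 / np.maximum(norm, 1e-300))[:, None]
            done = ~active  # converged/frozen subjects sit out the line search
            alphas = (1.0, 0.3, 0.08, 0.02, 4e-3, 5e-4)
            cands = np.stack([eta + a * step for a in alphas])
            fcs = fj(cands)  # one batched evaluation for the whole sweep
            for a_i in range(len(alphas)):
                newly = (fcs[a_i] <= f0 - 1e-12) & ~done
                eta[newly] = cands[a_i, newly]
                f0[newly] = fcs[a_i, newly]
                done |= newly
            frozen |= active & ~done
        if g is None:
            g, _ = _sanitize_gh(*gn(eta))
        return g

    # -- marginal objective --------------------------------------------------

    def objective(self, x):
        """OFV: -2 log approximate marginal likelihood (sum over subjects).

        Deterministic in `x` (the inner search always starts from the
        prior mean); repeated evaluations at the same point are memoised.
        """
        key = np.asarray(x, dtype=float).tobytes()
        if key in self._memo:
            return self._memo[key]
        val = self._objective_impl(x)
        if len(self._memo) > 64:
            self._memo.clear()
        self._memo[key] = val
        return val

    def _objective_impl(self, x):
        self.n_obj_evals += 1
        th, Om, sig_pl, sig_mk, betas = self.unpack(x)
        if self.q == 0:
            typ_obs = self._typ_rows(th, betas, "obs")
            typ_cens = self._typ_rows(th, betas, "cens") if len(self.prep.cens["t"]) else None
            return float(np.sum(self._data_neg2ll(typ_obs, typ_cens, sig_pl, sig_mk, None)))

        L = np.linalg.cholesky(Om)
        prior = (np.linalg.inv(Om), 2.0 * np.sum(np.log(np.diag(L))))

        def fj(eta):
            return self.joint_neg2ll(th, Om, sig_pl, sig_mk, betas, eta, _prior=prior)

        def gn(eta):
            return self._gn_grad_hess(th, betas, prior[0], sig_pl, sig_mk, eta)

        eta, f0 = self._inner(fj, gn)
        if self.settings.approximation == "laplace":
            # exact curvature at the mode for the Laplace determinant
            _, H = _sanitize_gh(*_fd_grad_hess(fj, eta, f0))
            Hpd = _make_pd(H, floor=1e-10)
            sign, logdet = np.linalg.slogdet(Hpd / 2.0)
            logdet = np.where(sign > 0, logdet, np.inf)
            ofv_i = f0 - self.q * LOG2PI + logdet
        else:  # foce: linearised marginal covariance at the mode
            ofv_i = self._foce_ofv(th, Om, sig_pl, sig_mk, betas, eta)
        ofv_i = np.where(np.isfinite(ofv_i), ofv_i, np.inf)
        return float(np.sum(ofv_i))

    def _linearize(self, th, betas, sig_pl, sig_mk, eta, h=_FD_H):
        """Predictions, residual SDs and d f/d eta at the given eta."""
        typ = self._typ_rows(th, betas, "obs")
        f = self._pred(typ, eta, "obs")
        d = self.prep.obs
        sd = np.maximum(f * np.where(d["milk"], sig_mk, sig_pl), SD_FLOOR_MGL)
        J = np.empty((self.prep.n_obs, self.q))
        for k in range(self.q):
            e = np.zeros(self.q)
            e[k] = h
            J[:, k] = (self._pred(typ, eta + e, "obs")
                       - self._pred(typ, eta - e, "obs")) / (2 * h)
        return f, sd, J

    def _foce_ofv(self, th, Om, sig_pl, sig_mk, betas, eta):
        f, sd, J = self._linearize(th, betas, sig_pl, sig_mk, eta)
        d = self.prep.obs
        r = d["y"] - f + np.sum(J * eta[d["subj"]], axis=1)
        out = np.zeros(self.prep.n_subj)
        for i in range(self.prep.n_subj):
            m = d["subj"] == i
            Ji = J[m]
            V = Ji @ Om @ Ji.T + np.diag(sd[m] ** 2)
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                V = V + 1e-10 * np.eye(V.shape[0])
                _, logdet = np.linalg.slogdet(V)
            ri = r[m]
            out[i] = m.sum() * LOG2PI + logdet + ri @ np.linalg.solve(V, ri)
        return out

    # -- post-fit ------------------------------------------------------------

    def ebe_and_shrinkage(self, x):
        th, Om, sig_pl, sig_mk, betas = self.unpack(x)
        ebe = pd.DataFrame({"ID": self.prep.ids})
        for n in ETA_NAMES:
            ebe[f"eta_{n}"] = 0.0
        shrink = {}
        if self.q:
            Oinv = np.linalg.inv(Om)

            def fj(eta):
                return self.joint_neg2ll(th, Om, sig_pl, sig_mk, betas, eta)

            def gn(eta):
                return self._gn_grad_hess(th, betas, Oinv, sig_pl, sig_mk, eta)

            eta, _ = self._inner(fj, gn, tol=1e-8, maxiter=100)
            for name, col in self.eta_cols.items():
                ebe[f"eta_{name}"] = eta[:, col]
                w = np.sqrt(Om[col, col])
                sd_eta = np.std(eta[:, col], ddof=1) if len(eta) > 1 else 0.0
                shrink[name] = 100.0 * (1.0 - sd_eta / w) if w > 0 else np.nan
        return ebe, shrink

    def subject_params(self, ebe: pd.DataFrame) -> pd.DataFrame:
        """Individual structural parameters per (ID, VISIT)."""
        th, _, _, _, betas = self.unpack(self._x_final)
        d = self.prep.obs["frame"]
        typ = self._typ_rows(th, betas, "obs")
        rows = pd.DataFrame({
            "ID": d["ID"].to_numpy(), "VISIT": d["VISIT"].to_numpy(),
            **{n.lower(): typ[n] for n in THETA_NAMES},
        })
        rows = rows.groupby(["ID", "VISIT"]).median().reset_index()
        rows = rows.merge(ebe, on="ID", how="left")
        for name in ETA_NAMES:
            rows[name.lower()] = rows[name.lower()] * np.exp(rows[f"eta_{name}"])
        return rows[["ID", "VISIT"] + [n.lower() for n in THETA_NAMES]]

    def population_model(self, x) -> PopulationModel:
        th, Om, sig_pl, sig_mk, _ = self.unpack(x)
        om3 = np.zeros((3, 3))
        for a, ia in self.eta_cols.items():
            for b, ib in self.eta_cols.items():
                om3[ETA_NAMES.index(a), ETA_NAMES.index(b)] = Om[ia, ib]
        return PopulationModel(
            StructuralParams(th["Ka"], th["CL"], th["Vc"], th["Kcb"], th["Rcb"]),
            om3, sig_pl, sig_mk,
        )

    def natural_params(self, x) -> dict:
        """Natural-scale parameter vector for delta-method SEs."""
        m = self.population_model(x)
        _, _, _, _, betas = self.unpack(x)
        out = {}
        for n in self.free_theta:
            out[n] = getattr(m.theta, n.lower())
        for n in self.settings.iiv_on:
            out[f"IIV_{n}_CV"] = m.iiv_cv[n]
        if self.clvc_block:
            out["IIV_CLVc_corr"] = m.corr_clvc
        if self.free_sig_pl:
            out["sigma_plasma_CV"] = 100.0 * m.sigma_plasma
        if self.free_sig_mk:
            out["sigma_milk_CV"] = 100.0 * m.sigma_milk
        for e, b in zip(self.effects, betas):
            if e.coefficient is None:
                out[f"beta_{e.parameter}_{e.covariate}"] = b
        return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def individual_joint_neg2ll(subject_records: pd.DataFrame, model: PopulationModel,
                            eta, settings: FitSettings | None = None) -> float:
    """-2 log joint density of one subject's records and random effects.

    The data term uses the proportional-error Gaussian model on the
    closed-form predictions with eta-dependent residual variance
    (interaction); the prior term is the N(0, Omega) density of eta.
    """
    settings = settings or FitSettings()
    eng = _Engine(subject_records, model, settings)
    if eng.prep.n_subj != 1:
        raise DataError("individual_joint_neg2ll expects records of one subject")
    x = eng.pack_init()
    th, Om, sig_pl, sig_mk, betas = eng.unpack(x)
    eta_full = np.asarray(eta, dtype=float).reshape(1, -1)
    if eta_full.shape[1] != eng.q:
        # caller passed a 3-vector in canonical order; select active columns
        eta_full = np.array([[eta_full[0, ETA_NAMES.index(n)] for n in settings.iiv_on]])
    return float(eng.joint_neg2ll(th, Om, sig_pl, sig_mk, betas, eta_full)[0])


def marginal_neg2ll(table: pd.DataFrame, model: PopulationModel,
                    settings: FitSettings | None = None) -> float:
    """OFV of the population model on the table (no parameter estimation).

    With a zero IIV covariance this reduces exactly to the eta=0
    fixed-effects -2 log-likelihood.
    """
    settings = settings or FitSettings()
    if np.allclose(np.diag(model.omega), 0.0):
        settings = replace(settings, iiv_on=())
    eng = _Engine(table, model, settings)
    return eng.objective(eng.pack_init())


def fit_model(table: pd.DataFrame, init: PopulationModel,
              settings: FitSettings | None = None,
              covariate_effects: tuple = ()) -> FitResult:
    """Maximise the approximate marginal likelihood over (theta, Omega, sigma).

    Returns a :class:`FitResult`; on optimizer non-convergence the
    best-found point is returned with ``converged=False`` and a warning.
    Standard errors (when requested) come from the central
    finite-difference Hessian of the OFV; a non-PD Hessian withholds
    them with an explanatory status.
    """
    settings = settings or FitSettings()
    eng = _Engine(table, init, settings, covariate_effects)
    x0 = eng.pack_init()

    def jac(x, h=3e-5):
        # central differences: the inner optimisation leaves ~1e-5 noise on
        # the objective, so a larger symmetric step beats the optimizer's
        # own forward differences
        g = np.empty_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (eng.objective(x + e) - eng.objective(x - e)) / (2 * h)
        return g

    def lbfgs(xs):
        return optimize.minimize(
            eng.objective, xs, jac=jac, method="L-BFGS-B", bounds=eng.bounds(),
            options=dict(maxiter=settings.maxiter, ftol=1e-9, gtol=1e-4),
        )

    def powell(xs):
        return optimize.minimize(
            eng.objective, xs, method="Powell", bounds=eng.bounds(),
            options=dict(maxiter=30, xtol=1e-6, ftol=1e-8),
        )

    # The profiled objective is smooth almost everywhere but the inner
    # mode can jump between basins, leaving kinks where a quasi-Newton
    # line search stalls with a large gradient.  Strategy: quasi-Newton
    # first, then a direction-set (Powell) rescue whenever the returned
    # point is clearly not stationary, then a final polish.
    res = lbfgs(x0)
    fun = res.fun
    grad_max = np.max(np.abs(res.jac))
    for _ in range(settings.rescue_rounds):
        if grad_max < 0.5:
            break
        resc = powell(res.x)
        pol = lbfgs(resc.x)
        best = min((res, resc, pol), key=lambda r: r.fun)
        improved = fun - best.fun
        res = best
        fun = res.fun
        grad_max = np.max(np.abs(jac(res.x)))
        if improved < 0.01:
            break
    if grad_max >= 1.0 and settings.rescue_rounds > 0:
        # last resort: an independent direction-set pass from the start
        alt = lbfgs(powell(x0).x)
        if alt.fun < fun:
            res = alt
            fun = res.fun
            grad_max = np.max(np.abs(jac(res.x)))
    x = res.x
    eng._x_final = x
    converged = eng.inner_ok and grad_max < 1.0
    if not converged:
        warnings.warn(
            f"fit did not fully converge (max gradient {grad_max:.3g}): {res.message}",
            RuntimeWarning,
        )
    ebe, shrink = eng.ebe_and_shrinkage(x)
    model = eng.population_model(x)
    # estimated covariate coefficients written back into the effect objects
    _, _, _, _, betas = eng.unpack(x)
    eff_out = tuple(
        replace(e, coefficient=float(b), center=c)
        for e, b, c in zip(eng.effects, betas, eng.centers)
    )
    fr = FitResult(
        model=model, ofv=float(fun), converged=converged,
        message=str(res.message), n_obj_evals=eng.n_obj_evals,
        ebe=ebe, shrinkage=shrink, covariate_effects=eff_out,
        settings=settings, engine=eng,
    )
    if settings.compute_se:
        _attach_se(fr, eng, x)
    return fr


def _attach_se(fr: FitResult, eng: _Engine, x: np.ndarray, h: float = 1e-4):
    n = len(x)
    Hm = np.empty((n, n))
    f0 = eng.objective(x)
    for i in range(n):
        for j in range(i, n):
            ei, ej = np.zeros(n), np.zeros(n)
            ei[i] = h
            ej[j] = h
            if i == j:
                Hm[i, i] = (eng.objective(x + ei) - 2 * f0 + eng.objective(x - ei)) / h**2
            else:
                v = (eng.objective(x + ei + ej) - eng.objective(x + ei - ej)
                     - eng.objective(x - ei + ej) + eng.objective(x - ei - ej)) / (4 * h**2)
                Hm[i, j] = Hm[j, i] = v
    eig = np.linalg.eigvalsh(Hm)
    if eig.min() <= 0:
        fr.se_status = "Hessian not positive definite; SEs withheld"
        return
    cov_x = 2.0 * np.linalg.inv(Hm)  # OFV = -2 LL
    # delta method to the natural scale
    nat0 = eng.natural_params(x)
    keys = list(nat0.keys())
    Jn = np.empty((len(keys), n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        np_p = eng.natural_params(x + e)
        np_m = eng.natural_params(x - e)
        Jn[:, j] = [(np_p[k] - np_m[k]) / (2 * h) for k in keys]
    cov_nat = Jn @ cov_x @ Jn.T
    se = {k: float(np.sqrt(max(cov_nat[i, i], 0.0))) for i, k in enumerate(keys)}
    fr.se = se
    fr.rse = {
        k: (100.0 * se[k] / abs(nat0[k]) if nat0[k] != 0 else np.nan) for k in keys
    }
    fr.cov_params = pd.DataFrame(cov_nat, index=keys, columns=keys)
    fr.se_status = "ok"


# ---------------------------------------------------------------------------
# likelihood ratio test / SCM / bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    delta_ofv: float
    df: int
    p_value: float
    significant: bool
    alpha: float
    warning: str | None = None


def lrt(ofv_reduced: float, ofv_full: float, df: int, alpha: float = 0.05) -> LRTResult:
    """Likelihood ratio test between nested fits (dOFV ~ chi2_df).

    Significance uses the conventional 2-decimal dOFV threshold (3.84 at
    df=1, alpha=0.05) so a drop of exactly 3.84 counts as significant.
    A negative dOFV (non-nested or failed fits) returns p=1 with a
    warning.
    """
    if df < 1:
        raise ParameterError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < 0:
        return LRTResult(delta, df, 1.0, False, alpha,
                         warning="negative dOFV: models may not be nested")
    p = float(stats.chi2.sf(delta, df))
    return LRTResult(float(delta), df, p, delta >= _dofv_threshold(alpha, df), alpha)


@dataclass
class SCMResult:
    selected: tuple
    fit: FitResult
    base_fit: FitResult
    trace: pd.DataFrame


def scm(table: pd.DataFrame, candidates, init: PopulationModel,
        settings: FitSettings | None = None,
        forward_alpha: float = 0.05, backward_alpha: float = 0.01) -> SCMResult:
    """Greedy stepwise covariate modelling with LRT thresholds.

    Forward inclusion accepts the best candidate with dOFV >= the
    forward threshold (3.84 for alpha=0.05, df=1); backward elimination
    then removes any covariate whose deletion costs less than the
    stricter backward threshold (6.63 for alpha=0.01).  The full
    decision trace is returned.
    """
    settings = settings or FitSettings()
    candidates = list(candidates)
    base = fit_model(table, init, settings)
    selected: list = []
    trace = []
    current = base

    def refit(effs, start_model):
        return fit_model(table, start_model, settings, covariate_effects=tuple(effs))

    thr_f = _dofv_threshold(forward_alpha, 1)
    thr_b = _dofv_threshold(backward_alpha, 1)
    remaining = candidates.copy()
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            f = refit(selected + [cand], current.model)
            delta = current.ofv - f.ofv
            trace.append(dict(phase="forward", step=step,
                              candidate=f"{cand.covariate}->{cand.parameter}({cand.form})",
                              ofv=f.ofv, delta_ofv=delta,
                              decision="candidate"))
            if best is None or delta > best[0]:
                best = (delta, cand, f)
        if best[0] >= thr_f:
            selected.append(best[1])
            remaining.remove(best[1])
            current = best[2]
            trace.append(dict(
                phase="forward", step=step,
                candidate=f"{best[1].covariate}->{best[1].parameter}({best[1].form})",
                ofv=current.ofv, delta_ofv=best[0], decision="included"))
        else:
            break
    # backward elimination
    changed = True
    while changed and selected:
        changed = False
        for cand in list(selected):
            others = [e for e in selected if e is not cand]
            f = refit(others, current.model)
            delta = f.ofv - current.ofv  # cost of removal
            keep = delta >= thr_b
            trace.append(dict(phase="backward", step=step,
                              candidate=f"{cand.covariate}->{cand.parameter}({cand.form})",
                              ofv=f.ofv, delta_ofv=delta,
                              decision="retained" if keep else "removed"))
            if not keep:
                selected.remove(cand)
                current = f
                changed = True
                break
    return SCMResult(tuple(current.covariate_effects), current, base,
                     pd.DataFrame(trace))


@dataclass
class BootstrapResult:
    table: pd.DataFrame          # per-parameter median and percentile CI
    samples: pd.DataFrame        # raw per-resample estimates
    n_requested: int
    n_failed: int
    warning: str | None = None


def bootstrap(table: pd.DataFrame, init: PopulationModel, n_resamples: int = 1000,
              seed=0, settings: FitSettings | None = None,
              ci: float = 95.0) -> BootstrapResult:
    """Nonparametric bootstrap resampling whole subjects, with refits.

    Each resample draws subjects with replacement (all of a subject's
    records move together), refits, and records natural-scale
    estimates; per-parameter medians and percentile CIs are reported.
    Failed fits are excluded and counted; >20% failures flags the CI
    table with a warning.
    """
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    ids = np.sort(table["ID"].unique())
    rows = []
    n_failed = 0
    for _ in range(n_resamples):
        draw = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for newid, sid in enumerate(draw, start=1):
            part = table[table["ID"] == sid].copy()
            part["ID"] = newid
            parts.append(part)
        bs = pd.concat(parts, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = fit_model(bs, init, settings)
            if not np.isfinite(f.ofv):
                raise NumericalError("non-finite OFV")
            rows.append(f.estimates)
        except Exception:
            n_failed += 1
    samples = pd.DataFrame(rows)
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    summary = samples.quantile([lo / 100, 0.5, hi / 100]).T
    summary.columns = [f"p{lo}", "median", f"p{hi}"]
    warn = None
    if n_resamples and n_failed / n_resamples > 0.20:
        warn = f"{n_failed}/{n_resamples} bootstrap fits failed"
        warnings.warn(warn, RuntimeWarning)
    return BootstrapResult(summary, samples, n_resamples, n_failed, warn)
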