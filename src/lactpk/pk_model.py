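"""Structural and population layers of the lactation PK model.

A one-compartment oral-absorption model describes maternal plasma
disposition (first-order absorption ``Ka``, apparent clearance ``CL/F``,
apparent central volume ``Vc/F``).  Breast milk is a hypothetical *effect
compartment* linked to plasma by a first-order equilibration rate ``Kcb``:

    dC_milk/dt = Kcb * (Rcb * C_plasma - C_milk)

so at steady state the milk AUC over one dosing interval is exactly
``Rcb`` times the plasma AUC — ``Rcb`` is the milk-to-plasma accumulation
ratio.  No mass leaves plasma into milk; the effect compartment only
delays and scales the plasma profile.

All concentrations are handled internally in mg/L; the public functions
return ng/mL (1 mg/L = 1000 ng/mL).  Closed forms are sums of
exponentials in {ke, Ka, Kcb}; steady state is obtained by analytic
superposition over an infinite dose train (accumulation factor
``1/(1 - exp(-rate*tau))`` on every exponential term).  A numerical ODE
integrator over an explicit dose train is kept alongside as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

# ---------------------------------------------------------------------------
# constants & errors
# ---------------------------------------------------------------------------

MGL_TO_NGML = 1000.0  # 1 mg/L == 1000 ng/mL

#: relative nudge applied when two first-order rates coincide (closed forms
#: have removable singularities at Ka == ke etc.; we perturb rather than
#: branch to the L'Hopital limit)
RATE_SEP = 1e-8

#: residual-error SD floor, mg/L (keeps the proportional-error likelihood
#: finite when a prediction is ~0)
SD_FLOOR_MGL = 1e-6

# reference (typical) lamivudine estimates used as package-wide defaults
REF_KA = 1.87      # 1/h
REF_CL = 19.4      # L/h (apparent, CL/F)
REF_VC = 184.0     # L   (apparent, Vc/F)
REF_KCB = 0.245    # 1/h
REF_RCB = 1.77     # milk:plasma accumulation ratio
REF_IIV_CL = 0.209    # SD of log-scale random effect (~= %CV/100)
REF_IIV_VC = 0.764
REF_IIV_RCB = 0.159
REF_CORR_CLVC = 0.42  # correlation between CL and Vc random effects
REF_SIGMA_PLASMA = 0.383  # proportional residual SD, plasma
REF_SIGMA_MILK = 0.305    # proportional residual SD, breast milk


class ParameterError(ValueError):
    """A structural or population parameter is outside its domain."""


class DataError(ValueError):
    """An observation table / input record violates the schema."""


class NumericalError(RuntimeError):
    """A numerical routine (ODE solver, optimizer) failed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters (apparent oral parameters).

    Attributes
    ----------
    ka : float
        First-order absorption rate constant (1/h).
    cl : float
        Apparent plasma clearance CL/F (L/h).
    vc : float
        Apparent central volume of distribution Vc/F (L).
    kcb : float
        Plasma-to-milk equilibration rate constant (1/h).
    rcb : float
        Milk accumulation (milk-to-plasma) ratio, dimensionless.
    """

    ka: float
    cl: float
    vc: float
    kcb: float
    rcb: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "vc", "kcb", "rcb"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/Vc (1/h)."""
        return self.cl / self.vc

    def replace(self, **kw) -> "StructuralParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: `dose` mg every `tau` h.

    ``steady_state=True`` (default) means an infinite dose train handled
    by analytic superposition; otherwise ``n_doses`` boluses have been
    given and times are measured from the last dose.
    """

    dose: float
    tau: float
    steady_state: bool = True
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterError(f"dose must be >= 0, got {self.dose!r}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau!r}")
        if not self.steady_state and self.n_doses < 1:
            raise ParameterError("n_doses must be >= 1")

    @property
    def daily_dose(self) -> float:
        """Dose rate in mg per 24 h."""
        return self.dose * 24.0 / self.tau


Q12_150 = DoseRegimen(dose=150.0, tau=12.0)
Q24_300 = DoseRegimen(dose=300.0, tau=24.0)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, IIV covariance and residual-error magnitudes.

    ``omega`` is the 3x3 covariance of the log-scale random effects in
    the order (CL, Vc, Rcb); the CL–Vc off-diagonal is free, Rcb is
    uncorrelated with the others.  ``sigma_plasma`` / ``sigma_milk`` are
    proportional residual SDs (CV fractions).  Ka and Kcb carry no
    inter-individual variability.
    """

    theta: StructuralParams
    omega: np.ndarray
    sigma_plasma: float
    sigma_milk: float

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (3, 3):
            raise ParameterError(f"omega must be 3x3, got shape {om.shape}")
        if not np.allclose(om, om.T, atol=1e-12):
            raise ParameterError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(om)) < -1e-10:
            raise ParameterError("omega must be positive semidefinite")
        if om[0, 2] != 0 or om[1, 2] != 0:
            raise ParameterError("Rcb random effect must be uncorrelated with CL, Vc")
        if self.sigma_plasma < 0 or self.sigma_milk < 0:
            raise ParameterError("sigma components must be >= 0")
        object.__setattr__(self, "omega", om)

    # -- convenience constructors -------------------------------------------

    @classmethod
    def from_cv(
        cls,
        theta: StructuralParams,
        iiv_cl: float,
        iiv_vc: float,
        iiv_rcb: float,
        corr_clvc: float,
        sigma_plasma: float,
        sigma_milk: float,
    ) -> "PopulationModel":
        """Build from SD-scale IIV magnitudes (%CV/100) and a CL–Vc correlation."""
        om = np.zeros((3, 3))
        om[0, 0] = iiv_cl**2
        om[1, 1] = iiv_vc**2
        om[2, 2] = iiv_rcb**2
        om[0, 1] = om[1, 0] = corr_clvc * iiv_cl * iiv_vc
        return cls(theta, om, sigma_plasma, sigma_milk)

    @classmethod
    def lamivudine_reference(cls) -> "PopulationModel":
        """Typical lamivudine lactation model (reference estimates)."""
        return cls.from_cv(
            StructuralParams(REF_KA, REF_CL, REF_VC, REF_KCB, REF_RCB),
            REF_IIV_CL,
            REF_IIV_VC,
            REF_IIV_RCB,
            REF_CORR_CLVC,
            REF_SIGMA_PLASMA,
            REF_SIGMA_MILK,
        )

    # -- reporting helpers ---------------------------------------------------

    @property
    def iiv_cv(self) -> dict:
        """IIV magnitudes as 100*sqrt(omega_kk) (the conventional %CV report)."""
        d = np.sqrt(np.diag(self.omega))
        return {"CL": 100 * d[0], "Vc": 100 * d[1], "Rcb": 100 * d[2]}

    @property
    def corr_clvc(self) -> float:
        d = np.sqrt(self.omega[0, 0] * self.omega[1, 1])
        return float(self.omega[0, 1] / d) if d > 0 else 0.0

    def draw_etas(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n iid 3-vectors of log-scale random effects from N(0, omega)."""
        return rng.multivariate_normal(np.zeros(3), self.omega, size=n, method="svd")


MATRICES = ("plasma", "milk")


# ---------------------------------------------------------------------------
# closed-form concentration curves
# ---------------------------------------------------------------------------


def _separate(a, b, rel: float = RATE_SEP):
    """Nudge rate `a` away from `b` where the two (nearly) coincide."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    close = np.abs(a - b) <= rel * np.abs(b)
    return np.where(close, b * (1.0 + rel), a)


def _accum(lam, tau, steady_state, n_doses):
    """Superposition accumulation factor for an exponential term exp(-lam*t)."""
    e = np.exp(-lam * tau)
    if steady_state:
        return 1.0 / (1.0 - e)
    if np.ndim(n_doses) == 0 and n_doses == 1:
        return np.ones_like(lam)
    return (1.0 - e**n_doses) / (1.0 - e)


def conc_mgl(
    t,
    dose,
    tau,
    ka,
    cl,
    vc,
    kcb,
    rcb,
    milk,
    steady_state=True,
    n_doses=1,
):
    """Vectorised closed-form concentration (mg/L) at time-after-dose `t`.

    All arguments broadcast.  `milk` is a boolean selector: False ->
    plasma, True -> effect-compartment milk concentration.  This is the
    computational kernel shared by the public API, the synthetic-study
    simulator and the likelihood.
    """
    t, dose, tau, ka, cl, vc, kcb, rcb, milk = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, dose, tau, ka, cl, vc, kcb, rcb)),
        np.asarray(milk, dtype=bool),
    )
    ke = cl / vc
    ka = _separate(ka, ke)
    kcb = _separate(_separate(kcb, ke), ka)

    amp = dose * ka / (vc * (ka - ke))  # mg/L
    # plasma: amp*e^{-ke t} - amp*e^{-ka t}
    lam = np.stack([ke, ka])
    c_pl = np.stack([amp, -amp])
    # milk: each plasma term (c, lam) maps to kcb*rcb*c/(kcb-lam) at lam,
    # with the balancing opposite-signed mass collected at rate kcb
    c_mk_terms = kcb * rcb * c_pl / (kcb - lam)
    lam_all = np.concatenate([lam, kcb[None]])
    c_mk = np.concatenate([c_mk_terms, -c_mk_terms.sum(axis=0)[None]])
    c_zero = np.zeros_like(kcb)
    c_all_pl = np.concatenate([c_pl, c_zero[None]])

    coef = np.where(milk[None], c_mk, c_all_pl)
    acc = _accum(lam_all, tau, steady_state, n_doses)
    out = np.sum(coef * acc * np.exp(-lam_all * t), axis=0)
    return np.maximum(out, 0.0)


def _conc_ngml(params: StructuralParams, regimen: DoseRegimen, t, milk: bool):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DataError("time after dose must be >= 0")
    out = MGL_TO_NGML * conc_mgl(
        t,
        regimen.dose,
        regimen.tau,
        params.ka,
        params.cl,
        params.vc,
        params.kcb,
        params.rcb,
        milk,
        steady_state=regimen.steady_state,
        n_doses=regimen.n_doses,
    )
    return float(out) if np.ndim(out) == 0 else out


def plasma_conc(params: StructuralParams, regimen: DoseRegimen, t):
    """Plasma concentration (ng/mL) at time-after-dose `t` (h)."""
    return _conc_ngml(params, regimen, t, milk=False)


def milk_conc(params: StructuralParams, regimen: DoseRegimen, t):
    """Breast-milk concentration (ng/mL) at time-after-dose `t` (h)."""
    return _conc_ngml(params, regimen, t, milk=True)


def auc_tau_ss(params: StructuralParams, regimen: DoseRegimen, matrix: str) -> float:
    """Analytic steady-state AUC over one dosing interval (ng/mL * h).

    At steady state the interval AUC of a superposed exponential-sum
    profile equals the single-dose AUC extrapolated to infinity,
    sum(c/lam) — giving Dose/CL for plasma and Rcb*Dose/CL for milk.
    """
    if matrix not in MATRICES:
        raise DataError(f"unknown matrix {matrix!r}")
    auc_pl = regimen.dose / params.cl  # mg/L * h
    auc = auc_pl * params.rcb if matrix == "milk" else auc_pl
    return float(auc * MGL_TO_NGML)


# ---------------------------------------------------------------------------
# ODE oracle
# ---------------------------------------------------------------------------


def integrate_odes(params: StructuralParams, regimen: DoseRegimen, t_grid):
    """Numerically integrate the depot/plasma/milk system over a dose train.

    Doses are boluses into the depot at 0, tau, ..., (n_doses-1)*tau;
    `t_grid` contains ascending absolute times (h) from the first dose.
    Returns a record array-like dict of numpy arrays with keys
    ``time``, ``plasma``, ``milk`` (ng/mL).  This routine is the
    independent oracle for the closed forms and is deliberately free of
    any shared code with them.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise DataError("t_grid must be 1-D, ascending and >= 0")
    if regimen.steady_state:
        raise DataError(
            "integrate_odes needs an explicit dose train; pass steady_state=False"
        )

    ka, ke, vc, kcb, rcb = params.ka, params.ke, params.vc, params.kcb, params.rcb

    def rhs(_t, y):
        a1, a2, c3 = y
        return [-ka * a1, ka * a1 - ke * a2, kcb * (rcb * a2 / vc - c3)]

    dose_times = regimen.tau * np.arange(regimen.n_doses)
    y = np.array([0.0, 0.0, 0.0])
    t0 = 0.0
    out = np.empty((t_grid.size, 3))
    served = np.zeros(t_grid.size, dtype=bool)
    # grid points that coincide with a dose time are served *before* the bolus
    for td in dose_times:
        pre = (t_grid <= td) & ~served
        if pre.any():
            out[pre] = _solve_segment(rhs, t0, y, t_grid[pre], params)
            served |= pre
        if td > t0:
            y = _solve_segment(rhs, t0, y, np.array([td]), params)[0]
            t0 = td
        y = y + np.array([regimen.dose, 0.0, 0.0])
    if not served.all():
        out[~served] = _solve_segment(rhs, t0, y, t_grid[~served], params)
    plasma = out[:, 1] / vc * MGL_TO_NGML
    milkc = out[:, 2] * MGL_TO_NGML
    return {"time": t_grid, "plasma": plasma, "milk": milkc}


def _solve_segment(rhs, t0, y0, t_eval, params):
    if t_eval.size == 0:
        return np.empty((0, 3))
    t_end = max(t_eval[-1], t0)
    if t_end == t0:
        return np.tile(y0, (t_eval.size, 1))
    sol = solve_ivp(
        rhs,
        (t0, t_end),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise NumericalError(f"ODE solver failed ({sol.message}) at params {params}")
    return sol.y.T


# ---------------------------------------------------------------------------
# individual parameters & residual error
# ---------------------------------------------------------------------------


def individual_params(theta: StructuralParams, eta) -> StructuralParams:
    """Apply exponential-model random effects (CL, Vc, Rcb order) to theta."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ParameterError("eta must be a finite 3-vector")
    return theta.replace(
        cl=theta.cl * float(np.exp(eta[0])),
        vc=theta.vc * float(np.exp(eta[1])),
        rcb=theta.rcb * float(np.exp(eta[2])),
    )


def apply_residual_error(pred, matrix, sigma, eps_draw):
    """Proportional residual error: observed = pred * (1 + eps).

    Parameters
    ----------
    pred : array-like, ng/mL, >= 0
    matrix : 'plasma' | 'milk'
    sigma : float or mapping matrix->float (proportional SD)
    eps_draw : standard-normal draw(s), scaled by sigma internally

    Returns (observed, blq_eligible) where negative realisations are
    truncated to 0 and flagged eligible for BLQ handling.
    """
    if matrix not in MATRICES:
        raise DataError(f"unknown matrix {matrix!r}")
    s = sigma[matrix] if isinstance(sigma, dict) else float(sigma)
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise DataError("pred must be >= 0")
    obs = pred * (1.0 + s * np.asarray(eps_draw, dtype=float))
    blq_eligible = obs < 0
    return np.where(blq_eligible, 0.0, obs), blq_eligible
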