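"""Goodness-of-fit residuals and prediction-corrected visual predictive checks.

CWRES follows the standard FOCE-based definition: each subject's
observation vector is linearised in the random effects at the empirical
Bayes mode, giving marginal mean  E_i = f_i(eta_hat) - J_i eta_hat  and
covariance  V_i = J_i Omega J_i' + diag(sd_i^2)  (interaction: the
proportional residual SD is evaluated at the conditional prediction);
CWRES_i = chol(V_i)^-1 (y_i - E_i).  Under a correctly specified model
these are approximately iid standard normal.

The pcVPC rescales every observation and simulation by
(bin median population prediction / record's population prediction),
removing design heterogeneity (two dose levels, two visits), then
compares observed percentiles per time bin with 90% confidence bands of
the same percentiles across simulated replicates of the study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .pk_model import MGL_TO_NGML, DataError, ParameterError

#: default time-bin edges (h), matched to the nominal sampling times
DEFAULT_BINS = (0.0, 1.0, 3.0, 6.0, 10.0, 14.0, 18.0, 24.0)

VPC_PERCENTILES = (5.0, 50.0, 95.0)


def cwres(table: pd.DataFrame, fit) -> pd.Series:
    """Conditional weighted residuals per maternal observation record.

    Returns a Series aligned with the rows of `table` that entered the
    likelihood; records in a subject whose linearised covariance is
    singular come back as NaN.
    """
    if not fit.converged:
        import warnings

        warnings.warn("CWRES from a non-converged fit", RuntimeWarning)
    eng = fit.engine
    x = eng._x_final
    th, Om, sig_pl, sig_mk, betas = eng.unpack(x)
    eta = _active_etas(fit, eng)
    f, sd, J = eng._linearize(th, betas, sig_pl, sig_mk, eta)
    d = eng.prep.obs
    r = d["y"] - f + np.sum(J * eta[d["subj"]], axis=1)
    out = np.full(eng.prep.n_obs, np.nan)
    for i in range(eng.prep.n_subj):
        m = d["subj"] == i
        Ji = J[m]
        V = Ji @ Om @ Ji.T + np.diag(sd[m] ** 2)
        try:
            L = np.linalg.cholesky(V)
            out[m] = solve_triangular(L, r[m], lower=True)
        except np.linalg.LinAlgError:
            continue  # flagged by NaN
    return pd.Series(out, index=d["frame"].index, name="CWRES")


def _active_etas(fit, eng) -> np.ndarray:
    """EBE matrix in the engine's eta-column order."""
    eta = np.zeros((eng.prep.n_subj, eng.q))
    ebe = fit.ebe.set_index("ID").reindex(eng.prep.ids)
    for name, col in eng.eta_cols.items():
        eta[:, col] = ebe[f"eta_{name}"].to_numpy()
    return eta


@dataclass
class VPCResult:
    """Numeric pcVPC summary (one row per matrix x time bin)."""

    stats: pd.DataFrame
    n_sim: int
    bin_edges: tuple
    pc_factors: pd.Series
    merged_bins: list


def pc_vpc(table: pd.DataFrame, fit, n_sim: int = 500, seed=0,
           bins=DEFAULT_BINS) -> VPCResult:
    """Prediction-corrected VPC of the fitted model, per matrix.

    Simulates `n_sim` replicates of the study at the estimated
    population parameters on the observed design, prediction-corrects
    observations and simulations by the bin-median population
    prediction, and summarises the 5th/50th/95th percentiles with 90%
    simulation bands.
    """
    if n_sim < 2:
        raise ParameterError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    eng = fit.engine
    x = eng._x_final
    th, Om, sig_pl, sig_mk, betas = eng.unpack(x)
    d = eng.prep.obs
    typ = eng._typ_rows(th, betas, "obs")
    pred = eng._pred(typ, None, "obs") * MGL_TO_NGML  # population prediction
    y_obs = d["y"] * MGL_TO_NGML
    t = d["t"]
    milk = d["milk"]

    edges, merged = _merge_empty_bins(np.asarray(bins, float), t)
    bin_id = np.clip(np.digitize(t, edges[1:-1]), 0, len(edges) - 2)

    # prediction-correction factors: bin-median PRED / record PRED
    pc = np.empty(len(t))
    for mk in (False, True):
        for b in range(len(edges) - 1):
            m = (milk == mk) & (bin_id == b)
            if m.any():
                pc[m] = np.median(pred[m]) / np.maximum(pred[m], 1e-12)
    pc_y = y_obs * pc

    # simulate replicates on the same design (batched over replicates)
    if eng.q:
        om_chol = np.linalg.cholesky(Om + 1e-300 * np.eye(eng.q))
        z = rng.standard_normal((n_sim, eng.prep.n_subj, eng.q))
        etas = z @ om_chol.T
        f_sim = eng._pred(typ, etas, "obs")
    else:
        f_sim = np.broadcast_to(pred / MGL_TO_NGML, (n_sim, len(t)))
    sig = np.where(milk, sig_mk, sig_pl)
    eps = rng.standard_normal((n_sim, len(t)))
    y_sim = np.maximum(f_sim * (1.0 + sig * eps), 0.0) * MGL_TO_NGML
    pc_sim = y_sim * pc

    rows = []
    for mk, label in ((False, "plasma"), (True, "milk")):
        for b in range(len(edges) - 1):
            m = (milk == mk) & (bin_id == b)
            if not m.any():
                continue
            obs_p = np.percentile(pc_y[m], VPC_PERCENTILES)
            sim_p = np.percentile(pc_sim[:, m], VPC_PERCENTILES, axis=1)  # (3, n_sim)
            lo = np.percentile(sim_p, 5.0, axis=1)
            hi = np.percentile(sim_p, 95.0, axis=1)
            med = np.percentile(sim_p, 50.0, axis=1)
            rows.append({
                "matrix": label, "bin": b,
                "t_lo": edges[b], "t_hi": edges[b + 1],
                "t_mid": 0.5 * (edges[b] + edges[b + 1]),
                "n_obs": int(m.sum()),
                "obs_p5": obs_p[0], "obs_p50": obs_p[1], "obs_p95": obs_p[2],
                "sim_p5_lo": lo[0], "sim_p5_med": med[0], "sim_p5_hi": hi[0],
                "sim_p50_lo": lo[1], "sim_p50_med": med[1], "sim_p50_hi": hi[1],
                "sim_p95_lo": lo[2], "sim_p95_med": med[2], "sim_p95_hi": hi[2],
            })
    stats = pd.DataFrame(rows)
    return VPCResult(stats, n_sim, tuple(edges), pd.Series(pc, index=d["frame"].index),
                     merged)


def _merge_empty_bins(edges: np.ndarray, t: np.ndarray):
    """Drop interior edges that would create empty bins (logged in result)."""
    edges = np.unique(edges)
    if len(edges) < 2:
        raise DataError("need at least two bin edges")
    merged = []
    changed = True
    while changed and len(edges) > 2:
        changed = False
        counts = np.histogram(t, bins=edges)[0]
        for b in range(len(counts)):
            if counts[b] == 0:
                drop = b if b > 0 else 1
                merged.append((edges[drop - 1] if drop else None, edges[drop]))
                edges = np.delete(edges, drop)
                changed = True
                break
    return edges, merged


def plot_vpc(vpc: VPCResult, path: str) -> None:
    """Two-panel pcVPC figure (plasma / milk) written to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
    for ax, label in zip(axes, ("plasma", "milk")):
        s = vpc.stats[vpc.stats["matrix"] == label]
        if len(s) == 0:
            continue
        tm = s["t_mid"]
        ax.fill_between(tm, s["sim_p5_lo"], s["sim_p5_hi"], alpha=0.25, color="tab:red")
        ax.fill_between(tm, s["sim_p50_lo"], s["sim_p50_hi"], alpha=0.25, color="tab:red")
        ax.fill_between(tm, s["sim_p95_lo"], s["sim_p95_hi"], alpha=0.25, color="tab:red")
        ax.plot(tm, s["sim_p50_med"], "r-", label="simulated median")
        ax.plot(tm, s["obs_p50"], "k-", label="observed median")
        ax.plot(tm, s["obs_p5"], "k--")
        ax.plot(tm, s["obs_p95"], "k--")
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("prediction-corrected concentration (ng/mL)")
        ax.set_title(label)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
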