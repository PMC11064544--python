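"""Model-evaluation operators: prediction-corrected VPC, NPDE and
goodness-of-fit summaries.

All three compare the observed event-record data against replicate datasets
simulated under the evaluated model with the real design (same subjects,
covariates and sampling times; fresh etas and residual draws).

pcVPC (Bergstrand-style): each observation and each simulated value is
rescaled by (bin median of typical predictions) / (subject's typical
prediction) before percentiles are formed, removing covariate-driven spread
from the comparison. Time bins default to quantile bins, merged when they
hold fewer than 10 observations.

NPDE: per subject, simulated observation vectors are used to estimate the
predictive mean and covariance; both observed and simulated vectors are
decorrelated with the simulated Cholesky factor, observations are ranked
among their simulated counterparts, and ranks map to standard-normal
quantiles. Under the true model the NPDE are approximately iid N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import _prepare, _Workspace
from .models import DrugModel, typical_params, _css1_kernel, _css2_kernel

__all__ = ["VpcResult", "NpdeResult", "pcvpc", "npde", "gof_table"]


@dataclass
class VpcResult:
    """Per-bin observed percentiles of prediction-corrected DV with
    simulation-based confidence intervals."""

    table: pd.DataFrame  # bin, t_mid, pctl, observed, ci_lo, ci_hi, n_obs
    bin_edges: np.ndarray
    n_sim: int


@dataclass
class NpdeResult:
    values: np.ndarray  # one per observation
    mean: float
    variance: float
    ks_statistic: float
    ks_pvalue: float
    ridged_subjects: int  # subjects needing a covariance ridge


def _typical_pred(model: DrugModel, ws: _Workspace) -> np.ndarray:
    typ = typical_params(model.fixed, ws.cov)
    s = ws.subj
    reg = model.regimen
    if model.n_compartments == 1:
        return _css1_kernel(reg.dose, reg.tau, typ["cl"][s], typ["v2"][s], typ["ka"][s], ws.t)
    return _css2_kernel(
        reg.dose, reg.tau, typ["cl"][s], typ["v2"][s], typ["v2"][s], typ["q"][s], typ["ka"][s], ws.t
    )


def _simulate_replicates(model: DrugModel, ws: _Workspace, n_sim: int, rng) -> np.ndarray:
    """(n_sim, n_obs) DV matrix under the model with the dataset's design."""
    typ = typical_params(model.fixed, ws.cov)
    re_ = model.random
    q = re_.n_eta
    n = ws.n
    s = ws.subj
    reg = model.regimen
    out = np.empty((n_sim, len(ws.t)))
    z = np.zeros(n)
    for r in range(n_sim):
        eta = rng.multivariate_normal(np.zeros(q), re_.omega_matrix(), size=n, method="eigh")
        cols = {name: eta[:, i] for i, name in enumerate(re_.eta_order)}
        cl = typ["cl"] * np.exp(cols.get("cl", z))
        v2 = typ["v2"] * np.exp(cols.get("v2", z))
        ka = typ["ka"] * np.exp(cols.get("ka", z))
        if model.n_compartments == 1:
            f = _css1_kernel(reg.dose, reg.tau, cl[s], v2[s], ka[s], ws.t)
        else:
            f = _css2_kernel(reg.dose, reg.tau, cl[s], v2[s], v2[s], typ["q"][s], ka[s], ws.t)
        ruv = np.exp(cols.get("ruv", z))[s]
        eps = rng.standard_normal(len(ws.t))
        out[r] = f * (1.0 + model.fixed.prop_error_sd * ruv * eps)
    return out


def _time_bins(t: np.ndarray, n_bins: int, min_per_bin: int = 10) -> np.ndarray:
    """Quantile-based bin edges, merging bins with too few observations."""
    qs = np.quantile(t, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) < 2:  # all observations share one time: a single bin
        edges = np.array([edges[0], edges[0]])
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        if counts.min() >= min_per_bin:
            break
        k = int(np.argmin(counts))
        drop = k + 1 if k < len(edges) - 2 else k
        edges = np.delete(edges, drop)
    return edges


def pcvpc(
    data: pd.DataFrame,
    model: DrugModel,
    n_sim: int = 200,
    bins: int = 8,
    seed=0,
    percentiles=(5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected visual predictive check."""
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile CIs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ws = _prepare(data)
    pred = _typical_pred(model, ws)
    edges = _time_bins(ws.t, bins)
    bin_idx = np.clip(np.searchsorted(edges, ws.t, side="right") - 1, 0, len(edges) - 2)

    # prediction correction: scale by bin-median PRED over subject's PRED
    bin_median_pred = np.array([np.median(pred[bin_idx == b]) for b in range(len(edges) - 1)])
    factor = bin_median_pred[bin_idx] / pred
    pc_obs = ws.y * factor

    sims = _simulate_replicates(model, ws, n_sim, rng) * factor[None, :]

    rows = []
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        if not np.any(sel):
            raise ValueError(f"empty time bin {b}")
        t_mid = float(np.median(ws.t[sel]))
        for p in percentiles:
            obs_p = float(np.percentile(pc_obs[sel], p))
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            lo, hi = np.percentile(sim_p, [2.5, 97.5])
            rows.append(
                {
                    "bin": b,
                    "t_mid": t_mid,
                    "pctl": p,
                    "observed": obs_p,
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                    "n_obs": int(sel.sum()),
                }
            )
    return VpcResult(table=pd.DataFrame(rows), bin_edges=edges, n_sim=n_sim)


def npde(data: pd.DataFrame, model: DrugModel, n_sim: int = 1000, seed=0) -> NpdeResult:
    """Normalised prediction distribution errors."""
    if n_sim < 500:
        raise ValueError("n_sim must be >= 500 for a stable decorrelation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ws = _prepare(data)
    sims = _simulate_replicates(model, ws, n_sim, rng)  # (K, n_obs)

    values = np.empty(len(ws.y))
    ridged = 0
    for i in range(ws.n):
        sel = ws.subj == i
        y = ws.y[sel]
        S = sims[:, sel]  # (K, m)
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            ridged += 1
            cov = cov + 1e-8 * np.eye(len(y)) * max(np.trace(cov) / len(y), 1e-12)
            L = np.linalg.cholesky(cov)
        y_dec = np.linalg.solve(L, y - mu)
        S_dec = np.linalg.solve(L, (S - mu).T).T  # (K, m)
        ranks = (S_dec < y_dec[None, :]).sum(axis=0)
        u = (ranks + 0.5) / (n_sim + 1.0)
        values[sel] = stats.norm.ppf(u)
    ks = stats.kstest(values, "norm")
    return NpdeResult(
        values=values,
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        ridged_subjects=ridged,
    )


def gof_table(data: pd.DataFrame, fit_result) -> pd.DataFrame:
    """Observed vs population/individual predictions with residuals.

    Returns one row per observation: PRED (typical prediction), IPRED
    (empirical-Bayes individual prediction), IWRES (individual weighted
    residual) and PWRES (population-standardized residual). The slope of the
    through-origin regression of DV on IPRED is attached as
    ``DataFrame.attrs["dv_ipred_slope"]``.
    """
    model = fit_result.model
    ws = _prepare(data)
    pred = _typical_pred(model, ws)

    order = [c[len("eta_"):] for c in fit_result.eta.columns if c.startswith("eta_")]
    eta = fit_result.eta[[f"eta_{n}" for n in order]].to_numpy()
    typ = typical_params(model.fixed, ws.cov)
    cols = {name: eta[:, i] for i, name in enumerate(order)}
    z = np.zeros(ws.n)
    cl = typ["cl"] * np.exp(cols.get("cl", z))
    v2 = typ["v2"] * np.exp(cols.get("v2", z))
    ka = typ["ka"] * np.exp(cols.get("ka", z))
    s = ws.subj
    reg = model.regimen
    if model.n_compartments == 1:
        ipred = _css1_kernel(reg.dose, reg.tau, cl[s], v2[s], ka[s], ws.t)
    else:
        ipred = _css2_kernel(reg.dose, reg.tau, cl[s], v2[s], v2[s], typ["q"][s], ka[s], ws.t)
    ruv = np.exp(cols.get("ruv", z))[s]
    sig_i = model.fixed.prop_error_sd * ruv * ipred
    iwres = np.where(sig_i > 0, (ws.y - ipred) / np.where(sig_i > 0, sig_i, 1.0), 0.0)
    sig_p = model.fixed.prop_error_sd * pred
    pwres = np.where(sig_p > 0, (ws.y - pred) / np.where(sig_p > 0, sig_p, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "ID": ws.ids[s],
            "TIME": ws.t,
            "DV": ws.y,
            "PRED": pred,
            "IPRED": ipred,
            "IWRES": iwres,
            "PWRES": pwres,
        }
    )
    denom = float(np.sum(ipred * ipred))
    out.attrs["dv_ipred_slope"] = float(np.sum(ws.y * ipred) / denom) if denom > 0 else np.nan
    return out
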