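"""Nonlinear mixed-effects estimation for the steady-state PK models.

The marginal likelihood is approximated per subject by a Laplace expansion
around the empirical Bayes mode of the random effects, with the residual
variance allowed to depend on the random effects ("with interaction"): for
subject i with eta ~ N(0, Omega) and observations y_ij,

    y_ij | eta ~ N( f_ij(eta), (sigma_prop * exp(eta_ruv) * f_ij(eta))^2 ),

    OFV_i = h_i(eta_hat) + log|Omega| + log|H_i| - q log 2,

where h_i(eta) = sum_j [log(2 pi s_ij^2) + (y_ij - f_ij)^2 / s_ij^2]
+ eta' Omega^-1 eta, eta_hat its minimizer and H_i its Hessian at the mode.
OFV differences between nested models are the covariate-selection statistic
(chi-square thresholds 6.63 / 10.83 for 1 d.f. at alpha = 0.01 / 0.001).

The optimizer works on transformed coordinates — log for positive
parameters (thetas, variances, the proportional-error magnitude),
identity for power exponents, atanh for the CL-V2 eta correlation — with
a quasi-Newton outer search and a damped-Newton inner search vectorized
across subjects. Standard errors come from a finite-difference Hessian of
the objective at the optimum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    CovariateTerm,
    DrugModel,
    FixedEffects,
    RandomEffectsSpec,
    typical_params,
    _css1_kernel,
    _css2_kernel,
)

__all__ = [
    "FitResult",
    "CovariateSearchResult",
    "BootstrapResult",
    "selection_thresholds",
    "ofv",
    "fit",
    "covariate_search",
    "bootstrap",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def selection_thresholds() -> tuple[float, float]:
    """(forward, backward) OFV-change thresholds: chi-square 1-d.f. quantiles
    at alpha = 0.01 and 0.001 (6.63 and 10.83 to printed precision)."""
    return (
        float(stats.chi2.ppf(0.99, 1)),
        float(stats.chi2.ppf(0.999, 1)),
    )


# ---------------------------------------------------------------------------
# dataset workspace
# ---------------------------------------------------------------------------


@dataclass
class _Workspace:
    t: np.ndarray  # (n_obs,) time after dose
    y: np.ndarray  # (n_obs,) DV
    subj: np.ndarray  # (n_obs,) subject row index 0..n-1
    ids: np.ndarray  # (n,) original IDs
    cov: pd.DataFrame  # per-subject baseline covariates
    n: int
    eta_cache: np.ndarray | None = None


def _prepare(data: pd.DataFrame) -> _Workspace:
    obs = data[(data["EVID"] == 0) & (data.get("BLQ", 0) == 0)]
    if obs["DV"].isna().any():
        raise ValueError("missing DV on observation rows")
    ids = np.array(sorted(data["ID"].unique()))
    counts = obs.groupby("ID").size()
    missing = [int(i) for i in ids if counts.get(i, 0) == 0]
    if missing:
        raise ValueError(f"subjects with no usable (non-BLQ) observations: {missing}")
    id_map = {sid: k for k, sid in enumerate(ids)}
    first = data.groupby("ID", as_index=False).first()
    first = first.set_index("ID").loc[ids].reset_index()
    drop = [c for c in ("WEEK", "TIME", "DV", "AMT", "EVID", "MDV", "BLQ", "DESIGN") if c in first]
    cov = first.drop(columns=drop)
    return _Workspace(
        t=obs["TIME"].to_numpy(dtype=float),
        y=obs["DV"].to_numpy(dtype=float),
        subj=obs["ID"].map(id_map).to_numpy(),
        ids=ids,
        cov=cov,
        n=len(ids),
    )


# ---------------------------------------------------------------------------
# conditional -2 log-likelihood and the Laplace objective
# ---------------------------------------------------------------------------


def _predict_obs(model: DrugModel, typ, ws: _Workspace, eta, order):
    """IPRED and residual SD for all observations given eta (n, q)."""
    # |eta| > 12 (a 160000-fold parameter shift) only arises from wild
    # optimizer excursions; clip to keep the arithmetic finite.
    eta = np.clip(eta, -12.0, 12.0)
    cols = {name: eta[:, i] for i, name in enumerate(order)}
    n = ws.n
    z = np.zeros(n)
    cl = typ["cl"] * np.exp(cols.get("cl", z))
    v2 = typ["v2"] * np.exp(cols.get("v2", z))
    ka = typ["ka"] * np.exp(cols.get("ka", z))
    s = ws.subj
    reg = model.regimen
    if model.n_compartments == 1:
        f = _css1_kernel(reg.dose, reg.tau, cl[s], v2[s], ka[s], ws.t)
    else:
        f = _css2_kernel(
            reg.dose, reg.tau, cl[s], v2[s], v2[s], typ["q"][s], ka[s], ws.t
        )
    ruv = np.exp(cols.get("ruv", z))[s]
    sig = model.fixed.prop_error_sd * ruv * np.abs(f)
    return f, sig


def _h_per_subject(model, typ, ws, eta, order, omega_inv):
    """h_i(eta): conditional -2 log-lik plus the eta quadratic form, per subject."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        f, sig = _predict_obs(model, typ, ws, eta, order)
        sig = np.maximum(sig, 1e-300)
        dev = _LOG2PI + 2.0 * np.log(sig) + ((ws.y - f) / sig) ** 2
        out = np.bincount(ws.subj, weights=np.nan_to_num(dev, nan=1e12, posinf=1e12), minlength=ws.n)
        out += np.einsum("ni,ij,nj->n", eta, omega_inv, eta)
    return out


def _fd_grad_hess(fun, eta, step=1e-4):
    """Central-difference gradient and Hessian of a vectorized per-subject
    objective, batched over subjects. eta: (n, q)."""
    n, q = eta.shape
    f0 = fun(eta)
    plus = np.empty((q, n))
    minus = np.empty((q, n))
    for k in range(q):
        d = np.zeros_like(eta)
        d[:, k] = step
        plus[k] = fun(eta + d)
        minus[k] = fun(eta - d)
    g = (plus - minus).T / (2.0 * step)
    H = np.empty((n, q, q))
    for k in range(q):
        H[:, k, k] = (plus[k] - 2.0 * f0 + minus[k]) / step**2
    for i in range(q):
        for j in range(i + 1, q):
            d1 = np.zeros_like(eta)
            d1[:, i] = step
            d2 = np.zeros_like(eta)
            d2[:, j] = step
            mixed = (
                fun(eta + d1 + d2) - fun(eta + d1 - d2) - fun(eta - d1 + d2) + fun(eta - d1 - d2)
            ) / (4.0 * step**2)
            H[:, i, j] = H[:, j, i] = mixed
    return f0, g, H


def _make_pd(H, floor=1e-8):
    """Eigenvalue-clip a batch of symmetric matrices to positive definite."""
    w, v = np.linalg.eigh(H)
    w = np.maximum(w, floor)
    return np.einsum("nik,nk,njk->nij", v, w, v), w


def _inner_laplace(model, typ, ws, order, omega, max_iter=60, gtol=1e-7):
    """Find per-subject eta modes and return (eta_hat, ofv_per_subject)."""
    n, q = ws.n, len(order)
    omega_inv = np.linalg.inv(omega)
    _, logdet_omega = np.linalg.slogdet(omega)

    def fun(eta):
        return _h_per_subject(model, typ, ws, eta, order, omega_inv)

    def newton(eta):
        eta = eta.copy()
        lam = np.full(n, 1e-6)
        g = None
        for _ in range(max_iter):
            f0, g, H = _fd_grad_hess(fun, eta)
            if np.max(np.abs(g)) < gtol:
                break
            Hpd, _ = _make_pd(H)
            Hd = Hpd + lam[:, None, None] * np.eye(q)[None]
            step_vec = -np.linalg.solve(Hd, g[..., None])[..., 0]
            cand = eta + step_vec
            h_new = fun(cand)
            better = h_new <= f0 + 1e-12
            eta[better] = cand[better]
            lam = np.where(better, np.maximum(lam / 4.0, 1e-10), lam * 10.0)
        return eta, fun(eta), g

    # warm start from the cached modes where they beat eta = 0 ...
    eta0 = np.zeros((n, q))
    if ws.eta_cache is not None and ws.eta_cache.shape == (n, q):
        use = fun(ws.eta_cache) < fun(eta0)
        eta0[use] = ws.eta_cache[use]
    eta, h0, g = newton(eta0)
    # ... but a poisoned cache can strand the iteration: re-solve any
    # unconverged subject from zero so the objective stays consistent
    if g is not None:
        stalled = np.max(np.abs(g), axis=1) > 1e-4
        if np.any(stalled):
            eta_r, h_r, _ = newton(np.where(stalled[:, None], 0.0, eta))
            better = h_r < h0
            eta[better] = eta_r[better]
            h0 = np.minimum(h0, h_r)
    # Hessian at the mode for the Laplace determinant
    _, _, G = _fd_grad_hess(fun, eta)
    Gpd, w = _make_pd(G, floor=1e-10)
    logdetG = np.sum(np.log(w), axis=1)
    ofv_i = h0 + logdet_omega + logdetG - q * np.log(2.0)
    ws.eta_cache = eta
    return eta, ofv_i


def _active_etas(model: DrugModel) -> tuple[str, ...]:
    re_ = model.random
    return tuple(name for name in re_.eta_order if re_.omega2[name] > 0)


def _active_omega(model: DrugModel, order) -> np.ndarray:
    re_ = model.random
    q = len(order)
    om = np.zeros((q, q))
    for i, name in enumerate(order):
        om[i, i] = re_.omega2[name]
    if re_.cov_cl_v2 and "cl" in order and "v2" in order:
        i, j = order.index("cl"), order.index("v2")
        om[i, j] = om[j, i] = re_.cov_cl_v2
    return om


def _ofv_workspace(model: DrugModel, ws: _Workspace) -> tuple[float, np.ndarray | None]:
    typ = typical_params(model.fixed, ws.cov)
    order = _active_etas(model)
    if not order:
        eta = np.zeros((ws.n, 0))
        f, sig = _predict_obs(model, typ, ws, eta, order)
        sig = np.maximum(sig, 1e-300)
        dev = _LOG2PI + 2.0 * np.log(sig) + ((ws.y - f) / sig) ** 2
        return float(np.sum(dev)), None
    omega = _active_omega(model, order)
    eta_hat, ofv_i = _inner_laplace(model, typ, ws, order, omega)
    return float(np.sum(ofv_i)), eta_hat


def ofv(data: pd.DataFrame, model: DrugModel) -> float:
    """-2 x approximate marginal log-likelihood of an event-record dataset
    under a model (BLQ rows excluded)."""
    value, _ = _ofv_workspace(model, _prepare(data))
    return value


# ---------------------------------------------------------------------------
# outer parameterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Param:
    name: str
    scale: str  # "log" | "identity" | "atanh"

    def to_internal(self, v: float) -> float:
        if self.scale == "log":
            return float(np.log(v))
        if self.scale == "atanh":
            return float(np.arctanh(v))
        return float(v)

    def to_natural(self, x: float) -> float:
        if self.scale == "log":
            return float(np.exp(x))
        if self.scale == "atanh":
            return float(np.tanh(x))
        return float(x)

    def se_natural(self, x: float, se_x: float) -> float:
        if self.scale == "log":
            return float(np.exp(x) * se_x)
        if self.scale == "atanh":
            return float((1.0 - np.tanh(x) ** 2) * se_x)
        return float(se_x)


def _default_free(model: DrugModel) -> list[str]:
    free = ["theta.cl", "theta.v2", "theta.ka"]
    if model.fixed.q_pop is not None:
        free.append("theta.q")
    for term in model.fixed.covariate_terms:
        if not term.fixed:
            free.append(f"beta.{term.target}:{term.covariate}")
    for name in model.random.eta_order:
        if model.random.omega2[name] > 0:
            free.append(f"omega2.{name}")
    order = _active_etas(model)
    if model.random.cov_cl_v2 and "cl" in order and "v2" in order:
        free.append("corr.cl_v2")
    free.append("sigma.prop")
    return free


def _param_spec(model: DrugModel, name: str) -> _Param:
    if name.startswith("beta."):
        target_cov = name[len("beta."):]
        tgt, covname = target_cov.split(":")
        for term in model.fixed.covariate_terms:
            if term.target == tgt and term.covariate == covname:
                return _Param(name, "log" if term.form == "categorical" else "identity")
        raise KeyError(f"no covariate term {name!r} in model")
    if name.startswith("corr."):
        return _Param(name, "atanh")
    return _Param(name, "log")


def _get_value(model: DrugModel, name: str) -> float:
    fx, re_ = model.fixed, model.random
    if name == "theta.cl":
        return fx.cl_pop
    if name == "theta.v2":
        return fx.v2_pop
    if name == "theta.ka":
        return fx.ka_pop
    if name == "theta.q":
        return fx.q_pop
    if name == "sigma.prop":
        return fx.prop_error_sd
    if name.startswith("omega2."):
        return re_.omega2[name.split(".", 1)[1]]
    if name == "corr.cl_v2":
        denom = np.sqrt(re_.omega2["cl"] * re_.omega2["v2"])
        return re_.cov_cl_v2 / denom if denom > 0 else 0.0
    if name.startswith("beta."):
        tgt, covname = name[len("beta."):].split(":")
        for term in fx.covariate_terms:
            if term.target == tgt and term.covariate == covname:
                return term.value
    raise KeyError(name)


def _set_values(model: DrugModel, values: dict[str, float]) -> DrugModel:
    fx, re_ = model.fixed, model.random
    fx_kwargs = {}
    for src, attr in (("theta.cl", "cl_pop"), ("theta.v2", "v2_pop"),
                      ("theta.ka", "ka_pop"), ("theta.q", "q_pop"),
                      ("sigma.prop", "prop_error_sd")):
        if src in values:
            fx_kwargs[attr] = values[src]
    terms = list(fx.covariate_terms)
    for i, term in enumerate(terms):
        key = f"beta.{term.target}:{term.covariate}"
        if key in values:
            terms[i] = replace(term, value=values[key])
    fx = replace(fx, covariate_terms=tuple(terms), **fx_kwargs)
    omega2 = dict(re_.omega2)
    for key, v in values.items():
        if key.startswith("omega2."):
            omega2[key.split(".", 1)[1]] = v
    cov = re_.cov_cl_v2
    if "corr.cl_v2" in values:
        cov = values["corr.cl_v2"] * np.sqrt(omega2["cl"] * omega2["v2"])
    re_ = RandomEffectsSpec(eta_order=re_.eta_order, omega2=omega2, cov_cl_v2=cov)
    return dataclasses.replace(model, fixed=fx, random=re_)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, precision and diagnostics of one NLME fit."""

    params: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    ofv: float
    converged: bool
    message: str
    model: DrugModel
    eta: pd.DataFrame  # empirical Bayes eta estimates per subject
    n_subjects: int
    n_obs: int
    n_function_evals: int = 0


def _fit_once(ws, model, params, x0, maxiter, ftol):
    spec = [_param_spec(model, p) for p in params]

    def build(x):
        values = {p.name: p.to_natural(xi) for p, xi in zip(spec, x)}
        return _set_values(model, values)

    evals = [0]

    def objective(x):
        evals[0] += 1
        try:
            m = build(x)
            val, _ = _ofv_workspace(m, ws)
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-6, "eps": 1e-5},
    )
    return res, build(res.x), evals[0]


def fit(
    data: pd.DataFrame,
    model: DrugModel,
    free: list[str] | None = None,
    fix: tuple[str, ...] = (),
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 200,
    ftol: float = 1e-10,
    jitter_sd: float = 0.1,
) -> FitResult:
    """Maximize the Laplace marginal likelihood over (theta, omega2, sigma).

    ``free`` names the estimated parameters (default: every structural theta,
    every non-allometric covariate value, every non-zero omega2, the CL-V2
    correlation when present, and the proportional-error magnitude); ``fix``
    removes names from that set. ``n_starts`` runs jittered multi-starts on
    the transformed scale and keeps the best optimum. Non-convergence is
    reported in the result, not raised.
    """
    ws = _prepare(data)
    params = [p for p in (free if free is not None else _default_free(model)) if p not in fix]
    spec = [_param_spec(model, p) for p in params]
    x_init = np.array([s.to_internal(_get_value(model, p)) for s, p in zip(spec, params)])

    rng = np.random.default_rng(seed)
    best = None
    best_model = None
    total_evals = 0
    for start in range(max(1, n_starts)):
        x0 = x_init if start == 0 else x_init + rng.normal(0.0, jitter_sd, len(x_init))
        ws.eta_cache = None
        res, m, nev = _fit_once(ws, model, params, x0, maxiter, ftol)
        total_evals += nev
        if best is None or res.fun < best.fun:
            best, best_model = res, m

    # precision: central-difference Hessian of the OFV at the optimum
    se_x = np.full(len(params), np.nan)
    try:
        H = _outer_hessian(
            lambda x: _fit_objective_value(ws, model, params, x), best.x
        )
        cov_x = 2.0 * np.linalg.inv(H)
        d = np.diag(cov_x)
        se_x = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass

    estimates = {p: s.to_natural(x) for p, s, x in zip(params, spec, best.x)}
    se = {p: s.se_natural(x, sx) for p, s, x, sx in zip(params, spec, best.x, se_x)}
    rse = {
        p: (100.0 * se[p] / abs(estimates[p]) if estimates[p] != 0 else np.nan)
        for p in params
    }
    _, eta_hat = _ofv_workspace(best_model, ws)
    order = _active_etas(best_model)
    eta_df = pd.DataFrame(
        {"ID": ws.ids, **{f"eta_{name}": (eta_hat[:, i] if eta_hat is not None else 0.0)
                          for i, name in enumerate(order)}}
    )
    if best.success:
        converged = True
    else:
        # line searches can terminate "abnormally" at machine precision;
        # accept if no coordinate perturbation improves the objective
        f0 = best.fun
        converged = True
        for i in range(len(best.x)):
            for sgn in (+1.0, -1.0):
                xp = best.x.copy()
                xp[i] += sgn * 1e-4
                if _fit_objective_value(ws, model, params, xp) < f0 - 0.05:
                    converged = False
                    break
            if not converged:
                break
    return FitResult(
        params=estimates,
        se=se,
        rse_percent=rse,
        ofv=float(best.fun),
        converged=bool(converged),
        message=str(best.message),
        model=best_model,
        eta=eta_df,
        n_subjects=ws.n,
        n_obs=len(ws.y),
        n_function_evals=total_evals,
    )


def _fit_objective_value(ws, model, params, x):
    spec = [_param_spec(model, p) for p in params]
    values = {p: s.to_natural(xi) for p, s, xi in zip(params, spec, x)}
    try:
        val, _ = _ofv_workspace(_set_values(model, values), ws)
    except (ValueError, np.linalg.LinAlgError):
        return 1e12
    return val if np.isfinite(val) else 1e12


def _outer_hessian(fun, x, step=1e-4):
    p = len(x)
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * step**2)
    return H


# ---------------------------------------------------------------------------
# covariate search
# ---------------------------------------------------------------------------


@dataclass
class CovariateSearchResult:
    steps: list[dict]
    final_model: DrugModel
    final_fit: FitResult | None
    retained: list[str]


def _candidate_with_reference(term: CovariateTerm, ws: _Workspace) -> CovariateTerm:
    if term.form == "power" and term.reference is None:
        med = float(np.median(ws.cov[term.covariate].to_numpy(dtype=float)))
        return replace(term, reference=med)
    return term


def covariate_search(
    data: pd.DataFrame,
    model: DrugModel,
    candidates: list[CovariateTerm],
    forward_dofv: float | None = None,
    backward_dofv: float | None = None,
    **fit_kwargs,
) -> CovariateSearchResult:
    """Greedy forward addition / backward elimination on OFV.

    Forward: at each round, fit every remaining candidate added to the
    current model; accept the largest OFV drop if it reaches the forward
    threshold (chi-square 1-d.f. at alpha = 0.01 by default). Power
    candidates without a reference are centered at the population median.
    Backward: from the full forward model, remove each estimated candidate
    term in turn; a term is dropped unless its removal worsens OFV by at
    least the backward threshold (alpha = 0.001 by default).
    """
    fwd_default, bwd_default = selection_thresholds()
    forward_dofv = fwd_default if forward_dofv is None else forward_dofv
    backward_dofv = bwd_default if backward_dofv is None else backward_dofv
    ws = _prepare(data)
    candidates = [_candidate_with_reference(c, ws) for c in candidates]

    steps: list[dict] = []

    def fit_model(m: DrugModel) -> FitResult:
        return fit(data, m, **fit_kwargs)

    def key(term: CovariateTerm) -> str:
        return f"{term.target}:{term.covariate}"

    if not candidates:
        return CovariateSearchResult(steps=[], final_model=model, final_fit=None, retained=[])

    current_fit = fit_model(model)
    current = current_fit.model  # carry fitted estimates forward
    remaining = list(candidates)
    added: list[str] = []
    while remaining:
        trials = []
        for cand in remaining:
            m = dataclasses.replace(
                current,
                fixed=replace(
                    current.fixed, covariate_terms=current.fixed.covariate_terms + (cand,)
                ),
            )
            fr = fit_model(m)
            dofv = current_fit.ofv - fr.ofv
            trials.append((dofv, cand, fr))
            steps.append(
                {
                    "phase": "forward",
                    "candidate": key(cand),
                    "delta_ofv": dofv,
                    "accepted": False,
                }
            )
        trials.sort(key=lambda tr: -tr[0])
        best_dofv, best_cand, best_fit_ = trials[0]
        if best_dofv >= forward_dofv:
            for s in steps[::-1]:
                if s["phase"] == "forward" and s["candidate"] == key(best_cand) and s["delta_ofv"] == best_dofv:
                    s["accepted"] = True
                    break
            current_fit = best_fit_
            current = best_fit_.model
            added.append(key(best_cand))
            remaining = [c for c in remaining if key(c) != key(best_cand)]
        else:
            break

    # backward elimination on the added terms
    changed = True
    while changed and added:
        changed = False
        worst = None
        for cand_key in added:
            terms = tuple(t for t in current.fixed.covariate_terms if key(t) != cand_key)
            m = dataclasses.replace(current, fixed=replace(current.fixed, covariate_terms=terms))
            fr = fit_model(m)
            dofv_removal = fr.ofv - current_fit.ofv
            steps.append(
                {
                    "phase": "backward",
                    "candidate": cand_key,
                    "delta_ofv": dofv_removal,
                    "accepted": dofv_removal >= backward_dofv,
                }
            )
            if dofv_removal < backward_dofv and (worst is None or dofv_removal < worst[0]):
                worst = (dofv_removal, cand_key, fr)
        if worst is not None:
            _, cand_key, fr = worst
            current_fit = fr
            current = fr.model
            added = [k for k in added if k != cand_key]
            changed = True

    return CovariateSearchResult(
        steps=steps,
        final_model=current,
        final_fit=current_fit,
        retained=list(added),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    estimates: pd.DataFrame  # one row per converged replicate
    median: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_replicates: int
    fraction_converged: float


def bootstrap(
    data: pd.DataFrame,
    model: DrugModel,
    n_replicates: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of a fit.

    Each replicate resamples subjects with replacement (preserving n),
    refits, and contributes its estimates; the summary is the per-parameter
    median and 2.5/97.5 percentiles over converged replicates.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    ids = sorted(data["ID"].unique())
    if len(ids) < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("n_starts", 1)
    rows = []
    n_conv = 0
    for rep in range(n_replicates):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(chosen, start=1):
            part = data[data["ID"] == sid].copy()
            part["ID"] = new_id
            parts.append(part)
        rep_data = pd.concat(parts, ignore_index=True)
        fr = fit(rep_data, model, seed=seed + rep + 1, **fit_kwargs)
        if fr.converged:
            n_conv += 1
            rows.append({"replicate": rep, **fr.params})
    est = pd.DataFrame(rows)
    pcols = [c for c in est.columns if c != "replicate"]
    med = {c: float(est[c].median()) for c in pcols}
    lo = {c: float(est[c].quantile(0.025)) for c in pcols}
    hi = {c: float(est[c].quantile(0.975)) for c in pcols}
    return BootstrapResult(
        estimates=est,
        median=med,
        ci_lower=lo,
        ci_upper=hi,
        n_replicates=n_replicates,
        fraction_converged=n_conv / n_replicates,
    )
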