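"""Final population-PK models for once-daily oral dolutegravir and lamivudine.

This module holds the structural and statistical pieces shared by every other
stage: covariate-to-parameter construction, steady-state closed-form
concentration prediction for one- and two-compartment models with first-order
absorption, the proportional residual-error model (whose magnitude itself
carries a subject-level random effect), and the log-normal variance
transforms.

Units follow the pharmacometric convention used throughout the package:
doses in mg, volumes in L, clearances in L/h, times in h — so a predicted
concentration amount/volume is in mg/L, identically ug/mL. Assay lower limits
of quantification quoted in ng/mL are stored converted (0.020 and
0.0025 ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CovariateTerm",
    "FixedEffects",
    "RandomEffectsSpec",
    "CovariateVector",
    "IndividualParameters",
    "DoseRegimen",
    "DrugModel",
    "load_model",
    "available_models",
    "build_individual_params",
    "typical_params",
    "css_one_compartment",
    "css_two_compartment",
    "predict_concentrations",
    "apply_residual_error",
    "iiv_percent_cv",
    "percent_cv_to_omega2",
    "covariate_effect_percent",
]

# Relative gap below which two first-order rate constants are treated as
# coincident and the analytic confluent (t * exp(-k t)) limit is used.
RATE_DEGENERACY_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate effect on a structural parameter.

    form "power": multiplier (x / reference) ** value, for continuous
    covariates centered at a reference value (e.g. weight 79 kg, bilirubin
    8 umol/L). ``fixed=True`` marks exponents pinned by allometric theory
    (0.75 on clearances, 1.0 on central volume) rather than estimated.

    form "categorical": multiplier value ** indicator for a 0/1 covariate,
    i.e. the ratio vs the reference category.
    """

    target: str
    covariate: str
    form: str  # "power" | "categorical"
    value: float
    reference: float | None = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("power", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power form requires a positive reference value")

    def multiplier(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "power":
            if np.any(x <= 0):
                raise ValueError(
                    f"non-positive value for power-form covariate {self.covariate!r}"
                )
            return (x / self.reference) ** self.value
        bad = ~np.isin(x, (0.0, 1.0))
        if np.any(bad):
            raise ValueError(
                f"categorical covariate {self.covariate!r} must be a 0/1 indicator"
            )
        return np.where(x > 0, self.value, 1.0)


@dataclass(frozen=True)
class FixedEffects:
    """Structural theta values plus covariate terms for one drug."""

    cl_pop: float
    v2_pop: float
    ka_pop: float
    q_pop: float | None = None
    v3_rule: str = "absent"  # "absent" | "equal_to_v2"
    covariate_terms: tuple[CovariateTerm, ...] = ()
    prop_error_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v2_pop", "ka_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.v3_rule not in ("absent", "equal_to_v2"):
            raise ValueError(f"unknown v3_rule {self.v3_rule!r}")
        if self.v3_rule == "equal_to_v2" and (self.q_pop is None or self.q_pop <= 0):
            raise ValueError("a peripheral compartment requires a positive q_pop")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Between-subject variance components (log-normal etas).

    ``eta_order`` lists which parameters carry an eta and fixes the layout of
    eta vectors everywhere: dolutegravir (cl, ruv); lamivudine (cl, v2, ruv)
    with (cl, v2) jointly normal using ``cov_cl_v2``. "ruv" is the eta on the
    magnitude of the proportional residual error.
    """

    eta_order: tuple[str, ...]
    omega2: Mapping[str, float]
    cov_cl_v2: float = 0.0

    def __post_init__(self) -> None:
        for name, w2 in self.omega2.items():
            if w2 < 0:
                raise ValueError(f"omega2[{name!r}] must be >= 0")
        for name in self.eta_order:
            if name not in self.omega2:
                raise ValueError(f"eta {name!r} has no omega2 entry")
        if self.cov_cl_v2 and not {"cl", "v2"} <= set(self.eta_order):
            raise ValueError("cov_cl_v2 given without both cl and v2 etas")
        if np.any(np.linalg.eigvalsh(self.omega_matrix()) < -1e-12):
            raise ValueError("omega matrix is not positive semi-definite")

    @property
    def n_eta(self) -> int:
        return len(self.eta_order)

    def omega_matrix(self) -> np.ndarray:
        q = self.n_eta
        om = np.zeros((q, q))
        for i, name in enumerate(self.eta_order):
            om[i, i] = self.omega2[name]
        if self.cov_cl_v2:
            i, j = self.eta_order.index("cl"), self.eta_order.index("v2")
            om[i, j] = om[j, i] = self.cov_cl_v2
        return om


@dataclass(frozen=True)
class CovariateVector:
    """One subject's baseline covariates.

    Continuous covariates must be positive; indicators are 0/1. ``extras``
    carries pass-through covariates (age, sex, creatinine clearance, smoking,
    CDC class, ...) used only when testing candidate covariate effects.
    """

    weight: float
    bilirubin: float = 8.0
    egfr: float = 99.0
    ethnicity: int = 0
    race_black: int = 0
    extras: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "weight": self.weight,
            "bilirubin": self.bilirubin,
            "egfr": self.egfr,
            "ethnicity": self.ethnicity,
            "race_black": self.race_black,
        }
        d.update(self.extras)
        return d


@dataclass(frozen=True)
class IndividualParameters:
    """Realized per-subject PK parameters after covariates and etas."""

    cl: float
    v2: float
    ka: float
    v3: float | None = None
    q: float | None = None
    f: float = 1.0
    ruv_scale: float = 1.0  # exp(eta_ruv), multiplies the residual magnitude

    def __post_init__(self) -> None:
        for name in ("cl", "v2", "ka", "f", "ruv_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if (self.v3 is None) != (self.q is None):
            raise ValueError("v3 and q must be given together")


@dataclass(frozen=True)
class DoseRegimen:
    dose: float  # mg
    tau: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.tau <= 0:
            raise ValueError("dose and tau must be positive")


@dataclass(frozen=True)
class DrugModel:
    """A complete model: fixed effects, random effects, regimen and LLOQ."""

    name: str
    n_compartments: int
    fixed: FixedEffects
    random: RandomEffectsSpec
    regimen: DoseRegimen
    lloq: float

    def with_fixed(self, fixed: FixedEffects) -> "DrugModel":
        return replace(self, fixed=fixed)


# ---------------------------------------------------------------------------
# model library I/O
# ---------------------------------------------------------------------------


def _model_from_dict(cfg: Mapping) -> DrugModel:
    theta = cfg["theta"]
    terms = tuple(
        CovariateTerm(
            target=t["target"],
            covariate=t["covariate"],
            form=t["form"],
            value=float(t["value"]),
            reference=float(t["reference"]) if "reference" in t else None,
            fixed=bool(t.get("fixed", False)),
        )
        for t in cfg.get("covariate_terms", ())
    )
    fixed = FixedEffects(
        cl_pop=float(theta["cl"]),
        v2_pop=float(theta["v2"]),
        ka_pop=float(theta["ka"]),
        q_pop=float(theta["q"]) if "q" in theta else None,
        v3_rule=cfg.get("v3_rule", "absent"),
        covariate_terms=terms,
        prop_error_sd=float(cfg["residual"]["proportional_sd"]),
    )
    re_cfg = cfg["random_effects"]
    random = RandomEffectsSpec(
        eta_order=tuple(re_cfg["eta_order"]),
        omega2={k: float(v) for k, v in re_cfg["omega2"].items()},
        cov_cl_v2=float(re_cfg.get("cov", {}).get("cl_v2", 0.0)),
    )
    return DrugModel(
        name=cfg["drug"],
        n_compartments=int(cfg["compartments"]),
        fixed=fixed,
        random=random,
        regimen=DoseRegimen(float(cfg["dose_mg"]), float(cfg["tau_h"])),
        lloq=float(cfg["lloq_ug_ml"]),
    )


_ALIASES = {"dtg": "dolutegravir", "3tc": "lamivudine"}


def available_models() -> list[str]:
    files = resources.files("dlpk.model_library")
    return sorted(p.name[: -len(".yaml")] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_model(name: str) -> DrugModel:
    """Load a shipped model definition ("dolutegravir"/"dtg", "lamivudine"/"3tc")
    by name, or any YAML model file by path."""
    key = _ALIASES.get(name.lower(), name.lower())
    try:
        text = resources.files("dlpk.model_library").joinpath(f"{key}.yaml").read_text()
    except FileNotFoundError:
        with open(name) as fh:
            text = fh.read()
    return _model_from_dict(yaml.safe_load(text))


def save_model(model: DrugModel, path: str) -> None:
    fx, re_ = model.fixed, model.random
    theta = {"cl": fx.cl_pop, "v2": fx.v2_pop, "ka": fx.ka_pop}
    if fx.q_pop is not None:
        theta["q"] = fx.q_pop
    cfg: dict = {
        "drug": model.name,
        "compartments": model.n_compartments,
        "dose_mg": model.regimen.dose,
        "tau_h": model.regimen.tau,
        "lloq_ug_ml": model.lloq,
        "theta": theta,
        "covariate_terms": [
            {
                "target": t.target,
                "covariate": t.covariate,
                "form": t.form,
                "value": t.value,
                **({"reference": t.reference} if t.reference is not None else {}),
                **({"fixed": True} if t.fixed else {}),
            }
            for t in fx.covariate_terms
        ],
        "random_effects": {
            "eta_order": list(re_.eta_order),
            "omega2": dict(re_.omega2),
            **({"cov": {"cl_v2": re_.cov_cl_v2}} if re_.cov_cl_v2 else {}),
        },
        "residual": {"proportional_sd": fx.prop_error_sd},
    }
    if fx.v3_rule != "absent":
        cfg["v3_rule"] = fx.v3_rule
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# covariate machinery
# ---------------------------------------------------------------------------


def _covariate_multipliers(fixed: FixedEffects, cov: Mapping[str, float]) -> dict[str, float]:
    mult = {"cl": 1.0, "v2": 1.0, "q": 1.0, "ka": 1.0}
    for term in fixed.covariate_terms:
        if term.covariate not in cov:
            raise KeyError(f"covariate {term.covariate!r} missing from covariate vector")
        mult[term.target] = mult[term.target] * float(term.multiplier(cov[term.covariate]))
    return mult


def typical_params(fixed: FixedEffects, cov_table) -> dict[str, np.ndarray]:
    """Vectorized typical-value (eta = 0) parameters for a covariate table.

    ``cov_table`` is a mapping of covariate name -> array (a pandas DataFrame
    works). Returns arrays for cl, v2, ka (and v3, q when present).
    """
    names = {t.covariate for t in fixed.covariate_terms}
    first = next(iter(names), None)
    if first is not None:
        n = len(np.asarray(cov_table[first]))
    elif hasattr(cov_table, "index"):
        n = len(cov_table.index)
    else:
        n = 1
    out = {
        "cl": np.full(n, fixed.cl_pop),
        "v2": np.full(n, fixed.v2_pop),
        "ka": np.full(n, fixed.ka_pop),
    }
    if fixed.q_pop is not None:
        out["q"] = np.full(n, fixed.q_pop)
    for term in fixed.covariate_terms:
        if term.target not in out:
            continue
        out[term.target] = out[term.target] * term.multiplier(np.asarray(cov_table[term.covariate], dtype=float))
    if fixed.v3_rule == "equal_to_v2":
        out["v3"] = out["v2"].copy()
    return out


def build_individual_params(
    fixed: FixedEffects,
    cov: CovariateVector | Mapping[str, float],
    eta: Sequence[float] | None = None,
    re_spec: RandomEffectsSpec | None = None,
) -> IndividualParameters:
    """Realize one subject's parameters from covariates and an eta vector.

    Each parameter is its structural theta times the product of its covariate
    multipliers, times exp(eta) where an eta applies (layout given by
    ``re_spec.eta_order``; defaults to (cl, ruv) for one-compartment models
    and (cl, v2, ruv) otherwise). ``eta=None`` means the typical subject.
    """
    if isinstance(cov, CovariateVector):
        cov = cov.as_dict()
    mult = _covariate_multipliers(fixed, cov)
    order = (
        re_spec.eta_order
        if re_spec is not None
        else (("cl", "ruv") if fixed.v3_rule == "absent" else ("cl", "v2", "ruv"))
    )
    if eta is None:
        eta = np.zeros(len(order))
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(order),):
        raise ValueError(f"eta must have length {len(order)} (order {order})")
    e = dict(zip(order, eta))
    cl = fixed.cl_pop * mult["cl"] * np.exp(e.get("cl", 0.0))
    v2 = fixed.v2_pop * mult["v2"] * np.exp(e.get("v2", 0.0))
    ka = fixed.ka_pop * mult["ka"] * np.exp(e.get("ka", 0.0))
    kwargs: dict = {}
    if fixed.v3_rule == "equal_to_v2":
        kwargs["v3"] = v2
        kwargs["q"] = fixed.q_pop * mult["q"]
    return IndividualParameters(
        cl=cl, v2=v2, ka=ka, ruv_scale=float(np.exp(e.get("ruv", 0.0))), **kwargs
    )


# ---------------------------------------------------------------------------
# steady-state closed forms
# ---------------------------------------------------------------------------
#
# Superposition of first-order absorption profiles at steady state puts an
# accumulation factor 1/(1 - exp(-lambda*tau)) on every exponential term:
#     g_lambda(t) = exp(-lambda t) / (1 - exp(-lambda tau)).
# When two rate constants coincide the partial-fraction coefficients blow up
# pairwise; the analytic confluent limit replaces the pair with the
# derivative  -d/dlambda [rho(lambda) g_lambda(t)]  which brings in the
# t*exp(-lambda t) term — no parameter perturbation needed.


def _g(lam, t, tau):
    return np.exp(-lam * t) / (-np.expm1(-lam * tau))


def _dg_dlam(lam, t, tau):
    # d/dlam of g_lambda(t) = -g * (t + tau*exp(-lam*tau)/(1-exp(-lam*tau)))
    r = np.exp(-lam * tau)
    return -_g(lam, t, tau) * (t + tau * r / (1.0 - r))


def _css1_kernel(dose, tau, cl, v, ka, t):
    dose, tau, cl, v, ka, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dose, tau, cl, v, ka, t))
    )
    shp = t.shape
    dose, tau, cl, v, ka, t = (np.ravel(x) for x in (dose, tau, cl, v, ka, t))
    k = cl / v
    out = np.empty(k.shape)
    degen = np.abs(ka - k) <= RATE_DEGENERACY_TOL * k
    ok = ~degen
    if np.any(ok):
        coef = dose[ok] * ka[ok] / (v[ok] * (ka[ok] - k[ok]))
        out[ok] = coef * (_g(k[ok], t[ok], tau[ok]) - _g(ka[ok], t[ok], tau[ok]))
    if np.any(degen):
        kd = k[degen]
        td, taud = t[degen], tau[degen]
        r = np.exp(-kd * taud)
        out[degen] = (
            dose[degen] * kd / v[degen]
            * _g(kd, td, taud)
            * (td + taud * r / (1.0 - r))
        )
    return out.reshape(shp)


def _css2_kernel(dose, tau, cl, v2, v3, q, ka, t):
    dose, tau, cl, v2, v3, q, ka, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dose, tau, cl, v2, v3, q, ka, t))
    )
    shp = t.shape
    dose, tau, cl, v2, v3, q, ka, t = (
        np.ravel(x) for x in (dose, tau, cl, v2, v3, q, ka, t)
    )
    k10 = cl / v2
    k23 = q / v2
    k32 = q / v3
    # vanishing peripheral exchange: exact one-compartment collapse
    tiny = (k23 < 1e-14) | (k32 < 1e-14)
    s = k10 + k23 + k32
    prod = k10 * k32
    disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = np.where(alpha > 0, prod / np.where(alpha > 0, alpha, 1.0), 0.0)
    coef = dose * ka / v2

    out = np.empty(k10.shape)
    lams = np.stack([alpha, beta, ka])  # (3, ...)

    def pairgap(i, j):
        return np.abs(lams[i] - lams[j]) / np.maximum(lams[i], lams[j])

    gaps = np.stack([pairgap(0, 1), pairgap(0, 2), pairgap(1, 2)])
    pair = np.argmin(gaps, axis=0)
    mingap = np.min(gaps, axis=0)
    degen = (mingap <= RATE_DEGENERACY_TOL) & ~tiny
    ok = ~degen & ~tiny

    if np.any(ok):
        a, b, kA = alpha[ok], beta[ok], ka[ok]
        k32o, to, tauo = k32[ok], t[ok], tau[ok]
        term = (
            (k32o - a) / ((b - a) * (kA - a)) * _g(a, to, tauo)
            + (k32o - b) / ((a - b) * (kA - b)) * _g(b, to, tauo)
            + (k32o - kA) / ((a - kA) * (b - kA)) * _g(kA, to, tauo)
        )
        out[ok] = coef[ok] * term
    if np.any(degen):
        # for each degenerate entry: the coincident pair (l1~l2) and the third
        pairsets = {0: (0, 1, 2), 1: (0, 2, 1), 2: (1, 2, 0)}
        for p, (i1, i2, i3) in pairsets.items():
            sel = degen & (pair == p)
            if not np.any(sel):
                continue
            lbar = 0.5 * (lams[i1][sel] + lams[i2][sel])
            l3 = lams[i3][sel]
            k32s, ts, taus = k32[sel], t[sel], tau[sel]
            third = (k32s - l3) / ((lams[i1][sel] - l3) * (lams[i2][sel] - l3)) * _g(l3, ts, taus)
            confl = -(
                (k32s - l3) / (l3 - lbar) ** 2 * _g(lbar, ts, taus)
                + (k32s - lbar) / (l3 - lbar) * _dg_dlam(lbar, ts, taus)
            )
            out[sel] = coef[sel] * (third + confl)
    if np.any(tiny):
        out[tiny] = _css1_kernel(dose[tiny], tau[tiny], cl[tiny], v2[tiny], ka[tiny], t[tiny])
    return out.reshape(shp)


def css_one_compartment(p: IndividualParameters, reg: DoseRegimen, t):
    """Steady-state concentration (ug/mL) of the one-compartment oral model
    at time ``t`` (h) within a dosing interval, for repeated dosing every
    ``reg.tau`` h. Scalar or array ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > reg.tau):
        raise ValueError("t must lie within [0, tau]")
    out = _css1_kernel(reg.dose * p.f, reg.tau, p.cl, p.v2, p.ka, t_arr)
    return out if out.shape else float(out)


def css_two_compartment(p: IndividualParameters, reg: DoseRegimen, t):
    """Steady-state central-compartment concentration (ug/mL) of the
    two-compartment oral model, via micro-constants k10 = CL/V2, k23 = Q/V2,
    k32 = Q/V3 and hybrid roots alpha/beta."""
    if p.v3 is None or p.q is None:
        raise ValueError("two-compartment prediction requires v3 and q")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > reg.tau):
        raise ValueError("t must lie within [0, tau]")
    out = _css2_kernel(reg.dose * p.f, reg.tau, p.cl, p.v2, p.v3, p.q, p.ka, t_arr)
    return out if out.shape else float(out)


def predict_concentrations(model: DrugModel, p: IndividualParameters, t, reg: DoseRegimen | None = None):
    """Dispatch to the drug's closed form (1- or 2-compartment)."""
    reg = reg or model.regimen
    if model.n_compartments == 1:
        return css_one_compartment(p, reg, t)
    return css_two_compartment(p, reg, t)


# ---------------------------------------------------------------------------
# residual error and variance transforms
# ---------------------------------------------------------------------------


def apply_residual_error(ipred, prop_sd: float, ruv_scale=1.0, epsilon=0.0):
    """Proportional residual-error model Y = IPRED * (1 + prop_sd * ruv_scale * eps).

    ``ruv_scale`` is the subject's exp(eta_ruv); ``epsilon`` a standard-normal
    draw. Large negative draws can yield negative Y; those are retained (BLQ
    flagging happens downstream), preserving the error distribution.
    """
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be non-negative")
    out = ipred * (1.0 + prop_sd * np.asarray(ruv_scale) * np.asarray(epsilon))
    return out if out.shape else float(out)


def iiv_percent_cv(omega2) -> float:
    """Percent coefficient of variation of a log-normal random effect:
    100 * sqrt(exp(omega2) - 1)."""
    omega2 = np.asarray(omega2, dtype=float)
    if np.any(omega2 < 0):
        raise ValueError("omega2 must be >= 0")
    out = 100.0 * np.sqrt(np.expm1(omega2))
    return out if out.shape else float(out)


def percent_cv_to_omega2(cv_percent) -> float:
    """Inverse of :func:`iiv_percent_cv`."""
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    out = np.log1p(cv * cv)
    return out if out.shape else float(out)


def covariate_effect_percent(
    form: str,
    covariate_value: float | None = None,
    reference: float | None = None,
    exponent_or_ratio: float = 1.0,
) -> float:
    """Percent change of a parameter vs its reference subject.

    power: 100 * ((x / reference) ** exponent - 1);
    categorical: 100 * (ratio - 1).
    """
    if form == "power":
        if covariate_value is None or covariate_value <= 0:
            raise ValueError("power form requires a positive covariate value")
        return 100.0 * ((covariate_value / reference) ** exponent_or_ratio - 1.0)
    if form == "categorical":
        return 100.0 * (exponent_or_ratio - 1.0)
    raise ValueError(f"unknown form {form!r}")
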