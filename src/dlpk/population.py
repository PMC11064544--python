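"""Virtual-population generator.

Emulates the phase-3 switch-study PK substudy population that the models were
built on: 361 virologically suppressed adults on once-daily dolutegravir
50 mg / lamivudine 300 mg, with baseline covariates calibrated to the
published demographic summary (medians, ranges and category proportions),
an intensive serial-sampling subset of 30 participants, and sparse sampling
windows at the remaining visits. Simulated observations carry the model's
between-subject variability and proportional residual error and are flagged
below the assay LLOQ.

Continuous covariates are drawn from truncated log-normal distributions
calibrated so the sample median sits at the published median and every value
lies inside the published range (treated as the approximate min/max of a
sample of 361, i.e. ~±2.7 SD on the log scale). Covariate correlations are
not imposed, except that body-surface area is computed from weight and height
(DuBois) rather than drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    DoseRegimen,
    DrugModel,
    typical_params,
    _css1_kernel,
    _css2_kernel,
)

__all__ = [
    "PopulationSpec",
    "SamplingSchedule",
    "draw_covariates",
    "assign_schedules",
    "simulate_dataset",
    "simulate_population",
    "INTENSIVE_TIMES",
    "SPARSE_VISITS",
]

#: serial-sampling grid at week 4 (h post-dose) for the intensive subset
INTENSIVE_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 10.0, 24.0)

#: sparse visit plan: week -> list of (lo, hi) windows in h post-dose.
#: week 8 and 12 each use one of the two windows (1-4 h / 4-12 h), the
#: pairing alternating between subjects; weeks 24/36/48 are pre-dose draws.
SPARSE_VISITS: dict[int, tuple] = {
    4: ((0.0, 0.0), (1.0, 1.0)),
    8: "window_pair",
    12: "window_pair",
    24: ((0.0, 0.0),),
    36: ((0.0, 0.0),),
    48: ((0.0, 0.0),),
}
_WINDOW_PAIR = ((1.0, 4.0), (4.0, 12.0))

# published demographic summary: name -> (median, min, max)
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float]] = {
    "age": (40.0, 20.0, 74.0),
    "weight": (78.8, 50.2, 153.0),
    "height": (176.5, 150.0, 195.6),
    "bilirubin": (8.0, 2.0, 34.0),
    "albumin": (45.0, 37.0, 53.0),
    "creatinine": (0.96, 0.52, 1.69),
    "egfr": (99.0, 44.0, 147.0),
    "crcl": (113.9, 56.3, 355.9),
}

# name -> probability of the indicator being 1
BINARY_COVARIATES: dict[str, float] = {
    "sex_male": 0.931,
    "race_black": 0.135,
    "ethnicity": 0.193,  # 1 = Hispanic/Latino
}

# multinomial label covariates (labels only; no PK effect)
LABEL_COVARIATES: dict[str, dict[str, float]] = {
    "smoking": {"never": 0.497, "former": 0.188, "current": 0.315},
    "cdc_class": {"1": 0.688, "2": 0.260, "3": 0.052},
}

#: span of the published range in ±SD units on the log scale
RANGE_SD_SPAN = 2.7


@dataclass(frozen=True)
class PopulationSpec:
    """Configuration of the virtual population (defaults = study conditions)."""

    n_subjects: int = 361
    n_intensive: int = 30
    continuous: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(CONTINUOUS_COVARIATES)
    )
    binary: Mapping[str, float] = field(default_factory=lambda: dict(BINARY_COVARIATES))
    labels: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in LABEL_COVARIATES.items()}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.n_intensive <= self.n_subjects:
            raise ValueError("need 0 <= n_intensive <= n_subjects")
        for name, (med, lo, hi) in self.continuous.items():
            if not lo <= med <= hi or lo <= 0:
                raise ValueError(f"infeasible range for {name!r}: median outside range")
        for name, p in self.binary.items():
            if not 0 <= p <= 1:
                raise ValueError(f"proportion for {name!r} outside [0, 1]")


@dataclass(frozen=True)
class SamplingSchedule:
    """One subject's sampling design."""

    subject: int
    design: str  # "intensive" | "sparse"
    weeks: tuple[int, ...]
    times: tuple[float, ...]  # actual h post-dose, aligned with weeks


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_trunc_lognormal(median, lo, hi, n, rng):
    if lo == hi:
        return np.full(n, float(lo))
    mu = np.log(median)
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * RANGE_SD_SPAN)
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = stats.truncnorm.rvs(a, b, size=n, random_state=rng)
    return np.exp(mu + sigma * z)


def draw_covariates(spec: PopulationSpec, seed=0) -> pd.DataFrame:
    """Draw a baseline covariate table (one row per subject).

    Continuous covariates: truncated log-normal per the published
    median/range; binary: Bernoulli at the published proportion; labels:
    categorical at the published proportions. Body-surface area is derived
    from weight and height via DuBois (0.007184 * W^0.425 * H^0.725).
    """
    rng = _rng(seed)
    n = spec.n_subjects
    data: dict = {"ID": np.arange(1, n + 1)}
    for name, (med, lo, hi) in spec.continuous.items():
        data[name] = _draw_trunc_lognormal(med, lo, hi, n, rng)
    for name, p in spec.binary.items():
        data[name] = (rng.random(n) < p).astype(int)
    for name, probs in spec.labels.items():
        cats = list(probs)
        pr = np.array([probs[c] for c in cats], dtype=float)
        pr = pr / pr.sum()
        drawn = rng.choice(cats, size=n, p=pr)
        if all(str(c).isdigit() for c in cats):  # numeric labels survive CSV round trips as ints
            drawn = drawn.astype(int)
        data[name] = drawn
    df = pd.DataFrame(data)
    if {"weight", "height"} <= set(df.columns):
        df["bsa"] = 0.007184 * df["weight"] ** 0.425 * df["height"] ** 0.725
    return df


def assign_schedules(n_subjects: int, n_intensive: int = 30, seed=0) -> list[SamplingSchedule]:
    """Assign per-subject sampling designs.

    Exactly ``n_intensive`` randomly chosen subjects receive the 10-point
    serial grid at week 4; every subject receives the sparse plan (week-4
    pre-dose/1 h for sparse-only subjects, the week-8/12 window pair
    alternated between subjects, pre-dose at weeks 24/36/48). Actual times in
    windows are uniform draws.
    """
    if n_intensive > n_subjects:
        raise ValueError("n_intensive cannot exceed n_subjects")
    rng = _rng(seed)
    intensive_ids = set(rng.choice(np.arange(1, n_subjects + 1), size=n_intensive, replace=False))
    schedules = []
    for sid in range(1, n_subjects + 1):
        weeks: list[int] = []
        times: list[float] = []
        intensive = sid in intensive_ids
        if intensive:
            weeks += [4] * len(INTENSIVE_TIMES)
            times += list(INTENSIVE_TIMES)
        else:
            for lo, hi in SPARSE_VISITS[4]:
                weeks.append(4)
                times.append(lo if lo == hi else float(rng.uniform(lo, hi)))
        flip = sid % 2  # alternate the week-8/12 window pairing
        for wk, win in ((8, _WINDOW_PAIR[flip]), (12, _WINDOW_PAIR[1 - flip])):
            weeks.append(wk)
            times.append(float(rng.uniform(*win)))
        for wk in (24, 36, 48):
            weeks.append(wk)
            times.append(0.0)
        schedules.append(
            SamplingSchedule(
                subject=sid,
                design="intensive" if intensive else "sparse",
                weeks=tuple(weeks),
                times=tuple(times),
            )
        )
    return schedules


def simulate_dataset(
    model: DrugModel,
    covariates: pd.DataFrame,
    schedules: list[SamplingSchedule],
    seed=0,
    regimen: DoseRegimen | None = None,
    lloq: float | None = None,
) -> pd.DataFrame:
    """Simulate an estimation-ready event-record dataset for one drug.

    Per subject: draw the eta vector (jointly normal per the model's omega
    block), realize individual parameters, evaluate the steady-state closed
    form at each scheduled time, apply proportional residual error, and flag
    DV below the LLOQ as BLQ (MDV=1). Dose rows (EVID=1) precede each visit's
    observations. TIME is time after dose within the visit's dosing interval.
    """
    rng = _rng(seed)
    regimen = regimen or model.regimen
    lloq = model.lloq if lloq is None else lloq
    re_spec = model.random
    q = re_spec.n_eta
    n = len(covariates)
    if {s.subject for s in schedules} != set(covariates["ID"]):
        raise ValueError("schedules and covariate table refer to different subjects")

    omega = re_spec.omega_matrix()
    etas = rng.multivariate_normal(np.zeros(q), omega, size=n, method="eigh")
    eta_cols = {name: etas[:, i] for i, name in enumerate(re_spec.eta_order)}

    typ = typical_params(model.fixed, covariates)
    cl = typ["cl"] * np.exp(eta_cols.get("cl", 0.0))
    v2 = typ["v2"] * np.exp(eta_cols.get("v2", 0.0))
    ka = typ["ka"] * np.exp(eta_cols.get("ka", 0.0))
    ruv_scale = np.exp(eta_cols.get("ruv", np.zeros(n)))

    id_to_row = {sid: i for i, sid in enumerate(covariates["ID"])}

    # lay out dose + observation rows, then predict in one vectorized pass
    rows_id, rows_wk, rows_t, rows_evid, rows_design, rows_subj = [], [], [], [], [], []
    for sched in schedules:
        i = id_to_row[sched.subject]
        for wk in sorted(set(sched.weeks)):
            rows_id.append(sched.subject); rows_wk.append(wk); rows_t.append(0.0)
            rows_evid.append(1); rows_design.append(sched.design); rows_subj.append(i)
            wk_times = sorted(t for w, t in zip(sched.weeks, sched.times) if w == wk)
            for t in wk_times:
                rows_id.append(sched.subject); rows_wk.append(wk); rows_t.append(float(t))
                rows_evid.append(0); rows_design.append(sched.design); rows_subj.append(i)

    evid = np.asarray(rows_evid)
    subj = np.asarray(rows_subj)
    t_arr = np.asarray(rows_t)
    obs = evid == 0
    io = subj[obs]
    if model.n_compartments == 1:
        ipred = _css1_kernel(regimen.dose, regimen.tau, cl[io], v2[io], ka[io], t_arr[obs])
    else:
        ipred = _css2_kernel(
            regimen.dose, regimen.tau, cl[io], v2[io], v2[io], typ["q"][io], ka[io], t_arr[obs]
        )
    eps = rng.standard_normal(obs.sum())
    dv_obs = ipred * (1.0 + model.fixed.prop_error_sd * ruv_scale[io] * eps)

    dv = np.full(len(evid), np.nan)
    dv[obs] = dv_obs
    blq = np.zeros(len(evid), dtype=int)
    blq[obs] = (dv_obs < lloq).astype(int)
    df = pd.DataFrame(
        {
            "ID": rows_id,
            "WEEK": rows_wk,
            "TIME": t_arr,
            "DV": dv,
            "AMT": np.where(evid == 1, regimen.dose, 0.0),
            "EVID": evid,
            "MDV": np.where(evid == 1, 1, blq),
            "BLQ": blq,
            "DESIGN": rows_design,
        }
    )
    cov_cols = [c for c in covariates.columns if c != "ID"]
    for c in cov_cols:
        df[c] = covariates[c].to_numpy()[subj]
    return df.reset_index(drop=True)


def simulate_population(
    model: DrugModel,
    spec: PopulationSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: covariates + schedules + simulated observations.

    Splits the seed into independent streams for the three stages so that
    e.g. the same covariate table can be re-paired with new observations.
    """
    spec = spec or PopulationSpec()
    ss = np.random.SeedSequence(seed)
    r_cov, r_sched, r_obs = (np.random.default_rng(s) for s in ss.spawn(3))
    cov = draw_covariates(spec, r_cov)
    sched = assign_schedules(spec.n_subjects, spec.n_intensive, r_sched)
    return simulate_dataset(model, cov, sched, r_obs)
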