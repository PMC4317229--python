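"""Synthetic cynomolgus-monkey study generator.

Emulates a five-study preclinical program (labels A–E): two single-dose
PK/PD studies, a two-dose toxicology study, and two GLP toxicology studies
with weekly dosing, totalling 119 actively treated animals (73 males, 46
females), IV/SC doses from 0.01 to 80 mg/kg, and ~1700 concentration
observations.  The generator reproduces the statistical structure the
population analysis assumes:

* lognormal interindividual variability on CL, Vc and Rtot with a CL–Vc
  correlation,
* proportional + additive residual error,
* assay censoring at a study-specific LLOQ (2 or 20 ng/mL),
* empirical anti-drug-antibody (ADA) contamination: a dose-dependent
  fraction of animals develops accelerated clearance from a random onset
  time (none at the 80 mg/kg dose level), and
* a two-step exclusion filter (ADA positivity, then a fold-deviation rule
  standing in for visual curation).

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelVariant, PKParameters
from .simulate import solve_population
from .units import (
    DEFAULT_DRUG,
    DrugProperties,
    Route,
    molar_to_ngml,
    ngml_to_molar,
)

__all__ = [
    "IIVSpec",
    "ResidualErrorSpec",
    "AdaSpec",
    "DoseGroup",
    "StudyDesign",
    "StudyDataset",
    "BodyWeightSummary",
    "packaged_designs",
    "sample_individuals",
    "apply_residual_error",
    "censor_lloq",
    "generate_dataset",
    "exclude_ada_points",
    "vpc_percentiles",
]


@dataclass(frozen=True)
class IIVSpec:
    """Lognormal interindividual variability, as CV fractions.

    The log-scale variance of a parameter is ln(1 + CV^2); CL and Vc etas
    are correlated.  Parameters without IIV are fixed at the typical value.
    """

    omega_cl: float = 0.441
    omega_vc: float = 0.461
    omega_rtot: float = 1.80
    corr_cl_vc: float = 0.642
    omega_ka: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_vc", "omega_rtot", "omega_ka"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.corr_cl_vc <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")

    def log_cov_cl_vc(self) -> np.ndarray:
        """2x2 log-scale covariance of (eta_CL, eta_Vc)."""
        s1 = np.sqrt(np.log1p(self.omega_cl**2))
        s2 = np.sqrt(np.log1p(self.omega_vc**2))
        cov = np.array(
            [[s1 * s1, self.corr_cl_vc * s1 * s2], [self.corr_cl_vc * s1 * s2, s2 * s2]]
        )
        if np.linalg.eigvalsh(cov)[0] < -1e-12:
            raise ValueError("CL-Vc covariance not positive semi-definite")
        return cov


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Proportional + additive residual error: DV = C*(1+e1) + e2."""

    proportional_cv: float = 0.201
    additive_sd: float = 1.11  # nmol/L

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("error components must be >= 0")


@dataclass(frozen=True)
class AdaSpec:
    """Empirical ADA model: selected animals switch to CL * multiplier at
    an onset time drawn uniformly on [onset_lo, onset_hi] days.  The
    affected fraction depends on the dose level; animals at >= 80 mg/kg
    never seroconvert."""

    clearance_multiplier: float = 2.2
    onset_lo: float = 14.0
    onset_hi: float = 28.0
    fraction_low: float = 0.8  # dose < 5 mg/kg
    fraction_mid: float = 0.5  # 5-20 mg/kg
    fraction_high: float = 0.0  # >= 80 mg/kg

    def __post_init__(self) -> None:
        if self.clearance_multiplier <= 1:
            raise ValueError("clearance multiplier must be > 1")

    def affected_fraction(self, dose_mg_per_kg: float) -> float:
        if dose_mg_per_kg < 5.0:
            return self.fraction_low
        if dose_mg_per_kg <= 20.0:
            return self.fraction_mid
        return self.fraction_high


@dataclass(frozen=True)
class BodyWeightSummary:
    """Lognormal body-weight distribution truncated to the observed range."""

    median: float = 2.8
    low: float = 2.1
    high: float = 6.4
    log_sd: float = 0.30


@dataclass(frozen=True)
class DoseGroup:
    dose_mg_per_kg: float
    route: Route
    n_animals: int
    n_males: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class StudyDesign:
    """One study: dose groups, dosing schedule, sampling days and LLOQ."""

    label: str
    groups: tuple[DoseGroup, ...]
    n_doses: int
    interval_days: float
    sampling_days: tuple[float, ...]
    lloq_ng_ml: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(
            self, "sampling_days", tuple(float(t) for t in self.sampling_days)
        )

    @property
    def n_treated(self) -> int:
        return sum(g.n_animals for g in self.groups)

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(k * self.interval_days for k in range(self.n_doses))


def packaged_designs() -> tuple[StudyDesign, ...]:
    """The five packaged monkey study designs (treated groups only).

    Group structure, dose levels, routes and LLOQs follow the study
    program; the sampling days are calibrated stand-ins (the true
    schedules are not public) chosen to give ~1700 observations in total:
    dense first-dose sampling, weekly/biweekly troughs during repeated
    dosing, and a washout tail.
    """
    single = (0.25, 1, 2, 4, 7, 10, 14, 21, 28, 42, 56, 70, 84)
    return (
        StudyDesign(
            label="A",
            groups=(
                DoseGroup(0.01, Route.IV, 3, 3),
                DoseGroup(0.1, Route.IV, 3, 3),
                DoseGroup(0.3, Route.IV, 3, 3),
                DoseGroup(3.0, Route.IV, 3, 3),
                DoseGroup(3.0, Route.SC, 3, 3),
            ),
            n_doses=1,
            interval_days=7.0,
            sampling_days=single,
            lloq_ng_ml=2.0,
        ),
        StudyDesign(
            label="B",
            groups=(
                DoseGroup(0.5, Route.SC, 8, 4),
                DoseGroup(80.0, Route.SC, 8, 4),
            ),
            n_doses=2,
            interval_days=7.0,
            sampling_days=(0.25, 1, 2, 4, 7, 8, 10, 14, 21, 28, 42, 56, 70),
            lloq_ng_ml=2.0,
        ),
        StudyDesign(
            label="C",
            groups=(
                DoseGroup(9.0, Route.IV, 6, 6),
                DoseGroup(9.0, Route.SC, 6, 6),
            ),
            n_doses=1,
            interval_days=7.0,
            sampling_days=single,
            lloq_ng_ml=2.0,
        ),
        StudyDesign(
            label="D",
            groups=(
                DoseGroup(5.0, Route.SC, 12, 6),
                DoseGroup(20.0, Route.SC, 12, 6),
                DoseGroup(80.0, Route.SC, 12, 6),
                DoseGroup(80.0, Route.IV, 12, 6),
            ),
            n_doses=13,
            interval_days=7.0,
            sampling_days=(0.25, 1, 2, 4, 7, 14, 28, 42, 56, 70, 84, 91, 98, 112, 126),
            lloq_ng_ml=20.0,
        ),
        StudyDesign(
            label="E",
            groups=(
                DoseGroup(20.0, Route.SC, 14, 7),
                DoseGroup(80.0, Route.SC, 14, 7),
            ),
            n_doses=24,
            interval_days=7.0,
            sampling_days=(
                0.25, 1, 2, 4, 7, 14, 28, 56, 84, 112, 140, 161, 168, 182, 210, 238,
            ),
            lloq_ng_ml=20.0,
        ),
    )


DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "ROUTE", "BW",
    "STUDY", "GROUP", "DOSE_MGKG", "LLOQ", "BLQ", "ADA", "EXCL", "EXPECTED",
]


@dataclass
class StudyDataset:
    """Rectangular record set: one row per dose event (EVID=1) or
    observation (EVID=0).  DV and EXPECTED are in nmol/L; AMT in mg; BW in
    kg.  EXPECTED carries the ADA-free model expectation used by the
    exclusion filter."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    @property
    def observations(self) -> pd.DataFrame:
        return self.table[self.table["EVID"] == 0]

    @property
    def modelling_view(self) -> pd.DataFrame:
        """Quantifiable, non-excluded observations (M1 BLQ handling)."""
        obs = self.observations
        return obs[(obs["MDV"] == 0) & (obs["BLQ"] == 0) & (obs["EXCL"] == 0)]

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.table.copy())


def sample_individuals(
    n: int,
    typical: PKParameters,
    iiv: IIVSpec,
    bw: BodyWeightSummary = BodyWeightSummary(),
    rng: np.random.Generator | int = 0,
) -> tuple[list[PKParameters], np.ndarray]:
    """Draw individual parameter sets and body weights.

    theta_i = theta * exp(eta_i) with eta multivariate normal: variances
    ln(1 + CV^2), CL–Vc correlated, Rtot (and optionally KA) independent.
    Body weights are lognormal around the median, truncated to the
    observed range by resampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cov = iiv.log_cov_cl_vc()
    eta_clvc = (
        rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
        if cov.any()
        else np.zeros((n, 2))
    )
    s_rtot = np.sqrt(np.log1p(iiv.omega_rtot**2))
    s_ka = np.sqrt(np.log1p(iiv.omega_ka**2))
    eta_rtot = rng.normal(0.0, s_rtot, size=n) if s_rtot > 0 else np.zeros(n)
    eta_ka = rng.normal(0.0, s_ka, size=n) if s_ka > 0 else np.zeros(n)

    weights = np.empty(n)
    mu = np.log(bw.median)
    for i in range(n):
        w = rng.lognormal(mu, bw.log_sd)
        while not (bw.low <= w <= bw.high):
            w = rng.lognormal(mu, bw.log_sd)
        weights[i] = w

    individuals = [
        typical.replace(
            cl=typical.cl * np.exp(eta_clvc[i, 0]),
            vc=typical.vc * np.exp(eta_clvc[i, 1]),
            rtot=typical.rtot * np.exp(eta_rtot[i]),
            ka=typical.ka * np.exp(eta_ka[i]),
        )
        for i in range(n)
    ]
    return individuals, weights


def apply_residual_error(
    true_conc: np.ndarray,
    spec: ResidualErrorSpec,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """DV = C*(1+e1) + e2 with e1 ~ N(0, cv^2), e2 ~ N(0, sd^2).

    Negative draws are floored at zero; returns (dv, floored_flag).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    e1 = rng.normal(0.0, spec.proportional_cv, size=c.shape)
    e2 = rng.normal(0.0, spec.additive_sd, size=c.shape)
    dv = c * (1.0 + e1) + e2
    floored = dv < 0.0
    return np.where(floored, 0.0, dv), floored


def censor_lloq(dataset: StudyDataset, lloq_ng_ml: Optional[float] = None) -> StudyDataset:
    """Flag observations with DV below the LLOQ as BLQ and remove them from
    the modelling view (MDV=1).  With ``lloq_ng_ml=None`` the per-row LLOQ
    column (study-specific) is used.  The strictly-below rule applies."""
    out = dataset.copy()
    tab = out.table
    obs = tab["EVID"] == 0
    lloq = tab["LLOQ"] if lloq_ng_ml is None else float(lloq_ng_ml)
    if np.any(np.asarray(lloq) <= 0):
        raise ValueError("LLOQ must be positive")
    dv_ngml = molar_to_ngml(tab["DV"].fillna(0.0).to_numpy())
    blq = obs & (dv_ngml < np.asarray(lloq))
    tab.loc[blq, "BLQ"] = 1
    tab.loc[blq, "MDV"] = 1
    return out


def _simulate_group(
    individuals: Sequence[PKParameters],
    weights: np.ndarray,
    group: DoseGroup,
    design: StudyDesign,
    cl_multipliers: Optional[np.ndarray] = None,
    cl_switch_times: Optional[np.ndarray] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> np.ndarray:
    """Noise-free concentrations (n, n_times) at the design sampling days."""
    n = len(individuals)
    amounts = np.outer(weights, [group.dose_mg_per_kg] * design.n_doses)
    cf, _ = solve_population(
        list(individuals),
        design.dose_times,
        amounts,
        [group.route] * design.n_doses,
        np.asarray(design.sampling_days, dtype=float),
        variant=ModelVariant.QE,
        cl_multipliers=cl_multipliers,
        cl_switch_times=cl_switch_times,
        rtol=rtol,
        atol=atol,
    )
    return cf


def generate_dataset(
    designs: Sequence[StudyDesign] | None = None,
    typical: PKParameters | None = None,
    iiv: IIVSpec | None = None,
    resid: ResidualErrorSpec | None = None,
    ada: AdaSpec | None = AdaSpec(),
    bw: BodyWeightSummary = BodyWeightSummary(),
    seed: int = 0,
    drug: DrugProperties = DEFAULT_DRUG,
) -> StudyDataset:
    """Generate the full synthetic program (or a subset of designs).

    Returns a NONMEM-style dataset with dose and observation rows, BLQ
    censoring applied, ADA flags set from each animal's onset time, and
    the ADA-free expectation in EXPECTED.  Pass ``ada=None`` to disable
    ADA contamination.  Deterministic given (designs, seed).
    """
    from .params import monkey_parameters  # local import to avoid cycle

    designs = tuple(designs) if designs is not None else packaged_designs()
    typical = typical or monkey_parameters()
    iiv = iiv if iiv is not None else IIVSpec()
    resid = resid if resid is not None else ResidualErrorSpec()
    rng = np.random.default_rng(seed)

    rows = []
    next_id = 1
    for design in designs:
        for gi, group in enumerate(design.groups):
            inds, weights = sample_individuals(group.n_animals, typical, iiv, bw, rng)
            n = group.n_animals
            if ada is not None:
                frac = ada.affected_fraction(group.dose_mg_per_kg)
                affected = rng.random(n) < frac
                onsets = rng.uniform(ada.onset_lo, ada.onset_hi, size=n)
            else:
                affected = np.zeros(n, dtype=bool)
                onsets = np.full(n, np.inf)
            expected = _simulate_group(inds, weights, group, design)
            if affected.any():
                mult = np.where(affected, ada.clearance_multiplier, 1.0)
                switch = np.where(affected, onsets, np.inf)
                # re-simulate the whole group with per-animal CL switches
                truth = _simulate_group(
                    inds, weights, group, design,
                    cl_multipliers=mult,
                    cl_switch_times=np.where(np.isfinite(switch), switch, 1e9),
                )
            else:
                truth = expected
            dv, _ = apply_residual_error(truth, resid, rng)
            samp = np.asarray(design.sampling_days)
            for i in range(n):
                aid = next_id
                next_id += 1
                for td in design.dose_times:
                    rows.append(
                        dict(
                            ID=aid, TIME=td, AMT=group.dose_mg_per_kg * weights[i],
                            DV=np.nan, EVID=1, MDV=1, ROUTE=group.route.value,
                            BW=weights[i], STUDY=design.label, GROUP=gi,
                            DOSE_MGKG=group.dose_mg_per_kg, LLOQ=design.lloq_ng_ml,
                            BLQ=0, ADA=0, EXCL=0, EXPECTED=np.nan,
                        )
                    )
                for j, tt in enumerate(samp):
                    rows.append(
                        dict(
                            ID=aid, TIME=tt, AMT=np.nan, DV=dv[i, j], EVID=0, MDV=0,
                            ROUTE=group.route.value, BW=weights[i],
                            STUDY=design.label, GROUP=gi,
                            DOSE_MGKG=group.dose_mg_per_kg, LLOQ=design.lloq_ng_ml,
                            BLQ=0, ADA=int(affected[i] and tt >= onsets[i]),
                            EXCL=0, EXPECTED=expected[i, j],
                        )
                    )
    tab = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    tab = tab.sort_values(["STUDY", "ID", "TIME", "EVID"], kind="stable")
    tab = tab.reset_index(drop=True)
    return censor_lloq(StudyDataset(tab))


def simulate_ada_impact(
    dataset: StudyDataset,
    onset_window: tuple[float, float] = (14.0, 28.0),
    clearance_multiplier: float = 2.2,
    affected_fraction_by_dose: Optional[dict] = None,
    seed: int = 0,
) -> StudyDataset:
    """Overlay ADA-accelerated clearance onto an ADA-free dataset.

    For each selected animal (sampled per dose level; by default none at
    >= 80 mg/kg), post-onset concentrations are re-simulated from the
    EXPECTED column's generating model with CL multiplied, and the ADA
    flag is set from the onset time.  This is a convenience wrapper for
    datasets generated with ``ada=None``; :func:`generate_dataset` applies
    the same mechanism inline.
    """
    if clearance_multiplier <= 1:
        raise ValueError("clearance multiplier must be > 1")
    spec = AdaSpec(
        clearance_multiplier=clearance_multiplier,
        onset_lo=onset_window[0],
        onset_hi=onset_window[1],
    )
    if affected_fraction_by_dose:
        # keys: thresholds "low" (<5), "mid" (5-20), "high" (>=80)
        spec = replace(
            spec,
            fraction_low=affected_fraction_by_dose.get("low", spec.fraction_low),
            fraction_mid=affected_fraction_by_dose.get("mid", spec.fraction_mid),
            fraction_high=affected_fraction_by_dose.get("high", spec.fraction_high),
        )
    from .params import monkey_parameters

    rng = np.random.default_rng(seed)
    typical = monkey_parameters()
    out = dataset.copy()
    tab = out.table
    for aid, sub in tab.groupby("ID"):
        obs = sub[sub["EVID"] == 0]
        doses = sub[sub["EVID"] == 1]
        if obs.empty or doses.empty:
            continue
        dose = float(obs["DOSE_MGKG"].iloc[0])
        if rng.random() >= spec.affected_fraction(dose):
            continue
        onset = rng.uniform(spec.onset_lo, spec.onset_hi)
        post = obs[obs["TIME"] >= onset]
        if post.empty:
            continue
        tab.loc[post.index, "ADA"] = 1
        # re-simulate this animal's regimen with the typical model, with
        # and without the CL switch, and rescale the observed values by
        # the simulated post-onset ratio
        dt = doses["TIME"].to_numpy()
        amts = doses["AMT"].to_numpy()[None, :]
        routes = [Route(r) for r in doses["ROUTE"]]
        t_obs = obs["TIME"].to_numpy()
        cf_free, _ = solve_population(
            [typical], dt, amts, routes, t_obs, rtol=1e-7, atol=1e-9
        )
        cf_ada, _ = solve_population(
            [typical], dt, amts, routes, t_obs,
            cl_multipliers=np.array([spec.clearance_multiplier]),
            cl_switch_times=np.array([onset]),
            rtol=1e-7, atol=1e-9,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cf_free[0] > 0, cf_ada[0] / np.maximum(cf_free[0], 1e-300), 1.0)
        sel = t_obs >= onset
        tab.loc[obs.index[sel], "DV"] = obs["DV"].to_numpy()[sel] * ratio[sel]
    return censor_lloq(out)


def exclude_ada_points(
    dataset: StudyDataset, deviation_threshold: float = 3.0
) -> tuple[StudyDataset, dict]:
    """Two-step exclusion filter.

    A quantifiable observation is excluded iff it is ADA-positive AND the
    observed value falls more than ``deviation_threshold``-fold below the
    model expectation (the reproducible surrogate for visual curation).
    Idempotent.  Returns the filtered dataset and a report with counts and
    the excluded fraction of all observation rows.
    """
    if deviation_threshold <= 0:
        raise ValueError("deviation threshold must be positive")
    out = dataset.copy()
    tab = out.table
    obs = tab["EVID"] == 0
    if tab.loc[obs & (tab["ADA"] == 1), "EXPECTED"].isna().any():
        raise ValueError("ADA-positive rows lack EXPECTED model concentrations")
    quantifiable = obs & (tab["BLQ"] == 0)
    with np.errstate(invalid="ignore"):
        deviant = tab["DV"] < tab["EXPECTED"] / deviation_threshold
    excl = quantifiable & (tab["ADA"] == 1) & deviant.fillna(False)
    tab["EXCL"] = 0
    tab.loc[excl, "EXCL"] = 1
    n_obs = int(obs.sum())
    n_excl = int(excl.sum())
    report = {
        "n_observations": n_obs,
        "n_ada_positive": int((obs & (tab["ADA"] == 1)).sum()),
        "n_excluded": n_excl,
        "fraction_excluded": n_excl / n_obs if n_obs else 0.0,
        "percent_excluded": 100.0 * n_excl / n_obs if n_obs else 0.0,
    }
    return out, report


def vpc_percentiles(
    typical: PKParameters,
    iiv: IIVSpec,
    resid: ResidualErrorSpec,
    design: StudyDesign,
    n_reps: int = 400,
    seed: int = 0,
    bw: BodyWeightSummary = BodyWeightSummary(),
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
    lloq_ng_ml: Optional[float] = None,
    min_quantifiable: int = 40,
) -> pd.DataFrame:
    """Visual-predictive-check bands for one study design.

    Simulates ``n_reps`` replicate datasets (IIV + residual error, no ADA)
    and returns, per dose group and nominal sampling time, the requested
    percentiles of the simulated observations pooled over replicates and
    animals.  With ``lloq_ng_ml`` the percentiles are conditional on
    quantifiability (simulated values below the limit are discarded, and
    rows with fewer than ``min_quantifiable`` remaining samples are
    omitted) — the right comparison basis for observed data that were
    themselves censored at the assay limit.  Deterministic given the seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    lloq_nm = ngml_to_molar(lloq_ng_ml) if lloq_ng_ml is not None else None
    rng = np.random.default_rng(seed)
    samp = np.asarray(design.sampling_days, dtype=float)
    sims = {gi: [] for gi in range(len(design.groups))}
    for _ in range(n_reps):
        for gi, group in enumerate(design.groups):
            inds, weights = sample_individuals(group.n_animals, typical, iiv, bw, rng)
            truth = _simulate_group(inds, weights, group, design)
            dv, _ = apply_residual_error(truth, resid, rng)
            sims[gi].append(dv)
    records = []
    for gi, group in enumerate(design.groups):
        pooled = np.concatenate(sims[gi], axis=0)  # (n_reps*n_animals, n_times)
        for j, tt in enumerate(samp):
            col = pooled[:, j]
            if lloq_nm is not None:
                col = col[col >= lloq_nm]
                if len(col) < min_quantifiable:
                    continue
            qs = np.percentile(col, percentiles)
            records.append(
                dict(
                    study=design.label,
                    group=gi,
                    dose_mg_per_kg=group.dose_mg_per_kg,
                    route=group.route.value,
                    time=tt,
                    p10=qs[0],
                    p50=qs[1],
                    p90=qs[2],
                )
            )
    return pd.DataFrame.from_records(records)
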