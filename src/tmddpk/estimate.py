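"""Population parameter estimation and PD (Emax) fitting.

The reference PK estimator is naive-pooled maximum likelihood: all
quantifiable, non-excluded observations are fit simultaneously with the
typical-value model under a proportional + additive normal error model,
with structural parameters estimated on the log scale.  A mixed-effects
stage adds lognormal interindividual variability on CL, Vc and Rtot via
per-individual MAP (empirical-Bayes) etas and an EM-type update of the
random-effect covariance, Omega = mean(eta eta' + H^-1), where H is the
Hessian of each individual's penalized objective — the Laplace-type
conditional approximation.  Standard errors come from the inverse observed
information (finite-difference Hessian of the pooled log-likelihood).

The PD side is an inhibitory Emax model E = E0*(1 - Emax*C/(EC50 + C)) for
free-receptor fluorescence intensity versus drug concentration, with the
ECp algebra ECp = EC50*p/(100-p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ModelVariant, PKParameters
from .simulate import solve_population
from .synthetic import IIVSpec, StudyDataset
from .units import Route

__all__ = [
    "FitResult",
    "EmaxParameters",
    "fit_pk_pooled",
    "fit_pk_mixed",
    "fit_emax",
    "ecp",
    "internalization_half_life",
]

ESTIMABLE = ("ka", "cl", "vc", "k12", "k21", "kd", "rtot", "kint")
FIT_RTOL = 1e-6
FIT_ATOL = 1e-8


@dataclass
class FitResult:
    """Estimation output: point estimates, precision, diagnostics."""

    estimates: PKParameters
    sigma_prop: float
    sigma_add: float
    objective: float
    converged: bool
    n_obs: int
    message: str = ""
    percent_se: dict = field(default_factory=dict)
    omegas: Optional[dict] = None  # CV-scale IIV estimates (mixed fit)
    corr_cl_vc: Optional[float] = None
    shrinkage: Optional[dict] = None
    individual_etas: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "estimates": self.estimates.to_dict(),
            "sigma_prop": self.sigma_prop,
            "sigma_add": self.sigma_add,
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "percent_se": self.percent_se,
        }
        if self.omegas is not None:
            out["omegas"] = self.omegas
            out["corr_cl_vc"] = self.corr_cl_vc
            out["shrinkage"] = self.shrinkage
        return out


@dataclass(frozen=True)
class EmaxParameters:
    """Inhibitory Emax model parameters.

    e0: baseline effect (MFI units); emax: maximal fractional suppression
    of baseline (0..1); ec50: concentration at half-maximal effect, µg/mL.
    """

    e0: float
    emax: float
    ec50: float

    def __post_init__(self) -> None:
        if self.e0 <= 0:
            raise ValueError("e0 must be positive")
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError("emax must be in [0, 1]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")

    def effect(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.e0 * (1.0 - self.emax * c / (self.ec50 + c))


# ---------------------------------------------------------------------------
# dataset -> batched prediction structure
# ---------------------------------------------------------------------------


@dataclass
class _Batch:
    dose_times: tuple
    routes: tuple
    amounts: np.ndarray  # (n, n_doses)
    times: np.ndarray  # union of observation times, sorted
    y: np.ndarray  # (n, nt) observed DV, NaN where absent
    ids: list

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)


def _build_batches(dataset: StudyDataset) -> list[_Batch]:
    view = dataset.modelling_view
    tab = dataset.table
    per_key: dict = {}
    for aid, sub in tab.groupby("ID", sort=True):
        doses = sub[sub["EVID"] == 1].sort_values("TIME")
        obs = view[view["ID"] == aid].sort_values("TIME")
        if doses.empty or obs.empty:
            continue
        key = (
            tuple(np.round(doses["TIME"].to_numpy(), 9)),
            tuple(doses["ROUTE"]),
        )
        per_key.setdefault(key, []).append(
            (aid, doses["AMT"].to_numpy(), obs["TIME"].to_numpy(), obs["DV"].to_numpy())
        )
    batches = []
    for (dt, routes), animals in per_key.items():
        times = np.unique(np.concatenate([a[2] for a in animals]))
        n = len(animals)
        y = np.full((n, len(times)), np.nan)
        amounts = np.zeros((n, len(dt)))
        ids = []
        for i, (aid, amt, t_obs, dv) in enumerate(animals):
            amounts[i] = amt
            idx = np.searchsorted(times, t_obs)
            y[i, idx] = dv
            ids.append(aid)
        batches.append(
            _Batch(
                dose_times=dt,
                routes=tuple(Route(r) for r in routes),
                amounts=amounts,
                times=times,
                y=y,
                ids=ids,
            )
        )
    return batches


def _predict_batch(
    p_list: Sequence[PKParameters], batch: _Batch, variant, rtol=FIT_RTOL, atol=FIT_ATOL
) -> np.ndarray:
    cf, _ = solve_population(
        list(p_list),
        batch.dose_times,
        batch.amounts,
        batch.routes,
        batch.times,
        variant=variant,
        rtol=rtol,
        atol=atol,
    )
    return cf


def _nll(obs: np.ndarray, pred: np.ndarray, sp: float, sa: float) -> float:
    v = (sp * pred) ** 2 + sa**2
    v = np.maximum(v, 1e-300)
    r = obs - pred
    return float(0.5 * np.sum(r * r / v + np.log(2.0 * np.pi * v)))


def fit_pk_pooled(
    dataset: StudyDataset,
    variant: ModelVariant | str = ModelVariant.QE,
    init: Optional[PKParameters] = None,
    fixed: Sequence[str] = ("kd",),
    estimate_sigma: bool = True,
    sigma_init: tuple[float, float] = (0.2, 1.0),
    compute_se: bool = False,
    maxiter: int = 200,
) -> FitResult:
    """Naive-pooled maximum-likelihood fit of the structural model.

    Structural parameters (all of KA, CL, Vc, K12, K21, Kd, Rtot, Kint
    except those in ``fixed``; Kd is fixed by default, F1 always) are
    estimated on the log scale with L-BFGS-B.  Residual-error parameters
    are co-estimated unless ``estimate_sigma=False``.  %SE (from the
    inverse observed information, computed by central finite differences)
    is reported when ``compute_se=True``.
    """
    if init is None:
        raise ValueError("initial parameter values are required")
    variant = ModelVariant(variant)
    batches = _build_batches(dataset)
    n_obs = int(sum(b.mask.sum() for b in batches))
    if n_obs == 0:
        raise ValueError("no quantifiable observations to fit")

    names = [n for n in ESTIMABLE if n not in set(fixed)]
    x0 = np.log([getattr(init, n) for n in names])
    if estimate_sigma:
        x0 = np.concatenate([x0, np.log(sigma_init)])

    def unpack(x):
        p = init.replace(**{n: float(np.exp(v)) for n, v in zip(names, x[: len(names)])})
        if estimate_sigma:
            sp, sa = np.exp(x[len(names) :])
        else:
            sp, sa = sigma_init
        return p, sp, sa

    def objective(x):
        total = 0.0
        try:
            p, sp, sa = unpack(x)
            for b in batches:
                pred = _predict_batch([p] * len(b.ids), b, variant)
                m = b.mask
                total += _nll(b.y[m], pred[m], sp, sa)
        except Exception:
            return 1e12
        if not np.isfinite(total):
            return 1e12
        return total

    bounds = [(v - 12.0, v + 12.0) for v in x0]
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6, "eps": 1e-5},
    )
    p_hat, sp_hat, sa_hat = unpack(res.x)

    pct_se: dict = {}
    if compute_se:
        hess = _fd_hessian(objective, res.x)
        try:
            cov = np.linalg.inv(hess)
            sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
            labels = names + (["sigma_prop", "sigma_add"] if estimate_sigma else [])
            pct_se = {n: 100.0 * s for n, s in zip(labels, sd_log)}
        except np.linalg.LinAlgError:
            pct_se = {}

    return FitResult(
        estimates=p_hat,
        sigma_prop=sp_hat,
        sigma_add=sa_hat,
        objective=float(res.fun),
        converged=bool(res.success),
        n_obs=n_obs,
        message=str(res.message),
        percent_se=pct_se,
    )


def _fd_hessian(f, x, eps=1e-4) -> np.ndarray:
    k = len(x)
    h = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


# ---------------------------------------------------------------------------
# mixed-effects (MAP etas + EM omega update)
# ---------------------------------------------------------------------------


def _omega_from_iiv(iiv: IIVSpec, effects: Sequence[str]) -> np.ndarray:
    var = {
        "cl": np.log1p(iiv.omega_cl**2),
        "vc": np.log1p(iiv.omega_vc**2),
        "rtot": np.log1p(iiv.omega_rtot**2),
        "ka": np.log1p(iiv.omega_ka**2),
    }
    k = len(effects)
    om = np.diag([var[e] for e in effects])
    if "cl" in effects and "vc" in effects:
        i, j = effects.index("cl"), effects.index("vc")
        om[i, j] = om[j, i] = iiv.corr_cl_vc * np.sqrt(var["cl"] * var["vc"])
    return om


def fit_pk_mixed(
    dataset: StudyDataset,
    variant: ModelVariant | str = ModelVariant.QE,
    init: Optional[PKParameters] = None,
    iiv_init: Optional[IIVSpec] = None,
    random_effects: Sequence[str] = ("cl", "vc", "rtot"),
    fixed: Sequence[str] = ("kd",),
    n_outer: int = 3,
    pooled_first: bool = True,
    sigma: Optional[tuple[float, float]] = None,
    maxiter_pooled: int = 200,
    update_theta: bool = True,
    maxiter_theta: int = 25,
) -> FitResult:
    """Iterated two-stage population fit with lognormal IIV.

    Typical values come from the naive-pooled stage (or ``init`` when
    ``pooled_first=False``); each sweep computes per-individual MAP etas
    under the current Omega prior (damped Newton with batched
    finite-difference derivatives), refines Omega by the EM update
    mean(eta eta' + H^-1), and — when ``update_theta`` — re-estimates the
    typical values and residual sigmas conditional on the current etas.
    Conditioning theta on the etas undoes most of the naive-pooling bias
    (the pooled stage absorbs skewed between-animal variability into the
    residual error and can let weakly identified parameters drift).
    Returns CV-scale IIV estimates, the CL–Vc correlation, and shrinkage
    diagnostics.
    """
    variant = ModelVariant(variant)
    iiv_init = iiv_init or IIVSpec()
    if all(
        getattr(iiv_init, f"omega_{e}", 0.0) == 0.0 for e in random_effects
    ):  # degenerate random effects: reduces to the pooled estimator
        return fit_pk_pooled(
            dataset, variant, init, fixed=fixed, maxiter=maxiter_pooled
        )

    if pooled_first:
        pooled = fit_pk_pooled(
            dataset, variant, init, fixed=fixed, maxiter=maxiter_pooled
        )
        theta = pooled.estimates
        sp, sa = pooled.sigma_prop, pooled.sigma_add
        base_obj = pooled.objective
        converged = pooled.converged
    else:
        if init is None:
            raise ValueError("init required when pooled_first=False")
        theta = init
        sp, sa = sigma or (0.2, 1.0)
        base_obj = np.nan
        converged = True
    if sigma is not None:
        sp, sa = sigma

    batches = _build_batches(dataset)
    ids = [aid for b in batches for aid in b.ids]
    n_ind = len(ids)
    effects = list(random_effects)
    omega = _omega_from_iiv(iiv_init, effects)
    k = len(effects)
    om_inv = np.linalg.inv(omega)

    def all_penalized(etas: np.ndarray) -> np.ndarray:
        """Penalized per-individual objective, evaluated with batched ODE
        solves (the objective is separable across individuals)."""
        out = np.empty(n_ind)
        pos = 0
        for b in batches:
            nb = len(b.ids)
            e = etas[pos : pos + nb]
            plist = [
                theta.replace(
                    **{
                        eff: getattr(theta, eff) * float(np.exp(e[i, d]))
                        for d, eff in enumerate(effects)
                    }
                )
                for i in range(nb)
            ]
            try:
                cf, _ = solve_population(
                    plist, b.dose_times, b.amounts, b.routes, b.times,
                    variant=variant, rtol=1e-5, atol=1e-7,
                )
                v = (sp * cf) ** 2 + sa**2
                nll_rows = 0.5 * ((b.y - cf) ** 2 / v + np.log(2.0 * np.pi * v))
                out[pos : pos + nb] = np.where(b.mask, nll_rows, 0.0).sum(axis=1)
            except Exception:
                out[pos : pos + nb] = 1e10
            pos += nb
        out += 0.5 * np.einsum("ni,ij,nj->n", etas, om_inv, etas)
        return out

    theta_names = [n for n in ESTIMABLE if n not in set(fixed)]

    def fit_theta(theta0: PKParameters, sp0: float, sa0: float):
        """Re-estimate typical values and sigmas conditional on the etas."""
        x0 = np.log([getattr(theta0, n) for n in theta_names] + [sp0, sa0])

        def obj(x):
            try:
                th = theta0.replace(
                    **{n: float(np.exp(v)) for n, v in zip(theta_names, x)}
                )
                spx, sax = np.exp(x[len(theta_names) :])
                total = 0.0
                pos = 0
                for b in batches:
                    nb = len(b.ids)
                    e = etas[pos : pos + nb]
                    plist = [
                        th.replace(
                            **{
                                eff: getattr(th, eff) * float(np.exp(e[i, d]))
                                for d, eff in enumerate(effects)
                            }
                        )
                        for i in range(nb)
                    ]
                    cf, _ = solve_population(
                        plist, b.dose_times, b.amounts, b.routes, b.times,
                        variant=variant, rtol=1e-5, atol=1e-7,
                    )
                    m = b.mask
                    total += _nll(b.y[m], cf[m], spx, sax)
                    pos += nb
            except Exception:
                return 1e12
            return total if np.isfinite(total) else 1e12

        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            bounds=[(v - 12.0, v + 12.0) for v in x0],
            options={"maxiter": maxiter_theta, "ftol": 1e-8, "eps": 1e-5},
        )
        th = theta0.replace(
            **{n: float(np.exp(v)) for n, v in zip(theta_names, res.x)}
        )
        spx, sax = np.exp(res.x[len(theta_names) :])
        return th, float(spx), float(sax)

    etas = np.zeros((n_ind, k))
    hessians = np.tile(om_inv, (n_ind, 1, 1))
    fd = 1e-3
    eye = np.eye(k)

    for sweep in range(n_outer):
        try:
            om_inv = np.linalg.inv(omega)
        except np.linalg.LinAlgError:
            warnings.warn("singular random-effect covariance; using diagonal")
            omega = np.diag(np.maximum(np.diag(omega), 1e-6))
            om_inv = np.linalg.inv(omega)

        # damped Newton on each individual's eta, with finite-difference
        # gradients/Hessians shared across individuals via batched solves
        lam = np.full(n_ind, 1e-2)
        f0 = all_penalized(etas)
        for it in range(12):
            grad = np.zeros((n_ind, k))
            hess = np.zeros((n_ind, k, k))
            fp, fm = {}, {}
            for d in range(k):
                fp[d] = all_penalized(etas + fd * eye[d])
                fm[d] = all_penalized(etas - fd * eye[d])
                grad[:, d] = (fp[d] - fm[d]) / (2 * fd)
                hess[:, d, d] = (fp[d] - 2 * f0 + fm[d]) / fd**2
            for d in range(k):
                for d2 in range(d + 1, k):
                    fpp = all_penalized(etas + fd * (eye[d] + eye[d2]))
                    cross = (fpp - fp[d] - fp[d2] + f0) / fd**2
                    hess[:, d, d2] = hess[:, d2, d] = cross
            step = np.zeros_like(etas)
            for i in range(n_ind):
                h_i = hess[i] + lam[i] * np.eye(k)
                w, v = np.linalg.eigh(h_i)
                w = np.maximum(w, 1e-4)
                step[i] = -(v @ ((v.T @ grad[i]) / w))
            step = np.clip(step, -1.5, 1.5)
            f_new = all_penalized(etas + step)
            improved = f_new <= f0 + 1e-10
            etas[improved] += step[improved]
            f0 = np.where(improved, f_new, f0)
            lam = np.where(improved, lam / 3.0, lam * 10.0)
            hessians = hess
            if np.max(np.abs(grad)) < 1e-3:
                break
            if not improved.any() and np.all(lam > 1e6):
                break

        h_invs = np.zeros((n_ind, k, k))
        for i in range(n_ind):
            try:
                h_inv = np.linalg.inv(hessians[i])
                if np.any(np.linalg.eigvalsh(h_inv) < 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                h_inv = omega  # uninformative individual: prior variance
            h_invs[i] = h_inv
        omega_new = (etas.T @ etas) / n_ind + h_invs.mean(axis=0)
        omega = 0.5 * (omega_new + omega_new.T)

        if update_theta and sweep < n_outer - 1:
            theta, sp, sa = fit_theta(theta, sp, sa)

    var = np.diag(omega)
    omegas = {e: float(np.sqrt(np.expm1(v))) for e, v in zip(effects, var)}
    corr = None
    if "cl" in effects and "vc" in effects:
        i, j = effects.index("cl"), effects.index("vc")
        denom = np.sqrt(var[i] * var[j])
        corr = float(omega[i, j] / denom) if denom > 0 else 0.0
    shrink = {
        e: float(1.0 - np.std(etas[:, i], ddof=1) / np.sqrt(var[i]))
        if var[i] > 0
        else 1.0
        for i, e in enumerate(effects)
    }
    eta_df = pd.DataFrame(etas, columns=[f"eta_{e}" for e in effects])
    eta_df.insert(0, "ID", ids)
    return FitResult(
        estimates=theta,
        sigma_prop=sp,
        sigma_add=sa,
        objective=base_obj,
        converged=converged,
        n_obs=int(sum(b.mask.sum() for b in batches)),
        omegas=omegas,
        corr_cl_vc=corr,
        shrinkage=shrink,
        individual_etas=eta_df,
    )


# ---------------------------------------------------------------------------
# PD: inhibitory Emax model
# ---------------------------------------------------------------------------


@dataclass
class EmaxFitResult:
    estimates: EmaxParameters
    se: dict
    objective: float
    converged: bool


def fit_emax(
    concentrations: np.ndarray,
    effects: np.ndarray,
    init: EmaxParameters = EmaxParameters(500.0, 0.9, 0.02),
) -> EmaxFitResult:
    """Least-squares fit of E = E0*(1 - Emax*C/(EC50 + C)).

    Requires at least 4 concentration–effect pairs; warns when the
    concentration range does not span the fitted EC50 (ill-conditioned
    EC50).
    """
    c = np.asarray(concentrations, dtype=float)
    e = np.asarray(effects, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentration-effect pairs")

    def model(cc, e0, emax, ec50):
        return e0 * (1.0 - emax * cc / (ec50 + cc))

    popt, pcov = optimize.curve_fit(
        model,
        c,
        e,
        p0=[init.e0, init.emax, init.ec50],
        bounds=([1e-12, 0.0, 1e-12], [np.inf, 1.0, np.inf]),
        maxfev=20000,
    )
    est = EmaxParameters(*popt)
    pos = c[c > 0]
    if len(pos) == 0 or pos.min() > est.ec50 or pos.max() < est.ec50:
        warnings.warn(
            "concentration range does not span EC50; estimate is ill-conditioned"
        )
    sd = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    resid = e - model(c, *popt)
    return EmaxFitResult(
        estimates=est,
        se={"e0": sd[0], "emax": sd[1], "ec50": sd[2]},
        objective=float(np.sum(resid**2)),
        converged=True,
    )


def ecp(ec50: float, p: float) -> float:
    """Concentration at p% of the maximal effect: ECp = EC50*p/(100-p)."""
    if not 0.0 < p < 100.0:
        raise ValueError("p must be in (0, 100)")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    return ec50 * p / (100.0 - p)


def internalization_half_life(kint: float) -> float:
    """Half-life (days) of the internalized drug–target complex, ln2/Kint."""
    if kint <= 0:
        raise ValueError("kint must be positive")
    return float(np.log(2.0) / kint)
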