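"""Structural PK model family.

The core model is a two-compartment disposition model with target-mediated
drug disposition (TMDD): drug binds a cell-surface receptor with high
affinity and the drug–receptor complex is internalized, producing a
nonlinear elimination route that saturates at high concentration.

Variants:

``QE``
    Quasi-equilibrium approximation with constant total target: binding is
    collapsed into the dissociation constant Kd and the free concentration
    is the positive root of the binding quadratic.  This is the default
    model.  The quasi-steady-state (QSS) approximation is the same code
    path with the steady-state constant Kss in place of Kd.
``FULL``
    Full binding kinetics (kon/koff), receptor turnover (ksyn/kdeg) and
    complex internalization.  Used as an internal oracle: as kon grows at
    fixed Kd = koff/kon the full model converges to QE.
``MM``
    Empirical comparator: two-compartment linear model with a parallel
    Michaelis–Menten elimination (Vmax, Km) from the central compartment.
``LINEAR``
    Two-compartment linear model (QE with Rtot = 0).

State layouts (concentrations in nmol/L, amounts in nmol, time in days):

* QE/QSS/LINEAR/MM: ``[A_depot, C_central, A_peripheral]`` where
  ``C_central`` is total drug for QE/QSS and free drug otherwise.
* FULL: ``[A_depot, C_free, R_free, RC_complex, A_peripheral]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np

__all__ = [
    "ModelVariant",
    "PKParameters",
    "free_concentration",
    "qe_rhs",
    "full_tmdd_rhs",
    "mm_rhs",
]


class ModelVariant(str, enum.Enum):
    QE = "QE"
    QSS = "QSS"
    FULL = "FULL"
    MM = "MM"
    LINEAR = "LINEAR"


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters for one species/individual.

    Units: ka [1/day], cl [mL/day], vc [mL], k12/k21 [1/day],
    kd/kss/rtot [nmol/L], kint [1/day], f1 dimensionless fraction.
    Optional full-model constants: kon [L/(nmol·day)], koff [1/day],
    ksyn [nmol/(L·day)], kdeg [1/day].  Optional Michaelis–Menten
    constants: vmax [nmol/(L·day)], km [nmol/L].
    """

    ka: float
    cl: float
    vc: float
    k12: float
    k21: float
    kd: float = 0.0
    rtot: float = 0.0
    kint: float = 0.0
    f1: float = 1.0
    kon: Optional[float] = None
    koff: Optional[float] = None
    ksyn: Optional[float] = None
    kdeg: Optional[float] = None
    vmax: Optional[float] = None
    km: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "vc", "k12", "k21", "kd", "rtot", "kint"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vc <= 0:
            raise ValueError("vc must be positive")
        if not 0.0 <= self.f1 <= 1.0:
            raise ValueError("f1 must be in [0, 1]")
        for name in ("kon", "koff", "ksyn", "kdeg", "vmax", "km"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kon is not None and self.koff is not None and self.kd > 0:
            # QE consistency: Kd = koff/kon when full constants are given
            if not np.isclose(self.kd, self.koff / self.kon, rtol=1e-6):
                raise ValueError("inconsistent binding constants: kd != koff/kon")

    def replace(self, **kw) -> "PKParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def with_full_binding(self, kon: float) -> "PKParameters":
        """Derive full-model constants consistent with the constant-Rtot QE
        simplification: koff = Kd*kon, kdeg = Kint, ksyn = Kint*Rtot."""
        if kon <= 0:
            raise ValueError("kon must be positive")
        return self.replace(
            kon=kon, koff=self.kd * kon, kdeg=self.kint, ksyn=self.kint * self.rtot
        )


def _free_conc(ctot, rtot, kd):
    """Positive root of Cf^2 + (Rtot + Kd - Ctot)*Cf - Kd*Ctot = 0.

    Numerically stable in both branches (avoids cancellation when
    Ctot < Rtot + Kd).  No input validation — internal use on solver state
    that may carry tiny negative round-off (clipped to zero).
    """
    ctot = np.maximum(ctot, 0.0)
    b = ctot - rtot - kd
    disc = np.sqrt(b * b + 4.0 * kd * ctot)
    neg = b < 0.0
    # disc - b >= -2b > 0 on the negative branch, so the division is safe
    denom = np.where(neg, disc - b, 1.0)
    cf = np.where(neg, 2.0 * kd * ctot / denom, 0.5 * (b + disc))
    return np.minimum(np.maximum(cf, 0.0), ctot)


def free_concentration(ctot, rtot, kd):
    """Free drug concentration under the quasi-equilibrium binding model.

    Cf = 0.5 * [(Ctot - Rtot - Kd) + sqrt((Ctot - Rtot - Kd)^2 + 4*Kd*Ctot)]

    All arguments in nmol/L; scalars or arrays.  Satisfies
    0 <= Cf <= Ctot and bound drug Ctot - Cf <= Rtot.
    """
    for name, v in (("ctot", ctot), ("rtot", rtot), ("kd", kd)):
        if np.any(np.asarray(v, dtype=float) < 0):
            raise ValueError(f"{name} must be non-negative")
    out = _free_conc(np.asarray(ctot, dtype=float), rtot, kd)
    return float(out) if np.isscalar(ctot) else out


def qe_rhs(t: float, y: np.ndarray, p: PKParameters) -> np.ndarray:
    """Right-hand side of the constant-Rtot QE (or QSS) TMDD system.

    y = [A_depot (nmol), Ctot (nmol/L), A_peripheral (nmol)].

    The linear clearance and peripheral exchange act on the free
    concentration Cf; complex internalization removes bound drug at rate
    Kint*(Ctot - Cf).  Total receptor is held constant (equivalent to
    receptor turnover with kdeg = Kint and ksyn = Kint*Rtot).
    """
    a, ctot, at = y
    vc_l = p.vc / 1000.0
    cl_l = p.cl / 1000.0
    cf = _free_conc(ctot, p.rtot, p.kd)
    at = max(at, 0.0)
    da = -p.ka * max(a, 0.0)
    dc = (
        p.ka * p.f1 * max(a, 0.0) / vc_l
        - (cl_l / vc_l) * cf
        - p.k12 * cf
        + p.k21 * at / vc_l
        - p.kint * (max(ctot, 0.0) - cf)
    )
    dat = p.k12 * cf * vc_l - p.k21 * at
    return np.array([da, dc, dat])


def mm_rhs(t: float, y: np.ndarray, p: PKParameters) -> np.ndarray:
    """Two-compartment linear model plus parallel Michaelis–Menten
    elimination -Vmax*C/(Km + C) on the central compartment.

    y = [A_depot, C (free = total), A_peripheral].
    """
    if p.vmax is None or p.km is None:
        raise ValueError("MM variant requires vmax and km")
    a, c, at = y
    vc_l = p.vc / 1000.0
    cl_l = p.cl / 1000.0
    c = max(c, 0.0)
    at = max(at, 0.0)
    da = -p.ka * max(a, 0.0)
    dc = (
        p.ka * p.f1 * max(a, 0.0) / vc_l
        - (cl_l / vc_l) * c
        - p.k12 * c
        + p.k21 * at / vc_l
        - p.vmax * c / (p.km + c)
    )
    dat = p.k12 * c * vc_l - p.k21 * at
    return np.array([da, dc, dat])


def full_tmdd_rhs(t: float, y: np.ndarray, p: PKParameters) -> np.ndarray:
    """Full TMDD system with explicit binding kinetics and receptor
    turnover.

    y = [A_depot, C_free, R_free, RC_complex, A_peripheral].
    """
    for name in ("kon", "koff", "ksyn", "kdeg"):
        if getattr(p, name) is None:
            raise ValueError(f"FULL variant requires {name}")
    a, c, r, rc, at = y
    vc_l = p.vc / 1000.0
    cl_l = p.cl / 1000.0
    c = max(c, 0.0)
    r = max(r, 0.0)
    rc = max(rc, 0.0)
    at = max(at, 0.0)
    bind = p.kon * c * r
    da = -p.ka * max(a, 0.0)
    dc = (
        p.ka * p.f1 * max(a, 0.0) / vc_l
        - (cl_l / vc_l) * c
        - p.k12 * c
        + p.k21 * at / vc_l
        - bind
        + p.koff * rc
    )
    dr = p.ksyn - p.kdeg * r - bind + p.koff * rc
    drc = bind - p.koff * rc - p.kint * rc
    dat = p.k12 * c * vc_l - p.k21 * at
    return np.array([da, dc, dr, drc, dat])


# ---------------------------------------------------------------------------
# Vectorized (population-batched) right-hand sides.  Parameters are given as
# a dict of 1-D arrays over individuals; the state is (n_states, n) flattened
# C-order.  Used by the population solver for speed.
# ---------------------------------------------------------------------------


def params_to_arrays(params_list) -> dict:
    """Stack a sequence of PKParameters into arrays for batched solving."""
    n = len(params_list)
    out = {}
    for name in ("ka", "cl", "vc", "k12", "k21", "kd", "rtot", "kint", "f1"):
        out[name] = np.array([getattr(p, name) for p in params_list], dtype=float)
    for name in ("vmax", "km", "kon", "koff", "ksyn", "kdeg"):
        vals = [getattr(p, name) for p in params_list]
        if all(v is not None for v in vals):
            out[name] = np.array(vals, dtype=float)
    out["n"] = n
    return out


def make_qe_rhs_batch(pa, cl_l):
    """Closure with per-segment precomputed derived constants.

    The returned callable reuses one output buffer: valid for LSODA/BDF
    (the derivative is copied on every call), not for RK solvers that
    retain stage arrays.
    """
    n = pa["n"]
    vc_l = pa["vc"] / 1000.0
    ka = pa["ka"]
    kaf = ka * pa["f1"] / vc_l
    k10 = cl_l / vc_l
    k12, k21 = pa["k12"], pa["k21"]
    k21v = k21 / vc_l
    k12v = k12 * vc_l
    kint, rtot, kd = pa["kint"], pa["rtot"], pa["kd"]
    out = np.empty(3 * n)

    def rhs(t, y):
        a = np.maximum(y[:n], 0.0)
        ctot = np.maximum(y[n : 2 * n], 0.0)
        at = np.maximum(y[2 * n :], 0.0)
        cf = _free_conc(ctot, rtot, kd)
        out[:n] = -ka * a
        out[n : 2 * n] = kaf * a - (k10 + k12) * cf + k21v * at - kint * (ctot - cf)
        out[2 * n :] = k12v * cf - k21 * at
        return out

    return rhs


def make_mm_rhs_batch(pa, cl_l):
    n = pa["n"]
    vc_l = pa["vc"] / 1000.0
    ka = pa["ka"]
    kaf = ka * pa["f1"] / vc_l
    k10 = cl_l / vc_l
    k12, k21 = pa["k12"], pa["k21"]
    k21v = k21 / vc_l
    k12v = k12 * vc_l
    vmax, km = pa["vmax"], pa["km"]
    out = np.empty(3 * n)

    def rhs(t, y):
        a = np.maximum(y[:n], 0.0)
        c = np.maximum(y[n : 2 * n], 0.0)
        at = np.maximum(y[2 * n :], 0.0)
        out[:n] = -ka * a
        out[n : 2 * n] = kaf * a - (k10 + k12) * c + k21v * at - vmax * c / (km + c)
        out[2 * n :] = k12v * c - k21 * at
        return out

    return rhs


def make_full_rhs_batch(pa, cl_l):
    n = pa["n"]
    vc_l = pa["vc"] / 1000.0
    ka = pa["ka"]
    kaf = ka * pa["f1"] / vc_l
    k10 = cl_l / vc_l
    k12, k21 = pa["k12"], pa["k21"]
    k21v = k21 / vc_l
    k12v = k12 * vc_l
    kint = pa["kint"]
    kon, koff, ksyn, kdeg = pa["kon"], pa["koff"], pa["ksyn"], pa["kdeg"]
    out = np.empty(5 * n)

    def rhs(t, y):
        a = np.maximum(y[:n], 0.0)
        c = np.maximum(y[n : 2 * n], 0.0)
        r = np.maximum(y[2 * n : 3 * n], 0.0)
        rc = np.maximum(y[3 * n : 4 * n], 0.0)
        at = np.maximum(y[4 * n :], 0.0)
        bind = kon * c * r
        out[:n] = -ka * a
        out[n : 2 * n] = kaf * a - (k10 + k12) * c + k21v * at - bind + koff * rc
        out[2 * n : 3 * n] = ksyn - kdeg * r - bind + koff * rc
        out[3 * n : 4 * n] = bind - koff * rc - kint * rc
        out[4 * n :] = k12v * c - k21 * at
        return out

    return rhs
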