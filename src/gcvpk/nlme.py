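"""Hierarchical nonlinear mixed-effects estimation for sparse PK data.

The model is the standard two-stage hierarchy: individual clearance and
volume are lognormal around covariate-driven typical values,

    CL_i = CL_typ(x_i) * exp(eta_CL,i),   Vd_i = Vd_typ(x_i) * exp(eta_Vd,i),

with diagonal Gaussian random effects (variances omega^2) and additive,
proportional or combined residual error on the concentration scale. The
marginal -2 log-likelihood per subject is approximated by a Laplace
expansion at the empirical-Bayes mode with a Gauss-Newton Hessian and
interaction (the residual variance is evaluated at the conditional
prediction) — a first-order-conditional (FOCE-I) style objective. With all
random-effect variances at zero the objective is the exact -2 log-likelihood
of the fixed-effect model, and for models linear in eta with additive error
the approximation is exact; both identities are enforced by the test suite.

Implementation notes. The inner problem (the random-effect mode of every
subject) is solved for all subjects simultaneously with a batched Newton
iteration: predictions and their analytic eta-gradients come from the
closed-form infusion superposition, the 2x2 Newton systems are solved in
closed form, steps are capped at one log-unit, and a deterministic probe
grid along the volume axis guards against the secondary modes that sparse
(one- or two-sample) subjects can exhibit. Fixed effects constrained
positive are estimated on the log scale, as are the random-effect and
residual standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from gcvpk.data import LLOQ, PKDataset, Subject

__all__ = [
    "ParamDef",
    "ModelSpec",
    "FitResult",
    "base_model_spec",
    "final_model_spec",
    "individual_neg2ll",
    "ebe",
    "ebes",
    "foce_ofv",
    "fit",
    "cwres",
    "aic",
    "bic",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_ETA_BOUND = 10.0   # |eta| beyond 10 log-units is never a sane conditional mode
_STEP_CAP = 1.0     # per-iteration Newton move cap, log-units
_PROBE_MULTIPLES = (-3.0, -1.5, 1.5, 3.0)


@dataclass(frozen=True)
class ParamDef:
    """One fixed effect: estimated on the log scale when ``positive``."""

    name: str
    init: float
    positive: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + variability configuration of one model run.

    ``cl`` and ``vd`` map (theta dict, Subject) to the typical clearance
    (L/h) and volume (L). Random effects are diagonal on (CL, Vd).
    """

    name: str
    params: tuple[ParamDef, ...]
    cl: Callable[[dict, Subject], float]
    vd: Callable[[dict, Subject], float]
    error_kind: str = "proportional"  # additive | proportional | combined
    omega_init: tuple[float, float] = (0.2, 0.4)  # SD of eta_CL, eta_Vd
    sigma_init: tuple[float, float] = (0.15, 0.1)  # (proportional, additive)
    # BLQ handling: "censored" contributes -2 log Phi((LLOQ-f)/sd) per
    # below-LLOQ record (dropping them instead truncates the error
    # distribution and biases the volume estimate upward on sparse designs)
    blq: str = "censored"

    def __post_init__(self) -> None:
        if self.error_kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error kind {self.error_kind!r}")
        if self.blq not in ("censored", "exclude"):
            raise ValueError(f"unknown blq policy {self.blq!r}")

    @property
    def n_sigma(self) -> int:
        return 2 if self.error_kind == "combined" else 1

    @property
    def n_par(self) -> int:
        """Fixed effects plus variance parameters (2 omegas + sigmas)."""
        return len(self.params) + 2 + self.n_sigma

    def with_inits(self, theta: dict, omega: tuple[float, float] | None = None,
                   sigma: tuple[float, float] | None = None) -> "ModelSpec":
        """Copy of this spec with warm-start initial values."""
        params = tuple(
            replace(p, init=float(theta.get(p.name, p.init))) for p in self.params
        )
        return replace(
            self,
            params=params,
            omega_init=omega if omega is not None else self.omega_init,
            sigma_init=sigma if sigma is not None else self.sigma_init,
        )


def base_model_spec() -> ModelSpec:
    """Covariate-free one-compartment model: CL and Vd typical values only."""
    return ModelSpec(
        name="base",
        params=(ParamDef("theta_cl", 4.0, True), ParamDef("theta_vd", 10.0, True)),
        cl=lambda th, s: th["theta_cl"],
        vd=lambda th, s: th["theta_vd"],
    )


def final_model_spec(wt_ref: float = 12.0) -> ModelSpec:
    """The final covariate model: allometric WT on Vd, KF and WT on CL."""
    return ModelSpec(
        name="final",
        params=(
            ParamDef("theta_cl", 4.0, True),
            ParamDef("theta_vd", 10.0, True),
            ParamDef("theta1", 0.75),
            ParamDef("theta2", 0.5),
            ParamDef("theta3", 0.75),
        ),
        cl=lambda th, s: th["theta_cl"]
        * s.kf ** th["theta2"]
        * (s.wt / wt_ref) ** th["theta3"],
        vd=lambda th, s: th["theta_vd"] * (s.wt / wt_ref) ** th["theta1"],
    )


# ---------------------------------------------------------------------------
# per-subject data preparation

@dataclass
class _SubjectData:
    subject: Subject
    t: np.ndarray          # observation times, h
    y: np.ndarray          # concentrations, ug/mL (LLOQ bound where censored)
    dose_t: np.ndarray
    amt: np.ndarray
    dur: np.ndarray
    cens: np.ndarray = None  # left-censored-at-LLOQ flags

    def __post_init__(self):
        if self.cens is None:
            self.cens = np.zeros(self.t.size, dtype=bool)


def _prepare(dataset: PKDataset, blq: str = "exclude") -> list[_SubjectData]:
    out = []
    for s in dataset.subjects:
        obs = dataset.observations.get(s.id, [])
        if blq == "exclude":
            obs = [o for o in obs if not o.below_loq]
        doses = dataset.doses.get(s.id, [])
        out.append(
            _SubjectData(
                subject=s,
                t=np.array([o.time for o in obs]),
                # a censored record carries only "value < LLOQ"
                y=np.array([LLOQ if o.below_loq else o.conc for o in obs]),
                dose_t=np.array([d.time for d in doses]),
                amt=np.array([d.amount for d in doses]),
                dur=np.array([d.infusion_duration for d in doses]),
                cens=np.array([o.below_loq for o in obs], dtype=bool),
            )
        )
    return out


def _conc(sd: _SubjectData, t: np.ndarray, cl: float, vd: float) -> np.ndarray:
    """Scalar-path superposition closed form for one subject."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ke = cl / vd
        dt = t[:, None] - sd.dose_t[None, :]
        infused = np.minimum(np.maximum(dt, 0.0), sd.dur[None, :])
        decay = np.maximum(dt - sd.dur[None, :], 0.0)
        contrib = (sd.amt / sd.dur / cl) * (1.0 - np.exp(-ke * infused)) \
            * np.exp(-ke * decay)
        return contrib.sum(axis=1)


def _resid_var(f: np.ndarray, sp: float, sa: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return (sp * f) ** 2 + sa**2


def individual_neg2ll(
    eta: np.ndarray,
    sd: _SubjectData,
    cl_typ: float,
    vd_typ: float,
    omega2: np.ndarray,
    sigma_prop: float,
    sigma_add: float,
) -> float:
    """Joint -2 log-likelihood of one subject's data and random effects.

    -2 [ sum_j log N(y_j; f_j, v_j) + log N(eta; 0, Omega) ] with
    v_j = (sigma_prop*f_j)^2 + sigma_add^2. Left-censored records contribute
    -2 log Phi((LLOQ - f_j)/sqrt(v_j)) instead. Dimensions whose omega^2 is
    zero carry no prior term (their eta must be zero).
    """
    eta = np.asarray(eta, dtype=float)
    with np.errstate(over="ignore"):
        cl = cl_typ * np.exp(eta[0])
        vd = vd_typ * np.exp(eta[1])
    f = _conc(sd, sd.t, cl, vd)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError(
            f"non-finite prediction for subject {sd.subject.id} at t={sd.t}"
        )
    v = _resid_var(f, sigma_prop, sigma_add)
    with np.errstate(divide="ignore"):
        if sd.y.size:
            q = ~sd.cens
            terms = np.where(
                q,
                _LOG2PI + np.log(v) + (sd.y - f) ** 2 / v,
                -2.0 * log_ndtr((sd.y - f) / np.sqrt(v)),
            )
            data = float(terms.sum())
        else:
            data = 0.0
    free = omega2 > 0
    prior = 0.0
    if free.any():
        prior = float(
            free.sum() * _LOG2PI
            + np.sum(np.log(omega2[free]))
            + np.sum(eta[free] ** 2 / omega2[free])
        )
    return data + prior


# ---------------------------------------------------------------------------
# batched inner problem: all subjects at once

class _BatchData:
    """Padded design arrays for vectorized evaluation across subjects.

    Padding is inert by construction: padded doses have rate 0 and padded
    observations carry weight 0 in every sum.
    """

    def __init__(self, subject_datas: list[_SubjectData]):
        self.sds = subject_datas
        n = len(subject_datas)
        mo = max(1, max((sd.t.size for sd in subject_datas), default=1))
        md = max(1, max((sd.dose_t.size for sd in subject_datas), default=1))
        self.n = n
        self.T = np.zeros((n, mo))
        self.Y = np.zeros((n, mo))
        self.W = np.zeros((n, mo))   # quantified-record weights
        self.C = np.zeros((n, mo))   # censored-record weights
        self.rate = np.zeros((n, md))
        self.infused = np.zeros((n, mo, md))
        self.decay = np.zeros((n, mo, md))
        self.nobs = np.zeros(n, dtype=int)
        for i, sd in enumerate(subject_datas):
            no, nd = sd.t.size, sd.dose_t.size
            self.nobs[i] = no
            if no:
                self.T[i, :no] = sd.t
                self.Y[i, :no] = sd.y
                self.W[i, :no] = (~sd.cens).astype(float)
                self.C[i, :no] = sd.cens.astype(float)
            if nd:
                self.rate[i, :nd] = sd.amt / sd.dur
                dt = self.T[i][:, None] - sd.dose_t[None, :]
                self.infused[i, :, :nd] = np.minimum(np.maximum(dt, 0.0), sd.dur)
                self.decay[i, :, :nd] = np.maximum(dt - sd.dur, 0.0)
        self.n_obs_total = int(self.nobs.sum())


def _bconc(bd: _BatchData, cl: np.ndarray, vd: np.ndarray, grad: bool = False,
           hess: bool = False):
    """Batched predictions (n, mo) and, optionally, analytic first and
    second derivatives wrt (eta_CL, eta_Vd) from the superposition closed
    form."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ke = cl / vd
        keN = ke[:, None, None]
        e_inf = np.exp(-keN * bd.infused)
        e_dec = np.exp(-keN * bd.decay)
        rc = (bd.rate / cl[:, None])[:, None, :]
        f = (rc * (1.0 - e_inf) * e_dec).sum(axis=2)
        if not grad:
            return f
        # d/dke of the per-dose profile, times R/CL, summed over doses
        s1 = (rc * (bd.infused * e_inf - bd.decay * (1.0 - e_inf)) * e_dec).sum(axis=2)
        h1 = ke[:, None] * s1
        a_cl = -f + h1
        a_vd = -h1
        if not hess:
            return f, a_cl, a_vd
        # d2/dke2, times R/CL, summed over doses
        tau, dlt = bd.infused, bd.decay
        s2 = (rc * (-tau * (tau + 2.0 * dlt) * e_inf
                    + dlt**2 * (1.0 - e_inf)) * e_dec).sum(axis=2)
        k2s2 = ke[:, None] ** 2 * s2
        f_uu = f - h1 + k2s2        # d2f/deta_cl2
        f_uw = -k2s2                # cross term
        f_ww = k2s2 + h1            # d2f/deta_vd2
        return f, a_cl, a_vd, f_uu, f_uw, f_ww


def _bg(bd: _BatchData, eta: np.ndarray, cl_t: np.ndarray, vd_t: np.ndarray,
        omega2: np.ndarray, sp: float, sa: float) -> np.ndarray:
    """Batched joint -2LL g(eta) per subject; +inf where invalid."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cl = cl_t * np.exp(eta[:, 0])
        vd = vd_t * np.exp(eta[:, 1])
        f = _bconc(bd, cl, vd)
        v = _resid_var(f, sp, sa)
        vs = np.where(bd.W + bd.C > 0, v, 1.0)
        term = _LOG2PI + np.log(vs) + (bd.Y - f) ** 2 / vs
        data = (bd.W * np.where(np.isfinite(term), term, np.inf)).sum(axis=1)
        if bd.C.any():
            z = (bd.Y - f) / np.sqrt(vs)
            cterm = -2.0 * log_ndtr(np.where(np.isfinite(z), z, -np.inf))
            data = data + (bd.C * np.where(np.isfinite(cterm), cterm, np.inf)).sum(axis=1)
        free = omega2 > 0
        prior = float(free.sum() * _LOG2PI + np.log(omega2[free]).sum())
        quad = (eta[:, free] ** 2 / omega2[free]).sum(axis=1) if free.any() else 0.0
        g = data + prior + quad
        g = np.where(np.isfinite(g), g, np.inf)
        g = np.where(np.abs(eta).max(axis=1) > _ETA_BOUND, np.inf, g)
        # subjects with no quantifiable data sit at the prior mode, g = prior
        return np.where(bd.nobs > 0, g, prior)


def _bnewton(bd: _BatchData, cl_t, vd_t, omega2, sp, sa, eta0,
             tol: float = 1e-6, max_iter: int = 60):
    """Batched damped Newton descent of g(eta) with Gauss-Newton Hessian.

    Returns (eta, g, converged). Dimensions with omega^2 = 0 are pinned at
    zero through an effectively infinite prior precision.
    """
    free = omega2 > 0
    iw = np.where(free, 1.0 / np.where(free, omega2, 1.0), 1e30)
    eta = np.array(eta0, dtype=float, copy=True)
    eta[:, ~free] = 0.0
    g = _bg(bd, eta, cl_t, vd_t, omega2, sp, sa)
    bad = ~np.isfinite(g) | (g > 1e8)
    if bad.any():
        eta[bad] = 0.0
        g = np.where(bad, _bg(bd, eta, cl_t, vd_t, omega2, sp, sa), g)
    has_data = bd.nobs > 0
    done = ~has_data | ~free.any()
    converged = done.copy()
    # Levenberg-Marquardt damping: the Gauss-Newton Hessian ignores the
    # prediction curvature, which makes pure Newton steps oscillate across
    # curved single-observation valleys
    lam = np.zeros(bd.n)
    for _ in range(max_iter):
        if done.all():
            break
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            cl = cl_t * np.exp(eta[:, 0])
            vd = vd_t * np.exp(eta[:, 1])
            f, a_cl, a_vd, f_uu, f_uw, f_ww = _bconc(bd, cl, vd, grad=True,
                                                     hess=True)
            v = np.where(bd.W + bd.C > 0, _resid_var(f, sp, sa), 1.0)
            r = bd.Y - f
            inv_v = bd.W / v
            # gradient with interaction (dv/deta) terms
            dterm = 1.0 / v - r**2 / v**2
            g0 = (-2.0 * a_cl * r * inv_v + 2.0 * sp**2 * f * a_cl * dterm * bd.W).sum(1) \
                + 2.0 * eta[:, 0] * iw[0]
            g1 = (-2.0 * a_vd * r * inv_v + 2.0 * sp**2 * f * a_vd * dterm * bd.W).sum(1) \
                + 2.0 * eta[:, 1] * iw[1]
            # Hessian: Gauss-Newton leading term plus the exact prediction
            # curvature (without it the iteration oscillates across curved
            # single-observation valleys); LM damping guards indefiniteness
            rv = -2.0 * r * inv_v
            h00 = 2.0 * (a_cl**2 * inv_v).sum(1) + (rv * f_uu).sum(1) + 2.0 * iw[0]
            h11 = 2.0 * (a_vd**2 * inv_v).sum(1) + (rv * f_ww).sum(1) + 2.0 * iw[1]
            h01 = 2.0 * (a_cl * a_vd * inv_v).sum(1) + (rv * f_uw).sum(1)
            if bd.C.any():
                # left-censored records: -2 log Phi(z), z = (LLOQ - f)/sd
                s = np.sqrt(v)
                z = r / s
                u = np.exp(-0.5 * z**2 - 0.5 * _LOG2PI - log_ndtr(z))  # phi/Phi
                fac = (1.0 + z * sp**2 * f / s) / s
                dz0 = -a_cl * fac
                dz1 = -a_vd * fac
                hz = 2.0 * u * (u + z)  # curvature of -2 log Phi, >= 0
                g0 = g0 + (bd.C * (-2.0 * u) * dz0).sum(1)
                g1 = g1 + (bd.C * (-2.0 * u) * dz1).sum(1)
                h00 = h00 + (bd.C * hz * dz0**2).sum(1)
                h11 = h11 + (bd.C * hz * dz1**2).sum(1)
                h01 = h01 + (bd.C * hz * dz0 * dz1).sum(1)
            grad_ok = np.isfinite(g0) & np.isfinite(g1)
            gmax = np.where(grad_ok, np.maximum(np.abs(g0), np.abs(g1)), np.inf)
            # pinned dimensions do not count toward convergence
            if not free[0]:
                gmax = np.where(grad_ok, np.abs(g1), np.inf)
            if not free[1]:
                gmax = np.where(grad_ok, np.abs(g0), np.inf)
            newly = ~done & (gmax < tol)
            converged |= newly
            done |= newly | ~grad_ok
            if done.all():
                break
            d00 = h00 * (1.0 + lam)
            d11 = h11 * (1.0 + lam)
            det = d00 * d11 - h01**2
            det = np.where((det > 0) & np.isfinite(det), det, np.nan)
            s0 = -(d11 * g0 - h01 * g1) / det
            s1 = -(d00 * g1 - h01 * g0) / det
            fallback = ~np.isfinite(s0) | ~np.isfinite(s1)
            s0 = np.where(fallback, -g0, s0)
            s1 = np.where(fallback, -g1, s1)
            norm = np.maximum(np.abs(s0), np.abs(s1))
            scale = np.where(norm > _STEP_CAP, _STEP_CAP / np.maximum(norm, 1e-300), 1.0)
            step = np.column_stack([s0 * scale, s1 * scale])
            step[:, ~free] = 0.0
        # batched backtracking line search
        alpha = np.ones(bd.n)
        accepted = done.copy()
        for _bt in range(12):
            trial = eta + alpha[:, None] * step
            gt = _bg(bd, trial, cl_t, vd_t, omega2, sp, sa)
            improve = ~accepted & (gt < g)
            eta[improve] = trial[improve]
            g[improve] = gt[improve]
            accepted |= improve
            if accepted.all():
                break
            alpha[~accepted] *= 0.5
        moved = alpha * np.maximum(np.abs(step[:, 0]), np.abs(step[:, 1]))
        # a vanishing accepted move means the mode is located to within
        # line-search resolution
        tiny = ~done & accepted & (moved < 1e-7)
        converged |= tiny
        done |= ~accepted | tiny  # exhausted line search: stationary point
        lam = np.where(accepted & (alpha >= 0.5), lam / 4.0,
                       np.maximum(lam * 4.0, 1e-3))
    return eta, g, converged | done


def _bmode(bd: _BatchData, cl_t, vd_t, omega2, sp, sa, eta0=None,
           max_iter: int = 60):
    """Batched conditional modes with a deterministic volume-axis probe for
    sparse subjects (the conditional objective can be multimodal when one
    observation constrains only a curve in eta-space)."""
    if eta0 is None:
        eta0 = np.zeros((bd.n, 2))
    eta, g, conv = _bnewton(bd, cl_t, vd_t, omega2, sp, sa, eta0,
                            max_iter=max_iter)
    if omega2[1] > 0:
        sparse = (bd.nobs > 0) & (bd.nobs <= 2)
        if sparse.any():
            g_best = np.full(bd.n, np.inf)
            eta_best = np.zeros((bd.n, 2))
            for m in _PROBE_MULTIPLES:
                e = np.zeros((bd.n, 2))
                e[:, 1] = m * np.sqrt(omega2[1])
                gp = _bg(bd, e, cl_t, vd_t, omega2, sp, sa)
                better = gp < g_best
                g_best = np.where(better, gp, g_best)
                eta_best[better] = e[better]
            trigger = sparse & (g_best < g)
            if trigger.any():
                start = np.where(trigger[:, None], eta_best, eta)
                eta2, g2, conv2 = _bnewton(bd, cl_t, vd_t, omega2, sp, sa, start,
                                           max_iter=max_iter)
                take = g2 < g
                eta[take] = eta2[take]
                g[take] = g2[take]
                conv = np.where(take, conv2, conv)
    return eta, g, conv


def _bofv(bd: _BatchData, cl_t, vd_t, omega2, sp, sa, eta0=None):
    """Batched FOCE-I/Laplace OFV: total and per-subject modes."""
    eta, g, conv = _bmode(bd, cl_t, vd_t, omega2, sp, sa, eta0)
    free = omega2 > 0
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cl = cl_t * np.exp(eta[:, 0])
        vd = vd_t * np.exp(eta[:, 1])
        f, a_cl, a_vd = _bconc(bd, cl, vd, grad=True)
        v = np.where(bd.W + bd.C > 0, _resid_var(f, sp, sa), 1.0)
        inv_v = bd.W / v
        term = _LOG2PI + np.log(v) + (bd.Y - f) ** 2 / v
        data = (bd.W * term).sum(axis=1)
        # conditional information M = H(g/2) at the mode (Laplace correction)
        m00 = (a_cl**2 * inv_v).sum(1)
        m11 = (a_vd**2 * inv_v).sum(1)
        m01 = (a_cl * a_vd * inv_v).sum(1)
        if bd.C.any():
            s = np.sqrt(v)
            z = (bd.Y - f) / s
            data = data + (bd.C * (-2.0 * log_ndtr(z))).sum(axis=1)
            u = np.exp(-0.5 * z**2 - 0.5 * _LOG2PI - log_ndtr(z))
            fac = (1.0 + z * sp**2 * f / s) / s
            dz0 = -a_cl * fac
            dz1 = -a_vd * fac
            hz2 = u * (u + z)  # half the -2logPhi curvature
            m00 = m00 + (bd.C * hz2 * dz0**2).sum(1)
            m11 = m11 + (bd.C * hz2 * dz1**2).sum(1)
            m01 = m01 + (bd.C * hz2 * dz0 * dz1).sum(1)
        if free.all():
            a = m00 + 1.0 / omega2[0]
            c = m11 + 1.0 / omega2[1]
            logdet_m = np.log(a * c - m01**2)
            ofv_i = (
                data + np.log(omega2).sum()
                + eta[:, 0] ** 2 / omega2[0] + eta[:, 1] ** 2 / omega2[1]
                + logdet_m
            )
        elif free.any():
            k = 0 if free[0] else 1
            m = (m00 if k == 0 else m11) + 1.0 / omega2[k]
            ofv_i = data + np.log(omega2[k]) + eta[:, k] ** 2 / omega2[k] + np.log(m)
        else:
            ofv_i = data
        ofv_i = np.where(bd.nobs > 0, ofv_i, 0.0)
    if not np.all(np.isfinite(ofv_i)):
        bad = [bd.sds[i].subject.id for i in np.flatnonzero(~np.isfinite(ofv_i))]
        raise FloatingPointError(f"non-finite likelihood contribution for {bad}")
    return float(ofv_i.sum()), eta, conv


def _typicals_vec(spec: ModelSpec, theta: dict, sds: list[_SubjectData]):
    try:
        cl_t = np.array([spec.cl(theta, sd.subject) for sd in sds], dtype=float)
        vd_t = np.array([spec.vd(theta, sd.subject) for sd in sds], dtype=float)
    except OverflowError as exc:  # extreme trial parameters
        raise FloatingPointError(str(exc)) from exc
    if np.any(~np.isfinite(cl_t)) or np.any(cl_t <= 0) \
            or np.any(~np.isfinite(vd_t)) or np.any(vd_t <= 0):
        raise FloatingPointError("non-positive typical CL/Vd")
    return cl_t, vd_t


def foce_ofv(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
    _cache: dict | None = None,
    _batch: _BatchData | None = None,
) -> float:
    """Objective function value (-2 log approximate marginal likelihood).

    ``omega`` holds the SDs of (eta_CL, eta_Vd); ``sigma`` is
    (proportional SD, additive SD) with the unused component zero.
    """
    bd = _batch if _batch is not None else _BatchData(_prepare(dataset, spec.blq))
    omega2 = np.asarray(omega, dtype=float) ** 2
    cl_t, vd_t = _typicals_vec(spec, theta, bd.sds)
    eta0 = _cache.get("eta") if _cache is not None else None
    total, eta, _ = _bofv(bd, cl_t, vd_t, omega2, sigma[0], sigma[1], eta0)
    if _cache is not None:
        _cache["eta"] = eta
    return total


def ebe(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
    subject_id: str,
) -> np.ndarray:
    """Empirical-Bayes estimate (posterior mode) of one subject's (eta_CL,
    eta_Vd). With no observations, or omega -> 0, the prior mode 0 is
    returned; non-convergence yields NaNs with a warning."""
    sds = [s for s in _prepare(dataset, spec.blq) if s.subject.id == subject_id]
    if not sds:
        raise KeyError(subject_id)
    bd = _BatchData(sds)
    omega2 = np.asarray(omega, dtype=float) ** 2
    cl_t, vd_t = _typicals_vec(spec, theta, sds)
    eta, _, conv = _bmode(bd, cl_t, vd_t, omega2, sigma[0], sigma[1],
                          max_iter=400)
    if not conv[0]:
        warnings.warn(f"EBE did not converge for subject {subject_id}", stacklevel=2)
        return np.full(2, np.nan)
    return eta[0]


def ebes(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Empirical-Bayes (eta_CL, eta_Vd) modes for every subject."""
    sds = _prepare(dataset, spec.blq)
    bd = _BatchData(sds)
    omega2 = np.asarray(omega, dtype=float) ** 2
    cl_t, vd_t = _typicals_vec(spec, theta, sds)
    eta, _, conv = _bmode(bd, cl_t, vd_t, omega2, sigma[0], sigma[1],
                          max_iter=400)
    return {
        sd.subject.id: (eta[i] if conv[i] else np.full(2, np.nan))
        for i, sd in enumerate(sds)
    }


def aic(ofv: float, n_par: int) -> float:
    """Akaike information criterion: OFV + 2 * n_par."""
    return ofv + 2.0 * n_par


def bic(ofv: float, n_par: int, n_obs: int) -> float:
    """Bayesian information criterion: OFV + ln(n_obs) * n_par."""
    return ofv + float(np.log(n_obs)) * n_par


@dataclass
class FitResult:
    """Estimates and diagnostics of one model run.

    ``omega`` and ``sigma`` are standard deviations (reporting convention:
    multiply by 100 for the published percent scale). ``residual_table`` has
    one row per non-BLQ observation with PRED, IPRED and CWRES.
    """

    spec: ModelSpec
    theta: dict
    omega: dict
    sigma: dict
    ofv: float
    aic: float
    bic: float
    n_par: int
    n_obs: int
    etas: dict
    residual_table: pd.DataFrame
    converged: bool
    message: str
    se_pct: dict | None = None

    def params_flat(self) -> dict:
        out = dict(self.theta)
        out.update(self.omega)
        out.update(self.sigma)
        return out

    def summary(self) -> str:
        lines = [f"model: {self.spec.name}  (converged={self.converged})",
                 f"OFV {self.ofv:.2f}  AIC {self.aic:.2f}  BIC {self.bic:.2f}  "
                 f"n_par {self.n_par}  n_obs {self.n_obs}"]
        for k, v in self.params_flat().items():
            se = ""
            if self.se_pct and k in self.se_pct and np.isfinite(self.se_pct[k]):
                se = f"  (SE {self.se_pct[k]:.1f}%)"
            lines.append(f"  {k:>10s} = {v:.4g}{se}")
        return "\n".join(lines)


def _pack(spec: ModelSpec) -> tuple[np.ndarray, list[tuple[str, bool]]]:
    """Initial transformed vector and (name, log-scale?) layout."""
    layout: list[tuple[str, bool]] = []
    x0 = []
    for p in spec.params:
        layout.append((p.name, p.positive))
        x0.append(np.log(p.init) if p.positive else p.init)
    for name, init in (("omega_cl", spec.omega_init[0]), ("omega_vd", spec.omega_init[1])):
        layout.append((name, True))
        x0.append(np.log(init))
    if spec.error_kind in ("proportional", "combined"):
        layout.append(("sigma_prop", True))
        x0.append(np.log(spec.sigma_init[0]))
    if spec.error_kind in ("additive", "combined"):
        layout.append(("sigma_add", True))
        x0.append(np.log(spec.sigma_init[1]))
    return np.array(x0, dtype=float), layout


def _unpack(x: np.ndarray, spec: ModelSpec, layout) -> tuple[dict, tuple, tuple]:
    values = {}
    for xi, (name, is_log) in zip(x, layout):
        values[name] = float(np.exp(xi)) if is_log else float(xi)
    theta = {p.name: values[p.name] for p in spec.params}
    omega = (values["omega_cl"], values["omega_vd"])
    sigma = (values.get("sigma_prop", 0.0), values.get("sigma_add", 0.0))
    return theta, omega, sigma


def fit(
    dataset: PKDataset,
    spec: ModelSpec,
    seed: int = 0,
    compute_se: bool = False,
    maxiter: int = 200,
    ftol: float = 1e-8,
    n_restarts: int = 3,
    n_polish: int = 4,
    nm_maxfev: int | None = None,
) -> FitResult:
    """Estimate fixed effects and variance components by FOCE.

    Nested optimization: inner batched Newton for all subjects' random-effect
    modes (warm-started across objective calls), outer optimization on
    log-transformed positives in two stages — a quasi-Newton approach phase
    (L-BFGS-B with numerical gradients) followed by up to ``n_polish``
    Nelder-Mead polish cycles, which are robust to the small kinks the
    conditional-mode search leaves in the objective surface. Up to
    ``n_restarts`` seeded perturbed restarts are made if the approach phase
    reports failure; the best point found is returned, flagged.

    Standard errors (percent of the estimate) come from the inverse of a
    finite-difference Hessian of the OFV on the natural scale; they are
    reported missing with a warning if that Hessian is not positive
    definite.
    """
    sds = _prepare(dataset, spec.blq)
    bd = _BatchData(sds)
    n_obs = bd.n_obs_total
    if n_obs == 0:
        raise ValueError("dataset has no quantifiable observations")
    x0, layout = _pack(spec)
    cache: dict = {}

    def objective(x):
        theta, omega, sigma = _unpack(x, spec, layout)
        try:
            return foce_ofv(dataset, spec, theta, omega, sigma,
                            _cache=cache, _batch=bd)
        except (FloatingPointError, OverflowError):
            return 1e10

    opts = {"maxiter": maxiter, "ftol": ftol, "eps": 1e-5, "maxcor": 20}
    rng = np.random.default_rng(seed)
    best = None
    x_start = x0
    message = ""
    converged = False
    for attempt in range(1 + n_restarts):
        res = minimize(objective, x_start, method="L-BFGS-B", options=opts)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            message = str(res.message)
            break
        message = str(res.message)
        x_start = best.x + rng.normal(0.0, 0.1, size=x0.size)
    res = best
    # Nelder-Mead polish: the finite-difference quasi-Newton phase stalls on
    # the small kinks that conditional-mode switches leave in the surface
    for _pass in range(n_polish):
        nm = minimize(objective, res.x, method="Nelder-Mead",
                      options={"maxfev": nm_maxfev or 120 * x0.size,
                               "xatol": 1e-4, "fatol": 1e-4})
        gained = res.fun - nm.fun
        if nm.fun < res.fun:
            res = nm
            converged = converged or bool(nm.success)
        if gained < 0.05:
            break

    theta, omega, sigma = _unpack(res.x, spec, layout)
    # report the cold-start OFV at the optimum: near-tied secondary modes of
    # single-sample subjects make the warm-tracked objective path-dependent
    # by O(1); the cold evaluation is reproducible from the parameters alone
    try:
        ofv = foce_ofv(dataset, spec, theta, omega, sigma, _batch=bd)
    except (FloatingPointError, OverflowError):
        ofv = float(res.fun)
    n_par = spec.n_par

    se_pct = None
    if compute_se:
        se_pct = _se_percent(
            _natural_objective(dataset, spec, bd, layout), res.x, layout
        )

    # EBEs, predictions, residuals at the optimum
    omega2 = np.asarray(omega) ** 2
    cl_t, vd_t = _typicals_vec(spec, theta, sds)
    eta, _, conv = _bmode(bd, cl_t, vd_t, omega2, sigma[0], sigma[1],
                          max_iter=400)
    eta_map: dict[str, np.ndarray] = {}
    rows = []
    for i, sd in enumerate(sds):
        eta_map[sd.subject.id] = eta[i]
        if sd.y.size == 0:
            continue
        f_ind = _conc(sd, sd.t, cl_t[i] * np.exp(eta[i, 0]),
                      vd_t[i] * np.exp(eta[i, 1]))
        f_pop = _conc(sd, sd.t, cl_t[i], vd_t[i])
        cw = _cwres_subject(sd, cl_t[i], vd_t[i], eta[i], omega2, sigma)
        for j in range(sd.y.size):
            if sd.cens[j]:
                continue  # censored records carry no residual
            rows.append({"ID": sd.subject.id, "TIME": sd.t[j], "DV": sd.y[j],
                         "PRED": f_pop[j], "IPRED": f_ind[j], "CWRES": cw[j]})
    table = pd.DataFrame(rows, columns=["ID", "TIME", "DV", "PRED", "IPRED", "CWRES"])
    return FitResult(
        spec=spec,
        theta=theta,
        omega={"omega_cl": omega[0], "omega_vd": omega[1]},
        sigma={"sigma_prop": sigma[0], "sigma_add": sigma[1]},
        ofv=ofv,
        aic=aic(ofv, n_par),
        bic=bic(ofv, n_par, n_obs),
        n_par=n_par,
        n_obs=n_obs,
        etas=eta_map,
        residual_table=table,
        converged=converged,
        message=message,
        se_pct=se_pct,
    )


def _natural_objective(dataset, spec, bd, layout):
    """OFV as a function of the natural-scale parameter vector (for SEs)."""
    cache: dict = {}

    def f(v):
        x = np.array([np.log(vi) if is_log else vi
                      for vi, (_, is_log) in zip(v, layout)])
        theta, omega, sigma = _unpack(x, spec, layout)
        try:
            return foce_ofv(dataset, spec, theta, omega, sigma,
                            _cache=cache, _batch=bd)
        except (FloatingPointError, OverflowError):
            return 1e10

    return f


def _se_percent(f_natural, x_opt, layout, rel_step: float = 1e-3) -> dict:
    """SE% = 100*SE/estimate from the inverse finite-difference Hessian of
    the OFV (the covariance of an ML estimate is 2*H^-1 for a -2LL)."""
    v0 = np.array([np.exp(xi) if is_log else xi
                   for xi, (_, is_log) in zip(x_opt, layout)])
    n = v0.size
    h = np.maximum(np.abs(v0) * rel_step, 1e-6)
    H = np.zeros((n, n))
    f0 = f_natural(v0)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                vp = v0.copy(); vp[i] += h[i]
                vm = v0.copy(); vm[i] -= h[i]
                H[i, i] = (f_natural(vp) - 2 * f0 + f_natural(vm)) / h[i] ** 2
            else:
                vpp = v0.copy(); vpp[i] += h[i]; vpp[j] += h[j]
                vpm = v0.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
                vmp = v0.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
                vmm = v0.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    f_natural(vpp) - f_natural(vpm) - f_natural(vmp) + f_natural(vmm)
                ) / (4 * h[i] * h[j])
    names = [name for name, _ in layout]
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, FloatingPointError):
        warnings.warn("OFV Hessian not positive definite; SEs reported missing",
                      stacklevel=2)
        return {n: float("nan") for n in names}
    with np.errstate(invalid="ignore"):
        return {name: float(100.0 * s / abs(v)) if v != 0 else float("nan")
                for name, s, v in zip(names, se, v0)}


def _conc_grad_eta(sd: _SubjectData, t: np.ndarray, cl: float, vd: float):
    """Scalar-path prediction and analytic gradient wrt (eta_CL, eta_Vd)."""
    bd = _BatchData([_SubjectData(sd.subject, t, np.zeros_like(t),
                                  sd.dose_t, sd.amt, sd.dur)])
    f, a_cl, a_vd = _bconc(bd, np.array([cl]), np.array([vd]), grad=True)
    return f[0], np.column_stack([a_cl[0], a_vd[0]])


def _cwres_subject(sd, cl_typ, vd_typ, eta, omega2, sigma) -> np.ndarray:
    """First-order-conditional decorrelated residuals for one subject."""
    free = np.flatnonzero(omega2 > 0)
    f, A_full = _conc_grad_eta(sd, sd.t, cl_typ * np.exp(eta[0]),
                               vd_typ * np.exp(eta[1]))
    v = _resid_var(f, sigma[0], sigma[1])
    if free.size == 0:
        return (sd.y - f) / np.sqrt(v)
    A = A_full[:, free]
    cov = A @ np.diag(omega2[free]) @ A.T + np.diag(v)
    resid = sd.y - (f - A @ eta[free])
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular conditional covariance for subject {sd.subject.id}",
                      stacklevel=2)
        return np.full(sd.y.size, np.nan)
    return np.linalg.solve(L, resid)


def cwres(dataset: PKDataset, fit_result: FitResult) -> pd.DataFrame:
    """Per-observation conditional weighted residuals of a fitted model,
    approximately standard normal when the model is correct."""
    return fit_result.residual_table[["ID", "TIME", "CWRES"]].copy()
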