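"""Covariate models for clearance and volume in the pediatric cohort.

The final model scales volume allometrically on body weight and clearance on
both the kidney-function ratio KF (eGFR/120) and weight, all centered at the
cohort median weight of 12 kg:

    Vd = theta_vd * (WT/12)^theta1
    CL = theta_cl * KF^theta2 * (WT/12)^theta3

Seven candidate parameterizations of the weight/age/BSA dependence of
clearance are also provided (fixed 3/4 allometry, estimated exponents on WT
or BSA, a sigmoid age-maturation factor, and WT/age/BSA-dependent exponents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Cohort median body weight used as the allometric reference, kg.
WT_REF = 12.0
#: Cohort median body surface area used to normalize BSA models, m^2.
#: The candidate-model table writes the generic WT form for the BSA rows;
#: normalizing by the cohort median BSA is the natural reading and is used here.
BSA_REF = 0.55


@dataclass(frozen=True)
class ThetaFinal:
    """Fixed effects of the final covariate model (with reporting-scale
    variability terms alongside, as they are published together)."""

    theta_vd: float = 11.35   # L, typical volume at 12 kg
    theta_cl: float = 5.23    # L/h, typical clearance at 12 kg, KF=1
    theta1: float = 0.80      # WT exponent on Vd
    theta2: float = 0.92      # KF exponent on CL
    theta3: float = 1.02      # WT exponent on CL
    wt_ref: float = WT_REF
    omega_vd: float = 0.6578  # sqrt of IIV variance on Vd (65.78 %)
    omega_cl: float = 0.1290  # sqrt of IIV variance on CL (12.90 %)
    sigma_prop: float = 0.0823  # proportional residual SD (8.23 %)

    def __post_init__(self) -> None:
        if self.theta_vd <= 0 or self.theta_cl <= 0:
            raise ValueError("typical values must be positive")


#: The published final-model estimates.
FINAL_ESTIMATES = ThetaFinal()


def final_vd(theta: ThetaFinal, wt) -> float:
    """Typical volume of distribution (L): theta_vd * (wt/wt_ref)^theta1."""
    wt = np.asarray(wt, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("wt must be positive")
    out = theta.theta_vd * (wt / theta.wt_ref) ** theta.theta1
    return float(out) if out.ndim == 0 else out


def final_cl(theta: ThetaFinal, wt, kf) -> float:
    """Typical clearance (L/h): theta_cl * kf^theta2 * (wt/wt_ref)^theta3."""
    wt = np.asarray(wt, dtype=float)
    kf = np.asarray(kf, dtype=float)
    if np.any(wt <= 0) or np.any(kf <= 0):
        raise ValueError("wt and kf must be positive")
    out = theta.theta_cl * kf ** theta.theta2 * (wt / theta.wt_ref) ** theta.theta3
    return float(out) if out.ndim == 0 else out


def maturation_factor(age: float, tm50: float, gamma: float) -> float:
    """Sigmoid maturation factor MF = 1 / (1 + (age/tm50)^-gamma).

    MF is 0.5 at age = tm50 and tends to 1 with age. At age 0 the limit is 0
    (for any finite positive gamma) and 0 is returned.
    """
    if tm50 <= 0 or gamma <= 0:
        raise ValueError("tm50 and gamma must be positive")
    if age < 0:
        raise ValueError("age must be >= 0")
    if age == 0:
        return 0.0
    return float(1.0 / (1.0 + (age / tm50) ** (-gamma)))


def dependent_exponent(
    x: float, k0: float, kmax: float, k50: float, gamma: float
) -> float:
    """Covariate-dependent allometric exponent.

    k1 = k0 - kmax * x^gamma / (k50^gamma + x^gamma), a sigmoid decline from
    k0 (at x=0) to k0-kmax, halfway at x = k50. ``x`` is weight (kg), age
    (years) or BSA (m^2) depending on the model.
    """
    if k50 <= 0:
        raise ValueError("k50 must be positive")
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0:
        return float(k0)
    return float(k0 - kmax * x**gamma / (k50**gamma + x**gamma))


class CandidateModel(str, Enum):
    """The seven candidate clearance parameterizations."""

    I = "I"      # fixed 3/4 allometric exponent on WT
    II = "II"    # estimated exponent on WT
    III = "III"  # estimated exponent on BSA
    IV = "IV"    # fixed 3/4 on WT with sigmoid age maturation
    V = "V"      # WT-dependent exponent on WT
    VI = "VI"    # age-dependent exponent on WT
    VII = "VII"  # BSA-dependent exponent on WT


@dataclass
class CandidateParams:
    """Parameters of one candidate clearance model; only the fields the
    chosen ``model_id`` uses are consulted."""

    model_id: CandidateModel
    theta_cl: float
    theta_vd: float = FINAL_ESTIMATES.theta_vd
    k1: float | None = None       # estimated exponent (II on WT, III on BSA)
    tm50: float | None = None     # years (IV)
    gamma: float | None = None    # Hill coefficient (IV-VII)
    k0: float | None = None       # exponent at covariate 0 (V-VII)
    kmax: float | None = None     # maximum exponent decrease (V-VII)
    k50: float | None = None      # kg / years / m^2 per model (V-VII)

    def __post_init__(self) -> None:
        self.model_id = CandidateModel(self.model_id)
        if self.theta_cl <= 0:
            raise ValueError("theta_cl must be positive")


def _require(params: CandidateParams, *names: str) -> None:
    for n in names:
        if getattr(params, n) is None:
            raise ValueError(
                f"model {params.model_id.value} requires parameter {n!r}"
            )


def candidate_cl(
    params: CandidateParams,
    wt: float,
    bsa: float | None = None,
    age: float | None = None,
) -> float:
    """Clearance (L/h) under one of the seven candidate models.

    The study dosed intravenously; the candidate table's "CL/F" is read with
    bioavailability F = 1 throughout.
    """
    if wt <= 0:
        raise ValueError("wt must be positive")
    m = params.model_id
    if m is CandidateModel.I:
        k1, mf = 0.75, 1.0
        base = wt / WT_REF
    elif m is CandidateModel.II:
        _require(params, "k1")
        k1, mf = params.k1, 1.0
        base = wt / WT_REF
    elif m is CandidateModel.III:
        _require(params, "k1")
        if bsa is None:
            raise ValueError("model III requires bsa")
        k1, mf = params.k1, 1.0
        base = bsa / BSA_REF
    elif m is CandidateModel.IV:
        _require(params, "tm50", "gamma")
        if age is None:
            raise ValueError("model IV requires age")
        k1 = 0.75
        mf = maturation_factor(age, params.tm50, params.gamma)
        base = wt / WT_REF
    elif m is CandidateModel.V:
        _require(params, "k0", "kmax", "k50", "gamma")
        k1 = dependent_exponent(wt, params.k0, params.kmax, params.k50, params.gamma)
        mf = 1.0
        base = wt / WT_REF
    elif m is CandidateModel.VI:
        _require(params, "k0", "kmax", "k50", "gamma")
        if age is None:
            raise ValueError("model VI requires age")
        k1 = dependent_exponent(age, params.k0, params.kmax, params.k50, params.gamma)
        mf = 1.0
        base = wt / WT_REF
    elif m is CandidateModel.VII:
        # The printed model VII row applies a BSA-driven exponent to the WT
        # power term; implemented as printed.
        _require(params, "k0", "kmax", "k50", "gamma")
        if bsa is None:
            raise ValueError("model VII requires bsa")
        k1 = dependent_exponent(bsa, params.k0, params.kmax, params.k50, params.gamma)
        mf = 1.0
        base = wt / WT_REF
    else:  # pragma: no cover
        raise ValueError(m)
    return float(params.theta_cl * base**k1 * mf)
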