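"""Stepwise covariate model building on the objective function value.

Candidates are screened for collinearity first (pairs with |r| > 0.5 are
never in the model simultaneously), then added one at a time when they drop
the OFV by at least 3.84 (the chi-square 1-df 5% critical value) and kept
after backward elimination only when their removal raises the OFV by at
least 6.63 (1%). Continuous covariates enter as power terms centered at the
cohort median; categorical covariates as exponential terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gcvpk.data import PKDataset, Subject
from gcvpk.nlme import FitResult, ModelSpec, ParamDef, fit

__all__ = [
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
    "CovariateCandidate",
    "SelectionTrace",
    "correlation_screen",
    "add_covariate",
    "forward_step",
    "stepwise_search",
]

log = logging.getLogger(__name__)

#: chi-square(1 df) critical value at alpha = 0.05 (forward inclusion).
FORWARD_DOFV = 3.84
#: chi-square(1 df) critical value at alpha = 0.01 (backward retention).
BACKWARD_DOFV = 6.63


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate effect to test on CL or Vd.

    ``form`` is ``"power"`` for continuous covariates — the typical value is
    multiplied by (cov/ref)^beta — or ``"exponential"`` for categorical ones
    (times exp(beta*cov)). ``name`` must be an attribute of
    :class:`~gcvpk.data.Subject` (wt, age, kf, bsa, scr, egfr, height) or
    ``sex`` (coded M=1, F=0).
    """

    target: str          # "CL" or "Vd"
    name: str
    form: str = "power"
    ref: float = 1.0     # centering value for power form

    def __post_init__(self) -> None:
        if self.target not in ("CL", "Vd"):
            raise ValueError("target must be 'CL' or 'Vd'")
        if self.form not in ("power", "exponential"):
            raise ValueError("form must be 'power' or 'exponential'")

    @property
    def label(self) -> str:
        return f"{self.target}-{self.name.upper()}"


def _cov_value(subject: Subject, name: str) -> float:
    if name == "sex":
        return 1.0 if subject.sex == "M" else 0.0
    return float(getattr(subject, name))


@dataclass
class SelectionTrace:
    """Ordered record of stepwise decisions, exportable in the familiar
    screening-table layout (step, covariates, OFV, dOFV, decision)."""

    steps: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "phase", "model", "ofv", "dofv", "decision"]
        )


def correlation_screen(
    covariates: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, set[frozenset]]:
    """Pairwise Pearson correlations and the mutually exclusive pairs.

    Returns the correlation matrix and the set of covariate-name pairs with
    |r| > ``threshold`` that must not enter the model together. Constant
    columns have undefined correlation and are dropped with a warning.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariate columns")
    keep = []
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            warnings.warn(f"covariate {col} is constant; excluded from screen",
                          stacklevel=2)
        else:
            keep.append(col)
    corr = covariates[keep].corr()
    excluded = {
        frozenset((a, b))
        for i, a in enumerate(keep)
        for b in keep[i + 1:]
        if abs(corr.loc[a, b]) > threshold
    }
    return corr, excluded


def add_covariate(spec: ModelSpec, cand: CovariateCandidate) -> ModelSpec:
    """Extend a model with one covariate effect (one new parameter, df=1)."""
    beta_name = f"beta_{cand.target.lower()}_{cand.name}"
    if any(p.name == beta_name for p in spec.params):
        raise ValueError(f"{cand.label} already in model {spec.name}")
    prev_cl, prev_vd = spec.cl, spec.vd

    if cand.form == "power":
        factor = lambda th, s: (_cov_value(s, cand.name) / cand.ref) ** th[beta_name]
    else:
        factor = lambda th, s: np.exp(th[beta_name] * _cov_value(s, cand.name))

    if cand.target == "CL":
        new_cl = lambda th, s: prev_cl(th, s) * factor(th, s)
        new_vd = prev_vd
    else:
        new_cl = prev_cl
        new_vd = lambda th, s: prev_vd(th, s) * factor(th, s)
    return replace(
        spec,
        name=f"{spec.name}+{cand.label}",
        params=spec.params + (ParamDef(beta_name, 0.1),),
        cl=new_cl,
        vd=new_vd,
    )


def _admissible(cand: CovariateCandidate, included: list[CovariateCandidate],
                excluded_pairs: set[frozenset]) -> bool:
    if any(c.target == cand.target and c.name == cand.name for c in included):
        return False
    for c in included:
        if frozenset((c.name, cand.name)) in excluded_pairs and c.name != cand.name:
            return False
    return True


def forward_step(
    current: FitResult,
    candidates: list[CovariateCandidate],
    dataset: PKDataset,
    included: list[CovariateCandidate] | None = None,
    excluded_pairs: set[frozenset] | None = None,
    dofv_threshold: float = FORWARD_DOFV,
    **fit_kwargs,
) -> tuple[CovariateCandidate, FitResult] | None:
    """Try each admissible candidate on the current model; return the one
    with the largest OFV drop if it reaches the inclusion threshold.

    Ties break toward the larger drop, then lexicographic label. Candidate
    fits that fail outright are skipped with a log entry.
    """
    included = included or []
    excluded_pairs = excluded_pairs or set()
    results: list[tuple[float, str, CovariateCandidate, FitResult]] = []
    for cand in candidates:
        if not _admissible(cand, included, excluded_pairs):
            continue
        try:
            spec = add_covariate(current.spec, cand).with_inits(
                current.theta,
                omega=(current.omega["omega_cl"], current.omega["omega_vd"]),
                sigma=(current.sigma["sigma_prop"] or 0.15,
                       current.sigma["sigma_add"] or 0.1),
            )
            res = fit(dataset, spec, **fit_kwargs)
        except Exception as exc:  # candidate failure must not kill the search
            log.warning("candidate %s failed to fit: %s", cand.label, exc)
            continue
        results.append((current.ofv - res.ofv, cand.label, cand, res))
    if not results:
        return None
    results.sort(key=lambda r: (-r[0], r[1]))
    drop, _, best_cand, best_res = results[0]
    if drop >= dofv_threshold:
        return best_cand, best_res
    return None


def stepwise_search(
    base: ModelSpec | FitResult,
    candidates: list[CovariateCandidate],
    dataset: PKDataset,
    excluded_pairs: set[frozenset] | None = None,
    forward_threshold: float = FORWARD_DOFV,
    backward_threshold: float = BACKWARD_DOFV,
    max_steps: int = 20,
    **fit_kwargs,
) -> tuple[FitResult, SelectionTrace]:
    """Forward inclusion to a full model, then backward elimination.

    Forward: repeat :func:`forward_step` until no admissible candidate drops
    the OFV by >= 3.84. Backward: remove each included covariate in turn,
    keeping those whose removal raises the OFV by >= 6.63. Emits a
    screening-table trace. A cycle guard terminates after ``max_steps``
    with a warning.
    """
    current = base if isinstance(base, FitResult) else fit(dataset, base, **fit_kwargs)
    trace: list[dict] = [
        {"step": 1, "phase": "base", "model": current.spec.name,
         "ofv": current.ofv, "dofv": np.nan, "decision": "base model"}
    ]
    included: list[CovariateCandidate] = []
    step = 1
    for _ in range(max_steps):
        out = forward_step(current, candidates, dataset, included,
                           excluded_pairs, forward_threshold, **fit_kwargs)
        if out is None:
            break
        cand, res = out
        step += 1
        trace.append({"step": step, "phase": "forward", "model": res.spec.name,
                      "ofv": res.ofv, "dofv": res.ofv - current.ofv,
                      "decision": f"include {cand.label} (p<0.05)"})
        included.append(cand)
        current = res
    else:
        warnings.warn("stepwise search hit the step limit; terminated", stacklevel=2)

    # backward elimination from the full model
    full = current
    for cand in list(included):
        remaining = [c for c in included if c is not cand]
        spec = full.spec  # rebuild from scratch with the remaining set
        reduced_spec = _rebuild(base, remaining)
        reduced_spec = reduced_spec.with_inits(
            {k: v for k, v in current.theta.items() if any(
                p.name == k for p in reduced_spec.params)},
            omega=(current.omega["omega_cl"], current.omega["omega_vd"]),
        )
        try:
            reduced = fit(dataset, reduced_spec, **fit_kwargs)
        except Exception as exc:
            log.warning("backward refit without %s failed: %s", cand.label, exc)
            continue
        rise = reduced.ofv - current.ofv
        step += 1
        if rise < backward_threshold:
            trace.append({"step": step, "phase": "backward",
                          "model": reduced.spec.name, "ofv": reduced.ofv,
                          "dofv": rise,
                          "decision": f"remove {cand.label} (p>0.01)"})
            included.remove(cand)
            current = reduced
        else:
            trace.append({"step": step, "phase": "backward",
                          "model": current.spec.name, "ofv": reduced.ofv,
                          "dofv": rise,
                          "decision": f"retain {cand.label} (p<0.01)"})
    return current, SelectionTrace(trace)


def _rebuild(base: ModelSpec | FitResult, covs: list[CovariateCandidate]) -> ModelSpec:
    spec = base.spec if isinstance(base, FitResult) else base
    for c in covs:
        spec = add_covariate(spec, c)
    return spec
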