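"""Model validation: nonparametric bootstrap, visual predictive check (VPC),
and normalized prediction distribution errors (NPDE).

All three condition on the observed design (dosing histories, sampling times
and covariates) and simulate new concentration vectors from the fitted
hierarchy when simulation is required.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gcvpk.data import PKDataset
from gcvpk.nlme import FitResult, ModelSpec, _conc, _prepare, fit


def _typicals(spec: ModelSpec, theta: dict, sd) -> tuple[float, float]:
    return float(spec.cl(theta, sd.subject)), float(spec.vd(theta, sd.subject))

__all__ = [
    "BootstrapResult",
    "VpcResult",
    "NpdeResult",
    "bootstrap_bias",
    "bootstrap",
    "simulate_observations",
    "vpc",
    "npde",
]

log = logging.getLogger(__name__)


def bootstrap_bias(median_estimate: float, final_estimate: float) -> float:
    """Percent bias of a bootstrap median against the final-model estimate:
    100 * (median - estimate) / estimate."""
    if final_estimate == 0:
        raise ZeroDivisionError("final estimate must be nonzero")
    return 100.0 * (median_estimate - final_estimate) / final_estimate


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap medians, 2.5/97.5 percentiles and percent
    bias against the reference fit; flagged when fewer than 80% of
    replicates converge."""

    table: pd.DataFrame  # index: parameter; columns: estimate, median, p2.5, p97.5, bias_pct
    n_replicates: int
    n_converged: int
    flagged: bool


def _resample(dataset: PKDataset, rng: np.random.Generator) -> PKDataset:
    """Subjects resampled with replacement to the original count; records
    travel with their subject. Duplicated subjects get fresh ids."""
    ids = [s.id for s in dataset.subjects]
    picks = rng.choice(len(ids), size=len(ids), replace=True)
    subjects, doses, obs = [], {}, {}
    from dataclasses import replace as dc_replace

    for k, idx in enumerate(picks):
        src = dataset.subjects[idx]
        new_id = f"B{k:04d}"
        s = dc_replace(src, id=new_id)
        subjects.append(s)
        doses[new_id] = list(dataset.doses[src.id])
        obs[new_id] = list(dataset.observations[src.id])
    return PKDataset(subjects=subjects, doses=doses, observations=obs)


def bootstrap(
    dataset: PKDataset,
    spec: ModelSpec,
    reference: FitResult,
    n_replicates: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric bootstrap of the model parameters.

    Each replicate resamples subjects with replacement, refits (warm-started
    from the reference estimates) and records the estimates; medians and
    2.5/97.5 percentiles are taken over converged replicates and the bias
    column applies :func:`bootstrap_bias` per parameter.
    """
    rng = np.random.default_rng(seed)
    warm = spec.with_inits(
        reference.theta,
        omega=(reference.omega["omega_cl"], reference.omega["omega_vd"]),
    )
    rows = []
    n_conv = 0
    for r in range(n_replicates):
        bs = _resample(dataset, rng)
        try:
            res = fit(bs, warm, seed=int(rng.integers(2**31)), **fit_kwargs)
        except Exception as exc:
            log.warning("bootstrap replicate %d failed: %s", r, exc)
            continue
        if res.converged:
            n_conv += 1
            rows.append(res.params_flat())
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    reps = pd.DataFrame(rows)
    ref_flat = reference.params_flat()
    table = pd.DataFrame(
        {
            "estimate": {k: ref_flat[k] for k in reps.columns},
            "median": reps.median(),
            "p2.5": reps.quantile(0.025),
            "p97.5": reps.quantile(0.975),
        }
    )
    table["bias_pct"] = [
        bootstrap_bias(m, e) if e != 0 else np.nan
        for m, e in zip(table["median"], table["estimate"])
    ]
    flagged = n_conv < 0.8 * n_replicates
    if flagged:
        warnings.warn(
            f"only {n_conv}/{n_replicates} bootstrap replicates converged",
            stacklevel=2,
        )
    return BootstrapResult(table=table, n_replicates=n_replicates,
                           n_converged=n_conv, flagged=flagged)


# ---------------------------------------------------------------------------
# simulation under a fitted model (shared by VPC and NPDE)

def simulate_observations(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate ``n_sim`` replicate concentration vectors on the observed
    design. Returns the observation table (ID, TIME, TAD, DV) and an
    (n_sim, n_obs) matrix of simulated concentrations (clipped at zero)."""
    subject_data = [sd for sd in _prepare(dataset) if sd.y.size]
    rows = []
    blocks = []
    for sd in subject_data:
        cl_typ, vd_typ = _typicals(spec, theta, sd)
        etas = rng.normal(0.0, 1.0, size=(n_sim, 2)) * np.asarray(omega)
        f = np.empty((n_sim, sd.y.size))
        for k in range(n_sim):
            f[k] = _conc(sd, sd.t, cl_typ * np.exp(etas[k, 0]),
                         vd_typ * np.exp(etas[k, 1]))
        eps_p = rng.normal(0.0, 1.0, size=f.shape)
        eps_a = rng.normal(0.0, 1.0, size=f.shape)
        y = f * (1.0 + sigma[0] * eps_p) + sigma[1] * eps_a
        blocks.append(np.maximum(y, 0.0))
        last_dose = np.array([sd.dose_t[sd.dose_t <= t].max() for t in sd.t])
        for j in range(sd.y.size):
            rows.append({"ID": sd.subject.id, "TIME": sd.t[j],
                         "TAD": sd.t[j] - last_dose[j], "DV": sd.y[j]})
    table = pd.DataFrame(rows)
    sims = np.concatenate(blocks, axis=1) if blocks else np.empty((n_sim, 0))
    return table, sims


@dataclass
class VpcResult:
    """Binned observed percentiles with simulated 95% bands per percentile.

    ``summary`` has one row per (bin, percentile) with the observed value
    and the band; ``coverage`` is the fraction of observed percentile points
    inside their bands.
    """

    summary: pd.DataFrame
    bin_edges: np.ndarray
    n_sim: int
    coverage: float


_VPC_PERCENTILES = (2.5, 50.0, 97.5)


def vpc(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
    n_sim: int = 1000,
    seed: int = 0,
    n_bins: int = 6,
    min_bin_size: int = 5,
) -> VpcResult:
    """Visual predictive check on time-after-last-dose bins.

    Observed 2.5/50/97.5 percentiles per bin are compared with the 95%
    interval of the same percentiles over ``n_sim`` simulated replicates.
    Equal-count bins are used (opportunistic sampling makes fixed-width
    bins unstable); bins below ``min_bin_size`` merge with a neighbor.
    """
    rng = np.random.default_rng(seed)
    table, sims = simulate_observations(dataset, spec, theta, omega, sigma, n_sim, rng)
    tad = table["TAD"].to_numpy()
    edges = np.unique(np.quantile(tad, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    # merge undersized bins leftward
    counts = np.bincount(idx, minlength=len(edges) - 1)
    while len(edges) > 2 and counts.min() < min_bin_size:
        b = int(counts.argmin())
        log.info("merging undersized VPC bin %d (n=%d)", b, counts[b])
        edges = np.delete(edges, b if b > 0 else 1)
        idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)

    rows = []
    inside = 0
    for b in range(len(edges) - 1):
        mask = idx == b
        obs_p = np.percentile(table.loc[mask, "DV"], _VPC_PERCENTILES)
        sim_p = np.percentile(sims[:, mask], _VPC_PERCENTILES, axis=1)  # (3, n_sim)
        lo = np.percentile(sim_p, 2.5, axis=1)
        hi = np.percentile(sim_p, 97.5, axis=1)
        med = np.percentile(sim_p, 50.0, axis=1)
        for p, o, l, m, h in zip(_VPC_PERCENTILES, obs_p, lo, med, hi):
            inside += int(l <= o <= h)
            rows.append({"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
                         "n": int(mask.sum()), "percentile": p, "observed": o,
                         "sim_lo": l, "sim_median": m, "sim_hi": h})
    summary = pd.DataFrame(rows)
    return VpcResult(summary=summary, bin_edges=edges, n_sim=n_sim,
                     coverage=inside / len(rows))


@dataclass
class NpdeResult:
    """Per-observation NPDE with the four calibration tests.

    Under a correct model the NPDE are standard normal: the Wilcoxon
    signed-rank test checks mean 0, a chi-square variance test checks
    variance 1, Shapiro-Wilk checks normality, and the global p-value is
    the Bonferroni combination (3 * min p, capped at 1).
    """

    table: pd.DataFrame  # ID, TIME, TAD, DV, PRED, NPDE
    p_wilcoxon: float
    p_variance: float
    p_shapiro: float
    p_global: float

    @property
    def values(self) -> np.ndarray:
        return self.table["NPDE"].to_numpy()


def npde(
    dataset: PKDataset,
    spec: ModelSpec,
    theta: dict,
    omega: tuple[float, float],
    sigma: tuple[float, float],
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors.

    Per subject, the observed vector and each simulated replicate are
    decorrelated with the Cholesky factor of the empirical covariance of
    the simulated vectors; the rank of each decorrelated observation within
    its simulated distribution is inverse-normal transformed. Subjects with
    a singular simulated covariance are excluded with a log entry. With one
    observation per subject the decorrelation reduces to centering/scaling,
    i.e. the plain inverse-normal rank statistic.
    """
    rng = np.random.default_rng(seed)
    subject_data = [sd for sd in _prepare(dataset) if sd.y.size]
    rows = []
    for sd in subject_data:
        cl_typ, vd_typ = _typicals(spec, theta, sd)
        etas = rng.normal(0.0, 1.0, size=(n_sim, 2)) * np.asarray(omega)
        f = np.empty((n_sim, sd.y.size))
        for k in range(n_sim):
            f[k] = _conc(sd, sd.t, cl_typ * np.exp(etas[k, 0]),
                         vd_typ * np.exp(etas[k, 1]))
        y_sim = f * (1.0 + sigma[0] * rng.normal(size=f.shape)) \
            + sigma[1] * rng.normal(size=f.shape)
        mean = y_sim.mean(axis=0)
        cov = np.cov(y_sim, rowvar=False).reshape(sd.y.size, sd.y.size)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            log.warning("singular simulated covariance; subject %s excluded",
                        sd.subject.id)
            continue
        y_star = np.linalg.solve(L, sd.y - mean)
        sim_star = np.linalg.solve(L, (y_sim - mean).T)  # (n_obs, n_sim)
        pde = (sim_star < y_star[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        vals = stats.norm.ppf(pde)
        f_pop = _conc(sd, sd.t, cl_typ, vd_typ)
        last_dose = np.array([sd.dose_t[sd.dose_t <= t].max() for t in sd.t])
        for j in range(sd.y.size):
            rows.append({"ID": sd.subject.id, "TIME": sd.t[j],
                         "TAD": sd.t[j] - last_dose[j], "DV": sd.y[j],
                         "PRED": f_pop[j], "NPDE": vals[j]})
    table = pd.DataFrame(rows)
    v = table["NPDE"].to_numpy()
    n = v.size
    p_wil = float(stats.wilcoxon(v).pvalue) if n >= 10 else float("nan")
    # two-sided chi-square test of Var = 1
    chi = (n - 1) * v.var(ddof=1)
    p_var = float(2 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1)))
    p_sha = float(stats.shapiro(v).pvalue)
    p_glob = float(min(1.0, 3.0 * min(p_wil, p_var, p_sha)))
    return NpdeResult(table=table, p_wilcoxon=p_wil, p_variance=p_var,
                      p_shapiro=p_sha, p_global=p_glob)
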