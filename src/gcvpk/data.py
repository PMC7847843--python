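"""Domain types and dataset I/O for the sparse pediatric PK study design.

The canonical on-disk format is a NONMEM-convention rectangular CSV: dose rows
carry ``EVID=1`` with ``AMT``/``DUR`` (or ``RATE``), observation rows carry
``EVID=0`` (or ``MDV=0``) with ``DV`` in ug/mL. Time is hours since each
subject's first dose; doses are mg. Covariates (WT, HT, AGE, SEX, SCR, EGFR)
are constant within subject; the first value wins and conflicts warn.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

#: Lower limit of quantification of the assay, ug/mL.
LLOQ = 0.1

#: Normal kidney function used to normalize eGFR into the KF ratio,
#: mL/min/1.73 m^2.
EGFR_NORMAL = 120.0


class DatasetFormatError(ValueError):
    """A mandatory column is missing or the file layout is wrong."""


class DatasetParseError(ValueError):
    """A cell could not be parsed as a number."""


class DatasetValidationError(ValueError):
    """The parsed records violate a study-design invariant."""


class RenalClass(str, Enum):
    """Renal function bands on eGFR (mL/min/1.73 m^2): cutoffs 30/60/90/120."""

    ELEVATED = "elevated"   # eGFR >= 120
    NORMAL = "normal"       # 90 <= eGFR < 120
    MILD = "mild"           # 60 <= eGFR < 90
    MODERATE = "moderate"   # 30 <= eGFR < 60
    SEVERE = "severe"       # eGFR < 30


def compute_bsa(height: float, wt: float) -> float:
    """Body surface area (m^2) by the Mosteller formula sqrt(height*wt/3600).

    Parameters
    ----------
    height : float
        Height in cm, > 0.
    wt : float
        Body weight in kg, > 0.
    """
    if height <= 0 or wt <= 0:
        raise ValueError(f"height and wt must be positive, got {height}, {wt}")
    return float(np.sqrt(height * wt / 3600.0))


def compute_kf(egfr: float) -> float:
    """Dimensionless kidney-function ratio: individual eGFR / 120."""
    if egfr <= 0:
        raise ValueError(f"egfr must be positive, got {egfr}")
    return egfr / EGFR_NORMAL


def classify_renal(egfr: float) -> RenalClass:
    """Classify renal function from eGFR; lower band edges are inclusive."""
    if egfr <= 0:
        raise ValueError(f"egfr must be positive, got {egfr}")
    if egfr >= 120:
        return RenalClass.ELEVATED
    if egfr >= 90:
        return RenalClass.NORMAL
    if egfr >= 60:
        return RenalClass.MILD
    if egfr >= 30:
        return RenalClass.MODERATE
    return RenalClass.SEVERE


# The pediatric eGFR formula used by the source study is not reproduced here;
# eGFR is an input column. A pluggable calculator hook exists for users who
# want to recompute it from SCR/height; the default passes the input through.
EgfrCalculator = Callable[[float, float, float], float]


def identity_egfr(egfr: float, scr: float, height: float) -> float:
    """Default eGFR calculator: return the provided eGFR unchanged."""
    return egfr


@dataclass(frozen=True)
class Subject:
    """One study subject with covariates and derived renal descriptors.

    Units: wt kg, height cm, age years, scr umol/L, egfr mL/min/1.73 m^2.
    ``bsa`` (m^2), ``kf`` (eGFR/120) and ``renal_class`` are derived at
    construction and must not be supplied.
    """

    id: str
    wt: float
    height: float
    age: float
    sex: str
    scr: float
    egfr: float
    bsa: float = field(init=False)
    kf: float = field(init=False)
    renal_class: RenalClass = field(init=False)

    def __post_init__(self) -> None:
        if self.wt <= 0 or self.height <= 0:
            raise ValueError(f"subject {self.id}: wt and height must be positive")
        if self.age < 0:
            raise ValueError(f"subject {self.id}: age must be non-negative")
        if self.sex not in ("M", "F"):
            raise ValueError(f"subject {self.id}: sex must be 'M' or 'F'")
        if self.egfr <= 0:
            raise ValueError(f"subject {self.id}: egfr must be positive")
        object.__setattr__(self, "bsa", compute_bsa(self.height, self.wt))
        object.__setattr__(self, "kf", compute_kf(self.egfr))
        object.__setattr__(self, "renal_class", classify_renal(self.egfr))


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order IV infusion: ``amount`` mg over ``infusion_duration`` h."""

    time: float
    amount: float
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be > 0")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Observation:
    """A timed serum concentration (ug/mL); below_loq flags conc < LLOQ."""

    time: float
    conc: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class PKDataset:
    """Per-subject dosing histories and sparse concentration observations."""

    subjects: list[Subject]
    doses: dict[str, list[DoseEvent]]
    observations: dict[str, list[Observation]]

    def __post_init__(self) -> None:
        ids = {s.id for s in self.subjects}
        for sid, obs in self.observations.items():
            if sid not in ids:
                raise DatasetValidationError(f"observations for unknown subject {sid}")
            dose_list = self.doses.get(sid, [])
            if obs and not dose_list:
                raise DatasetValidationError(f"subject {sid} has observations but no dose")
            if obs and dose_list and min(o.time for o in obs) < min(d.time for d in dose_list):
                raise DatasetValidationError(
                    f"subject {sid} has an observation before the first dose"
                )
            times = [o.time for o in obs]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise DatasetValidationError(
                    f"subject {sid}: observation times must be strictly increasing"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(v) for v in self.observations.values())

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def covariate_frame(self) -> pd.DataFrame:
        """One row per subject: WT, HT, AGE, SEX (1=M), SCR, EGFR, BSA, KF."""
        return pd.DataFrame(
            {
                "ID": [s.id for s in self.subjects],
                "WT": [s.wt for s in self.subjects],
                "HT": [s.height for s in self.subjects],
                "AGE": [s.age for s in self.subjects],
                "SEX": [1.0 if s.sex == "M" else 0.0 for s in self.subjects],
                "SCR": [s.scr for s in self.subjects],
                "EGFR": [s.egfr for s in self.subjects],
                "BSA": [s.bsa for s in self.subjects],
                "KF": [s.kf for s in self.subjects],
            }
        ).set_index("ID")

    def manifest(self) -> dict:
        """JSON-ready summary: counts plus covariate summaries (cohort layout)."""
        cov = self.covariate_frame()
        summaries = {}
        for col in ("AGE", "WT", "HT", "BSA", "SCR", "EGFR"):
            v = cov[col]
            summaries[col] = {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(v.median()),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        classes = pd.Series([s.renal_class.value for s in self.subjects])
        return {
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "sex": {"M": int((cov["SEX"] == 1).sum()), "F": int((cov["SEX"] == 0).sum())},
            "renal_classes": classes.value_counts().to_dict(),
            "covariates": summaries,
        }


_MANDATORY = ["ID", "TIME", "AMT", "DV", "WT", "HT", "AGE", "SEX", "SCR", "EGFR"]


def _parse_sex(value) -> str:
    if isinstance(value, str) and value.strip().upper() in ("M", "F"):
        return value.strip().upper()
    try:
        return "M" if float(value) == 1 else "F"
    except (TypeError, ValueError):
        raise DatasetParseError(f"cannot interpret SEX value {value!r}")


def read_dataset(
    path: str | Path,
    egfr_calculator: EgfrCalculator = identity_egfr,
) -> PKDataset:
    """Read a NONMEM-convention CSV into a :class:`PKDataset`.

    Dose rows are identified by ``EVID=1`` (or, lacking EVID, ``AMT>0``);
    observation rows by ``EVID=0``/``MDV=0``. ``DUR`` gives the infusion
    duration in hours; ``RATE`` (mg/h) is accepted instead, with
    duration = AMT/RATE.

    Raises
    ------
    DatasetFormatError
        If a mandatory column is missing.
    DatasetParseError
        If a numeric cell fails to parse (the row number is reported).
    DatasetValidationError
        If an observation precedes its subject's first dose.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str).rename(columns=str.upper)
    for col in _MANDATORY:
        if col not in df.columns:
            raise DatasetFormatError(f"mandatory column {col} is missing")
    if "DUR" not in df.columns and "RATE" not in df.columns:
        raise DatasetFormatError("either DUR or RATE column is required")

    numeric_cols = [c for c in df.columns if c not in ("ID", "SEX")]
    for col in numeric_cols:
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "" or pd.isna(raw):
                continue
            try:
                float(raw)
            except ValueError:
                raise DatasetParseError(
                    f"non-numeric value {raw!r} in column {col}, row {i + 2}"
                )
        # float() is correctly rounded (pandas' fast parser can be 1 ulp off,
        # which would break the bit-exact round-trip guarantee)
        df[col] = [
            np.nan if pd.isna(raw) or raw == "" else float(raw) for raw in df[col]
        ]

    subjects: list[Subject] = []
    doses: dict[str, list[DoseEvent]] = {}
    observations: dict[str, list[Observation]] = {}
    for sid, grp in df.groupby("ID", sort=False):
        cov = {}
        for col in ("WT", "HT", "AGE", "SCR", "EGFR"):
            vals = grp[col].dropna().unique()
            if len(vals) == 0:
                raise DatasetValidationError(f"subject {sid}: covariate {col} missing")
            if len(vals) > 1:
                warnings.warn(
                    f"subject {sid}: covariate {col} not constant; first value wins",
                    stacklevel=2,
                )
            cov[col] = float(vals[0])
        sex = _parse_sex(grp["SEX"].dropna().iloc[0])
        egfr = egfr_calculator(cov["EGFR"], cov["SCR"], cov["HT"])
        subjects.append(
            Subject(
                id=str(sid), wt=cov["WT"], height=cov["HT"], age=cov["AGE"],
                sex=sex, scr=cov["SCR"], egfr=egfr,
            )
        )
        dose_list: list[DoseEvent] = []
        obs_list: list[Observation] = []
        for _, row in grp.iterrows():
            evid = row.get("EVID")
            if pd.isna(evid) if evid is not None else True:
                evid = 1.0 if (not pd.isna(row["AMT"]) and row["AMT"] > 0) else 0.0
            if evid == 1:
                amt = float(row["AMT"])
                if "DUR" in df.columns and not pd.isna(row.get("DUR")):
                    dur = float(row["DUR"])
                elif "RATE" in df.columns and not pd.isna(row.get("RATE")):
                    dur = amt / float(row["RATE"])
                else:
                    raise DatasetValidationError(
                        f"subject {sid}: dose at t={row['TIME']} lacks DUR/RATE"
                    )
                dose_list.append(DoseEvent(float(row["TIME"]), amt, dur))
            else:
                mdv = row.get("MDV")
                if mdv is not None and not pd.isna(mdv) and mdv == 1:
                    continue
                conc = float(row["DV"])
                obs_list.append(Observation(float(row["TIME"]), conc, conc < LLOQ))
        doses[str(sid)] = sorted(dose_list, key=lambda d: d.time)
        observations[str(sid)] = sorted(obs_list, key=lambda o: o.time)

    return PKDataset(subjects=subjects, doses=doses, observations=observations)


def write_dataset(dataset: PKDataset, path: str | Path) -> None:
    """Write a :class:`PKDataset` back to the canonical CSV dialect.

    Numeric fields round-trip bit-exactly through :func:`read_dataset`
    (``repr`` formatting of Python floats).
    """
    rows: list[dict] = []
    for s in dataset.subjects:
        events: list[tuple[float, int, dict]] = []
        for d in dataset.doses.get(s.id, []):
            events.append((d.time, 0, {"EVID": 1, "AMT": repr(d.amount),
                                       "DUR": repr(d.infusion_duration),
                                       "DV": "", "MDV": 1}))
        for o in dataset.observations.get(s.id, []):
            events.append((o.time, 1, {"EVID": 0, "AMT": "", "DUR": "",
                                       "DV": repr(o.conc), "MDV": 0}))
        for t, _, ev in sorted(events, key=lambda e: (e[0], e[1])):
            rows.append({
                "ID": s.id, "TIME": repr(t), **ev,
                "WT": repr(s.wt), "HT": repr(s.height), "AGE": repr(s.age),
                "SEX": s.sex, "SCR": repr(s.scr), "EGFR": repr(s.egfr),
            })
    cols = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV",
            "WT", "HT", "AGE", "SEX", "SCR", "EGFR"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_manifest(dataset: PKDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.manifest(), indent=2))
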