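"""Virtual study generation and the shared dataset interchange format.

The generator emulates the clinical design behind the model: OUD patients on
chronic once-daily sublingual buprenorphine/naloxone, sampled pre-dose and at
0.5, 1, 2, 3, 4, 6 and 8 h after a witnessed dose, four analytes quantified
with an LLOQ of 0.05 ng/mL, eleven analyzable subjects with doses split
roughly 3 x 4 mg, 7 x 8 mg and 1 x 16 mg (mean 7.6 mg).  Steady state is
produced the way the patients produce it — a history of prior daily doses —
rather than by an analytic cyclic state.

The interchange format is a NONMEM-flavoured CSV with columns
ID, TIME, AMT, EVID, MDV, DVID, DV, BLQ, DOSE, AGE, WT, SEX: dose rows carry
EVID=1 and AMT in mg (prior doses at negative times), observation rows carry
EVID=0 and DV in ng/mL, DVID 1-4 = BUP, Nor-BUP, BUP-g, Nor-BUP-g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import DoseEvent, ThetaSet, simulate_profile
from .population import OmegaSpec, SigmaSpec, as_rng, sample_individuals

__all__ = [
    "StudyDesign",
    "Dataset",
    "DatasetFormatError",
    "generate_study",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DVID", "DV", "BLQ",
                   "DOSE", "AGE", "WT", "SEX"]


class DatasetFormatError(ValueError):
    """Malformed dataset file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class StudyDesign:
    """Design of one emulated study."""

    n_subjects: int = 11
    dose_allocation: Mapping[float, int] = field(
        default_factory=lambda: {4.0: 3, 8.0: 7, 16.0: 1}
    )
    times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    steady_state: bool = True
    n_prior_doses: int = 14
    lloq: float = 0.05
    dose_interval: float = 24.0
    split_dose_history: bool = False  # emulate the patients' twice-daily self-dosing
    #: optional missing-sample pattern: subject ID -> times without a sample
    missing: Mapping[int, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if sum(self.dose_allocation.values()) != self.n_subjects:
            raise ValueError("dose allocation must sum to n_subjects")
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must start at 0 and increase")
        if self.lloq <= 0:
            raise ValueError("LLOQ must be > 0")

    @property
    def doses_per_subject(self) -> list[float]:
        out: list[float] = []
        for dose, count in self.dose_allocation.items():
            out.extend([float(dose)] * count)
        return out


@dataclass
class Dataset:
    """A study: subject covariates, dosing records and observation records."""

    subjects: pd.DataFrame  # ID, DOSE, AGE, WT, SEX
    doses: pd.DataFrame  # ID, TIME, AMT (mg)
    observations: pd.DataFrame  # ID, TIME, DVID, DV, BLQ, MDV
    design: StudyDesign | None = None
    lloq: float = 0.05

    @property
    def n_subjects(self) -> int:
        return int(self.subjects["ID"].nunique())

    def subject_doses(self, sid) -> list[DoseEvent]:
        """Dose events for one subject, shifted so the earliest dose is t=0."""
        d = self.doses[self.doses["ID"] == sid].sort_values("TIME")
        t0 = float(d["TIME"].min())
        return [DoseEvent(float(t) - t0, float(a)) for t, a in zip(d["TIME"], d["AMT"])]

    def time_offset(self, sid) -> float:
        """Hours between a subject's first dose and the observation time origin."""
        d = self.doses[self.doses["ID"] == sid]
        return -float(d["TIME"].min())

    def to_frame(self) -> pd.DataFrame:
        """Single NONMEM-style table with one row per dose or observation."""
        cov = self.subjects.set_index("ID")
        rows = []
        for _, r in self.doses.iterrows():
            rows.append({"ID": r["ID"], "TIME": r["TIME"], "AMT": r["AMT"], "EVID": 1,
                         "MDV": 1, "DVID": 0, "DV": np.nan, "BLQ": 0})
        for _, r in self.observations.iterrows():
            rows.append({"ID": r["ID"], "TIME": r["TIME"], "AMT": 0.0, "EVID": 0,
                         "MDV": int(r["MDV"]), "DVID": int(r["DVID"]),
                         "DV": r["DV"], "BLQ": int(r["BLQ"])})
        df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                            ascending=[True, True, False])
        for c in ("DOSE", "AGE", "WT", "SEX"):
            df[c] = df["ID"].map(cov[c])
        return df[DATASET_COLUMNS].reset_index(drop=True)


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates near the recruited cohort's means (46.7 y, 68 kg, balanced sex)."""
    age = rng.normal(46.7, 0.15 * 46.7, n).clip(21, 80)
    wt = rng.normal(68.0, 0.15 * 68.0, n).clip(40, 130)
    sex = np.array([i % 2 for i in range(n)])  # 0=male, 1=female, balanced
    return pd.DataFrame({"AGE": np.round(age, 1), "WT": np.round(wt, 1), "SEX": sex})


def generate_study(
    design: StudyDesign | None = None,
    theta: ThetaSet | None = None,
    omega: OmegaSpec | None = None,
    sigma: SigmaSpec | None = None,
    seed=None,
) -> Dataset:
    """Simulate one study following the design.

    Each subject gets a chronic dosing history (``n_prior_doses`` daily doses,
    optionally split in two administrations) ending with the witnessed study
    dose at time 0, is solved with individual log-normal parameters, observed
    on the design grid with log-additive residual error, and flagged BLQ where
    the simulated value falls below the LLOQ.
    """
    design = design or StudyDesign()
    theta = theta or ThetaSet()
    omega = omega if omega is not None else OmegaSpec()
    sigma = sigma if sigma is not None else SigmaSpec()
    rng = as_rng(seed)

    n = design.n_subjects
    doses_mg = design.doses_per_subject
    individuals = sample_individuals(theta, omega, n, rng)
    cov = _covariates(rng, n)
    subjects = pd.DataFrame({"ID": np.arange(1, n + 1), "DOSE": doses_mg}).join(cov)

    tau = design.dose_interval
    obs_rows, dose_rows = [], []
    times = np.asarray(design.times, dtype=float)
    for i, ind in enumerate(individuals, start=1):
        dose = doses_mg[i - 1]
        sched: list[tuple[float, float]] = []
        if design.steady_state:
            for k in range(design.n_prior_doses, 0, -1):
                if design.split_dose_history:
                    sched.append((-k * tau, dose / 2))
                    sched.append((-k * tau + tau / 2, dose / 2))
                else:
                    sched.append((-k * tau, dose))
        sched.append((0.0, dose))
        for t, a in sched:
            dose_rows.append({"ID": i, "TIME": t, "AMT": a})

        t0 = sched[0][0]
        events = [DoseEvent(t - t0, a) for t, a in sched]
        keep = times
        if design.missing and i in design.missing:
            keep = np.array([t for t in times if t not in set(design.missing[i])])
        prof = simulate_profile(ind.theta, events, keep - t0)
        eps = rng.normal(0.0, 1.0, size=prof.values.shape) * sigma.as_array()
        dv = prof.values * np.exp(eps)
        for j in range(4):
            for t, v in zip(keep, dv[:, j]):
                obs_rows.append(
                    {"ID": i, "TIME": float(t), "DVID": j + 1, "DV": float(v),
                     "BLQ": int(v < design.lloq), "MDV": 0}
                )

    return Dataset(
        subjects=subjects,
        doses=pd.DataFrame(dose_rows),
        observations=pd.DataFrame(obs_rows),
        design=design,
        lloq=design.lloq,
    )


def write_dataset(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_dataset(path) -> Dataset:
    """Parse and validate the interchange CSV (see module docstring).

    Raises :class:`DatasetFormatError` with a line number for malformed rows,
    including an observation that precedes any dose for its subject.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetFormatError(f"missing columns {missing_cols}")
    df = df.copy()
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    for _, r in df.iterrows():
        line = int(r["_line"])
        if r["EVID"] not in (0, 1):
            raise DatasetFormatError(f"EVID must be 0 or 1, got {r['EVID']}", line)
        if r["EVID"] == 0:
            if not (1 <= r["DVID"] <= 4):
                raise DatasetFormatError(f"DVID must be 1-4, got {r['DVID']}", line)
            if r["MDV"] == 0 and not np.isfinite(r["DV"]):
                raise DatasetFormatError("observation row without a DV value", line)
            if r["MDV"] == 0 and r["DV"] <= 0:
                raise DatasetFormatError(f"DV must be > 0, got {r['DV']}", line)
        else:
            if not np.isfinite(r["AMT"]) or r["AMT"] < 0:
                raise DatasetFormatError(f"dose row with bad AMT {r['AMT']}", line)

    for sid, sub in df.groupby("ID"):
        d = sub[sub["EVID"] == 1]
        if d.empty:
            line = int(sub["_line"].iloc[0])
            raise DatasetFormatError(f"subject {sid} has no dose record", line)
        first_dose_t = d["TIME"].min()
        early = sub[(sub["EVID"] == 0) & (sub["TIME"] < first_dose_t)]
        if not early.empty:
            raise DatasetFormatError(
                f"subject {sid} has an observation before any dose",
                int(early["_line"].iloc[0]),
            )

    subjects = (
        df.groupby("ID")[["DOSE", "AGE", "WT", "SEX"]].first().reset_index()
    )
    doses = df[df["EVID"] == 1][["ID", "TIME", "AMT"]].reset_index(drop=True)
    obs = df[df["EVID"] == 0][["ID", "TIME", "DVID", "DV", "BLQ", "MDV"]].reset_index(
        drop=True
    )
    obs = obs.astype({"DVID": int, "BLQ": int, "MDV": int})
    return Dataset(subjects=subjects, doses=doses, observations=obs)
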