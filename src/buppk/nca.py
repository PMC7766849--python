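"""Non-compartmental analysis: Cmax/tmax, trough, trapezoidal AUC and molar
metabolic-pathway ratios.

The study design samples 0-8 h after a steady-state dose, far shorter than the
~37 h terminal half-life of buprenorphine, so no terminal-slope extrapolation
is attempted for observed data: the reported exposure is AUC over the sampling
window by the linear trapezoidal rule.

Metabolic-pathway activity is summarized with molar AUC ratios:
CYP3A4-mediated N-demethylation as (AUC_NorBUP/MW + AUC_NorBUPg/MW) over
AUC_BUP/MW, and UGT-mediated glucuronidation as AUC_BUPg/MW over AUC_BUP/MW.
Molar masses are configuration (defaults below, g/mol).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import ANALYTES

__all__ = [
    "MOLAR_MASSES",
    "NCAResult",
    "MolarRatioResult",
    "auc_trapezoid",
    "cmax_tmax",
    "compute_nca",
    "dose_normalize",
    "metabolic_ratios",
    "cohort_nca",
    "cohort_summary",
]

#: default molar masses, g/mol
MOLAR_MASSES: dict[str, float] = {
    "BUP": 467.6,
    "Nor-BUP": 413.5,
    "BUP-g": 643.8,
    "Nor-BUP-g": 589.7,
}


@dataclass(frozen=True)
class NCAResult:
    """Exposure metrics for one subject/analyte over the sampling window."""

    c0: float  # pre-dose trough, ng/mL (nan when no t=0 sample)
    cmax: float  # ng/mL
    tmax: float  # h
    auc: float  # ng*h/mL over the sampling window
    dose_mg: float | None = None
    cmax_dn: float | None = None  # (ng/mL)/mg
    auc_dn: float | None = None  # (ng*h/mL)/mg


@dataclass(frozen=True)
class MolarRatioResult:
    cyp_ratio: float  # (AUC_NorBUP + AUC_NorBUPg) : AUC_BUP, molar
    ugt_ratio: float  # AUC_BUPg : AUC_BUP, molar


def _check_profile(times, concentrations):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.size == 0 or t.shape != c.shape:
        raise ValueError("times and concentrations must be matching non-empty 1-D arrays")
    if np.any(np.diff(t) <= 0):
        if t.size > 1:
            raise ValueError("times must be strictly increasing")
    return t, c


def auc_trapezoid(times, concentrations) -> float:
    """Linear trapezoidal AUC; zero for a single observation."""
    t, c = _check_profile(times, concentrations)
    if t.size == 1:
        return 0.0
    return float(np.trapezoid(c, t))


def cmax_tmax(times, concentrations) -> tuple[float, float]:
    """Maximum observed concentration and its time (earliest on ties)."""
    t, c = _check_profile(times, concentrations)
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def compute_nca(times, concentrations, dose_mg: float | None = None) -> NCAResult:
    """Full per-profile NCA; ``c0`` is the sample at time zero if present."""
    t, c = _check_profile(times, concentrations)
    cmax, tmax = cmax_tmax(t, c)
    c0 = float(c[0]) if t[0] == 0.0 else float("nan")
    res = NCAResult(c0=c0, cmax=cmax, tmax=tmax, auc=auc_trapezoid(t, c), dose_mg=dose_mg)
    return dose_normalize(res, dose_mg) if dose_mg is not None else res


def dose_normalize(nca: NCAResult, dose_mg: float) -> NCAResult:
    """Per-subject dose normalization of Cmax and AUC."""
    if dose_mg is None or dose_mg <= 0:
        raise ValueError(f"dose must be > 0, got {dose_mg}")
    return dataclasses.replace(
        nca, dose_mg=dose_mg, cmax_dn=nca.cmax / dose_mg, auc_dn=nca.auc / dose_mg
    )


def metabolic_ratios(
    auc_bup: float,
    auc_norbup: float,
    auc_bupg: float,
    auc_norbupg: float,
    molar_masses: Mapping[str, float] | None = None,
) -> MolarRatioResult:
    """Molar AUC ratios of the CYP and UGT pathways."""
    mm = dict(MOLAR_MASSES if molar_masses is None else molar_masses)
    for a in ANALYTES:
        if mm.get(a, 0) <= 0:
            raise ValueError(f"molar mass for {a} must be > 0")
    if min(auc_bup, auc_norbup, auc_bupg, auc_norbupg) < 0:
        raise ValueError("AUCs must be non-negative")
    if auc_bup == 0:
        raise ZeroDivisionError("AUC of BUP is zero: molar ratios undefined")
    bup = auc_bup / mm["BUP"]
    return MolarRatioResult(
        cyp_ratio=(auc_norbup / mm["Nor-BUP"] + auc_norbupg / mm["Nor-BUP-g"]) / bup,
        ugt_ratio=(auc_bupg / mm["BUP-g"]) / bup,
    )


def cohort_nca(dataset, molar_masses: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-subject NCA of a study dataset, one row per subject x analyte.

    Below-quantification observations are excluded listwise before any metric
    is computed.  Molar pathway ratios are attached to the BUP row of each
    subject (columns ``cyp_ratio``/``ugt_ratio``).
    """
    obs = dataset.observations
    obs = obs[(obs.get("BLQ", 0) == 0) & (obs.get("MDV", 0) == 0)]
    rows = []
    for sid, sub in obs.groupby("ID"):
        dose = float(dataset.subjects.set_index("ID").loc[sid, "DOSE"])
        aucs = {}
        for dvid, grp in sub.groupby("DVID"):
            analyte = ANALYTES[int(dvid) - 1]
            grp = grp.sort_values("TIME")
            res = compute_nca(grp["TIME"].to_numpy(), grp["DV"].to_numpy(), dose_mg=dose)
            aucs[analyte] = res.auc
            rows.append(
                {
                    "ID": sid,
                    "ANALYTE": analyte,
                    "DOSE": dose,
                    "C0": res.c0,
                    "CMAX": res.cmax,
                    "TMAX": res.tmax,
                    "AUC": res.auc,
                    "CMAX_DN": res.cmax_dn,
                    "AUC_DN": res.auc_dn,
                }
            )
        if aucs.get("BUP", 0) > 0 and len(aucs) == 4:
            mr = metabolic_ratios(
                aucs["BUP"], aucs["Nor-BUP"], aucs["BUP-g"], aucs["Nor-BUP-g"], molar_masses
            )
            for r in rows[-4:]:
                if r["ID"] == sid and r["ANALYTE"] == "BUP":
                    r["cyp_ratio"] = mr.cyp_ratio
                    r["ugt_ratio"] = mr.ugt_ratio
    return pd.DataFrame(rows)


def cohort_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort means/SD per analyte.  Dose-normalized summaries are means of the
    per-subject ratios, not ratios of means."""
    cols = [c for c in ("DOSE", "C0", "CMAX", "TMAX", "AUC", "CMAX_DN", "AUC_DN",
                        "cyp_ratio", "ugt_ratio") if c in per_subject.columns]
    return per_subject.groupby("ANALYTE")[cols].agg(["mean", "std"])
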