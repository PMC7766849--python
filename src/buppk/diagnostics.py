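"""Simulation-based model evaluation: prediction-corrected visual predictive
checks and goodness-of-fit tables.

A pc-VPC simulates many replicate studies on the observed design, bins
observations by nominal sampling time, rescales observed and simulated values
in each bin by ``median(PRED in bin) / PRED_ij`` (so dose and design
differences do not inflate the spread), and overlays the observed 2.5th/50th/
97.5th percentiles on the 95% prediction intervals of those same percentiles
across the simulated replicates.  The computational contract is the result
table; plotting is a thin optional layer on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import _predict_log, _prepare_subjects, _eb_objective, _IIV_IDX
from .model_core import ANALYTES, PARAM_ORDER, ThetaSet
from .population import IIV_PARAMETERS, OmegaSpec, SigmaSpec, as_rng

__all__ = ["VPCResult", "prediction_correct", "pcvpc", "gof_tables", "plot_vpc"]

_PCTS = (2.5, 50.0, 97.5)


@dataclass(frozen=True)
class VPCResult:
    """Observed percentile curves and simulated percentile bands per analyte/bin.

    ``table`` columns: ANALYTE, BIN (nominal time), n_obs, obs_p2.5/50/97.5,
    and for each percentile the 95% prediction-interval bounds
    (``sim_p50_lo``/``sim_p50_hi`` etc.) across replicate studies.
    """

    table: pd.DataFrame
    n_sim: int
    bins: np.ndarray


def prediction_correct(
    observations: np.ndarray,
    population_predictions: np.ndarray,
    bins: np.ndarray,
) -> np.ndarray:
    """Prediction-corrected values: ``Y_ij * median(PRED in bin) / PRED_ij``.

    ``bins`` assigns each record to a bin label.  Records with a non-positive
    PRED are returned as NaN (excluded); a bin whose every PRED is
    non-positive is dropped with a warning.
    """
    y = np.asarray(observations, dtype=float)
    pred = np.asarray(population_predictions, dtype=float)
    bins = np.asarray(bins)
    if y.shape != pred.shape or y.shape != bins.shape:
        raise ValueError("observations, predictions and bins must align")
    out = np.full_like(y, np.nan)
    for b in np.unique(bins):
        m = bins == b
        ok = m & (pred > 0)
        if not ok.any():
            warnings.warn(f"bin {b!r}: no positive predictions, dropped")
            continue
        med = np.median(pred[ok])
        out[ok] = y[ok] * med / pred[ok]
    return out


def pcvpc(
    dataset,
    theta: ThetaSet,
    omega: OmegaSpec,
    sigma: SigmaSpec,
    n_sim: int = 1000,
    bins: Sequence[float] | None = None,
    seed=None,
) -> VPCResult:
    """Prediction-corrected VPC of ``dataset`` under the given model.

    ``n_sim`` replicate studies are simulated on the dataset's own design
    (same subjects, dosing histories and sampling times).  Default binning is
    by the nominal sampling times present in the data.
    """
    if n_sim < 50:
        warnings.warn(f"n_sim={n_sim} is small; percentile bands will be unstable")
    rng = as_rng(seed)
    subjects = _prepare_subjects(dataset)

    # population predictions on the design
    pred = {s.sid: np.exp(_predict_log(s, theta)) for s in subjects}
    times = np.concatenate([s.nominal_times for s in subjects])
    analyte = np.concatenate([s.obs_analyte for s in subjects])
    obs = np.concatenate([np.exp(s.log_dv) for s in subjects])
    preds = np.concatenate([pred[s.sid] for s in subjects])

    if bins is None:
        bin_edges = np.unique(times)
    else:
        bin_edges = np.asarray(bins, dtype=float)
    # assign each record to the nearest nominal time
    bin_of = bin_edges[np.argmin(np.abs(times[:, None] - bin_edges[None, :]), axis=1)]

    labels = analyte.astype(float) * 1e6 + bin_of  # composite analyte/time label
    pc_obs = prediction_correct(obs, preds, labels)

    sim_pcts = np.full((n_sim, 4, bin_edges.size, 3), np.nan)
    omega_sd = omega.as_array()
    sig = sigma.as_array()
    for r in range(n_sim):
        sim_vals = np.empty_like(obs)
        pos = 0
        for s in subjects:
            eta = rng.normal(0.0, omega_sd)
            ind = theta.replace(
                **{p: getattr(theta, p) * np.exp(eta[j])
                   for j, p in enumerate(IIV_PARAMETERS)}
            )
            ip = np.exp(_predict_log(s, ind))
            eps = rng.normal(0.0, 1.0, ip.size) * sig[s.obs_analyte]
            sim_vals[pos:pos + ip.size] = ip * np.exp(eps)
            pos += ip.size
        pc_sim = prediction_correct(sim_vals, preds, labels)
        for a in range(4):
            for bi, b in enumerate(bin_edges):
                m = (analyte == a) & (bin_of == b) & np.isfinite(pc_sim)
                if m.any():
                    sim_pcts[r, a, bi] = np.percentile(pc_sim[m], _PCTS)

    rows = []
    for a in range(4):
        for bi, b in enumerate(bin_edges):
            m = (analyte == a) & (bin_of == b) & np.isfinite(pc_obs)
            if not m.any():
                continue
            op = np.percentile(pc_obs[m], _PCTS)
            row = {"ANALYTE": ANALYTES[a], "BIN": float(b), "n_obs": int(m.sum()),
                   "obs_p2.5": op[0], "obs_p50": op[1], "obs_p97.5": op[2]}
            for j, pct in enumerate(("p2.5", "p50", "p97.5")):
                col = sim_pcts[:, a, bi, j]
                col = col[np.isfinite(col)]
                row[f"sim_{pct}_lo"] = float(np.percentile(col, 2.5))
                row[f"sim_{pct}_hi"] = float(np.percentile(col, 97.5))
            rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, bins=bin_edges)


def gof_tables(dataset, fit) -> pd.DataFrame:
    """Per-observation goodness-of-fit table on the log scale.

    Columns: ID, TIME, ANALYTE, DV, PRED (population), IPRED (empirical-Bayes
    individual prediction), RES, IRES, IWRES.  One row per non-censored
    observation.
    """
    from scipy import optimize

    subjects = _prepare_subjects(dataset)
    sigma2 = np.maximum(fit.sigma.as_array() ** 2, 1e-12)
    omega_sd = np.maximum(fit.omega.as_array(), 1e-8)
    mu = np.log(fit.theta.as_array())
    rows = []
    for s in subjects:
        logpred = _predict_log(s, fit.theta)
        if fit.omega.is_zero:
            eta = np.zeros(len(_IIV_IDX))
        else:
            nlj = _eb_objective(s, mu, np.zeros(len(PARAM_ORDER)), omega_sd, sigma2)
            eta = optimize.minimize(nlj, np.zeros(len(_IIV_IDX)),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-6}).x
        phi = mu.copy()
        phi[_IIV_IDX] += eta
        logipred = _predict_log(s, ThetaSet.from_array(np.exp(phi)))
        ires = s.log_dv - logipred
        rows.append(
            pd.DataFrame(
                {
                    "ID": s.sid,
                    "TIME": s.nominal_times,
                    "ANALYTE": [ANALYTES[a] for a in s.obs_analyte],
                    "DV": np.exp(s.log_dv),
                    "PRED": np.exp(logpred),
                    "IPRED": np.exp(logipred),
                    "RES": s.log_dv - logpred,
                    "IRES": ires,
                    "IWRES": ires / np.sqrt(sigma2[s.obs_analyte]),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def plot_vpc(result: VPCResult, path=None):
    """Optional figure: one panel per analyte (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, a in zip(axes.ravel(), ANALYTES):
        t = result.table[result.table["ANALYTE"] == a].sort_values("BIN")
        if t.empty:
            continue
        for pct, color in (("p2.5", "tab:blue"), ("p50", "tab:red"), ("p97.5", "tab:blue")):
            ax.fill_between(t["BIN"], t[f"sim_{pct}_lo"], t[f"sim_{pct}_hi"],
                            alpha=0.25, color=color, lw=0)
            ax.plot(t["BIN"], t[f"obs_{pct}"], color=color, marker="o", ms=3)
        ax.set_yscale("log")
        ax.set_title(a)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("pc concentration (ng/mL)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
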