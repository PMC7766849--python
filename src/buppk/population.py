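"""Between-subject variability and residual error on top of the structural model.

Inter-individual variability (IIV) is log-normal: for each subject the five
parameters that carry variability (k24, k23, k35, k45, k50) are
``p_i = p_pop * exp(eta_i)`` with ``eta_i ~ N(0, omega_p^2)``, which keeps every
individual parameter positive.  Residual unexplained variability is additive on
the log scale with an analyte-specific standard deviation, i.e. observed
concentrations are log-normally distributed around the individual prediction.

The table of estimates reports both blocks as percentages; the default reading
is ``sqrt(omega^2) * 100`` (the usual mixed-effects convention for log-scale
standard deviations), with the ``ln(1 + CV^2)`` convention available through
:meth:`OmegaSpec.from_percent`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ANALYTES,
    ConcentrationProfile,
    Regimen,
    ThetaSet,
    simulate_profile,
)

__all__ = [
    "IIV_PARAMETERS",
    "OmegaSpec",
    "SigmaSpec",
    "IndividualParameters",
    "sample_individuals",
    "apply_residual_error",
    "simulate_population",
    "as_rng",
]

#: parameters carrying inter-individual variability in the final model
IIV_PARAMETERS = ("k24", "k23", "k35", "k45", "k50")


def as_rng(seed) -> np.random.Generator:
    """Accept a seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class OmegaSpec:
    """Log-scale IIV standard deviations (unitless); zero means no variability."""

    k24: float = 0.41
    k23: float = 0.63
    k35: float = 0.70
    k45: float = 0.56
    k50: float = 0.54

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"omega.{f.name} must be >= 0, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {p: float(getattr(self, p)) for p in IIV_PARAMETERS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in IIV_PARAMETERS])

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.as_array() == 0))

    @classmethod
    def none(cls) -> "OmegaSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_percent(cls, percent: Mapping[str, float], convention: str = "sd") -> "OmegaSpec":
        """Build from table percentages.

        ``convention="sd"``: percent = 100*sqrt(omega^2) (default reading);
        ``convention="cv"``: percent is a coefficient of variation and
        omega = sqrt(ln(1 + CV^2)).
        """
        out = {}
        for p in IIV_PARAMETERS:
            cv = percent.get(p, 0.0) / 100.0
            out[p] = cv if convention == "sd" else float(np.sqrt(np.log1p(cv**2)))
        return cls(**out)


@dataclass(frozen=True)
class SigmaSpec:
    """Per-analyte residual SD on the log scale (unitless)."""

    bup: float = 0.38
    norbup: float = 0.29
    bupg: float = 0.80
    norbupg: float = 0.26

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"sigma.{f.name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        """SDs in ``ANALYTES`` order (BUP, Nor-BUP, BUP-g, Nor-BUP-g)."""
        return np.array([self.bup, self.norbup, self.bupg, self.norbupg])

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.as_array() == 0))

    @classmethod
    def none(cls) -> "SigmaSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class IndividualParameters:
    """One subject's realized parameter set and the random effects behind it."""

    theta: ThetaSet
    etas: Mapping[str, float]


def sample_individuals(
    theta: ThetaSet, omega: OmegaSpec, n: int, seed=None
) -> list[IndividualParameters]:
    """Draw ``n`` subjects with log-normally distributed individual parameters."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = as_rng(seed)
    etas = {p: rng.normal(0.0, getattr(omega, p), size=n) for p in IIV_PARAMETERS}
    out = []
    for i in range(n):
        e = {p: float(etas[p][i]) for p in IIV_PARAMETERS}
        out.append(
            IndividualParameters(
                theta.replace(**{p: getattr(theta, p) * np.exp(e[p]) for p in IIV_PARAMETERS}),
                e,
            )
        )
    return out


def apply_residual_error(
    profile: ConcentrationProfile, sigma: SigmaSpec, seed=None
) -> np.ndarray:
    """Observed concentrations: log(DV) = log(pred) + eps, eps ~ N(0, sigma_analyte^2).

    Returns an array shaped like ``profile.values``.  Raises if any prediction
    is non-positive (the log-scale error model is undefined there).
    """
    pred = profile.values
    if np.any(pred <= 0):
        raise ValueError("residual error on the log scale needs positive predictions")
    rng = as_rng(seed)
    eps = rng.normal(0.0, 1.0, size=pred.shape) * sigma.as_array()
    return pred * np.exp(eps)


def simulate_population(
    theta: ThetaSet,
    omega: OmegaSpec,
    sigma: SigmaSpec,
    regimen: Regimen,
    times: Sequence[float],
    n: int,
    seed=None,
) -> pd.DataFrame:
    """Simulate a virtual cohort on a common design.

    Each subject receives the regimen's doses (a finite ``n_doses`` is
    required), is solved deterministically with their individual parameters,
    and observed with residual error at the absolute ``times`` (hours since
    the first dose).  Returns one row per subject x time x analyte with
    columns ID, TIME, DVID, ANALYTE, PRED (noise-free individual prediction)
    and DV.
    """
    rng = as_rng(seed)
    doses = regimen.doses(regimen.n_doses if regimen.n_doses is not None else 1)
    individuals = sample_individuals(theta, omega, n, rng)
    rows = []
    times = np.asarray(times, dtype=float)
    for i, ind in enumerate(individuals, start=1):
        prof = simulate_profile(ind.theta, doses, times)
        dv = apply_residual_error(prof, sigma, rng) if not sigma.is_zero else prof.values
        for j, a in enumerate(ANALYTES):
            rows.append(
                pd.DataFrame(
                    {
                        "ID": i,
                        "TIME": times,
                        "DVID": j + 1,
                        "ANALYTE": a,
                        "PRED": prof.values[:, j],
                        "DV": dv[:, j],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
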