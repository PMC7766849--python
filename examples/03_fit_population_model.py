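"""Fit the population model to simulated data by SAEM.

Generates a 30-subject study from known parameters, then re-estimates them
with deliberately small iteration counts so the example runs in under a
minute; a real analysis would use the defaults (300 burn-in + 200 smoothing,
2 chains).  Printed: estimate vs truth for a few key parameters and the
final importance-sampling OFV.
"""

import numpy as np

from buppk import (
    OmegaSpec, SAEMSettings, SigmaSpec, StudyDesign, ThetaSet,
    generate_study, saem_fit,
)

truth = ThetaSet()
design = StudyDesign(
    n_subjects=30, dose_allocation={8.0: 30},
    times=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0), steady_state=False,
)
study = generate_study(design, truth, OmegaSpec(), SigmaSpec(), seed=1)

rng = np.random.default_rng(2)
init = ThetaSet.from_array(truth.as_array() * np.exp(rng.uniform(-0.3, 0.3, 13)))
fit = saem_fit(
    study, init, OmegaSpec(), SigmaSpec(),
    settings=SAEMSettings(n_burnin=80, n_smooth=60, n_chains=1,
                          mcmc_sweeps=1, ofv_samples=200),
    seed=3,
)

print(f"converged: {fit.converged}   OFV: {fit.ofv:.1f}")
print(f"{'parameter':<10} {'estimate':>10} {'truth':>10}")
for p in ("ka", "k12", "k24", "k23", "v2"):
    print(f"{p:<10} {getattr(fit.theta, p):10.3f} {getattr(truth, p):10.3f}")
print(f"{'omega k23':<10} {fit.omega.k23:10.3f} {0.63:10.3f}")
print(f"{'sigma BUP':<10} {fit.sigma.bup:10.3f} {0.38:10.3f}")
print(
    "\nEstimates sit near the generating values; the residual SDs are on the "
    "log scale (0.38 means ~38% multiplicative noise on BUP concentrations)."
)
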