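"""Simulation experiments: parameter recovery, null calibration, injection.

These are the package's self-checks of the full simulate -> fit -> summarise
loop, run at a reduced scale (a 48-stratum stress scheme, short MCMC runs)
chosen so each experiment completes in minutes on one CPU:

* ``recovery_experiment`` — does the 95% CrI for sigma_u cover the known
  generating value across replicates?
* ``null_calibration`` — with sigma_u = 0, does the posterior VPC stay
  near zero?
* ``injection_experiment`` — is an injected intersectional shift delta on
  one well-populated stratum flagged (CrI excludes 0) and ranked extreme
  by the model-2 residuals?
* ``null_flag_rate`` — with no injections, how many well-populated strata
  are (falsely) flagged? Nominal rate is 5% for 95% CrIs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .metrics import stratum_residuals
from .model import MAIHDAModel, McmcConfig
from .simulate import inject_intersectional_effect, simulate_survey, stress_truth

__all__ = [
    "recovery_experiment",
    "null_calibration",
    "injection_experiment",
    "null_flag_rate",
]


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % 2**31) for s in ss.generate_state(2 * n, dtype=np.uint32)[:n]]


def recovery_experiment(
    sigma_u: float = 0.8,
    n: int = 4000,
    n_replicates: int = 20,
    seed: int = 0,
    config: McmcConfig | None = None,
    tier: str = "model2_main",
) -> pd.DataFrame:
    """Fit ``tier`` to fresh synthetic data per replicate; check CrI coverage.

    Returns one row per replicate with the posterior median of sigma_u, its
    95% CrI, and whether the interval covers the generating value.
    """
    config = config or McmcConfig.test_scale()
    rows = []
    for i, s in enumerate(_replicate_seeds(seed, n_replicates)):
        truth = stress_truth(sigma_u=sigma_u, n=n, seed=s)
        dataset, _ = simulate_survey(truth)
        model = MAIHDAModel(dataset, truth.outcome, tier=tier)
        fit = model.fit(
            dataclasses.replace(config, seed=s), check_convergence=False
        )
        lo, hi = fit.credible_interval("sigma_u")
        rows.append(
            {
                "replicate": i,
                "sigma_true": sigma_u,
                "sigma_median": fit.posterior_median("sigma_u"),
                "lo95": lo,
                "hi95": hi,
                "covered": lo <= sigma_u <= hi,
            }
        )
    return pd.DataFrame(rows)


def null_calibration(
    n: int = 4000,
    n_replicates: int = 10,
    seed: int = 0,
    config: McmcConfig | None = None,
) -> pd.DataFrame:
    """sigma_u = 0 data fitted with the null model; posterior median VPC."""
    config = config or McmcConfig.test_scale()
    rows = []
    for i, s in enumerate(_replicate_seeds(seed, n_replicates)):
        truth = stress_truth(sigma_u=0.0, n=n, seed=s, with_main_effects=False)
        dataset, _ = simulate_survey(truth)
        fit = MAIHDAModel(dataset, truth.outcome, tier="model1_null").fit(
            dataclasses.replace(config, seed=s), check_convergence=False
        )
        rows.append(
            {
                "replicate": i,
                "vpc_median": float(np.median(fit.vpc_draws)),
                "sigma_median": fit.posterior_median("sigma_u"),
            }
        )
    return pd.DataFrame(rows)


def injection_experiment(
    delta: float = 1.5,
    sigma_u: float = 0.3,
    n: int = 6000,
    n_replicates: int = 20,
    seed: int = 0,
    config: McmcConfig | None = None,
) -> pd.DataFrame:
    """Inject a log-odds shift on one stratum; ask model 2 to find it.

    The shift goes on the all-reference combination of a balanced
    48-stratum scheme (expected size n/48, so n = 6000 keeps it >= 100
    with high probability).  A detection means the stratum's 95% CrI
    excludes zero on the positive side; ``rank_from_top`` is 1 when the
    stratum has the largest residual.
    """
    config = config or McmcConfig.test_scale()
    rows = []
    for i, s in enumerate(_replicate_seeds(seed, n_replicates)):
        truth = stress_truth(sigma_u=sigma_u, n=n, seed=s)
        combo = tuple(f.reference for f in truth.scheme.factors)
        truth = inject_intersectional_effect(truth, combo, delta)
        dataset, _ = simulate_survey(truth)
        model = MAIHDAModel(dataset, truth.outcome, tier="model2_main")
        fit = model.fit(
            dataclasses.replace(config, seed=s), check_convergence=False
        )
        res = stratum_residuals(fit)
        sid = model.strata.id_of(combo)
        row = res.loc[res["stratum_id"] == sid].iloc[0]
        rows.append(
            {
                "replicate": i,
                "n_j": int(row["n_households"]),
                "median": float(row["median"]),
                "lo95": float(row["lo95"]),
                "flagged_positive": bool(row["lo95"] > 0),
                "rank_from_top": int(model.strata.n_observed - row["rank"] + 1),
            }
        )
    return pd.DataFrame(rows)


def null_flag_rate(
    sigma_u: float = 0.3,
    n: int = 6000,
    n_replicates: int = 10,
    min_stratum_size: int = 50,
    seed: int = 0,
    config: McmcConfig | None = None,
) -> pd.DataFrame:
    """False-flag rate of model-2 residuals when no effect is injected.

    Only well-populated strata enter the denominator; sparsely observed
    cells have wide, shrunken intervals that rarely flag either way.
    """
    config = config or McmcConfig.test_scale()
    rows = []
    for i, s in enumerate(_replicate_seeds(seed, n_replicates)):
        truth = stress_truth(sigma_u=sigma_u, n=n, seed=s)
        dataset, _ = simulate_survey(truth)
        fit = MAIHDAModel(dataset, truth.outcome, tier="model2_main").fit(
            dataclasses.replace(config, seed=s), check_convergence=False
        )
        res = stratum_residuals(fit)
        big = res.loc[res["n_households"] >= min_stratum_size]
        rows.append(
            {
                "replicate": i,
                "n_strata": len(big),
                "n_flagged": int(big["significant"].sum()),
                "flag_rate": float(big["significant"].mean()),
            }
        )
    return pd.DataFrame(rows)
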