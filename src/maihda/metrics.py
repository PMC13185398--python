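"""Intersectional summary measures: VPC, PCV, odds ratios, stratum residuals.

On the latent-response scale of a logistic multilevel model, the level-1
residual variance is fixed at pi^2/3 ~= 3.29, so the variance partition
coefficient (VPC) of the stratum effects is

    VPC = sigma_u^2 / (sigma_u^2 + pi^2/3)

and the proportional change in variance (PCV) of a comparison model k
against the null model is (sigma_1^2 - sigma_k^2) / sigma_1^2.  The default
PCV is computed from the stratum variances; a VPC-difference variant is
available via ``method="vpc"``.

Point stratum variance is the square of the posterior median of sigma_u;
per-draw posterior summaries (median and 95% CrI of the per-draw VPC) are
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey import ValidationError

__all__ = [
    "LOGISTIC_LEVEL1_VARIANCE",
    "vpc_latent",
    "pcv",
    "or_summary",
    "stratum_residuals",
    "metrics_report",
    "MetricsReport",
]

#: Latent-scale level-1 variance of the standard logistic distribution.
LOGISTIC_LEVEL1_VARIANCE = math.pi**2 / 3.0


def vpc_latent(sigma2_u):
    """Latent-scale variance partition coefficient of a stratum variance.

    Accepts a scalar or an array of variances (log-odds scale); returns
    sigma2_u / (sigma2_u + pi^2/3), in [0, 1).
    """
    arr = np.asarray(sigma2_u, dtype=float)
    if (arr < 0).any():
        raise ValidationError("stratum variance must be >= 0")
    out = arr / (arr + LOGISTIC_LEVEL1_VARIANCE)
    return float(out) if np.isscalar(sigma2_u) or arr.ndim == 0 else out


def pcv(sigma2_ref: float, sigma2_cmp: float) -> float:
    """Proportional change in variance of a comparison model vs the null.

    (sigma2_ref - sigma2_cmp) / sigma2_ref; negative when the comparison
    model has *more* stratum variance than the reference.
    """
    if sigma2_ref <= 0:
        raise ValidationError("reference variance must be > 0")
    if sigma2_cmp < 0:
        raise ValidationError("comparison variance must be >= 0")
    return (sigma2_ref - sigma2_cmp) / sigma2_ref


def or_summary(results) -> pd.DataFrame:
    """Odds-ratio table: posterior median of exp(beta) with 95% CrI per effect.

    Includes the intercept (baseline odds at reference categories).  The
    ``significant`` flag marks intervals excluding 1.
    """
    names = ["intercept", *results.fixed_effect_names]
    rows = []
    for name in names:
        odds = np.exp(results.get(name))
        lo, med, hi = np.quantile(odds, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "or_median": float(med),
                "or_lo95": float(lo),
                "or_hi95": float(hi),
                "significant": bool(hi < 1.0 or lo > 1.0),
            }
        )
    return pd.DataFrame(rows)


def stratum_residuals(results, level: float = 0.95) -> pd.DataFrame:
    """Per-stratum residual intersectional effects, ranked ascending.

    For each observed stratum: the posterior median and equal-tailed CrI of
    u_j, the predicted stratum probability at reference covariates
    (inverse-logit of median intercept + median u_j), an ascending rank by
    median residual (ties broken by stratum id), and a flag for CrIs
    excluding zero.  A positive flagged residual means higher utilisation
    than the additive main effects predict.
    """
    from scipy.special import expit

    table = results.model.strata.table
    u = results.u_draws  # (draws, J)
    a = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(u, [a, 0.5, 1.0 - a], axis=0)
    b0 = results.posterior_median("intercept")
    out = table[["stratum_id", *results.model.scheme.names, "n_households"]].copy()
    out["median"] = med
    out["lo95"] = lo
    out["hi95"] = hi
    out["pred_prob"] = expit(b0 + med)
    out["significant"] = (hi < 0.0) | (lo > 0.0)
    order = np.lexsort((out["stratum_id"].to_numpy(), med))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


@dataclass
class MetricsReport:
    """Table-2-shaped report over the three model tiers.

    ``variance_table`` rows are indexed by tier with point stratum variance,
    its 95% CrI, point and per-draw VPC, and PCV against the null model.
    ``or_tables`` maps tier -> odds-ratio DataFrame.
    """

    outcome: str
    variance_table: pd.DataFrame
    or_tables: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.variance_table.to_csv(path, index=False)

    def __str__(self) -> str:
        t = self.variance_table.copy()
        cols = ["tier", "sigma2_u", "vpc_pct", "pcv_pct"]
        return f"MetricsReport for {self.outcome!r}\n" + t[cols].to_string(
            index=False, float_format=lambda v: f"{v:.2f}"
        )


def _tier_row(results) -> dict:
    sigma = results.sigma_draws
    med_sigma = float(np.median(sigma))
    s2_point = med_sigma**2
    s2_lo, s2_hi = np.quantile(sigma**2, [0.025, 0.975])
    vpc_draws = vpc_latent(sigma**2)
    v_lo, v_med, v_hi = np.quantile(vpc_draws, [0.025, 0.5, 0.975])
    return {
        "tier": results.model.spec.tier,
        "sigma2_u": s2_point,
        "sigma2_lo95": float(s2_lo),
        "sigma2_hi95": float(s2_hi),
        "vpc": vpc_latent(s2_point),
        "vpc_pct": 100.0 * vpc_latent(s2_point),
        "vpc_draw_median": float(v_med),
        "vpc_draw_lo95": float(v_lo),
        "vpc_draw_hi95": float(v_hi),
    }


def metrics_report(model1, model2, model3=None, method: str = "variance") -> MetricsReport:
    """Combine the three tiers' posteriors into a VPC/PCV/OR report.

    ``method`` selects the PCV definition: ``"variance"`` (from stratum
    variances; matches the printed tables) or ``"vpc"`` (from VPC
    differences, as the prose describes).  All fits must share the outcome
    and the stratum structure.
    """
    if method not in ("variance", "vpc"):
        raise ValidationError(f"unknown PCV method {method!r}")
    fits = [m for m in (model1, model2, model3) if m is not None]
    outcome = model1.model.spec.outcome
    base_labels = model1.model.strata.labels()
    for fit in fits[1:]:
        if fit.model.spec.outcome != outcome:
            raise ValidationError("all models must be fitted on the same outcome")
        if fit.model.strata.labels() != base_labels:
            raise ValidationError("all models must share the stratum structure")

    rows = [_tier_row(f) for f in fits]
    ref_s2 = rows[0]["sigma2_u"]
    ref_vpc = rows[0]["vpc"]
    for i, row in enumerate(rows):
        if i == 0:
            row["pcv"] = np.nan
            row["pcv_pct"] = np.nan
        elif method == "variance":
            row["pcv"] = pcv(ref_s2, row["sigma2_u"])
            row["pcv_pct"] = 100.0 * row["pcv"]
        else:
            row["pcv"] = (ref_vpc - row["vpc"]) / ref_vpc
            row["pcv_pct"] = 100.0 * row["pcv"]
    table = pd.DataFrame(rows)
    or_tables = {f.model.spec.tier: or_summary(f) for f in fits}
    return MetricsReport(outcome, table, or_tables)
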