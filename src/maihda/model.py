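"""Bayesian multilevel logistic MAIHDA models.

Three nested model tiers are fitted to a binary healthcare-utilisation
outcome with households (level 1) nested in intersectional social strata
(level 2):

* ``model1_null``      eta_ij = beta0 + u_j
* ``model2_main``      eta_ij = beta0 + x_ij' beta + u_j   (factor dummies)
* ``model3_adjusted``  adds explanatory covariates to the model-2 design

with u_j ~ Normal(0, sigma_u^2) and y_ij ~ Bernoulli(logit^-1(eta_ij)).
Regularising priors: Normal(0, 1) on the intercept and fixed effects, and a
half-Student-t (default nu=2, scale 10) on the stratum standard deviation
sigma_u.

Inference is full-Bayes MCMC: Hamiltonian Monte Carlo with analytic
gradients on the non-centred parameterisation u_j = sigma_u * z_j (and
sigma_u sampled on the log scale), which keeps sparse strata well-behaved.
Records are aggregated to unique (stratum, design-row) groups so each
gradient costs O(groups), not O(households).

Usage follows the Model/Results convention::

    model = MAIHDAModel.from_dataframe(df, outcome="hu_within", tier="model2_main")
    res = model.fit(McmcConfig.test_scale(seed=1))
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._hmc import sample_chain
from .strata import StratumTable, build_strata
from .survey import (
    INT_COVARIATE,
    FactorScheme,
    SurveyDataset,
    ValidationError,
    default_scheme,
    from_dataframe as _survey_from_dataframe,
)

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "McmcConfig",
    "MAIHDAModel",
    "MAIHDAResults",
    "DegenerateOutcomeError",
]

TIERS = ("model1_null", "model2_main", "model3_adjusted")


class DegenerateOutcomeError(ValueError):
    """The analysis-set outcome is constant; a logistic fit is undefined."""


@dataclass(frozen=True)
class PriorSpec:
    """Regularising priors: N(0, fixed_sd^2) on fixed effects, half-t on sigma_u."""

    fixed_sd: float = 1.0
    sigma_df: float = 2.0
    sigma_scale: float = 10.0

    def flattened(self, sd: float = 100.0) -> "PriorSpec":
        """Near-flat variant used when comparing against maximum likelihood."""
        return replace(self, fixed_sd=sd)


@dataclass(frozen=True)
class ModelSpec:
    """Which tier is fitted to which outcome, and with which priors."""

    outcome: str
    tier: str = "model2_main"
    covariates: tuple[str, ...] = ()
    priors: PriorSpec = PriorSpec()

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}; expected one of {TIERS}")
        if self.tier != "model3_adjusted" and self.covariates:
            raise ValidationError("covariates are only part of the model3 design")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run lengths. ``iterations`` and ``burn_in`` are per chain."""

    chains: int = 4
    iterations: int = 20000
    burn_in: int = 2000
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 48

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("need >= 2 chains for split-Rhat")
        if not 0 < self.burn_in < self.iterations:
            raise ValidationError("require 0 < burn_in < iterations")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        """Production run lengths (20,000 iterations, 2,000 burn-in)."""
        return cls(chains=4, iterations=20000, burn_in=2000, seed=seed)

    @classmethod
    def test_scale(cls, seed: int = 0) -> "McmcConfig":
        """Short run lengths for simulation studies and tests."""
        return cls(chains=4, iterations=2500, burn_in=500, seed=seed)

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in)


def _log_half_t(x: float, df: float, scale: float) -> float:
    """log density of the half-Student-t on (0, inf); -inf for x <= 0."""
    if x <= 0:
        return -math.inf
    c = (
        math.log(2.0)
        + gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
    )
    return c - (df + 1.0) / 2.0 * math.log1p((x / scale) ** 2 / df)


class MAIHDAModel:
    """One MAIHDA model tier bound to an analysis set.

    Construction performs the per-outcome complete-case selection (outcome,
    all six factors, and — for model 3 — the requested covariates), builds
    the stratum table from the analysis set, and assembles the dummy-coded
    fixed-effect design against each factor's declared reference category.
    """

    def __init__(
        self,
        dataset: SurveyDataset,
        outcome: str,
        tier: str = "model2_main",
        covariates: Sequence[str] | None = None,
        priors: PriorSpec = PriorSpec(),
    ) -> None:
        covariates = tuple(covariates or ())
        self.spec = ModelSpec(outcome, tier, covariates, priors)
        self.dataset = dataset
        self.scheme: FactorScheme = dataset.scheme

        frame = dataset.analysis_set(outcome)
        for cov in covariates:
            if cov not in dataset.covariate_schema:
                raise ValidationError(f"covariate {cov!r} not in covariate schema")
            frame = frame.loc[frame[cov].notna()]
        if frame.empty:
            raise ValidationError(f"empty analysis set for outcome {outcome!r}")
        y = frame[outcome].to_numpy(dtype=int)
        if y.min() == y.max():
            raise DegenerateOutcomeError(
                f"outcome {outcome!r} is constant ({y[0]}) in the analysis set"
            )
        self.frame = frame
        sub = SurveyDataset(frame.reset_index(drop=True), dataset.scheme, dict(dataset.covariate_schema))
        self.strata: StratumTable = build_strata(sub)
        self._j = self.strata.assignments.to_numpy() - 1  # 0-based stratum index
        self.n_strata = self.strata.n_observed
        self.nobs = len(frame)

        self._design_names, X = self._build_design(sub.frame)
        self._aggregate(y, X)

    # -- design ------------------------------------------------------------

    def _design_columns(self) -> list[tuple[str, str, str]]:
        """(kind, variable, category) for each fixed-effect column."""
        cols: list[tuple[str, str, str]] = []
        if self.spec.tier == "model1_null":
            return cols
        for f in self.scheme.factors:
            for cat in f.categories[1:]:
                cols.append(("factor", f.name, cat))
        if self.spec.tier == "model3_adjusted":
            for cov in self.spec.covariates:
                spec = self.dataset.covariate_schema[cov]
                if spec == INT_COVARIATE:
                    cols.append(("int", cov, ""))
                else:
                    for cat in spec[1:]:
                        cols.append(("cat", cov, cat))
        return cols

    def _build_design(self, frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        cols = self._design_columns()
        names: list[str] = []
        self._int_centers: dict[str, float] = {}
        mats = []
        for kind, var, cat in cols:
            if kind == "int":
                vals = frame[var].to_numpy(dtype=float)
                center = float(np.mean(vals))
                self._int_centers[var] = center
                mats.append(vals - center)
                names.append(var)
            else:
                mats.append((frame[var] == cat).to_numpy(dtype=float))
                names.append(f"{var}[{cat}]")
        X = np.column_stack(mats) if mats else np.empty((len(frame), 0))
        return names, X

    def _aggregate(self, y: np.ndarray, X: np.ndarray) -> None:
        """Collapse records to unique (stratum, design-row) binomial groups."""
        key = np.column_stack([self._j.astype(float), X])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        g = uniq.shape[0]
        self._gn = np.bincount(inv, minlength=g).astype(float)
        self._gy = np.bincount(inv, weights=y, minlength=g)
        self._gj = uniq[:, 0].astype(int)
        self._gX = uniq[:, 1:]
        self._n_groups = g

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        tier: str = "model2_main",
        covariates: Sequence[str] | None = None,
        scheme: FactorScheme | None = None,
        covariate_schema: Mapping[str, tuple[str, ...] | str] | None = None,
        priors: PriorSpec = PriorSpec(),
    ) -> "MAIHDAModel":
        dataset = _survey_from_dataframe(df, scheme or default_scheme(), covariate_schema)
        return cls(dataset, outcome, tier, covariates, priors)

    # -- densities ---------------------------------------------------------

    @property
    def fixed_effect_names(self) -> list[str]:
        return list(self._design_names)

    @property
    def param_names(self) -> list[str]:
        return (
            ["intercept", *self._design_names, "sigma_u"]
            + [f"u[{i + 1}]" for i in range(self.n_strata)]
        )

    def loglike(self, beta0: float, beta: np.ndarray, u: np.ndarray) -> float:
        """Binomial log likelihood of the aggregated groups."""
        eta = beta0 + self._gX @ beta + u[self._gj]
        return float(np.sum(self._gy * eta - self._gn * np.logaddexp(0.0, eta)))

    def loglike_records(self, beta0: float, beta: np.ndarray, u: np.ndarray,
                        frame: pd.DataFrame | None = None) -> float:
        """Naive per-record Bernoulli sum (reference path for tests)."""
        frame = self.frame if frame is None else frame
        total = 0.0
        for _, rec in frame.iterrows():
            eta = self.linear_predictor(rec, beta0=beta0, beta=beta, u=u)
            y = int(rec[self.spec.outcome])
            total += y * eta - np.logaddexp(0.0, eta)
        return float(total)

    def log_prior(self, beta0: float, beta: np.ndarray, sigma_u: float,
                  u: np.ndarray) -> float:
        """Joint log prior at one parameter point; -inf when sigma_u <= 0."""
        if sigma_u <= 0:
            return -math.inf
        s = self.spec.priors.fixed_sd
        fixed = np.concatenate(([beta0], np.atleast_1d(beta)))
        lp = float(
            np.sum(-0.5 * (fixed / s) ** 2 - 0.5 * math.log(2 * math.pi) - math.log(s))
        )
        lp += _log_half_t(sigma_u, self.spec.priors.sigma_df, self.spec.priors.sigma_scale)
        lp += float(
            np.sum(
                -0.5 * (u / sigma_u) ** 2
                - 0.5 * math.log(2 * math.pi)
                - math.log(sigma_u)
            )
        )
        return lp

    def linear_predictor(
        self,
        record: Mapping[str, object] | pd.Series,
        beta0: float,
        beta: np.ndarray | Mapping[str, float],
        u: np.ndarray | None = None,
        u_value: float | None = None,
    ) -> float:
        """Log odds beta0 + x'beta + u_j for one household record.

        ``beta`` may be an array in design order or a name->value mapping.
        The stratum effect comes from ``u`` (indexed by the record's stratum)
        or explicitly via ``u_value``.
        """
        eta = float(beta0)
        if isinstance(beta, Mapping):
            beta = np.array([beta.get(n, 0.0) for n in self._design_names])
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        for (kind, var, cat), b in zip(self._design_columns(), beta):
            if kind == "int":
                eta += b * (float(record[var]) - self._int_centers.get(var, 0.0))
            else:
                eta += b * (record[var] == cat)
        if u_value is not None:
            eta += u_value
        elif u is not None:
            combo = tuple(str(record[name]) for name in self.scheme.names)
            j = self.strata.id_of(combo) - 1  # KeyError if the stratum is unknown
            eta += float(np.atleast_1d(u)[j])
        return eta

    # -- posterior in HMC coordinates --------------------------------------

    def _logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = len(self._design_names)
        J = self.n_strata
        beta0 = theta[0]
        beta = theta[1 : 1 + p]
        z = theta[1 + p : 1 + p + J]
        tau = theta[-1]
        if abs(tau) > 40.0:  # overflow guard; treated as a divergence
            return -math.inf, np.zeros_like(theta)
        sigma = math.exp(tau)
        s2 = self.spec.priors.fixed_sd**2
        df, scale = self.spec.priors.sigma_df, self.spec.priors.sigma_scale

        eta = beta0 + self._gX @ beta + sigma * z[self._gj]
        ll = np.sum(self._gy * eta - self._gn * np.logaddexp(0.0, eta))
        lp = (
            ll
            - 0.5 * (beta0**2 + float(beta @ beta)) / s2
            - 0.5 * float(z @ z)
            - (df + 1.0) / 2.0 * math.log1p(sigma**2 / (df * scale**2))
            + tau
        )

        r = self._gy - self._gn * expit(eta)
        grad = np.empty_like(theta)
        grad[0] = np.sum(r) - beta0 / s2
        if p:
            grad[1 : 1 + p] = self._gX.T @ r - beta / s2
        rj = np.bincount(self._gj, weights=r, minlength=J)
        grad[1 + p : 1 + p + J] = sigma * rj - z
        grad[-1] = (
            sigma * float(rj @ z)
            - (df + 1.0) * sigma**2 / (df * scale**2 + sigma**2)
            + 1.0
        )
        return float(lp), grad

    # -- fitting -----------------------------------------------------------

    def fit(self, config: McmcConfig | None = None,
            check_convergence: bool = True) -> "MAIHDAResults":
        """Sample the posterior; identical config and seed give identical draws."""
        config = config or McmcConfig.test_scale()
        p = len(self._design_names)
        J = self.n_strata
        dim = 1 + p + J + 1
        ybar = float(self._gy.sum() / self._gn.sum())
        base0 = math.log(ybar / (1.0 - ybar))

        ss = np.random.SeedSequence(config.seed)
        chains = []
        warnings: list[str] = []
        n_div = 0
        for child in ss.spawn(config.chains):
            rng = np.random.default_rng(child)
            x0 = np.zeros(dim)
            x0[0] = base0 + 0.2 * rng.standard_normal()
            if p:
                x0[1 : 1 + p] = 0.1 * rng.standard_normal(p)
            x0[1 + p : 1 + p + J] = 0.1 * rng.standard_normal(J)
            x0[-1] = math.log(0.5) + 0.2 * rng.standard_normal()
            res = sample_chain(
                self._logp_grad,
                x0,
                config.iterations,
                config.burn_in,
                rng,
                target_accept=config.target_accept,
                max_leapfrog=config.max_leapfrog,
            )
            chains.append(res)
            n_div += res.n_divergent

        raw = np.stack([c.draws for c in chains])  # (chains, draws, dim)
        sigma = np.exp(raw[:, :, -1])
        u = sigma[:, :, None] * raw[:, :, 1 + p : 1 + p + J]
        draws = np.concatenate(
            [raw[:, :, : 1 + p], sigma[:, :, None], u], axis=2
        )
        if n_div:
            warnings.append(f"{n_div} post-warmup divergent transitions across chains")
        results = MAIHDAResults(
            draws=draws,
            param_names=self.param_names,
            model=self,
            config=config,
            warnings=warnings,
            accept_rates=tuple(c.accept_rate for c in chains),
        )
        if check_convergence:
            from .diagnostics import split_rhat

            bad = []
            for k, name in enumerate(results.param_names):
                arr = draws[:, :, k]
                if np.ptp(arr) == 0:
                    continue
                r = split_rhat(arr)
                if r >= 1.01:
                    bad.append(f"{name} (Rhat={r:.3f})")
            if bad:
                warnings.append(
                    "convergence warning: Rhat >= 1.01 for " + ", ".join(bad)
                )
        return results


@dataclass
class MAIHDAResults:
    """Posterior draws and summaries of one fitted MAIHDA model.

    ``draws`` has shape (chains, retained iterations, parameters) with the
    parameter order ``intercept, <fixed effects>, sigma_u, u[1..J]``.
    """

    draws: np.ndarray
    param_names: list[str]
    model: MAIHDAModel
    config: McmcConfig
    warnings: list[str] = field(default_factory=list)
    accept_rates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        assert self.draws.shape[2] == len(self.param_names)
        assert np.isfinite(self.draws).all()

    # -- accessors ---------------------------------------------------------

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def _idx(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def chains_of(self, name: str) -> np.ndarray:
        """(chains, draws) array for one parameter."""
        return self.draws[:, :, self._idx(name)]

    def get(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.chains_of(name).reshape(-1)

    @property
    def fixed_effect_names(self) -> list[str]:
        return self.model.fixed_effect_names

    @property
    def sigma_draws(self) -> np.ndarray:
        return self.get("sigma_u")

    @property
    def u_draws(self) -> np.ndarray:
        """(retained, J) stratum-effect draws."""
        J = self.model.n_strata
        return self.draws[:, :, -J:].reshape(-1, J)

    @property
    def vpc_draws(self) -> np.ndarray:
        from .metrics import vpc_latent

        return vpc_latent(self.sigma_draws**2)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.get(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.get(name)))

    def mcse_mean(self, name: str) -> float:
        """Monte-Carlo standard error of the posterior mean of one parameter."""
        from .diagnostics import ess_mean

        x = self.chains_of(name)
        return float(np.std(x, ddof=1) / math.sqrt(ess_mean(x)))

    # -- reporting ---------------------------------------------------------

    def diagnostics(self):
        from .diagnostics import diagnostics_report

        return diagnostics_report(self)

    def or_table(self) -> pd.DataFrame:
        from .metrics import or_summary

        return or_summary(self)

    def stratum_residuals(self) -> pd.DataFrame:
        from .metrics import stratum_residuals

        return stratum_residuals(self)

    def summary(self, include_strata: bool = False) -> pd.DataFrame:
        """Posterior medians, 95% CrIs and diagnostics per parameter."""
        from .diagnostics import ess_bulk, ess_tail, split_rhat

        rows = []
        J = self.model.n_strata
        names = self.param_names if include_strata else self.param_names[: -J]
        for name in names:
            x = self.chains_of(name)
            flat = x.reshape(-1)
            lo, hi = np.quantile(flat, [0.025, 0.975])
            constant = np.ptp(x) == 0
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(flat)),
                    "mean": float(np.mean(flat)),
                    "sd": float(np.std(flat, ddof=1)),
                    "ci95_lo": float(lo),
                    "ci95_hi": float(hi),
                    "rhat": np.nan if constant else split_rhat(x),
                    "ess_bulk": np.nan if constant else ess_bulk(x),
                    "ess_tail": np.nan if constant else ess_tail(x),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = (
            f"MAIHDA {self.model.spec.tier} on {self.model.spec.outcome!r}: "
            f"{self.model.nobs} households in {self.model.n_strata} strata, "
            f"{self.n_retained} retained draws"
        )
        table = self.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}")
        warn = "\n".join(f"! {w}" for w in self.warnings)
        return "\n".join(s for s in (head, table, warn) if s)

    # -- persistence -------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Flat long-format CSV: chain, iteration, parameter, value."""
        c, d, k = self.draws.shape
        frame = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d * k),
                "iteration": np.tile(np.repeat(np.arange(d), k), c),
                "parameter": np.tile(self.param_names, c * d),
                "value": self.draws.reshape(-1),
            }
        )
        frame.to_csv(path, index=False)

    @staticmethod
    def draws_from_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
        """Reload a persisted draw file into (chains, draws, params) form."""
        frame = pd.read_csv(path)
        names = list(dict.fromkeys(frame["parameter"]))
        c = frame["chain"].nunique()
        d = frame["iteration"].nunique()
        arr = frame["value"].to_numpy().reshape(c, d, len(names))
        return arr, names

    # -- plotting ----------------------------------------------------------

    def plot_caterpillar(self, ax=None, path: str | Path | None = None):
        """Caterpillar plot: stratum residuals ranked with 95% CrI whiskers."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        res = self.stratum_residuals().sort_values("rank")
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = res["rank"].to_numpy()
        ax.errorbar(
            x,
            res["median"],
            yerr=[res["median"] - res["lo95"], res["hi95"] - res["median"]],
            fmt="o",
            ms=3,
            lw=0.8,
            capsize=0,
            color="tab:blue",
            ecolor="lightsteelblue",
        )
        sig = res["significant"].to_numpy(dtype=bool)
        ax.plot(x[sig], res["median"].to_numpy()[sig], "o", ms=4, color="tab:red")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("stratum rank (ascending residual)")
        ax.set_ylabel("stratum residual (log odds)")
        ax.set_title(f"{self.model.spec.tier} / {self.model.spec.outcome}")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
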