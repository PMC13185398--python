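"""Synthetic household-survey generator with known ground truth.

The real Freetown survey is restricted, so every quantitative check in this
package runs on synthetic data whose generative model matches the structure
the analysis assumes: six categorical social factors drawn independently
from configurable marginal prevalences, a stratum random effect u_j ~
Normal(0, sigma_u^2) attached to each *realised* factor combination (plus
optional injected intersectional shifts delta), additive fixed effects on
the log-odds scale, independent categorical covariates, and a Bernoulli
outcome through the inverse logit.

The implied latent-scale variance partition coefficient of a truth is
sigma_u^2 / (sigma_u^2 + pi^2/3) by construction, which is what parameter-
recovery tests exploit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey import (
    INT_COVARIATE,
    Factor,
    FactorScheme,
    SurveyDataset,
    ValidationError,
    default_covariate_schema,
    default_scheme,
)

__all__ = [
    "SimulationTruth",
    "simulate_survey",
    "inject_intersectional_effect",
    "default_truth",
    "stress_scheme",
    "stress_truth",
]

LOGISTIC_VARIANCE = math.pi**2 / 3.0


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth generative parameters for one survey outcome.

    ``main_effects`` maps ``(factor, category)`` to a log-odds effect for
    non-reference categories; ``covariate_effects`` likewise for categorical
    covariates, or ``(name, "per_unit")`` for integer covariates.
    ``deviations`` maps a full factor combination to an extra log-odds shift
    added to that stratum's random effect (an injected intersectional
    effect).  ``variant_shifts`` optionally emits extra outcome columns that
    share the stratum effects but shift the intercept; formal-provider
    variants thin utilising households with probability ``formal_given_use``.
    """

    scheme: FactorScheme
    factor_prevalences: Mapping[str, tuple[float, ...]]
    intercept: float
    main_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    covariate_schema: Mapping[str, tuple[str, ...] | str] = field(default_factory=dict)
    covariate_prevalences: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    covariate_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma_u: float = 0.0
    deviations: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    n: int = 4871
    seed: int = 0
    outcome: str = "hu_within"
    variant_shifts: Mapping[str, float] = field(default_factory=dict)
    formal_given_use: float | None = None
    household_size_mean: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValidationError("sigma_u must be >= 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for f in self.scheme.factors:
            p = np.asarray(self.factor_prevalences[f.name], dtype=float)
            if len(p) != len(f.categories):
                raise ValidationError(
                    f"prevalence vector for {f.name!r} has wrong length"
                )
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValidationError(
                    f"prevalence vector for {f.name!r} must be non-negative and sum to 1"
                )
        for combo in self.deviations:
            self.scheme.validate_combination(combo)
        for (fname, cat) in self.main_effects:
            factor = self.scheme[fname]
            if cat not in factor.categories:
                raise ValidationError(f"main effect on unknown category {fname}:{cat}")
            if cat == factor.reference:
                raise ValidationError(
                    f"main effect declared on reference category of {fname!r}"
                )

    @property
    def implied_vpc(self) -> float:
        """Latent-scale VPC implied by sigma_u, exact by construction."""
        s2 = self.sigma_u**2
        return s2 / (s2 + LOGISTIC_VARIANCE)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factors": [
                {"name": f.name, "categories": list(f.categories)}
                for f in self.scheme.factors
            ],
            "factor_prevalences": {k: list(v) for k, v in self.factor_prevalences.items()},
            "intercept": self.intercept,
            "main_effects": [[k[0], k[1], v] for k, v in self.main_effects.items()],
            "covariate_schema": {
                k: (v if isinstance(v, str) else list(v))
                for k, v in self.covariate_schema.items()
            },
            "covariate_prevalences": {
                k: list(v) for k, v in self.covariate_prevalences.items()
            },
            "covariate_effects": [[k[0], k[1], v] for k, v in self.covariate_effects.items()],
            "sigma_u": self.sigma_u,
            "deviations": [[list(k), v] for k, v in self.deviations.items()],
            "n": self.n,
            "seed": self.seed,
            "outcome": self.outcome,
            "variant_shifts": dict(self.variant_shifts),
            "formal_given_use": self.formal_given_use,
            "household_size_mean": self.household_size_mean,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        scheme = FactorScheme(
            tuple(Factor(f["name"], tuple(f["categories"])) for f in d["factors"])
        )
        return cls(
            scheme=scheme,
            factor_prevalences={k: tuple(v) for k, v in d["factor_prevalences"].items()},
            intercept=d["intercept"],
            main_effects={(a, b): v for a, b, v in d["main_effects"]},
            covariate_schema={
                k: (v if isinstance(v, str) else tuple(v))
                for k, v in d["covariate_schema"].items()
            },
            covariate_prevalences={
                k: tuple(v) for k, v in d["covariate_prevalences"].items()
            },
            covariate_effects={(a, b): v for a, b, v in d["covariate_effects"]},
            sigma_u=d["sigma_u"],
            deviations={tuple(k): v for k, v in d["deviations"]},
            n=d["n"],
            seed=d["seed"],
            outcome=d["outcome"],
            variant_shifts=d.get("variant_shifts", {}),
            formal_given_use=d.get("formal_given_use"),
            household_size_mean=d.get("household_size_mean", 4.0),
        )


def default_truth(n: int = 4871, seed: int = 0, sigma_u: float = 0.25) -> SimulationTruth:
    """Study-condition defaults emulating the Freetown within-settlement HU.

    Factor prevalences follow the survey's marginal distribution; the
    intercept and main effects are the main-effects-model log odds ratios
    (reference categories: female, single, no income activity, food secure,
    no disability, Cockle Bay); sigma_u defaults to the residual stratum
    scale after main effects.
    """
    scheme = default_scheme()
    prev = {
        "hoh_gender": (0.275, 0.725),
        "marital": (0.252, 0.632, 0.116),
        "income_activity": (0.246, 0.754),
        "food_security": (0.497, 0.503),
        "disability": (0.934, 0.066),
        "settlement": (0.230, 0.288, 0.482),
    }
    main = {
        ("hoh_gender", "male"): math.log(0.96),
        ("marital", "married_cohabit_engaged"): math.log(1.05),
        ("marital", "divorced_separated_widowed"): math.log(1.20),
        ("income_activity", "yes"): math.log(1.35),
        ("food_security", "food_insecure"): math.log(1.32),
        ("disability", "yes"): math.log(1.32),
        ("settlement", "dwazark"): math.log(2.62),
        ("settlement", "moyiba"): math.log(0.85),
    }
    cov_schema = default_covariate_schema()
    cov_prev = {
        "residence_length": (0.075, 0.297, 0.199, 0.429),
        "tenure": (0.576, 0.297, 0.099, 0.028),
        "water_distance": (0.317, 0.303, 0.135, 0.221, 0.024),
        "water_shortage": (0.609, 0.389, 0.002),
        "toilet_flush": (0.762, 0.238),
        "toilet_bucket": (0.682, 0.318),
        "shared_toilet": (0.705, 0.285, 0.010),
        "waste_payment": (0.792, 0.208),
        "environmental_disaster": (0.073, 0.927),
        "income_business": (0.638, 0.362),
        "income_private_salaried": (0.875, 0.125),
    }
    cov_eff = {
        ("tenure", "landlord"): math.log(0.75),
        ("toilet_flush", "yes"): math.log(1.51),
        ("environmental_disaster", "yes"): math.log(0.59),
        ("household_size", "per_unit"): math.log(1.04),
    }
    return SimulationTruth(
        scheme=scheme,
        factor_prevalences=prev,
        intercept=math.log(0.19),
        main_effects=main,
        covariate_schema=cov_schema,
        covariate_prevalences=cov_prev,
        covariate_effects=cov_eff,
        sigma_u=sigma_u,
        n=n,
        seed=seed,
        outcome="hu_within",
        variant_shifts={"hu_outside": 0.35},
        formal_given_use=0.75,
    )


def stress_scheme(category_counts: tuple[int, ...] = (2, 2, 2, 2, 3)) -> FactorScheme:
    """Small generic scheme for simulation studies (default 48 combinations)."""
    factors = tuple(
        Factor(f"f{i + 1}", tuple(f"c{j}" for j in range(k)))
        for i, k in enumerate(category_counts)
    )
    return FactorScheme(factors)


def stress_truth(
    sigma_u: float,
    n: int = 4000,
    seed: int = 0,
    intercept: float = -0.8,
    with_main_effects: bool = True,
) -> SimulationTruth:
    """Balanced 48-stratum truth for recovery / calibration experiments.

    Balanced prevalences keep every combination well populated (expected
    cell size n/48), which is the stress regime for estimating sigma_u.
    """
    scheme = stress_scheme()
    prev = {
        f.name: tuple([1.0 / len(f.categories)] * len(f.categories))
        for f in scheme.factors
    }
    main = {}
    if with_main_effects:
        effects = [0.3, -0.2, 0.25, -0.15, 0.2, 0.4]
        i = 0
        for f in scheme.factors:
            for cat in f.categories[1:]:
                main[(f.name, cat)] = effects[i % len(effects)]
                i += 1
    return SimulationTruth(
        scheme=scheme,
        factor_prevalences=prev,
        intercept=intercept,
        main_effects=main,
        sigma_u=sigma_u,
        n=n,
        seed=seed,
    )


def inject_intersectional_effect(
    truth: SimulationTruth, combo, delta: float
) -> SimulationTruth:
    """Return a truth whose stratum shift for ``combo`` is increased by delta."""
    combo = truth.scheme.validate_combination(combo)
    dev = dict(truth.deviations)
    new = dev.get(combo, 0.0) + delta
    if new == 0.0:
        dev.pop(combo, None)
    else:
        dev[combo] = new
    return dataclasses.replace(truth, deviations=dev)


def _lex_codes(draws: dict[str, np.ndarray], scheme: FactorScheme) -> np.ndarray:
    codes = np.zeros(next(iter(draws.values())).shape, dtype=np.int64)
    for f in scheme.factors:
        codes = codes * len(f.categories) + draws[f.name]
    return codes


def _decode(code: int, scheme: FactorScheme) -> tuple[str, ...]:
    sizes = [len(f.categories) for f in scheme.factors]
    out = []
    rem = int(code)
    for size in reversed(sizes):
        out.append(rem % size)
        rem //= size
    return tuple(f.categories[c] for f, c in zip(scheme.factors, out[::-1]))


def simulate_survey(
    truth: SimulationTruth, include_variants: bool = False
) -> tuple[SurveyDataset, dict[tuple[str, ...], float]]:
    """Draw one survey dataset from the truth.

    Returns the dataset and the realised stratum effects (sigma_u * z + delta,
    keyed by factor combination, for realised combinations only).  A stratum
    effect is drawn once per realised combination, in lexicographic order, so
    the same seed reproduces the same dataset regardless of record order.
    """
    rng = np.random.default_rng(truth.seed)
    scheme = truth.scheme
    n = truth.n

    factor_draws: dict[str, np.ndarray] = {}
    eta = np.full(n, truth.intercept)
    for f in scheme.factors:
        p = np.asarray(truth.factor_prevalences[f.name], dtype=float)
        d = rng.choice(len(f.categories), size=n, p=p)
        factor_draws[f.name] = d
        for j, cat in enumerate(f.categories):
            beta = truth.main_effects.get((f.name, cat), 0.0)
            if beta:
                eta += beta * (d == j)

    cov_cols: dict[str, np.ndarray] = {}
    for name, spec in truth.covariate_schema.items():
        if spec == INT_COVARIATE:
            vals = 1 + rng.poisson(max(truth.household_size_mean - 1.0, 0.0), size=n)
            cov_cols[name] = vals
            beta = truth.covariate_effects.get((name, "per_unit"), 0.0)
            if beta:
                eta += beta * vals
        else:
            p = truth.covariate_prevalences.get(name)
            if p is None:
                p = [1.0 / len(spec)] * len(spec)
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValidationError(f"invalid prevalence vector for covariate {name!r}")
            d = rng.choice(len(spec), size=n, p=p)
            cov_cols[name] = d
            for j, cat in enumerate(spec):
                beta = truth.covariate_effects.get((name, cat), 0.0)
                if beta:
                    eta += beta * (d == j)

    codes = _lex_codes(factor_draws, scheme)
    observed = np.unique(codes)
    z = rng.standard_normal(observed.size)
    effects: dict[tuple[str, ...], float] = {}
    u_by_code = {}
    for code, zi in zip(observed, z):
        combo = _decode(code, scheme)
        u = truth.sigma_u * zi + truth.deviations.get(combo, 0.0)
        effects[combo] = u
        u_by_code[code] = u
    eta = eta + np.array([u_by_code[c] for c in codes])

    y = (rng.random(n) < expit(eta)).astype(int)

    data = {"household_id": [f"hh{i:05d}" for i in range(n)], truth.outcome: y}
    if include_variants:
        for name, shift in truth.variant_shifts.items():
            data[name] = (rng.random(n) < expit(eta + shift)).astype(int)
        if "hu_within" in data and "hu_outside" in data:
            data["hu_combined"] = np.maximum(data["hu_within"], data["hu_outside"])
        if truth.formal_given_use is not None:
            thin = rng.random(n) < truth.formal_given_use
            for base in ("hu_within", "hu_outside"):
                if base in data:
                    data[f"{base}_formal"] = (data[base] & thin).astype(int)
    for f in scheme.factors:
        data[f.name] = [f.categories[c] for c in factor_draws[f.name]]
    for name, spec in truth.covariate_schema.items():
        if spec == INT_COVARIATE:
            data[name] = cov_cols[name]
        else:
            data[name] = [spec[c] for c in cov_cols[name]]

    frame = pd.DataFrame(data)
    frame["household_id"] = frame["household_id"].astype("string")
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].astype("string")
    for out in data:
        if out.startswith("hu_"):
            frame[out] = frame[out].astype("Int64")
    dataset = SurveyDataset(frame, scheme, dict(truth.covariate_schema))
    return dataset, effects
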