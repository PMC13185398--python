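"""Household survey data: schemas, I/O, recoding and descriptive tables.

The analysis operates on a household-level cross-sectional survey with binary
healthcare-utilisation (HU) outcomes, six categorical social-position factors
that define the intersectional strata, and a set of categorical explanatory
covariates.  This module owns the tabular representation (a validated pandas
DataFrame wrapped in :class:`SurveyDataset`), CSV round-tripping, the
food-security recode, and Table-1-style descriptive cross-tabulations.

Missing values are represented by the empty string on disk and by ``pd.NA``
in memory; they are preserved, never imputed.  Analysis sets differ by
outcome (complete-case per outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorScheme",
    "SurveyDataset",
    "CrossTab",
    "OUTCOME_NAMES",
    "SchemaError",
    "ValidationError",
    "default_scheme",
    "default_covariate_schema",
    "read_survey",
    "write_survey",
    "recode_food_security",
    "descriptive_table",
]

#: The five HU outcome variants carried by the survey schema.
OUTCOME_NAMES = (
    "hu_within",
    "hu_outside",
    "hu_combined",
    "hu_within_formal",
    "hu_outside_formal",
)

ID_COLUMN = "household_id"

#: Marker for integer-valued covariates (e.g. household size) in a covariate
#: schema; categorical covariates list their labels instead.
INT_COVARIATE = "int"


class SchemaError(ValueError):
    """A declared column is absent or the file disagrees with the schema."""


class ValidationError(ValueError):
    """A cell value is not a member of its declared category set."""


@dataclass(frozen=True)
class Factor:
    """One social-position factor: ordered categories, first = reference."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValidationError(f"factor {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError(f"factor {self.name!r} has duplicate categories")

    @property
    def reference(self) -> str:
        return self.categories[0]


@dataclass(frozen=True)
class FactorScheme:
    """Ordered collection of the factors that define intersectional strata."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate factor names in scheme")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def n_combinations(self) -> int:
        """Number of possible strata = product of category counts."""
        out = 1
        for f in self.factors:
            out *= len(f.categories)
        return out

    def combinations(self) -> Iterator[tuple[str, ...]]:
        """All possible factor combinations in lexicographic (declared) order."""
        import itertools

        yield from itertools.product(*(f.categories for f in self.factors))

    def validate_combination(self, combo: Sequence[str]) -> tuple[str, ...]:
        combo = tuple(combo)
        if len(combo) != len(self.factors):
            raise ValidationError(
                f"combination has {len(combo)} entries, scheme has {len(self.factors)} factors"
            )
        for f, label in zip(self.factors, combo):
            if label not in f.categories:
                raise ValidationError(
                    f"label {label!r} is not a category of factor {f.name!r}"
                )
        return combo


def default_scheme() -> FactorScheme:
    """The six-factor scheme for the Freetown informal-settlements survey.

    Reference categories (first label of each factor) follow the model's
    dummy coding: female head, single, no income activity, food secure, no
    disability, Cockle Bay.  Category counts 2,3,2,2,2,3 give 144 possible
    strata.
    """
    return FactorScheme(
        (
            Factor("hoh_gender", ("female", "male")),
            Factor(
                "marital",
                ("single", "married_cohabit_engaged", "divorced_separated_widowed"),
            ),
            Factor("income_activity", ("no", "yes")),
            Factor("food_security", ("food_secure", "food_insecure")),
            Factor("disability", ("no", "yes")),
            Factor("settlement", ("cockle_bay", "dwazark", "moyiba")),
        )
    )


def default_covariate_schema() -> dict[str, tuple[str, ...] | str]:
    """Representative household-level explanatory covariates.

    A subset of the survey's predisposing and enabling variables; users may
    declare their own schema with any categorical covariates.  "dont_know" is
    kept as a valid level where the instrument allowed it.
    """
    return {
        "household_size": INT_COVARIATE,
        "residence_length": ("0_1y", "1_5y", "6_10y", "gt_10y"),
        "tenure": ("tenant", "landlord", "free_living", "other"),
        "water_distance": ("lt_30min", "30min_1h", "1_2h", "gt_2h", "dont_know"),
        "water_shortage": ("yes", "no", "dont_know"),
        "toilet_flush": ("no", "yes"),
        "toilet_bucket": ("no", "yes"),
        "shared_toilet": ("yes", "no", "not_applicable"),
        "waste_payment": ("no", "yes"),
        "environmental_disaster": ("no", "yes"),
        "income_business": ("no", "yes"),
        "income_private_salaried": ("no", "yes"),
    }


@dataclass
class SurveyDataset:
    """Validated household survey table.

    ``frame`` columns: ``household_id``, any subset of :data:`OUTCOME_NAMES`
    (nullable Int64, values 0/1), one column per factor and per covariate
    (pandas ``string`` dtype, ``pd.NA`` = missing; integer covariates are
    nullable Int64).
    """

    frame: pd.DataFrame
    scheme: FactorScheme
    covariate_schema: dict[str, tuple[str, ...] | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.frame[ID_COLUMN]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate household id {dup!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(c for c in OUTCOME_NAMES if c in self.frame.columns)

    def analysis_set(self, outcome: str) -> pd.DataFrame:
        """Complete cases for one outcome: non-missing outcome and factors."""
        if outcome not in self.frame.columns:
            raise SchemaError(f"outcome column {outcome!r} not in dataset")
        mask = self.frame[outcome].notna()
        for name in self.scheme.names:
            mask &= self.frame[name].notna()
        return self.frame.loc[mask]


def _check_columns(df: pd.DataFrame, scheme: FactorScheme, covariate_schema) -> None:
    needed = [ID_COLUMN, *scheme.names, *covariate_schema]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if not any(c in df.columns for c in OUTCOME_NAMES):
        raise SchemaError(f"no outcome column among {OUTCOME_NAMES}")


def _validate_categorical(df: pd.DataFrame, column: str, allowed: Sequence[str]) -> None:
    col = df[column]
    bad = col.notna() & ~col.isin(list(allowed))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {row}, column {column!r}: value {col.iloc[row]!r} "
            f"not in declared categories {tuple(allowed)}"
        )


def _coerce(df: pd.DataFrame, scheme: FactorScheme, covariate_schema) -> pd.DataFrame:
    df = df.copy()
    df[ID_COLUMN] = df[ID_COLUMN].astype("string")
    for out in OUTCOME_NAMES:
        if out in df.columns:
            vals = df[out].replace("", pd.NA)
            coerced = pd.to_numeric(vals, errors="coerce").astype("Int64")
            bad = vals.notna() & coerced.isna()
            bad |= coerced.notna() & ~coerced.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {row}, column {out!r}: outcome must be 0, 1 or missing"
                )
            df[out] = coerced
    for f in scheme.factors:
        df[f.name] = df[f.name].replace("", pd.NA).astype("string")
        _validate_categorical(df, f.name, f.categories)
    for name, spec in covariate_schema.items():
        if spec == INT_COVARIATE:
            vals = df[name].replace("", pd.NA)
            coerced = pd.to_numeric(vals, errors="coerce").astype("Int64")
            bad = (vals.notna() & coerced.isna()) | (coerced.notna() & (coerced < 0))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {row}, column {name!r}: expected non-negative integer"
                )
            df[name] = coerced
        else:
            df[name] = df[name].replace("", pd.NA).astype("string")
            _validate_categorical(df, name, spec)
    return df


def read_survey(
    path: str | Path,
    scheme: FactorScheme | None = None,
    covariate_schema: Mapping[str, tuple[str, ...] | str] | None = None,
) -> SurveyDataset:
    """Read and validate a household survey CSV.

    The file is comma-separated UTF-8 with a header row; the empty string
    marks a missing value.  Rows with category labels outside the declared
    schema raise :class:`ValidationError` naming row, column and value.
    """
    scheme = scheme or default_scheme()
    covariate_schema = dict(
        covariate_schema if covariate_schema is not None else default_covariate_schema()
    )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, scheme, covariate_schema)
    df = _coerce(df, scheme, covariate_schema)
    return SurveyDataset(df, scheme, covariate_schema)


def from_dataframe(
    df: pd.DataFrame,
    scheme: FactorScheme | None = None,
    covariate_schema: Mapping[str, tuple[str, ...] | str] | None = None,
) -> SurveyDataset:
    """Build a validated :class:`SurveyDataset` from an in-memory DataFrame."""
    scheme = scheme or default_scheme()
    covariate_schema = dict(
        covariate_schema if covariate_schema is not None else default_covariate_schema()
    )
    df = df.astype(str).replace({"<NA>": "", "nan": ""})
    _check_columns(df, scheme, covariate_schema)
    df = _coerce(df, scheme, covariate_schema)
    return SurveyDataset(df, scheme, covariate_schema)


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the canonical CSV form (header, empty string = missing)."""
    cols = [ID_COLUMN]
    cols += [c for c in OUTCOME_NAMES if c in dataset.frame.columns]
    cols += list(dataset.scheme.names)
    cols += list(dataset.covariate_schema)
    out = dataset.frame[cols].copy()
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Recoding

_FOOD_SECURITY_RECODE = {
    "never": "food_secure",
    "rarely_1_2": "food_secure",
    "sometimes_3_10": "food_insecure",
    "often_gt_10": "food_insecure",
}


def recode_food_security(failed_to_eat_frequency: str) -> str:
    """Collapse the four-level failed-to-eat frequency into food security.

    A household is food secure if, in the past month, it never or only rarely
    (once or twice) failed to eat its preferred food for lack of resources;
    sometimes (3-10 times) or often (more than 10 times) codes food insecure.
    """
    try:
        return _FOOD_SECURITY_RECODE[failed_to_eat_frequency]
    except KeyError:
        raise ValidationError(
            f"unknown failed-to-eat frequency {failed_to_eat_frequency!r}; "
            f"expected one of {tuple(_FOOD_SECURITY_RECODE)}"
        ) from None


# ---------------------------------------------------------------------------
# Descriptive tables


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (table convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CrossTab:
    """One variable's rows of a descriptive table for a single outcome.

    ``rows`` columns: category, n_no, n_yes, n_total, pct_of_total, pct_yes.
    Percentages are rounded half-up to one decimal; ``pct_yes`` is the
    within-row utilisation percentage.
    """

    variable: str
    rows: pd.DataFrame
    grand_total: int

    def __post_init__(self) -> None:
        r = self.rows
        assert (r["n_no"] + r["n_yes"] == r["n_total"]).all()


def _crosstab(sub: pd.DataFrame, variable: str, outcome: str, categories, grand: int) -> CrossTab:
    rows = []
    col = sub[variable]
    for cat in categories:
        sel = sub.loc[col == cat, outcome]
        n_yes = int((sel == 1).sum())
        n_tot = int(sel.notna().sum())
        rows.append(
            {
                "category": cat,
                "n_no": n_tot - n_yes,
                "n_yes": n_yes,
                "n_total": n_tot,
                "pct_of_total": round_half_up(100.0 * n_tot / grand) if grand else 0.0,
                "pct_yes": round_half_up(100.0 * n_yes / n_tot) if n_tot else 0.0,
            }
        )
    return CrossTab(variable, pd.DataFrame(rows), grand)


def descriptive_table(dataset: SurveyDataset, outcome: str) -> list[CrossTab]:
    """Table-1-style cross-tabulations of every factor and covariate by HU.

    Records missing the outcome are excluded from this outcome's table only.
    The final CrossTab (variable ``"total"``) carries the grand-total row.
    Raises on an empty analysis set.
    """
    if outcome not in dataset.frame.columns:
        raise SchemaError(f"outcome column {outcome!r} not in dataset")
    sub = dataset.frame.loc[dataset.frame[outcome].notna()]
    if sub.empty:
        raise ValidationError(f"no records with non-missing outcome {outcome!r}")
    grand = len(sub)
    tables: list[CrossTab] = []
    for f in dataset.scheme.factors:
        tables.append(_crosstab(sub, f.name, outcome, f.categories, grand))
    for name, spec in dataset.covariate_schema.items():
        if spec == INT_COVARIATE:
            continue  # integer covariates are summarised by the model, not Table 1 rows
        tables.append(_crosstab(sub, name, outcome, spec, grand))
    n_yes = int((sub[outcome] == 1).sum())
    total_rows = pd.DataFrame(
        [
            {
                "category": "total",
                "n_no": grand - n_yes,
                "n_yes": n_yes,
                "n_total": grand,
                "pct_of_total": 100.0,
                "pct_yes": round_half_up(100.0 * n_yes / grand),
            }
        ]
    )
    tables.append(CrossTab("total", total_rows, grand))
    return tables


def descriptive_frame(tables: list[CrossTab]) -> pd.DataFrame:
    """Flatten CrossTabs to one exportable DataFrame."""
    parts = []
    for t in tables:
        block = t.rows.copy()
        block.insert(0, "variable", t.variable)
        parts.append(block)
    return pd.concat(parts, ignore_index=True)
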