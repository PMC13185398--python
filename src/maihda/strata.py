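"""Intersectional strata: cross-classification of the social factors.

A stratum is one observed combination of the categorical social-position
factors (e.g. male head x single x no income activity x food insecure x
disability x Moyiba).  Strata are the level-2 units of the multilevel model:
households (level 1) are nested within them.  Only observed combinations
receive an id (and later a random effect); unobserved cells are countable
but carry no id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey import FactorScheme, SurveyDataset, ValidationError

__all__ = ["StratumTable", "SparseStrataReport", "build_strata", "sparse_strata_report"]


@dataclass
class StratumTable:
    """Observed strata with 1-based ids in lexicographic factor order.

    ``table`` columns: ``stratum_id``, one column per factor, ``n_households``.
    ``assignments`` maps each eligible record (by frame index) to its stratum
    id; records missing any factor appear in ``excluded`` with a reason.
    """

    table: pd.DataFrame
    scheme: FactorScheme
    assignments: pd.Series
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_observed(self) -> int:
        return len(self.table)

    @property
    def n_possible(self) -> int:
        return self.scheme.n_combinations

    @property
    def counts(self) -> np.ndarray:
        return self.table["n_households"].to_numpy()

    def combination_of(self, stratum_id: int) -> tuple[str, ...]:
        row = self.table.loc[self.table["stratum_id"] == stratum_id]
        if row.empty:
            raise KeyError(f"no observed stratum with id {stratum_id}")
        return tuple(row.iloc[0][list(self.scheme.names)])

    def id_of(self, combo) -> int:
        combo = self.scheme.validate_combination(combo)
        mask = np.ones(len(self.table), dtype=bool)
        for name, label in zip(self.scheme.names, combo):
            mask &= (self.table[name] == label).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"combination {combo} not observed")
        return int(self.table["stratum_id"].iloc[idx[0]])

    def labels(self) -> list[str]:
        """Human-readable combination label per stratum, id order."""
        return [
            " / ".join(row)
            for row in self.table[list(self.scheme.names)].to_numpy()
        ]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_strata(dataset: SurveyDataset, scheme: FactorScheme | None = None) -> StratumTable:
    """Cross-classify the social factors into observed strata.

    Ids are assigned 1..K in lexicographic order of the scheme's declared
    category order, so labelling is reproducible across runs and record
    permutations.  Records with any missing factor are excluded (with an
    audit trail), never silently dropped.
    """
    scheme = scheme or dataset.scheme
    df = dataset.frame
    names = list(scheme.names)
    missing_mask = df[names].isna().any(axis=1)
    excluded = df.loc[missing_mask, ["household_id", *names]].copy()
    if not excluded.empty:
        reason = df.loc[missing_mask, names].isna().apply(
            lambda r: "missing_factor:" + ",".join(c for c in names if r[c]), axis=1
        )
        excluded["reason"] = reason
    eligible = df.loc[~missing_mask, names]

    # integer code per factor in declared category order -> lexicographic key
    codes = np.zeros(len(eligible), dtype=np.int64)
    for f in scheme.factors:
        cat = pd.Categorical(eligible[f.name], categories=list(f.categories))
        codes = codes * len(f.categories) + cat.codes
    order = np.unique(codes)
    key_to_id = {k: i + 1 for i, k in enumerate(order)}
    ids = pd.Series(
        [key_to_id[k] for k in codes], index=eligible.index, name="stratum_id"
    )

    # decode each observed key back to its combination
    sizes = [len(f.categories) for f in scheme.factors]
    rows = []
    counts = pd.Series(codes).value_counts()
    for k in order:
        combo = []
        rem = int(k)
        for size in reversed(sizes):
            combo.append(rem % size)
            rem //= size
        combo = combo[::-1]
        row = {"stratum_id": key_to_id[k]}
        for f, c in zip(scheme.factors, combo):
            row[f.name] = f.categories[c]
        row["n_households"] = int(counts[k])
        rows.append(row)
    table = pd.DataFrame(rows)
    return StratumTable(table, scheme, ids, excluded)


@dataclass
class SparseStrataReport:
    """Count and share of observed strata below a size threshold."""

    threshold: int
    n_observed: int
    n_flagged: int
    flagged: pd.DataFrame

    @property
    def pct_flagged(self) -> float:
        return 100.0 * self.n_flagged / self.n_observed if self.n_observed else 0.0


def sparse_strata_report(table: StratumTable, threshold: int = 5) -> SparseStrataReport:
    """Flag strata with fewer than ``threshold`` households.

    Small cells are retained in the model (the hierarchical prior shrinks
    them); this report only audits how many there are, since many sparse
    cells reduce the power to detect intersectional deviations.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    flagged = table.table.loc[table.table["n_households"] < threshold].copy()
    return SparseStrataReport(threshold, table.n_observed, len(flagged), flagged)
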