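"""Bundled synthetic example datasets.

The real Freetown household survey is restricted, so nothing here is actual
survey data.  ``synthetic_margins_survey`` is a synthetic reconstruction
built to be *exactly consistent with the published marginal counts* of the
survey's descriptive table — the grand totals (1,437/4,821 utilising within
the settlement; 1,553/4,838 outside) and the disability and food-security
rows for utilisation outside (136/319 and 954/2,434).  Joint cells are
filled in deterministically; variables other than those named are constant
filler, so only the stated margins are meaningful.
"""

from __future__ import annotations

import pandas as pd

from .survey import SurveyDataset, default_scheme, from_dataframe

__all__ = ["synthetic_margins_survey"]


def synthetic_margins_survey() -> SurveyDataset:
    """Synthetic 4,871-household dataset reproducing the published margins.

    A deterministic joint (disability x food security x HU outside) layout
    consistent with the published marginal rows; 33 households miss the
    outside outcome and 50 miss the within outcome, reproducing the
    per-outcome analysis-set sizes (4,838 and 4,821).
    """
    # (disability, food_security, cell size, utilised outside)
    cells = [
        ("yes", "food_insecure", 200, 100),
        ("yes", "food_secure", 119, 36),
        ("no", "food_insecure", 2234, 854),
        ("no", "food_secure", 2285, 563),
    ]
    disability: list[str] = []
    food: list[str] = []
    hu_outside: list[object] = []
    for dis, fs, n, n_yes in cells:
        disability.extend([dis] * n)
        food.extend([fs] * n)
        hu_outside.extend([1] * n_yes + [0] * (n - n_yes))
    n_total = 4871
    n_extra = n_total - len(disability)  # 33 records missing hu_outside
    disability.extend(["no"] * n_extra)
    food.extend(["food_secure"] * n_extra)
    hu_outside.extend([""] * n_extra)

    hu_within = [""] * 50 + [1] * 1437 + [0] * (n_total - 50 - 1437)

    df = pd.DataFrame(
        {
            "household_id": [f"hh{i:05d}" for i in range(n_total)],
            "hu_within": hu_within,
            "hu_outside": hu_outside,
            "hoh_gender": "female",
            "marital": "single",
            "income_activity": "no",
            "food_security": food,
            "disability": disability,
            "settlement": "cockle_bay",
        }
    )
    return from_dataframe(df, default_scheme(), covariate_schema={})
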