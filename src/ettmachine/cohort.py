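"""Patient-level cohort container.

A cohort couples a rectangular pandas table with the variable roles needed by
every downstream stage: which column is the binary site exposure, which
columns are outcomes (and of what type), and which are covariates (possibly
with missing entries, stored as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COL = "site_large"
ID_COL = "patient_id"

VALID_OUTCOME_TYPES = {"binary", "continuous"}
VALID_COVARIATE_TYPES = {"continuous", "binary", "categorical"}


@dataclass
class CohortTable:
    """Rows = patients; one binary site column (1 = large-volume center),
    outcome columns, and covariate columns that may contain NaN."""

    df: pd.DataFrame
    outcomes: dict[str, str] = field(default_factory=dict)  # name -> binary|continuous
    covariates: dict[str, str] = field(default_factory=dict)  # name -> type

    def __post_init__(self) -> None:
        df = self.df
        if SITE_COL not in df.columns:
            raise ValueError(f"cohort is missing the site column {SITE_COL!r}")
        if ID_COL not in df.columns:
            df = df.copy()
            df.insert(0, ID_COL, np.arange(len(df)))
            self.df = df
        if df[ID_COL].duplicated().any():
            raise ValueError("patient ids are not unique")
        site = df[SITE_COL]
        if site.isna().any():
            raise ValueError("site column contains missing values")
        if not set(np.unique(site)).issubset({0, 1}):
            raise ValueError(f"site column must be coded 0/1, got {sorted(set(site))}")
        for name, kind in self.outcomes.items():
            if kind not in VALID_OUTCOME_TYPES:
                raise ValueError(f"unknown outcome type {kind!r} for {name!r}")
            if name not in df.columns:
                raise ValueError(f"declared outcome {name!r} not in table")
        for name, kind in self.covariates.items():
            if kind not in VALID_COVARIATE_TYPES:
                raise ValueError(f"unknown covariate type {kind!r} for {name!r}")
            if name not in df.columns:
                raise ValueError(f"declared covariate {name!r} not in table")
        if self.outcomes and not any(
            self.df[name].notna().all() for name in self.outcomes
        ):
            raise ValueError("at least one outcome must be fully observed")

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def site(self) -> np.ndarray:
        return self.df[SITE_COL].to_numpy(dtype=int)

    def outcome_values(self, name: str) -> np.ndarray:
        if name not in self.outcomes:
            raise KeyError(f"unknown outcome {name!r}; declared: {sorted(self.outcomes)}")
        return self.df[name].to_numpy(dtype=float)

    def outcome_mask(self, name: str) -> np.ndarray:
        """Boolean mask of rows with the outcome observed."""
        return self.df[name].notna().to_numpy()

    def covariate_frame(self) -> pd.DataFrame:
        return self.df[list(self.covariates)]

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.df.loc[mask].reset_index(drop=True),
            outcomes=dict(self.outcomes),
            covariates=dict(self.covariates),
        )
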