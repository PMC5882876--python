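"""In-memory cohort container shared by the simulator, preprocessing and pipeline.

A cohort is a participants x features table plus per-feature metadata, a
per-participant treatment-arm label and a remission outcome (binary, or an
HRSD-17 total in [0, 52] still to be dichotomised).
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd

#: metadata columns every cohort carries per feature
META_COLUMNS = ("kind", "vtype", "maf", "levels", "mean", "sd")


@dataclasses.dataclass
class Cohort:
    """Participants x features with metadata, drug arm and outcome.

    Parameters
    ----------
    features
        ``n x p`` frame; SNP dosages coded additively (0/1/2, possibly NaN),
        clinical variables ordinal/binary/continuous.
    feature_meta
        Indexed by feature name. ``kind`` is ``"genetic"`` or ``"clinical"``;
        ``vtype`` one of ``"dosage"``, ``"ordinal"``, ``"binary"``,
        ``"continuous"``; ``levels`` the admissible value set for
        ordinal/binary columns (used for post-imputation rounding).
    drug
        Per-participant arm label (e.g. ``"A"`` / ``"B"``).
    outcome
        Binary remission indicator, or integer HRSD totals when
        ``outcome_kind == "hrsd_score"``.
    """

    features: pd.DataFrame
    feature_meta: pd.DataFrame
    drug: np.ndarray
    outcome: np.ndarray
    outcome_kind: str = "binary"
    config: Any = None

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.drug) != n or len(self.outcome) != n:
            raise ValueError("features, drug and outcome must have equal length")
        missing = [c for c in self.features.columns if c not in self.feature_meta.index]
        if missing:
            raise ValueError(f"feature_meta lacks entries for: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def genetic_columns(self) -> list[str]:
        meta = self.feature_meta.loc[list(self.features.columns)]
        return list(meta.index[meta["kind"] == "genetic"])

    @property
    def clinical_columns(self) -> list[str]:
        meta = self.feature_meta.loc[list(self.features.columns)]
        return list(meta.index[meta["kind"] == "clinical"])

    def restrict_features(self, columns: list[str]) -> "Cohort":
        """Return a cohort with only the given feature columns (order preserved)."""
        return Cohort(
            features=self.features[columns].copy(),
            feature_meta=self.feature_meta.loc[columns].copy(),
            drug=self.drug.copy(),
            outcome=self.outcome.copy(),
            outcome_kind=self.outcome_kind,
            config=self.config,
        )

    def arm_mask(self, drug: str) -> np.ndarray:
        return np.asarray(self.drug == drug)
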