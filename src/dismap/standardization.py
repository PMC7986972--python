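"""Direct age standardization and deprivation-quintile classification.

The age-adjusted count for a (county, race) pair is the standard-population
weighted sum of its age-specific counts, y*_ir = sum_a pi_a * y_iar — a
convex combination of the age-specific counts, generally non-integer. The
deprivation classifier splits county ADI scores into the lower 20%, middle
60% and upper 20%, and sets the model's binary indicator x2 = 1 for
counties strictly below the lower threshold (the least disadvantaged
quintile, since higher ADI means more disadvantage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdjustedCountTable", "AdiClassification", "age_adjust_counts", "classify_adi"]


@dataclass(frozen=True)
class AdjustedCountTable:
    """Age-adjusted counts y*_ir, one per (county, race)."""

    counties: tuple[str, ...]
    races: tuple[int, ...]
    y_star: np.ndarray  # (I, R), non-negative reals

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, r, self.y_star[i, k])
            for i, c in enumerate(self.counties)
            for k, r in enumerate(self.races)
        ]
        return pd.DataFrame(rows, columns=["county", "race", "y_star"])


@dataclass(frozen=True)
class AdiClassification:
    """Quintile grouping of county deprivation scores."""

    x2: np.ndarray                 # 1 = below the lower percentile threshold
    labels: tuple[str, ...]        # "Q1", "Q2-4" or "Q5" per county
    lower_threshold: float
    upper_threshold: float


def age_adjust_counts(counts, std_weights, counties=None, races=None,
                      round_adjusted: bool = False) -> AdjustedCountTable:
    """Directly age-standardize stratified counts.

    Parameters
    ----------
    counts
        Array ``(I, R, A)`` of cases per (county, race, age-group) cell, or
        an :class:`~dismap.data_model.IncidenceDataset` (in which case the
        weights argument may be None).
    std_weights
        Standard-population proportions over age groups, summing to 1.
    round_adjusted
        Round y* to the nearest integer (for comparison against
        integer-count likelihood fits); the default keeps the real value.
    """
    from .data_model import IncidenceDataset, NormalizationError, SchemaError

    if isinstance(counts, IncidenceDataset):
        ds = counts
        counts, counties, races = ds.counts, ds.counties, ds.races
        if std_weights is None:
            std_weights = ds.std_weights
    counts = np.asarray(counts, dtype=float)
    weights = np.asarray(std_weights, dtype=float)
    if counts.shape[-1] != weights.shape[0]:
        raise SchemaError(
            f"counts have {counts.shape[-1]} age groups but weights have "
            f"{weights.shape[0]}"
        )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise NormalizationError(
            f"standard-population weights sum to {weights.sum():.6g}, expected 1"
        )
    if np.any(counts < 0):
        raise SchemaError("negative age-specific count")
    y_star = counts @ weights
    if round_adjusted:
        y_star = np.round(y_star)
    I, R = y_star.shape
    return AdjustedCountTable(
        counties=tuple(counties) if counties is not None else tuple(
            f"county{i:02d}" for i in range(I)
        ),
        races=tuple(races) if races is not None else tuple(range(R)),
        y_star=y_star,
    )


def classify_adi(scores, lower_pct: float = 20.0, upper_pct: float = 80.0) -> AdiClassification:
    """Split deprivation scores into lower/middle/upper quantile groups.

    Thresholds use the linear-interpolation quantile (the order-statistic
    scheme x_(k) + gamma*(x_(k+1) - x_(k)) with k = floor(1 + p(n-1)), the
    common "type 7" default). A county is flagged x2 = 1 iff its score is
    strictly below the lower threshold; on distinct scores with n = 33 and
    lower_pct = 20 this flags exactly 7 counties. Labels map the flagged
    counties to Q1 (least disadvantaged), scores at or above the upper
    threshold to Q5, and the rest to Q2-4.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need at least two county scores")
    if np.ptp(scores) == 0:
        raise ValueError(
            "degenerate classification: all deprivation scores identical"
        )
    if not (0 < lower_pct < upper_pct <= 100):
        raise ValueError("require 0 < lower_pct < upper_pct <= 100")
    lower = float(np.percentile(scores, lower_pct, method="linear"))
    upper = float(np.percentile(scores, upper_pct, method="linear"))
    x2 = (scores < lower).astype(int)
    labels = np.where(x2 == 1, "Q1", np.where(scores >= upper, "Q5", "Q2-4"))
    return AdiClassification(
        x2=x2,
        labels=tuple(labels.tolist()),
        lower_threshold=lower,
        upper_threshold=upper,
    )
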