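"""Entropy-weight composite pollution index.

Region-by-year indicator tables (industrial SO2, industrial dust,
industrial wastewater, annual mean PM2.5) are combined into a single
Environmental Pollution Index by the entropy weight method: indicators
whose normalized shares are more dispersed across observations (lower
Shannon entropy) are more informative and receive larger weights.

Steps, for indicator j over rows i:

1. min–max normalize each column over the pooled region-year panel,
   direction-aware: x' = (x - min)/(max - min), or (max - x)/(max - min)
   for inverse-direction (larger-is-cleaner) indicators;
2. shares p_ij = x'_ij / sum_i x'_ij;
3. entropy e_j = -(1/ln n) sum_i p_ij ln p_ij  (0 ln 0 := 0);
4. weights w_j = (1 - e_j) / sum_k (1 - e_k);
5. index_i = sum_j w_j x'_ij, in [0, 1].

Normalization over the pooled panel (rather than within year) keeps the
index comparable across years.  Constant columns carry no information
and are excluded from weighting with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["normalize_indicators", "entropy_weights", "composite_index",
           "CompositeIndexModel"]

DEFAULT_INDICATORS = ("so2", "dust", "wastewater", "pm25")


def normalize_indicators(table: pd.DataFrame,
                         columns: Sequence[str] = DEFAULT_INDICATORS,
                         directions: Mapping[str, int] | None = None
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Direction-aware min–max normalization per column.

    ``directions`` maps column -> +1 (larger is more polluted, the
    default for every indicator) or -1 (inverse).  Returns the
    normalized frame and the list of constant columns flagged as
    degenerate (left as NaN and excluded from weighting).
    """
    if len(table) < 2:
        raise ValueError("indicator table needs at least 2 rows")
    directions = dict(directions or {})
    if (table[list(columns)].to_numpy(dtype=float) < 0).any():
        raise ValueError("raw indicator values must be non-negative")
    out = {}
    degenerate: list[str] = []
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            degenerate.append(col)
            out[col] = np.full_like(x, np.nan)
            continue
        if directions.get(col, 1) >= 0:
            out[col] = (x - lo) / (hi - lo)
        else:
            out[col] = (hi - x) / (hi - lo)
    return pd.DataFrame(out, index=table.index), degenerate


def entropy_weights(normalized: pd.DataFrame) -> pd.Series:
    """Shannon-entropy divergence weights over non-degenerate columns.

    Columns that are entirely NaN (flagged degenerate) are excluded; an
    all-degenerate matrix raises.
    """
    cols = [c for c in normalized.columns if not normalized[c].isna().all()]
    if not cols:
        raise ValueError("all indicator columns are degenerate")
    mat = normalized[cols].to_numpy(dtype=float)
    if np.nanmin(mat) < 0 or np.nanmax(mat) > 1:
        raise ValueError("normalized values must lie in [0, 1]")
    n = mat.shape[0]
    colsum = mat.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("normalized column sums must be positive")
    p = mat / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e
    if d.sum() <= 0:
        raise ValueError("all indicators have maximal entropy; weights undefined")
    w = d / d.sum()
    return pd.Series(w, index=cols, name="weight")


def composite_index(normalized: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted sum of normalized indicators per row, in [0, 1]."""
    cols = list(weights.index)
    if len(cols) != normalized[cols].shape[1]:
        raise ValueError("weight length must equal retained column count")
    mat = normalized[cols].to_numpy(dtype=float)
    return pd.Series(mat @ weights.to_numpy(), index=normalized.index, name="index")


@dataclass
class CompositeIndexModel:
    """Fitted entropy-weight index: normalized matrix, per-indicator
    entropies and weights, and the per-(region, year) index values."""

    normalized: pd.DataFrame
    entropies: pd.Series
    weights: pd.Series
    index: pd.Series
    keys: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   columns: Sequence[str] = DEFAULT_INDICATORS,
                   directions: Mapping[str, int] | None = None
                   ) -> "CompositeIndexModel":
        """Build the index from a region-by-year indicator table with
        ``region_id`` and ``year`` key columns."""
        if table.duplicated(subset=["region_id", "year"]).any():
            raise ValueError("duplicate (region_id, year) rows in indicator table")
        normalized, degenerate = normalize_indicators(table, columns, directions)
        weights = entropy_weights(normalized)
        n = mat_entropy(normalized[weights.index])
        idx = composite_index(normalized, weights)
        return cls(normalized=normalized, entropies=n, weights=weights,
                   index=idx, keys=table[["region_id", "year"]].copy(),
                   degenerate=degenerate)

    def index_frame(self) -> pd.DataFrame:
        out = self.keys.copy()
        out["pollution_index"] = self.index.to_numpy()
        return out

    def merge_into_panel(self, panel: pd.DataFrame,
                         column: str = "pollution_index") -> pd.DataFrame:
        """Join the index onto a panel by (region_id, wave year)."""
        frame = self.index_frame().rename(columns={"pollution_index": column})
        merged = panel.merge(frame, left_on=["region_id", "wave"],
                             right_on=["region_id", "year"], how="left")
        return merged.drop(columns=["year"])


def mat_entropy(normalized: pd.DataFrame) -> pd.Series:
    """Per-column Shannon entropy e_j of the normalized-share matrix."""
    mat = normalized.to_numpy(dtype=float)
    n = mat.shape[0]
    p = mat / mat.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-plogp.sum(axis=0) / np.log(n), index=normalized.columns,
                     name="entropy")
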