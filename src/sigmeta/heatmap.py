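"""Heatmap matrix conventions: log transform, row normalisation, clustering.

Abundance heatmaps use a log10(x + 1) transform for visibility, then each
row is divided by its maximum so relative differences between samples show
per taxon.  Row and column orders come from average-linkage hierarchical
clustering (Bray-Curtis across samples, correlation across taxa); the
ordering is cosmetic and never feeds statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class HeatmapMatrix:
    """Transformed matrix plus display orders."""

    matrix: pd.DataFrame
    row_order: list
    col_order: list

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _safe_order(values: np.ndarray, metric: str, method: str) -> np.ndarray:
    if values.shape[0] < 3:
        return np.arange(values.shape[0])
    dist = pdist(values, metric=metric)
    dist = np.nan_to_num(dist, nan=1.0)  # constant rows: treat as maximally far
    return leaves_list(linkage(dist, method=method))


def heatmap_matrix(
    values: pd.DataFrame, linkage_method: str = "average"
) -> HeatmapMatrix:
    """log10(x+1)-transform and row-normalise a taxa × samples matrix.

    All-zero rows are left as zeros and excluded from clustering (appended
    at the end of the row order, with a warning).
    """
    if (np.asarray(values) < 0).any():
        raise DataError("heatmap input must be non-negative")
    logged = np.log10(np.asarray(values, dtype=float) + 1.0)
    row_max = logged.max(axis=1)
    zero_rows = row_max == 0
    if zero_rows.any():
        logger.warning("%d all-zero rows excluded from clustering", zero_rows.sum())
    scale = np.where(zero_rows, 1.0, row_max)
    normed = logged / scale[:, None]
    matrix = pd.DataFrame(normed, index=values.index, columns=values.columns)

    live = matrix.loc[~zero_rows]
    row_idx = _safe_order(np.asarray(live), "correlation", linkage_method)
    row_order = list(live.index[row_idx]) + list(matrix.index[zero_rows])
    col_idx = _safe_order(np.asarray(values, dtype=float).T, "braycurtis", linkage_method)
    col_order = list(matrix.columns[col_idx])
    return HeatmapMatrix(matrix=matrix, row_order=row_order, col_order=col_order)
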