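"""Array preprocessing: log2 transform, quantile normalization, replicate collapse.

Input intensity tables are assumed background-corrected upstream; values must
be strictly positive before the log transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import ExpressionMatrix, ProbeAnnotation

__all__ = ["quantile_normalize", "collapse_replicates", "preprocess"]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean of sorted columns) distribution.

    Tied values within a column receive the mean of the reference values at
    their tied ranks, so within-column rank order is preserved up to ties.
    """
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("quantile normalization requires finite values")
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        col = np.empty(arr.shape[0])
        col[order[:, j]] = reference
        # average the reference over tied input values
        s = pd.Series(col, index=rows)
        out[:, j] = s.groupby(arr[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_replicates(values: pd.DataFrame, ann: ProbeAnnotation) -> pd.DataFrame:
    """Replace technically replicated probes (shared platform id) by their median.

    Each collapsed row keeps the probe id of the group's first member (in
    matrix order), so downstream probe-level annotation still applies.
    """
    ann.require_probes(values.index)
    groups = ann.replicate_group_of().reindex(values.index)
    collapsed = values.groupby(groups, sort=False).median()
    representative = (
        pd.Series(values.index, index=groups.to_numpy())
        .groupby(level=0, sort=False)
        .first()
    )
    return collapsed.rename(index=representative.to_dict())


def preprocess(raw: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """log2 -> quantile normalization -> median collapse of replicate probes."""
    arr = raw.values
    bad = ~(arr.to_numpy(dtype=float) > 0) | ~np.isfinite(arr.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive intensity at probe "
            f"{arr.index[i]!r}, sample {arr.columns[j]!r}: {arr.iat[i, j]}"
        )
    logged = np.log2(arr)
    normalized = quantile_normalize(logged)
    collapsed = collapse_replicates(normalized, ann)
    return ExpressionMatrix(
        values=collapsed,
        pair_map=dict(raw.pair_map),
        group_labels=dict(raw.group_labels),
    )
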