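"""Per-assignment FDR curves, their extremes, and smoothed density summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .base import ExpressionMatrix, GroupAssignment, ProbeAnnotation
from .stats import GeneStatTable, disambiguate_probes, moderated_t

__all__ = ["NullEnsemble", "ensemble_curves", "most_extreme_assignment", "smooth_density"]


@dataclass
class NullEnsemble:
    """Ranked adjusted-p curves for a set of two-group assignments.

    ``curves[i]`` holds, for assignment ``i``, the per-gene raw and
    FDR-adjusted p-values ordered by ascending raw p (columns ``rank``,
    ``p``, ``p_adjusted``).
    """

    assignments: list[GroupAssignment]
    curves: list[pd.DataFrame]
    alpha: float = 0.05
    tables: list[GeneStatTable] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.assignments) != len(self.curves):
            raise ValueError("one curve per assignment required")

    def significant_counts(self, alpha: float | None = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        return np.array([(c["p_adjusted"] < a).sum() for c in self.curves])

    def pooled_raw_p(self) -> np.ndarray:
        return np.concatenate([c["p"].to_numpy() for c in self.curves])


def ensemble_curves(
    matrix: ExpressionMatrix,
    assignments: Sequence[GroupAssignment],
    ann: ProbeAnnotation | None = None,
    prior_df: float | None = None,
    readjust: bool = True,
    alpha: float = 0.05,
    keep_tables: bool = False,
) -> NullEnsemble:
    """Moderated t -> (probe disambiguation) -> BH curve, per assignment.

    With ``ann`` given, probes targeting the same gene are first reduced to
    the lowest-p probe (BH re-applied afterwards when ``readjust``).
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("need at least one assignment")
    curves, tables = [], []
    for a in assignments:
        tab = moderated_t(matrix, a, prior_df=prior_df)
        if ann is not None:
            tab = disambiguate_probes(tab, ann, readjust=readjust)
        curve = tab.ranked_curve()
        curves.append(curve[["rank", "p", "p_adjusted"]])
        if keep_tables:
            tables.append(tab)
    return NullEnsemble(
        assignments=assignments,
        curves=curves,
        alpha=alpha,
        tables=tables if keep_tables else None,
    )


def most_extreme_assignment(
    ensemble: NullEnsemble, alpha: float = 0.05
) -> GroupAssignment:
    """The assignment with the most FDR-adjusted p-values below alpha.

    Ties are broken by the smallest minimum adjusted p, then by input order.
    """
    counts = ensemble.significant_counts(alpha)
    min_adj = np.array([c["p_adjusted"].min() for c in ensemble.curves])
    best = 0
    for i in range(1, len(counts)):
        if counts[i] > counts[best] or (
            counts[i] == counts[best] and min_adj[i] < min_adj[best]
        ):
            best = i
    return ensemble.assignments[best]


def smooth_density(
    ensemble: NullEnsemble,
    grid_size: tuple[int, int] = (200, 200),
    bandwidth: tuple[float, float] | None = None,
    bandwidth_scale: float = 1.0,
    pad_sigmas: float = 5.0,
):
    """Gaussian-kernel 2-D density of the ensemble curves over (log10 rank, p).

    Curve points are binned on a regular grid padded by ``pad_sigmas``
    bandwidths and smoothed with a Gaussian kernel (Silverman's rule per axis
    unless ``bandwidth`` is given, times ``bandwidth_scale``).  The returned
    density integrates to 1 over the grid.  All-identical curves yield a
    delta-like ridge rather than an error.

    Returns ``(x_grid, y_grid, density)`` with ``density[i, j]`` at
    ``(x_grid[i], y_grid[j])``.
    """
    if len(ensemble.curves) < 2:
        raise ValueError("need at least two curves for a density summary")
    x = np.concatenate(
        [np.log10(c["rank"].to_numpy(dtype=float)) for c in ensemble.curves]
    )
    y = np.concatenate([c["p_adjusted"].to_numpy(dtype=float) for c in ensemble.curves])
    n = x.size
    if bandwidth is None:
        # Silverman per axis for a 2-D product kernel
        factor = n ** (-1.0 / 6.0)
        hx = max(factor * x.std(), 1e-3)
        hy = max(factor * y.std(), 1e-3)
    else:
        hx, hy = bandwidth
    hx *= bandwidth_scale
    hy *= bandwidth_scale

    nx, ny = grid_size
    if nx < 2 or ny < 2:
        raise ValueError("grid must have at least 2 points per axis")
    x_lo, x_hi = x.min() - pad_sigmas * hx, x.max() + pad_sigmas * hx
    y_lo, y_hi = y.min() - pad_sigmas * hy, y.max() + pad_sigmas * hy
    x_grid = np.linspace(x_lo, x_hi, nx)
    y_grid = np.linspace(y_lo, y_hi, ny)
    dx = x_grid[1] - x_grid[0]
    dy = y_grid[1] - y_grid[0]

    hist, _, _ = np.histogram2d(x, y, bins=[nx, ny], range=[[x_lo - dx / 2, x_hi + dx / 2],
                                                            [y_lo - dy / 2, y_hi + dy / 2]])
    density = gaussian_filter(hist, sigma=(hx / dx, hy / dy), mode="constant")
    total = density.sum() * dx * dy
    if total <= 0:
        raise ValueError("density collapsed to zero mass")
    return x_grid, y_grid, density / total
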