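"""Moderated t gene ranking, BH-FDR adjustment, probe disambiguation.

The moderated t shrinks gene-wise pooled variances toward a common prior
variance ``s0**2`` with prior degrees of freedom ``d0`` estimated by
method-of-moments on the log sample variances (a scaled-F fit in the style of
empirical-Bayes microarray analysis): the posterior variance is
``(d0*s0**2 + dg*sg**2) / (d0 + dg)`` and two-sided p-values come from the t
distribution with ``d0 + dg`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .base import ExpressionMatrix, GroupAssignment, ProbeAnnotation, pooled_variance

__all__ = ["GeneStatTable", "moderated_t", "bh_adjust", "disambiguate_probes"]

logger = logging.getLogger(__name__)


@dataclass
class GeneStatTable:
    """Per-gene moderated statistics with the fitted shrinkage hyperparameters.

    ``table`` is indexed by probe (or gene) id with columns ``mean_diff``,
    ``t``, ``p`` and ``p_adjusted``.
    """

    table: pd.DataFrame
    prior_df: float  # d0
    prior_var: float  # s0**2
    assignment: GroupAssignment | None = field(default=None, repr=False)

    def ranked_curve(self) -> pd.DataFrame:
        """Adjusted p over the gene rank ordered by ascending raw p."""
        ordered = self.table.sort_values(["p", "t"], kind="stable")
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(ordered) + 1),
                "id": ordered.index,
                "p": ordered["p"].to_numpy(),
                "p_adjusted": ordered["p_adjusted"].to_numpy(),
            }
        )

    def n_significant(self, alpha: float = 0.05) -> int:
        return int((self.table["p_adjusted"] < alpha).sum())


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, dg: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0**2) to gene-wise pooled variances.

    Moments of ``log(s2)`` under the scaled-F model determine the prior: the
    excess variance of the log variances beyond trigamma(dg/2) is
    trigamma(d0/2).  Non-positive excess means the variances are no more
    dispersed than chi-square sampling alone explains, and the prior df is
    infinite (full shrinkage).
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive gene variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    evar = z.var(ddof=1) - float(special.polygamma(1, dg / 2.0))
    if not np.isfinite(evar) or evar <= 0:
        logger.info("moment fit gave non-positive excess variance; d0 = inf")
        return np.inf, float(np.exp(e.mean()))
    d0 = float(2.0 * _trigamma_inverse(evar))
    s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    matrix: ExpressionMatrix,
    assignment: GroupAssignment,
    prior_df: float | None = None,
) -> GeneStatTable:
    """Two-group moderated t per gene with empirical-Bayes variance shrinkage.

    ``prior_df`` overrides the estimated d0 (``0`` gives the ordinary pooled
    two-sample t; ``inf`` shrinks every variance fully to s0**2).
    """
    g1, g2 = list(assignment.group1), list(assignment.group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(g1) | set(g2)) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"assignment names unknown samples: {sorted(missing)}")
    x1 = matrix.values[g1].to_numpy(dtype=float)
    x2 = matrix.values[g2].to_numpy(dtype=float)
    n1, n2 = len(g1), len(g2)
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    s2, dg = pooled_variance(x1, x2)

    if prior_df is not None and float(prior_df) == 0.0:
        # ordinary pooled t: no shrinkage, so no prior fit is needed
        d0, s0_2 = 0.0, 0.0
    else:
        d0, s0_2 = fit_variance_prior(s2, dg)
        if prior_df is not None:
            d0 = float(prior_df)
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df = np.inf
    else:
        post_var = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df = d0 + dg
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # degenerate genes: zero posterior variance
    zero = se == 0.0
    t[zero & (diff == 0.0)] = 0.0
    t[zero & (diff > 0.0)] = np.inf
    t[zero & (diff < 0.0)] = -np.inf
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"mean_diff": diff, "t": t, "p": p, "p_adjusted": bh_adjust(p)},
        index=matrix.values.index,
    )
    return GeneStatTable(table=table, prior_df=d0, prior_var=s0_2, assignment=assignment)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def disambiguate_probes(
    stats_table: GeneStatTable,
    ann: ProbeAnnotation,
    readjust: bool = True,
) -> GeneStatTable:
    """Keep, per gene symbol, only the probe with the lowest raw p-value.

    Ties are broken by the lexicographically smallest probe id.  By default
    BH is re-applied on the surviving gene-level p-values (``readjust=False``
    keeps the probe-level adjusted values instead).
    """
    tab = stats_table.table
    ann.require_probes(tab.index)
    gene = ann.gene_of().reindex(tab.index)
    work = tab.assign(_gene=gene.to_numpy(), _probe=tab.index)
    work = work.sort_values(["_gene", "p", "_probe"], kind="stable")
    best = work.drop_duplicates("_gene", keep="first")
    out = best.set_index("_gene").drop(columns=[]).rename_axis("gene_symbol")
    out = out.sort_index()
    probe_col = out.pop("_probe")
    if readjust:
        out = out.assign(p_adjusted=bh_adjust(out["p"].to_numpy()))
    out = out.assign(probe_id=probe_col)
    return GeneStatTable(
        table=out,
        prior_df=stats_table.prior_df,
        prior_var=stats_table.prior_var,
        assignment=stats_table.assignment,
    )
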