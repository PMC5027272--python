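"""Synthetic cohort and sibling-paired expression generators.

The cohort generator draws mixed two-phenotype embryo cohorts under exactly
the assumptions of :mod:`embryomix.mixture` and is the Monte-Carlo oracle for
that module.  The expression generator emulates the design of a two-condition
single-blastomere microarray study: 8 sibling pairs of control (ICSI)
blastomeres (16 arrays) plus 8 treatment (phICSI) blastomeres, ~44K probes
with a technically replicated subset, log-normal baseline intensities, a
shared within-pair latent effect, and a configurable set of truly
differentially expressed genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .denull import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "SimulatedCohort",
    "ExpressionConfig",
    "SimulatedExpressionStudy",
    "simulate_cohort",
    "simulate_cohort_counts",
    "simulate_expression",
    "write_fixtures",
]


def _validate_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated mixed cohort plus its independently assayed embryos."""

    phenotype: np.ndarray  # 1 or 2 per embryo
    developed: np.ndarray  # bool per embryo
    assayed_state: np.ndarray  # 1 or 2 per assayed embryo (length k)
    seed: int
    params: dict

    @property
    def n_term(self) -> int:
        return int(self.developed.sum())

    @property
    def n_term_phenotype2(self) -> int:
        return int((self.developed & (self.phenotype == 2)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "embryo": np.arange(len(self.phenotype)),
                "label": np.where(self.phenotype == 2, "II", "I"),
                "developed": self.developed.astype(int),
            }
        )


def simulate_cohort(
    N: int,
    rho: float,
    q1: float,
    q2: float,
    k: int = 0,
    seed: int = 0,
    state_concordance: float = 1.0,
) -> SimulatedCohort:
    """Draw one cohort of N embryos with a hidden phenotype-II fraction rho.

    Each embryo is phenotype-II with probability ``rho`` and develops to term
    at rate ``q1`` (phenotype-I) or ``q2`` (phenotype-II).  ``k`` additional
    embryos are assayed for their modification state; by default the state is
    fully concordant with the phenotype label (``state_concordance = 1``),
    matching the model's 100%-correlated-modifications assumption.
    """
    rho = _validate_prob("rho", rho)
    q1 = _validate_prob("q1", q1)
    q2 = _validate_prob("q2", q2)
    state_concordance = _validate_prob("state_concordance", state_concordance)
    if N < 1:
        raise ValueError("N must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    phenotype = np.where(rng.random(N) < rho, 2, 1)
    developed = rng.random(N) < np.where(phenotype == 2, q2, q1)
    assayed_label = np.where(rng.random(k) < rho, 2, 1)
    flip = rng.random(k) >= state_concordance
    assayed_state = np.where(flip, 3 - assayed_label, assayed_label)
    return SimulatedCohort(
        phenotype=phenotype,
        developed=developed,
        assayed_state=assayed_state,
        seed=int(seed),
        params={"N": N, "rho": rho, "q1": q1, "q2": q2, "k": k},
    )


def simulate_cohort_counts(
    N: int,
    rho: float,
    q1: float,
    q2: float,
    size: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Aggregate view of ``size`` independent cohorts (vectorized).

    Draws, per replicate, the phenotype-II count m ~ Binomial(N, rho) and the
    developed-to-term counts from each subpopulation — distributionally
    identical to aggregating per-embryo :func:`simulate_cohort` draws, which a
    property test asserts.  Columns: ``m``, ``term_from_2``, ``term_from_1``,
    ``term_total``.
    """
    rho = _validate_prob("rho", rho)
    q1 = _validate_prob("q1", q1)
    q2 = _validate_prob("q2", q2)
    if N < 1 or size < 1:
        raise ValueError("N and size must be >= 1")
    rng = np.random.default_rng(seed)
    m = rng.binomial(N, rho, size=size)
    term2 = rng.binomial(m, q2)
    term1 = rng.binomial(N - m, q1)
    return pd.DataFrame(
        {"m": m, "term_from_2": term2, "term_from_1": term1, "term_total": term1 + term2}
    )


@dataclass(frozen=True)
class ExpressionConfig:
    """Generator settings for a sibling-paired two-condition array study.

    Defaults emulate the study design this package targets: 8 control sibling
    pairs (16 arrays) plus 8 treatment arrays on a ~44K-probe platform, with
    73 truly differentially expressed genes shifted by two residual standard
    deviations.  Intensities are generated on the log2 scale: per-gene
    baseline ~ Normal(8, 1.5) (log-normal on the raw intensity scale,
    spanning ~6 log2 units across genes), plus a pair-level latent effect,
    plus Gaussian noise.  ``pair_rho`` is the within-pair correlation of the
    residual (pair effect + noise) and defaults to a small value: on real
    single-blastomere arrays technical noise dominates the shared embryo
    effect.
    """

    n_genes: int = 44000
    n_pairs: int = 8
    n_extra_group: int = 8
    n_de_genes: int = 73
    de_effect_sd_units: float = 2.0
    residual_sd: float = 0.5
    pair_rho: float = 0.04
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    replicate_fraction: float = 0.05
    replicate_copies: int = 2

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        _validate_prob("pair_rho", self.pair_rho)
        _validate_prob("replicate_fraction", self.replicate_fraction)
        if self.residual_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.replicate_copies < 2:
            raise ValueError("replicate_copies must be >= 2")


@dataclass(frozen=True)
class SimulatedExpressionStudy:
    matrix: ExpressionMatrix  # log2 intensities, probe level
    annotation: ProbeAnnotation
    de_genes: tuple[str, ...]
    effects: pd.Series = field(repr=False)  # per-DE-gene log2 shift
    config: ExpressionConfig = field(repr=False)
    seed: int = 0


def simulate_expression(
    config: ExpressionConfig | None = None, seed: int = 0
) -> SimulatedExpressionStudy:
    """Generate a sibling-paired two-condition log2 expression study.

    Sample value = gene baseline + pair effect (control siblings share it)
    + group effect (declared DE genes only, applied to the treatment group)
    + independent Gaussian noise.  A ``replicate_fraction`` of genes is
    represented by ``replicate_copies`` technical-replicate probes carrying
    independent noise.
    """
    config = config or ExpressionConfig()
    rng = np.random.default_rng(seed)
    g, p, e = config.n_genes, config.n_pairs, config.n_extra_group
    n_control = 2 * p
    n_samples = n_control + e

    pair_sd = config.residual_sd * np.sqrt(config.pair_rho)
    noise_sd = config.residual_sd * np.sqrt(1.0 - config.pair_rho)

    genes = np.array([f"gene{i:05d}" for i in range(g)])
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)

    de_idx = rng.choice(g, size=config.n_de_genes, replace=False)
    effects = np.zeros(g)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    effects[de_idx] = signs * config.de_effect_sd_units * config.residual_sd

    # latent signal per gene x sample (before technical replication / noise)
    signal = np.tile(baseline[:, None], (1, n_samples))
    pair_effects = rng.normal(0.0, pair_sd, size=(g, p))
    for j in range(p):
        signal[:, 2 * j] += pair_effects[:, j]
        signal[:, 2 * j + 1] += pair_effects[:, j]
    # treatment samples each get their own latent "pair" term (one cell each)
    signal[:, n_control:] += rng.normal(0.0, pair_sd, size=(g, e))
    signal[:, n_control:] += effects[:, None]

    # expand genes to probes (technical replicates carry independent noise)
    n_rep = int(round(config.replicate_fraction * g))
    rep_gene_idx = rng.choice(g, size=n_rep, replace=False)
    copies = np.ones(g, dtype=int)
    copies[rep_gene_idx] = config.replicate_copies
    probe_gene_idx = np.repeat(np.arange(g), copies)
    probe_ids = []
    counters: dict[int, int] = {}
    for gi in probe_gene_idx:
        c = counters.get(gi, 0)
        counters[gi] = c + 1
        probe_ids.append(f"probe{gi:05d}_{c}")
    probe_ids = np.array(probe_ids)

    values = signal[probe_gene_idx, :] + rng.normal(
        0.0, noise_sd, size=(len(probe_ids), n_samples)
    )

    sample_ids = [f"ICSI_p{j + 1}{s}" for j in range(p) for s in ("a", "b")]
    sample_ids += [f"phICSI_{j + 1}" for j in range(e)]
    pair_map = {
        sid: f"pair{j + 1}" for j in range(p) for sid in sample_ids[2 * j: 2 * j + 2]
    }
    group_labels = {
        sid: ("ICSI" if i < n_control else "phICSI")
        for i, sid in enumerate(sample_ids)
    }
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pair_map=pair_map,
        group_labels=group_labels,
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_symbol": genes[probe_gene_idx],
                # probes of one gene share a platform (replicate-group) id
                "replicate_group": [f"AGI_{gi:05d}" for gi in probe_gene_idx],
            }
        )
    )
    return SimulatedExpressionStudy(
        matrix=matrix,
        annotation=annotation,
        de_genes=tuple(sorted(genes[de_idx])),
        effects=pd.Series(effects[de_idx], index=genes[de_idx]).sort_index(),
        config=config,
        seed=int(seed),
    )


def write_fixtures(obj: SimulatedCohort | SimulatedExpressionStudy, directory: str) -> list[str]:
    """Write the TSV files consumed by the CLI; returns the paths written.

    Round-tripping an expression study through these files reproduces the
    matrix to full float precision (values are written with repr precision).
    """
    os.makedirs(directory, exist_ok=True)
    written: list[str] = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = os.path.join(directory, name)
        tmp = path + ".tmp"
        df.to_csv(tmp, sep="\t", index=index, float_format=None)
        os.replace(tmp, path)
        written.append(path)

    if isinstance(obj, SimulatedCohort):
        _write(obj.to_frame(), "cohort.tsv")
        k = len(obj.assayed_state)
        _write(
            pd.DataFrame(
                {
                    "assayed_embryo": np.arange(k),
                    "state": np.where(obj.assayed_state == 2, "II-like", "I-like"),
                }
            ),
            "assayed.tsv",
        )
    elif isinstance(obj, SimulatedExpressionStudy):
        mat = obj.matrix.values.copy()
        mat.index.name = "probe_id"
        _write(mat, "expression.tsv", index=True)
        _write(obj.annotation.table, "annotation.tsv")
        rows = [
            {
                "sample_id": sid,
                "pair_id": obj.matrix.pair_map.get(sid, ""),
                "condition": obj.matrix.group_labels.get(sid, ""),
            }
            for sid in obj.matrix.sample_ids
        ]
        _write(pd.DataFrame(rows), "samples.tsv")
        _write(
            pd.DataFrame({"gene_symbol": list(obj.de_genes)}), "truth_de_genes.tsv"
        )
    else:
        raise TypeError(f"cannot write fixtures for {type(obj).__name__}")
    return written
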