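"""Shared containers for the differential-expression null pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ProbeAnnotation", "GroupAssignment"]


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities with sibling-pair/group metadata.

    ``values`` rows are probe ids, columns are sample ids.  ``pair_map`` maps
    sample id -> sibling-pair id (each pair naming exactly two samples);
    ``group_labels`` maps sample id -> condition label.
    """

    values: pd.DataFrame
    pair_map: dict[str, str] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        unknown = set(self.pair_map) | set(self.group_labels)
        unknown -= set(self.values.columns)
        if unknown:
            raise ValueError(f"metadata names unknown samples: {sorted(unknown)}")
        counts: dict[str, int] = {}
        for pair in self.pair_map.values():
            counts[pair] = counts.get(pair, 0) + 1
        bad = [p for p, c in counts.items() if c != 2]
        if bad:
            raise ValueError(f"sibling pairs must name exactly two samples: {bad}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def pairs(self) -> dict[str, tuple[str, str]]:
        """pair id -> its two sample ids, in column order."""
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids:
            if sid in self.pair_map:
                out.setdefault(self.pair_map[sid], []).append(sid)
        return {k: (v[0], v[1]) for k, v in out.items()}

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels.get(s) == label]


@dataclass(frozen=True)
class ProbeAnnotation:
    """probe id -> gene symbol plus technical-replicate (platform id) groups."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol, replicate_group

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table misses columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("annotation has duplicated probe ids")
        if "replicate_group" not in self.table.columns:
            object.__setattr__(
                self,
                "table",
                self.table.assign(replicate_group=self.table["probe_id"]),
            )

    def require_probes(self, probe_ids) -> None:
        missing = set(probe_ids) - set(self.table["probe_id"])
        if missing:
            raise ValueError(
                f"{len(missing)} probes lack annotation, e.g. {sorted(missing)[:3]}"
            )

    def gene_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"]

    def replicate_group_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["replicate_group"]


@dataclass(frozen=True)
class GroupAssignment:
    """A disjoint two-group split of the analysed samples."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    respects_pairing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "group1", tuple(self.group1))
        object.__setattr__(self, "group2", tuple(self.group2))
        if set(self.group1) & set(self.group2):
            raise ValueError("assignment groups must be disjoint")
        if len(set(self.group1)) != len(self.group1) or len(set(self.group2)) != len(
            self.group2
        ):
            raise ValueError("duplicate sample in assignment group")

    @property
    def key(self) -> tuple[frozenset, frozenset]:
        return frozenset(self.group1), frozenset(self.group2)

    def unordered_key(self) -> frozenset:
        return frozenset((frozenset(self.group1), frozenset(self.group2)))


def pooled_variance(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-wise two-group pooled variance and its degrees of freedom."""
    n1, n2 = x1.shape[1], x2.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    dg = n1 + n2 - 2
    return ((n1 - 1) * v1 + (n2 - 1) * v2) / dg, dg
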