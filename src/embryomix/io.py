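"""TSV readers/writers and run configuration.

All tabular exchange formats are tab-separated UTF-8 with a mandatory header
row and '.' decimal separator.  Output files are written to a temporary name
and atomically renamed, so failures never leave partial results behind.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .denull import ExpressionMatrix, ProbeAnnotation
from .mixture import RateEstimate

__all__ = [
    "RunConfig",
    "read_count_table",
    "read_expression",
    "read_annotation",
    "read_sample_table",
    "read_gpr_like",
    "atomic_write_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable record of one CLI run (subcommand + resolved parameters)."""

    subcommand: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "."
    strategy: str | None = None
    log_level: str = "INFO"

    def to_yaml(self, path: str) -> None:
        _atomic_write_text(path, yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
        return cls(**raw)


def _atomic_write_text(path: str, text: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


def atomic_write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    tmp = f"{path}.tmp"
    df.to_csv(tmp, sep="\t", index=index)
    os.replace(tmp, path)


def read_count_table(path: str) -> list[tuple[str, RateEstimate]]:
    """Read a condition/developed/transferred TSV into rate estimates.

    Malformed rows are rejected with their line number.  An empty file yields
    an empty list with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"condition", "developed", "transferred"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty count table", path)
        return []
    out: list[tuple[str, RateEstimate]] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        try:
            developed = int(row["developed"])
            transferred = int(row["transferred"])
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}:{line}: non-integer count ({err})") from None
        try:
            out.append((str(row["condition"]), RateEstimate(developed, transferred)))
        except ValueError as err:
            raise ValueError(f"{path}:{line}: {err}") from None
    return out


def read_expression(
    path: str,
    samples_path: str | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column probe id, header = sample ids).

    ``samples_path`` optionally provides the sample_id/pair_id/condition map.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    pair_map: dict[str, str] = {}
    group_labels: dict[str, str] = {}
    if samples_path:
        pair_map, group_labels = read_sample_table(samples_path)
    return ExpressionMatrix(values=values, pair_map=pair_map, group_labels=group_labels)


def read_sample_table(path: str) -> tuple[dict[str, str], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "pair_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pair_map = {
        r.sample_id: r.pair_id for r in df.itertuples() if r.pair_id
    }
    group_labels = {
        r.sample_id: r.condition for r in df.itertuples() if r.condition
    }
    return pair_map, group_labels


def read_annotation(path: str) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeAnnotation(df)


def read_gpr_like(path: str, foreground: str = "F635 Median", background: str = "B635 Median") -> pd.DataFrame:
    """Minimal GenePix-results-style reader: probe id + one intensity column.

    Only the probe identifier and foreground/background intensity columns are
    consumed; the background-subtracted intensity is clipped at a small
    positive floor so downstream log transforms stay defined.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = next((c for c in ("ID", "Name", "probe_id") if c in df.columns), None)
    if id_col is None or foreground not in df.columns or background not in df.columns:
        raise ValueError(
            f"{path}: need an ID/Name column plus {foreground!r} and {background!r}"
        )
    intensity = (
        df[foreground].astype(float) - df[background].astype(float)
    ).clip(lower=0.5)
    return pd.DataFrame({"probe_id": df[id_col].astype(str), "intensity": intensity})


def frame_from_profile(rho_grid: np.ndarray, p_values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"rho": rho_grid, "P": p_values})
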