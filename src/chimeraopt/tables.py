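"""Sequence-function table schema and block-pattern statistics.

The on-disk schema is a flat CSV with one row per replicate measurement:
``block_string, strain, replicate, titer_total_mg_per_L, active`` plus
optional per-chain-length columns (``C6`` .. ``C16``).  Deposited datasets
and simulator output share this schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["load_table", "save_table", "matches_pattern", "pattern_contrast", "PatternContrast"]

REQUIRED_COLUMNS = ["block_string", "titer_total_mg_per_L"]


def load_table(path) -> pd.DataFrame:
    """Read a sequence-function CSV and validate the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def save_table(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def matches_pattern(block_string: str, pattern: str) -> bool:
    """Wildcard match of a block string against a pattern like
    ``"X-XXXBXXAB"`` (X matches any label; positions align one to one)."""
    if len(block_string) != len(pattern):
        return False
    return all(p in ("X", "x") or p == c for p, c in zip(pattern, block_string))


@dataclass
class PatternContrast:
    """Mean titers of chimeras matching a block pattern vs the rest."""

    pattern: str
    mean_match: float
    mean_rest: float
    n_match: int
    n_rest: int
    n_records: int


def pattern_contrast(table: pd.DataFrame, pattern: str) -> PatternContrast:
    """Average per-chimera mean titer for pattern-matching chimeras versus
    the complement, plus the raw record count.

    Chimera means are computed first (so replicate counts do not weight the
    contrast), matching how per-sequence averages are usually reported.
    """
    df = pd.DataFrame(table)
    means = df.groupby("block_string", sort=True)["titer_total_mg_per_L"].mean()
    mask = means.index.to_series().apply(lambda s: matches_pattern(s, pattern)).to_numpy()
    match, rest = means[mask], means[~mask]
    return PatternContrast(
        pattern=pattern,
        mean_match=float(match.mean()) if len(match) else float("nan"),
        mean_rest=float(rest.mean()) if len(rest) else float("nan"),
        n_match=int(len(match)),
        n_rest=int(len(rest)),
        n_records=int(len(df)),
    )
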