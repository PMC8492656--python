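"""SCHEMA disruption scoring and RASPP breakpoint selection.

The SCHEMA energy E of a chimera counts (with ensemble weights) the residue
contacts whose amino-acid pair does not co-occur in any single parent — a
proxy for structural disruption introduced by recombination.  The mutation
level m is the Hamming distance to the closest parent.  RASPP searches
breakpoint placements that trade the library-average disruption <E> against
library diversity <m>: a dynamic program finds the minimum-<E> partition for
each minimum-block-length constraint, and candidates are binned along <m>,
keeping the least disruptive partition per bin.

Library averages here are taken over the full block-label assignment space
(every parent offered at every block, duplicates counted with multiplicity),
which is what an actual combinatorial assembly produces;
:func:`library_averages` can instead average over the deduplicated distinct
space when asked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_space import (
    BlockPartition,
    Chimera,
    ParentSet,
    _aligned_translate,
    enumerate_space,
)
from .structure_contacts import ContactMap

__all__ = [
    "DisruptionScore",
    "RasppCandidate",
    "RasppResult",
    "schema_E",
    "schema_E_many",
    "mutation_level",
    "library_averages",
    "raspp",
]


@dataclass(frozen=True)
class DisruptionScore:
    """SCHEMA energy and mutation level of one chimera."""

    E: float
    m: int


def _pair_in_some_parent(parents: ParentSet, i: int, j: int, a: str, b: str) -> bool:
    return any(seq[i] == a and seq[j] == b for seq in parents.sequences)


def schema_E(
    chimera: Chimera,
    parents: ParentSet,
    partition: BlockPartition,
    contact_map: ContactMap,
) -> float:
    """Weighted count of contacts broken by the chimera.

    A contact (i, j) is intact iff some single parent carries the chimera's
    residue pair at both columns.
    """
    seq = _aligned_translate(chimera, parents, partition)
    L = parents.aligned_length
    total = 0.0
    for i, j, w in contact_map.contacts:
        if not (0 <= i < L and 0 <= j < L):
            raise ValueError(f"contact ({i}, {j}) outside alignment of length {L}")
        if not _pair_in_some_parent(parents, i, j, seq[i], seq[j]):
            total += w
    return total


class _BrokenTables:
    """Per segment-pair (P x P) matrices of weighted broken-contact mass.

    Segment 0 is the AHR domain, segments 1..n are the ATR blocks.  Entry
    ``M[(a, b)][pa, pb]`` is the summed weight of contacts with one column in
    segment a donated by parent pa and the other in segment b donated by
    parent pb that co-occur in no single parent.  Same-segment contacts are
    never broken and carry no entry.
    """

    def __init__(self, parents: ParentSet, partition: BlockPartition, contact_map: ContactMap):
        S = parents.char_matrix()
        P = parents.n_parents
        L = parents.aligned_length
        seg = partition.segment_of_column(L)
        self.n_segments = partition.n_blocks + 1
        self.tables: dict[tuple[int, int], np.ndarray] = {}
        for i, j, w in contact_map.contacts:
            if not (0 <= i < L and 0 <= j < L):
                raise ValueError(f"contact ({i}, {j}) outside alignment of length {L}")
            a, b = int(seg[i]), int(seg[j])
            if a == b:
                continue
            tab = self.tables.setdefault((a, b), np.zeros((P, P)))
            for pa in range(P):
                for pb in range(P):
                    if not _pair_in_some_parent(parents, i, j, S[pa, i], S[pb, j]):
                        tab[pa, pb] += w

    def energies(self, labels: np.ndarray) -> np.ndarray:
        """E for each row of an (N, n_segments) parent-index matrix."""
        out = np.zeros(labels.shape[0])
        for (a, b), tab in self.tables.items():
            out += tab[labels[:, a], labels[:, b]]
        return out


def _label_matrix(
    parents: ParentSet, partition: BlockPartition, chimeras: Sequence[Chimera]
) -> np.ndarray:
    idx = {name: p for p, name in enumerate(parents.names)}
    out = np.empty((len(chimeras), partition.n_blocks + 1), dtype=int)
    for r, c in enumerate(chimeras):
        out[r, 0] = idx[c.ahr_parent]
        for b, lab in enumerate(c.atr_blocks):
            out[r, b + 1] = idx[lab]
    return out


def schema_E_many(
    chimeras: Sequence[Chimera],
    parents: ParentSet,
    partition: BlockPartition,
    contact_map: ContactMap,
) -> np.ndarray:
    """Vectorized :func:`schema_E` over many chimeras."""
    tables = _BrokenTables(parents, partition, contact_map)
    return tables.energies(_label_matrix(parents, partition, chimeras))


def mutation_level(
    chimera: Chimera, parents: ParentSet, partition: BlockPartition
) -> int:
    """Hamming distance (aligned columns) to the closest parent."""
    seq = _aligned_translate(chimera, parents, partition)
    return min(
        sum(a != b for a, b in zip(seq, parent)) for parent in parents.sequences
    )


def _segment_mismatch_tables(parents: ParentSet, partition: BlockPartition) -> list[np.ndarray]:
    """Per segment: (P_donor, P_reference) column-mismatch counts."""
    S = parents.char_matrix()
    P = parents.n_parents
    segments = [(0, parents.domain_split)] + partition.block_segments(parents.aligned_length)
    tables = []
    for s, e in segments:
        tab = np.zeros((P, P), dtype=int)
        for pd in range(P):
            for pr in range(P):
                tab[pd, pr] = int(np.sum(S[pd, s:e] != S[pr, s:e]))
        tables.append(tab)
    return tables


def _mutation_levels(labels: np.ndarray, mismatch_tables: list[np.ndarray]) -> np.ndarray:
    P = mismatch_tables[0].shape[0]
    n = labels.shape[0]
    dist = np.zeros((n, P), dtype=int)
    for seg, tab in enumerate(mismatch_tables):
        dist += tab[labels[:, seg]]
    return dist.min(axis=1)


def _all_label_tuples(
    parents: ParentSet, n_blocks: int, ahr_parents: Sequence[str] | None
) -> np.ndarray:
    P = parents.n_parents
    ahr_idx = (
        [0] if ahr_parents is None else sorted(parents.index(a) for a in ahr_parents)
    )
    combos = np.array(list(itertools.product(ahr_idx, *([range(P)] * n_blocks))), dtype=int)
    return combos


def library_averages(
    partition: BlockPartition,
    parents: ParentSet,
    contact_map: ContactMap,
    ahr_parents: Sequence[str] | None = None,
    distinct: bool = True,
) -> tuple[float, float]:
    """Library mean SCHEMA energy and mean mutation level.

    ``distinct=True`` averages over the deduplicated enumerated space (one
    representative per distinct protein); ``distinct=False`` averages over
    all block-label assignments with multiplicity, the convention used by
    the RASPP search.
    """
    tables = _BrokenTables(parents, partition, contact_map)
    mismatch = _segment_mismatch_tables(parents, partition)
    if distinct:
        space = enumerate_space(parents, partition, ahr_parents)
        labels = _label_matrix(parents, partition, space)
    else:
        labels = _all_label_tuples(parents, partition.n_blocks, ahr_parents)
    E = tables.energies(labels)
    m = _mutation_levels(labels, mismatch)
    return float(E.mean()), float(m.mean())


@dataclass(frozen=True)
class RasppCandidate:
    breakpoints: tuple[int, ...]
    mean_E: float
    mean_m: float


@dataclass
class RasppResult:
    """Binned frontier of breakpoint placements."""

    candidates: list[RasppCandidate]
    n_blocks: int
    allowed_columns: tuple[int, ...]
    min_block_len: int
    bin_width: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("breakpoints\tmean_E\tmean_m\n")
            for c in self.candidates:
                bps = ",".join(str(b) for b in c.breakpoints)
                fh.write(f"{bps}\t{c.mean_E:.6g}\t{c.mean_m:.6g}\n")


def _mean_broken_fraction(parents: ParentSet, i: int, j: int) -> float:
    """Fraction of independent (donor_i, donor_j) parent pairs broken."""
    S = parents.char_matrix()
    P = parents.n_parents
    broken = 0
    for pa in range(P):
        for pb in range(P):
            if not _pair_in_some_parent(parents, i, j, S[pa, i], S[pb, j]):
                broken += 1
    return broken / (P * P)


def raspp(
    parents: ParentSet,
    contact_map: ContactMap,
    n_blocks: int,
    allowed_columns: Sequence[int] | None = None,
    min_block_len: int = 4,
    ahr_parents: Sequence[str] | None = None,
    bin_width: float = 1.0,
) -> RasppResult:
    """RASPP frontier search over breakpoint placements in the ATR region.

    For each minimum-block-length constraint from ``min_block_len`` up to
    the feasibility limit, a dynamic program finds the placement of
    ``n_blocks - 1`` breakpoints (drawn from ``allowed_columns``) minimizing
    the library mean SCHEMA energy.  Candidates are scored exactly, binned
    along mean mutation level (integer-width bins by default), reduced to
    the best candidate per bin, and filtered to the nondominated set.

    ``allowed_columns`` abstracts assembly constraints (e.g. Golden Gate
    compatible columns); it defaults to every ATR-internal column.
    """
    L = parents.aligned_length
    split = parents.domain_split
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if allowed_columns is None:
        allowed_columns = range(split + 1, L)
    allowed = sorted(set(int(c) for c in allowed_columns))
    if any(c <= split or c >= L for c in allowed):
        raise ValueError("allowed breakpoint columns must lie strictly inside the ATR region")
    if n_blocks == 1:
        partition = BlockPartition((), split)
        mean_E, mean_m = library_averages(
            partition, parents, contact_map, ahr_parents, distinct=False
        )
        return RasppResult(
            [RasppCandidate((), mean_E, mean_m)], 1, tuple(allowed), min_block_len, bin_width
        )
    if not allowed:
        raise ValueError("allowed_columns is empty: no feasible breakpoints")
    atr_len = L - split
    max_min_len = atr_len // n_blocks
    if min_block_len > max_min_len:
        raise ValueError(
            f"infeasible constraints: min_block_len={min_block_len} x n_blocks={n_blocks} "
            f"exceeds the ATR length {atr_len}"
        )

    # Endpoints: domain split, candidate breakpoints, alignment end.
    endpoints = [split] + allowed + [L]
    n_end = len(endpoints)
    pos = {e: k for k, e in enumerate(endpoints)}

    # mass[u, v]: summed w * mean-broken-fraction of ATR contacts entirely
    # inside [endpoints[u], endpoints[v]) — the disruption "saved" by keeping
    # those columns in one block.
    seed_mass = np.zeros((n_end, n_end))
    cross_terms = 0.0  # contacts never inside a single block (AHR-involved)
    S_cols = parents.aligned_length
    for i, j, w in contact_map.contacts:
        if not (0 <= i < S_cols and 0 <= j < S_cols):
            raise ValueError(f"contact ({i}, {j}) outside alignment")
        frac = _mean_broken_fraction(parents, i, j)
        if frac == 0.0:
            continue
        if i < split or j < split:
            # AHR is a single non-recombined segment; an AHR-ATR contact's
            # broken mass does not depend on the partition (computed exactly
            # by library_averages for the reported stats).
            continue
        a = int(np.searchsorted(endpoints, i, side="right") - 1)
        b = int(np.searchsorted(endpoints, j, side="right"))
        if b >= n_end:
            b = n_end - 1
        # inside [u, v) iff u <= a and v >= b
        seed_mass[a, b] += w * frac
    # Accumulate: mass[u, v] = sum_{a >= u, b <= v} seed_mass[a, b]
    mass = np.cumsum(seed_mass[::-1, :], axis=0)[::-1, :]
    mass = np.cumsum(mass, axis=1)

    candidates: dict[tuple[int, ...], RasppCandidate] = {}
    for lmin in range(min_block_len, max_min_len + 1):
        best = _raspp_dp(endpoints, mass, n_blocks, lmin)
        if best is None:
            continue
        bps = best
        if bps not in candidates:
            partition = BlockPartition(bps, split)
            mean_E, mean_m = library_averages(
                partition, parents, contact_map, ahr_parents, distinct=False
            )
            candidates[bps] = RasppCandidate(bps, mean_E, mean_m)

    if not candidates:
        raise ValueError("no feasible partition under the given constraints")

    # Bin along mean_m, keep min mean_E per bin (ties: lexicographic bps).
    bins: dict[int, RasppCandidate] = {}
    for cand in candidates.values():
        key = int(np.floor(cand.mean_m / bin_width))
        cur = bins.get(key)
        if (
            cur is None
            or cand.mean_E < cur.mean_E - 1e-12
            or (abs(cand.mean_E - cur.mean_E) <= 1e-12 and cand.breakpoints < cur.breakpoints)
        ):
            bins[key] = cand
    frontier = sorted(bins.values(), key=lambda c: (c.mean_m, c.mean_E, c.breakpoints))
    # Nondominated filter: drop candidates with both higher E and lower m.
    kept: list[RasppCandidate] = []
    for cand in frontier:
        dominated = any(
            other.mean_E <= cand.mean_E + 1e-12 and other.mean_m >= cand.mean_m - 1e-12
            and (other.mean_E < cand.mean_E - 1e-12 or other.mean_m > cand.mean_m + 1e-12)
            for other in frontier
            if other is not cand
        )
        if not dominated:
            kept.append(cand)
    return RasppResult(kept, n_blocks, tuple(allowed), min_block_len, bin_width)


def _raspp_dp(
    endpoints: list[int], mass: np.ndarray, n_blocks: int, min_block_len: int
) -> tuple[int, ...] | None:
    """Max within-block mass placement of n_blocks-1 breakpoints.

    Returns the lexicographically smallest optimal breakpoint tuple, or
    None when infeasible.  Minimizing library <E> is equivalent to
    maximizing the retained within-block contact mass.
    """
    n_end = len(endpoints)
    last = n_end - 1
    NEG = -np.inf
    # best[k][v]: (value, breakpoints tuple) using k blocks covering
    # [endpoints[0], endpoints[v])
    best: list[list] = [[None] * n_end for _ in range(n_blocks + 1)]
    best[0][0] = (0.0, ())
    for k in range(1, n_blocks + 1):
        for v in range(1, n_end):
            if k == n_blocks and v != last:
                continue
            top = None
            for u in range(v):
                prev = best[k - 1][u]
                if prev is None:
                    continue
                if endpoints[v] - endpoints[u] < min_block_len:
                    continue
                val = prev[0] + mass[u, v]
                bps = prev[1] + ((endpoints[v],) if v != last else ())
                if top is None or val > top[0] + 1e-15 or (
                    abs(val - top[0]) <= 1e-15 and bps < top[1]
                ):
                    top = (val, bps)
            best[k][v] = top
    final = best[n_blocks][last]
    return None if final is None else final[1]
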