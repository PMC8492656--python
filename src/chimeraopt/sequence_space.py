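"""Parents, blocks, chimeras, and the one-hot encodings consumed by the models.

A recombination library is defined by a set of aligned parent proteins, a
domain split separating the non-recombined N-terminal (AHR) domain from the
recombined C-terminal (ATR) domain, and a set of breakpoints partitioning the
ATR region into contiguous sequence blocks.  A chimera is written as a block
string such as ``"A-ATBBAAAB"``: the letter before the dash names the parent
donating the AHR domain, and the remaining letters name, block by block, the
parent each ATR block is inherited from.

Two one-hot encodings are provided for the kernel models: the *hamming*
scheme indicates the amino-acid option present at each variable alignment
column, and the *structure* scheme indicates the residue-pair combination
present at each contacting column pair.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParentSet",
    "BlockPartition",
    "Chimera",
    "Encoding",
    "ChimeraEncoder",
    "parse_chimera",
    "format_chimera",
    "canonicalize",
    "parental_chimeras",
    "translate",
    "enumerate_space",
    "encode",
    "block_distance",
]


class ChimeraFormatError(ValueError):
    """Raised when a block string or its labels are malformed."""


@dataclass(frozen=True)
class ParentSet:
    """Aligned parent sequences with single-letter labels.

    Parameters
    ----------
    names : ordered single-character parent labels, e.g. ``("A", "B", "T")``.
    sequences : aligned amino-acid strings, one per parent, equal length.
        Gap characters (``-``) are permitted if present in the alignment.
    domain_split : 0-based alignment column at which the recombined ATR
        domain begins; the AHR domain occupies columns ``[0, domain_split)``.
    """

    names: tuple[str, ...]
    sequences: tuple[str, ...]
    domain_split: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "sequences", tuple(str(s).upper() for s in self.sequences))
        if len(self.names) < 2:
            raise ValueError("a ParentSet needs at least two parents")
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences must pair up")
        if any(len(n) != 1 for n in self.names):
            raise ValueError("parent labels must be single characters")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parent labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if not 0 < self.domain_split < self.aligned_length:
            raise ValueError("domain_split must lie strictly inside the alignment")

    @property
    def aligned_length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_parents(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise ChimeraFormatError(f"unknown parent label {label!r}") from None

    def char_matrix(self) -> np.ndarray:
        """Parents-by-columns character matrix (dtype '<U1')."""
        return np.array([list(s) for s in self.sequences])

    @classmethod
    def from_fasta(cls, path, domain_split: int, names: Sequence[str] | None = None) -> "ParentSet":
        """Read an aligned FASTA file (>=2 records of equal length).

        Record labels default to the first character of each FASTA id.
        """
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) < 2:
            raise ValueError(f"{path}: need >=2 aligned records, found {len(records)}")
        if names is None:
            names = [rec.id[0] for rec in records]
        return cls(tuple(names), tuple(str(rec.seq) for rec in records), domain_split)


@dataclass(frozen=True)
class BlockPartition:
    """Breakpoints partitioning the ATR region into contiguous blocks.

    Coordinates are 0-based alignment columns, intervals half-open.  With
    breakpoints ``(b1, .., bk)`` the blocks are ``[split, b1), [b1, b2), ..,
    [bk, L)``.  Block indices are 0-based internally; user-facing output adds
    one so that "block 6" means the sixth block.
    """

    breakpoints: tuple[int, ...]
    domain_split: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints", tuple(int(b) for b in self.breakpoints))
        bps = self.breakpoints
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if bps and bps[0] <= self.domain_split:
            raise ValueError("breakpoints must lie strictly after the domain split")

    @property
    def n_blocks(self) -> int:
        return len(self.breakpoints) + 1

    def block_segments(self, aligned_length: int) -> list[tuple[int, int]]:
        """Half-open column intervals of the ATR blocks."""
        if self.breakpoints and self.breakpoints[-1] >= aligned_length:
            raise ValueError("breakpoints fall outside the alignment")
        edges = [self.domain_split, *self.breakpoints, aligned_length]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def segment_of_column(self, aligned_length: int) -> np.ndarray:
        """Per-column segment index: 0 = AHR, 1..n_blocks = ATR blocks."""
        seg = np.zeros(aligned_length, dtype=int)
        for b, (s, e) in enumerate(self.block_segments(aligned_length), start=1):
            seg[s:e] = b
        return seg

    def to_json(self) -> str:
        return json.dumps({"breakpoints": list(self.breakpoints), "domain_split": self.domain_split})

    @classmethod
    def from_json(cls, text: str) -> "BlockPartition":
        d = json.loads(text)
        return cls(tuple(d["breakpoints"]), int(d["domain_split"]))


@dataclass(frozen=True, order=True)
class Chimera:
    """One library member: an AHR parent label plus per-block ATR labels."""

    ahr_parent: str
    atr_blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atr_blocks", tuple(self.atr_blocks))

    def __str__(self) -> str:
        return f"{self.ahr_parent}-{''.join(self.atr_blocks)}"

    def with_block(self, block: int, label: str) -> "Chimera":
        blocks = list(self.atr_blocks)
        blocks[block] = label
        return replace(self, atr_blocks=tuple(blocks))


def format_chimera(chimera: Chimera) -> str:
    return str(chimera)


def parse_chimera(
    text: str,
    parents: ParentSet | None = None,
    n_blocks: int | None = None,
) -> Chimera:
    """Parse a block string like ``"A-ATBBAAAB"``.

    When ``parents`` is given every label is checked against the parent
    alphabet; when ``n_blocks`` is given the block count is enforced.  The
    error names the first offending character.
    """
    text = str(text).strip()
    if text.count("-") != 1:
        raise ChimeraFormatError(f"{text!r}: expected '<ahr>-<blocks>' with a single dash")
    ahr, blocks = text.split("-")
    if len(ahr) != 1 or not blocks:
        raise ChimeraFormatError(f"{text!r}: expected a single AHR label before the dash")
    if parents is not None:
        alphabet = set(parents.names)
        for ch in ahr + blocks:
            if ch not in alphabet:
                raise ChimeraFormatError(f"{text!r}: unknown parent label {ch!r}")
    if n_blocks is not None and len(blocks) != n_blocks:
        raise ChimeraFormatError(f"{text!r}: expected {n_blocks} block labels, found {len(blocks)}")
    return Chimera(ahr, tuple(blocks))


def _block_option_groups(
    parents: ParentSet, partition: BlockPartition
) -> list[dict[str, str]]:
    """Per block: map parent label -> canonical label of its block sequence.

    Parents donating identical block subsequences collapse onto the
    lexicographically smallest label among them.
    """
    segments = partition.block_segments(parents.aligned_length)
    groups: list[dict[str, str]] = []
    for s, e in segments:
        by_seq: dict[str, str] = {}
        mapping: dict[str, str] = {}
        for name, seq in zip(parents.names, parents.sequences):
            sub = seq[s:e]
            if sub not in by_seq or name < by_seq[sub]:
                by_seq[sub] = min(by_seq.get(sub, name), name)
        for name, seq in zip(parents.names, parents.sequences):
            mapping[name] = by_seq[seq[s:e]]
        groups.append(mapping)
    return groups


def canonicalize(chimera: Chimera, parents: ParentSet, partition: BlockPartition) -> Chimera:
    """Replace each block label by the smallest label donating the same sequence."""
    groups = _block_option_groups(parents, partition)
    if len(chimera.atr_blocks) != partition.n_blocks:
        raise ChimeraFormatError(
            f"{chimera}: has {len(chimera.atr_blocks)} blocks, partition defines {partition.n_blocks}"
        )
    blocks = tuple(groups[b][label] for b, label in enumerate(chimera.atr_blocks))
    return Chimera(chimera.ahr_parent, blocks)


def parental_chimeras(
    parents: ParentSet,
    partition: BlockPartition,
    ahr_parent: str | None = None,
) -> list[Chimera]:
    """The canonical all-one-parent chimeras (AHR label fixed, by default to
    the first parent, mirroring the fixed-AHR library design)."""
    ahr = parents.names[0] if ahr_parent is None else ahr_parent
    return [
        canonicalize(Chimera(ahr, (name,) * partition.n_blocks), parents, partition)
        for name in parents.names
    ]


def _aligned_translate(chimera: Chimera, parents: ParentSet, partition: BlockPartition) -> str:
    if len(chimera.atr_blocks) != partition.n_blocks:
        raise ValueError(
            f"chimera has {len(chimera.atr_blocks)} blocks but partition defines {partition.n_blocks}"
        )
    if partition.domain_split != parents.domain_split:
        raise ValueError("partition and parents disagree on the domain split")
    segments = partition.block_segments(parents.aligned_length)
    ahr_seq = parents.sequences[parents.index(chimera.ahr_parent)]
    out = [ahr_seq[: parents.domain_split]]
    for (s, e), label in zip(segments, chimera.atr_blocks):
        out.append(parents.sequences[parents.index(label)][s:e])
    return "".join(out)


def translate(
    chimera: Chimera,
    parents: ParentSet,
    partition: BlockPartition,
    keep_gaps: bool = False,
) -> str:
    """Amino-acid sequence of a chimera under block inheritance.

    Gaps inherited from the donating parent's block are removed unless
    ``keep_gaps`` is set (the gapped form preserves alignment coordinates).
    """
    aligned = _aligned_translate(chimera, parents, partition)
    return aligned if keep_gaps else aligned.replace("-", "")


def enumerate_space(
    parents: ParentSet,
    partition: BlockPartition,
    ahr_parents: Sequence[str] | None = None,
) -> list[Chimera]:
    """All distinct chimeric proteins, one canonical representative each.

    Blocks that are identical between parents are collapsed, so the count is
    the product over blocks of the number of distinct parental block
    sequences, times the number of AHR options offered (default: only the
    first parent's AHR, as in a fixed-AHR library).
    """
    if ahr_parents is None:
        ahr_parents = (parents.names[0],)
    for a in ahr_parents:
        parents.index(a)
    groups = _block_option_groups(parents, partition)
    options = [sorted(set(g.values())) for g in groups]
    space = [
        Chimera(ahr, combo)
        for ahr in sorted(ahr_parents)
        for combo in itertools.product(*options)
    ]
    return space


@dataclass(frozen=True)
class Encoding:
    """A one-hot feature vector plus the meaning of each feature."""

    vector: np.ndarray
    scheme: str
    feature_index: tuple


class ChimeraEncoder:
    """Vectorized one-hot encoder over a chimera space.

    Schemes
    -------
    hamming : one indicator per distinct parental residue option at each
        alignment column (columns conserved across all parents are dropped
        by default; ``keep_conserved`` retains them as always-1 features).
    structure : one indicator per distinct parental residue-pair combination
        at each contacting column pair; requires a contact map.  Pair
        combinations created by recombination but absent from every parent
        encode as all-zero for that contact.
    block : one indicator per distinct parental block sequence at each
        segment (coarse block-level alternative).
    """

    def __init__(
        self,
        parents: ParentSet,
        partition: BlockPartition,
        scheme: str = "hamming",
        contact_map=None,
        keep_conserved: bool = False,
    ) -> None:
        if scheme not in ("hamming", "structure", "block"):
            raise ValueError(f"unknown encoding scheme {scheme!r}")
        if scheme == "structure" and contact_map is None:
            raise ValueError("the structure scheme requires a contact map")
        self.parents = parents
        self.partition = partition
        self.scheme = scheme
        self.contact_map = contact_map
        self.keep_conserved = keep_conserved

        S = parents.char_matrix()
        L = parents.aligned_length
        P = parents.n_parents
        self._seg_of_col = partition.segment_of_column(L)
        self._n_segments = partition.n_blocks + 1

        feature_index: list = []
        if scheme in ("hamming", "block"):
            # Per-segment lookup tables: T[seg][parent] -> feature chunk.
            chunks: list[np.ndarray] = [
                np.zeros((P, 0)) for _ in range(self._n_segments)
            ]
            if scheme == "hamming":
                for col in range(L):
                    opts = sorted(set(S[:, col]))
                    if len(opts) == 1 and not keep_conserved:
                        continue
                    seg = self._seg_of_col[col]
                    block = np.zeros((P, len(opts)))
                    for p in range(P):
                        block[p, opts.index(S[p, col])] = 1.0
                    chunks[seg] = np.hstack([chunks[seg], block])
                    feature_index.extend((col, o) for o in opts)
            else:
                segments = [(0, parents.domain_split)] + partition.block_segments(L)
                for seg, (s, e) in enumerate(segments):
                    subs = [seq[s:e] for seq in parents.sequences]
                    opts = sorted(set(subs))
                    if len(opts) == 1 and not keep_conserved:
                        continue
                    block = np.zeros((P, len(opts)))
                    for p, sub in enumerate(subs):
                        block[p, opts.index(sub)] = 1.0
                    chunks[seg] = np.hstack([chunks[seg], block])
                    feature_index.extend((seg, o) for o in opts)
            self._tables = chunks
        else:
            # Per-contact tables indexed by the (parent at i, parent at j) pair.
            tables: list[tuple[int, int, np.ndarray]] = []
            for i, j, _w in contact_map.contacts:
                pairs = sorted({(S[p, i], S[p, j]) for p in range(P)})
                if len(pairs) == 1 and not keep_conserved:
                    continue
                tab = np.zeros((P, P, len(pairs)))
                for pi in range(P):
                    for pj in range(P):
                        pair = (S[pi, i], S[pj, j])
                        if pair in pairs:
                            tab[pi, pj, pairs.index(pair)] = 1.0
                tables.append((int(self._seg_of_col[i]), int(self._seg_of_col[j]), tab))
                feature_index.extend((i, j, a, b) for a, b in pairs)
            self._pair_tables = tables

        self.feature_index_ = tuple(feature_index)
        self.n_features_ = len(feature_index)

    def label_matrix(self, chimeras: Sequence[Chimera]) -> np.ndarray:
        """(N, n_blocks+1) matrix of parent indices; column 0 is the AHR."""
        idx = {name: p for p, name in enumerate(self.parents.names)}
        out = np.empty((len(chimeras), self._n_segments), dtype=int)
        for r, c in enumerate(chimeras):
            if len(c.atr_blocks) != self.partition.n_blocks:
                raise ValueError(f"{c}: block count mismatch")
            try:
                out[r, 0] = idx[c.ahr_parent]
                for b, lab in enumerate(c.atr_blocks):
                    out[r, b + 1] = idx[lab]
            except KeyError as err:
                raise ChimeraFormatError(f"{c}: unknown parent label {err.args[0]!r}") from None
        return out

    def encode_many(self, chimeras: Sequence[Chimera]) -> np.ndarray:
        labels = self.label_matrix(chimeras)
        if self.scheme in ("hamming", "block"):
            parts = [
                tab[labels[:, seg]]
                for seg, tab in enumerate(self._tables)
                if tab.shape[1]
            ]
            if not parts:
                return np.zeros((len(chimeras), 0))
            return np.hstack(parts)
        parts = [tab[labels[:, si], labels[:, sj]] for si, sj, tab in self._pair_tables]
        if not parts:
            return np.zeros((len(chimeras), 0))
        return np.hstack(parts)

    def encode(self, chimera: Chimera) -> np.ndarray:
        return self.encode_many([chimera])[0]


def encode(
    chimera: Chimera,
    scheme: str,
    parents: ParentSet,
    partition: BlockPartition,
    contact_map=None,
    keep_conserved: bool = False,
) -> Encoding:
    """One-shot encoding of a single chimera (see :class:`ChimeraEncoder`)."""
    enc = ChimeraEncoder(parents, partition, scheme, contact_map, keep_conserved)
    return Encoding(enc.encode(chimera), scheme, enc.feature_index_)


def block_distance(
    chimera: Chimera,
    parents: ParentSet,
    partition: BlockPartition | None = None,
) -> int:
    """Minimum over parents of the number of ATR blocks not inherited from
    that parent.

    With a partition the comparison is sequence-aware: a block whose donated
    subsequence matches the reference parent's counts as inherited even if
    its label differs.
    """
    if partition is not None:
        groups = _block_option_groups(parents, partition)
        best = len(chimera.atr_blocks)
        for name in parents.names:
            d = sum(
                groups[b][lab] != groups[b][name]
                for b, lab in enumerate(chimera.atr_blocks)
            )
            best = min(best, d)
        return best
    return min(
        sum(lab != name for lab in chimera.atr_blocks) for name in parents.names
    )
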