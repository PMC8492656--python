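"""Ensemble-weighted residue contact maps and interface-charge statistics.

Contact maps are derived from an ensemble of structural models of one parent
domain: two residues are in contact when any pair of their heavy atoms lies
within a distance cutoff (4.5 angstrom by default), and each contact is
weighted by the fraction of models in which it appears.  Sequence-adjacent
pairs carry no recombination signal and are excluded by default.

The interface utilities select enzyme residues near a docked partner chain
(an acyl carrier protein in the motivating application) and score chimeras
by their net interface charge, i.e. positives (K, R) minus negatives (D, E).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .sequence_space import BlockPartition, ParentSet, parse_chimera, translate

__all__ = [
    "ContactMap",
    "InterfaceSet",
    "compute_contact_map",
    "select_interface",
    "net_interface_charge",
    "charge_titer_correlation",
    "ChargeTiterResult",
    "load_structure_models",
    "ungapped_to_alignment_columns",
]

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass(frozen=True)
class ContactMap:
    """Weighted residue-residue contacts in alignment-column coordinates.

    ``contacts`` holds ``(i, j, weight)`` with ``i < j`` and weight equal to
    the fraction of ensemble models containing the contact.
    """

    contacts: tuple[tuple[int, int, float], ...]
    cutoff_angstrom: float
    n_models: int

    def __post_init__(self) -> None:
        seen = set()
        cleaned = []
        for i, j, w in self.contacts:
            i, j, w = int(i), int(j), float(w)
            if i >= j:
                raise ValueError(f"contact ({i}, {j}) must have i < j")
            if not 0.0 < w <= 1.0:
                raise ValueError(f"contact ({i}, {j}) weight {w} outside (0, 1]")
            if (i, j) in seen:
                raise ValueError(f"duplicate contact ({i}, {j})")
            seen.add((i, j))
            cleaned.append((i, j, w))
        object.__setattr__(self, "contacts", tuple(sorted(cleaned)))

    def __len__(self) -> int:
        return len(self.contacts)

    def weights(self) -> dict[tuple[int, int], float]:
        return {(i, j): w for i, j, w in self.contacts}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tweight\n")
            for i, j, w in self.contacts:
                fh.write(f"{i}\t{j}\t{w:.6g}\n")

    @classmethod
    def from_tsv(cls, path, cutoff_angstrom: float = 4.5, n_models: int = 1) -> "ContactMap":
        contacts = []
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("i"):
                fh.seek(0)
            for line in fh:
                if line.strip():
                    i, j, w = line.split("\t")
                    contacts.append((int(i), int(j), float(w)))
        return cls(tuple(contacts), cutoff_angstrom, n_models)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff_angstrom": self.cutoff_angstrom,
                "n_models": self.n_models,
                "contacts": [list(c) for c in self.contacts],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ContactMap":
        d = json.loads(text)
        return cls(tuple(tuple(c) for c in d["contacts"]), d["cutoff_angstrom"], d["n_models"])


@dataclass(frozen=True)
class InterfaceSet:
    """Enzyme alignment columns within a radius of a docked partner chain."""

    positions: frozenset[int]
    radius_angstrom: float
    partner_chain: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", frozenset(int(p) for p in self.positions))
        if self.radius_angstrom <= 0:
            raise ValueError("radius must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "positions": sorted(self.positions),
                "radius_angstrom": self.radius_angstrom,
                "partner_chain": self.partner_chain,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "InterfaceSet":
        d = json.loads(text)
        return cls(frozenset(d["positions"]), d["radius_angstrom"], d["partner_chain"])


def ungapped_to_alignment_columns(aligned_sequence: str) -> list[int]:
    """Map ungapped residue order (0-based) to alignment columns for the
    parent whose structure was modeled."""
    return [col for col, ch in enumerate(aligned_sequence) if ch != "-"]


def _residue_atom_coords(model) -> list[np.ndarray]:
    """Per-residue heavy-atom coordinate arrays, in residue order.

    Accepts a biotite ``AtomArray`` or a pre-split list of (n_atoms, 3)
    arrays (one entry per residue).  Hydrogens are ignored; altloc handling
    is done at load time (first conformer).
    """
    if isinstance(model, (list, tuple)):
        return [np.asarray(r, dtype=float).reshape(-1, 3) for r in model]
    import biotite.structure as struc

    atoms = model
    mask = np.ones(atoms.array_length(), dtype=bool)
    element = atoms.element
    mask &= np.asarray([e.upper() != "H" for e in element])
    atoms = atoms[mask]
    out = []
    for start, stop in zip(*_residue_bounds(atoms)):
        out.append(np.asarray(atoms.coord[start:stop], dtype=float))
    return out


def _residue_bounds(atoms):
    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms)
    stops = np.append(starts[1:], atoms.array_length())
    return starts, stops


def _contacting_pairs(
    residues: list[np.ndarray], cutoff: float, min_separation: int
) -> set[tuple[int, int]]:
    """Residue index pairs with any-atom distance <= cutoff."""
    coords = np.vstack(residues)
    owner = np.repeat(np.arange(len(residues)), [len(r) for r in residues])
    tree = cKDTree(coords)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        ra, rb = int(owner[a]), int(owner[b])
        if ra == rb:
            continue
        i, j = min(ra, rb), max(ra, rb)
        if j - i >= min_separation:
            pairs.add((i, j))
    return pairs


def compute_contact_map(
    models: Sequence,
    cutoff: float = 4.5,
    min_separation: int = 2,
    column_map: Sequence[int] | None = None,
) -> ContactMap:
    """Ensemble-weighted contact map.

    Parameters
    ----------
    models : structural models sharing residue numbering — biotite
        ``AtomArray`` objects or lists of per-residue coordinate arrays.
    cutoff : any-atom distance threshold in angstrom.
    min_separation : pairs with ``|i - j| < min_separation`` are dropped
        (sequence-adjacent contacts are always intact under recombination).
    column_map : optional map from residue order index to alignment column
        (see :func:`ungapped_to_alignment_columns`); identity when omitted.
    """
    if len(models) == 0:
        raise ValueError("empty structure ensemble")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per_model = [_residue_atom_coords(m) for m in models]
    n_res = {len(r) for r in per_model}
    if len(n_res) != 1:
        raise ValueError(f"models disagree on residue count: {sorted(n_res)}")
    n_residues = n_res.pop()
    if column_map is not None:
        column_map = list(column_map)
        if len(column_map) != n_residues:
            raise ValueError(
                f"column_map covers {len(column_map)} residues, models have {n_residues}"
            )
    counts: dict[tuple[int, int], int] = {}
    for residues in per_model:
        for pair in _contacting_pairs(residues, cutoff, min_separation):
            counts[pair] = counts.get(pair, 0) + 1
    n = len(per_model)
    contacts = []
    for (i, j), k in counts.items():
        if column_map is not None:
            i, j = column_map[i], column_map[j]
            i, j = min(i, j), max(i, j)
        contacts.append((i, j, k / n))
    return ContactMap(tuple(contacts), cutoff, n)


def load_structure_models(paths: Iterable) -> list:
    """Load PDB files as biotite AtomArrays (first altloc, first model each;
    a single multi-model file yields one AtomArray per model)."""
    import biotite.structure.io.pdb as pdb

    import biotite.structure as struc

    models = []
    for path in paths:
        pfile = pdb.PDBFile.read(str(path))
        stack = pfile.get_structure(altloc="first")
        if isinstance(stack, struc.AtomArrayStack):
            models.extend(stack[m] for m in range(stack.stack_depth()))
        else:
            models.append(stack)
    return models


def select_interface(
    complex_structure,
    partner_chain: str,
    radius: float = 10.0,
    enzyme_chain: str | None = None,
    column_map: Sequence[int] | None = None,
) -> InterfaceSet:
    """Enzyme residues with any atom within ``radius`` of any partner atom.

    ``complex_structure`` is a biotite AtomArray of the docked complex, or a
    tuple ``(enzyme_residue_coords, partner_coords)`` for toy inputs.
    """
    if isinstance(complex_structure, tuple) and len(complex_structure) == 2:
        enzyme_residues = [
            np.asarray(r, dtype=float).reshape(-1, 3) for r in complex_structure[0]
        ]
        partner_coords = np.asarray(complex_structure[1], dtype=float).reshape(-1, 3)
    else:
        atoms = complex_structure
        chains = set(atoms.chain_id)
        if partner_chain not in chains:
            raise ValueError(f"chain {partner_chain!r} not in structure (has {sorted(chains)})")
        heavy = np.asarray([e.upper() != "H" for e in atoms.element])
        partner_mask = (atoms.chain_id == partner_chain) & heavy
        if enzyme_chain is None:
            enzyme_mask = (atoms.chain_id != partner_chain) & heavy
        else:
            if enzyme_chain not in chains:
                raise ValueError(f"chain {enzyme_chain!r} not in structure")
            enzyme_mask = (atoms.chain_id == enzyme_chain) & heavy
        partner_coords = np.asarray(atoms.coord[partner_mask], dtype=float)
        enzyme_residues = _residue_atom_coords(atoms[enzyme_mask])
    tree = cKDTree(partner_coords)
    positions = set()
    for idx, res in enumerate(enzyme_residues):
        d, _ = tree.query(res, k=1)
        if np.min(d) <= radius:
            positions.add(column_map[idx] if column_map is not None else idx)
    return InterfaceSet(frozenset(positions), radius, partner_chain)


def net_interface_charge(
    sequence: str,
    interface: InterfaceSet | Iterable[int],
    count_histidine: bool = False,
) -> int:
    """Positives minus negatives at interface positions.

    ``sequence`` is indexed by the interface's coordinate system (alignment
    columns when the interface was mapped; pass the gapped chimera sequence
    in that case).  Histidine is neutral unless ``count_histidine``.
    """
    positions = interface.positions if isinstance(interface, InterfaceSet) else set(interface)
    positive = set(POSITIVE_RESIDUES) | ({"H"} if count_histidine else set())
    charge = 0
    for p in positions:
        if not 0 <= p < len(sequence):
            raise IndexError(f"interface position {p} outside sequence of length {len(sequence)}")
        ch = sequence[p]
        if ch in positive:
            charge += 1
        elif ch in NEGATIVE_RESIDUES:
            charge -= 1
    return charge


@dataclass
class ChargeTiterResult:
    """Pearson correlation between interface charge and mean titer."""

    r: float
    pvalue: float
    per_chimera: "object"  # pandas DataFrame: block_string, charge, mean_titer

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def charge_titer_correlation(
    table,
    interface: InterfaceSet,
    parents: ParentSet,
    partition: BlockPartition,
    count_histidine: bool = False,
) -> ChargeTiterResult:
    """Correlate net interface charge with mean total titer across chimeras.

    ``table`` is a sequence-function table (replicate level or aggregated)
    with columns ``block_string`` and ``titer_total_mg_per_L``.
    """
    import pandas as pd
    from scipy import stats

    df = pd.DataFrame(table)
    if "titer_total_mg_per_L" not in df.columns or "block_string" not in df.columns:
        raise ValueError("table needs block_string and titer_total_mg_per_L columns")
    means = df.groupby("block_string", sort=True)["titer_total_mg_per_L"].mean()
    if len(means) < 3:
        raise ValueError("need titers for at least 3 chimeras")
    charges = []
    for bs in means.index:
        chim = parse_chimera(bs, parents, partition.n_blocks)
        seq = translate(chim, parents, partition, keep_gaps=True)
        charges.append(net_interface_charge(seq, interface, count_histidine))
    out = pd.DataFrame(
        {"block_string": means.index, "charge": charges, "mean_titer": means.values}
    )
    if np.std(charges) == 0 or np.std(means.values) == 0:
        warnings.warn("zero variance in charges or titers; correlation undefined")
        return ChargeTiterResult(float("nan"), float("nan"), out)
    r, p = stats.pearsonr(out["charge"], out["mean_titer"])
    return ChargeTiterResult(float(r), float(p), out)
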