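"""Synthetic fitness landscapes, assay emulation, and titer-table utilities.

This module stands in for the wet-lab loop: it defines block-additive (plus
pairwise-epistatic) fatty-alcohol titer landscapes over a chimera space, an
inactivation mechanism tied to structural disruption (logistic in the SCHEMA
energy E, a hard E threshold, or a block-distance cap), and replicate-level
measurement noise with a chain-length product split.  It also implements the
internal-standard quantitation arithmetic used to convert GC peak areas to
concentrations, and the replicate aggregation that forms sequence-function
tables.

Everything generated here is synthetic: the landscape emulates the
*statistical structure* of in vivo chimera titer data (a handful of strongly
beneficial blocks, a majority-inactive space, ~20% replicate spread, a
C16-dominant product distribution), not any measured enzyme.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema_raspp import schema_E, schema_E_many
from .sequence_space import (
    BlockPartition,
    Chimera,
    ParentSet,
    block_distance,
    canonicalize,
    enumerate_space,
    translate,
)
from .structure_contacts import ContactMap, InterfaceSet, net_interface_charge

__all__ = [
    "LandscapeSpec",
    "AssayRecord",
    "SimulatedAssay",
    "true_titer",
    "measure",
    "aggregate",
    "quantitate_internal_standard",
    "QuantitationResult",
    "synthetic_parents",
    "synthetic_contact_map",
    "random_landscape",
    "demo_system",
    "DemoSystem",
]

TABLE_COLUMNS = ["block_string", "strain", "replicate", "titer_total_mg_per_L", "active"]


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic block-additive titer landscape.

    Titer (mg/L) of a chimera is ``base + AHR effect + sum of block effects
    + sum of epistasis terms (+ charge_coef * net interface charge)``,
    clipped at zero, and multiplied by zero when the inactivation rule
    fires.  Effects are keyed by canonical block labels so that parents
    donating identical block sequences share effects.

    ``inactivation`` is one of
      {"rule": "logistic_E", "midpoint": e0, "scale": s}  — a chimera is
          inactive with probability sigmoid((E - e0)/s), decided once per
          chimera by a deterministic draw derived from ``seed``;
      {"rule": "threshold_E", "e0": e0}                    — inactive iff E > e0;
      {"rule": "block_distance", "max": d}                 — inactive iff the
          block distance to the nearest parent exceeds d;
      None                                                 — always active.
    """

    parents: ParentSet
    partition: BlockPartition
    contact_map: ContactMap
    base: float = 10.0
    block_effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    ahr_effects: Mapping[str, float] = field(default_factory=dict)
    epistasis: Mapping[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    inactivation: Mapping | None = None
    noise_sd: float = 2.0
    noise_rel: float = 0.2
    chain_weights: Mapping[str, float] = field(
        default_factory=lambda: {"C16": 0.7, "C14": 0.25, "C12": 0.05}
    )
    activity_threshold: float = 1.0
    seed: int = 0
    charge_coef: float = 0.0
    interface: InterfaceSet | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_rel < 0:
            raise ValueError("noise parameters must be nonnegative")
        total = sum(self.chain_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"chain-length mixture weights sum to {total}, expected 1")

    def space(self) -> list[Chimera]:
        return enumerate_space(self.parents, self.partition)


def _chimera_uniform(seed: int, chimera: Chimera) -> float:
    """Deterministic per-chimera uniform draw in [0, 1)."""
    digest = zlib.crc32(str(chimera).encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, digest]))
    return float(rng.random())


def _additive_titer(spec: LandscapeSpec, chimera: Chimera, clip: bool = True) -> float:
    t = spec.base + float(spec.ahr_effects.get(chimera.ahr_parent, 0.0))
    combo = [(b, lab) for b, lab in enumerate(chimera.atr_blocks)]
    for key in combo:
        t += float(spec.block_effects.get(key, 0.0))
    if spec.epistasis:
        present = set(combo)
        for (k1, k2), eff in spec.epistasis.items():
            if k1 in present and k2 in present:
                t += float(eff)
    if spec.charge_coef and spec.interface is not None:
        seq = translate(chimera, spec.parents, spec.partition, keep_gaps=True)
        t += spec.charge_coef * net_interface_charge(seq, spec.interface)
    return max(t, 0.0) if clip else t


def _is_inactive(spec: LandscapeSpec, chimera: Chimera, E: float | None = None) -> bool:
    rule = spec.inactivation
    if rule is None:
        return False
    kind = rule["rule"]
    if kind == "threshold_E":
        if E is None:
            E = schema_E(chimera, spec.parents, spec.partition, spec.contact_map)
        return E > rule["e0"]
    if kind == "logistic_E":
        if E is None:
            E = schema_E(chimera, spec.parents, spec.partition, spec.contact_map)
        z = (E - rule["midpoint"]) / max(rule["scale"], 1e-12)
        p = 1.0 / (1.0 + np.exp(-z))
        return _chimera_uniform(spec.seed, chimera) < p
    if kind == "block_distance":
        return block_distance(chimera, spec.parents, spec.partition) > rule["max"]
    raise ValueError(f"unknown inactivation rule {kind!r}")


def true_titer(spec: LandscapeSpec, chimera: Chimera) -> float:
    """Noiseless titer (mg/L); zero when the inactivation rule fires."""
    chimera = canonicalize(chimera, spec.parents, spec.partition)
    if _is_inactive(spec, chimera):
        return 0.0
    return _additive_titer(spec, chimera)


def true_titers(spec: LandscapeSpec, chimeras: Sequence[Chimera]) -> np.ndarray:
    """Vectorized :func:`true_titer` (shares one SCHEMA energy pass)."""
    chimeras = [canonicalize(c, spec.parents, spec.partition) for c in chimeras]
    needs_E = spec.inactivation is not None and spec.inactivation["rule"] in (
        "threshold_E",
        "logistic_E",
    )
    energies = (
        schema_E_many(chimeras, spec.parents, spec.partition, spec.contact_map)
        if needs_E
        else [None] * len(chimeras)
    )
    out = np.empty(len(chimeras))
    for k, (c, E) in enumerate(zip(chimeras, energies)):
        out[k] = 0.0 if _is_inactive(spec, c, E) else _additive_titer(spec, c)
    return out


@dataclass(frozen=True)
class AssayRecord:
    """One replicate measurement of one chimera in one strain."""

    chimera: Chimera
    strain: str
    replicate: int
    chain_titers: Mapping[str, float]
    total: float
    active: bool

    def as_row(self) -> dict:
        row = {
            "block_string": str(self.chimera),
            "strain": self.strain,
            "replicate": self.replicate,
            "titer_total_mg_per_L": self.total,
            "active": self.active,
        }
        row.update(self.chain_titers)
        return row


def measure(
    spec: LandscapeSpec,
    chimera: Chimera,
    n_replicates: int = 3,
    seed: int | None = None,
    strain: str = "sim",
) -> list[AssayRecord]:
    """Simulate replicate titer measurements of one chimera.

    Replicate totals are ``max(0, true + Gaussian noise)`` with noise sd
    ``noise_sd + noise_rel * true``; the chain-length split follows the
    mixture weights.  Reproducible given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    true = true_titer(spec, chimera)
    if seed is None:
        seed = spec.seed
    digest = zlib.crc32(f"{strain}:{chimera}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))
    sd = spec.noise_sd + spec.noise_rel * true
    records = []
    for rep in range(1, n_replicates + 1):
        total = max(0.0, true + rng.normal(0.0, sd)) if sd > 0 else true
        chains = {k: w * total for k, w in spec.chain_weights.items()}
        records.append(
            AssayRecord(
                chimera,
                strain,
                rep,
                chains,
                total,
                total > spec.activity_threshold,
            )
        )
    return records


def records_to_frame(records: Iterable[AssayRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


class SimulatedAssay:
    """Measurement oracle over a landscape, for campaign orchestration."""

    def __init__(self, spec: LandscapeSpec, strain: str = "sim") -> None:
        self.spec = spec
        self.strain = strain

    def measure(self, chimera: Chimera, n_replicates: int, seed: int) -> pd.DataFrame:
        return records_to_frame(
            measure(self.spec, chimera, n_replicates, seed, self.strain)
        )

    def space(self) -> list[Chimera]:
        return self.spec.space()


def aggregate(table, activity_threshold: float = 1.0) -> pd.DataFrame:
    """Per-(chimera, strain) mean, sample sd (n-1; zero when n = 1), n, and
    active flag (mean titer above the threshold)."""
    df = pd.DataFrame(table)
    if df.empty:
        raise ValueError("no records to aggregate")
    grouped = df.groupby(["block_string", "strain"], sort=True)["titer_total_mg_per_L"]
    out = grouped.agg(
        titer_total_mg_per_L="mean",
        titer_sd=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
        n="count",
    ).reset_index()
    out["active"] = out["titer_total_mg_per_L"] > activity_threshold
    return out


@dataclass
class QuantitationResult:
    """Per-species concentrations plus per-species failures."""

    concentrations: dict[int, float]
    errors: dict[int, str]


def quantitate_internal_standard(
    areas: Mapping[int, float],
    standards: Mapping[int, tuple[float, float]],
) -> QuantitationResult:
    """Internal-standard quantitation of even-chain analytes.

    Each even-chain species i is bracketed by odd-chain internal standards
    i-1 and i+1 with known concentrations and measured areas:

        C_i = A_i * avg(C_{i-1}, C_{i+1}) / avg(A_{i-1}, A_{i+1})

    ``standards`` maps odd chain length -> (concentration, area).  A species
    with a missing bracket or nonpositive standard areas is reported in
    ``errors``; the others are still computed.
    """
    concentrations: dict[int, float] = {}
    errors: dict[int, str] = {}
    for i, area in sorted(areas.items()):
        lo, hi = i - 1, i + 1
        if lo not in standards or hi not in standards:
            errors[i] = f"missing bracketing standard C{lo} or C{hi}"
            continue
        (c_lo, a_lo), (c_hi, a_hi) = standards[lo], standards[hi]
        avg_area = (a_lo + a_hi) / 2.0
        if a_lo <= 0 or a_hi <= 0 or avg_area <= 0:
            errors[i] = f"nonpositive standard area for C{lo}/C{hi}"
            continue
        concentrations[i] = area * ((c_lo + c_hi) / 2.0) / avg_area
    return QuantitationResult(concentrations, errors)


# ---------------------------------------------------------------------------
# Synthetic study system: parents, contacts, and a calibrated landscape.
# ---------------------------------------------------------------------------

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def synthetic_parents(
    seed: int = 0,
    names: Sequence[str] = ("A", "B", "T"),
    n_ahr: int = 45,
    n_atr: int = 160,
    n_blocks: int = 8,
    identity: float = 0.72,
    conserved_block: tuple[int, tuple[str, str]] | None = (5, ("A", "B")),
) -> tuple[ParentSet, BlockPartition]:
    """Generate a synthetic aligned parent family and block partition.

    Column identity mimics a 60-81%-identity family.  ``conserved_block``
    forces one ATR block (0-based index) to be perfectly conserved between
    two parents, reproducing the combinatorics of a library whose distinct
    size is smaller than (number of parents)^(number of blocks); every other
    block is guaranteed to differ between every pair of parents.  Gap-free
    by construction.
    """
    rng = np.random.default_rng(seed)
    P = len(names)
    L = n_ahr + n_atr
    cols = np.empty((P, L), dtype="<U1")
    for c in range(L):
        if rng.random() < identity:
            cols[:, c] = rng.choice(list(_AMINO_ACIDS))
        else:
            base_aa = rng.choice(list(_AMINO_ACIDS), size=P, replace=True)
            # guarantee at least two options in a "variable" column
            if len(set(base_aa)) == 1:
                alt = rng.choice([a for a in _AMINO_ACIDS if a != base_aa[0]])
                base_aa[rng.integers(P)] = alt
            cols[:, c] = base_aa

    # even block partition of the ATR region
    edges = np.linspace(n_ahr, L, n_blocks + 1).astype(int)
    partition = BlockPartition(tuple(int(e) for e in edges[1:-1]), n_ahr)
    segments = partition.block_segments(L)

    name_idx = {n: k for k, n in enumerate(names)}
    if conserved_block is not None:
        b, (p1, p2) = conserved_block
        s, e = segments[b]
        cols[name_idx[p2], s:e] = cols[name_idx[p1], s:e]

    # every other parent pair must differ within every block (and the forced
    # pair must still differ from the third parent within the forced block)
    for b, (s, e) in enumerate(segments):
        for i in range(P):
            for j in range(i + 1, P):
                if conserved_block is not None and b == conserved_block[0]:
                    pair = {name_idx[conserved_block[1][0]], name_idx[conserved_block[1][1]]}
                    if {i, j} == pair:
                        continue
                if np.all(cols[i, s:e] == cols[j, s:e]):
                    c = int(rng.integers(s, e))
                    alt = rng.choice([a for a in _AMINO_ACIDS if a != cols[i, c]])
                    cols[j, c] = alt
    sequences = tuple("".join(row) for row in cols)
    return ParentSet(tuple(names), sequences, n_ahr), partition


def synthetic_contact_map(
    aligned_length: int,
    seed: int = 0,
    cutoff: float = 8.0,
    n_models: int = 5,
    coordinate_noise: float = 0.6,
) -> ContactMap:
    """Contact map of a synthetic compact chain (one pseudo-atom per column).

    Residue coordinates follow a self-attracting random walk with a 3.8 A
    step confined to a sphere, giving local plus long-range contacts the way
    a folded domain does; an ensemble of ``n_models`` noise-perturbed copies
    yields fractional weights.  Synthetic stand-in for an ensemble of
    homology models.
    """
    from .structure_contacts import compute_contact_map

    rng = np.random.default_rng(seed)
    radius = 3.0 * aligned_length ** (1.0 / 3.0)
    coords = np.zeros((aligned_length, 3))
    for k in range(1, aligned_length):
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        nxt = coords[k - 1] + step
        # reflect back toward the origin to stay compact
        if np.linalg.norm(nxt) > radius:
            nxt = coords[k - 1] - step
        coords[k] = nxt
    models = []
    for _ in range(n_models):
        jittered = coords + rng.normal(0.0, coordinate_noise, size=coords.shape)
        models.append([jittered[i : i + 1] for i in range(aligned_length)])
    return compute_contact_map(models, cutoff=cutoff, min_separation=2)


def random_landscape(
    parents: ParentSet,
    partition: BlockPartition,
    contact_map: ContactMap,
    seed: int = 0,
    base: float = 10.0,
    effect_range: float = 15.0,
    n_epistasis: int = 10,
    epistasis_range: float = 8.0,
    inactive_fraction: float = 0.7,
    noise_sd: float = 2.0,
    noise_rel: float = 0.2,
    parent_titers: Sequence[float] = (11.0, 25.0, 8.0),
    activity_threshold: float = 1.0,
) -> LandscapeSpec:
    """Sample a calibrated landscape over the given chimera space.

    Block effects are uniform on +-``effect_range`` mg/L per distinct block
    option, with first-block effects adjusted so the parental chimeras hit
    ``parent_titers`` exactly.  Pairwise epistasis couples ``n_epistasis``
    random block-option pairs.  The logistic-in-E inactivation midpoint is
    placed at the (1 - inactive_fraction) quantile of the library's SCHEMA
    energy so roughly that share of the space is inactive while the parents
    (E = 0) stay active.
    """
    rng = np.random.default_rng(seed)
    space = enumerate_space(parents, partition)
    labels_per_block = [
        sorted({c.atr_blocks[b] for c in space}) for b in range(partition.n_blocks)
    ]
    block_effects: dict[tuple[int, str], float] = {}
    for b, labs in enumerate(labels_per_block):
        for lab in labs:
            block_effects[(b, lab)] = float(rng.uniform(-effect_range, effect_range))
    # map non-canonical labels onto their canonical twin's effect
    parentals = {
        name: canonicalize(
            Chimera(parents.names[0], (name,) * partition.n_blocks), parents, partition
        )
        for name in parents.names
    }
    for b in range(partition.n_blocks):
        for name in parents.names:
            canon = parentals[name].atr_blocks[b]
            block_effects.setdefault((b, name), block_effects[(b, canon)])

    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    n_blocks = partition.n_blocks
    for _ in range(n_epistasis):
        b1, b2 = sorted(rng.choice(n_blocks, size=2, replace=False))
        l1 = labels_per_block[b1][rng.integers(len(labels_per_block[b1]))]
        l2 = labels_per_block[b2][rng.integers(len(labels_per_block[b2]))]
        epistasis[((int(b1), l1), (int(b2), l2))] = float(
            rng.uniform(-epistasis_range, epistasis_range)
        )

    # pin parental titers by adjusting the first-block effects
    if len(parent_titers) != parents.n_parents:
        raise ValueError("parent_titers must give one target per parent")
    draft = LandscapeSpec(
        parents,
        partition,
        contact_map,
        base=base,
        block_effects=block_effects,
        epistasis=epistasis,
        inactivation=None,
        noise_sd=noise_sd,
        noise_rel=noise_rel,
        seed=seed,
        activity_threshold=activity_threshold,
    )
    first_block_labels = {parentals[name].atr_blocks[0] for name in parents.names}
    if len(first_block_labels) != parents.n_parents:
        raise ValueError(
            "parents share a first-block sequence; parental titers cannot be pinned"
        )
    for name, target in zip(parents.names, parent_titers):
        current = _additive_titer(draft, parentals[name], clip=False)
        canon0 = parentals[name].atr_blocks[0]
        block_effects[(0, canon0)] += target - current
        block_effects[(0, name)] = block_effects[(0, canon0)]

    # calibrate the inactivation midpoint on the library's E distribution
    if inactive_fraction <= 0:
        inactivation = None
    else:
        energies = schema_E_many(space, parents, partition, contact_map)
        midpoint = float(np.quantile(energies, 1.0 - inactive_fraction))
        scale = max(float(np.std(energies)) / 10.0, 1e-6)
        inactivation = {"rule": "logistic_E", "midpoint": midpoint, "scale": scale}
    return replace(draft, block_effects=dict(block_effects), inactivation=inactivation)


@dataclass
class DemoSystem:
    """A complete synthetic study system ready for closed-loop runs."""

    parents: ParentSet
    partition: BlockPartition
    contact_map: ContactMap
    landscape: LandscapeSpec

    def assay(self, strain: str = "sim") -> SimulatedAssay:
        return SimulatedAssay(self.landscape, strain)


def demo_system(seed: int = 0, **landscape_kwargs) -> DemoSystem:
    """Default synthetic system: 3 parents, 8 ATR blocks with one block
    conserved between two parents (so the distinct library holds
    2 x 3^7 = 4374 chimeras), an ensemble-weighted synthetic contact map,
    and a calibrated majority-inactive landscape."""
    parents, partition = synthetic_parents(seed=seed)
    contact_map = synthetic_contact_map(parents.aligned_length, seed=seed + 1)
    landscape = random_landscape(
        parents, partition, contact_map, seed=seed + 2, **landscape_kwargs
    )
    return DemoSystem(parents, partition, contact_map, landscape)
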