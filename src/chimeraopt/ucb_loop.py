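"""Batch-mode upper-confidence-bound sequence optimization.

Each design round scores every untested, classifier-passing chimera by
UCB = posterior mean + beta * posterior sd (beta = 1 by default) under the
linear-kernel GP.  Batches are assembled by *hallucination*: the UCB-optimal
sequence is added to the training set with its predicted titer as a
pseudo-observation, the GP is refit, and the next UCB optimum is taken,
until the batch is full.  Hallucinated observations never persist into the
campaign's measurement table.

:func:`run_campaign` orchestrates the full closed loop against a measurement
oracle (the landscape simulator, or a recorded table in replay mode): a
greedy maximally informative seed round followed by UCB rounds, refitting
the classifier and regressor on all accumulated real data after each round.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .landscape_sim import aggregate
from .models import ActivityClassifier, LinearKernelGP, loo_cv_scan
from .seed_design import greedy_seed_select
from .sequence_space import (
    BlockPartition,
    Chimera,
    ChimeraEncoder,
    ParentSet,
    block_distance,
    parental_chimeras,
)

__all__ = [
    "Proposal",
    "RoundRecord",
    "CampaignConfig",
    "CampaignState",
    "ucb_scores",
    "combined_ucb",
    "filter_pool",
    "batch_select",
    "run_campaign",
    "random_campaign",
    "TableOracle",
]

logger = logging.getLogger(__name__)


def ucb_scores(model: LinearKernelGP, X, beta: float = 1.0) -> np.ndarray:
    """Posterior mean + beta * posterior sd for each candidate encoding."""
    mean, std = model.predict(X, return_std=True)
    return mean + beta * std


def combined_ucb(models: Sequence[LinearKernelGP], X, beta: float = 1.0) -> np.ndarray:
    """Sum of per-strain UCB scores (used for multi-strain objectives)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dims = {m.n_features_in_ for m in models}
    if len(dims) != 1 or X.shape[1] not in dims:
        raise ValueError("models and candidates must share one encoding dimension")
    return np.sum([ucb_scores(m, X, beta) for m in models], axis=0)


def filter_pool(
    space: Sequence[Chimera],
    tested: set[str] | Sequence[str],
    classifier: ActivityClassifier | None = None,
    encoder: ChimeraEncoder | None = None,
    max_block_distance: int | None = None,
    parents: ParentSet | None = None,
    partition: BlockPartition | None = None,
) -> list[Chimera]:
    """Candidate pool: space minus tested, predicted-inactive, and (when a
    cap is given) chimeras too many block exchanges from every parent."""
    tested = set(str(t) for t in tested)
    pool = [c for c in space if str(c) not in tested]
    if max_block_distance is not None:
        if parents is None:
            raise ValueError("the block-distance filter needs the parent set")
        pool = [
            c for c in pool if block_distance(c, parents, partition) <= max_block_distance
        ]
    if classifier is not None:
        if encoder is None:
            raise ValueError("classifier filtering needs an encoder")
        if pool:
            keep = classifier.predict_proba_active(encoder.encode_many(pool)) >= classifier.cutoff
            pool = [c for c, k in zip(pool, keep) if k]
    if not pool:
        raise ValueError(
            "candidate pool is empty; relax the classifier cutoff, the block-distance "
            "cap, or test fewer sequences per round"
        )
    return pool


@dataclass(frozen=True)
class Proposal:
    """One proposed chimera with its selection-time statistics."""

    chimera: Chimera
    ucb: float
    mean: float
    sd: float


def batch_select(
    model: LinearKernelGP,
    pool: Sequence[Chimera],
    X_pool: np.ndarray,
    batch_size: int,
    beta: float = 1.0,
) -> list[Proposal]:
    """Batch-mode UCB selection with hallucinated retraining.

    Repeats: take the UCB argmax (ties to the smallest block string), append
    it to the training set with its posterior mean as a pseudo-observation,
    refit, rescore.  The hallucinations live only inside this routine.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    order = sorted(range(len(pool)), key=lambda k: str(pool[k]))
    pool = [pool[k] for k in order]
    X_pool = np.asarray(X_pool, dtype=float)[order]
    if len(pool) < batch_size:
        warnings.warn(
            f"pool holds {len(pool)} candidates, fewer than batch_size={batch_size}; "
            "returning a shorter batch"
        )
        batch_size = len(pool)
    X_aug = model.X_train_.copy()
    y_aug = model.y_train_.copy()
    current = model
    available = np.ones(len(pool), dtype=bool)
    batch: list[Proposal] = []
    for _ in range(batch_size):
        mean, std = current.predict(X_pool, return_std=True)
        scores = np.where(available, mean + beta * std, -np.inf)
        top = scores.max()
        pick = int(np.flatnonzero(scores >= top - 1e-12)[0])
        available[pick] = False
        batch.append(Proposal(pool[pick], float(scores[pick]), float(mean[pick]), float(std[pick])))
        X_aug = np.vstack([X_aug, X_pool[pick : pick + 1]]) if X_aug.size else X_pool[pick : pick + 1].copy()
        y_aug = np.append(y_aug, mean[pick])
        current = clone(model).fit(X_aug, y_aug)
    return batch


@dataclass
class RoundRecord:
    """What one design round saw and proposed."""

    index: int
    pool_size: int
    sigma2: float
    classifier_used: bool
    max_block_distance: int | None
    proposals: list[Proposal]

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "pool_size": self.pool_size,
            "sigma2": self.sigma2,
            "classifier_used": self.classifier_used,
            "max_block_distance": self.max_block_distance,
            "proposals": [
                {
                    "block_string": str(p.chimera),
                    "ucb": p.ucb,
                    "mean": p.mean,
                    "sd": p.sd,
                }
                for p in self.proposals
            ],
        }


@dataclass
class CampaignConfig:
    """Closed-loop campaign settings.

    ``max_block_distance`` maps round index -> cap; rounds not listed are
    unrestricted.  Early rounds default to a cap of 4 exchanges, mirroring
    the practice of biasing early sampling toward functional sequences; the
    cap is lifted from round 4 on.  ``sigma2="loo"`` rescans the kernel
    variance by LOO each round; a float fixes it.
    """

    n_rounds: int = 10
    batch_size: int = 10
    beta: float = 1.0
    n_seed: int = 20
    n_replicates: int = 3
    activity_threshold: float = 1.0
    noise_variance: float = 1.0
    sigma2: float | str = "loo"
    scheme: str = "hamming"
    seed: int = 0
    max_block_distance: Mapping[int, int] = field(
        default_factory=lambda: {1: 4, 2: 4, 3: 4}
    )
    classifier_min_active: int = 2
    gp_on_active_only: bool = False
    include_parents_in_seed: bool = True
    loo_method: str = "refit"

    def as_dict(self) -> dict:
        return {
            "n_rounds": self.n_rounds,
            "batch_size": self.batch_size,
            "beta": self.beta,
            "n_seed": self.n_seed,
            "n_replicates": self.n_replicates,
            "activity_threshold": self.activity_threshold,
            "noise_variance": self.noise_variance,
            "sigma2": self.sigma2,
            "scheme": self.scheme,
            "seed": self.seed,
            "max_block_distance": {str(k): v for k, v in self.max_block_distance.items()},
            "classifier_min_active": self.classifier_min_active,
            "gp_on_active_only": self.gp_on_active_only,
            "include_parents_in_seed": self.include_parents_in_seed,
        }


@dataclass
class CampaignState:
    """Cumulative measurements plus per-round records."""

    records: pd.DataFrame
    rounds: list[RoundRecord]
    config: CampaignConfig
    seed: int

    def measured_strings(self) -> set[str]:
        return set(self.records["block_string"]) if len(self.records) else set()

    def best_measured(self) -> tuple[str, float]:
        agg = aggregate(self.records, self.config.activity_threshold)
        row = agg.loc[agg["titer_total_mg_per_L"].idxmax()]
        return str(row["block_string"]), float(row["titer_total_mg_per_L"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config.as_dict(),
                "rounds": [r.as_dict() for r in self.rounds],
                "records": self.records.to_dict(orient="records"),
            }
        )


class TableOracle:
    """Replay oracle over a recorded sequence-function table."""

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = pd.DataFrame(table)
        if "block_string" not in self.table.columns:
            raise ValueError("replay table needs a block_string column")

    def measure(self, chimera: Chimera, n_replicates: int, seed: int) -> pd.DataFrame:
        rows = self.table[self.table["block_string"] == str(chimera)]
        if rows.empty:
            raise KeyError(str(chimera))
        return rows.copy()


def _fit_round_models(
    agg: pd.DataFrame,
    encoder: ChimeraEncoder,
    parents: ParentSet,
    partition: BlockPartition,
    config: CampaignConfig,
) -> tuple[LinearKernelGP, ActivityClassifier | None, float]:
    from .sequence_space import parse_chimera

    chims = [parse_chimera(bs, parents, partition.n_blocks) for bs in agg["block_string"]]
    X = encoder.encode_many(chims)
    y = agg["titer_total_mg_per_L"].to_numpy(dtype=float)
    active = y > config.activity_threshold

    classifier = None
    if active.sum() >= config.classifier_min_active and (~active).sum() >= 1:
        classifier = ActivityClassifier(threshold=config.activity_threshold).fit(X, y)

    if isinstance(config.sigma2, str):
        if len(y) >= 3 and np.std(y) > 0:
            report = loo_cv_scan(
                X,
                y,
                noise_variance=config.noise_variance,
                method=config.loo_method,
                center_y=(config.loo_method != "fast"),
            )
            sigma2 = report.chosen_sigma2
        else:
            sigma2 = 1.0
    else:
        sigma2 = float(config.sigma2)

    if config.gp_on_active_only and active.sum() >= 2:
        X_fit, y_fit = X[active], y[active]
    else:
        X_fit, y_fit = X, y
    gp = LinearKernelGP(sigma2=sigma2, noise_variance=config.noise_variance).fit(X_fit, y_fit)
    return gp, classifier, sigma2


def run_campaign(
    oracle,
    parents: ParentSet,
    partition: BlockPartition,
    config: CampaignConfig,
    contact_map=None,
    space: Sequence[Chimera] | None = None,
    seed_chimeras: Sequence[Chimera] | None = None,
) -> CampaignState:
    """Run the closed loop: seed round then ``n_rounds`` UCB rounds.

    ``oracle.measure(chimera, n_replicates, seed)`` must return replicate
    rows in the sequence-function table schema.  All randomness derives from
    ``config.seed``; rerunning with the same oracle and seed reproduces the
    identical campaign.  An oracle failure for a proposed chimera is logged
    and the chimera excluded from fitting.
    """
    from .sequence_space import enumerate_space

    rng = np.random.default_rng(config.seed)
    if space is None:
        space = enumerate_space(parents, partition)
    encoder = ChimeraEncoder(parents, partition, config.scheme, contact_map)

    frames: list[pd.DataFrame] = []
    measured: set[str] = set()

    def _measure_batch(chimeras: Sequence[Chimera]) -> None:
        for chim in chimeras:
            if str(chim) in measured:
                continue
            sub_seed = int(rng.integers(2**31))
            try:
                frames.append(oracle.measure(chim, config.n_replicates, sub_seed))
            except KeyError:
                logger.warning("no measurement available for %s; skipping", chim)
                continue
            measured.add(str(chim))

    # --- seed round -------------------------------------------------------
    initial = parental_chimeras(parents, partition) if config.include_parents_in_seed else []
    if seed_chimeras is None:
        plan = greedy_seed_select(space, encoder, config.n_seed, initial_set=initial)
        seed_chimeras = plan.selected
    _measure_batch(list(initial) + list(seed_chimeras))
    rounds: list[RoundRecord] = []

    # --- UCB rounds -------------------------------------------------------
    for rnd in range(1, config.n_rounds + 1):
        records = pd.concat(frames, ignore_index=True)
        agg = aggregate(records, config.activity_threshold)
        gp, classifier, sigma2 = _fit_round_models(agg, encoder, parents, partition, config)
        cap = config.max_block_distance.get(rnd)
        try:
            pool = filter_pool(
                space, measured, classifier, encoder, cap, parents, partition
            )
        except ValueError:
            logger.warning(
                "round %d: filters emptied the pool; retrying without the classifier", rnd
            )
            pool = filter_pool(space, measured, None, encoder, cap, parents, partition)
        X_pool = encoder.encode_many(pool)
        batch = batch_select(gp, pool, X_pool, config.batch_size, config.beta)
        rounds.append(
            RoundRecord(rnd, len(pool), sigma2, classifier is not None, cap, batch)
        )
        logger.info(
            "round %d: pool=%d sigma2=%.3g classifier=%s proposals=%s",
            rnd,
            len(pool),
            sigma2,
            classifier is not None,
            [str(p.chimera) for p in batch],
        )
        _measure_batch([p.chimera for p in batch])

    records = pd.concat(frames, ignore_index=True)
    return CampaignState(records, rounds, config, config.seed)


def random_campaign(
    oracle,
    space: Sequence[Chimera],
    budget: int,
    seed: int,
    n_replicates: int = 3,
    activity_threshold: float = 1.0,
) -> pd.DataFrame:
    """Uniform random-search baseline at the same measurement budget."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(space), size=min(budget, len(space)), replace=False)
    frames = []
    for i in idx:
        sub_seed = int(rng.integers(2**31))
        frames.append(oracle.measure(space[int(i)], n_replicates, sub_seed))
    return pd.concat(frames, ignore_index=True)
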