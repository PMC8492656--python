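"""Greedy maximally informative seed selection.

The initial experimental batch is chosen to maximize the Gaussian mutual
information between the chosen set S and the full chimera landscape L under
the linear-kernel Gaussian process prior.  Because S is a subset of L this
reduces to maximizing the Gaussian entropy H(S) = 1/2 log det(2*pi*e*K_SS),
a submodular set function, so the greedy algorithm that repeatedly adds the
sequence with the largest entropy gain carries the usual (1 - 1/e)
approximation guarantee.

The entropy gain of adding x to S is 1/2 log(2*pi*e * v) where v is the
predictive variance of x given S (the Schur complement of K_SS in
K_{S+x,S+x}), so the greedy step is a maximum-posterior-variance pick.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .sequence_space import Chimera, ChimeraEncoder, parental_chimeras

__all__ = ["SeedPlan", "gaussian_entropy", "greedy_seed_select"]

_LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


def _jitter(K: np.ndarray, jitter_scale: float) -> float:
    diag_mean = float(np.mean(np.diag(K))) if K.size else 1.0
    return jitter_scale * max(diag_mean, 1.0)


def gaussian_entropy(
    X: np.ndarray, sigma2: float = 1.0, jitter_scale: float = 1e-8
) -> float:
    """Gaussian entropy of the encodings' linear-kernel covariance.

    H = 1/2 log det(2*pi*e*(sigma2 * X X^T + jitter * I)).  The jitter
    (``jitter_scale`` times the mean kernel diagonal) keeps duplicate or
    rank-deficient subsets finite instead of raising.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("subset must be nonempty")
    K = sigma2 * (X @ X.T)
    j = _jitter(K, jitter_scale)
    for attempt in range(6):
        try:
            L = cholesky(K + (j * 10**attempt) * np.eye(K.shape[0]), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - jitter escalation always succeeds in practice
        raise np.linalg.LinAlgError("kernel matrix not positive definite")
    return 0.5 * K.shape[0] * _LOG_2PIE + float(np.sum(np.log(np.diag(L))))


@dataclass
class SeedPlan:
    """Result of greedy seed selection."""

    selected: list[Chimera]
    initial: tuple[Chimera, ...]
    objective_trace: list[float]
    kernel_scheme: str

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rank", "block_string", "entropy_after"])
            for rank, (chim, h) in enumerate(zip(self.selected, self.objective_trace), 1):
                writer.writerow([rank, str(chim), f"{h:.10g}"])


def greedy_seed_select(
    space: Sequence[Chimera],
    encoder: ChimeraEncoder,
    n_select: int,
    initial_set: Sequence[Chimera] | None = None,
    sigma2: float = 1.0,
    jitter_scale: float = 1e-8,
    count_includes_initial: bool = False,
) -> SeedPlan:
    """Greedy entropy-maximizing selection from the chimera space.

    ``initial_set`` defaults to the parental chimeras.  ``n_select`` counts
    new additions; set ``count_includes_initial`` to make it the total size
    of initial set plus additions.  Ties in entropy gain are broken toward
    the smallest block string.
    """
    if initial_set is None:
        initial_set = parental_chimeras(encoder.parents, encoder.partition)
    initial = tuple(initial_set)
    n_new = n_select - len(initial) if count_includes_initial else n_select
    if n_new < 0:
        raise ValueError("n_select smaller than the initial set")
    order = sorted(range(len(space)), key=lambda k: str(space[k]))
    space_sorted = [space[k] for k in order]
    X = encoder.encode_many(space_sorted)
    chosen_strings = {str(c) for c in initial}
    available = np.array([str(c) not in chosen_strings for c in space_sorted])
    if n_new > int(available.sum()):
        raise ValueError("n_select exceeds the number of untested sequences in the space")

    X_init = encoder.encode_many(list(initial)) if initial else np.zeros((0, X.shape[1]))
    S = [row for row in X_init]
    selected: list[Chimera] = []
    trace: list[float] = []
    prior_var = sigma2 * np.einsum("ij,ij->i", X, X)
    j = jitter_scale * max(float(prior_var.mean()) if prior_var.size else 1.0, 1.0)

    for _ in range(n_new):
        if S:
            Xs = np.vstack(S)
            Kss = sigma2 * (Xs @ Xs.T) + j * np.eye(len(S))
            L = cholesky(Kss, lower=True)
            Kxs = sigma2 * (X @ Xs.T)
            V = solve_triangular(L, Kxs.T, lower=True)
            cond_var = prior_var + j - np.einsum("ij,ij->j", V, V)
        else:
            cond_var = prior_var + j
        cond_var = np.maximum(cond_var, j * 1e-6)
        gains = 0.5 * (_LOG_2PIE + np.log(cond_var))
        gains = np.where(available, gains, -np.inf)
        top = gains.max()
        if not np.isfinite(top):
            raise ValueError("candidate pool exhausted")
        # ties within numerical noise resolve to the smallest block string,
        # which is the first index because candidates are string-sorted
        pick = int(np.flatnonzero(gains >= top - 1e-12)[0])
        available[pick] = False
        selected.append(space_sorted[pick])
        S.append(X[pick])
        trace.append(gaussian_entropy(np.vstack(S), sigma2, jitter_scale))
    return SeedPlan(selected, initial, trace, encoder.scheme)
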