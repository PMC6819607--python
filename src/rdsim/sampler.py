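"""Respondent-driven sampling from a networked population.

Recruitment proceeds wave by wave from randomly drawn seeds.  Each
participant receives a fixed number of coupons and offers them to uniformly
chosen, not-yet-sampled neighbours; every offer is accepted independently
with the response probability (identical in both groups).  A declined offer
consumes the coupon.  Nobody is recruited twice.  Sampling stops when the
target sample size is reached, truncating mid-wave in randomized enrolment
order.  If every chain dies before the target is reached, a replacement seed
is drawn (when allowed) and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netpop import NetworkedPopulation

__all__ = [
    "SamplerConfig",
    "RDSSample",
    "DeadChainError",
    "UndefinedCorrelationError",
    "draw_seeds",
    "rds_sample",
    "sampling_frequency_correlation",
]


class DeadChainError(RuntimeError):
    """All recruitment chains exhausted before reaching the target size."""


class UndefinedCorrelationError(ValueError):
    """Sampling-frequency correlation undefined (a constant vector)."""


@dataclass(frozen=True)
class SamplerConfig:
    n_seeds: int = 10
    coupons: int = 3
    response_prob: float = 0.5
    target_n: int = 500
    allow_reseed: bool = True

    def __post_init__(self) -> None:
        if self.n_seeds < 1 or self.coupons < 1 or self.target_n < 1:
            raise ValueError("n_seeds, coupons and target_n must be >= 1")
        if not (0.0 < self.response_prob <= 1.0):
            raise ValueError("response_prob must be in (0, 1]")


@dataclass
class RDSSample:
    """A recruitment forest with participant traits.

    ``table`` has one row per participant: id, seed_id, recruiter_id (-1 for
    seeds), wave, degree, group, X_predict, X_NULL — in enrolment order.
    """

    table: pd.DataFrame
    n_reseeds: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def waves(self) -> int:
        return int(self.table["wave"].max())

    @property
    def seed_ids(self) -> np.ndarray:
        return self.table.loc[self.table["wave"] == 0, "id"].to_numpy()

    @property
    def recruits_per_productive_seed(self) -> float:
        """(n - #productive seeds) / #productive seeds.

        A seed is productive if its chain recruited at least one other
        participant.
        """
        seeds = self.seed_ids
        chain_sizes = self.table["seed_id"].value_counts()
        productive = int((chain_sizes[chain_sizes.index.isin(seeds)] > 1).sum())
        if productive == 0:
            return 0.0
        return (self.n - productive) / productive


def draw_seeds(pop: NetworkedPopulation, k: int, rng=None) -> np.ndarray:
    """Draw ``k`` distinct seed ids uniformly at random."""
    if k > pop.n:
        raise ValueError(f"cannot draw {k} seeds from {pop.n} nodes")
    rng = np.random.default_rng(rng)
    return rng.choice(pop.n, size=k, replace=False)


def rds_sample(
    pop: NetworkedPopulation,
    config: SamplerConfig = SamplerConfig(),
    rng=None,
    adjacency: list[np.ndarray] | None = None,
) -> RDSSample:
    """Draw one respondent-driven sample.

    ``adjacency`` can be precomputed (``pop.adjacency()``) and shared across
    replicates to avoid rebuilding it per sample.
    """
    if config.target_n > pop.n:
        raise ValueError("target_n exceeds population size")
    rng = np.random.default_rng(rng)
    adj = adjacency if adjacency is not None else pop.adjacency()

    sampled = np.zeros(pop.n, dtype=bool)
    rows: list[tuple] = []  # (id, seed_id, recruiter_id, wave)
    n_reseeds = 0

    def enroll(node: int, seed: int, recruiter: int, wave: int) -> None:
        sampled[node] = True
        rows.append((node, seed, recruiter, wave))

    seeds = draw_seeds(pop, config.n_seeds, rng)
    for s in rng.permutation(seeds):
        if len(rows) >= config.target_n:
            break
        enroll(int(s), int(s), -1, 0)

    # frontier holds (node, seed, wave) of participants yet to use coupons
    frontier = [(r[0], r[1], r[3]) for r in rows]
    while len(rows) < config.target_n:
        if not frontier:
            if not config.allow_reseed:
                raise DeadChainError(
                    f"chains exhausted at n={len(rows)} < target {config.target_n}"
                )
            unsampled = np.flatnonzero(~sampled)
            new_seed = int(unsampled[rng.integers(len(unsampled))])
            enroll(new_seed, new_seed, -1, 0)
            n_reseeds += 1
            frontier = [(new_seed, new_seed, 0)]
            continue
        next_frontier: list[tuple[int, int, int]] = []
        # randomized enrolment order within the wave
        for node, seed, wave in [frontier[i] for i in rng.permutation(len(frontier))]:
            if len(rows) >= config.target_n:
                break
            candidates = adj[node][~sampled[adj[node]]]
            k = min(config.coupons, len(candidates))
            if k == 0:
                continue
            invited = rng.choice(candidates, size=k, replace=False)
            accepted = invited[rng.random(k) < config.response_prob]
            for rec in accepted:
                if len(rows) >= config.target_n:
                    break
                if sampled[rec]:  # invited earlier this wave by someone else
                    continue
                enroll(int(rec), seed, node, wave + 1)
                next_frontier.append((int(rec), seed, wave + 1))
        frontier = next_frontier

    ids = np.array([r[0] for r in rows])
    table = pd.DataFrame(
        {
            "id": ids,
            "seed_id": [r[1] for r in rows],
            "recruiter_id": [r[2] for r in rows],
            "wave": [r[3] for r in rows],
            "degree": pop.degrees[ids],
            "group": pop.groups[ids],
            "X_predict": pop.x_predict[ids],
            "X_NULL": pop.x_null[ids],
        }
    )
    return RDSSample(table=table, n_reseeds=n_reseeds)


def sampling_frequency_correlation(
    pop: NetworkedPopulation,
    n_samples: int,
    config: SamplerConfig = SamplerConfig(),
    rng=None,
) -> float:
    """Pearson correlation between node inclusion frequency and degree.

    Draws ``n_samples`` independent RDS samples and counts, for every node
    in the population, the number of samples it appears in.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(rng)
    adj = pop.adjacency()
    freq = np.zeros(pop.n, dtype=np.int64)
    for _ in range(n_samples):
        s = rds_sample(pop, config, rng, adjacency=adj)
        freq[s.table["id"].to_numpy()] += 1
    if freq.std() == 0 or pop.degrees.std() == 0:
        raise UndefinedCorrelationError("constant frequency or degree vector")
    return float(np.corrcoef(freq, pop.degrees)[0, 1])
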