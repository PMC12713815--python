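"""Distribution-matched subsampling.

Two procedures are provided.  :func:`matched_subsample` is the iterative
random-search matcher used when a large corpus must be cut down to the size
of a smaller reference while keeping the word-count distributions
comparable: it draws candidate subsets uniformly at random, scores each one
against the reference with a 1D permutation test on word counts, and keeps
the least-diverging candidate, operationalised as the one with the largest
permutation p-value (ties broken by smaller observed statistic, then
earliest iteration).  :func:`range_matched_sample` matches on the *range*
of an already-computed quantity (perplexity): it samples uniformly from the
pool items whose score lies inside the [min, max] band of a small target
group, the procedure used when contrasting a small subgroup (e.g. blind or
clinical dreamers) against the general pool.

Both procedures are fully seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import Corpus
from .errors import EmptyOverlapError, InvalidArgumentError
from .perplexity import PerplexityRecord
from .stats import permutation_test_1d


@dataclass
class MatchResult:
    """Selected subset plus the full candidate audit trail."""

    selected: Corpus
    candidate_stats: list[tuple[int, float, float]]  # (iteration, statistic, p)
    seed: int
    n_iterations: int
    best_iteration: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_iterations": self.n_iterations,
                "best_iteration": self.best_iteration,
                "candidate_stats": [
                    {"iteration": i, "statistic": s, "p": p}
                    for i, s, p in self.candidate_stats
                ],
                "selected_item_ids": [it.item_id for it in self.selected],
            },
            sort_keys=True,
        )


def matched_subsample(
    pool: Corpus,
    reference: Corpus,
    n_iterations: int = 250,
    seed: int = 0,
    stat_fn: Callable[[Sequence[float], Sequence[float], int], tuple[float, float]]
    | None = None,
    n_permutations: int = 1000,
) -> MatchResult:
    """Random-search a subset of ``pool`` (size = ``len(reference)``) whose
    word-count distribution diverges least from ``reference``.

    Each iteration draws a subset without replacement (draws are independent
    across iterations), evaluates ``stat_fn(subset_wc, reference_wc, seed)
    -> (statistic, p)`` — by default the 1D permutation test on word counts
    — and the candidate with the maximal p-value wins.
    """
    if len(pool) < len(reference):
        raise InvalidArgumentError(
            f"pool ({len(pool)}) must be at least as large as the reference "
            f"({len(reference)})"
        )
    if n_iterations < 1:
        raise InvalidArgumentError("n_iterations must be >= 1")

    ref_wc = np.asarray(reference.word_counts(), dtype=float)
    pool_wc = np.asarray(pool.word_counts(), dtype=float)
    size = len(reference)

    if stat_fn is None:
        def stat_fn(a, b, s):
            res = permutation_test_1d(a, b, n_permutations=n_permutations, seed=s)
            return res.statistic, res.p_raw

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_iterations)
    stats_log: list[tuple[int, float, float]] = []
    best = None  # (p, -stat, -iteration) maximised
    best_idx = None
    best_iter = 0
    for it, child in enumerate(children):
        draw_seed, test_seed = child.spawn(2)
        rng = np.random.default_rng(draw_seed)
        idx = rng.choice(len(pool), size=size, replace=False)
        stat, p = stat_fn(
            pool_wc[idx], ref_wc, int(test_seed.generate_state(1)[0] % (2**31))
        )
        stats_log.append((it, float(stat), float(p)))
        key = (p, -stat, -it)
        if best is None or key > best:
            best = key
            best_idx = idx
            best_iter = it
    selected = Corpus(
        items=[pool.items[i] for i in sorted(best_idx)],
        provenance=f"{pool.provenance}|matched",
    )
    return MatchResult(
        selected=selected,
        candidate_stats=stats_log,
        seed=seed,
        n_iterations=n_iterations,
        best_iteration=best_iter,
    )


def range_matched_sample(
    pool: Sequence[PerplexityRecord],
    target_group: Sequence[PerplexityRecord],
    seed: int = 0,
) -> list[PerplexityRecord]:
    """Uniform sample from pool records whose perplexity lies within the
    [min, max] band of the target group's perplexities (inclusive).

    The sample size equals the target group's size; if fewer pool records
    fall inside the band, all of them are returned.  No overlap at all is
    an explicit error.
    """
    if not pool or not target_group:
        raise InvalidArgumentError("pool and target_group must be nonempty")
    ppls = [r.ppl for r in target_group]
    lo, hi = min(ppls), max(ppls)
    eligible = [r for r in pool if lo <= r.ppl <= hi]
    if not eligible:
        raise EmptyOverlapError(
            f"no pool item has perplexity within the target range [{lo}, {hi}]"
        )
    size = min(len(target_group), len(eligible))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=size, replace=False)
    return [eligible[i] for i in sorted(idx)]
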