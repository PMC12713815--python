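"""End-to-end analyses: whole-corpus comparison and subgroup contrasts.

:func:`compare_corpora` reproduces the corpus-versus-corpus design: filter
both corpora to the word-count band, cut the larger one down to the
smaller's size with distribution-matched subsampling, score every item's
perplexity under one language model, then test (a) the joint
(word count, perplexity) distributions with the 2D KS test and (b) the
perplexity distributions alone with a 1D permutation test, Holm-adjusting
the declared family of p-values.

:func:`group_analysis` contrasts two levels of a metadata field (gender,
vision, clinical) within one scored corpus; for small-group contrasts the
majority pool is first range-matched on perplexity to the minority group.

Correlation helpers relate perplexity to report length and to year of
collection (Spearman).

Every run is deterministic given its configuration seed; reports embed a
hash of the configuration and per-stage log lines for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, filter_nonempty, filter_word_count
from .errors import InvalidArgumentError
from .lms import LanguageModel, NGramSpec, fit_ngram_lm
from .matching import matched_subsample, range_matched_sample
from .perplexity import (
    PerplexityRecord,
    WindowConfig,
    default_window,
    ppl_corpus_concat,
    ppl_per_item,
)
from .stats import (
    SpearmanResult,
    holm_adjust,
    ks2d_test,
    permutation_test_1d,
    spearman,
)

#: metadata fields whose small-group contrasts are range-matched by default
SMALL_GROUP_FIELDS = ("vision", "clinical")


@dataclass
class AnalysisConfig:
    """Knobs of a pipeline run.

    ``lm`` may be a :class:`~dreamppl.lms.LanguageModel`; when ``None`` an
    additively smoothed n-gram (``lm_order``, ``lm_alpha``) is fitted on the
    pooled input corpora — symmetric across groups, so it cannot bias a
    two-sample contrast.  ``ks2d_mode`` selects the analytic or permutation
    p-value for the 2D test.  ``holm_family`` lists the test identifiers
    adjusted together; ``None`` means all tests the analysis runs.
    """

    lm: LanguageModel | None = None
    lm_order: int = 2
    lm_alpha: float = 0.5
    window: WindowConfig | None = None
    filter_lo: int = 30
    filter_hi: int = 250
    n_match_iterations: int = 250
    n_permutations: int = 10_000
    alpha: float = 0.05
    ks2d_mode: str = "analytic"
    range_match: bool = True
    holm_family: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k not in ("lm", "window")}
        d["lm"] = type(self.lm).__name__ if self.lm is not None else "pooled-ngram"
        if self.window is not None:
            d["window"] = [self.window.max_length, self.window.stride]
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Full machine-readable result of one analysis run."""

    analysis: str
    per_item: list[dict] = field(default_factory=list)
    whole_corpus_ppl: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    group_summaries: dict = field(default_factory=dict)
    holm_family: list[str] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def per_item_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_item)


def _summary(records: Sequence[PerplexityRecord]) -> dict:
    ppl = np.array([r.ppl for r in records if r.error is None])
    wc = np.array(
        [r.word_count for r in records if r.error is None and r.word_count is not None]
    )
    out = {
        "n": int(ppl.size),
        "ppl_mean": float(ppl.mean()) if ppl.size else None,
        "ppl_sd": float(ppl.std(ddof=1)) if ppl.size > 1 else None,
    }
    if wc.size:
        out["wc_mean"] = float(wc.mean())
        out["wc_sd"] = float(wc.std(ddof=1)) if wc.size > 1 else None
    return out


def _resolve_lm(config: AnalysisConfig, *corpora: Corpus) -> LanguageModel:
    if config.lm is not None:
        return config.lm
    items = [it for c in corpora for it in c]
    return fit_ngram_lm(items, NGramSpec(config.lm_order, config.lm_alpha))


def _apply_holm(tests: dict, family: list[str]) -> None:
    present = [name for name in family if name in tests]
    adjusted = holm_adjust([tests[name]["p_raw"] for name in present])
    for name, adj in zip(present, adjusted):
        tests[name]["p_adjusted"] = adj


def _points(records: Sequence[PerplexityRecord]) -> np.ndarray:
    return np.array(
        [[r.word_count, r.ppl] for r in records if r.error is None], dtype=float
    )


def _clean(records: Sequence[PerplexityRecord]) -> list[PerplexityRecord]:
    return [r for r in records if r.error is None and np.isfinite(r.ppl)]


def compare_corpora(
    corpus_a: Corpus, corpus_b: Corpus, config: AnalysisConfig | None = None
) -> StudyReport:
    """Corpus-level comparison on (word count, perplexity).

    Stages: word-count filters -> matched subsample of the larger corpus
    down to the smaller's size -> per-item perplexity under one model ->
    2D KS test on (word count, perplexity) and 1D permutation test on
    perplexity -> Holm adjustment across the family.
    """
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_match, seed_1d, seed_2d = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    report = StudyReport(analysis="compare_corpora")
    stages = report.stages

    corpora = {}
    for name, corpus in (("a", corpus_a), ("b", corpus_b)):
        n_in = len(corpus)
        filtered = filter_word_count(
            filter_nonempty(corpus), config.filter_lo, config.filter_hi
        )
        if not len(filtered):
            raise InvalidArgumentError(
                f"corpus {name!r} is empty after filtering to "
                f"[{config.filter_lo}, {config.filter_hi}] words"
            )
        corpora[name] = filtered
        stages.append({"stage": f"filter:{name}", "n_in": n_in, "n_out": len(filtered)})

    # cut the larger corpus down to the smaller's size
    a, b = corpora["a"], corpora["b"]
    if len(a) != len(b):
        big, small = ("a", "b") if len(a) > len(b) else ("b", "a")
        match = matched_subsample(
            corpora[big],
            corpora[small],
            n_iterations=config.n_match_iterations,
            seed=seed_match,
            n_permutations=min(config.n_permutations, 1000),
        )
        stages.append(
            {
                "stage": f"matched_subsample:{big}",
                "n_in": len(corpora[big]),
                "n_out": len(match.selected),
                "best_iteration": match.best_iteration,
                "seed": seed_match,
            }
        )
        corpora[big] = match.selected
        a, b = corpora["a"], corpora["b"]

    lm = _resolve_lm(config, a, b)
    window = config.window or default_window(lm)
    rec_a = ppl_per_item(a, lm, window)
    rec_b = ppl_per_item(b, lm, window)
    for name, corpus, recs in (("a", a, rec_a), ("b", b, rec_b)):
        report.whole_corpus_ppl[name] = ppl_corpus_concat(
            corpus, lm, window, item_id=f"corpus:{name}"
        ).ppl
        for r in recs:
            d = r.to_dict()
            d["corpus"] = name
            report.per_item.append(d)
        report.group_summaries[name] = _summary(recs)
    rec_a, rec_b = _clean(rec_a), _clean(rec_b)
    stages.append({"stage": "score", "n_a": len(rec_a), "n_b": len(rec_b)})

    res2d = ks2d_test(
        _points(rec_a),
        _points(rec_b),
        mode=config.ks2d_mode,
        n_permutations=min(config.n_permutations, 1000),
        seed=seed_2d,
    )
    res1d = permutation_test_1d(
        [r.ppl for r in rec_a],
        [r.ppl for r in rec_b],
        n_permutations=config.n_permutations,
        seed=seed_1d,
    )
    report.tests = {"ks2d_wc_ppl": res2d.to_dict(), "perm_ppl": res1d.to_dict()}
    family = config.holm_family or list(report.tests)
    _apply_holm(report.tests, family)
    report.holm_family = family
    report.meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "lm": type(lm).__name__,
        "window": [window.max_length, window.stride],
        "alpha": config.alpha,
    }
    return report


def group_analysis(
    corpus: Corpus,
    group_field: str,
    ppl_records: Sequence[PerplexityRecord],
    config: AnalysisConfig | None = None,
) -> StudyReport:
    """Two-level subgroup contrast within one scored corpus.

    Splits the scored records by ``group_field`` (gender, vision or
    clinical), optionally range-matches the majority pool to the minority
    group's perplexity band (default for the small-group fields), then runs
    the 2D KS test on (word count, perplexity) plus 1D permutation tests on
    perplexity and on word count alone, Holm-adjusted as one family.
    """
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_range, seed_ppl, seed_wc, seed_2d = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    by_id = {it.item_id: it for it in corpus}
    levels: dict[str, list[PerplexityRecord]] = {}
    for rec in _clean(ppl_records):
        item = by_id.get(rec.item_id)
        if item is None:
            continue
        level = getattr(item, group_field, None)
        if level is None:
            continue
        if rec.word_count is None:
            rec.word_count = item.word_count
        levels.setdefault(level, []).append(rec)
    if len(levels) < 2:
        raise InvalidArgumentError(
            f"group field {group_field!r} has {len(levels)} non-missing "
            "level(s); need at least 2"
        )
    # contrast the two largest levels
    (lev1, recs1), (lev2, recs2) = sorted(
        levels.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )[:2]
    report = StudyReport(analysis=f"group:{group_field}")
    report.stages.append(
        {"stage": "split", "levels": {lev1: len(recs1), lev2: len(recs2)}}
    )

    do_range_match = config.range_match and group_field in SMALL_GROUP_FIELDS
    if do_range_match:
        pool, target = (recs1, recs2)  # recs1 is the majority by sort order
        pool = range_matched_sample(pool, target, seed=seed_range)
        report.stages.append(
            {
                "stage": "range_matched_sample",
                "n_in": len(recs1),
                "n_out": len(pool),
                "seed": seed_range,
            }
        )
        recs1 = pool

    for lev, recs in ((lev1, recs1), (lev2, recs2)):
        report.group_summaries[lev] = _summary(recs)
        for r in recs:
            d = r.to_dict()
            d["group"] = lev
            report.per_item.append(d)

    res2d = ks2d_test(
        _points(recs1),
        _points(recs2),
        mode=config.ks2d_mode,
        n_permutations=min(config.n_permutations, 1000),
        seed=seed_2d,
    )
    res_ppl = permutation_test_1d(
        [r.ppl for r in recs1],
        [r.ppl for r in recs2],
        n_permutations=config.n_permutations,
        seed=seed_ppl,
    )
    res_wc = permutation_test_1d(
        [r.word_count for r in recs1],
        [r.word_count for r in recs2],
        n_permutations=config.n_permutations,
        seed=seed_wc,
    )
    report.tests = {
        "ks2d_wc_ppl": res2d.to_dict(),
        "perm_ppl": res_ppl.to_dict(),
        "perm_words": res_wc.to_dict(),
    }
    family = config.holm_family or list(report.tests)
    _apply_holm(report.tests, family)
    report.holm_family = family
    report.meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "group_field": group_field,
        "levels": [lev1, lev2],
        "range_matched": do_range_match,
        "alpha": config.alpha,
    }
    return report


def year_correlation(
    corpus: Corpus, ppl_records: Sequence[PerplexityRecord]
) -> SpearmanResult:
    """Spearman correlation between year of collection and perplexity;
    undated items are excluded."""
    by_id = {it.item_id: it for it in corpus}
    pairs = [
        (by_id[r.item_id].year_mid, r.ppl)
        for r in _clean(ppl_records)
        if r.item_id in by_id and by_id[r.item_id].year_mid is not None
    ]
    if len(pairs) < 3:
        raise InvalidArgumentError(
            f"need at least 3 dated items, found {len(pairs)}"
        )
    years, ppls = zip(*pairs)
    return spearman(years, ppls)


def length_correlation(ppl_records: Sequence[PerplexityRecord]) -> SpearmanResult:
    """Spearman correlation between word count and perplexity."""
    pairs = [
        (r.word_count, r.ppl) for r in _clean(ppl_records) if r.word_count is not None
    ]
    if len(pairs) < 3:
        raise InvalidArgumentError("need at least 3 records with word counts")
    wc, ppls = zip(*pairs)
    return spearman(wc, ppls)


def binned_mean_se(ppl_records: Sequence[PerplexityRecord], bin_width: int = 10):
    """Mean perplexity and standard error by integer word-count bin, as a
    DataFrame — the data behind length-vs-perplexity interaction plots."""
    import pandas as pd

    rows = [
        (r.word_count, r.ppl)
        for r in _clean(ppl_records)
        if r.word_count is not None
    ]
    df = pd.DataFrame(rows, columns=["word_count", "ppl"])
    df["bin"] = (df["word_count"] // bin_width) * bin_width
    g = df.groupby("bin")["ppl"]
    out = g.agg(["mean", "count"])
    out["se"] = g.std(ddof=1) / np.sqrt(out["count"])
    return out.reset_index()


def plot_binned(records_by_label: dict, bin_width: int = 10, ax=None):
    """Optional cosmetic plot of binned mean±SE perplexity per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, recs in records_by_label.items():
        tab = binned_mean_se(recs, bin_width)
        ax.plot(tab["bin"], tab["mean"], label=label)
        ax.fill_between(
            tab["bin"], tab["mean"] - tab["se"], tab["mean"] + tab["se"], alpha=0.3
        )
    ax.set_xlabel("words per item")
    ax.set_ylabel("mean perplexity")
    ax.legend()
    return ax
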