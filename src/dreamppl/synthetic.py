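"""Synthetic corpus generator with controllable entropy, lengths and groups.

The generator emulates the statistical structure the analysis pipeline
assumes of its inputs — two corpora (dream-report-like and reference-like)
with overlapping word-count distributions in the 30–250-word band, per-item
group labels (gender, vision, clinical), and tunable between-group
differences in source entropy and length — while making no attempt at
linguistic realism.

Texts are sampled from Dirichlet-parameterised n-gram sources: every
context's next-token distribution is an independent draw from a symmetric
``Dirichlet(concentration)`` prior, so the concentration parameter controls
source entropy in closed form (small -> peaked, low-entropy, predictable
text; large -> near-uniform, high-entropy text).

Seeding convention: the source table of a group is seeded by
``(source_seed, effective concentration)``, so groups or corpora whose
effective concentrations are equal share *one* source — null configurations
are therefore exactly exchangeable and permutation tests are calibrated by
construction — while different concentrations yield independent sources.
Item-level sampling (lengths, token draws, metadata) is seeded by the
spec's own seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, TextItem
from .errors import InvalidArgumentError
from .lms import BOS, CategoricalNGramLM

_GENDER = {"male", "female"}
_VISION = {"blind", "sighted"}
_CLINICAL = {"clinical", "control"}


@dataclass(frozen=True)
class LengthLaw:
    """Word-count distribution: uniform on [lo, hi], or lognormal(mu, sigma)
    truncated to [lo, hi].  The [30, 250] default matches the word-count
    band the corpus filters keep."""

    kind: str = "uniform"  # "uniform" | "lognormal"
    lo: int = 30
    hi: int = 250
    mu: float = 4.7
    sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise InvalidArgumentError(f"unknown length law {self.kind!r}")
        if not 1 <= self.lo <= self.hi:
            raise InvalidArgumentError("need 1 <= lo <= hi")

    def sample(self, rng: np.random.Generator, shift: int = 0) -> int:
        if self.kind == "uniform":
            n = int(rng.integers(self.lo, self.hi + 1))
        else:
            n = int(round(rng.lognormal(self.mu, self.sigma)))
        return int(np.clip(n + shift, self.lo, self.hi))


@dataclass(frozen=True)
class GroupEffect:
    """Per-group generator effect: the group's source concentration is the
    spec concentration times ``concentration_mult`` (…<1 = more predictable
    text), and its sampled lengths are shifted by ``length_shift`` words
    (clamped to the length law's band)."""

    concentration_mult: float = 1.0
    length_shift: int = 0
    proportion: float | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic corpus."""

    vocab_size: int = 50
    source_order: int = 2
    concentration: float = 1.0
    length_law: LengthLaw = field(default_factory=LengthLaw)
    n_items: int = 100
    group_effects: Mapping[str, GroupEffect] | None = None
    seed: int = 0
    year_range: tuple[int, int] | None = None
    source: str = "synthetic"
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.vocab_size < 2:
            raise InvalidArgumentError("vocab_size must be >= 2")
        if self.source_order < 1:
            raise InvalidArgumentError("source_order must be >= 1")
        if self.concentration <= 0:
            raise InvalidArgumentError("concentration must be positive")
        if self.n_items < 0:
            raise InvalidArgumentError("n_items must be >= 0")


def _source_seed_seq(source_seed: int, concentration: float) -> np.random.SeedSequence:
    # stable derivation: equal effective concentrations share a source
    tag = zlib.crc32(f"{concentration:.12g}".encode())
    return np.random.SeedSequence([int(source_seed) % (2**31), tag])


def _enumerate_contexts(vocab: tuple[str, ...], order: int) -> list[tuple[str, ...]]:
    k = order - 1
    contexts: list[tuple[str, ...]] = []

    def rec(prefix: tuple[str, ...], pad_left: int) -> None:
        if len(prefix) == k:
            contexts.append(prefix)
            return
        if len(prefix) < pad_left:
            rec(prefix + (BOS,), pad_left)
        else:
            for w in vocab:
                rec(prefix + (w,), pad_left)

    for pad in range(k, -1, -1):
        rec((), pad)
    # drop duplicates while preserving order (pad=0 path regenerates none)
    seen = set()
    uniq = []
    for c in contexts:
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    return uniq


def make_source(
    spec: SyntheticSpec,
    concentration: float | None = None,
    source_seed: int | None = None,
) -> CategoricalNGramLM:
    """Draw a Dirichlet-parameterised n-gram source for a spec.

    Every valid context (including BOS-padded start contexts) receives an
    independent ``Dirichlet(concentration * 1_V)`` next-token distribution.
    Deterministic in ``(source_seed, concentration)``.
    """
    conc = spec.concentration if concentration is None else concentration
    if conc <= 0:
        raise InvalidArgumentError("concentration must be positive")
    sseed = spec.seed if source_seed is None else source_seed
    rng = np.random.default_rng(_source_seed_seq(sseed, conc))
    vocab = tuple(f"w{i:03d}" for i in range(spec.vocab_size))
    contexts = _enumerate_contexts(vocab, spec.source_order)
    tables = {
        ctx: rng.dirichlet(np.full(spec.vocab_size, conc)) for ctx in contexts
    }
    return CategoricalNGramLM(spec.source_order, vocab, tables)


def _assign_groups(spec: SyntheticSpec) -> list[str | None]:
    if not spec.group_effects:
        return [None] * spec.n_items
    labels = list(spec.group_effects)
    props = np.array(
        [spec.group_effects[g].proportion or (1.0 / len(labels)) for g in labels]
    )
    props = props / props.sum()
    counts = np.floor(props * spec.n_items).astype(int)
    for i in range(spec.n_items - counts.sum()):  # round-robin remainder
        counts[i % len(labels)] += 1
    assignment: list[str | None] = []
    for lab, c in zip(labels, counts):
        assignment.extend([lab] * int(c))
    return assignment[: spec.n_items]


def generate_corpus(
    spec: SyntheticSpec, source_seed: int | None = None
) -> Corpus:
    """Sample a corpus of ``spec.n_items`` labelled items from the spec's
    Dirichlet n-gram source(s); every word count lies within the length
    law's [lo, hi] band by construction."""
    effects = dict(spec.group_effects or {})
    groups = _assign_groups(spec)
    sources: dict[str | None, CategoricalNGramLM] = {}
    for lab in set(groups):
        mult = effects[lab].concentration_mult if lab is not None else 1.0
        sources[lab] = make_source(
            spec, concentration=spec.concentration * mult, source_seed=source_seed
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), 917]))
    items: list[TextItem] = []
    for i, lab in enumerate(groups):
        shift = effects[lab].length_shift if lab is not None else 0
        length = spec.length_law.sample(rng, shift=shift)
        tokens = sources[lab].sample(length, rng)
        year_raw = None
        if spec.year_range is not None:
            year_raw = str(int(rng.integers(spec.year_range[0], spec.year_range[1] + 1)))
        items.append(
            TextItem(
                item_id=f"{spec.provenance}-{i:06d}",
                text=" ".join(tokens),
                source=spec.source,
                gender=lab if lab in _GENDER else None,
                vision=lab if lab in _VISION else None,
                clinical=lab if lab in _CLINICAL else None,
                series=None if (lab is None or lab in _GENDER | _VISION | _CLINICAL) else lab,
                year_raw=year_raw,
            )
        )
    return Corpus(items=items, provenance=spec.provenance)


def generate_paired_study(
    spec_dream: SyntheticSpec,
    spec_reference: SyntheticSpec,
    source_seed: int | None = None,
) -> tuple[Corpus, Corpus]:
    """Generate a paired study: a dream-like and a reference-like corpus.

    Both corpora draw their sources with the same ``source_seed`` (default:
    ``spec_dream.seed``), so equal concentrations mean a *shared* source (an
    exact null), while different concentrations produce a controlled
    predictability effect with overlapping length distributions.
    """
    sseed = spec_dream.seed if source_seed is None else source_seed
    if spec_dream.vocab_size != spec_reference.vocab_size or (
        spec_dream.source_order != spec_reference.source_order
    ):
        raise InvalidArgumentError(
            "paired specs must share vocab_size and source_order"
        )
    a = generate_corpus(spec_dream, source_seed=sseed)
    b = generate_corpus(spec_reference, source_seed=sseed)
    return a, b
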