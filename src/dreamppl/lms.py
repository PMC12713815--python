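"""Language-model contract and self-contained reference models.

All scoring in this package goes through the :class:`LanguageModel` contract:
a model exposes a deterministic tokenizer and natural-log conditional
probabilities ``log_prob(target, context)`` that are properly normalised over
its vocabulary for every context.  Perplexity (see :mod:`dreamppl.perplexity`)
is defined purely in terms of this contract, so any autoregressive model —
a uniform baseline, an additively smoothed n-gram, a cache-interpolated
n-gram, or a pretrained transformer behind :func:`external_lm_adapter` — can
be plugged into the same pipeline.

Log-probabilities are natural logarithms throughout.

The reference models exist so the whole analysis pipeline is exercisable and
testable without multi-gigabyte pretrained weights; the adapter wraps real
pretrained models when the optional ``transformers``/``torch`` stack is
installed, and fails loudly when it is not.
"""

from __future__ import annotations

import json
import math
import re
from abc import ABC, abstractmethod
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AdapterLoadError, ContractError, InvalidArgumentError

#: Reserved start-of-sequence symbol.  Appears only in contexts, never as a
#: scoring target, so conditional distributions stay normalised over ``vocab``.
BOS = "<s>"

#: Reserved unknown-word symbol; part of the vocabulary of fitted models
#: (unless an explicit vocabulary omits it) so out-of-vocabulary tokens keep
#: distributions proper.
UNK = "<unk>"

#: Reserved end-of-sequence symbol.  Appended to training sequences whenever
#: it is part of the vocabulary, so that every occurrence of a context —
#: including one at the end of a text — has a continuation event and
#: conditional distributions stay normalised.
EOS = "</s>"

NEG_INF = float("-inf")

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def word_tokenize(text: str) -> list[str]:
    """Deterministic reference tokenizer: lowercase, whitespace-delimited,
    with punctuation split off as separate tokens."""
    return _TOKEN_RE.findall(text.lower())


class LanguageModel(ABC):
    """Contract for autoregressive models used by the perplexity machinery.

    Implementations guarantee:

    * ``exp(log_prob)`` sums to 1 (within 1e-9) over ``vocab`` for any
      fixed context;
    * ``log_prob(t, c) <= 0`` everywhere;
    * ``tokenize`` is deterministic.
    """

    #: tokens the model can score (excludes :data:`BOS`)
    vocab: tuple[str, ...]
    #: maximum number of tokens (context plus target) per forward window
    max_context: int
    #: start symbol used to pad the first conditionals, or None
    bos: str | None = BOS

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @abstractmethod
    def log_prob(self, target: str, context: Sequence[str]) -> float:
        """Natural-log probability of ``target`` given the ordered ``context``."""

    def tokenize(self, text: str) -> list[str]:
        return word_tokenize(text)

    def distribution(self, context: Sequence[str]) -> np.ndarray:
        """Probability vector over ``vocab`` for ``context`` (diagnostics)."""
        return np.exp([self.log_prob(t, context) for t in self.vocab])


class UniformLM(LanguageModel):
    """Assigns every vocabulary token probability ``1/vocab_size`` regardless
    of context.  Perplexity of any sequence equals ``vocab_size`` exactly,
    which makes this the analytic oracle for the scoring machinery."""

    def __init__(self, vocab_size: int, max_context: int = 1024) -> None:
        if vocab_size < 1:
            raise InvalidArgumentError(f"vocab_size must be >= 1, got {vocab_size}")
        if max_context < 1:
            raise InvalidArgumentError(f"max_context must be >= 1, got {max_context}")
        self.vocab = tuple(f"w{i}" for i in range(vocab_size))
        self.max_context = max_context
        self._logp = -math.log(vocab_size)

    def log_prob(self, target: str, context: Sequence[str]) -> float:
        return self._logp


@dataclass(frozen=True)
class NGramSpec:
    """Configuration for fitting an additively smoothed n-gram model.

    order
        Markov order: each token is conditioned on the ``order - 1``
        preceding tokens (1 = unigram).
    smoothing_alpha
        Additive (Lidstone) mass added to every count.  Must be positive if
        the model will score events unseen in training; with ``alpha == 0``
        unseen events receive log-probability ``-inf`` (flagged downstream,
        never raised).
    vocab
        Optional explicit vocabulary, honoured verbatim (UNK/EOS behaviour
        applies only if those symbols are included).  Defaults to all
        tokens observed in the training corpus plus UNK and EOS.
    """

    order: int = 2
    smoothing_alpha: float = 0.5
    vocab: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidArgumentError(f"order must be >= 1, got {self.order}")
        if self.smoothing_alpha < 0:
            raise InvalidArgumentError("smoothing_alpha must be nonnegative")


class NGramLM(LanguageModel):
    """Additively smoothed n-gram model over the reference tokenizer.

    Conditional probability of a target ``t`` after context ``c`` (the last
    ``order - 1`` tokens, padded on the left with :data:`BOS`):

        p(t | c) = (count(c, t) + alpha) / (count(c) + alpha * V)

    where ``V`` is the vocabulary size and ``count(c)`` sums the
    continuation events of ``c``.  With the default (inferred) vocabulary,
    UNK and EOS are included and every training text is terminated by an
    EOS event, so ``count(c)`` equals the number of occurrences of the
    context.  An explicit ``NGramSpec.vocab`` is honoured verbatim: UNK and
    EOS behaviours are active only if those symbols are part of it.  BOS is
    never part of ``V``.
    """

    def __init__(
        self,
        order: int,
        alpha: float,
        vocab: Sequence[str],
        counts: Mapping[tuple[str, ...], Mapping[str, int]],
    ) -> None:
        self.order = order
        self.alpha = float(alpha)
        self.vocab = tuple(vocab)
        self.max_context = 1_000_000  # n-gram cost does not grow with context
        self._vocab_set = frozenset(self.vocab)
        self._counts: dict[tuple[str, ...], Counter] = {
            tuple(k): Counter(v) for k, v in counts.items()
        }
        self._totals = {k: sum(v.values()) for k, v in self._counts.items()}

    # -- fitting ---------------------------------------------------------

    @classmethod
    def fit(cls, texts: Iterable[str], spec: NGramSpec) -> "NGramLM":
        token_lists = [word_tokenize(t) for t in texts]
        if not token_lists:
            raise InvalidArgumentError("cannot fit an n-gram model on an empty corpus")
        if spec.vocab is not None:
            vocab = tuple(dict.fromkeys(spec.vocab))
            known = frozenset(vocab)
            if UNK in known:
                token_lists = [
                    [t if t in known else UNK for t in toks] for toks in token_lists
                ]
            else:
                oov = {t for toks in token_lists for t in toks} - known
                if oov:
                    raise InvalidArgumentError(
                        "training corpus contains tokens outside the explicit "
                        f"vocabulary and UNK is not part of it: {sorted(oov)[:5]}"
                    )
        else:
            observed = sorted({t for toks in token_lists for t in toks})
            vocab = tuple(observed + [UNK, EOS])
        if EOS in vocab:
            token_lists = [toks + [EOS] for toks in token_lists]
        pad = (BOS,) * (spec.order - 1)
        counts: dict[tuple[str, ...], Counter] = {}
        for toks in token_lists:
            padded = pad + tuple(toks)
            for i in range(len(toks)):
                ctx = padded[i : i + spec.order - 1]
                counts.setdefault(ctx, Counter())[padded[i + spec.order - 1]] += 1
        return cls(spec.order, spec.smoothing_alpha, vocab, counts)

    # -- scoring ---------------------------------------------------------

    def _normalise_context(self, context: Sequence[str]) -> tuple[str, ...]:
        k = self.order - 1
        ctx = tuple(context)[-k:] if k else ()
        if UNK in self._vocab_set:
            ctx = tuple(
                t if (t in self._vocab_set or t == BOS) else UNK for t in ctx
            )
        if len(ctx) < k:
            ctx = (BOS,) * (k - len(ctx)) + ctx
        return ctx

    def log_prob(self, target: str, context: Sequence[str]) -> float:
        if target in self._vocab_set:
            tgt = target
        elif UNK in self._vocab_set:
            tgt = UNK
        else:
            return NEG_INF  # outside the model's event space
        ctx = self._normalise_context(context)
        c_joint = self._counts.get(ctx, {}).get(tgt, 0)
        c_ctx = self._totals.get(ctx, 0)
        num = c_joint + self.alpha
        den = c_ctx + self.alpha * len(self.vocab)
        if num == 0.0:
            return NEG_INF  # alpha == 0 and unseen event: flagged, not raised
        if den == 0.0:
            return NEG_INF
        return math.log(num) - math.log(den)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "order": self.order,
            "alpha": self.alpha,
            "vocab": list(self.vocab),
            "counts": {
                " ".join(ctx): dict(counter)
                for ctx, counter in self._counts.items()
            },
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NGramLM":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        counts = {
            tuple(k.split(" ")) if k else (): v
            for k, v in payload["counts"].items()
        }
        return cls(payload["order"], payload["alpha"], payload["vocab"], counts)


def make_uniform_lm(vocab_size: int, max_context: int = 1024) -> UniformLM:
    """Uniform model over ``vocab_size`` tokens; analytic scoring oracle."""
    return UniformLM(vocab_size, max_context)


def fit_ngram_lm(corpus: Iterable, spec: NGramSpec) -> NGramLM:
    """Fit an additively smoothed n-gram model on a corpus.

    ``corpus`` may be an iterable of strings, of objects with a ``.text``
    attribute (:class:`dreamppl.corpus_io.TextItem`), or a
    :class:`dreamppl.corpus_io.Corpus`.
    """
    items = getattr(corpus, "items", corpus)
    texts = [getattr(it, "text", it) for it in items]
    return NGramLM.fit(texts, spec)


class CategoricalNGramLM(LanguageModel):
    """N-gram model defined directly by per-context probability tables.

    Used by the synthetic-data generator: each context maps to an explicit
    categorical distribution over the vocabulary, so entropy is controlled
    exactly and sequences can be sampled.  Valid contexts are all
    ``(BOS,)*j + w_1..w_{order-1-j}`` suffix patterns.
    """

    def __init__(
        self,
        order: int,
        vocab: Sequence[str],
        tables: Mapping[tuple[str, ...], np.ndarray],
    ) -> None:
        self.order = order
        self.vocab = tuple(vocab)
        self.max_context = 1_000_000
        self._index = {t: i for i, t in enumerate(self.vocab)}
        self._tables = {tuple(k): np.asarray(v, dtype=float) for k, v in tables.items()}
        self._log_tables = {
            k: np.log(np.maximum(v, 1e-300)) for k, v in self._tables.items()
        }
        self._cum = {k: np.cumsum(v) for k, v in self._tables.items()}

    def _context_key(self, context: Sequence[str]) -> tuple[str, ...]:
        k = self.order - 1
        ctx = tuple(context)[-k:] if k else ()
        if len(ctx) < k:
            ctx = (BOS,) * (k - len(ctx)) + ctx
        return ctx

    def log_prob(self, target: str, context: Sequence[str]) -> float:
        idx = self._index.get(target)
        if idx is None:
            return NEG_INF
        table = self._log_tables.get(self._context_key(context))
        if table is None:
            return NEG_INF
        return float(table[idx])

    def sample(self, length: int, rng: np.random.Generator) -> list[str]:
        """Draw ``length`` tokens by running the Markov chain from BOS."""
        k = self.order - 1
        ctx = (BOS,) * k
        us = rng.random(length)
        out: list[str] = []
        for u in us:
            cum = self._cum[ctx]
            idx = int(np.searchsorted(cum, u * cum[-1], side="right"))
            idx = min(idx, len(self.vocab) - 1)
            tok = self.vocab[idx]
            out.append(tok)
            if k:
                ctx = (ctx + (tok,))[-k:]
        return out


class CacheNGramLM(LanguageModel):
    """Interpolated cache n-gram model (Kuhn & De Mori style).

    Mixes a fixed base model with an additively smoothed n-gram "cache"
    estimated from the tokens already seen in the current context:

        p(t | c) = (1 - lam) * p_base(t | c) + lam * p_cache(t | c)

    For ``cache_order=1`` the cache is the in-context unigram distribution
    ``(count_c(t) + beta) / (len(c) + beta * V)``; for ``cache_order=2`` it
    is the in-context bigram continuation distribution of the last token.
    Both components are proper distributions over the same vocabulary, so
    the mixture is too.  Because the cache sharpens as the context grows,
    later tokens of a document are systematically easier to predict — the
    desk-scale analogue of a large LM exploiting a growing context window,
    and the mechanism by which longer documents obtain lower perplexity
    from the scoring model alone.
    """

    def __init__(
        self,
        base: LanguageModel,
        lam: float = 0.5,
        beta: float = 0.5,
        cache_order: int = 1,
    ) -> None:
        if not 0.0 <= lam <= 1.0:
            raise InvalidArgumentError("interpolation weight lam must be in [0, 1]")
        if beta <= 0:
            raise InvalidArgumentError("cache smoothing beta must be positive")
        if cache_order not in (1, 2):
            raise InvalidArgumentError("cache_order must be 1 or 2")
        self.base = base
        self.lam = float(lam)
        self.beta = float(beta)
        self.cache_order = cache_order
        self.vocab = base.vocab
        self.max_context = base.max_context
        self._vocab_set = frozenset(base.vocab)

    def tokenize(self, text: str) -> list[str]:
        return self.base.tokenize(text)

    def _map(self, t: str) -> str:
        return t if t in self._vocab_set else UNK

    def log_prob(self, target: str, context: Sequence[str]) -> float:
        p_base = math.exp(self.base.log_prob(target, context))
        tgt = self._map(target)
        ctx = [self._map(t) for t in context]
        n = len(ctx)
        v = len(self.vocab)
        if self.cache_order == 1 or n == 0:
            count = sum(1 for t in ctx if t == tgt)
            total = n
        else:
            last = ctx[-1]
            count = sum(
                1 for i in range(n - 1) if ctx[i] == last and ctx[i + 1] == tgt
            )
            total = sum(1 for i in range(n - 1) if ctx[i] == last)
        p_cache = (count + self.beta) / (total + self.beta * v)
        p = (1.0 - self.lam) * p_base + self.lam * p_cache
        return math.log(p) if p > 0 else NEG_INF


def external_lm_adapter(model_name: str, device: str = "cpu") -> LanguageModel:
    """Wrap a pretrained autoregressive transformer behind the contract.

    Requires the optional ``transformers`` + ``torch`` stack (``pip install
    dreamppl[lm]``) and resolvable pretrained weights.  Absence of either is
    a loud :class:`AdapterLoadError` — the pipeline never silently
    substitutes a different model.
    """
    try:
        import torch  # noqa: F401
        from transformers import AutoModelForCausalLM, AutoTokenizer
    except ImportError as exc:  # pragma: no cover - absent in the test env
        raise AdapterLoadError(
            "external_lm_adapter requires the optional 'transformers' and "
            "'torch' packages (install with: pip install dreamppl[lm]); "
            f"import failed: {exc}"
        ) from exc

    try:  # pragma: no cover - requires network/weights
        tokenizer = AutoTokenizer.from_pretrained(model_name)
        model = AutoModelForCausalLM.from_pretrained(model_name).to(device).eval()
    except Exception as exc:  # pragma: no cover
        raise AdapterLoadError(
            f"could not load pretrained weights for {model_name!r}: {exc}"
        ) from exc

    class _TransformerLM(LanguageModel):  # pragma: no cover
        def __init__(self) -> None:
            self.vocab = tuple(
                tokenizer.convert_ids_to_tokens(range(tokenizer.vocab_size))
            )
            self.max_context = int(
                getattr(model.config, "n_positions", None)
                or getattr(model.config, "max_position_embeddings")
            )
            self.bos = tokenizer.bos_token

        def tokenize(self, text: str) -> list[str]:
            return tokenizer.tokenize(text)

        def log_prob(self, target: str, context: Sequence[str]) -> float:
            if len(context) + 1 > self.max_context:
                raise ContractError(
                    f"context of {len(context)} tokens exceeds max_context="
                    f"{self.max_context}; use strided scoring"
                )
            ids = tokenizer.convert_tokens_to_ids(list(context) or [tokenizer.bos_token])
            tgt_id = tokenizer.convert_tokens_to_ids([target])[0]
            with torch.no_grad():
                logits = model(torch.tensor([ids], device=device)).logits[0, -1]
                logp = torch.log_softmax(logits, dim=-1)[tgt_id]
            return float(logp)

    return _TransformerLM()
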