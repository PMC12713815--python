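"""Perplexity of token sequences under a language model.

Perplexity of a sequence ``X = (x_0, ..., x_t)`` is the exponentiated mean
negative log-likelihood

    PPL(X) = exp( -(1/N) * sum_i log p(x_i | x_<i) )

with natural logs and ``N`` the number of scored tokens.  The first token is
conditioned on the model's start symbol (n-gram models pad their context
with BOS), so every token contributes one conditional.

Two scoring modes are provided.  ``single`` scores a sequence that fits in
one model window, conditioning every token on its full in-sequence prefix.
``strided`` slides a fixed-size window by a stride, scoring in each window
only the tokens not already scored and conditioning them on the preceding
tokens *inside* the window; this trades context for compute on sequences
longer than the model's window.  For sequences that fit in one window the
two modes coincide exactly.

Zero-probability events yield infinite perplexity carried on a flagged
record rather than an exception, so one pathological item cannot abort a
corpus run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ContractError, InvalidArgumentError
from .lms import NEG_INF, LanguageModel

DEFAULT_STRIDE = 512


@dataclass(frozen=True)
class WindowConfig:
    """Strided-window geometry: ``max_length`` tokens per window (context
    plus target), advanced by ``stride`` tokens."""

    max_length: int
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise InvalidArgumentError("max_length must be >= 1")
        if not 1 <= self.stride <= self.max_length:
            raise InvalidArgumentError(
                f"stride must be in [1, max_length], got stride={self.stride}, "
                f"max_length={self.max_length}"
            )


def default_window(lm: LanguageModel) -> WindowConfig:
    """Stride-512 window at the model's maximum context size."""
    return WindowConfig(
        max_length=lm.max_context, stride=min(DEFAULT_STRIDE, lm.max_context)
    )


@dataclass
class PerplexityRecord:
    """Per-sequence perplexity together with how it was computed.

    ``ppl`` is positive, and infinite iff a zero-probability token occurred
    (``zero_prob`` flag).  ``n_windows`` counts model forward windows, the
    quantity the stride trades off.  ``error`` is set (and ``ppl`` is NaN)
    when an item could not be scored, e.g. an over-length item in
    single-window mode.
    """

    item_id: str
    ppl: float
    n_scored_tokens: int
    mode: str  # "single" | "strided"
    window: WindowConfig | None = None
    n_windows: int = 1
    zero_prob: bool = False
    word_count: int | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        d = {
            "item_id": self.item_id,
            "ppl": self.ppl,
            "n_scored_tokens": self.n_scored_tokens,
            "mode": self.mode,
            "n_windows": self.n_windows,
            "zero_prob": self.zero_prob,
            "word_count": self.word_count,
            "error": self.error,
        }
        if self.window is not None:
            d["max_length"] = self.window.max_length
            d["stride"] = self.window.stride
        return d


def _finish(nll: float, n: int, saw_zero: bool) -> tuple[float, bool]:
    if saw_zero:
        return math.inf, True
    return math.exp(nll / n), False


def ppl_single(
    seq: Sequence[str], lm: LanguageModel, item_id: str = ""
) -> PerplexityRecord:
    """Score a sequence in one window, each token conditioned on its full
    prefix.  Requires ``len(seq) <= lm.max_context``."""
    tokens = list(seq)
    if not tokens:
        raise InvalidArgumentError("cannot score an empty sequence")
    if len(tokens) > lm.max_context:
        raise ContractError(
            f"sequence of {len(tokens)} tokens exceeds max_context="
            f"{lm.max_context}; use ppl_strided"
        )
    nll = 0.0
    saw_zero = False
    for i, tok in enumerate(tokens):
        lp = lm.log_prob(tok, tokens[:i])
        if lp == NEG_INF:
            saw_zero = True
        else:
            nll -= lp
    ppl, flagged = _finish(nll, len(tokens), saw_zero)
    return PerplexityRecord(
        item_id=item_id,
        ppl=ppl,
        n_scored_tokens=len(tokens),
        mode="single",
        zero_prob=flagged,
    )


def ppl_strided(
    seq: Sequence[str],
    lm: LanguageModel,
    window: WindowConfig,
    item_id: str = "",
) -> PerplexityRecord:
    """Score a sequence with strided sliding windows.

    Windows of ``window.max_length`` tokens advance by ``window.stride``; in
    each window only the tokens not covered by a previous window are scored,
    conditioned on the tokens before them within the window.  Equals
    :func:`ppl_single` exactly whenever the sequence fits in one window.
    """
    tokens = list(seq)
    if not tokens:
        raise InvalidArgumentError("cannot score an empty sequence")
    n = len(tokens)
    nll = 0.0
    scored = 0
    n_windows = 0
    saw_zero = False
    prev_end = 0
    for begin in range(0, n, window.stride):
        end = min(begin + window.max_length, n)
        n_windows += 1
        for i in range(prev_end, end):
            lp = lm.log_prob(tokens[i], tokens[begin:i])
            if lp == NEG_INF:
                saw_zero = True
            else:
                nll -= lp
            scored += 1
        prev_end = end
        if end == n:
            break
    ppl, flagged = _finish(nll, scored, saw_zero)
    return PerplexityRecord(
        item_id=item_id,
        ppl=ppl,
        n_scored_tokens=scored,
        mode="strided",
        window=window,
        n_windows=n_windows,
        zero_prob=flagged,
    )


def ppl_corpus_concat(
    items: Iterable,
    lm: LanguageModel,
    window: WindowConfig | None = None,
    item_id: str = "corpus",
) -> PerplexityRecord:
    """Whole-corpus perplexity: items joined into one long string (newline
    separated; the reference tokenizer treats the newline as whitespace, so
    items are simply abutted) and scored with strided windows."""
    texts = [getattr(it, "text", it) for it in items]
    if not texts:
        raise InvalidArgumentError("cannot score an empty corpus")
    tokens = lm.tokenize("\n".join(texts))
    win = window if window is not None else default_window(lm)
    rec = ppl_strided(tokens, lm, win, item_id=item_id)
    return rec


def ppl_per_item(
    items: Iterable,
    lm: LanguageModel,
    window: WindowConfig | None = None,
) -> list[PerplexityRecord]:
    """Single-window perplexity per item, order preserving.

    Items that exceed the window (rare by construction: the corpus filters
    keep texts far below any model's window) are recorded as error entries
    rather than aborting the run.
    """
    win = window if window is not None else default_window(lm)
    out: list[PerplexityRecord] = []
    for idx, it in enumerate(items):
        text = getattr(it, "text", it)
        item_id = getattr(it, "item_id", str(idx))
        wc = getattr(it, "word_count", None)
        tokens = lm.tokenize(text)
        if len(tokens) > win.max_length:
            out.append(
                PerplexityRecord(
                    item_id=item_id,
                    ppl=math.nan,
                    n_scored_tokens=0,
                    mode="single",
                    window=win,
                    word_count=wc,
                    error=f"item has {len(tokens)} tokens > max_length={win.max_length}",
                )
            )
            continue
        rec = ppl_single(tokens, lm, item_id=item_id)
        rec.window = win
        rec.word_count = wc
        out.append(rec)
    return out


def records_to_jsonl(records: Iterable[PerplexityRecord]) -> str:
    """Serialize records as JSON-lines (one record object per line)."""
    import json

    return "\n".join(json.dumps(r.to_dict(), sort_keys=True) for r in records)
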