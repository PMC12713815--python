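"""Corpus containers, JSON-lines / text-directory I/O, filters, and
year-of-collection parsing.

A corpus is an ordered list of :class:`TextItem` records — one document per
record, with the metadata fields dream-report collections carry (gender,
year of collection, series, vision and clinical status).  Word counts are
tokenizer-independent whitespace counts of the raw text, computed on load;
they predate (and are deliberately distinct from) any model tokenization.

The year-of-collection annotations of dream archives are free-form strings
("1985", "1897–1918", "Mid-1980s", "?").  :func:`convert_year` maps them to
a single integer by midpoint/decade rules, with an explicit exception map
for the handful of archive entries whose published conversion does not
follow the rules.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

from .errors import InvalidArgumentError

_DASHES = re.compile(r"[–—−]")  # normalise unicode dashes in spans

#: Archive rows whose published integer conversion does not follow the
#: midpoint/decade rules; reproduced verbatim rather than guessed at.
YEAR_EXCEPTIONS: dict[str, int] = {
    "1999": 2010,
    "1940s-1950s & 1990s": 1960,
}


@dataclass
class TextItem:
    """One document (dream report, reference article, or synthetic text).

    ``word_count`` is the whitespace word count of ``text`` and is computed
    automatically when not supplied.  ``year_mid`` is derived from
    ``year_raw`` via :func:`convert_year` when not supplied.
    """

    item_id: str
    text: str
    word_count: int | None = None
    source: str = "synthetic"  # "dream" | "reference" | "synthetic"
    gender: str | None = None  # "male" | "female"
    year_raw: str | None = None
    year_mid: int | None = None
    series: str | None = None
    vision: str | None = None  # "blind" | "sighted"
    clinical: str | None = None  # "clinical" | "control"

    def __post_init__(self) -> None:
        if self.word_count is None:
            self.word_count = len(self.text.split())
        if self.year_mid is None and self.year_raw is not None:
            self.year_mid = convert_year(self.year_raw)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass
class Corpus:
    """Ordered collection of items with unique ids."""

    items: list[TextItem] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})[:5]
            raise InvalidArgumentError(f"duplicate item_ids in corpus: {dup}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[TextItem]:
        return iter(self.items)

    def __getitem__(self, i: int) -> TextItem:
        return self.items[i]

    def word_counts(self) -> list[int]:
        return [it.word_count for it in self.items]


_FIELDS = {
    "item_id", "text", "word_count", "source", "gender",
    "year_raw", "year_mid", "series", "vision", "clinical",
}


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from a JSON-lines file or a directory of .txt files.

    ``format`` is ``"jsonl"`` or ``"text_dir"``; inferred from the path when
    omitted.  JSON-lines records must carry a ``"text"`` field; malformed
    records raise with their line number.
    """
    p = Path(path)
    if format is None:
        format = "text_dir" if p.is_dir() else "jsonl"
    if format == "text_dir":
        items = [
            TextItem(item_id=f.stem, text=f.read_text(encoding="utf-8"))
            for f in sorted(p.glob("*.txt"))
        ]
        return Corpus(items=items, provenance=str(p))
    if format != "jsonl":
        raise InvalidArgumentError(f"unknown corpus format: {format!r}")
    items = []
    with open(p, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise InvalidArgumentError(
                    f"{p}:{lineno}: malformed JSON record: {exc}"
                ) from exc
            if "text" not in rec:
                raise InvalidArgumentError(
                    f"{p}:{lineno}: record is missing the 'text' field"
                )
            rec = {k: v for k, v in rec.items() if k in _FIELDS}
            rec.setdefault("item_id", f"item{lineno:06d}")
            items.append(TextItem(**rec))
    return Corpus(items=items, provenance=str(p))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as UTF-8 JSON-lines, one object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for it in corpus:
            fh.write(json.dumps(it.to_dict(), sort_keys=True) + "\n")


_HEADING = re.compile(r"^\s*(=+[^=]*=*\s*$|#{1,6}\s)")


def _is_empty_or_title_only(text: str) -> bool:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        return True
    # drop a leading heading line ("= Title =", "# Title"); empty remainder
    # means the record is title-only
    if _HEADING.match(lines[0]):
        lines = lines[1:]
    return not any(ln.strip() for ln in lines)


def filter_nonempty(corpus: Corpus) -> Corpus:
    """Drop items whose body is empty or consists only of a title line."""
    return Corpus(
        items=[it for it in corpus if not _is_empty_or_title_only(it.text)],
        provenance=corpus.provenance,
    )


def filter_word_count(corpus: Corpus, lo: int, hi: int) -> Corpus:
    """Keep items with ``lo <= word_count <= hi`` (inclusive bounds), in
    stable order.  The canonical analysis band is [30, 250] words."""
    if lo > hi:
        raise InvalidArgumentError(f"lo must be <= hi, got lo={lo}, hi={hi}")
    return Corpus(
        items=[it for it in corpus if lo <= it.word_count <= hi],
        provenance=corpus.provenance,
    )


def _parse_point(token: str) -> int | None:
    """One endpoint: '1985', '1990s', 'Mid-1980s', 'Late 1990s'."""
    t = token.strip().lower().replace("-", " ")
    m = re.fullmatch(r"(?:(mid|late|early)\s+)?(\d{4})(s?)", t)
    if not m:
        return None
    qualifier, year, decade = m.group(1), int(m.group(2)), m.group(3)
    if decade:
        if qualifier == "mid":
            return year + 5
        if qualifier == "late":
            return year + 8
        if qualifier == "early":
            return year + 2
        return year
    return year


def convert_year(year_raw: str | None) -> int | None:
    """Convert a free-form year-of-collection string to an integer year.

    Rules: a single year maps to itself; a span "A–B" maps to
    ``floor((A+B)/2)``; decade phrases map to the decade start ("1990s" →
    1990), mid-decade ("Mid-1980s" → 1985) or late decade ("Late 1990s" →
    1998).  Unparsable strings (including "?") map to ``None``.  A small
    exception map reproduces archive rows that deviate from these rules.
    """
    if year_raw is None:
        return None
    key = _DASHES.sub("-", str(year_raw).strip())
    if key in YEAR_EXCEPTIONS:
        return YEAR_EXCEPTIONS[key]
    parts = [p for p in key.split("-") if p != ""]
    # re-join decade phrases split by their own hyphen ("Mid-1980s")
    if len(parts) == 2 and parts[0].lower() in ("mid", "late", "early"):
        parts = [f"{parts[0]} {parts[1]}"]
    if len(parts) == 1:
        return _parse_point(parts[0])
    if len(parts) == 2:
        a, b = _parse_point(parts[0]), _parse_point(parts[1])
        if a is None or b is None:
            return None
        return (a + b) // 2
    return None


def attach_year_mid(corpus: Corpus) -> Corpus:
    """Recompute ``year_mid`` from ``year_raw`` for every item."""
    for it in corpus:
        it.year_mid = convert_year(it.year_raw)
    return corpus
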