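import numpy as np
import pytest

from dreamppl import Corpus, TextItem
from dreamppl.lms import LanguageModel


class CertaintyLM(LanguageModel):
    """Degenerate stub assigning probability 1 to every queried token.

    Not a proper distribution — used only to pin down the ppl == 1 limit.
    """

    def __init__(self, vocab_size: int = 4, max_context: int = 4096) -> None:
        self.vocab = tuple(f"w{i}" for i in range(vocab_size))
        self.max_context = max_context

    def log_prob(self, target, context):
        return 0.0


def make_word_corpus(word_counts, prefix="it", provenance="wc") -> Corpus:
    """Corpus whose items have exactly the given whitespace word counts."""
    items = [
        TextItem(item_id=f"{prefix}{i}", text=" ".join(["tok"] * int(n)))
        for i, n in enumerate(word_counts)
    ]
    return Corpus(items=items, provenance=provenance)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_corpus():
    return Corpus(
        items=[
            TextItem("d1", "i was walking in a garden full of red flowers",
                     source="dream", gender="female", year_raw="1985–1997"),
            TextItem("d2", "a dog chased me down the street and i could not run",
                     source="dream", gender="male", year_raw="1962"),
            TextItem("d3", "the house was my house but also not my house",
                     source="dream", gender="female", year_raw="?"),
            TextItem("d4", "we flew over the city at night without any plane",
                     source="dream", gender="male", year_raw="Mid-1980s"),
        ],
        provenance="toy",
    )
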