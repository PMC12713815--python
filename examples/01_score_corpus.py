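"""Score per-item perplexity of a synthetic dream-like corpus.

Generates a small corpus from a Dirichlet-parameterised bigram source, fits
an additively smoothed bigram model on it, and prints each item's
perplexity: the exponentiated mean negative log-likelihood of its tokens.
Lower perplexity = more predictable text.
"""

import numpy as np

from dreamppl import NGramSpec, SyntheticSpec, fit_ngram_lm, generate_corpus, ppl_per_item

spec = SyntheticSpec(n_items=8, vocab_size=50, concentration=0.5, seed=7, provenance="demo")
corpus = generate_corpus(spec)
lm = fit_ngram_lm(corpus, NGramSpec(order=2, smoothing_alpha=0.5))
records = ppl_per_item(corpus, lm)

print(f"{'item':<12} {'words':>5} {'tokens':>6} {'ppl':>8}")
for item, rec in zip(corpus, records):
    print(f"{rec.item_id:<12} {item.word_count:>5} {rec.n_scored_tokens:>6} {rec.ppl:>8.2f}")
print(f"\nmean ppl = {np.mean([r.ppl for r in records]):.2f}  "
      "(how surprising the corpus is, on average, to the scoring model)")
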