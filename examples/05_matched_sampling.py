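"""Distribution-matched subsampling of a large pool to a reference size.

Draws 100 random candidate subsets of the pool, scores each against the
reference with a permutation test on word counts, and keeps the least
diverging one — the procedure used to cut a large report archive down to a
reference corpus's size without confounding the comparison by length.
"""

import numpy as np

from dreamppl import Corpus, TextItem, matched_subsample

rng = np.random.default_rng(0)

# pool and reference share the 30-250-word band with slightly different
# shapes, the situation the filters are designed to leave behind
pool_wc = rng.integers(30, 251, size=600)
ref_wc = np.clip(rng.normal(130, 45, size=80).astype(int), 30, 250)
pool = Corpus([TextItem(f"p{i}", "w " * int(n)) for i, n in enumerate(pool_wc)], "pool")
ref = Corpus([TextItem(f"r{i}", "w " * int(n)) for i, n in enumerate(ref_wc)], "ref")

result = matched_subsample(pool, ref, n_iterations=100, seed=1, n_permutations=499)

it, stat, p = result.candidate_stats[result.best_iteration]
print(f"pool mean words      = {np.mean(pool.word_counts()):.1f}")
print(f"reference mean words = {np.mean(ref.word_counts()):.1f}")
print(f"selected subset mean = {np.mean(result.selected.word_counts()):.1f}")
print(f"winning iteration {it}: |mean diff| = {stat:.2f}, permutation p = {p:.3f}")
print("(the selected subset is the candidate whose word-count distribution")
print(" diverges least from the reference, i.e. with the largest p)")
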