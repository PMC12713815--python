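"""Compare a dream-like corpus against a reference corpus end to end.

The dream-like corpus is generated from a lower-entropy (more predictable)
source than the reference, with the same length distribution — emulating
the scenario where dream reports are easier for a language model to predict
than encyclopedia articles of similar length.  The pipeline filters both
corpora to the 30-250-word band, matches sizes, scores per-item perplexity,
and tests the joint (word count, perplexity) distributions (2D KS) and the
perplexity margins (permutation test), Holm-correcting the family.
"""

from dreamppl import AnalysisConfig, SyntheticSpec, compare_corpora, generate_paired_study

spec_dream = SyntheticSpec(
    n_items=150, concentration=0.4, seed=11, provenance="dream", source="dream"
)
spec_ref = SyntheticSpec(
    n_items=200, concentration=2.0, seed=12, provenance="wiki", source="reference"
)
dream, wiki = generate_paired_study(spec_dream, spec_ref)

config = AnalysisConfig(n_permutations=2000, n_match_iterations=50, seed=1)
report = compare_corpora(dream, wiki, config)

print("whole-corpus perplexity (items concatenated into one string):")
for name, ppl in report.whole_corpus_ppl.items():
    print(f"  corpus {name}: {ppl:.2f}")
print("\nper-item summaries:")
for name, s in report.group_summaries.items():
    print(f"  corpus {name}: n={s['n']}  mean ppl={s['ppl_mean']:.2f} "
          f"(sd {s['ppl_sd']:.2f})  mean words={s['wc_mean']:.1f}")
print("\ntests (Holm-adjusted within the family):")
for name, t in report.tests.items():
    print(f"  {name}: statistic={t['statistic']:.3f}  p={t['p_raw']:.4g}  "
          f"p_holm={t['p_adjusted']:.4g}")
print("\nA significant 2D test says the joint length/perplexity clouds differ; "
      "the 1D test attributes it to perplexity specifically.")
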