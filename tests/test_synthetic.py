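"""Synthetic corpus generator: entropy control, lengths, group effects."""

import math

import numpy as np
import pytest

from dreamppl import (
    GroupEffect,
    LengthLaw,
    NGramSpec,
    SyntheticSpec,
    filter_word_count,
    fit_ngram_lm,
    generate_corpus,
    generate_paired_study,
    make_source,
    permutation_test_1d,
    ppl_per_item,
    ppl_single,
    spearman,
)
from dreamppl.errors import InvalidArgumentError


class TestMakeSource:
    def test_near_zero_concentration_is_near_deterministic(self, rng):
        spec = SyntheticSpec(vocab_size=20, concentration=1e-4, seed=3)
        src = make_source(spec)
        toks = src.sample(200, rng)
        rec = ppl_single(toks, src)
        assert rec.ppl < 1.2

    def test_same_seed_same_tables(self, rng):
        spec = SyntheticSpec(vocab_size=10, concentration=0.7, seed=11)
        a, b = make_source(spec), make_source(spec)
        probe = [("w003", ["w001"]), ("w000", ["w009"]), ("w005", [])]
        assert [a.log_prob(t, c) for t, c in probe] == [
            b.log_prob(t, c) for t, c in probe
        ]

    def test_flat_prior_binary_vocab_entropy_near_one_bit(self, rng):
        # high concentration -> near-uniform binary source -> ~1 bit/token
        spec = SyntheticSpec(vocab_size=2, source_order=1, concentration=500.0, seed=5)
        src = make_source(spec)
        toks = src.sample(10_000, rng)
        p1 = np.mean([t == src.vocab[0] for t in toks])
        entropy_bits = -(p1 * math.log2(p1) + (1 - p1) * math.log2(1 - p1))
        assert abs(entropy_bits - 1.0) < 0.05

    def test_equal_concentration_shares_source_across_specs(self):
        a = SyntheticSpec(vocab_size=8, concentration=1.5, seed=100)
        b = SyntheticSpec(vocab_size=8, concentration=1.5, seed=200)
        sa = make_source(a, source_seed=42)
        sb = make_source(b, source_seed=42)
        assert sa.log_prob("w001", ["w000"]) == sb.log_prob("w001", ["w000"])


class TestGenerateCorpus:
    def test_word_counts_always_in_band(self):
        spec = SyntheticSpec(n_items=60, seed=2, length_law=LengthLaw("uniform", 30, 250))
        corpus = generate_corpus(spec)
        assert len(filter_word_count(corpus, 30, 250)) == len(corpus) == 60

    def test_lognormal_lengths_clamped_to_band(self):
        spec = SyntheticSpec(
            n_items=60, seed=2, length_law=LengthLaw("lognormal", 30, 250)
        )
        assert all(30 <= it.word_count <= 250 for it in generate_corpus(spec))

    def test_zero_items_empty_corpus(self):
        assert len(generate_corpus(SyntheticSpec(n_items=0, seed=1))) == 0

    def test_seed_determinism(self):
        spec = SyntheticSpec(n_items=10, seed=77)
        a, b = generate_corpus(spec), generate_corpus(spec)
        assert [i.text for i in a] == [i.text for i in b]

    def test_group_labels_populate_metadata_fields(self):
        spec = SyntheticSpec(
            n_items=20,
            seed=4,
            group_effects={"male": GroupEffect(), "female": GroupEffect()},
        )
        genders = {it.gender for it in generate_corpus(spec)}
        assert genders == {"male", "female"}

    def test_length_shift_moves_group_word_counts(self):
        spec = SyntheticSpec(
            n_items=200,
            seed=8,
            length_law=LengthLaw("uniform", 30, 120),
            group_effects={
                "male": GroupEffect(length_shift=-25),
                "female": GroupEffect(length_shift=25),
            },
        )
        corpus = generate_corpus(spec)
        wc = {g: [] for g in ("male", "female")}
        for it in corpus:
            wc[it.gender].append(it.word_count)
        assert np.mean(wc["male"]) < np.mean(wc["female"])

    def test_low_entropy_group_scores_lower_ppl(self):
        """Groups differing only in source concentration separate in mean
        perplexity under a held-out-fitted scoring model, replicate after
        replicate."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            effects = {
                "male": GroupEffect(concentration_mult=0.2),
                "female": GroupEffect(concentration_mult=5.0),
            }
            spec = SyntheticSpec(
                n_items=60, seed=9000 + rep, group_effects=effects, provenance="t"
            )
            heldout = SyntheticSpec(
                n_items=40, seed=19000 + rep, group_effects=effects, provenance="h"
            )
            corpus = generate_corpus(spec)
            fit_corpus = generate_corpus(heldout, source_seed=spec.seed)
            lm = fit_ngram_lm(fit_corpus, NGramSpec(order=2, smoothing_alpha=0.5))
            recs = ppl_per_item(corpus, lm)
            means = {}
            for it, r in zip(corpus, recs):
                means.setdefault(it.gender, []).append(r.ppl)
            hits += np.mean(means["male"]) < np.mean(means["female"])
        assert hits / n_rep >= 0.95

    def test_no_length_entropy_coupling_by_construction(self):
        """With a single group, realised length is independent of the
        (single) source: the generator cannot leak a length-predictability
        correlation of its own."""
        spec = SyntheticSpec(n_items=300, seed=15)
        corpus = generate_corpus(spec)
        src = make_source(spec)
        # per-item ppl under the TRUE source: no systematic length trend
        recs = ppl_per_item(corpus, src)
        res = spearman([it.word_count for it in corpus], [r.ppl for r in recs])
        assert abs(res.rho) < 0.12


class TestPairedStudy:
    def test_same_spec_same_seed_identical(self):
        spec = SyntheticSpec(n_items=15, seed=33)
        a, b = generate_paired_study(spec, spec)
        assert [i.text for i in a] == [i.text for i in b]

    def test_identical_specs_different_seeds_usually_null(self):
        """Same generating conditions, fresh item draws: the perplexity
        permutation test should stay non-significant in most replicates."""
        nonsig = 0
        n_rep = 25
        for rep in range(n_rep):
            sa = SyntheticSpec(n_items=40, seed=40000 + 2 * rep, provenance="a")
            sb = SyntheticSpec(n_items=40, seed=40001 + 2 * rep, provenance="b")
            ca, cb = generate_paired_study(sa, sb)
            lm = fit_ngram_lm(
                list(ca) + list(cb), NGramSpec(order=2, smoothing_alpha=0.5)
            )
            pa = [r.ppl for r in ppl_per_item(ca, lm)]
            pb = [r.ppl for r in ppl_per_item(cb, lm)]
            res = permutation_test_1d(pa, pb, n_permutations=199, seed=rep)
            nonsig += res.p_raw > 0.05
        assert nonsig / n_rep >= 0.9

    def test_entropy_effect_without_length_effect(self):
        """Concentration differs, lengths share one law: the word-count test
        stays null while the perplexity test fires."""
        sa = SyntheticSpec(n_items=150, concentration=0.3, seed=71, provenance="a")
        sb = SyntheticSpec(n_items=150, concentration=3.0, seed=72, provenance="b")
        ca, cb = generate_paired_study(sa, sb)
        lm = fit_ngram_lm(list(ca) + list(cb), NGramSpec(order=2, smoothing_alpha=0.5))
        pa = [r.ppl for r in ppl_per_item(ca, lm)]
        pb = [r.ppl for r in ppl_per_item(cb, lm)]
        res_ppl = permutation_test_1d(pa, pb, n_permutations=499, seed=1)
        res_wc = permutation_test_1d(
            [float(i.word_count) for i in ca],
            [float(i.word_count) for i in cb],
            n_permutations=499,
            seed=2,
        )
        assert res_ppl.p_raw <= 0.05
        assert res_wc.p_raw > 0.05

    def test_incompatible_vocabularies_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_paired_study(
                SyntheticSpec(vocab_size=10), SyntheticSpec(vocab_size=20)
            )

    def test_entropy_monotonicity_of_mean_ppl(self):
        """Mean per-item perplexity increases with source concentration
        under one fixed scoring model."""
        levels = (0.2, 1.0, 5.0)
        corpora = {}
        for c in levels:
            spec = SyntheticSpec(
                n_items=40, concentration=c, seed=55, provenance=f"c{c}"
            )
            corpora[c] = generate_corpus(spec, source_seed=999)
        lm = fit_ngram_lm(
            [it for c in corpora.values() for it in c],
            NGramSpec(order=2, smoothing_alpha=0.5),
        )
        means = [
            np.mean([r.ppl for r in ppl_per_item(corpora[c], lm)]) for c in levels
        ]
        assert means[0] < means[1] < means[2]
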