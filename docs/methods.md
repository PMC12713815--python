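# Methods

## The question the pipeline answers

Given two corpora of short documents — dream reports and a reference of
more formally structured text, or two subgroups of one report collection —
are the documents of one systematically more *predictable* to an
autoregressive language model than the documents of the other?
Predictability is measured by perplexity, and "systematically" is decided
by nonparametric two-sample tests on the per-document scores.

## Perplexity

For a token sequence `X = (x_0, …, x_t)` under a model with conditional
probabilities `p(x_i | x_<i)`,

    PPL(X) = exp( −(1/N) Σ_i log p(x_i | x_<i) ),

with natural logarithms and `N` the number of scored tokens.  Choices made
where the definition leaves room:

* **First token.** `x_0` is conditioned on a reserved start symbol (n-gram
  models left-pad their context with BOS), so all `N` tokens contribute one
  conditional and `PPL` is defined for length-1 sequences.
* **Averaging unit.** The mean is per *model token*.  Whitespace word
  counts are carried separately as metadata; they drive the corpus filters
  and the length axes of the analyses, never the denominator of the score.
* **Zero-probability events** (possible only with unsmoothed models) give
  an infinite score on a flagged record instead of an exception, so one
  pathological document cannot abort a corpus run.  Flagged records are
  excluded from the statistical stages.
* **Two modes.** Documents that fit in one model window are scored in
  `single` mode, each token conditioned on its full in-document prefix —
  the primary mode, since filtered documents (≤ 250 words) are far below
  any realistic window.  Longer sequences (notably whole-corpus
  concatenations) use `strided` mode: windows of `max_length` tokens
  advance by `stride` (default 512), each window scoring only tokens not
  scored before, conditioned on the preceding tokens inside the window.
  When a sequence fits one window the two modes coincide exactly, and the
  suite holds strided scoring to a brute-force window-enumeration oracle at
  1e-9 relative.
* **Corpus concatenation** joins documents with a newline; the reference
  tokenizer treats it as whitespace, so reference-model corpus scores see
  the documents abutted.  A subword tokenizer behind the external adapter
  sees a real newline token.

## Language models

All scoring goes through one contract: a deterministic `tokenize`, a
vocabulary, and natural-log `log_prob(target, context)` normalised over
the vocabulary for every context.  Self-contained reference models make
the pipeline testable with no pretrained weights:

* **Uniform** — every token `1/V`; perplexity of anything is exactly `V`,
  the analytic oracle for the scoring machinery.
* **Additively smoothed n-gram** — `p(t|c) = (count(c,t)+α) /
  (count(c)+αV)`.  The reference tokenizer lowercases, splits on
  whitespace and splits punctuation off.  With an inferred vocabulary, UNK
  and EOS are included and every training text ends with an EOS event, so
  `count(c)` equals the number of occurrences of the context and every
  conditional, including at text ends, is a proper distribution.  An
  explicit vocabulary is honoured verbatim (no symbols injected).  Default
  α = 0.5, a neutral midpoint between add-one (too flat for small
  vocabularies) and tiny-α (near-ML, brittle on unseen events); α = 0 is
  allowed and yields flagged −inf log-probabilities on unseen events.
* **Categorical n-gram** — explicit per-context probability tables; the
  synthetic generator's source class (below), also usable as a scorer.
* **Cache-interpolated n-gram** (Kuhn–De Mori) — mixes a fixed base model
  with an in-context cache, `(1−λ)·p_base + λ·p_cache`, cache either the
  unigram distribution of the preceding tokens or (``cache_order=2``) the
  continuation distribution of the last token.  Defaults λ = 0.5,
  β = 0.5 (cache smoothing).  This is the desk-scale analogue of a large
  model exploiting its growing context window.
* **External adapter** — wraps a pretrained causal transformer behind the
  same contract via the optional `transformers`/`torch` extra.  A missing
  backend or unresolvable weights raise immediately; the pipeline never
  substitutes silently.  Adapter numerics are outside the test surface,
  which by design needs no downloads.

## Corpus handling

Documents carry the metadata of dream archives: gender, free-form year of
collection, series, vision and clinical status.  Word counts are
whitespace counts of the raw text, computed on load.  Filters: drop
empty/title-only records (a leading `= Title =` or `# Title` line with
nothing after it), then keep documents with 30–250 words inclusive — the
band in which report and reference length distributions overlap.
Inclusivity of both bounds is a documented reading of "between 30 and
250"; the filters are idempotent and order-stable.

Year strings parse by rules — single year; span `A–B` → `floor((A+B)/2)`;
`YYYYs` → decade start; `Mid-/Late-` → +5/+8 — plus a two-row exception
map for archive entries whose published conversions deviate from any rule
("1999" → 2010, "1940s–1950s & 1990s" → 1960).  The exceptions are
reproduced, not rationalised.  Unparsable strings (including "?") become
missing values and drop out of year analyses.

## Matched sampling

When two corpora differ in size, the larger is cut to the smaller's size
by random search: `n_iterations` (default 250) candidate subsets are drawn
uniformly without replacement (independently across iterations), each
compared to the reference with the 1D permutation test on word counts, and
the candidate with the largest p-value wins — "least diverging"
operationalised as maximal permutation p, since the permutation test is
the comparison criterion.  Ties break toward the smaller observed
statistic, then the earlier iteration.  The full candidate log (iteration,
statistic, p) is kept for audit, and the whole procedure is
seed-deterministic.  Note the search selects among *uniform* subsets: it
equalises distributions that already overlap (the post-filter situation it
is designed for) and cannot synthesise a match between disjoint ones.

Small-group contrasts (vision, clinical) instead match on the *range* of
the already-computed perplexity scores: the majority pool is restricted to
the minority group's [min, max] perplexity band, then sampled uniformly at
the minority's size (all eligible records if fewer; zero overlap is an
explicit error).  Equal sample sizes keep the downstream two-sample tests
simple; the matched-size choice is this package's, as is exposing the
unmatched variant through configuration.

## Statistics

* **1D permutation test.**  Statistic `|mean(a) − mean(b)|` (two-sided by
  construction; the minimal-assumption default, logged in the result).
  Monte-Carlo p-value with the add-one rule `p = (1 + #{null ≥ obs}) /
  (1 + B)`, valid at any `B`; default `B` = 10 000.  An exact mode
  enumerates all `C(n1+n2, n1)` assignments for small inputs and returns
  the plain proportion.
* **2D Kolmogorov–Smirnov** (Fasano–Franceschini variant of the Peacock
  test).  Quadrants are centred at each data point of each sample;
  `D_k` is the maximal absolute difference of empirical quadrant fractions
  over sample `k`'s centers; `D = (D_1 + D_2)/2 ∈ [0, 1]`.  Boundary
  points, the center included, count toward the closed lower/left
  quadrants — the convention of the classic `quadct` routine, applied
  identically in the implementation and the test oracle.  A consequence
  worth knowing: because a center always occupies its own closed quadrant,
  same-quadrant separation tops out at `1 − 1/(2n)`, and `D = 1` is
  attained only when each sample has a center whose off-diagonal quadrant
  is center-free.  P-values: permutation mode (pool, re-split, recompute,
  add-one rule) or the large-sample analytic approximation
  `Q_KS(D√n̄ / (1 + √(1−r̄²)(0.25 − 0.75/√n̄)))` with `n̄ = n1·n2/(n1+n2)`
  and `r̄²` the mean squared per-sample Pearson correlation; effective
  n̄ < 20 attaches an unreliability warning.  The suite checks analytic
  against permutation agreement within 0.05 on 100-point clouds.
* **Spearman correlation** — tie-averaged ranks with the large-sample t
  approximation (delegated to scipy); constant inputs return a flagged
  missing value.
* **Holm step-down** — `adj_(i) = max_{j≤i} min(1, (m−j+1)·p_(j))`,
  returned in input order; cross-checked against statsmodels.  Which tests
  form a family is a configuration field (`holm_family`); by default each
  analysis adjusts exactly the tests it runs (2D + 1D perplexity for a
  corpus comparison; 2D + perplexity + word count for a group contrast),
  and every adjusted p in a report is traceable to its family.

## Synthetic data

The generator emulates the *statistical* structure the pipeline assumes —
never linguistic content.  Sources are n-gram models (default bigram over
a 50-word vocabulary) whose per-context next-token distributions are
independent draws from a symmetric Dirichlet(κ): small κ gives peaked,
low-entropy, repetitive text; large κ near-uniform, high-entropy text.
Document lengths are uniform on [30, 250] words by default (truncated
lognormal available), so every generated document survives the word-count
filter.  Groups are labels (gender/vision/clinical metadata) carrying two
effects: a concentration multiplier (entropy) and a length shift, with no
built-in coupling between length and entropy — so any length–perplexity
correlation in an analysis is attributable to scoring, which the suite
exploits.

Seeding: a group's source table is seeded by *(source seed, effective
concentration)*.  Groups or paired corpora with equal effective
concentrations therefore share one source, making null configurations
exactly exchangeable — permutation calibration holds by construction —
while different concentrations give independent, systematically different
sources.  Item-level draws use the spec's own seed.  A consequence: two
groups with *different* concentrations get independent sources, so even
nearby multipliers can separate sharply under a discriminating scorer;
null checks should use equal multipliers.

## What the measurements show

All quantities below are computed by the test suite and
`scripts/acceptance.py` at run time; problem sizes are chosen so the whole
suite runs in a couple of minutes on one core.

* Scoring: uniform-model identity (exactly V), certainty identity
  (exactly 1), single/strided equivalence, and brute-force-oracle
  agreement (50 random model/sequence/window combinations, 1e-9 relative).
* 2D KS: double-loop-oracle agreement on 100 random pairs (n, m ≤ 30),
  tie-heavy integer grids included.
* Permutation test: exact-enumeration agreement on 6-element inputs;
  type-I error within [0.03, 0.07] at α = 0.05 over 1000 null replicates
  (n = 30/30, B = 199); power > 0.9 against a 1-SD shift at n = 50.
* Holm: closed-form agreement on randomized vectors, ordering and
  monotonicity preserved.
* Matched sampling: with the pool drawn from the reference's word-count
  distribution (uniform 30–250, pool 250, reference 50) and 100
  iterations, the selected subset's p exceeds 0.05 in ≥ 95 of 100 runs.
* Effect recovery: two groups differing only in source concentration
  (multipliers 0.2 vs 5.0, 30 documents per group, scorer fit on 40
  held-out documents from the same sources) are detected — right
  direction and significant 1D test — in ≥ 95 of 100 replicates.  Null
  pipelines (shared source, fresh item draws, 30 + 30 documents) reject
  within [0.02, 0.08] of nominal α = 0.05; 500 replicates put the
  measurement's Monte-Carlo sd (~1 %) well inside that ± 3 % band, and an
  independent 1000-replicate measurement of the same configuration gave
  0.058.
* Direction phenomena: a fixed cache-interpolated scorer (unigram base fit
  on 120 held-out documents, bigram cache, λ = 0.5) over 400
  variable-length documents from one common κ = 0.3 source yields a
  negative length–perplexity Spearman correlation (ρ ≈ −0.6 at these
  conditions) — sign reproduced from scoring alone, no magnitude claim.
  A fixed *n-gram* scorer shows none (|ρ| < 0.1), which is exactly the
  point: the correlation needs a growing-context scorer, not a generator
  artifact.

## What passing these tests does not show

Synthetic sources are stationary n-gram processes with no semantics,
discourse structure, topic drift or vocabulary burstiness beyond what a
Dirichlet bigram induces; group labels carry only the two planted effects.
Results on real dream reports additionally depend on the pretrained model
(via the external adapter), its tokenizer, and corpus idiosyncrasies none
of which are modelled here.  The suite validates the *machinery* —
scoring, matching, testing, correction — and the directions it forces by
construction, not any empirical claim about real corpora.

## Known limitations

* Per-token `log_prob` calls make the reference path O(n²) in document
  length for the cache model; fine at ≤ 250 words, not meant for long
  documents.
* The analytic 2D KS p-value is a large-sample approximation; below
  effective n ≈ 20 it is flagged and the permutation mode should be used.
* The external adapter scores one token per forward pass; it is a contract
  reference, not an efficient batch scorer.
* `matched_subsample` is random search, faithful to the procedure it
  implements; it is not an optimal matching and degrades gracefully (best
  of the candidates) when pool and reference distributions differ
  strongly.
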