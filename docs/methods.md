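# Methods

## The process model

A code is a deterministic map `L` from a finite meaning set to strings
over an alphabet Σ; a source `p_M` weights the meanings. The analyzed
object is the stationary process obtained by sampling meanings i.i.d.,
emitting `s = L(m)`, and concatenating the forms in both directions with a
single reserved delimiter `#` ∉ Σ between consecutive forms. Observation
is at a uniformly random symbol position, which is equivalent to drawing a
form with probability reweighted by `|s| + 1` (its symbols plus its
delimiter) and then a position within `s·#` uniformly.

Non-injective codes are allowed in the core: meanings that share a form
have their probabilities summed when the process is built. Analyses that
presuppose unambiguity (the bijection enumeration, the meaning-permutation
baselines) assert injectivity explicitly. Zero-probability meanings are
dropped; they cannot affect any process statistic.

### n-gram statistics and the exact truncation

Because forms are independent given the delimiter, conditioning past a
delimiter adds nothing: every length-n window statistic equals its
delimiter-padded within-form version. The n-window table therefore
collects, for each form, one window ending at each symbol of `s·#`,
left-padded with delimiters where the window would cross the form start
(window weight ∝ `prob(s)`). The conditional entropy is

```
h_n = H[window] − H[context],
```

where the context is the window's first `n − 1` symbols — including the
all-delimiter context that arises at a form's first symbol. `h_1` is the
marginal symbol entropy. (Taking the difference of the n- and (n−1)-window
tables instead would *not* converge: for uniform-length forms those two
tables carry the same partition from `n = L_max + 1` on, which would force
the tail differences to zero rather than to the entropy rate. The
context-marginal formula is the direct transcription of
`h_n = H[X_t | X_{t−n+1..t−1}]` and matches brute-force estimates from
sampled streams, which the tests check.)

Once the context reaches back to the previous delimiter — at
`n = L_max + 2`, with `L_max` the longest form — `h_n` is constant, so the
entropy rate is `h = h_{L_max+2}` (the implementation verifies
`h_{L_max+3} = h_{L_max+2}` to 1e-12) and

```
E = Σ_{n=1}^{L_max+1} (h_n − h)
```

is an exact finite sum, not a truncation approximation.

### The independent oracle

E is also the mutual information between past and future at a stationary
cut. Drawing (form `s`, cut `k ∈ 0..|s|`) with weight `prob(s)/Z`, the
prefix `s[:k]` is a sufficient statistic of the entire past and the suffix
`s[k:]·#` of the entire future, so `E = I[prefix : suffix]`. This
computation shares no code path with the h-series route; the two agree to
~1e-14 on random instances (tested at 1e-9 over 200 instances).

### Numerical conventions

All logarithms are base 2; results are in bits. Distribution checks use
float64 with tolerance 1e-12 (sum-to-one is validated at 1e-9 for
user-supplied tables, then renormalized); probabilities below 1e-15 are
treated as zero; oracle equality is asserted at 1e-9; the convergence and
invariance checks at 1e-12. E is clipped at zero when round-off produces
values like −1e-16. Degenerate inputs: an empty-string form contributes
only its delimiter position; a one-form process has `h = 0` and
`E = log2`-scale information about the position phase only.

The engine packs windows into integers (delimiter = 0, last symbol least
significant, so the context marginal is a `// base` grouping). Small code
spaces use a dense bincount; large alphabets (word-level analyses, long
forms) switch to an incremental scheme that prepends one symbol per level
and re-compresses ids, recovering the context of a window at position `j`
as the one-shorter window at `j − 1`. Ranked-table ties are broken by a
stable sort on (E, code identifier). The position-scramble enumeration
evaluates one member of each time-reversal pair and shares the value
(reversal invariance is exact and separately tested); the order
enumeration for the hierarchical source computes all 720 orders because
its reversal-tie claim is itself under test.

## Sources

* Coin flips: `Bernoulli(2/3) × Bernoulli(2/3+ε) × Bernoulli(2/3+2ε)`,
  default ε = 0.05.
* Tied coins: `p_α(ijk) = p(i)·[(1−α) p(j)p(k) + (α/2)δ_jk]`; α moves
  I[M2:M3] from 0 to 1 bit.
* Zipfian: `p(m_i) ∝ (i+1)^−1` (exponent configurable).
* Hierarchical: six five-valued variables mixed through nested couplings
  (α = 0.01, β = 0.20, γ = 0.99); every `q(·)` over a multi-variable
  domain is a Zipfian over the lexicographically ordered product set —
  the natural reading when only "Zipfian over its domain" is fixed.
* Empirical: probability ∝ count + s. With s > 0 (default 1/2) the
  support is the full cross-product of attested feature values, so unseen
  paradigm cells receive mass; with s = 0 only observed tuples (used for
  phrase tables).

## Candidate codes in the tied-coin sweep

The holistic two-letter block for a pair of bits is `(x XOR y, y)`: any
bijection of two bits onto two letters necessarily has one letter that is
a single input bit (up to complement), so "holistic" here means the other
letter is the parity, the maximally mixed choice. The same block is
applied to the natural grouping (M2,M3) and the unnatural grouping
(M1,M2), keeping total length 3. A consequence of ε > 0 is that at α = 0
exactly — where all three coins are independent and no grouping is
favored by the source — the natural block sits on the *more biased* pair
and therefore carries slightly more inter-letter correlation than the
unnatural one (~0.009 bits). The meaningful orderings are: the fully
systematic code is the minimum at α = 0, and the natural block code is
strictly better than the unnatural one for every α > 0, overtaking the
systematic code as the coupling grows.

## Corpus pipelines

Permutation p-values are `#(E_baseline < E_attested)/n_samples` with a
strict inequality, so ties count against the attested forms
(conservative). Letter-level analyses treat every character — stem
dummies X/Y/Z, whitespace, diacritic-bearing characters — as one symbol;
the whitespace in adjective–noun forms participates in the non-local
scramble like any other symbol. The non-local baseline draws one
permutation per form length per sample, shared by all forms of that
length, keeping the scramble a deterministic function of the form while
covering length heterogeneity. The manner-preserving scramble seeds each
word's permutation from (global seed, word string), so identical words
scramble identically across a lexicon and the manner-class skeleton is
preserved exactly.

Noun-phrase order analysis works at the word level (words are atomic
symbols) over all 24 arrangements of determiner / numeral / adjective /
noun; reversed orders tie exactly, leaving 12 distinct values. When a
typology table is supplied, the fit is ordinary least squares of the
natural-log genus count on E with the Pearson correlation reported;
orders with zero genus count are excluded (log undefined) — a recorded
limitation. No typology counts ship with the package; a schema and the
four-row example phrase table are included
(`predinfo/data/example_phrases.tsv`).

Norm binarization thresholds each feature at its unweighted mean across
words (strictly greater → 1); constant features binarize to all-zero with
a warning. Cross-word MI uses the verb–object pair distribution; the
"within" matrix averages the verb-side and object-side feature MIs under
that same distribution.

The CoNLL-U reader is a minimal parser for the 10-column tab format
(comments, multiword ranges and empty nodes skipped; malformed lines
reported with their line number). Extraction rules: adjacent `amod`
ADJ–NOUN wordform pairs in linear order; noun phrases as a NOUN head
lemma with `det`/`nummod`/`amod` dependent lemmas, one adjective kept at
random (seeded) when several modify the same noun; `obj` NOUN dependents
of VERB heads.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical premises* of the corpus inputs,
not their content:

* **Paradigm** (agglutinative): form = stem dummy `X` + one suffix per
  feature in fixed order; each feature marks value 0 with a zero suffix
  and other values with a feature-specific vowel plus a fixed per-slot
  number of consonants (2/3/2/1 characters for number / case / possessor
  / definiteness), which makes concatenation provably unambiguous while
  different marked-feature combinations still mix within a form-length
  class. Counts are a
  multinomial draw from a product of Zipfian per-feature marginals
  (features approximately independent). The fusional control replaces the
  suffix structure with random fused suffixes of similar lengths; its
  length-matched baseline p-values are accordingly unremarkable.
* **Lexicon**: CV-syllable words whose vowel depends on the preceding
  consonant and whose syllable-initial consonant depends on the previous
  one, each with probability `strictness` (default 0.9). These are
  exactly the local dependencies a manner-preserving scramble destroys;
  at strictness 0 the scramble is statistically neutral.
* **Phrases**: Zipfian nouns; determiner/numeral/adjective present with
  fixed slot probabilities and values following a deterministic per-noun
  preference with the slot's coupling probability (determiner–noun
  strongest by default, 0.9), so the minimum-E order places D adjacent
  to the noun.
* **Norms**: content features copy a per-word latent class with flip
  probability 0.15; the number feature is an independent Bernoulli;
  verb–object pairs agree in latent class with probability
  `0.5 + coupling/2`. Norm-word frequencies use a milder skew (Zipf
  exponent 0.6 over 600 words): under a full Zipf(1) weighting the
  effective sample size of the weighted MI estimates grows only
  logarithmically and the generator's premise would fail for occasional
  seeds by estimator noise alone; the real norm datasets emulated here
  are orders of magnitude larger.

What passing tests on these inputs shows is that the *pipelines* draw the
expected conclusions when their statistical premises hold; it does not
show that any particular natural language satisfies those premises —
that requires the real treebanks, vocabulary lists and norm datasets,
which the pipelines accept in the same TSV/CoNLL-U formats but which are
not redistributed here.

## Problem sizes

Default analysis sizes: 8-meaning coin-flip codes (40,320 bijections
enumerated exhaustively), 100-meaning Zipfian source with length-8 forms
(40,320 position scrambles), 15,625-meaning hierarchical source (720
orders), paradigms of 96 cells, lexica of 250 words, phrase tables from
20,000 observations, 630 norm words. Baseline ensembles default to 10,000
samples in the CLI; the packaged end-to-end checks run them at 1,000
samples, which already separates the attested configurations from the
baselines by wide margins.

## Known limitations

* Only within-utterance predictive information is modeled; processes with
  divergent long-range E (connected text) and hidden-state constructions
  are out of scope.
* E is symmetric under time reversal, so the analyses cannot distinguish
  mirror-image orders; reports flag reversal pairs instead.
* The systematicity score counts features with a dedicated bijective
  position; graded or distributed systematicity is not measured.
* The regression in the word-order analysis drops zero-count orders.
* Smoothing (add-1/2) is not scale-free: multiplying all paradigm counts
  by a constant shifts E slightly (the smoothing mass shrinks relative to
  the data); the tests compare at matched scales.
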