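"""Seeded generators for paradigm, lexicon, phrase and semantic-norm tables.

The generators emulate the *statistical premises* of the corresponding
corpus inputs — concatenative suffixal morphology with near-independent
Zipfian feature marginals, local phonotactic co-occurrence constraints,
noun phrases whose determiner choice depends on the noun, and semantic
norms whose content features share a latent class while a number feature
stays independent — without attempting lexical realism. Every generator is
a pure function of its configuration (bit-identical re-runs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_pipeline import NormMatrix
from .sources import zipf_probs


@dataclass(frozen=True)
class GeneratorConfig:
    """Sizes and structure strengths for all synthetic inputs.

    Coupling/strictness values live in [0, 1]; 0 removes the corresponding
    statistical structure and 1 makes it deterministic.
    """

    seed: int = 0
    # paradigm (suffixal morphology)
    paradigm_mode: str = "agglutinative"  # or "fusional"
    feature_names: tuple[str, ...] = ("number", "case", "possessor", "definiteness")
    feature_cardinalities: tuple[int, ...] = (2, 8, 3, 2)
    # marked-suffix length (vowel + consonants) per feature slot
    suffix_lengths: tuple[int, ...] = (2, 3, 2, 1)
    paradigm_total_count: int = 50_000
    # lexicon (phonotactics)
    n_words: int = 250
    min_syllables: int = 1
    max_syllables: int = 3
    strictness: float = 0.9
    # noun phrases
    n_phrase_obs: int = 20_000
    n_nouns: int = 25
    n_dets: int = 3
    n_nums: int = 3
    n_adjs: int = 8
    p_det: float = 0.6
    p_num: float = 0.08
    p_adj: float = 0.35
    det_noun_coupling: float = 0.9
    adj_noun_coupling: float = 0.4
    num_noun_coupling: float = 0.1
    # semantic norms
    n_norm_words: int = 600
    n_content_features: int = 10
    n_latent_classes: int = 2
    content_flip: float = 0.15
    p_number: float = 0.35
    n_verbs: int = 30
    n_pair_obs: int = 4000
    pair_coupling: float = 0.2
    zipf_exponent: float = 1.0
    # frequency skew used for norm words; milder than full Zipf so the
    # weighted MI estimates keep a usable effective sample size
    norm_freq_exponent: float = 0.6

    def __post_init__(self) -> None:
        for name in ("strictness", "det_noun_coupling", "adj_noun_coupling",
                     "num_noun_coupling", "content_flip", "pair_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_words, self.n_nouns, self.n_norm_words, self.n_phrase_obs) < 1:
            raise ValueError("sizes must be >= 1")


# ---------------------------------------------------------------------------
# morphological paradigms
# ---------------------------------------------------------------------------

_SUFFIX_VOWELS = "aeiou"
_SUFFIX_CONSONANTS = "ktnmrslzgd"


def _agglutinative_suffixes(config: GeneratorConfig, rng) -> list[list[str]]:
    """One suffix per feature value: the zero value is unmarked (empty
    suffix); marked values are a feature-specific vowel plus consonants of a
    fixed per-feature length (an affix slot has a characteristic shape;
    different marked-feature combinations still mix within a form-length
    class because slot lengths differ). The feature-specific vowel makes
    concatenations unambiguous."""
    if len(config.suffix_lengths) != len(config.feature_cardinalities):
        raise ValueError("need one suffix length per feature")
    suffixes = []
    for f, card in enumerate(config.feature_cardinalities):
        n_cons = config.suffix_lengths[f] - 1
        if card > 2 and n_cons < 1:
            raise ValueError(
                f"feature {f}: cardinality {card} needs suffix length >= 2"
            )
        vowel = _SUFFIX_VOWELS[f % len(_SUFFIX_VOWELS)]
        per_value = [""]
        used = set()
        for v in range(1, card):
            while True:
                cons = "".join(rng.choice(list(_SUFFIX_CONSONANTS), size=n_cons))
                if cons not in used:
                    used.add(cons)
                    break
            per_value.append(vowel + cons)
        suffixes.append(per_value)
    return suffixes


def gen_paradigm(config: GeneratorConfig) -> pd.DataFrame:
    """A complete noun paradigm table (feature columns, ``form``, ``count``).

    Agglutinative mode: form = stem dummy ``X`` plus one suffix per feature
    in fixed order. Fusional mode (control): a single fused random suffix
    per feature tuple, with a similar form-length distribution but no
    feature-wise structure. Counts are a multinomial draw from a product of
    Zipfian feature marginals, so features are approximately independent.
    """
    rng = np.random.default_rng([config.seed, 101])
    cards = config.feature_cardinalities
    cells = list(itertools.product(*(range(c) for c in cards)))
    marginals = [zipf_probs(c, config.zipf_exponent) for c in cards]
    joint = np.array([np.prod([marginals[f][v] for f, v in enumerate(cell)]) for cell in cells])
    counts = rng.multinomial(config.paradigm_total_count, joint / joint.sum())

    if config.paradigm_mode == "agglutinative":
        suffixes = _agglutinative_suffixes(config, rng)
        forms = ["X" + "".join(suffixes[f][v] for f, v in enumerate(cell)) for cell in cells]
    elif config.paradigm_mode == "fusional":
        agg = _agglutinative_suffixes(config, rng)
        lengths = [sum(len(agg[f][v]) for f, v in enumerate(cell)) for cell in cells]
        forms = []
        used: set[str] = set()
        alphabet = list(_SUFFIX_CONSONANTS + _SUFFIX_VOWELS)
        for L in lengths:
            while True:
                s = "X" + "".join(rng.choice(alphabet, size=max(L, 1)))
                if s not in used:
                    used.add(s)
                    break
            forms.append(s)
    else:
        raise ValueError(f"unknown paradigm mode {config.paradigm_mode!r}")
    if len(set(forms)) != len(forms):
        raise RuntimeError("generated paradigm is not injective")
    data = {
        name: [cell[f] for cell in cells] for f, name in enumerate(config.feature_names)
    }
    data["form"] = forms
    data["count"] = counts
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# phonemic lexicon
# ---------------------------------------------------------------------------

PHONEME_MANNERS = {
    "p": "stop", "t": "stop", "k": "stop", "b": "stop", "d": "stop", "g": "stop",
    "f": "fric", "s": "fric", "v": "fric", "z": "fric",
    "m": "nas", "n": "nas",
    "l": "liq", "r": "liq",
    "a": "vow", "e": "vow", "i": "vow", "o": "vow", "u": "vow",
}

_CONSONANTS = [p for p, m in PHONEME_MANNERS.items() if m != "vow"]
_VOWELS = [p for p, m in PHONEME_MANNERS.items() if m == "vow"]


def gen_lexicon(config: GeneratorConfig) -> pd.DataFrame:
    """A vocabulary list with local phonotactic constraints.

    Words are CV syllable sequences. With probability ``strictness`` each
    vowel is determined by the preceding consonant and each syllable-initial
    consonant by the previous syllable's consonant (fixed preference maps);
    otherwise segments are drawn freely. High strictness creates strong
    adjacent-segment statistics that a manner-class-preserving scramble
    destroys; at strictness 0 the scramble is statistically neutral.
    Columns: ``word``, ``phonemes``, ``manners``, ``frequency`` (Zipfian).
    """
    rng = np.random.default_rng([config.seed, 202])
    pref_vowel = {c: _VOWELS[i % len(_VOWELS)] for i, c in enumerate(_CONSONANTS)}
    pref_next = {c: _CONSONANTS[(i + 3) % len(_CONSONANTS)] for i, c in enumerate(_CONSONANTS)}
    words: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    guard = 0
    while len(words) < config.n_words:
        guard += 1
        if guard > 100 * config.n_words:
            raise RuntimeError("phonotactic sampler failed to produce enough types")
        n_syll = int(rng.integers(config.min_syllables, config.max_syllables + 1))
        segs: list[str] = []
        prev_c = None
        for _ in range(n_syll):
            if prev_c is not None and rng.random() < config.strictness:
                c = pref_next[prev_c]
            else:
                c = _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            v = (
                pref_vowel[c]
                if rng.random() < config.strictness
                else _VOWELS[int(rng.integers(len(_VOWELS)))]
            )
            segs.extend((c, v))
            prev_c = c
        w = tuple(segs)
        if w not in seen:
            seen.add(w)
            words.append(w)
    freq = zipf_probs(len(words), config.zipf_exponent)
    return pd.DataFrame(
        {
            "word": ["".join(w) for w in words],
            "phonemes": [" ".join(w) for w in words],
            "manners": [" ".join(PHONEME_MANNERS[p] for p in w) for w in words],
            "frequency": freq,
        }
    )


# ---------------------------------------------------------------------------
# noun phrase tables
# ---------------------------------------------------------------------------


def gen_phrase_table(config: GeneratorConfig) -> pd.DataFrame:
    """Noun-phrase counts with configurable slot-value coupling to the noun.

    Nouns are Zipfian; a determiner / numeral / adjective is present with
    its slot probability, and its value either follows a deterministic
    per-noun preference (with the slot's coupling probability) or is drawn
    uniformly. Defaults make the determiner-noun dependence strongest.
    Columns: ``determiner``, ``numeral``, ``adjective``, ``noun``, ``count``.
    """
    rng = np.random.default_rng([config.seed, 303])
    nouns = [f"n{i}" for i in range(config.n_nouns)]
    dets = [f"d{i}" for i in range(config.n_dets)]
    nums = [f"m{i}" for i in range(config.n_nums)]
    adjs = [f"a{i}" for i in range(config.n_adjs)]
    pref = {
        "det": {n: dets[int(rng.integers(len(dets)))] for n in nouns},
        "num": {n: nums[int(rng.integers(len(nums)))] for n in nouns},
        "adj": {n: adjs[int(rng.integers(len(adjs)))] for n in nouns},
    }
    p_noun = zipf_probs(len(nouns), config.zipf_exponent)
    counts: dict[tuple, int] = {}
    slots = (
        ("det", dets, config.p_det, config.det_noun_coupling),
        ("num", nums, config.p_num, config.num_noun_coupling),
        ("adj", adjs, config.p_adj, config.adj_noun_coupling),
    )
    for _ in range(config.n_phrase_obs):
        noun = nouns[int(rng.choice(len(nouns), p=p_noun))]
        values = []
        for name, inventory, p_present, coupling in slots:
            if rng.random() >= p_present:
                values.append("")
            elif rng.random() < coupling:
                values.append(pref[name][noun])
            else:
                values.append(inventory[int(rng.integers(len(inventory)))])
        key = (*values, noun)
        counts[key] = counts.get(key, 0) + 1
    rows = [list(k) + [c] for k, c in sorted(counts.items())]
    return pd.DataFrame(
        rows, columns=["determiner", "numeral", "adjective", "noun", "count"]
    )


def gen_adjnoun_pairs(config: GeneratorConfig) -> pd.DataFrame:
    """Adjective-noun pair counts with selectional dependence, as a
    letter-level input (columns ``word1``, ``word2``, ``count``).

    Word forms are short CV strings so that the pair table supports a
    character-level analysis; each noun prefers one adjective with
    probability ``adj_noun_coupling``.
    """
    rng = np.random.default_rng([config.seed, 404])

    def cv_word(prefix_pool):
        return "".join(
            prefix_pool[int(rng.integers(len(prefix_pool)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(int(rng.integers(1, 3)))
        )

    def distinct_words(n):
        out: list[str] = []
        seen: set[str] = set()
        while len(out) < n:
            w = cv_word(_CONSONANTS)
            if w not in seen:
                seen.add(w)
                out.append(w)
        return out

    nouns = distinct_words(config.n_nouns)
    adjs = distinct_words(config.n_adjs)
    p_noun = zipf_probs(len(nouns), config.zipf_exponent)
    pref = {n: adjs[int(rng.integers(len(adjs)))] for n in nouns}
    counts: dict[tuple, int] = {}
    for _ in range(config.n_phrase_obs // 4):
        noun = nouns[int(rng.choice(len(nouns), p=p_noun))]
        if rng.random() < config.adj_noun_coupling:
            adj = pref[noun]
        else:
            adj = adjs[int(rng.integers(len(adjs)))]
        counts[(adj, noun)] = counts.get((adj, noun), 0) + 1
    rows = [list(k) + [c] for k, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["word1", "word2", "count"])


# ---------------------------------------------------------------------------
# semantic norms
# ---------------------------------------------------------------------------


def gen_semantic_norms(config: GeneratorConfig) -> NormMatrix:
    """Binary norm features with correlated content and independent number.

    Content features copy a per-word latent class (flipped with probability
    ``content_flip``), so they are mutually informative; the ``number``
    feature is an independent Bernoulli. Verb-object pairs couple the two
    words' latent classes with probability ``0.5 + pair_coupling/2`` of
    agreement, making within-word feature MI exceed across-word MI.
    """
    if config.n_content_features < 2:
        raise ValueError("need at least two content features")
    rng = np.random.default_rng([config.seed, 505])
    words = [f"w{i}" for i in range(config.n_norm_words)]
    verbs = [f"v{i}" for i in range(config.n_verbs)]
    all_words = words + verbs
    if config.n_latent_classes == 1:
        z = {w: 0 for w in all_words}
        base = 0.5  # features pure noise: independent
    else:
        z = {w: int(rng.integers(2)) for w in all_words}
        base = None
    feats = {}
    for w in all_words:
        row = []
        for _ in range(config.n_content_features):
            if base is not None:
                row.append(int(rng.random() < base))
            else:
                bit = z[w]
                if rng.random() < config.content_flip:
                    bit = 1 - bit
                row.append(bit)
        row.append(int(rng.random() < config.p_number))
        feats[w] = row
    names = [f"content{i}" for i in range(config.n_content_features)] + ["number"]
    features = pd.DataFrame.from_dict(feats, orient="index", columns=names)
    freqs = pd.Series(
        np.concatenate(
            [zipf_probs(len(words), config.norm_freq_exponent),
             zipf_probs(len(verbs), config.norm_freq_exponent)]
        )
        / 2.0,
        index=all_words,
    )
    # verb-object pairs: object class agrees with verb class with
    # probability 0.5 + pair_coupling / 2
    nouns_by_class: dict[int, list[str]] = {0: [], 1: []}
    for w in words:
        nouns_by_class[z[w]].append(w)
    if any(not v for v in nouns_by_class.values()):
        nouns_by_class = {0: words, 1: words}
    p_verb = zipf_probs(len(verbs), config.zipf_exponent)
    counts: dict[tuple, int] = {}
    for _ in range(config.n_pair_obs):
        v = verbs[int(rng.choice(len(verbs), p=p_verb))]
        cls = z[v] if rng.random() < 0.5 + config.pair_coupling / 2 else 1 - z[v]
        pool = nouns_by_class[cls]
        o = pool[int(rng.integers(len(pool)))]
        counts[(v, o)] = counts.get((v, o), 0) + 1
    pairs = pd.DataFrame(
        [list(k) + [c] for k, c in sorted(counts.items())],
        columns=["verb", "object", "count"],
    )
    return NormMatrix(features=features, frequencies=freqs, pairs=pairs)
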