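"""Attested-vs-baseline pipelines on small hand-written fixtures."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from predinfo.corpus_pipeline import (
    BaselineEnsemble,
    adjnoun_test,
    binarize_norms,
    cross_word_feature_mi,
    extract_from_conllu,
    morphology_test,
    NormMatrix,
    pairwise_feature_mi,
    phonotactics_test,
    word_order_analysis,
)

# a miniature suffixal paradigm in the style of an agglutinating noun:
# number x case, stem dummy X, dative plural "Xoknak"
HUNGARIAN_STYLE = pd.DataFrame(
    {
        "number": [0, 0, 0, 1, 1, 1],
        "case": [0, 1, 2, 0, 1, 2],
        "form": ["X", "Xot", "Xnak", "Xok", "Xokot", "Xoknak"],
        "count": [500, 120, 60, 180, 40, 20],
    }
)

# templatic root-and-pattern forms with three stem dummies (broken plural)
ARABIC_STYLE = pd.DataFrame(
    {
        "number": [0, 0, 1, 1],
        "case": [0, 1, 0, 1],
        "form": ["XaYZun", "XaYZin", "'aXYāZun", "'aXYāZin"],
        "count": [300, 100, 80, 30],
    }
)


class TestMorphology:
    def test_suffixal_fixture_runs(self):
        ens = morphology_test(HUNGARIAN_STYLE, n_samples=50, seed=0)
        assert np.isfinite(ens.E_attested)
        assert set(ens.p) == {"nonlocal", "unnatural", "length_matched"}
        assert all(0.0 <= p <= 1.0 for p in ens.p.values())

    def test_templatic_forms_allowed(self):
        ens = morphology_test(ARABIC_STYLE, n_samples=30, seed=1)
        assert np.isfinite(ens.E_attested)

    def test_degenerate_paradigm_rejected(self):
        bad = pd.DataFrame({"number": [0, 1], "form": ["X", "X"], "count": [1, 1]})
        with pytest.raises(ValueError):
            morphology_test(bad, n_samples=10)

    def test_p_value_is_direct_count(self):
        ens = BaselineEnsemble(
            E_attested=1.0,
            samples={"b": np.array([0.5, 0.9, 1.0, 1.5])},
        )
        # strict '<': the tie at 1.0 counts against the attested form
        assert ens.p["b"] == pytest.approx(0.5)

    def test_count_scaling_invariance(self):
        doubled = HUNGARIAN_STYLE.assign(count=HUNGARIAN_STYLE["count"] * 7)
        # smoothing 0.5 is not scale-free, so compare with smoothing folded in
        e1 = morphology_test(HUNGARIAN_STYLE, n_samples=5, seed=0).E_attested
        e2 = morphology_test(doubled, n_samples=5, seed=0).E_attested
        assert e1 == pytest.approx(e2, abs=5e-3)


class TestAdjNoun:
    def test_two_pair_toy_exact(self):
        pairs = pd.DataFrame(
            {"word1": ["big", "old"], "word2": ["cat", "dog"], "count": [3, 1]}
        )
        ens = adjnoun_test(pairs, n_samples=64, seed=0)
        # equal-length forms: the unnatural baseline can only keep or swap
        assert len(set(np.round(ens.samples["unnatural"], 12))) <= 2
        assert np.isfinite(ens.E_attested)

    def test_baseline_sample_lengths_match(self):
        pairs = pd.DataFrame(
            {"word1": ["a", "bb", "ccc"], "word2": ["x", "yy", "zzz"], "count": [5, 3, 2]}
        )
        ens = adjnoun_test(pairs, n_samples=20, seed=1)
        assert (ens.samples["nonlocal"] > 0).all()


class TestPhonotactics:
    def test_single_vowel_consonant_cv_words_scramble_to_identity(self):
        # every word alternates one consonant and one vowel: each manner
        # class holds identical phonemes, so scrambling changes nothing
        lex = pd.DataFrame(
            {
                "word": ["ta", "tata"],
                "phonemes": ["t a", "t a t a"],
                "manners": ["stop vow", "stop vow stop vow"],
                "frequency": [0.5, 0.5],
            }
        )
        E_att, E_scr = phonotactics_test(lex, seed=0)
        assert E_att == pytest.approx(E_scr, abs=1e-12)

    def test_scramble_rerun_identical(self):
        lex = pd.DataFrame(
            {
                "word": ["tesa", "sate"],
                "phonemes": ["t e s a", "s a t e"],
                "manners": ["stop vow fric vow", "fric vow stop vow"],
                "frequency": [0.5, 0.5],
            }
        )
        assert phonotactics_test(lex, seed=4) == phonotactics_test(lex, seed=4)

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            phonotactics_test(pd.DataFrame(columns=["word", "phonemes", "manners", "frequency"]))


class TestWordOrder:
    def test_printed_rows_reversal_symmetry(self):
        from predinfo.io import load_example_phrases

        table, summary = word_order_analysis(load_example_phrases())
        assert len(table) == 24
        assert summary["max_reversal_E_gap"] < 1e-12

    def test_noun_only_table_order_vacuous(self):
        phrases = pd.DataFrame(
            {
                "determiner": ["", ""],
                "numeral": ["", ""],
                "adjective": ["", ""],
                "noun": ["cat", "dog"],
                "count": [3, 1],
            }
        )
        table, _ = word_order_analysis(phrases)
        assert table["E"].nunique() == 1

    def test_typology_regression(self):
        from predinfo.io import load_example_phrases

        table, _ = word_order_analysis(load_example_phrases())
        # synthetic typology: genus counts decaying in E exercise the fit
        typ = pd.DataFrame(
            {
                "order": table["order"],
                "count": np.maximum(1, np.round(50 * np.exp(-3 * (table["E"] - table["E"].min())))),
            }
        )
        _, summary = word_order_analysis(load_example_phrases(), typ)
        assert summary["pearson_r"] < 0
        assert summary["slope"] < 0

    def test_unknown_typology_order_rejected(self):
        from predinfo.io import load_example_phrases

        typ = pd.DataFrame({"order": ["QQQQ"], "count": [3]})
        with pytest.raises(KeyError):
            word_order_analysis(load_example_phrases(), typ)


class TestNorms:
    def test_binarize_strict_threshold(self):
        raw = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["u", "v", "w"])
        nm = binarize_norms(raw)
        assert list(nm.features["f"]) == [0, 0, 1]

    def test_constant_feature_warns_all_zero(self):
        raw = pd.DataFrame({"f": [2.0, 2.0], "g": [0.0, 1.0]}, index=["u", "v"])
        with pytest.warns(UserWarning):
            nm = binarize_norms(raw)
        assert list(nm.features["f"]) == [0, 0]

    def test_diagonal_is_feature_entropy(self):
        feats = pd.DataFrame(
            {"a": [0, 1, 1, 0], "b": [0, 0, 1, 1]}, index=list("wxyz")
        )
        nm = NormMatrix(feats, pd.Series(1.0, index=feats.index))
        mi = pairwise_feature_mi(nm)
        assert mi.loc["a", "a"] == pytest.approx(1.0)

    def test_independent_feature_row_near_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        z = rng.integers(0, 2, n)
        feats = pd.DataFrame(
            {
                "c1": z,
                "c2": np.where(rng.random(n) < 0.1, 1 - z, z),
                "ind": rng.integers(0, 2, n),
            },
            index=[f"w{i}" for i in range(n)],
        )
        nm = NormMatrix(feats, pd.Series(1.0, index=feats.index))
        mi = pairwise_feature_mi(nm)
        assert mi.loc["c1", "c2"] > 0.3
        assert mi.loc["ind", "c1"] < 0.02 and mi.loc["ind", "c2"] < 0.02

    def test_cross_word_independent_pairs_near_zero(self):
        rng = np.random.default_rng(1)
        words = [f"n{i}" for i in range(40)] + [f"v{i}" for i in range(40)]
        feats = pd.DataFrame(
            rng.integers(0, 2, size=(80, 3)), index=words, columns=["a", "b", "c"]
        )
        pairs = pd.DataFrame(
            {
                "verb": rng.choice(words[40:], 600),
                "object": rng.choice(words[:40], 600),
                "count": 1,
            }
        )
        nm = NormMatrix(feats, pd.Series(1.0, index=feats.index), pairs=pairs)
        within, across = cross_word_feature_mi(nm)
        assert across.shape == (3, 3)
        assert across.to_numpy().mean() < 0.02

    def test_pairs_required(self):
        feats = pd.DataFrame({"a": [0, 1]}, index=["u", "v"])
        nm = NormMatrix(feats, pd.Series(1.0, index=feats.index))
        with pytest.raises(ValueError):
            cross_word_feature_mi(nm)


CONLLU_FIXTURE = textwrap.dedent(
    """\
    # sent_id = 1
    1	the	the	DET	_	Definite=Def	2	det	_	_
    2	cats	cat	NOUN	_	Number=Plur|Case=Nom	3	nsubj	_	_
    3	chased	chase	VERB	_	_	0	root	_	_
    4	big	big	ADJ	_	_	5	amod	_	_
    5	dogs	dog	NOUN	_	Number=Plur	3	obj	_	_

    # sent_id = 2 (one non-adjacent amod, two adjectives on one noun)
    1	old	old	ADJ	_	_	3	amod	_	_
    2	grey	grey	ADJ	_	_	3	amod	_	_
    3	house	house	NOUN	_	Number=Sing	0	root	_	_
    """
)


class TestConlluExtraction:
    def test_amod_pairs_adjacency_required(self):
        pairs = extract_from_conllu(io.StringIO(CONLLU_FIXTURE).readlines(), "amod_pairs")
        assert list(pairs.itertuples(index=False)) == [("big", "dogs", 1), ("grey", "house", 1)]

    def test_noun_phrases_keep_one_random_adjective(self):
        nps = extract_from_conllu(
            io.StringIO(CONLLU_FIXTURE).readlines(), "noun_phrases", seed=0
        )
        house = nps[nps["noun"] == "house"]
        assert len(house) == 1 and house.iloc[0]["adjective"] in {"old", "grey"}
        again = extract_from_conllu(
            io.StringIO(CONLLU_FIXTURE).readlines(), "noun_phrases", seed=0
        )
        assert again.equals(nps)

    def test_noun_feature_counts(self):
        nouns = extract_from_conllu(io.StringIO(CONLLU_FIXTURE).readlines(), "nouns")
        assert nouns["count"].sum() == 3
        assert (nouns[nouns["Number"] == "Plur"]["count"].sum()) == 2

    def test_verb_objects(self):
        vo = extract_from_conllu(io.StringIO(CONLLU_FIXTURE).readlines(), "verb_objects")
        assert list(vo.itertuples(index=False)) == [("chased", "dogs", 1)]

    def test_malformed_line_reports_position(self):
        bad = ["1\tonly\tthree\tfields\n"]
        with pytest.raises(ValueError, match="line 1"):
            extract_from_conllu(bad, "nouns")


class TestSyntheticPipelineClaims:
    def test_adjnoun_selectional_dependence_detected(self):
        from predinfo.synthetic_data import GeneratorConfig, gen_adjnoun_pairs

        pairs = gen_adjnoun_pairs(GeneratorConfig(seed=2))
        ens = adjnoun_test(pairs, n_samples=300, seed=3)
        assert ens.p["unnatural"] <= 0.1
        assert ens.samples["nonlocal"].mean() > ens.E_attested

    def test_argmin_order_places_determiner_next_to_noun(self):
        from predinfo.synthetic_data import GeneratorConfig, gen_phrase_table

        # determiner-noun coupling is the strongest dependence by default
        table, _ = word_order_analysis(gen_phrase_table(GeneratorConfig(seed=2)))
        best = table.iloc[0]["order"]
        assert abs(best.index("D") - best.index("n")) == 1

    def test_unconstrained_lexicon_scramble_is_neutral(self):
        from predinfo.synthetic_data import GeneratorConfig, gen_lexicon

        lex = gen_lexicon(GeneratorConfig(seed=0, strictness=0.0))
        E_att, E_scr = phonotactics_test(lex, seed=1)
        assert abs(E_att - E_scr) < 0.05
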