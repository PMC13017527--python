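"""Code builders, counterfactual baselines, and structural scores."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predinfo.codes import (
    BlockStructure,
    apply_position_permutation,
    blocks_contiguous,
    count_systematic_features,
    digit_subforms,
    enumerate_bijections,
    is_well_nested,
    manner_preserving_scramble,
    permute_meanings,
    permute_meanings_length_matched,
    random_bijection_code,
    random_position_permutation,
    systematic_code,
)
from predinfo.process_model import AmbiguityError, Code, Source, build_process, excess_entropy
from predinfo.sources import COINFLIP_SPEC, FeatureSpec, product_bernoulli_source

CUBE = ["".join(t) for t in itertools.product("01", repeat=3)]

MANNERS = {"f": "fric", "s": "fric", "t": "stop", "d": "stop", "a": "vow", "e": "vow"}


class TestSystematicCode:
    def test_identity_digits(self):
        code = systematic_code(COINFLIP_SPEC, digit_subforms(COINFLIP_SPEC))
        assert "".join(code.form((1, 0, 1))) == "101"

    def test_two_digit_zipf_decomposition(self):
        spec = FeatureSpec(("d1", "d2"), (10, 10))
        words = [[f"<{v}>" for v in range(10)], [f"[{v}]" for v in range(10)]]
        subforms = [
            {v: (w,) for v, w in enumerate(ws)} for ws in words
        ]
        code = systematic_code(spec, subforms)
        assert code.form((8, 9)) == ("<8>", "[9]")

    def test_injective_when_subforms_fixed_length(self):
        code = systematic_code(COINFLIP_SPEC, digit_subforms(COINFLIP_SPEC))
        assert code.is_injective()

    def test_noninjective_subform_rejected(self):
        bad = [{0: "a", 1: "a"}] + digit_subforms(COINFLIP_SPEC)[1:]
        with pytest.raises(AmbiguityError):
            systematic_code(COINFLIP_SPEC, bad)


class TestBijections:
    def test_forced_and_seeded(self):
        s = Source(("m",), np.array([1.0]))
        assert random_bijection_code(s, ["x"]).form("m") == ("x",)
        s8 = product_bernoulli_source()
        c1 = random_bijection_code(s8, CUBE, seed=5)
        c2 = random_bijection_code(s8, CUBE, seed=5)
        assert c1.mapping == c2.mapping and c1.is_injective()

    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 6)])
    def test_enumeration_counts(self, n, expected):
        codes = list(enumerate_bijections(list(range(n)), [str(i) for i in range(n)]))
        assert len(codes) == expected
        assert len({tuple(sorted(c.mapping.items())) for c in codes}) == expected

    def test_size_guard(self):
        with pytest.raises(ValueError):
            next(enumerate_bijections(list(range(11)), [str(i) for i in range(11)]))


class TestPositionPermutation:
    def test_identity(self):
        code = Code({0: "abc", 1: "xyz"})
        assert apply_position_permutation(code, {3: (0, 1, 2)}).mapping == code.mapping

    def test_interleave_example(self):
        code = Code({0: "aaaabbbb"})
        perm = {8: (4, 0, 1, 2, 5, 6, 3, 7)}
        assert "".join(apply_position_permutation(code, perm).form(0)) == "baaabbab"

    def test_permutation_then_inverse(self):
        code = Code({0: "abcd", 1: "wxyz"})
        p = (2, 0, 3, 1)
        inv = tuple(np.argsort(p))
        roundtrip = apply_position_permutation(
            apply_position_permutation(code, {4: p}), {4: inv}
        )
        assert roundtrip.mapping == code.mapping

    def test_missing_length_rejected(self):
        with pytest.raises(KeyError):
            apply_position_permutation(Code({0: "ab"}), {3: (0, 1, 2)})

    def test_identity_unique_E_preserver_up_to_reversal(self):
        # on a generic instance, only the identity and the full reversal
        # leave E unchanged among all position permutations
        rng = np.random.default_rng(11)
        source = Source(tuple(range(6)), np.array([0.3, 0.25, 0.2, 0.12, 0.08, 0.05]))
        forms = ["000", "001", "011", "100", "110", "111"]
        code = Code(dict(zip(source.meanings, forms)))
        E0 = excess_entropy(build_process(source, code))
        preserving = [
            p
            for p in itertools.permutations(range(3))
            if abs(
                excess_entropy(
                    build_process(source, apply_position_permutation(code, {3: p}))
                )
                - E0
            )
            < 1e-12
        ]
        assert preserving == [(0, 1, 2), (2, 1, 0)]


class TestMeaningPermutations:
    def test_form_multiset_preserved(self):
        code = Code(dict(zip(range(8), CUBE)))
        for seed in range(5):
            pm = permute_meanings(code, seed)
            assert sorted(pm.forms()) == sorted(code.forms())

    def test_single_meaning_unchanged(self):
        code = Code({0: "abc"})
        assert permute_meanings(code, 3).mapping == code.mapping

    def test_weighted_E_changes_but_forms_do_not(self):
        source = Source(tuple(range(4)), np.array([0.55, 0.25, 0.15, 0.05]))
        code = Code(dict(zip(range(4), ["aa", "ab", "b", "ba"])))
        E0 = excess_entropy(build_process(source, code))
        changed = False
        for seed in range(8):
            pm = permute_meanings(code, seed)
            assert sorted(pm.forms()) == sorted(code.forms())
            if abs(excess_entropy(build_process(source, pm)) - E0) > 1e-9:
                changed = True
        assert changed

    def test_length_matched_preserves_lengths(self):
        code = Code(dict(zip(range(5), ["a", "b", "cc", "dd", "ee"])))
        for seed in range(5):
            pl = permute_meanings_length_matched(code, seed)
            for m in code.mapping:
                assert len(pl.form(m)) == len(code.form(m))

    def test_distinct_lengths_force_identity(self):
        code = Code(dict(zip(range(3), ["a", "bb", "ccc"])))
        assert permute_meanings_length_matched(code, 9).mapping == code.mapping

    def test_noninjective_rejected(self):
        with pytest.raises(AmbiguityError):
            permute_meanings(Code({0: "a", 1: "a"}), 0)


class TestMannerScramble:
    def test_target_form_reachable(self):
        seen = {
            "".join(manner_preserving_scramble("fasted", MANNERS, seed))
            for seed in range(200)
        }
        assert "sefdat" in seen

    def test_deterministic_per_seed_and_word(self):
        a = manner_preserving_scramble("fasted", MANNERS, 5)
        assert a == manner_preserving_scramble("fasted", MANNERS, 5)

    def test_all_distinct_classes_unchanged(self):
        assert manner_preserving_scramble("fat", MANNERS, 3) == tuple("fat")

    def test_unknown_phoneme_rejected(self):
        with pytest.raises(KeyError):
            manner_preserving_scramble("xyz", MANNERS, 0)

    @given(st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_manner_skeleton_preserved(self, seed):
        word = "stadef"
        out = manner_preserving_scramble(word, MANNERS, seed)
        assert [MANNERS[p] for p in out] == [MANNERS[p] for p in word]
        assert sorted(out) == sorted(word)


class TestSystematicityScore:
    def test_identity_scores_three(self):
        code = systematic_code(COINFLIP_SPEC, digit_subforms(COINFLIP_SPEC))
        assert count_systematic_features(code, COINFLIP_SPEC) == 3

    def test_bitflip_still_three(self):
        subs = [{0: "0", 1: "1"}, {0: "0", 1: "1"}, {0: "1", 1: "0"}]
        code = systematic_code(COINFLIP_SPEC, subs)
        assert count_systematic_features(code, COINFLIP_SPEC) == 3

    def test_xor_position_loses_one_feature(self):
        # first position = M1 XOR M2: only M2 and M3 keep a dedicated position
        code = Code(
            {
                m: (str(m[0] ^ m[1]), str(m[1]), str(m[2]))
                for m in COINFLIP_SPEC.meanings()
            }
        )
        assert count_systematic_features(code, COINFLIP_SPEC) == 2

    def test_holistic_scores_zero(self):
        # a code where no position is a function of a single feature
        forms = ["000", "011", "101", "110", "111", "100", "010", "001"]
        code = Code(dict(zip(COINFLIP_SPEC.meanings(), forms)))
        assert count_systematic_features(code, COINFLIP_SPEC) == 0

    def test_length_mismatch_rejected(self):
        code = Code({m: "0000" for m in COINFLIP_SPEC.meanings()})
        with pytest.raises(ValueError):
            count_systematic_features(code, COINFLIP_SPEC)


class TestBlockStructures:
    BLOCKS = BlockStructure(blocks=((0, 1, 2, 3), (4, 5, 6, 7)))
    TREE = BlockStructure(
        blocks=((0, 1, 2), (3, 4, 5)), tree=((0, 1), (0, 1, 2), (3, 4), (3, 4, 5))
    )

    def test_identity_contiguous(self):
        assert blocks_contiguous(tuple(range(8)), self.BLOCKS)

    def test_block_swap_contiguous(self):
        assert blocks_contiguous((4, 5, 6, 7, 0, 1, 2, 3), self.BLOCKS)

    def test_interleave_not_contiguous(self):
        assert not blocks_contiguous((0, 4, 1, 5, 2, 6, 3, 7), self.BLOCKS)

    def test_identity_well_nested(self):
        assert is_well_nested(tuple(range(6)), self.TREE)

    def test_interleaved_not_well_nested(self):
        assert not is_well_nested((0, 3, 1, 4, 2, 5), self.TREE)

    def test_well_nested_count_of_720(self):
        # frozen by exhaustive check: 2 block orders x 4 x 4 internal
        # arrangements keeping each pair adjacent
        count = sum(
            is_well_nested(p, self.TREE) for p in itertools.permutations(range(6))
        )
        assert count == 32

    def test_baseline_generators_preserve_length_multisets(self):
        rng = np.random.default_rng(0)
        code = Code(dict(zip(range(6), ["ab", "ba", "abc", "cab", "a", "c"])))
        lengths = sorted(len(f) for f in code.forms())
        perm = random_position_permutation([len(f) for f in code.forms()], rng)
        scrambled = apply_position_permutation(code, perm)
        assert sorted(len(f) for f in scrambled.forms()) == lengths
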