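"""Code builders, counterfactual baselines, and structural scores.

Builds systematic codes (one subform per feature, concatenated), holistic
codes (arbitrary bijections), and the counterfactual baselines used in the
attested-vs-baseline analyses: position scrambles (non-local), meaning
permutations (unnatural), length-matched meaning permutations, and the
manner-class-preserving phoneme scramble. Also scores codes for the number
of systematically expressed features, block contiguity, and well-nestedness.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .process_model import AmbiguityError, Code, Form, Source, as_form
from .sources import FeatureSpec

#: one permutation per form length; new_form[i] = old_form[perm[length][i]]
PositionPermutation = Mapping[int, Sequence[int]]


@dataclass(frozen=True)
class BlockStructure:
    """An ordered partition of string positions into blocks ('words'),
    optionally with a tree of nested position groups ('phrases')."""

    blocks: tuple[tuple[int, ...], ...]
    tree: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        flat = [p for b in self.blocks for p in b]
        if len(set(flat)) != len(flat):
            raise ValueError("blocks must be disjoint")

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for b in self.blocks for p in b)


# ---------------------------------------------------------------------------
# code builders
# ---------------------------------------------------------------------------


def systematic_code(
    spec: FeatureSpec,
    subforms: Sequence[Mapping[int, str | Form]],
    order: Sequence[int] | None = None,
) -> Code:
    """The homomorphic code: L(m) is the concatenation of one subform per
    feature value, in the given feature order (default: spec order).

    Each per-feature value->subform map must be injective.
    """
    if len(subforms) != spec.k:
        raise ValueError("need one subform map per feature variable")
    order = tuple(order) if order is not None else tuple(range(spec.k))
    if sorted(order) != list(range(spec.k)):
        raise ValueError("order must be a permutation of the feature indices")
    canon = []
    for i, sub in enumerate(subforms):
        forms = [as_form(sub[v]) for v in range(spec.cardinalities[i])]
        if len(set(forms)) != len(forms):
            raise AmbiguityError(f"subform map for variable {i} is not injective")
        canon.append(forms)
    mapping = {
        m: tuple(itertools.chain.from_iterable(canon[i][m[i]] for i in order))
        for m in spec.meanings()
    }
    return Code(mapping)


def digit_subforms(spec: FeatureSpec) -> list[dict[int, str]]:
    """One-symbol-per-value subforms using decimal digit characters."""
    if max(spec.cardinalities) > 10:
        raise ValueError("digit subforms support cardinality <= 10")
    return [{v: str(v) for v in range(c)} for c in spec.cardinalities]


def random_bijection_code(
    source: Source, forms: Sequence[str | Form], seed: int | np.random.Generator = 0
) -> Code:
    """A uniformly random bijection from the source's meanings onto ``forms``."""
    forms = [as_form(f) for f in forms]
    if len(set(forms)) != len(forms):
        raise ValueError("forms must be distinct")
    if len(forms) != len(source.meanings):
        raise ValueError(
            f"{len(source.meanings)} meanings but {len(forms)} forms"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(forms))
    return Code({m: forms[perm[i]] for i, m in enumerate(source.meanings)})


def enumerate_bijections(
    meanings: Sequence, forms: Sequence[str | Form]
) -> Iterator[Code]:
    """Yield every bijection meanings -> forms exactly once (n! codes)."""
    if len(meanings) != len(forms):
        raise ValueError("meanings and forms must have equal size")
    if len(meanings) > 10:
        raise ValueError("refusing to enumerate more than 10! bijections")
    forms = [as_form(f) for f in forms]
    for perm in itertools.permutations(forms):
        yield Code(dict(zip(meanings, perm)))


# ---------------------------------------------------------------------------
# counterfactual baselines
# ---------------------------------------------------------------------------


def random_position_permutation(
    lengths: Iterable[int], rng: np.random.Generator
) -> dict[int, tuple[int, ...]]:
    """One uniformly random permutation per distinct form length."""
    return {l: tuple(rng.permutation(l)) for l in sorted(set(lengths))}


def apply_position_permutation(code: Code, perm: PositionPermutation) -> Code:
    """Scramble every form: new_form[i] = old_form[perm[len][i]].

    The same permutation applies to every form of a given length, keeping the
    scramble a deterministic function of the form.
    """
    mapping = {}
    for m, f in code.mapping.items():
        if len(f) not in perm:
            raise KeyError(f"no permutation for form length {len(f)}")
        p = perm[len(f)]
        mapping[m] = tuple(f[p[i]] for i in range(len(f)))
    return Code(mapping)


def permute_meanings(code: Code, seed: int | np.random.Generator = 0) -> Code:
    """The 'unnatural' baseline: reassign forms to meanings uniformly at
    random (the multiset of forms is preserved exactly)."""
    code.require_injective()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meanings = list(code.mapping)
    forms = list(code.mapping.values())
    perm = rng.permutation(len(meanings))
    return Code({m: forms[perm[i]] for i, m in enumerate(meanings)})


def permute_meanings_length_matched(
    code: Code, seed: int | np.random.Generator = 0
) -> Code:
    """Unnatural baseline restricted to equal-form-length classes: every
    meaning keeps a form of the length it had."""
    code.require_injective()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_len: dict[int, list] = {}
    for m, f in code.mapping.items():
        by_len.setdefault(len(f), []).append(m)
    mapping = {}
    for l, ms in by_len.items():
        forms = [code.mapping[m] for m in ms]
        perm = rng.permutation(len(ms))
        for i, m in enumerate(ms):
            mapping[m] = forms[perm[i]]
    return Code({m: mapping[m] for m in code.mapping})


def manner_preserving_scramble(
    word: Sequence[str] | str,
    manner_classes: Mapping[str, str],
    seed: int = 0,
) -> Form:
    """Deterministically scramble a word's phonemes within manner classes.

    Positions are grouped by the manner class of their phoneme; within each
    class group a permutation is applied. The permutation is derived from
    ``(seed, word identity)``, so the same word always scrambles the same way
    across a lexicon, and the word's manner-class skeleton is unchanged.
    """
    phonemes = as_form(word)
    try:
        classes = [manner_classes[p] for p in phonemes]
    except KeyError as e:
        raise KeyError(f"phoneme {e.args[0]!r} has no manner class") from e
    word_key = zlib.crc32(" ".join(phonemes).encode("utf-8"))
    rng = np.random.default_rng([seed, word_key])
    out = list(phonemes)
    for cls in sorted(set(classes)):
        idx = [i for i, c in enumerate(classes) if c == cls]
        perm = rng.permutation(len(idx))
        members = [phonemes[i] for i in idx]
        for slot, i in enumerate(idx):
            out[i] = members[perm[slot]]
    return tuple(out)


# ---------------------------------------------------------------------------
# structural scores
# ---------------------------------------------------------------------------


def count_systematic_features(code: Code, spec: FeatureSpec) -> int:
    """Number of features expressed systematically by some string position.

    A feature M_i is counted when there is a position j whose symbol is a
    bijective function of M_i alone (constant in all other features), with
    each position claimed by at most one feature (maximum bipartite
    matching). A fully systematic code scores k, a holistic one 0.
    """
    meanings = spec.meanings()
    forms = [code.form(m) for m in meanings]
    lengths = {len(f) for f in forms}
    if lengths != {spec.k}:
        raise ValueError("code must be fixed-length with one position per feature")
    edges: dict[int, list[int]] = {i: [] for i in range(spec.k)}
    for i in range(spec.k):
        for j in range(spec.k):
            value_to_sym: dict[int, set] = {}
            for m, f in zip(meanings, forms):
                value_to_sym.setdefault(m[i], set()).add(f[j])
            syms = [s for s in value_to_sym.values()]
            constant_within = all(len(s) == 1 for s in syms)
            distinct_across = len({next(iter(s)) for s in syms}) == len(syms)
            if constant_within and distinct_across:
                edges[i].append(j)

    match: dict[int, int] = {}  # position -> feature

    def try_assign(i: int, seen: set[int]) -> bool:
        for j in edges[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match or try_assign(match[j], seen):
                match[j] = i
                return True
        return False

    return sum(try_assign(i, set()) for i in range(spec.k))


def _image_contiguous(perm: Sequence[int], group: Iterable[int]) -> bool:
    group = set(group)
    img = [i for i, p in enumerate(perm) if p in group]
    if not img:
        return True
    return max(img) - min(img) + 1 == len(img)


def blocks_contiguous(perm: Sequence[int], blocks: BlockStructure) -> bool:
    """True iff every block's positions map to a contiguous index interval
    under the permutation (new_form[i] = old_form[perm[i]])."""
    return all(_image_contiguous(perm, b) for b in blocks.blocks)


def is_well_nested(perm: Sequence[int], tree: BlockStructure) -> bool:
    """True iff every tree group's positions map to a contiguous interval."""
    groups = tree.tree if tree.tree is not None else tree.blocks
    return all(_image_contiguous(perm, g) for g in groups)
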