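"""Attested-vs-counterfactual analyses on paradigm, phrase, lexicon and
semantic-norm tables.

Each analysis computes the exact predictive information E of an attested
form inventory under an empirical source distribution, and compares it
against ensembles of counterfactual baselines (position scrambles, random
form-meaning reassignments, length-matched reassignments, manner-preserving
phoneme scrambles). Permutation p-values report the fraction of baseline
samples with *lower* E than the attested forms, following the convention
that ties count against the attested configuration.

Tables are plain pandas DataFrames with documented columns:

* paradigm: one column per grammatical feature, then ``form`` (string with
  stem dummy symbols such as ``X``), ``count``.
* phrases: ``determiner``, ``numeral``, ``adjective``, ``noun`` (empty
  string for an absent slot), ``count``.
* adjective-noun pairs: ``word1``, ``word2`` (linear order), ``count``.
* lexicon: ``word``, ``phonemes`` (space-separated), ``manners``
  (space-separated, aligned), ``frequency``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codes import (
    apply_position_permutation,
    manner_preserving_scramble,
    permute_meanings,
    permute_meanings_length_matched,
    random_position_permutation,
)
from .process_model import (
    Code,
    FormProcess,
    Source,
    build_process,
    excess_entropy,
    mutual_information,
)
from .sources import empirical_source


@dataclass
class BaselineEnsemble:
    """Attested E plus sampled counterfactual E values per baseline."""

    E_attested: float
    samples: dict[str, np.ndarray]

    @property
    def p(self) -> dict[str, float]:
        """Fraction of baseline samples with E strictly below the attested
        value (ties count against the attested forms)."""
        return {
            name: float((s < self.E_attested).mean())
            for name, s in self.samples.items()
        }

    def summary(self) -> dict:
        out = {"E_attested": self.E_attested, "p": self.p}
        out["baseline_mean_E"] = {
            name: float(s.mean()) for name, s in self.samples.items()
        }
        return out


def _feature_columns(df: pd.DataFrame, reserved: set[str]) -> list[str]:
    return [c for c in df.columns if c not in reserved]


def _E_of_code(source: Source, code: Code) -> float:
    return excess_entropy(build_process(source, code))


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def morphology_test(
    paradigm: pd.DataFrame, n_samples: int = 10000, seed: int = 0
) -> BaselineEnsemble:
    """Letter-level E of inflected forms vs three counterfactual baselines.

    The source over grammatical feature tuples is proportional to corpus
    counts with add-1/2 smoothing over the cross-product of attested feature
    values; the paradigm must provide a form for every cell. Baselines:
    ``nonlocal`` (a fresh position permutation per form length per sample),
    ``unnatural`` (random form-meaning reassignment) and ``length_matched``
    (reassignment within equal-length classes).
    """
    feat_cols = _feature_columns(paradigm, {"form", "count"})
    if not feat_cols:
        raise ValueError("paradigm table needs feature columns")
    if paradigm["form"].nunique() < 2:
        raise ValueError("degenerate paradigm: need at least two distinct forms")
    counts = {
        tuple(row[c] for c in feat_cols): float(row["count"])
        for _, row in paradigm.iterrows()
    }
    form_of = {
        tuple(row[c] for c in feat_cols): str(row["form"])
        for _, row in paradigm.iterrows()
    }
    source = empirical_source(counts, smoothing=0.5)
    missing = [m for m in source.meanings if m not in form_of]
    if missing:
        raise ValueError(
            f"paradigm is incomplete: no form for feature cells {missing[:3]}..."
        )
    code = Code({m: form_of[m] for m in source.meanings})
    E_att = _E_of_code(source, code)
    rng = np.random.default_rng(seed)
    lengths = [len(f) for f in code.forms()]
    samples = {
        "nonlocal": np.empty(n_samples),
        "unnatural": np.empty(n_samples),
        "length_matched": np.empty(n_samples),
    }
    for i in range(n_samples):
        perm = random_position_permutation(lengths, rng)
        samples["nonlocal"][i] = _E_of_code(
            source, apply_position_permutation(code, perm)
        )
        samples["unnatural"][i] = _E_of_code(source, permute_meanings(code, rng))
        samples["length_matched"][i] = _E_of_code(
            source, permute_meanings_length_matched(code, rng)
        )
    return BaselineEnsemble(E_attested=E_att, samples=samples)


# ---------------------------------------------------------------------------
# adjective-noun pairs
# ---------------------------------------------------------------------------


def adjnoun_test(
    pairs: pd.DataFrame, n_samples: int = 10000, seed: int = 0
) -> BaselineEnsemble:
    """Letter-level E of two-word phrases vs unnatural and non-local baselines.

    The meaning is the word pair, the form is the two words joined by a
    space (the space is an ordinary symbol and participates in the position
    scramble); the source is proportional to pair frequency.
    """
    cols = (
        ("word1", "word2")
        if "word1" in pairs.columns
        else ("adjective", "noun")
    )
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    agg = pairs.groupby(list(cols), as_index=False)["count"].sum()
    meanings = [tuple(r) for r in agg[list(cols)].itertuples(index=False)]
    counts = dict(zip(meanings, agg["count"].astype(float)))
    source = empirical_source(counts, smoothing=0.0)
    code = Code({m: f"{m[0]} {m[1]}" for m in source.meanings})
    E_att = _E_of_code(source, code)
    rng = np.random.default_rng(seed)
    lengths = [len(f) for f in code.forms()]
    samples = {"nonlocal": np.empty(n_samples), "unnatural": np.empty(n_samples)}
    for i in range(n_samples):
        perm = random_position_permutation(lengths, rng)
        samples["nonlocal"][i] = _E_of_code(
            source, apply_position_permutation(code, perm)
        )
        samples["unnatural"][i] = _E_of_code(source, permute_meanings(code, rng))
    return BaselineEnsemble(E_attested=E_att, samples=samples)


# ---------------------------------------------------------------------------
# phonotactics
# ---------------------------------------------------------------------------


def phonotactics_test(lexicon: pd.DataFrame, seed: int = 0) -> tuple[float, float]:
    """Phoneme-level E of a vocabulary list vs its manner-preserving scramble.

    The source is uniform over word types. Every word is scrambled
    deterministically (same word, same scramble) within manner classes;
    returns ``(E_attested, E_scrambled)``.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    forms = []
    scrambled = []
    for _, row in lexicon.iterrows():
        phonemes = tuple(str(row["phonemes"]).split())
        manners = str(row["manners"]).split()
        if len(manners) != len(phonemes):
            raise ValueError(f"word {row['word']!r}: phoneme/manner length mismatch")
        classes = dict(zip(phonemes, manners))
        forms.append(phonemes)
        scrambled.append(manner_preserving_scramble(phonemes, classes, seed=seed))

    def uniform_process(fs) -> FormProcess:
        agg: dict[tuple, float] = {}
        for f in fs:
            agg[f] = agg.get(f, 0.0) + 1.0
        keys = list(agg)
        return FormProcess(
            forms=tuple(keys), probs=np.array([agg[k] for k in keys]) / len(fs)
        )

    return (
        excess_entropy(uniform_process(forms)),
        excess_entropy(uniform_process(scrambled)),
    )


# ---------------------------------------------------------------------------
# noun-phrase word order
# ---------------------------------------------------------------------------

NP_SLOTS = ("D", "N", "A", "n")
_SLOT_COLUMNS = {"D": "determiner", "N": "numeral", "A": "adjective", "n": "noun"}


def np_orders() -> list[str]:
    """The 24 slot orders of determiner, numeral, adjective, noun."""
    return ["".join(p) for p in itertools.permutations(NP_SLOTS)]


def word_order_analysis(
    phrases: pd.DataFrame, typology: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Word-level E of every noun-phrase slot order, optionally joined with
    typological genus counts.

    Each attested phrase is realized in each of the 24 orders by arranging
    its present slots accordingly; words are atomic symbols. When a typology
    table (columns ``order``, ``count``) is given, an OLS regression of
    log(genus count) on E is fit and the Pearson correlation reported;
    orders with zero genus count are excluded from the regression. Reversed
    orders necessarily share the same E (time-reversal symmetry); the
    summary flags the 12 reversal pairs.
    """
    if len(phrases) == 0:
        raise ValueError("empty phrase table")
    if "noun" not in phrases.columns or (phrases["noun"].astype(str) == "").any():
        raise ValueError("every phrase needs a noun")
    slot_values = []
    for _, row in phrases.iterrows():
        present = {}
        for slot, col in _SLOT_COLUMNS.items():
            v = str(row[col]) if col in phrases.columns and pd.notna(row[col]) else ""
            if v:
                present[slot] = v
        slot_values.append((present, float(row["count"])))

    rows = []
    for order in np_orders():
        agg: dict[tuple, float] = {}
        for present, c in slot_values:
            form = tuple(present[s] for s in order if s in present)
            agg[form] = agg.get(form, 0.0) + c
        keys = list(agg)
        probs = np.array([agg[k] for k in keys])
        proc = FormProcess(forms=tuple(keys), probs=probs / probs.sum())
        rows.append({"order": order, "E": excess_entropy(proc)})
    table = pd.DataFrame(rows)

    summary: dict = {
        "reversal_pairs": [
            (o, o[::-1]) for o in np_orders() if o < o[::-1]
        ],
    }
    Emap = dict(zip(table["order"], table["E"]))
    summary["max_reversal_E_gap"] = max(
        abs(Emap[a] - Emap[b]) for a, b in summary["reversal_pairs"]
    )
    if typology is not None:
        unknown = set(typology["order"]) - set(Emap)
        if unknown:
            raise KeyError(f"typology orders not matching slot labels: {unknown}")
        table = table.merge(typology, on="order", how="left")
        table["count"] = table["count"].fillna(0)
        fit = table[table["count"] > 0]
        x = fit["E"].to_numpy()
        y = np.log(fit["count"].to_numpy())
        res = stats.linregress(x, y)
        summary.update(
            {
                "pearson_r": float(res.rvalue),
                "slope": float(res.slope),
                "p_value": float(res.pvalue),
                "n_orders_in_fit": int(len(fit)),
            }
        )
    return table.sort_values(["E", "order"], kind="stable").reset_index(drop=True), summary


# ---------------------------------------------------------------------------
# semantic features
# ---------------------------------------------------------------------------


@dataclass
class NormMatrix:
    """Binary semantic features per word, word frequencies, and optionally a
    (verb, object, count) pair table."""

    features: pd.DataFrame  # words x features, values in {0, 1}
    frequencies: pd.Series  # indexed like features
    pairs: pd.DataFrame | None = None  # columns verb, object, count

    def __post_init__(self) -> None:
        vals = self.features.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("norm features must be binary")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be nonnegative")


def binarize_norms(
    raw: pd.DataFrame, frequencies: pd.Series | None = None
) -> NormMatrix:
    """Recode each real-valued norm as 1 iff it strictly exceeds that
    feature's unweighted mean across words. Constant features come out
    all-zero (with a warning)."""
    if len(raw) < 2:
        raise ValueError("need at least two words")
    means = raw.mean(axis=0)
    constant = raw.columns[(raw.nunique(axis=0) == 1)]
    if len(constant):
        warnings.warn(
            f"constant norm feature(s) {list(constant)} binarize to all-0",
            stacklevel=2,
        )
    binary = (raw > means).astype(int)
    if frequencies is None:
        frequencies = pd.Series(1.0, index=raw.index)
    return NormMatrix(features=binary, frequencies=frequencies.astype(float))


def _binary_pair_mi(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    joint: dict = {}
    for xi, yi, wi in zip(x, y, w):
        joint[(xi, yi)] = joint.get((xi, yi), 0.0) + wi
    return mutual_information(joint)


def pairwise_feature_mi(norms: NormMatrix) -> pd.DataFrame:
    """I[f_i : f_j] between all feature pairs under the word-frequency
    distribution; the diagonal holds the feature entropies H[f_i]."""
    w = norms.frequencies.to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("frequencies must be normalizable")
    w = w / w.sum()
    F = norms.features.to_numpy()
    names = list(norms.features.columns)
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            out[i, j] = out[j, i] = _binary_pair_mi(F[:, i], F[:, j], w)
    return pd.DataFrame(out, index=names, columns=names)


def cross_word_feature_mi(norms: NormMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-word vs across-word feature MI for verb-object pairs.

    Under the pair-frequency distribution: ``within[i, j]`` is the MI
    between features i and j of the same word, averaged over the verb and
    object positions; ``across[i, j]`` is the MI between feature i of the
    verb and feature j of the object (not symmetric in general).
    """
    if norms.pairs is None or len(norms.pairs) == 0:
        raise ValueError("norms carry no verb-object pair table")
    pairs = norms.pairs
    known = set(norms.features.index)
    pairs = pairs[pairs["verb"].isin(known) & pairs["object"].isin(known)]
    if len(pairs) == 0:
        raise ValueError("no pair has both words in the norm matrix")
    w = pairs["count"].to_numpy(dtype=float)
    w = w / w.sum()
    FV = norms.features.loc[pairs["verb"]].to_numpy()
    FO = norms.features.loc[pairs["object"]].to_numpy()
    names = list(norms.features.columns)
    k = len(names)
    within = np.zeros((k, k))
    across = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            across[i, j] = _binary_pair_mi(FV[:, i], FO[:, j], w)
            if j >= i:
                within[i, j] = within[j, i] = 0.5 * (
                    _binary_pair_mi(FV[:, i], FV[:, j], w)
                    + _binary_pair_mi(FO[:, i], FO[:, j], w)
                )
    return (
        pd.DataFrame(within, index=names, columns=names),
        pd.DataFrame(across, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# CoNLL-U extraction
# ---------------------------------------------------------------------------

MORPH_FEATURES = ("Number", "Case", "Number[psor]", "Definite")


class ConlluParseError(ValueError):
    pass


def _iter_conllu_sentences(lines):
    sent: list[dict] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            if sent:
                yield sent
                sent = []
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise ConlluParseError(
                f"line {lineno}: expected 10 tab-separated fields, got {len(fields)}"
            )
        tok_id = fields[0]
        if "-" in tok_id or "." in tok_id:  # multiword ranges / empty nodes
            continue
        try:
            idx = int(tok_id)
            head = int(fields[6]) if fields[6] != "_" else 0
        except ValueError as e:
            raise ConlluParseError(f"line {lineno}: bad token or head id") from e
        feats = {}
        if fields[5] not in ("_", ""):
            for kv in fields[5].split("|"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    feats[k] = v
        sent.append(
            {
                "id": idx,
                "form": fields[1],
                "lemma": fields[2],
                "upos": fields[3],
                "feats": feats,
                "head": head,
                "deprel": fields[7].split(":")[0],
            }
        )
    if sent:
        yield sent


def extract_from_conllu(
    source, mode: str, seed: int = 0, features: tuple[str, ...] = MORPH_FEATURES
) -> pd.DataFrame:
    """Count tables from a CoNLL-U treebank.

    Modes: ``nouns`` (grammatical-feature tuples of NOUN tokens),
    ``amod_pairs`` (noun heads with an *adjacent* ADJ dependent of relation
    amod, in linear order), ``noun_phrases`` (noun head lemma with det /
    nummod / amod dependent lemmas; one random adjective kept when several
    modify the same noun) and ``verb_objects`` (VERB head with obj NOUN
    dependent). ``source`` is a path or an iterable of lines.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as fh:
            return extract_from_conllu(list(fh), mode, seed=seed, features=features)
    rng = np.random.default_rng(seed)
    counts: dict[tuple, int] = {}
    for sent in _iter_conllu_sentences(source):
        by_id = {t["id"]: t for t in sent}
        if mode == "nouns":
            for t in sent:
                if t["upos"] == "NOUN":
                    key = tuple(t["feats"].get(f, "None") for f in features)
                    counts[key] = counts.get(key, 0) + 1
        elif mode == "amod_pairs":
            for t in sent:
                head = by_id.get(t["head"])
                if (
                    t["deprel"] == "amod"
                    and t["upos"] == "ADJ"
                    and head is not None
                    and head["upos"] == "NOUN"
                    and abs(head["id"] - t["id"]) == 1
                ):
                    first, second = sorted((t, head), key=lambda x: x["id"])
                    key = (first["form"], second["form"])
                    counts[key] = counts.get(key, 0) + 1
        elif mode == "noun_phrases":
            for t in sent:
                if t["upos"] != "NOUN":
                    continue
                deps = [d for d in sent if d["head"] == t["id"]]
                slots = {}
                for rel, pos, slot in (
                    ("det", "DET", "determiner"),
                    ("nummod", "NUM", "numeral"),
                    ("amod", "ADJ", "adjective"),
                ):
                    cands = [d for d in deps if d["deprel"] == rel and d["upos"] == pos]
                    if len(cands) > 1:
                        cands = [cands[int(rng.integers(len(cands)))]]
                    slots[slot] = cands[0]["lemma"] if cands else ""
                key = (slots["determiner"], slots["numeral"], slots["adjective"], t["lemma"])
                counts[key] = counts.get(key, 0) + 1
        elif mode == "verb_objects":
            for t in sent:
                head = by_id.get(t["head"])
                if (
                    t["deprel"] == "obj"
                    and t["upos"] == "NOUN"
                    and head is not None
                    and head["upos"] == "VERB"
                ):
                    key = (head["form"], t["form"])
                    counts[key] = counts.get(key, 0) + 1
        else:
            raise ValueError(f"unknown extraction mode {mode!r}")

    columns = {
        "nouns": list(features),
        "amod_pairs": ["word1", "word2"],
        "noun_phrases": ["determiner", "numeral", "adjective", "noun"],
        "verb_objects": ["verb", "object"],
    }[mode]
    rows = [list(k) + [c] for k, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=columns + ["count"])
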