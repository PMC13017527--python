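"""Readers and writers for the plain-text table formats.

All tables are UTF-8, tab-delimited TSV with ``#``-prefixed comment lines.
Schemas:

* code: ``meaning_id``, ``probability``, ``form`` — the form is a
  whitespace-free symbol string, or whitespace-separated tokens in
  word-level mode; ``#`` is reserved as the delimiter symbol.
* count table: one column per feature variable, final column ``count``.
* paradigm: feature columns, ``form``, ``count``.
* phrases: ``determiner``, ``numeral``, ``adjective``, ``noun``, ``count``.
* lexicon: ``word``, ``phonemes``, ``manners``, ``frequency``.
* typology: ``order`` (a permutation of the slot labels ``DNAn``), ``count``
  (number of unrelated language genera attesting the order).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .process_model import Code, Source, as_form


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, **kw)


def read_code_tsv(path, word_level: bool = False) -> tuple[Source, Code]:
    """Read a (source, code) pair from a code TSV."""
    df = _read_tsv(path, dtype={"meaning_id": str, "form": str})
    probs = df["probability"].astype(float).to_numpy()
    source = Source(tuple(df["meaning_id"]), probs)
    forms = [
        tuple(f.split()) if word_level else as_form(f) for f in df["form"]
    ]
    code = Code(dict(zip(df["meaning_id"], forms)))
    return source, code


def write_code_tsv(path, source: Source, code: Code, word_level: bool = False) -> None:
    rows = [
        {
            "meaning_id": m,
            "probability": p,
            "form": (" " if word_level else "").join(code.form(m)),
        }
        for m, p in source.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_table(path) -> dict[tuple, float]:
    """Feature-tuple counts; every column but the last is a feature."""
    df = _read_tsv(path)
    feat_cols = list(df.columns[:-1])
    return {
        tuple(row[c] for c in feat_cols): float(row[df.columns[-1]])
        for _, row in df.iterrows()
    }


def read_paradigm_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["count"] = df["count"].astype(float)
    return df


def read_phrase_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    df["count"] = df["count"].astype(float)
    return df


def read_lexicon_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"word": str, "phonemes": str, "manners": str})
    df["frequency"] = df["frequency"].astype(float)
    return df


def read_typology_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"order": str})
    df["count"] = df["count"].astype(float)
    return df


def read_norms_tsv(path) -> pd.DataFrame:
    """Real-valued norms: ``word`` column, then one column per feature."""
    df = _read_tsv(path)
    return df.set_index("word").astype(float)


def load_example_phrases() -> pd.DataFrame:
    """The packaged four-row noun-phrase count fixture."""
    ref = importlib.resources.files("predinfo.data").joinpath("example_phrases.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_phrase_tsv(p)
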