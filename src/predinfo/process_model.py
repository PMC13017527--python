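"""Exact predictive information (excess entropy) of discrete codes.

A *code* maps meanings to strings of symbols. Sampling meanings i.i.d. from a
*source* distribution, emitting their forms, and joining consecutive forms
with a reserved delimiter ``#`` yields a stationary symbol process. This
module computes, exactly and in closed form, the n-gram conditional entropies
h_n of that process, its entropy rate h, and its predictive information
(excess entropy)

    E = sum_{n>=1} (h_n - h) = I[past : future],

the mutual information between the semi-infinite past and future of the
process. Because the delimiter statistically severs consecutive forms, every
conditioning window is equivalent to a delimiter-padded within-form window,
h_n is exactly constant for n >= L_max + 2 (L_max the longest form), and the
infinite sum truncates exactly after L_max + 1 terms.

Two independent routes to E are provided: the truncated h_n series
(:func:`predictive_information`) and a direct past/future mutual-information
computation over cut positions (:func:`excess_entropy_cut_oracle`). They
agree to numerical precision on every instance; tests enforce this.

All entropies are in base-2 bits.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


DELIMITER = "#"

#: tolerance for probability-distribution validity checks
DIST_TOL = 1e-12
#: probabilities below this are treated as exactly zero
PROB_FLOOR = 1e-15
#: tolerance for the finite-convergence check of the entropy rate
CONV_TOL = 1e-12


class InvalidDistributionError(ValueError):
    """Probabilities are negative or do not sum to one."""


class ReservedSymbolError(ValueError):
    """A form contains the reserved delimiter symbol."""


class ConvergenceError(RuntimeError):
    """The n-gram entropy series failed its exact finite-convergence check."""


class AmbiguityError(ValueError):
    """A code required to be unambiguous (injective) is not."""


Form = tuple[str, ...]


def as_form(value: str | Sequence[str]) -> Form:
    """Canonicalize a form: a ``str`` is split into characters, any other
    sequence is taken as a tuple of whole-symbol tokens (word-level mode)."""
    if isinstance(value, str):
        return tuple(value)
    return tuple(value)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alphabet:
    """A finite ordered symbol inventory plus a reserved delimiter."""

    symbols: tuple[str, ...]
    delimiter: str = DELIMITER

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("alphabet must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if self.delimiter in self.symbols:
            raise ReservedSymbolError("delimiter must not be an alphabet symbol")


@dataclass(frozen=True)
class Source:
    """A probability distribution over a finite set of meanings.

    Meanings may be atoms (ints, strings) or tuples over feature variables.
    """

    meanings: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if len(self.meanings) != probs.size:
            raise ValueError("meanings and probs differ in length")
        if len(set(self.meanings)) != len(self.meanings):
            raise ValueError("meanings must be distinct")
        _check_distribution(probs)
        probs = np.where(probs < PROB_FLOOR, 0.0, probs)
        object.__setattr__(self, "meanings", tuple(self.meanings))
        object.__setattr__(self, "probs", probs / probs.sum())

    @classmethod
    def from_dict(cls, d: Mapping) -> "Source":
        items = list(d.items())
        return cls(tuple(k for k, _ in items), np.array([v for _, v in items]))

    def prob(self, meaning) -> float:
        return float(self.probs[self.meanings.index(meaning)])

    def items(self):
        return zip(self.meanings, self.probs)

    def support(self) -> tuple:
        """Meanings with nonzero probability."""
        return tuple(m for m, p in self.items() if p > 0)


@dataclass(frozen=True)
class Code:
    """A deterministic map from meanings to forms (tuples of symbols)."""

    mapping: Mapping

    def __post_init__(self) -> None:
        canon = {m: as_form(f) for m, f in self.mapping.items()}
        object.__setattr__(self, "mapping", canon)

    @classmethod
    def from_strings(cls, d: Mapping[object, str]) -> "Code":
        return cls(dict(d))

    def form(self, meaning) -> Form:
        return self.mapping[meaning]

    def meanings(self) -> tuple:
        return tuple(self.mapping)

    def forms(self) -> tuple[Form, ...]:
        return tuple(self.mapping.values())

    def is_injective(self) -> bool:
        forms = list(self.mapping.values())
        return len(set(forms)) == len(forms)

    def require_injective(self) -> "Code":
        if not self.is_injective():
            raise AmbiguityError("code is not injective")
        return self


@dataclass(frozen=True)
class FormProcess:
    """The stationary process induced by a (source, code) pair.

    Holds the aggregated ``(form, probability)`` pairs and the delimiter. The
    process itself is: i.i.d. forms joined by single delimiters, observed at a
    uniformly random symbol position (which length-reweights forms).
    """

    forms: tuple[Form, ...]
    probs: np.ndarray
    delimiter: str = DELIMITER
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        _check_distribution(probs)
        forms = tuple(as_form(f) for f in self.forms)
        if len(set(forms)) != len(forms):
            raise ValueError("forms must be aggregated (distinct)")
        for f in forms:
            if self.delimiter in f:
                raise ReservedSymbolError(
                    f"form {f!r} contains the delimiter {self.delimiter!r}"
                )
        keep = probs >= PROB_FLOOR
        object.__setattr__(self, "forms", tuple(f for f, k in zip(forms, keep) if k))
        object.__setattr__(self, "probs", probs[keep] / probs[keep].sum())

    @property
    def L_max(self) -> int:
        return max((len(f) for f in self.forms), default=0)

    def _int_encoding(self):
        """Symbol-integer encoding of the forms; delimiter is id 0."""
        if "ints" not in self._cache:
            symbols = sorted({tok for f in self.forms for tok in f})
            sym_id = {s: i + 1 for i, s in enumerate(symbols)}
            rows = [
                np.array([sym_id[t] for t in f], dtype=np.int64) for f in self.forms
            ]
            self._cache["ints"] = (rows, len(symbols) + 1)
        return self._cache["ints"]


@dataclass(frozen=True)
class NgramTable:
    """Distribution over length-n windows of the process."""

    n: int
    probs: Mapping[Form, float]

    def marginal_last_dropped(self) -> Mapping[Form, float]:
        out: dict[Form, float] = {}
        for w, p in self.probs.items():
            out[w[:-1]] = out.get(w[:-1], 0.0) + p
        return out


@dataclass(frozen=True)
class EResult:
    """Predictive information with its supporting entropy series."""

    E: float
    h: float
    h_series: tuple[float, ...]
    N: int

    def to_dict(self) -> dict:
        return {"E": self.E, "h": self.h, "h_series": list(self.h_series), "N": self.N}


# ---------------------------------------------------------------------------
# elementary information measures
# ---------------------------------------------------------------------------


def _check_distribution(probs: np.ndarray) -> None:
    if probs.size == 0:
        raise InvalidDistributionError("empty distribution")
    if np.any(probs < -DIST_TOL):
        raise InvalidDistributionError("negative probability")
    if abs(float(probs.sum()) - 1.0) > 1e-9:
        raise InvalidDistributionError(f"probabilities sum to {probs.sum()}, not 1")


def _entropy_of(probs: np.ndarray) -> float:
    p = probs[probs > 0]
    return float(-(p * np.log2(p)).sum())


def entropy(dist: Mapping | Sequence[float] | np.ndarray) -> float:
    """Shannon entropy H[p] in bits; 0·log 0 = 0.

    Accepts a mapping ``outcome -> probability`` or a bare probability vector.
    Raises :class:`InvalidDistributionError` for negative entries or a sum
    away from one.
    """
    if isinstance(dist, Mapping):
        probs = np.array(list(dist.values()), dtype=float)
    else:
        probs = np.asarray(dist, dtype=float)
    _check_distribution(probs)
    return _entropy_of(probs)


def mutual_information(joint: Mapping) -> float:
    """I[X:Y] in bits from a joint table over ``(x, y)`` pairs.

    Computed as H[X] + H[Y] − H[X,Y]; tiny negative round-off is clipped to 0.
    """
    probs = np.array(list(joint.values()), dtype=float)
    _check_distribution(probs)
    px: dict = {}
    py: dict = {}
    for (x, y), p in joint.items():
        px[x] = px.get(x, 0.0) + p
        py[y] = py.get(y, 0.0) + p
    mi = (
        _entropy_of(np.array(list(px.values())))
        + _entropy_of(np.array(list(py.values())))
        - _entropy_of(probs)
    )
    if mi < -1e-9:
        raise InvalidDistributionError(f"mutual information {mi} < 0")
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# process construction and n-gram statistics
# ---------------------------------------------------------------------------


def build_process(source: Source, code: Code, delimiter: str = DELIMITER) -> FormProcess:
    """Aggregate the weighted forms of ``code`` under ``source``.

    Meanings sharing a form (non-injective codes) have their probabilities
    summed. Zero-probability meanings are dropped. The code must provide a
    form for every meaning in the source support.
    """
    agg: dict[Form, float] = {}
    for m, p in source.items():
        if p <= 0:
            continue
        if m not in code.mapping:
            raise KeyError(f"code is not total: no form for meaning {m!r}")
        f = code.form(m)
        agg[f] = agg.get(f, 0.0) + float(p)
    forms = tuple(agg)
    probs = np.array([agg[f] for f in forms])
    return FormProcess(forms=forms, probs=probs, delimiter=delimiter)


def _window_weights(process: FormProcess):
    """Flat (form index, within-form position) arrays and their weights.

    Each form ``s`` contributes ``|s|+1`` window endpoints (one per symbol of
    ``s·#``); endpoint weight is prob(s)/Z with Z = sum_s prob(s)(|s|+1): the
    length reweighting of the stationary construction.
    """
    lengths = np.array([len(f) for f in process.forms], dtype=np.int64)
    k_idx = np.repeat(np.arange(len(process.forms)), lengths + 1)
    j_idx = np.concatenate([np.arange(l + 1) for l in lengths])
    w = process.probs[k_idx]
    return k_idx, j_idx, w / w.sum(), lengths


def ngram_distribution(process: FormProcess, n: int) -> NgramTable:
    """Distribution of length-n windows, one ending at each symbol of each
    ``form·#``, left-padded with delimiters past the form start."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = process.delimiter
    table: dict[Form, float] = {}
    _, _, w, _ = _window_weights(process)
    i = 0
    for f, _p in zip(process.forms, process.probs):
        padded = (d,) * n + f + (d,)
        for j in range(len(f) + 1):
            win = padded[j + 1 : j + 1 + n]
            table[win] = table.get(win, 0.0) + float(w[i])
            i += 1
    return NgramTable(n=n, probs=table)


def conditional_entropy_hn(process: FormProcess, n: int) -> float:
    """h_n: entropy of the next symbol given the previous n−1 symbols.

    Computed from the n-window table as H[window] − H[window's length-(n−1)
    context prefix]; h_1 is the marginal symbol entropy.
    """
    table = ngram_distribution(process, n)
    joint = np.array(list(table.probs.values()))
    ctx: dict[Form, float] = {}
    for win, p in table.probs.items():
        ctx[win[:-1]] = ctx.get(win[:-1], 0.0) + p
    return _entropy_of(joint) - _entropy_of(np.array(list(ctx.values())))


#: largest dense code space for the sort-free bincount regime
_BINCOUNT_LIMIT = 1 << 22


def _h_series_from_ints(
    rows: list[np.ndarray], probs: np.ndarray, base: int, N: int
) -> np.ndarray:
    """h_1..h_N for the process with integer-encoded forms (delimiter = 0).

    Windows of length n end at each symbol of every ``form·#`` and are
    left-padded with delimiters; h_n = H[window] − H[window minus its last
    symbol]. Windows are packed into scalar codes with the last symbol least
    significant (so the context marginal is a ``// base`` grouping). Small
    code spaces use a dense bincount; otherwise window ids are grown
    incrementally (prepend one symbol per level, re-compress), with the
    context of a window at position j recovered as the one-shorter window
    ending at position j−1.
    """
    K = len(rows)
    lengths = np.array([len(r) for r in rows], dtype=np.int64)
    L_max = int(lengths.max(initial=0))
    width = N + L_max + 2
    P = np.zeros((K, width), dtype=np.int64)
    for k, r in enumerate(rows):
        P[k, N : N + len(r)] = r
    # extended endpoint set: j = -1..len(form); j >= 0 carry weight
    k_e = np.repeat(np.arange(K), lengths + 2)
    j_e = np.concatenate([np.arange(-1, l + 1) for l in lengths])
    mask = j_e >= 0
    w = probs[k_e[mask]]
    w = w / w.sum()
    cols = N + j_e
    hs = np.empty(N)

    if float(base) ** N <= _BINCOUNT_LIMIT:
        colsm = cols[mask]
        k_m = k_e[mask]
        codes = np.zeros(mask.sum(), dtype=np.int64)
        powmul = 1
        for n in range(1, N + 1):
            codes += P[k_m, colsm - n + 1] * powmul
            powmul *= base
            pj = np.bincount(codes, weights=w, minlength=powmul)
            Hj = _entropy_of(pj)
            Hc = _entropy_of(pj.reshape(-1, base).sum(axis=1)) if n > 1 else 0.0
            hs[n - 1] = Hj - Hc
        return hs

    S = np.zeros(len(k_e), dtype=np.int64)
    prev_S = S
    idx_pos = np.flatnonzero(mask)
    for n in range(1, N + 1):
        pair = S * base + P[k_e, cols - n + 1]
        _, S = np.unique(pair, return_inverse=True)
        Hj = _entropy_of(np.bincount(S[idx_pos], weights=w))
        if n == 1:
            Hc = 0.0
        else:
            Hc = _entropy_of(np.bincount(prev_S[idx_pos - 1], weights=w))
        hs[n - 1] = Hj - Hc
        prev_S = S
    return hs


def h_series(process: FormProcess, N: int) -> np.ndarray:
    """Exact h_1..h_N of the process (vectorized path)."""
    rows, base = process._int_encoding()
    return _h_series_from_ints(rows, process.probs, base, N)


def entropy_rate(process: FormProcess) -> float:
    """Entropy rate h, reached exactly at n = L_max + 2.

    By the padding construction the conditioning window then always reaches
    the previous delimiter; equality h_{L_max+2} = h_{L_max+3} is verified.
    """
    L = process.L_max
    hs = h_series(process, L + 3)
    if abs(hs[L + 2] - hs[L + 1]) > CONV_TOL:
        raise ConvergenceError(
            f"h_{L + 2}={hs[L + 1]} != h_{L + 3}={hs[L + 2]}: "
            "entropy rate did not converge at n = L_max + 2"
        )
    return float(hs[L + 1])


def predictive_information(process: FormProcess) -> EResult:
    """Predictive information E = sum_{n=1}^{L_max+1} (h_n − h), exactly.

    The truncation is exact because h_n = h for all n >= L_max + 2 (checked).
    Returns the full h series h_1..h_{L_max+2} (the last entry equals h).
    """
    L = process.L_max
    hs = h_series(process, L + 3)
    h = float(hs[L + 1])
    if abs(hs[L + 2] - h) > CONV_TOL:
        raise ConvergenceError("h_n did not converge at n = L_max + 2")
    E = float(np.sum(hs[: L + 1]) - (L + 1) * h)
    if E < -1e-9:
        raise ConvergenceError(f"negative predictive information {E}")
    return EResult(E=max(E, 0.0), h=h, h_series=tuple(hs[: L + 2]), N=L + 2)


def excess_entropy(process: FormProcess) -> float:
    """Convenience: the scalar E of :func:`predictive_information`."""
    return predictive_information(process).E


def excess_entropy_cut_oracle(process: FormProcess) -> float:
    """E as the past/future mutual information at a random cut.

    A (form s, cut k in 0..|s|) pair is drawn with weight prob(s)/Z; the past
    class is the prefix s[:k], the future class the suffix s[k:]·#. Because
    the delimiter severs consecutive forms, these classes are sufficient
    statistics of the full past and future, so I[past : future] is E. This is
    an independent derivation from the h_n series route.
    """
    d = process.delimiter
    _, _, w, _ = _window_weights(process)
    joint: dict[tuple[Form, Form], float] = {}
    i = 0
    for f in process.forms:
        for k in range(len(f) + 1):
            key = (f[:k], f[k:] + (d,))
            joint[key] = joint.get(key, 0.0) + float(w[i])
            i += 1
    return mutual_information(joint)


def sample_stream(
    process: FormProcess, length: int, seed: int | np.random.Generator = 0
) -> tuple[str, ...]:
    """Sample ``length`` symbols of the process: i.i.d. forms joined by single
    delimiters, starting at a form boundary. For Monte-Carlo validation only."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[str] = []
    while len(out) < length:
        f = process.forms[rng.choice(len(process.forms), p=process.probs)]
        out.extend(f)
        out.append(process.delimiter)
    return tuple(out[:length])


def plugin_hn(stream: Sequence[str], n: int) -> float:
    """Plug-in (maximum-likelihood) estimate of h_n from a sampled stream."""
    counts: dict[tuple, int] = {}
    ctx: dict[tuple, int] = {}
    for i in range(n - 1, len(stream)):
        win = tuple(stream[i - n + 1 : i + 1])
        counts[win] = counts.get(win, 0) + 1
        ctx[win[:-1]] = ctx.get(win[:-1], 0) + 1
    total = sum(counts.values())
    pj = np.array(list(counts.values())) / total
    pc = np.array(list(ctx.values())) / total
    return _entropy_of(pj) - _entropy_of(pc)


# ---------------------------------------------------------------------------
# invariance helpers
# ---------------------------------------------------------------------------


def relabel_process(process: FormProcess, mapping: Mapping[str, str]) -> FormProcess:
    """Apply a symbol bijection to every form (E is invariant under this)."""
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("symbol relabeling must be a bijection")
    forms = tuple(tuple(mapping[t] for t in f) for f in process.forms)
    return FormProcess(forms=forms, probs=process.probs, delimiter=process.delimiter)


def reverse_process(process: FormProcess) -> FormProcess:
    """Reverse every form in time (E is invariant under time reversal)."""
    forms = tuple(f[::-1] for f in process.forms)
    return FormProcess(forms=forms, probs=process.probs, delimiter=process.delimiter)


def random_instance(
    rng: np.random.Generator,
    max_meanings: int = 16,
    max_symbols: int = 4,
    max_len: int = 5,
) -> FormProcess:
    """A random small (source, code) process, for oracle-equivalence checks."""
    n_sym = int(rng.integers(1, max_symbols + 1))
    n_available = sum(n_sym**l for l in range(max_len + 1))
    n_m = int(rng.integers(1, min(max_meanings, n_available) + 1))
    symbols = [chr(ord("a") + i) for i in range(n_sym)]
    forms = set()
    while len(forms) < n_m:
        l = int(rng.integers(0, max_len + 1))
        forms.add(tuple(rng.choice(symbols, size=l)))
    probs = rng.random(n_m) + 1e-3
    return FormProcess(forms=tuple(forms), probs=probs / probs.sum())
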