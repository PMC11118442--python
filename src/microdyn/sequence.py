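"""Symbolic sequence statistics: IBS distance, MSNRI, and LZ complexity.

A microstate label sequence is first compressed to its *transition sequence*
(consecutive duplicates collapsed, e.g. ``AACCDDBBBBDDCCA -> ACDBDCA``), which
retains only the state-change information.  Two transition sequences are
compared with the information-based similarity (IBS) distance: every
overlapping m-symbol word is counted in each sequence, words are ranked by
descending frequency within each sequence, and the mean absolute rank
difference — weighted by each word's Shannon-entropy contribution — gives a
distance in [0, 1].

The microstate sequence non-randomness index (MSNRI) is the IBS distance
between a transition sequence and randomly shuffled surrogates of itself: a
sequence with real temporal structure sits far from its shuffles, a random
one is close to them.  Conventions adopted here (and fixed for determinism):

* the vocabulary is the union of words observed in either sequence (size K),
  and the distance is normalized by K - 1;
* within a sequence, ranks are assigned by descending probability with
  lexicographic tie-break; words absent from a sequence take p = 0 and rank
  after all present words, lexicographically among themselves;
* entropy terms use the natural log (the base cancels in the weights);
* MSNRI is reported as 100 x the mean distance over the surrogates.

MSLZC is the LZ76 exhaustive-history complexity of the transition sequence
divided by its length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, EmptyResultError, ParameterError
from .microstate import UNLABELED, LabelSequence

DEFAULT_M = 8
DEFAULT_N_SURROGATES = 20

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class TransitionSequence:
    """Duplicate-collapsed symbol sequence over a finite alphabet."""

    symbols: str
    source_id: str = ""

    def __post_init__(self) -> None:
        s = self.symbols
        if any(s[i] == s[i + 1] for i in range(len(s) - 1)):
            raise ParameterError("transition sequence has consecutive "
                                 "duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def alphabet(self) -> set[str]:
        return set(self.symbols)


def collapse(symbols: str) -> str:
    """Drop consecutive duplicate symbols."""
    return "".join(c for i, c in enumerate(symbols)
                   if i == 0 or c != symbols[i - 1])


def to_transition_sequence(seq: LabelSequence | str | np.ndarray,
                           source_id: str = "") -> TransitionSequence:
    """Build a transition sequence from labels.

    Unlabeled frames are dropped first, then consecutive duplicates are
    collapsed.  Accepts a :class:`LabelSequence`, an integer label array, or
    a symbol string.
    """
    if isinstance(seq, LabelSequence):
        labels = seq.labels
        source_id = source_id or seq.source_id
        symbols = "".join(_ALPHABET[v] for v in labels if v != UNLABELED)
    elif isinstance(seq, str):
        symbols = seq
    else:
        labels = np.asarray(seq)
        symbols = "".join(_ALPHABET[int(v)] for v in labels
                          if int(v) != UNLABELED)
    if not symbols:
        raise EmptyResultError("no labeled content to build a transition "
                               "sequence from")
    return TransitionSequence(symbols=collapse(symbols), source_id=source_id)


def extract_words(ts: TransitionSequence | str, m: int) -> dict[str, int]:
    """Counts of all overlapping m-symbol words (sliding by one symbol)."""
    s = ts.symbols if isinstance(ts, TransitionSequence) else ts
    if m < 1:
        raise ParameterError("word length m must be >= 1")
    if len(s) < m:
        raise ParameterError(
            f"sequence of length {len(s)} too short for m={m}")
    counts: dict[str, int] = {}
    for i in range(len(s) - m + 1):
        w = s[i:i + m]
        counts[w] = counts.get(w, 0) + 1
    return counts


def _rank_words(counts: dict[str, int], vocabulary: list[str]
                ) -> tuple[dict[str, float], dict[str, int]]:
    """Probabilities and ranks of every vocabulary word in one sequence.

    Present words are ranked 1..n by descending probability (lexicographic
    tie-break); absent words (p = 0) follow, lexicographically.
    """
    total = sum(counts.values())
    p = {w: counts.get(w, 0) / total for w in vocabulary}
    present = sorted((w for w in vocabulary if p[w] > 0),
                     key=lambda w: (-p[w], w))
    absent = sorted(w for w in vocabulary if p[w] == 0)
    ranks = {w: i + 1 for i, w in enumerate(present + absent)}
    return p, ranks


def ibs_distance(ts1: TransitionSequence | str, ts2: TransitionSequence | str,
                 m: int) -> float:
    """Information-based similarity distance between two symbol sequences.

    D = sum_w |R1(w) - R2(w)| * F(w) / (K - 1) over the union vocabulary of
    size K, with F(w) the normalized Shannon-entropy weight
    (-p1 log p1 - p2 log p2) / Z.  D lies in [0, 1]; identical sequences give
    0.
    """
    c1 = extract_words(ts1, m)
    c2 = extract_words(ts2, m)
    vocabulary = sorted(set(c1) | set(c2))
    k = len(vocabulary)
    if k < 2:
        raise DegenerateInputError(
            "union vocabulary must contain at least 2 words")
    p1, r1 = _rank_words(c1, vocabulary)
    p2, r2 = _rank_words(c2, vocabulary)

    def _ent(p: float) -> float:
        return -p * math.log(p) if p > 0 else 0.0

    e = {w: _ent(p1[w]) + _ent(p2[w]) for w in vocabulary}
    z = sum(e.values())
    if z > 0:
        f = {w: e[w] / z for w in vocabulary}
    else:
        # both sequences concentrate all mass on one word each
        f = {w: 1.0 / k for w in vocabulary}
    return sum(abs(r1[w] - r2[w]) * f[w] for w in vocabulary) / (k - 1)


def shuffle_surrogate(ts: TransitionSequence, rng: np.random.Generator,
                      max_tries: int = 100) -> TransitionSequence:
    """Uniform random permutation of the symbols, re-collapsed.

    Shuffling preserves the symbol distribution but destroys ordering;
    re-collapsing keeps the result a valid transition sequence.
    """
    symbols = np.array(list(ts.symbols))
    for _ in range(max_tries):
        perm = collapse("".join(rng.permutation(symbols)))
        if len(perm) >= 2:
            return TransitionSequence(symbols=perm, source_id=ts.source_id)
    raise DegenerateInputError("could not build a usable surrogate")


def msnri(ts: TransitionSequence | str, m: int = DEFAULT_M,
          n_surrogates: int = DEFAULT_N_SURROGATES, seed: int = 0) -> float:
    """Microstate sequence non-randomness index.

    Mean IBS distance between ``ts`` and ``n_surrogates`` shuffled
    surrogates, reported on a x100 display scale.  ``n_surrogates=1``
    reproduces the single-shuffle definition.  Deterministic given ``seed``.
    """
    if isinstance(ts, str):
        ts = TransitionSequence(symbols=collapse(ts))
    if len(ts) < m + 1:
        raise ParameterError("sequence too short for the requested m")
    rng = np.random.default_rng(seed)
    dists = []
    for _ in range(n_surrogates):
        surrogate = shuffle_surrogate(ts, rng)
        while len(surrogate) < m:
            surrogate = shuffle_surrogate(ts, rng)
        dists.append(ibs_distance(ts, surrogate, m))
    return 100.0 * float(np.mean(dists))


def lz76_complexity(s: str) -> int:
    """Number of phrases in the LZ76 exhaustive production history of ``s``.

    Scanning left to right, each new phrase is the shortest prefix of the
    remaining suffix that has not appeared as a substring of everything seen
    so far (including the phrase's own body minus its last symbol).
    """
    n = len(s)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and s[i:i + length] in s[:i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def mslzc(ts: TransitionSequence | str) -> float:
    """Normalized LZ76 complexity of a transition sequence: c(n) / n."""
    s = ts.symbols if isinstance(ts, TransitionSequence) else ts
    if len(s) < 2:
        raise ParameterError("sequence too short for LZ complexity")
    return lz76_complexity(s) / len(s)


def symbolize_timeseries(x: np.ndarray) -> str:
    """Binary increment coding of a 1-D series.

    Symbol t is '1' if x(t+1) > x(t) else '0'; the result has length n - 1.
    No duplicate-collapsing is applied (the raw stream is the object of
    interest for time-series complexity), so treat the output as a plain
    symbol string.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("need a 1-D series of length >= 2")
    return "".join("1" if b > a else "0" for a, b in zip(x[:-1], x[1:]))


def timeseries_nri(x: np.ndarray, m: int = DEFAULT_M,
                   n_surrogates: int = DEFAULT_N_SURROGATES,
                   seed: int = 0) -> float:
    """Non-randomness index of a raw time series via binary symbolization.

    Like :func:`msnri` but on the uncollapsed increment-coded stream:
    surrogates are plain shuffles of the binary symbols.
    """
    s = symbolize_timeseries(x)
    if len(s) < m + 1:
        raise ParameterError("series too short for the requested m")
    rng = np.random.default_rng(seed)
    arr = np.array(list(s))
    dists = []
    for _ in range(n_surrogates):
        surrogate = "".join(rng.permutation(arr))
        dists.append(ibs_distance(s, surrogate, m))
    return 100.0 * float(np.mean(dists))


def timeseries_lzc(x: np.ndarray) -> float:
    """Normalized LZ76 complexity of the increment-coded series."""
    s = symbolize_timeseries(x)
    return lz76_complexity(s) / len(s)
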