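"""Domain types for call-combination corpora.

A :class:`Corpus` is a collection of call sequences (a plain bigram list is
the special case where every sequence has length two).  Bigrams are
extracted with either an adjacent-overlapping window — sequence
``A,B,C`` yields ``(A,B)`` and ``(B,C)`` — or a non-overlapping window,
which yields ``(A,B)`` only.  Extracted bigrams are cross-tabulated into a
:class:`BigramCountTable`, the square ordered-pair count matrix that both
collocation statistics consume.

Marginal conventions
--------------------
For a table with counts ``c[a][b]`` over ``n_pairs`` bigram tokens:

* ``f_first(a)``  — row marginal: tokens of ``a`` in the first slot,
* ``f_second(b)`` — column marginal: tokens of ``b`` in the second slot,
* ``f_token(a) = f_first(a) + f_second(a)`` — total call tokens of ``a``,

so that ``sum(f_token) = n_calls = 2 * n_pairs`` for a pure bigram corpus.
A self-pair ``(A,A)`` contributes 2 to ``f_token(A)``, keeping the token
ledger exact.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RepertoireError, UnknownLabelError

__all__ = [
    "Repertoire",
    "Corpus",
    "BigramCountTable",
    "tabulate_bigrams",
    "marginals",
    "WINDOW_OVERLAP",
    "WINDOW_DISJOINT",
]

WINDOW_OVERLAP = "overlap"
WINDOW_DISJOINT = "disjoint"
_WINDOWS = (WINDOW_OVERLAP, WINDOW_DISJOINT)


def _clean_label(label: str) -> str:
    if not isinstance(label, str):
        raise RepertoireError(f"call labels must be text, got {type(label).__name__}")
    cleaned = label.strip()
    if not cleaned:
        raise RepertoireError("call labels must not be empty or whitespace-only")
    return cleaned


@dataclass(frozen=True)
class Repertoire:
    """Ordered inventory of distinct call-type labels.

    Labels are case-sensitive and trimmed of surrounding whitespace.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        # An empty repertoire is allowed so an empty corpus has a valid
        # (all-zero) table; any actual analysis needs >= 2 call types.
        cleaned = tuple(_clean_label(x) for x in labels)
        if len(set(cleaned)) != len(cleaned):
            dupes = sorted({x for x in cleaned if cleaned.count(x) > 1})
            raise RepertoireError(f"duplicate call labels: {dupes}")
        object.__setattr__(self, "labels", cleaned)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownLabelError(str(label)) from None


@dataclass(frozen=True)
class Corpus:
    """A multiset of call sequences over a repertoire.

    ``sequences`` holds ordered call-label tuples; a pure bigram corpus is
    one where every sequence has length 2.  ``provenance`` is a free-text
    note recording where the corpus came from (file path, simulation seed).
    """

    sequences: tuple[tuple[str, ...], ...]
    repertoire: Repertoire
    provenance: str = ""

    def __init__(
        self,
        sequences: Iterable[Sequence[str]],
        repertoire: Repertoire | None = None,
        provenance: str = "",
    ):
        seqs = tuple(tuple(_clean_label(c) for c in s) for s in sequences)
        if repertoire is None:
            seen: dict[str, None] = {}
            for s in seqs:
                for c in s:
                    seen.setdefault(c, None)
            repertoire = Repertoire(seen)
        else:
            for s in seqs:
                for c in s:
                    if c not in repertoire:
                        raise UnknownLabelError(c)
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "repertoire", repertoire)
        object.__setattr__(self, "provenance", provenance)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]] | Counter,
        repertoire: Repertoire | None = None,
        provenance: str = "",
    ) -> "Corpus":
        """Build a pure bigram corpus from pair tokens or a pair Counter."""
        if isinstance(pairs, Counter):
            expanded: list[tuple[str, str]] = []
            for (a, b), k in sorted(pairs.items()):
                if k < 0:
                    raise RepertoireError(f"negative count for pair {(a, b)}")
                expanded.extend([(a, b)] * int(k))
            pairs = expanded
        return cls(pairs, repertoire=repertoire, provenance=provenance)

    @property
    def is_pair_list(self) -> bool:
        return all(len(s) == 2 for s in self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sequences)

    def bigrams(self, window: str = WINDOW_OVERLAP) -> Counter:
        """Extract bigram tokens under the given window mode.

        Both modes coincide on a pure pair list.  Sequences of length < 2
        contribute no bigrams.
        """
        if window not in _WINDOWS:
            raise ValueError(f"window must be one of {_WINDOWS}, got {window!r}")
        out: Counter = Counter()
        step = 1 if window == WINDOW_OVERLAP else 2
        for s in self.sequences:
            for i in range(0, len(s) - 1, step):
                out[(s[i], s[i + 1])] += 1
        return out

    def tokens(self, window: str = WINDOW_OVERLAP) -> list[str]:
        """All call tokens taking part in bigrams, in extraction order."""
        toks: list[str] = []
        for (a, b), k in sorted(self.bigrams(window).items()):
            toks.extend([a, b] * k)
        return toks


@dataclass(frozen=True)
class BigramCountTable:
    """Square ordered-pair count matrix with its marginals.

    ``counts[i, j]`` is the number of bigram tokens whose first call is
    ``labels[i]`` and second call is ``labels[j]``.
    """

    labels: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the repertoire labels")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("bigram counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("bigram counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @classmethod
    def from_counter(cls, bigram_counts: Counter, repertoire: Repertoire) -> "BigramCountTable":
        labels = repertoire.labels
        idx = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for (a, b), k in bigram_counts.items():
            if a not in idx:
                raise UnknownLabelError(a)
            if b not in idx:
                raise UnknownLabelError(b)
            counts[idx[a], idx[b]] += k
        return cls(labels=tuple(labels), counts=counts)

    # -- totals and marginals -------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_calls(self) -> int:
        return 2 * self.n_pairs

    @property
    def f_first(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=list(self.labels), name="f_first")

    @property
    def f_second(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=list(self.labels), name="f_second")

    @property
    def f_token(self) -> pd.Series:
        s = self.f_first + self.f_second
        s.name = "f_token"
        return s

    def count(self, first: str, second: str) -> int:
        i = self.labels.index(first) if first in self.labels else None
        j = self.labels.index(second) if second in self.labels else None
        if i is None:
            raise UnknownLabelError(first)
        if j is None:
            raise UnknownLabelError(second)
        return int(self.counts[i, j])

    def scale(self, c: int) -> "BigramCountTable":
        """Multiply every cell by a positive integer factor."""
        if int(c) != c or c < 1:
            raise ValueError("scale factor must be a positive integer")
        return BigramCountTable(labels=self.labels, counts=self.counts * int(c))

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame, rows = first slot, columns = second slot."""
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def observed_pairs(self) -> list[tuple[str, str]]:
        """Ordered pairs with a positive count, sorted lexicographically."""
        ii, jj = np.nonzero(self.counts)
        return sorted((self.labels[i], self.labels[j]) for i, j in zip(ii, jj))


def tabulate_bigrams(corpus: Corpus, window: str = WINDOW_OVERLAP) -> BigramCountTable:
    """Cross-tabulate a corpus into a bigram count table.

    An empty corpus yields a valid all-zero table (``n_pairs == 0``).
    """
    return BigramCountTable.from_counter(corpus.bigrams(window), corpus.repertoire)


def marginals(table: BigramCountTable) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Return the ``(f_first, f_second, f_token)`` marginal vectors."""
    return table.f_first, table.f_second, table.f_token
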