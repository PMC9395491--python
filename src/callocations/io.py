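"""Reading and writing delimited call-combination files.

Two dialects are supported, with the delimiter auto-detected from the file
extension (``.csv`` → comma, anything else → tab):

* **pair list** — header ``first,second[,count]``; one bigram type per
  row, absent count defaults to 1, repeated rows aggregate by summation.
* **sequence file** — long format ``sequence_id,position,call`` with
  consecutive integer positions per sequence starting at 1.

Each reader logs a parse report (rows read, rows aggregated, labels
discovered) at INFO level.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from pathlib import Path

import pandas as pd

from .corpus import Corpus, Repertoire
from .errors import ParseError

__all__ = [
    "read_pairs",
    "read_sequences",
    "write_corpus",
    "write_frame",
    "detect_delimiter",
]

logger = logging.getLogger(__name__)

PAIR_HEADER = ("first", "second")
SEQ_HEADER = ("sequence_id", "position", "call")


def detect_delimiter(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _open_rows(path: str | Path, delimiter: str):
    with open(path, newline="") as handle:
        yield from csv.reader(handle, delimiter=delimiter)


def read_pairs(path: str | Path, repertoire: Repertoire | None = None) -> Corpus:
    """Read a pair-list file into a pure bigram corpus.

    An empty file yields an empty corpus with a warning.
    """
    path = Path(path)
    delimiter = detect_delimiter(path)
    rows = list(_open_rows(path, delimiter))
    if not rows:
        logger.warning("pair file %s is empty", path)
        return Corpus([], repertoire=repertoire, provenance=str(path))

    header = tuple(h.strip().lower() for h in rows[0])
    if header not in (PAIR_HEADER, PAIR_HEADER + ("count",)):
        raise ParseError(
            f"expected header 'first,second[,count]', got {','.join(rows[0])!r}",
            line=1,
        )
    has_count = len(header) == 3

    pairs: Counter = Counter()
    n_rows = 0
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(row)}", line=lineno
            )
        first, second = row[0].strip(), row[1].strip()
        if not first or not second:
            raise ParseError("empty call label", line=lineno)
        if has_count:
            try:
                count = int(row[2])
            except ValueError:
                raise ParseError(f"count {row[2]!r} is not an integer", line=lineno)
            if count < 0:
                raise ParseError(f"negative count {count}", line=lineno)
        else:
            count = 1
        pairs[(first, second)] += count
        n_rows += 1

    corpus = Corpus.from_pairs(pairs, repertoire=repertoire, provenance=str(path))
    logger.info(
        "read %s: %d rows, %d distinct pair types, %d pair tokens, %d call labels",
        path,
        n_rows,
        len(pairs),
        sum(pairs.values()),
        len(corpus.repertoire),
    )
    return corpus


def read_sequences(path: str | Path, repertoire: Repertoire | None = None) -> Corpus:
    """Read a long-format sequence file into a corpus of call sequences."""
    path = Path(path)
    delimiter = detect_delimiter(path)
    rows = list(_open_rows(path, delimiter))
    if not rows:
        logger.warning("sequence file %s is empty", path)
        return Corpus([], repertoire=repertoire, provenance=str(path))

    header = tuple(h.strip().lower() for h in rows[0])
    if header != SEQ_HEADER:
        raise ParseError(
            f"expected header 'sequence_id,position,call', got {','.join(rows[0])!r}",
            line=1,
        )

    by_sequence: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    n_rows = 0
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != 3:
            raise ParseError(f"expected 3 fields, got {len(row)}", line=lineno)
        seq_id, pos_text, call = row[0].strip(), row[1].strip(), row[2].strip()
        if not seq_id or not call:
            raise ParseError("empty sequence id or call label", line=lineno)
        try:
            pos = int(pos_text)
        except ValueError:
            raise ParseError(f"position {pos_text!r} is not an integer", line=lineno)
        if seq_id not in by_sequence:
            by_sequence[seq_id] = []
            order.append(seq_id)
        by_sequence[seq_id].append((pos, call))
        n_rows += 1

    sequences = []
    for seq_id in order:
        entries = sorted(by_sequence[seq_id])
        positions = [p for p, _ in entries]
        if positions != list(range(1, len(entries) + 1)):
            raise ParseError(
                f"sequence {seq_id!r} positions are not consecutive from 1: "
                f"{positions}"
            )
        sequences.append(tuple(call for _, call in entries))

    corpus = Corpus(sequences, repertoire=repertoire, provenance=str(path))
    logger.info(
        "read %s: %d rows, %d sequences, %d call tokens, %d call labels",
        path,
        n_rows,
        len(sequences),
        corpus.n_tokens,
        len(corpus.repertoire),
    )
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as an aggregated pair list (sorted, deterministic)."""
    path = Path(path)
    delimiter = detect_delimiter(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["first", "second", "count"])
        for (a, b), k in sorted(corpus.bigrams().items()):
            writer.writerow([a, b, k])


def write_frame(
    frame: pd.DataFrame,
    path: str | Path,
    round_digits: int | None = None,
) -> None:
    """Write a results frame as delimited text (delimiter by extension)."""
    out = frame.copy()
    if round_digits is not None:
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(round_digits)
    out.to_csv(path, sep=detect_delimiter(path), index=False)
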