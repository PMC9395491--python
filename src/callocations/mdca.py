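"""Multiple Distinctive Collocation Analysis (MDCA).

Each ordered call pair ``(first, second)`` in a bigram count table is
scored with a signed, log-transformed binomial tail probability ("pbin").
With ``k`` the observed pair count, ``n`` the first-slot marginal of the
first call, and ``p`` the second-slot marginal proportion of the second
call (``f_second(second) / n_pairs``):

* ``k > n*p``  → attraction, ``score = -log10 P(X >= k)``, ``X ~ Bin(n, p)``
* ``k < n*p``  → repulsion,  ``score = +log10 P(X <= k)`` (negative)
* ``k == n*p`` → independent, ``score = 0``

Absolute scores translate to the usual significance bands
(``|pbin| > 3``: p < 0.001, ``> 2``: p < 0.01, ``> 1.3``: p < 0.05,
otherwise NS).  Because each ordered pair is scored separately, MDCA also
exposes linearisation: whether a combination is tied to one call order.

Scores carry no multiplicity correction — the banding thresholds apply to
the raw per-pair tails.  :func:`mdca_frame` additionally reports a
Holm-adjusted band column for users who want family-wise control over the
full matrix of tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .corpus import BigramCountTable
from .errors import AnalysisError, UnknownLabelError
from .result import ATTRACTION, INDEPENDENT, REPULSION, CollocationResult

__all__ = [
    "mdca_score",
    "mdca_matrix",
    "mdca_frame",
    "score_matrix",
    "significance_band",
    "order_asymmetry",
    "OrderAsymmetry",
    "BANDS",
]

#: (threshold on |score|, band label), strict inequalities, checked in order.
BANDS: tuple[tuple[float, str], ...] = (
    (3.0, "p<0.001"),
    (2.0, "p<0.01"),
    (1.3, "p<0.05"),
)

NS = "NS"


def significance_band(score: float) -> str:
    """Map a signed pbin score to its significance-band label.

    Bands are applied to ``|score|`` with strict inequalities:
    ``>3 → p<0.001``, ``>2 → p<0.01``, ``>1.3 → p<0.05``, else ``NS``.
    """
    if not math.isfinite(score):
        raise AnalysisError(f"cannot band a non-finite score: {score!r}")
    mag = abs(score)
    for threshold, label in BANDS:
        if mag > threshold:
            return label
    return NS


def mdca_score(table: BigramCountTable, first: str, second: str) -> CollocationResult:
    """Score one ordered pair with the signed binomial-tail statistic.

    Requires ``f_first(first) > 0``: a call that never occupies the first
    slot has no trials to test.
    """
    if first not in table.labels:
        raise UnknownLabelError(first)
    n = int(table.f_first[first])
    if n == 0:
        raise AnalysisError(
            f"{first!r} never occurs in the first slot; the ordered pair "
            f"({first}, {second}) has no trials"
        )
    k = table.count(first, second)
    n_pairs = table.n_pairs
    p = float(table.f_second[second]) / n_pairs
    expected = n * p
    if p == 0.0 and k > 0:
        raise AnalysisError(
            f"internal inconsistency: ({first}, {second}) observed {k} times "
            f"but {second!r} has zero second-slot frequency"
        )

    if k > expected:
        tail = float(binom.sf(k - 1, n, p))  # P(X >= k)
        score = -math.log10(tail)
        direction = ATTRACTION
    elif k < expected:
        tail = float(binom.cdf(k, n, p))  # P(X <= k)
        score = math.log10(tail)
        direction = REPULSION
    else:
        score = 0.0
        direction = INDEPENDENT

    return CollocationResult(
        pair=(first, second),
        observed=k,
        trials=n,
        success_prob=p,
        expected=expected,
        score=score,
        direction=direction,
        band=significance_band(score),
    )


def mdca_matrix(table: BigramCountTable) -> dict[tuple[str, str], CollocationResult]:
    """Score every ordered pair whose first call has first-slot trials.

    Returns a mapping ``(first, second) -> CollocationResult`` covering all
    ordered pairs (including unobserved ones) with ``f_first(first) > 0``.
    """
    results: dict[tuple[str, str], CollocationResult] = {}
    f_first = table.f_first
    for first in table.labels:
        if f_first[first] == 0:
            continue
        for second in table.labels:
            results[(first, second)] = mdca_score(table, first, second)
    return results


def _holm_bands(scores: pd.Series) -> list[str]:
    # Per-pair p-values are 10**(-|score|); Holm then re-banded on the
    # -log10 adjusted p scale so both columns read in the same units.
    pvals = np.power(10.0, -scores.abs().to_numpy(dtype=float))
    adjusted = multipletests(pvals, method="holm")[1]
    with np.errstate(divide="ignore"):
        mags = -np.log10(adjusted)
    return [significance_band(min(m, 350.0)) for m in mags]


def mdca_frame(table: BigramCountTable) -> pd.DataFrame:
    """Tidy MDCA results, one row per scorable ordered pair.

    Columns: ``first, second, observed, trials, success_prob, expected,
    score, direction, band, band_holm``; sorted by score descending then
    lexicographically.
    """
    results = mdca_matrix(table)
    rows = [
        {
            "first": r.pair[0],
            "second": r.pair[1],
            "observed": r.observed,
            "trials": r.trials,
            "success_prob": r.success_prob,
            "expected": r.expected,
            "score": r.score,
            "direction": r.direction,
            "band": r.band,
        }
        for r in results.values()
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "first",
            "second",
            "observed",
            "trials",
            "success_prob",
            "expected",
            "score",
            "direction",
            "band",
        ],
    )
    if frame.empty:
        frame["band_holm"] = pd.Series(dtype=str)
        return frame
    frame["band_holm"] = _holm_bands(frame["score"])
    frame = frame.sort_values(
        ["score", "first", "second"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def score_matrix(table: BigramCountTable) -> pd.DataFrame:
    """Wide pbin matrix: rows = second unit, columns = first unit.

    Cells for first calls with no first-slot trials are NaN.
    """
    results = mdca_matrix(table)
    mat = pd.DataFrame(np.nan, index=list(table.labels), columns=list(table.labels))
    for (first, second), r in results.items():
        mat.loc[second, first] = r.score
    mat.index.name = "second"
    mat.columns.name = "first"
    return mat


class OrderAsymmetry:
    """Linearisation report for an unordered call pair.

    ``forward`` and ``reverse`` are the two directed results (``None`` when
    that direction has no first-slot trials).  ``classification`` is

    * ``ordered``       — exactly one direction is a significant attraction,
    * ``bidirectional`` — both directions are,
    * ``none``          — neither is.
    """

    def __init__(
        self,
        a: str,
        b: str,
        forward: CollocationResult | None,
        reverse: CollocationResult | None,
    ):
        self.pair = (a, b)
        self.forward = forward
        self.reverse = reverse
        n_sig = sum(self._significant(r) for r in (forward, reverse))
        self.classification = {0: "none", 1: "ordered", 2: "bidirectional"}[n_sig]

    @staticmethod
    def _significant(r: CollocationResult | None) -> bool:
        return r is not None and r.direction == ATTRACTION and r.band != NS

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"OrderAsymmetry({self.pair[0]}-{self.pair[1]}: {self.classification})"


def order_asymmetry(table: BigramCountTable, a: str, b: str) -> OrderAsymmetry:
    """Report whether the combination ``{a, b}`` is tied to one call order."""
    if a == b:
        raise AnalysisError("order asymmetry needs two distinct call types")
    for label in (a, b):
        if label not in table.labels:
            raise UnknownLabelError(label)

    def _maybe(first: str, second: str) -> CollocationResult | None:
        if table.f_first[first] == 0:
            return None
        return mdca_score(table, first, second)

    return OrderAsymmetry(a, b, _maybe(a, b), _maybe(b, a))
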