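"""Mutual Information Collocation Analysis (MICA).

Pointwise mutual information in bits for unordered call pairs.  With
``obs`` the order-collapsed pair count (``counts[a][b] + counts[b][a]``
for distinct calls) and ``f_token`` the per-call token frequency over a
corpus of ``n_calls`` call tokens,

    expected  E(a, b) = f_token(a) * f_token(b) / n_calls
    score     = log2(obs / E(a, b))

A score of 0 means the two calls pair at exactly the chance rate; positive
scores mark attraction, negative scores repulsion.  Because both observed
and expected counts scale linearly with corpus size, the score is exactly
invariant under uniform scaling of the corpus — unlike the binomial
statistic, which grows with sample size.  The flip side is sensitivity to
the internal frequency distribution: of two fully exclusive combinations,
the rarer one earns the larger score.

An unobserved pair has no finite log-ratio; it is reported with score NaN,
direction ``not-observed`` and band ``NA`` rather than −inf, and no
pseudo-count smoothing is applied.

The same band labels used for the binomial statistic are attached to
``|score|`` as a reading convention; for an information measure they are
descriptive labels, not calibrated significance tests.
"""

from __future__ import annotations

import math

import pandas as pd

from .corpus import BigramCountTable
from .errors import AnalysisError, UnknownLabelError
from .mdca import significance_band
from .result import ATTRACTION, INDEPENDENT, NOT_OBSERVED, REPULSION, CollocationResult

__all__ = ["mica_score", "mica_table", "mica_frame", "BAND_NA"]

BAND_NA = "NA"


def mica_score(table: BigramCountTable, a: str, b: str) -> CollocationResult:
    """Score one unordered call pair in bits of shared information.

    Both calls must occur somewhere in the corpus (``f_token > 0``).
    The pair is reported alphabetically sorted; ``mica_score(t, a, b)``
    and ``mica_score(t, b, a)`` are identical.
    """
    for label in (a, b):
        if label not in table.labels:
            raise UnknownLabelError(label)
        if table.f_token[label] == 0:
            raise AnalysisError(f"{label!r} has zero token frequency in this corpus")

    if a == b:
        observed = table.count(a, a)
    else:
        observed = table.count(a, b) + table.count(b, a)
    f_tok = table.f_token
    expected = float(f_tok[a]) * float(f_tok[b]) / table.n_calls
    pair = (a, b) if a <= b else (b, a)

    if observed == 0:
        return CollocationResult(
            pair=pair,
            observed=0,
            trials=None,
            success_prob=None,
            expected=expected,
            score=math.nan,
            direction=NOT_OBSERVED,
            band=BAND_NA,
        )

    score = math.log2(observed / expected)
    if score > 0:
        direction = ATTRACTION
    elif score < 0:
        direction = REPULSION
    else:
        direction = INDEPENDENT
    return CollocationResult(
        pair=pair,
        observed=observed,
        trials=None,
        success_prob=None,
        expected=expected,
        score=score,
        direction=direction,
        band=significance_band(score),
    )


def mica_table(
    table: BigramCountTable, include_unobserved: bool = False
) -> list[CollocationResult]:
    """Score unordered pairs over the corpus's occurring call types.

    By default only pairs with a positive order-collapsed count are
    returned; ``include_unobserved=True`` lists every unordered pair of
    occurring calls.  Results are sorted by score descending (NaN last),
    then alphabetically.
    """
    present = [c for c in table.labels if table.f_token[c] > 0]
    results = []
    for i, a in enumerate(present):
        for b in present[i:]:
            r = mica_score(table, a, b)
            if r.observed > 0 or include_unobserved:
                results.append(r)
    results.sort(
        key=lambda r: (
            0 if math.isfinite(r.score) else 1,
            -(r.score if math.isfinite(r.score) else 0.0),
            r.pair,
        )
    )
    return results


def mica_frame(table: BigramCountTable, include_unobserved: bool = False) -> pd.DataFrame:
    """Tidy MICA results: ``call_a, call_b, observed, expected, score,
    direction, band`` with the unordered pair written alphabetically."""
    rows = [
        {
            "call_a": r.pair[0],
            "call_b": r.pair[1],
            "observed": r.observed,
            "expected": r.expected,
            "score": r.score,
            "direction": r.direction,
            "band": r.band,
        }
        for r in mica_table(table, include_unobserved=include_unobserved)
    ]
    return pd.DataFrame(
        rows,
        columns=["call_a", "call_b", "observed", "expected", "score", "direction", "band"],
    )
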