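"""Shared result container for collocation scores."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CollocationResult",
    "ATTRACTION",
    "REPULSION",
    "INDEPENDENT",
    "NOT_OBSERVED",
]

ATTRACTION = "attraction"
REPULSION = "repulsion"
INDEPENDENT = "independent"
NOT_OBSERVED = "not-observed"


@dataclass(frozen=True)
class CollocationResult:
    """One scored call pair.

    Attributes
    ----------
    pair:
        The scored pair.  Ordered ``(first, second)`` for the distinctive
        (binomial) analysis; alphabetically sorted for the order-collapsed
        mutual-information analysis.
    observed:
        Observed bigram-token count (the binomial ``k`` where applicable).
    trials:
        Binomial ``n`` (first-slot marginal of the first call); ``None``
        for the mutual-information statistic, which has no trial count.
    success_prob:
        Binomial success probability ``p`` in [0, 1]; ``None`` where not
        applicable.
    expected:
        Chance expectation ``E`` for the pair count under independence.
    score:
        Signed statistic: −log10 binomial tail probability (distinctive)
        or log2 observed/expected in bits (mutual information).  ``nan``
        for an unobserved pair under the mutual-information statistic.
    direction:
        ``attraction`` (observed above expectation), ``repulsion`` (below),
        ``independent`` (exactly at expectation) or ``not-observed``.
    band:
        Significance-band label derived from ``|score|``.
    """

    pair: tuple[str, str]
    observed: int
    trials: int | None
    success_prob: float | None
    expected: float
    score: float
    direction: str
    band: str

    def __post_init__(self):
        if self.expected < 0:
            raise ValueError("expected count must be non-negative")
        if self.trials is not None and self.observed > self.trials:
            raise ValueError("observed exceeds the number of trials")
        if math.isfinite(self.score):
            if self.score > 0 and self.direction != ATTRACTION:
                raise ValueError("positive score requires direction 'attraction'")
            if self.score < 0 and self.direction != REPULSION:
                raise ValueError("negative score requires direction 'repulsion'")
            if self.score == 0 and self.direction != INDEPENDENT:
                raise ValueError("zero score requires direction 'independent'")
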