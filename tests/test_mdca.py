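"""Signed binomial-tail collocation statistic (distinctive analysis)."""

import math
from collections import Counter
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from callocations import (
    AnalysisError,
    Corpus,
    Repertoire,
    SyntheticSpec,
    mdca_matrix,
    mdca_score,
    order_asymmetry,
    shuffle_null,
    significance_band,
    simulate_corpus,
    tabulate_bigrams,
)
from callocations.mdca import mdca_frame


def upper_tail(k: int, n: int, p: float) -> float:
    """Brute-force P(X >= k) by term-by-term pmf summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def lower_tail(k: int, n: int, p: float) -> float:
    """Brute-force P(X <= k) by term-by-term pmf summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


class TestScore:
    @pytest.mark.parametrize(
        "pair, expected",
        [(("Huff", "Puff"), 2.4), (("Peep", "Howl"), 2.5), (("Howl", "Peep"), 2.5)],
    )
    def test_small_exclusive_values(self, se_table, pair, expected):
        r = mdca_score(se_table, *pair)
        assert round(r.score, 1) == expected
        assert r.direction == "attraction"

    @pytest.mark.parametrize(
        "pair, expected",
        [(("Huff", "Puff"), 24.1), (("Peep", "Howl"), 25.3), (("Howl", "Peep"), 25.1)],
    )
    def test_large_exclusive_values(self, le_table, pair, expected):
        assert round(mdca_score(le_table, *pair).score, 1) == expected

    def test_huff_puff_binomial_ingredients(self, se_table):
        r = mdca_score(se_table, "Huff", "Puff")
        assert (r.observed, r.trials) == (4, 4)
        assert r.success_prob == pytest.approx(4 / 16)
        assert r.expected == pytest.approx(1.0)

    def test_observed_equal_expected_is_independent(self):
        pairs = Counter({("A", "B"): 1, ("C", "B"): 1, ("A", "D"): 1, ("C", "D"): 1})
        table = tabulate_bigrams(Corpus.from_pairs(pairs))
        r = mdca_score(table, "A", "B")
        assert r.expected == pytest.approx(1.0)
        assert r.direction == "independent"
        assert r.score == 0.0

    def test_saturated_single_pair_type_is_independent(self):
        table = tabulate_bigrams(Corpus.from_pairs(Counter({("A", "B"): 5})))
        r = mdca_score(table, "A", "B")
        assert r.success_prob == 1.0
        assert r.direction == "independent"
        assert r.score == 0.0

    def test_unobserved_pair_scored_as_repulsion(self):
        pairs = Counter({("A", "B"): 6, ("C", "D"): 6, ("A", "D"): 2})
        table = tabulate_bigrams(Corpus.from_pairs(pairs))
        r = mdca_score(table, "C", "B")
        assert r.observed == 0 and r.expected > 0
        assert r.direction == "repulsion"
        assert r.score == pytest.approx(math.log10(lower_tail(0, 6, 6 / 14)))
        assert r.score < 0

    def test_first_slot_absent_raises(self, se_table):
        with pytest.raises(AnalysisError, match="first slot"):
            mdca_score(se_table, "Puff", "Huff")  # Puff never leads

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 6), min_size=16, max_size=16),
        data=st.data(),
    )
    def test_matches_bruteforce_pmf_summation(self, counts, data):
        """Tail probabilities agree with explicit pmf sums (rel err < 1e-12)."""
        labels = ("A", "B", "C", "D")
        mat = np.array(counts, dtype=np.int64).reshape(4, 4)
        table = tabulate_bigrams(
            Corpus.from_pairs(
                Counter(
                    {
                        (labels[i], labels[j]): int(mat[i, j])
                        for i in range(4)
                        for j in range(4)
                        if mat[i, j]
                    }
                ),
                repertoire=Repertoire(labels),
            )
        )
        if table.n_pairs == 0:
            return
        scorable = [a for a in labels if table.f_first[a] > 0]
        first = data.draw(st.sampled_from(scorable))
        second = data.draw(st.sampled_from(labels))
        r = mdca_score(table, first, second)
        assert table.f_first[first] <= 25  # oracle regime
        k, n, p = r.observed, r.trials, r.success_prob
        if r.direction == "attraction":
            assert 10.0 ** (-r.score) == pytest.approx(upper_tail(k, n, p), rel=1e-12)
        elif r.direction == "repulsion":
            assert 10.0**r.score == pytest.approx(lower_tail(k, n, p), rel=1e-12)
        else:
            assert k == pytest.approx(n * p)


class TestMatrix:
    def test_small_exclusive_matrix(self, se_table):
        results = mdca_matrix(se_table)
        observed = {pair: r for pair, r in results.items() if r.observed > 0}
        assert sorted(observed) == [("Howl", "Peep"), ("Huff", "Puff"), ("Peep", "Howl")]
        assert [round(observed[p].score, 1) for p in sorted(observed)] == [2.5, 2.4, 2.5]

    def test_matrix_cells_equal_per_pair_scores(self, se_table):
        for (a, b), r in mdca_matrix(se_table).items():
            assert r == mdca_score(se_table, a, b)

    def test_frame_orders_by_score_then_lexicographic(self, se_table):
        frame = mdca_frame(se_table)
        assert list(frame["score"]) == sorted(frame["score"], reverse=True)
        assert "band_holm" in frame.columns


class TestBands:
    @pytest.mark.parametrize(
        "score, band",
        [
            (2.4, "p<0.01"),
            (0.0, "NS"),
            (1.3, "NS"),  # strict boundary
            (1.31, "p<0.05"),
            (-2.4, "p<0.01"),  # applied to |score|
            (3.0, "p<0.01"),
            (3.01, "p<0.001"),
        ],
    )
    def test_band_thresholds(self, score, band):
        assert significance_band(score) == band

    def test_non_finite_score_rejected(self):
        with pytest.raises(AnalysisError):
            significance_band(math.nan)


class TestOrderAsymmetry:
    def test_strictly_ordered_pair(self, se_table):
        rep = order_asymmetry(se_table, "Huff", "Puff")
        assert rep.classification == "ordered"
        assert rep.reverse is None  # Puff never occupies the first slot

    def test_order_flexible_pair(self, se_table):
        assert order_asymmetry(se_table, "Peep", "Howl").classification == "bidirectional"

    def test_never_cooccurring_pair(self):
        pairs = Counter({("A", "B"): 5, ("C", "D"): 5, ("A", "D"): 5, ("C", "B"): 5})
        table = tabulate_bigrams(Corpus.from_pairs(pairs))
        assert order_asymmetry(table, "A", "C").classification == "none"


class TestScalingAndRecombination:
    @pytest.mark.parametrize("factor", [2, 10])
    def test_exclusive_scores_scale_linearly(self, se_table, factor):
        # For pairs with k = n the tail is p**n, so scaling is exact.
        for pair in [("Huff", "Puff"), ("Peep", "Howl"), ("Howl", "Peep")]:
            base = mdca_score(se_table, *pair).score
            scaled = mdca_score(se_table.scale(factor), *pair).score
            assert scaled == pytest.approx(factor * base, rel=1e-12)

    def test_background_recombination_weakens_score(self, se_table):
        """Holding the pair count fixed, partner promiscuity lowers pbin."""
        base = mdca_score(se_table, "Huff", "Puff").score
        previous = base
        counter = Counter({("Huff", "Puff"): 4, ("Peep", "Howl"): 5, ("Howl", "Peep"): 7})
        for extra in range(1, 6):
            counter[("Huff", "Bark")] = extra
            counter[("Grunt", "Puff")] = extra
            table = tabulate_bigrams(
                Corpus.from_pairs(counter, repertoire=Repertoire(se_table.labels))
            )
            score = mdca_score(table, "Huff", "Puff").score
            assert score < previous
            previous = score
        assert previous < base


class TestShuffleNullCalibration:
    def test_false_positive_rate_under_permutation_null(self):
        """Averaged over 200 token shuffles, <= 10% of pairs band significant."""
        spec = SyntheticSpec(
            background_pairs=60, background_policy="recombine-uniform", seed=7
        )
        base = simulate_corpus(spec)
        rates = []
        for seed in range(200):
            null = shuffle_null(base, seed=seed)
            results = mdca_matrix(tabulate_bigrams(null))
            sig = sum(r.band != "NS" for r in results.values())
            rates.append(sig / len(results))
        assert np.mean(rates) <= 0.10
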