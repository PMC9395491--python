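"""Combined collocation report.

The two statistics are complementary — the binomial analysis rewards
frequent, well-supported combinations and exposes call order, while the
information analysis is size-invariant and flags rare exclusive pairs — so
the report runs both, classifies linearisation per observed pair, and
ranks candidate combinations jointly across the two analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .corpus import BigramCountTable, Corpus, tabulate_bigrams
from .mdca import mdca_frame, order_asymmetry
from .mica import mica_frame

__all__ = ["ReportBundle", "run_report", "render_report"]


@dataclass(frozen=True)
class ReportBundle:
    """All outputs of a combined run on one corpus."""

    table: BigramCountTable
    mdca: pd.DataFrame
    mica: pd.DataFrame
    ordering: pd.DataFrame
    joint: pd.DataFrame


def _unordered_observed(table: BigramCountTable) -> list[tuple[str, str]]:
    seen = set()
    for a, b in table.observed_pairs():
        seen.add((a, b) if a <= b else (b, a))
    return sorted(seen)


def _ordering_frame(table: BigramCountTable) -> pd.DataFrame:
    rows = []
    for a, b in _unordered_observed(table):
        if a == b:
            continue
        rep = order_asymmetry(table, a, b)
        rows.append(
            {
                "call_a": a,
                "call_b": b,
                "score_ab": rep.forward.score if rep.forward else math.nan,
                "score_ba": rep.reverse.score if rep.reverse else math.nan,
                "classification": rep.classification,
            }
        )
    return pd.DataFrame(
        rows, columns=["call_a", "call_b", "score_ab", "score_ba", "classification"]
    )


def _joint_frame(mdca: pd.DataFrame, mica: pd.DataFrame) -> pd.DataFrame:
    """Rank observed unordered pairs over both analyses.

    For each pair the stronger attraction score of its two orders stands
    in for the binomial analysis.  Pairs are ranked within each analysis
    (1 = strongest) and ordered by the rank sum, ties broken
    alphabetically — pairs near the top are candidates under *both*
    statistics.
    """
    if mica.empty:
        return pd.DataFrame(
            columns=[
                "call_a",
                "call_b",
                "mdca_score",
                "mica_score",
                "mdca_rank",
                "mica_rank",
                "rank_sum",
            ]
        )
    observed = mdca[mdca["observed"] > 0]
    best_mdca: dict[tuple[str, str], float] = {}
    for row in observed.itertuples():
        key = tuple(sorted((row.first, row.second)))
        best_mdca[key] = max(best_mdca.get(key, -math.inf), row.score)
    rows = []
    for row in mica.itertuples():
        key = (row.call_a, row.call_b)
        rows.append(
            {
                "call_a": key[0],
                "call_b": key[1],
                "mdca_score": best_mdca.get(key, math.nan),
                "mica_score": row.score,
            }
        )
    joint = pd.DataFrame(rows)
    joint["mdca_rank"] = joint["mdca_score"].rank(ascending=False, method="min")
    joint["mica_rank"] = joint["mica_score"].rank(ascending=False, method="min")
    joint["rank_sum"] = joint["mdca_rank"] + joint["mica_rank"]
    return joint.sort_values(
        ["rank_sum", "call_a", "call_b"], kind="mergesort"
    ).reset_index(drop=True)


def run_report(corpus: Corpus, window: str = "overlap") -> ReportBundle:
    """Run both collocation analyses plus ordering on one corpus."""
    table = tabulate_bigrams(corpus, window=window)
    mdca = mdca_frame(table)
    mica = mica_frame(table)
    return ReportBundle(
        table=table,
        mdca=mdca,
        mica=mica,
        ordering=_ordering_frame(table),
        joint=_joint_frame(mdca, mica),
    )


def render_report(bundle: ReportBundle, round_digits: int | None = None) -> str:
    """Render a bundle as deterministic plain text."""

    def fmt(frame: pd.DataFrame) -> str:
        if frame.empty:
            return "(no pairs)"
        out = frame.copy()
        if round_digits is not None:
            for col in out.columns:
                if pd.api.types.is_float_dtype(out[col]):
                    out[col] = out[col].round(round_digits)
        return out.to_string(index=False)

    sections = [
        f"corpus: {bundle.table.n_pairs} bigram tokens, "
        f"{bundle.table.n_calls} call tokens, "
        f"{len(bundle.table.labels)} call types",
        "== Multiple Distinctive Collocation Analysis ==",
        fmt(bundle.mdca),
        "== Mutual Information Collocation Analysis ==",
        fmt(bundle.mica),
        "== Linearisation (order asymmetry) ==",
        fmt(bundle.ordering),
        "== Joint ranking (rank sum over both analyses) ==",
        fmt(bundle.joint),
    ]
    return "\n\n".join(sections) + "\n"
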