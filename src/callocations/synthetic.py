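"""Synthetic call-combination corpora.

Reconstructs the four artificial data sets used to benchmark the two
collocation statistics, and generalises their design to arbitrary
planted-bigram corpora.  The design crosses two factors:

* **size** — small (S) or large (L, every count ×10);
* **recombination** — exclusive (E: the three target bigrams are the whole
  corpus) or recombinatorial (R: background pairs mix the remaining
  repertoire around the fixed targets).

The common backbone is a 10-call repertoire and three planted bigrams:
Huff-Puff ×4 (rare, strictly ordered), Peep-Howl ×5 and Howl-Peep ×7
(frequent, order-flexible).  Totals per data set: SE 16 pairs / 32 calls,
SR 49 / 98, LE 160 / 320, LR 490 / 980.

Planting is exact — the stated counts are placed verbatim, never sampled.
For the recombinatorial sets only the totals are fixed by design; the
background composition is drawn uniformly at random over ordered pairs
outside the planted bigrams (seeded, recorded in the corpus provenance),
or taken verbatim from a user-supplied background table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import Corpus, Repertoire
from .errors import SpecError

__all__ = [
    "SyntheticSpec",
    "simulate_corpus",
    "build_paper_dataset",
    "shuffle_null",
    "DEFAULT_REPERTOIRE",
    "PLANTED_BIGRAMS",
    "DATASET_NAMES",
]

#: 10 hypothetical call types spanning tonal (whistles, twitters) to noisy
#: (barks, coughs) calls, sized like a typical primate vocal repertoire.
DEFAULT_REPERTOIRE = Repertoire(
    (
        "Huff",
        "Puff",
        "Peep",
        "Howl",
        "Whistle",
        "Twitter",
        "Bark",
        "Cough",
        "Grunt",
        "Trill",
    )
)

#: The three target bigrams common to all four benchmark data sets.
PLANTED_BIGRAMS: tuple[tuple[str, str, int], ...] = (
    ("Huff", "Puff", 4),
    ("Peep", "Howl", 5),
    ("Howl", "Peep", 7),
)

#: name -> (scale, total pairs)
_DATASETS = {
    "SE": (1, 16),
    "SR": (1, 49),
    "LE": (10, 160),
    "LR": (10, 490),
}
DATASET_NAMES = tuple(_DATASETS)

POLICY_EXCLUSIVE = "exclusive"
POLICY_UNIFORM = "recombine-uniform"
POLICY_TABLE = "from-table"
_POLICIES = (POLICY_EXCLUSIVE, POLICY_UNIFORM, POLICY_TABLE)


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative recipe for a simulated planted-bigram corpus.

    ``scale`` multiplies both the planted counts and the background, so a
    spec describes a family of size-scaled corpora with identical
    composition proportions.  Total pairs generated:
    ``scale * (sum of planted counts + background_pairs)``.
    """

    repertoire: Repertoire = DEFAULT_REPERTOIRE
    planted: tuple[tuple[str, str, int], ...] = PLANTED_BIGRAMS
    background_pairs: int = 0
    background_policy: str = POLICY_EXCLUSIVE
    scale: int = 1
    seed: int | None = None
    background_table: tuple[tuple[str, str, int], ...] | None = None
    #: labels the uniform background may draw on (None = whole repertoire).
    #: Restricting it to the non-planted labels keeps planted bigrams
    #: exclusive while the rest of the repertoire recombines.
    background_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "planted", tuple((a, b, int(k)) for a, b, k in self.planted)
        )
        seen = set()
        for a, b, k in self.planted:
            if k < 1:
                raise SpecError(f"planted count for ({a}, {b}) must be >= 1, got {k}")
            if (a, b) in seen:
                raise SpecError(f"planted pair ({a}, {b}) duplicated in spec")
            seen.add((a, b))
            for label in (a, b):
                if label not in self.repertoire:
                    raise SpecError(f"planted label {label!r} not in repertoire")
        if self.background_pairs < 0:
            raise SpecError("background_pairs must be >= 0")
        if self.background_policy not in _POLICIES:
            raise SpecError(
                f"background_policy must be one of {_POLICIES}, "
                f"got {self.background_policy!r}"
            )
        if self.background_policy == POLICY_EXCLUSIVE and self.background_pairs != 0:
            raise SpecError("exclusive policy requires background_pairs == 0")
        if self.background_policy == POLICY_UNIFORM and self.background_pairs > 0:
            if self.seed is None:
                raise SpecError("recombine-uniform backgrounds need a seed")
        if self.background_policy == POLICY_TABLE:
            if self.background_table is None:
                raise SpecError("from-table policy needs a background_table")
            total = sum(k for _, _, k in self.background_table)
            if total != self.background_pairs:
                raise SpecError(
                    f"background_table holds {total} pairs, spec says "
                    f"{self.background_pairs}"
                )
        if self.background_labels is not None:
            object.__setattr__(
                self, "background_labels", tuple(self.background_labels)
            )
            for label in self.background_labels:
                if label not in self.repertoire:
                    raise SpecError(f"background label {label!r} not in repertoire")
        if int(self.scale) != self.scale or self.scale < 1:
            raise SpecError("scale must be a positive integer")

    @property
    def total_pairs(self) -> int:
        return self.scale * (sum(k for _, _, k in self.planted) + self.background_pairs)

    # -- key-value serialisation ---------------------------------------------

    def to_file(self, path: str | Path) -> None:
        data = {
            "repertoire": list(self.repertoire.labels),
            "planted": [[a, b, k] for a, b, k in self.planted],
            "background_pairs": self.background_pairs,
            "background_policy": self.background_policy,
            "scale": self.scale,
            "seed": self.seed,
        }
        if self.background_table is not None:
            data["background_table"] = [[a, b, k] for a, b, k in self.background_table]
        if self.background_labels is not None:
            data["background_labels"] = list(self.background_labels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SpecError(f"spec file {path} is not a key-value mapping")
        try:
            return cls(
                repertoire=Repertoire(data["repertoire"]),
                planted=tuple((a, b, int(k)) for a, b, k in data["planted"]),
                background_pairs=int(data.get("background_pairs", 0)),
                background_policy=data.get("background_policy", POLICY_EXCLUSIVE),
                scale=int(data.get("scale", 1)),
                seed=data.get("seed"),
                background_table=(
                    tuple((a, b, int(k)) for a, b, k in data["background_table"])
                    if "background_table" in data
                    else None
                ),
                background_labels=(
                    tuple(data["background_labels"])
                    if "background_labels" in data
                    else None
                ),
            )
        except KeyError as exc:
            raise SpecError(f"spec file {path} is missing key {exc}") from None


def _background_counter(spec: SyntheticSpec, rng: np.random.Generator) -> Counter:
    """Draw the background pair multiset for one corpus (already scaled)."""
    n_background = spec.background_pairs * spec.scale
    if n_background == 0:
        return Counter()
    if spec.background_policy == POLICY_TABLE:
        return Counter(
            {(a, b): k * spec.scale for a, b, k in spec.background_table}
        )
    # recombine-uniform: ordered pairs of distinct calls outside the
    # planted bigrams, drawn uniformly with replacement.
    planted_pairs = {(a, b) for a, b, _ in spec.planted}
    support = spec.background_labels or spec.repertoire.labels
    candidates = [
        (a, b)
        for a in support
        for b in support
        if a != b and (a, b) not in planted_pairs
    ]
    if not candidates:
        raise SpecError("no candidate background pairs outside the planted bigrams")
    draws = rng.integers(0, len(candidates), size=n_background)
    return Counter(candidates[i] for i in draws)


def simulate_corpus(spec: SyntheticSpec) -> Corpus:
    """Generate a corpus from a spec; deterministic given the seed.

    Planted counts appear exactly as specified (times ``scale``);
    background pairs are drawn per the spec's policy.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = Counter({(a, b): k * spec.scale for a, b, k in spec.planted})
    pairs.update(_background_counter(spec, rng))
    provenance = (
        f"simulate_corpus(policy={spec.background_policy}, scale={spec.scale}, "
        f"background_pairs={spec.background_pairs}, seed={spec.seed})"
    )
    corpus = Corpus.from_pairs(pairs, repertoire=spec.repertoire, provenance=provenance)
    assert len(corpus.sequences) == spec.total_pairs
    return corpus


def _load_background_table(path: str | Path) -> tuple[tuple[str, str, int], ...]:
    from .io import read_pairs  # local import to avoid a cycle

    corpus = read_pairs(path)
    return tuple((a, b, k) for (a, b), k in sorted(corpus.bigrams().items()))


def build_paper_dataset(
    name: str,
    seed: int | None = None,
    background_table: str | Path | None = None,
) -> Corpus:
    """Build one of the four benchmark data sets (SE, SR, LE, LR).

    SE and LE are fully determined by their design (the three planted
    bigrams, ×1 or ×10) and need no seed.  SR and LR fix only the planted
    counts and the totals (49 / 490 pairs); their background is drawn at
    random over the recombining repertoire unless an explicit
    ``background_table`` pair-list file reproduces a reference background.
    """
    name = name.upper()
    if name not in _DATASETS:
        raise SpecError(f"unknown data set {name!r}; expected one of {DATASET_NAMES}")
    scale, total = _DATASETS[name]
    planted_total = sum(k for _, _, k in PLANTED_BIGRAMS)  # 16 per unit scale
    background = total // scale - planted_total

    if background == 0:
        spec = SyntheticSpec(scale=scale, seed=seed)
    elif background_table is not None:
        bg = _load_background_table(background_table)
        bg_total = sum(k for _, _, k in bg)
        if bg_total != background:
            raise SpecError(
                f"background table for {name} holds {bg_total} pairs per unit "
                f"scale; expected {background} (total {total} pairs)"
            )
        spec = SyntheticSpec(
            background_pairs=background,
            background_policy=POLICY_TABLE,
            background_table=bg,
            scale=scale,
            seed=seed,
        )
    else:
        if seed is None:
            raise SpecError(f"{name} without a background table needs a seed")
        spec = SyntheticSpec(
            background_pairs=background,
            background_policy=POLICY_UNIFORM,
            scale=scale,
            seed=seed,
        )
    corpus = simulate_corpus(spec)
    return Corpus(
        corpus.sequences,
        repertoire=corpus.repertoire,
        provenance=f"build_paper_dataset({name}, seed={seed})",
    )


def shuffle_null(corpus: Corpus, seed: int) -> Corpus:
    """Permutation null: re-pair all call tokens at random.

    All ``2 * n_pairs`` call tokens are permuted and re-paired
    sequentially, preserving every token frequency exactly while
    destroying the pair structure.
    """
    tokens = corpus.tokens()
    if not tokens:
        raise SpecError("cannot shuffle an empty corpus")
    rng = np.random.default_rng(seed)
    shuffled = [tokens[i] for i in rng.permutation(len(tokens))]
    pairs = [
        (shuffled[i], shuffled[i + 1]) for i in range(0, len(shuffled) - 1, 2)
    ]
    return Corpus(
        pairs,
        repertoire=corpus.repertoire,
        provenance=f"shuffle_null(seed={seed}) of [{corpus.provenance}]",
    )
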