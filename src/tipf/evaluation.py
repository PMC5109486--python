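"""Evaluation of interaction recovery: threshold curves, hold-out splits,
and the exact test used to compare validation hit rates.

The evaluation universe is the full compound x target combination space of
the reference standard, with explicitly known-inactive pairs excluded by
default (they form their own candidate class rather than negatives; a flag
restores them as negatives).  Sensitivity, specificity, precision and the
enrichment factor (precision over the positive base rate) are computed at
similarity-score thresholds; hold-out validation splits the positive pairs
at random, rebuilds profiles from the training pairs only and measures
recovery of the held-out pairs along a top-N rank axis.

The two-sided Fisher exact test follows the minimum-likelihood convention:
the p-value sums the hypergeometric probabilities of every table with the
observed margins that is no more probable than the observed one, using
exact rational arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import numpy as np

from .curation import CurationConfig, InteractionMatrix, build_interaction_matrix
from .fingerprints import DEFAULT_MIN_TC, build_tipfs
from .screening import CandidateScore, score_candidates

__all__ = [
    "ConfusionCounts",
    "MetricPoint",
    "MetricCurve",
    "HoldoutRow",
    "HoldoutResult",
    "ContingencyTable2x2",
    "confusion_at_threshold",
    "metric_curve",
    "holdout_validate",
    "fisher_exact_two_sided",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def universe(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def precision(self) -> float:
        """tp / (tp + fp); defined as 0 when nothing is predicted positive."""
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0


@dataclass(frozen=True)
class MetricPoint:
    threshold: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    enrichment_factor: float
    precision_defined: bool


@dataclass(frozen=True)
class MetricCurve:
    """Recovery metrics as a function of the similarity-score threshold."""

    points: tuple[MetricPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(p.threshold for p in self.points)

    def write_tsv(self, path: str, decimals: int = 6) -> None:
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write(
                "threshold\ttp\tfp\tfn\ttn\tsensitivity\tspecificity"
                "\tprecision\tef\n"
            )
            for p in self.points:
                c = p.counts
                fh.write(
                    f"{p.threshold:.{decimals}f}\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}"
                    f"\t{p.sensitivity:.{decimals}f}\t{p.specificity:.{decimals}f}"
                    f"\t{p.precision:.{decimals}f}\t{p.enrichment_factor:.{decimals}f}\n"
                )


def confusion_at_threshold(
    candidates: Iterable[CandidateScore],
    matrix: InteractionMatrix,
    threshold: float | Fraction,
    materialization_floor: float | Fraction = DEFAULT_MIN_TC,
    count_known_inactives_as_negatives: bool = False,
) -> ConfusionCounts:
    """Label every compound-target combination at a score threshold.

    Predicted-positive combinations are the scored candidates with
    ``tc_max >= threshold``; everything unscored (no co-binder, or below the
    materialization floor used at scoring time) counts as predicted-negative.
    Thresholds below the floor are rejected because the unmaterialized
    candidates would silently inflate the negatives.
    """
    threshold = Fraction(threshold)
    if threshold < Fraction(materialization_floor):
        raise ValueError(
            f"threshold {float(threshold)} is below the scoring floor "
            f"{float(Fraction(materialization_floor))}; fp/tn would be wrong"
        )
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")

    excluded = (
        frozenset() if count_known_inactives_as_negatives else matrix.known_inactives
    )
    universe = matrix.n_combinations - len(excluded)
    predicted = {
        (c.compound_id, c.target_id)
        for c in candidates
        if c.tc_max >= threshold and (c.compound_id, c.target_id) not in excluded
    }
    tp = len(predicted & matrix.positives)
    fp = len(predicted) - tp
    fn = len(matrix.positives) - tp
    tn = universe - len(matrix.positives) - fp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metric_curve(
    candidates: Iterable[CandidateScore],
    matrix: InteractionMatrix,
    thresholds: Sequence[float],
    materialization_floor: float | Fraction = DEFAULT_MIN_TC,
    count_known_inactives_as_negatives: bool = False,
) -> MetricCurve:
    """Sensitivity/specificity/precision/enrichment at each threshold.

    The enrichment factor is precision divided by the positive base rate of
    the evaluation universe, so the all-inclusive threshold gives EF = 1.
    """
    if not matrix.positives:
        raise ValueError("metrics are undefined with no positive interactions")
    candidates = list(candidates)
    excluded = 0 if count_known_inactives_as_negatives else len(matrix.known_inactives)
    universe = matrix.n_combinations - excluded
    base_rate = len(matrix.positives) / universe

    points = []
    for thr in thresholds:
        counts = confusion_at_threshold(
            candidates,
            matrix,
            thr,
            materialization_floor,
            count_known_inactives_as_negatives,
        )
        defined = counts.tp + counts.fp > 0
        precision = counts.precision
        points.append(
            MetricPoint(
                threshold=float(thr),
                counts=counts,
                sensitivity=counts.sensitivity,
                specificity=counts.specificity,
                precision=precision,
                enrichment_factor=precision / base_rate,
                precision_defined=defined,
            )
        )
    return MetricCurve(points=tuple(points))


@dataclass(frozen=True)
class HoldoutRow:
    """Recovery metrics at one top-N rank threshold."""

    rank: int
    n_test_recovered: int
    sensitivity_scoreable: float
    sensitivity_all: float
    specificity: float


@dataclass(frozen=True)
class HoldoutResult:
    train_fraction: float
    seed: int
    n_train_pairs: int
    n_test_pairs: int
    n_test_scoreable: int
    n_test_unscoreable: int
    n_candidates: int
    rows: tuple[HoldoutRow, ...] = field(default_factory=tuple)

    def write_tsv(self, path: str, decimals: int = 6) -> None:
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write(
                "rank\tn_test_recovered\tsensitivity_scoreable"
                "\tsensitivity_all\tspecificity\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.rank}\t{r.n_test_recovered}"
                    f"\t{r.sensitivity_scoreable:.{decimals}f}"
                    f"\t{r.sensitivity_all:.{decimals}f}"
                    f"\t{r.specificity:.{decimals}f}\n"
                )


def holdout_validate(
    positives: Iterable[tuple[str, str]] | InteractionMatrix,
    train_fraction: float,
    seed: int,
    rank_thresholds: Sequence[int],
    config: CurationConfig | None = None,
    min_tc: float | Fraction = 0.0,
    split_unit: str = "pair",
) -> HoldoutResult:
    """Random hold-out validation of interaction recovery.

    The positive pairs are split uniformly at random (pair level by default;
    ``split_unit="compound"`` holds out whole compounds).  Fingerprints and
    candidate scores are computed from training pairs only, with the
    minimum-targets filter re-applied to the training matrix.  The ranked
    prediction list contains the scored combinations that are *not* training
    positives (known inputs are not predictions), ordered by score
    descending with ties by compound then target; at each rank threshold N,
    sensitivity is the fraction of held-out pairs found in the top N —
    reported both over the scoreable test pairs (those whose compound and
    target survive in the training universe) and over all test pairs.
    Specificity is computed over the training-universe combinations that
    are neither training positives nor held-out positives.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if split_unit not in ("pair", "compound"):
        raise ValueError("split_unit must be 'pair' or 'compound'")
    config = config or CurationConfig()
    if isinstance(positives, InteractionMatrix):
        pairs = sorted(positives.positives)
    else:
        pairs = sorted(set(positives))
    rng = np.random.default_rng(seed)

    if split_unit == "pair":
        order = rng.permutation(len(pairs))
        n_train = int(round(train_fraction * len(pairs)))
        train_pairs = {pairs[i] for i in order[:n_train]}
    else:
        compounds = sorted({c for c, _ in pairs})
        order = rng.permutation(len(compounds))
        n_train = int(round(train_fraction * len(compounds)))
        train_compounds = {compounds[i] for i in order[:n_train]}
        train_pairs = {p for p in pairs if p[0] in train_compounds}
    test_pairs = set(pairs) - train_pairs
    if not test_pairs:
        raise ValueError("empty test set: train_fraction leaves nothing held out")
    if not train_pairs:
        raise ValueError("empty training set")

    train_matrix = build_interaction_matrix(train_pairs, config=config)
    tipfs = build_tipfs(train_matrix)
    candidates = score_candidates(tipfs, train_matrix, min_tc=min_tc)
    ranked = sorted(
        (
            c
            for c in candidates
            if (c.compound_id, c.target_id) not in train_matrix.positives
        ),
        key=lambda c: (-c.tc_max, c.compound_id, c.target_id),
    )

    cset, tset = set(train_matrix.compounds), set(train_matrix.targets)
    scoreable = {p for p in test_pairs if p[0] in cset and p[1] in tset}
    n_unscoreable = len(test_pairs) - len(scoreable)
    negatives = (
        train_matrix.n_combinations - len(train_matrix.positives) - len(scoreable)
    )

    rows = []
    for rank in rank_thresholds:
        if rank < 1:
            raise ValueError("rank thresholds must be positive")
        top = ranked[:rank]
        top_pairs = {(c.compound_id, c.target_id) for c in top}
        recovered = len(top_pairs & scoreable)
        fp = len(top_pairs - scoreable)
        rows.append(
            HoldoutRow(
                rank=rank,
                n_test_recovered=recovered,
                sensitivity_scoreable=recovered / len(scoreable) if scoreable else 0.0,
                sensitivity_all=recovered / len(test_pairs),
                specificity=(negatives - fp) / negatives if negatives else 0.0,
            )
        )
    return HoldoutResult(
        train_fraction=train_fraction,
        seed=seed,
        n_train_pairs=len(train_pairs),
        n_test_pairs=len(test_pairs),
        n_test_scoreable=len(scoreable),
        n_test_unscoreable=n_unscoreable,
        n_candidates=len(candidates),
        rows=tuple(rows),
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are the two groups, columns the outcome present/absent counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


# Relative slack on the "no more probable than observed" comparison; guards
# against spurious exclusion of tables tied with the observed probability.
_FISHER_REL_TOL = Fraction(1, 10**7)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by minimum-likelihood enumeration.

    Under fixed margins the first cell follows a hypergeometric law; the
    p-value is the total probability of every admissible table whose
    probability does not exceed the observed table's, evaluated with exact
    integer binomial coefficients.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    denom = comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    observed = prob(a)
    cutoff = observed * (1 + _FISHER_REL_TOL)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = prob(k)
        if p_k <= cutoff:
            total += p_k
    return float(min(total, Fraction(1)))


def write_fisher_result(table: ContingencyTable2x2, p_value: float, path: str) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        json.dump(
            {
                "table": [[table.a, table.b], [table.c, table.d]],
                "p_value": p_value,
                "method": "fisher_exact_two_sided_minimum_likelihood",
            },
            fh,
            indent=2,
        )
        fh.write("\n")
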