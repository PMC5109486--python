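"""Multi-target virtual screening by maximum profile similarity.

Every compound-target combination is scored by the maximum Tanimoto
similarity between the compound's target-interaction profile and the
profiles of the compounds known to bind that target (the compound itself is
excluded from the maximization, so known interactions are recovered without
self-match inflation).  The known binder achieving the maximum is recorded
as the candidate's reference compound.  Scored combinations are classified
as known-positive (already in the reference standard), known-inactive
(explicit inactive evidence) or novel — the repositioning candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Sequence

from .curation import InteractionMatrix
from .fingerprints import DEFAULT_MIN_TC, TIPF, all_pairs_similarity

__all__ = [
    "CandidateScore",
    "CandidatePartition",
    "score_candidates",
    "classify_candidates",
    "select_candidates",
    "write_candidates",
    "write_partition",
]

STATUS_KNOWN_POSITIVE = "known_positive"
STATUS_KNOWN_INACTIVE = "known_inactive"
STATUS_NOVEL = "novel"


@dataclass(frozen=True)
class CandidateScore:
    """One scored compound-target combination.

    ``tc_max`` is the exact maximum Tanimoto coefficient against the known
    binders of the target; ``reference_compound_id`` the binder achieving it
    (ties broken lexicographically); ``status`` is None until classified.
    """

    compound_id: str
    target_id: str
    tc_max: Fraction
    reference_compound_id: str
    status: str | None = None

    def __post_init__(self) -> None:
        if self.reference_compound_id == self.compound_id:
            raise ValueError("a candidate may not reference itself")
        if not 0 <= self.tc_max <= 1:
            raise ValueError("tc_max must lie in [0, 1]")


@dataclass(frozen=True)
class CandidatePartition:
    """Counts of the three candidate classes; the sum identity is enforced."""

    n_total: int
    n_known_positive: int
    n_known_inactive: int
    n_novel: int

    def __post_init__(self) -> None:
        if min(
            self.n_total, self.n_known_positive, self.n_known_inactive, self.n_novel
        ) < 0:
            raise ValueError("partition counts must be non-negative")
        if self.n_total != self.n_known_positive + self.n_known_inactive + self.n_novel:
            raise ValueError(
                "partition identity violated: "
                f"{self.n_total} != {self.n_known_positive} + "
                f"{self.n_known_inactive} + {self.n_novel}"
            )


def score_candidates(
    tipfs: dict[str, TIPF],
    matrix: InteractionMatrix,
    min_tc: float | Fraction = DEFAULT_MIN_TC,
) -> list[CandidateScore]:
    """Score every compound-target combination reachable above ``min_tc``.

    For compound c and target t, the score is
    ``max over binders b != c of tanimoto(c, b)``; combinations whose
    maximum falls below ``min_tc`` are not materialized (every unscored
    combination is below threshold by construction).  Output is sorted by
    (target_id, -tc_max, compound_id).
    """
    profiles = {c: matrix.profile(c) for c in matrix.compounds}
    edges = all_pairs_similarity(tipfs, min_tc)

    best: dict[tuple[str, str], tuple[Fraction, str]] = {}

    def offer(compound: str, reference: str, tc: Fraction) -> None:
        for target in profiles[reference]:
            key = (compound, target)
            cur = best.get(key)
            if cur is None or tc > cur[0] or (tc == cur[0] and reference < cur[1]):
                best[key] = (tc, reference)

    for e in edges:
        offer(e.compound_a, e.compound_b, e.tc)
        offer(e.compound_b, e.compound_a, e.tc)

    candidates = [
        CandidateScore(c, t, tc, ref) for (c, t), (tc, ref) in best.items()
    ]
    candidates.sort(key=lambda s: (s.target_id, -s.tc_max, s.compound_id))
    return candidates


def classify_candidates(
    candidates: Iterable[CandidateScore],
    matrix: InteractionMatrix,
) -> tuple[list[CandidateScore], CandidatePartition]:
    """Attach known-positive / known-inactive / novel status to candidates."""
    compounds, targets = set(matrix.compounds), set(matrix.targets)
    annotated: list[CandidateScore] = []
    n_pos = n_inact = n_novel = 0
    for cand in candidates:
        if cand.compound_id not in compounds or cand.target_id not in targets:
            raise ValueError(
                f"candidate ({cand.compound_id}, {cand.target_id}) "
                f"references an unknown compound or target"
            )
        pair = (cand.compound_id, cand.target_id)
        if pair in matrix.positives:
            status = STATUS_KNOWN_POSITIVE
            n_pos += 1
        elif pair in matrix.known_inactives:
            status = STATUS_KNOWN_INACTIVE
            n_inact += 1
        else:
            status = STATUS_NOVEL
            n_novel += 1
        annotated.append(replace(cand, status=status))
    partition = CandidatePartition(
        n_total=n_pos + n_inact + n_novel,
        n_known_positive=n_pos,
        n_known_inactive=n_inact,
        n_novel=n_novel,
    )
    return annotated, partition


def select_candidates(
    candidates: Iterable[CandidateScore],
    target_id: str | None = None,
    whitelist: Iterable[str] | None = None,
    status: str | None = STATUS_NOVEL,
    top_k: int | None = None,
    known_targets: Iterable[str] | None = None,
) -> list[CandidateScore]:
    """Rank candidates for a target, restricted to a compound whitelist.

    The whitelist is a plain id list (e.g. approved and experimental drugs,
    natural products).  Default status filter is novel — the repositioning
    candidates.  Sorted by tc_max descending, ties by compound_id; truncated
    to ``top_k`` when given.  ``known_targets`` enables validation of
    ``target_id``.
    """
    if target_id is not None and known_targets is not None:
        if target_id not in set(known_targets):
            raise ValueError(f"unknown target_id {target_id!r}")
    wl = set(whitelist) if whitelist is not None else None
    chosen = [
        c
        for c in candidates
        if (target_id is None or c.target_id == target_id)
        and (wl is None or c.compound_id in wl)
        and (status is None or c.status == status)
    ]
    chosen.sort(key=lambda c: (-c.tc_max, c.compound_id))
    return chosen[:top_k] if top_k is not None else chosen


def write_candidates(
    candidates: Sequence[CandidateScore], path: str, decimals: int = 6
) -> None:
    """Write the candidate table sorted by (target_id, -tc_max, compound_id)."""
    rows = sorted(candidates, key=lambda c: (c.target_id, -c.tc_max, c.compound_id))
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("compound_id\ttarget_id\ttc_max\treference_compound_id\tstatus\n")
        for c in rows:
            fh.write(
                f"{c.compound_id}\t{c.target_id}\t{float(c.tc_max):.{decimals}f}"
                f"\t{c.reference_compound_id}\t{c.status or ''}\n"
            )


def write_partition(partition: CandidatePartition, path: str) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        json.dump(
            {
                "n_total": partition.n_total,
                "n_known_positive": partition.n_known_positive,
                "n_known_inactive": partition.n_known_inactive,
                "n_novel": partition.n_novel,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
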