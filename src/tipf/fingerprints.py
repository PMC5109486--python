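"""Target interaction profile fingerprints and Tanimoto all-pairs search.

A profile fingerprint is a binary vector over the target universe with a 1
at every protein the compound is known to bind, stored sparsely as the
sorted set of on positions.  Similarity between two compounds is the
Tanimoto coefficient of their on-bit sets, |A∩B| / |A∪B|, computed as an
exact ratio of integers so threshold comparisons have no floating-point
edge artifacts.

The all-pairs search uses an inverted index over targets (a pair with
tc > 0 must share at least one target) plus the cardinality bound
tc <= min(|A|,|B|)/max(|A|,|B|); both prunes are lossless, so the output is
identical to the naive double loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .curation import InteractionMatrix

__all__ = [
    "TIPF",
    "SimilarityEdge",
    "build_tipfs",
    "tanimoto",
    "tanimoto_fraction",
    "all_pairs_similarity",
    "write_edges",
]

DEFAULT_MIN_TC = 0.5


@dataclass(frozen=True)
class TIPF:
    """A compound's sparse binary target-interaction fingerprint."""

    compound_id: str
    on_bits: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "on_bits", frozenset(self.on_bits))
        if not self.on_bits:
            raise ValueError(f"fingerprint of {self.compound_id} has no on bits")
        if any(b < 0 for b in self.on_bits):
            raise ValueError("on-bit indices must be non-negative")

    def __len__(self) -> int:
        return len(self.on_bits)

    @property
    def sorted_bits(self) -> tuple[int, ...]:
        return tuple(sorted(self.on_bits))


@dataclass(frozen=True)
class SimilarityEdge:
    """An unordered compound pair with its Tanimoto coefficient.

    Canonical orientation: ``compound_a < compound_b`` lexicographically.
    ``tc`` is exact (a :class:`fractions.Fraction`); use ``float(edge.tc)``
    for display.
    """

    compound_a: str
    compound_b: str
    tc: Fraction

    def __post_init__(self) -> None:
        if not self.compound_a < self.compound_b:
            raise ValueError("edges must be oriented compound_a < compound_b")
        if not 0 <= self.tc <= 1:
            raise ValueError("tc must lie in [0, 1]")


def build_tipfs(matrix: InteractionMatrix) -> dict[str, TIPF]:
    """One fingerprint per matrix compound; bit i is on iff the compound
    binds ``matrix.targets[i]``."""
    index = {t: i for i, t in enumerate(matrix.targets)}
    bits: dict[str, set[int]] = {c: set() for c in matrix.compounds}
    for c, t in matrix.positives:
        bits[c].add(index[t])
    return {c: TIPF(c, frozenset(b)) for c, b in bits.items()}


def tanimoto_fraction(a: TIPF, b: TIPF) -> Fraction:
    """Exact Tanimoto coefficient |A∩B| / |A∪B| of two fingerprints."""
    if not a.on_bits and not b.on_bits:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits) + len(b.on_bits) - inter
    return Fraction(inter, union)


def tanimoto(a: TIPF, b: TIPF) -> float:
    """Tanimoto coefficient as a float in [0, 1]."""
    return float(tanimoto_fraction(a, b))


def all_pairs_similarity(
    tipfs: Iterable[TIPF] | dict[str, TIPF],
    min_tc: float | Fraction = DEFAULT_MIN_TC,
) -> list[SimilarityEdge]:
    """All unordered fingerprint pairs with tc >= ``min_tc``.

    Equivalent to the O(n^2) double loop; the inverted index restricts
    candidate pairs to those sharing a target and the cardinality bound
    skips pairs that cannot reach the threshold.  Edges are sorted by
    (compound_a, compound_b).
    """
    if isinstance(tipfs, dict):
        fps = list(tipfs.values())
    else:
        fps = list(tipfs)
    if not 0 <= min_tc <= 1:
        raise ValueError(f"min_tc must lie in [0, 1], got {min_tc}")
    min_tc = Fraction(min_tc)
    fps.sort(key=lambda f: f.compound_id)

    # Inverted index: target bit -> fingerprint positions carrying it.
    by_bit: dict[int, list[int]] = {}
    for i, fp in enumerate(fps):
        for bit in fp.on_bits:
            by_bit.setdefault(bit, []).append(i)

    edges: list[SimilarityEdge] = []
    for i, fp in enumerate(fps):
        candidates: set[int] = set()
        for bit in fp.on_bits:
            candidates.update(j for j in by_bit[bit] if j > i)
        na = len(fp.on_bits)
        for j in sorted(candidates):
            other = fps[j]
            nb = len(other.on_bits)
            # tc <= min(|A|,|B|) / max(|A|,|B|): lossless upper bound.
            if Fraction(min(na, nb), max(na, nb)) < min_tc:
                continue
            tc = tanimoto_fraction(fp, other)
            if tc >= min_tc:
                edges.append(SimilarityEdge(fp.compound_id, other.compound_id, tc))
    if min_tc == 0:
        # The index only finds pairs sharing a target; at threshold zero the
        # disjoint pairs (tc = 0) belong in the output too.
        seen = {(e.compound_a, e.compound_b) for e in edges}
        for i, fp in enumerate(fps):
            for other in fps[i + 1 :]:
                key = (fp.compound_id, other.compound_id)
                if key not in seen:
                    edges.append(SimilarityEdge(*key, Fraction(0)))
    edges.sort(key=lambda e: (e.compound_a, e.compound_b))
    return edges


def write_edges(edges: Sequence[SimilarityEdge], path: str, decimals: int = 6) -> None:
    """Write ``compound_a<TAB>compound_b<TAB>tc`` sorted rows."""
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("compound_a\tcompound_b\ttc\n")
        for e in sorted(edges, key=lambda e: (e.compound_a, e.compound_b)):
            fh.write(f"{e.compound_a}\t{e.compound_b}\t{float(e.tc):.{decimals}f}\n")
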