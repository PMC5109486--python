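"""Synthetic bioactivity data with pharmacological-family structure.

The screening method rests on one statistical assumption: compounds fall
into pharmacological families that share most of their target interactions,
with sparse cross-family sharing.  The generator emulates exactly that —
each family owns a disjoint block of targets, each compound carries a
configurable fraction of its family's block plus random out-of-family noise
interactions — and wraps the clean pairs in raw assay records, optionally
decorated with the pathologies the curation rules must catch ("not active"
comments, potencies above the ceiling, non-single-protein targets,
duplicate assays).

Known interactions can be *masked*: removed from the emitted records but
listed in the truth object, with a closed-form expected recovery score in
the noiseless identical-profile case.  If a compound's family block has m
targets and every compound carries all of them, removing one pair (c, t)
leaves c with m-1 of the m targets; any fully-profiled family member b that
binds t then gives tanimoto(c, b) = (m-1)/m, which is the maximum, so the
masked pair must be recovered with exactly that score.

Everything is driven by one seeded generator; identical seeds produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import (
    DEFAULT_COLUMN_MAP,
    REASON_COMMENT_EXCLUDED,
    REASON_POTENCY_CEILING,
    REASON_TARGET_TYPE,
)

__all__ = [
    "RecordDecorations",
    "SyntheticSpec",
    "MaskedPair",
    "SyntheticTruth",
    "generate",
    "emit_fixture_suite",
]


@dataclass(frozen=True)
class RecordDecorations:
    """How many pathological raw records to inject (0 = none).

    n_inactive_comment  -> "Not Active" records on out-of-profile pairs
                           (become known-inactives after curation)
    n_high_potency      -> ">= ceiling" potency records on out-of-profile
                           pairs (rejected by the potency rule)
    n_bad_target_type   -> records against PROTEIN COMPLEX pseudo-targets
                           (rejected by the target-type rule)
    n_duplicate_assays  -> second assay records for existing positive pairs
                           (collapsed by assay clustering, no new pairs)
    """

    n_inactive_comment: int = 0
    n_high_potency: int = 0
    n_bad_target_type: int = 0
    n_duplicate_assays: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_inactive_comment,
            self.n_high_potency,
            self.n_bad_target_type,
            self.n_duplicate_assays,
        ) < 0:
            raise ValueError("decoration counts must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give 4 families of 10 compounds over 20-target blocks, each
    compound carrying 90% of its block plus 2% cross-family noise — a small
    but realistically clustered interaction matrix whose compounds clear the
    default 15-target curation floor.
    """

    n_families: int = 4
    compounds_per_family: int = 10
    targets_per_family: int = 20
    within_family_share: float = 0.9
    cross_family_noise: float = 0.02
    n_masked_pairs: int = 0
    raw_record_decorations: RecordDecorations = field(
        default_factory=RecordDecorations
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.compounds_per_family < 1:
            raise ValueError("need at least one family and one compound per family")
        if self.targets_per_family < 1:
            raise ValueError("need at least one target per family")
        if not 0 < self.within_family_share <= 1:
            raise ValueError("within_family_share must lie in (0, 1]")
        if not 0 <= self.cross_family_noise < 1:
            raise ValueError("cross_family_noise must lie in [0, 1)")
        if self.n_masked_pairs < 0:
            raise ValueError("n_masked_pairs must be non-negative")

    @property
    def n_compounds(self) -> int:
        return self.n_families * self.compounds_per_family

    @property
    def n_targets(self) -> int:
        return self.n_families * self.targets_per_family


@dataclass(frozen=True)
class MaskedPair:
    """A held-back interaction and, when derivable, its expected score."""

    compound_id: str
    target_id: str
    expected_score: Fraction | None


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated table."""

    positives: frozenset[tuple[str, str]]  # pre-masking
    emitted_positives: frozenset[tuple[str, str]]
    masked: tuple[MaskedPair, ...]
    family_of_compound: dict[str, int]
    family_targets: dict[int, tuple[str, ...]]
    expected_rejections: tuple[tuple[str, str, str], ...]  # (compound, target, reason)
    duplicated_pairs: frozenset[tuple[str, str]]
    seed: int

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "positives": sorted(map(list, self.positives)),
            "emitted_positives": sorted(map(list, self.emitted_positives)),
            "masked": [
                {
                    "compound_id": m.compound_id,
                    "target_id": m.target_id,
                    "expected_score": (
                        None
                        if m.expected_score is None
                        else [m.expected_score.numerator, m.expected_score.denominator]
                    ),
                }
                for m in self.masked
            ],
            "family_of_compound": self.family_of_compound,
            "family_targets": {str(k): list(v) for k, v in self.family_targets.items()},
            "expected_rejections": sorted(map(list, self.expected_rejections)),
            "duplicated_pairs": sorted(map(list, self.duplicated_pairs)),
        }


def _cid(i: int) -> str:
    return f"C{i:04d}"


def _tid(i: int) -> str:
    return f"T{i:04d}"


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a raw bioactivity table and its ground truth.

    The table uses the ChEMBL-export column dialect the curation reader
    expects by default.  Masked pairs are absent from the table; at most one
    pair is masked per compound so the noiseless expected score stays in
    closed form.
    """
    rng = np.random.default_rng(spec.seed)

    family_targets: dict[int, tuple[str, ...]] = {}
    family_of_compound: dict[str, int] = {}
    positives: set[tuple[str, str]] = set()

    all_targets = [_tid(i + 1) for i in range(spec.n_targets)]
    for f in range(spec.n_families):
        block = tuple(
            all_targets[f * spec.targets_per_family : (f + 1) * spec.targets_per_family]
        )
        family_targets[f] = block
        for j in range(spec.compounds_per_family):
            cid = _cid(f * spec.compounds_per_family + j + 1)
            family_of_compound[cid] = f
            if spec.within_family_share >= 1.0:
                carried = list(block)
            else:
                k = max(1, int(round(spec.within_family_share * len(block))))
                carried = sorted(
                    rng.choice(np.array(block), size=k, replace=False).tolist()
                )
            positives.update((cid, t) for t in carried)
            if spec.cross_family_noise > 0:
                outside = [t for t in all_targets if t not in block]
                draws = rng.random(len(outside)) < spec.cross_family_noise
                positives.update(
                    (cid, t) for t, hit in zip(outside, draws) if hit
                )

    if spec.n_masked_pairs > len(positives):
        raise ValueError("cannot mask more pairs than were generated")
    if spec.n_masked_pairs > spec.n_compounds:
        raise ValueError(
            "at most one pair is masked per compound; reduce n_masked_pairs"
        )

    masked: list[MaskedPair] = []
    masked_of: dict[str, str] = {}
    if spec.n_masked_pairs:
        compounds_with_pairs = sorted({c for c, _ in positives})
        chosen = rng.choice(
            np.array(compounds_with_pairs), size=spec.n_masked_pairs, replace=False
        )
        for cid in sorted(chosen.tolist()):
            own = sorted(t for c, t in positives if c == cid)
            t = str(rng.choice(np.array(own)))
            masked_of[cid] = t
    noiseless_identical = (
        spec.within_family_share >= 1.0 and spec.cross_family_noise == 0
    )
    for cid, t in sorted(masked_of.items()):
        expected: Fraction | None = None
        if noiseless_identical:
            f = family_of_compound[cid]
            m = len(family_targets[f])
            family_members = [c for c, g in family_of_compound.items() if g == f]
            # Binders of t other than cid whose own masked pair is not (b, t).
            binders = [
                b for b in family_members if b != cid and masked_of.get(b) != t
            ]
            intact = [b for b in binders if b not in masked_of]
            if intact:
                expected = Fraction(m - 1, m)
            elif binders:
                expected = Fraction(m - 2, m)
        masked.append(MaskedPair(cid, t, expected))

    emitted = {p for p in positives if masked_of.get(p[0]) != p[1]}

    # --- raw records -----------------------------------------------------
    cols = DEFAULT_COLUMN_MAP
    rows: list[dict[str, str]] = []

    def add_row(
        cid: str,
        tid: str,
        assay: str,
        target_type: str = "SINGLE PROTEIN",
        comment: str = "",
        value: str = "100.0",
        units: str = "nM",
        relation: str = "=",
        assay_type: str = "B",
        organism: str = "Homo sapiens",
    ) -> None:
        rows.append(
            {
                cols["compound_id"]: cid,
                cols["target_id"]: tid,
                cols["target_type"]: target_type,
                cols["assay_id"]: assay,
                cols["activity_comment"]: comment,
                cols["potency_value"]: value,
                cols["potency_units"]: units,
                cols["potency_relation"]: relation,
                cols["assay_type"]: assay_type,
                cols["organism"]: organism,
            }
        )

    assay_counter = 0

    def next_assay() -> str:
        nonlocal assay_counter
        assay_counter += 1
        return f"A{assay_counter:05d}"

    for cid, tid in sorted(emitted):
        add_row(cid, tid, next_assay())

    deco = spec.raw_record_decorations
    expected_rejections: list[tuple[str, str, str]] = []
    duplicated: set[tuple[str, str]] = set()

    compounds = sorted(family_of_compound)
    non_pairs = sorted(
        {
            (c, t)
            for c in compounds
            for t in all_targets
            if (c, t) not in positives
        }
    )

    def draw_non_pairs(n: int, used: set[tuple[str, str]]) -> list[tuple[str, str]]:
        pool = [p for p in non_pairs if p not in used]
        if n > len(pool):
            raise ValueError("not enough free compound-target slots to decorate")
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx.tolist())]

    used: set[tuple[str, str]] = set()
    for cid, tid in draw_non_pairs(deco.n_inactive_comment, used):
        used.add((cid, tid))
        add_row(cid, tid, next_assay(), comment="Not Active", value="", units="", relation="")
        expected_rejections.append((cid, tid, REASON_COMMENT_EXCLUDED))
    for cid, tid in draw_non_pairs(deco.n_high_potency, used):
        used.add((cid, tid))
        add_row(cid, tid, next_assay(), value="50000.0", relation=">")
        expected_rejections.append((cid, tid, REASON_POTENCY_CEILING))
    for i in range(deco.n_bad_target_type):
        cid = compounds[int(rng.integers(len(compounds)))]
        tid = f"X{i + 1:04d}"
        add_row(cid, tid, next_assay(), target_type="PROTEIN COMPLEX")
        expected_rejections.append((cid, tid, REASON_TARGET_TYPE))
    if deco.n_duplicate_assays:
        emitted_sorted = sorted(emitted)
        idx = rng.choice(
            len(emitted_sorted),
            size=min(deco.n_duplicate_assays, len(emitted_sorted)),
            replace=False,
        )
        for i in sorted(idx.tolist()):
            cid, tid = emitted_sorted[i]
            add_row(cid, tid, next_assay(), assay_type="F", organism="Rattus norvegicus")
            duplicated.add((cid, tid))

    frame = pd.DataFrame(rows, columns=list(cols.values()))
    truth = SyntheticTruth(
        positives=frozenset(positives),
        emitted_positives=frozenset(emitted),
        masked=tuple(masked),
        family_of_compound=family_of_compound,
        family_targets=family_targets,
        expected_rejections=tuple(expected_rejections),
        duplicated_pairs=frozenset(duplicated),
        seed=spec.seed,
    )
    return frame, truth


def write_dataset(
    frame: pd.DataFrame, truth: SyntheticTruth, out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` and ``<stem>.truth.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / f"{stem}.tsv"
    truth_path = out / f"{stem}.truth.json"
    frame.to_csv(table, sep="\t", index=False, lineterminator="\n")
    with open(truth_path, "w", newline="\n", encoding="utf-8") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return table, truth_path


#: Specs of the named unit-test fixtures.
FIXTURE_SPECS: dict[str, SyntheticSpec] = {
    # Every curation rule exercised on a tiny matrix.
    "curation_edge_cases": SyntheticSpec(
        n_families=2,
        compounds_per_family=3,
        targets_per_family=18,
        within_family_share=1.0,
        cross_family_noise=0.0,
        raw_record_decorations=RecordDecorations(
            n_inactive_comment=4,
            n_high_potency=3,
            n_bad_target_type=2,
            n_duplicate_assays=5,
        ),
        seed=11,
    ),
    # Two identical 16-target profiles, one pair masked: recovery 15/16.
    "two_compound_closed_form": SyntheticSpec(
        n_families=1,
        compounds_per_family=2,
        targets_per_family=16,
        within_family_share=1.0,
        cross_family_noise=0.0,
        n_masked_pairs=1,
        seed=5,
    ),
    # 60-compound instance for the exhaustive scoring oracle.
    "oracle_case": SyntheticSpec(
        n_families=5,
        compounds_per_family=12,
        targets_per_family=22,
        within_family_share=0.85,
        cross_family_noise=0.03,
        seed=23,
    ),
}


def emit_fixture_suite(out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write the named fixtures used by the unit tests plus a manifest.

    The manifest records, per fixture, the generation parameters, expected
    downstream values (masked-pair scores, intended rejection reasons) and
    row counts.  ``seed`` offsets every fixture seed, defaulting to the
    frozen per-fixture seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    paths: dict[str, Path] = {}
    for stem, base_spec in FIXTURE_SPECS.items():
        spec = (
            base_spec
            if seed is None
            else SyntheticSpec(
                **{
                    **base_spec.__dict__,
                    "seed": (base_spec.seed + seed) % (2**31),
                }
            )
        )
        frame, truth = generate(spec)
        table, truth_path = write_dataset(frame, truth, out, stem)
        paths[stem] = table
        manifest[stem] = {
            "table": table.name,
            "truth": truth_path.name,
            "n_rows": int(len(frame)),
            "seed": spec.seed,
            "expected_masked_scores": [
                {
                    "compound_id": m.compound_id,
                    "target_id": m.target_id,
                    "expected_score": (
                        None
                        if m.expected_score is None
                        else [m.expected_score.numerator, m.expected_score.denominator]
                    ),
                }
                for m in truth.masked
            ],
            "expected_rejections": sorted(map(list, truth.expected_rejections)),
        }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", newline="\n", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths
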