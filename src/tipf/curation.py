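"""Curation of raw compound-target bioactivity tables into a reference standard.

A reference standard is the curated set of compound-target interactions used
to build target-interaction profiles.  Raw assay measurements (one row per
measurement, ChEMBL-export shaped) pass through three stages:

1. :func:`read_bioactivity_table` — parse the tab-separated table.
2. :func:`cluster_assays_by_protein` — collapse assays measuring the same
   compound-target pair.
3. :func:`curate_records` + :func:`build_interaction_matrix` — apply the
   filtering rules (single-protein targets only, drop uninformative activity
   comments, reject weak potencies above a ceiling, keep only compounds with
   enough distinct targets) and assemble the binary interaction matrix.

All outputs are deterministically ordered so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BioactivityRecord",
    "CurationConfig",
    "InteractionMatrix",
    "CurationError",
    "EmptyReferenceStandardError",
    "DEFAULT_COLUMN_MAP",
    "read_bioactivity_table",
    "cluster_assays_by_protein",
    "curate_records",
    "build_interaction_matrix",
    "build_reference_standard",
    "write_reference_standard",
    "read_reference_standard",
    "write_rejections",
]

# Rejection reason codes (machine readable, exactly one per rejected record).
REASON_TARGET_TYPE = "TARGET_TYPE"
REASON_COMMENT_EXCLUDED = "COMMENT_EXCLUDED"
REASON_POTENCY_CEILING = "POTENCY_CEILING"
REASON_UNIT_UNSUPPORTED = "UNIT_UNSUPPORTED"


class CurationError(ValueError):
    """Configuration or consistency problem during curation."""


class EmptyReferenceStandardError(CurationError):
    """No compound survived the curation filters."""


@dataclass(frozen=True)
class BioactivityRecord:
    """One assay measurement of a compound against a target.

    ``potency_value`` is in the units given by ``potency_units`` (nM in
    curated ChEMBL exports); ``potency_relation`` qualifies it ("=", ">",
    "<", ">=", "<=" or ``None`` when the cell is empty).
    """

    compound_id: str
    target_id: str
    target_type: str = "SINGLE PROTEIN"
    assay_id: str = ""
    activity_comment: str = ""
    potency_value: float | None = None
    potency_units: str | None = None
    potency_relation: str | None = None
    assay_type: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.compound_id or not self.target_id:
            raise CurationError("compound_id and target_id must be non-empty")
        if self.potency_value is not None:
            if not math.isfinite(self.potency_value) or self.potency_value < 0:
                raise CurationError(
                    f"potency_value must be finite and >= 0, got {self.potency_value!r}"
                )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.compound_id, self.target_id)


@dataclass(frozen=True)
class CurationConfig:
    """Parameters of the curation rules.

    potency_ceiling_nM
        Measurements established as weaker than this (relation ">"/">=" at or
        above the ceiling, or a measured value above it when
        ``reject_measured_above_ceiling``) are rejected.  Default 50,000 nM.
    min_targets_per_compound
        Compounds with fewer distinct curated targets are dropped from the
        reference standard; profiles need enough on-bits to be informative.
        Default 15.
    allowed_target_types
        Only these target types enter the standard (default single proteins).
    excluded_comments / inactive_comments
        Case-insensitive substrings of the activity comment.  A record whose
        comment matches an excluded substring never becomes a positive; if it
        also matches an inactive substring the pair is recorded as an
        explicit known-inactive.
    """

    potency_ceiling_nM: float = 50_000.0
    min_targets_per_compound: int = 15
    allowed_target_types: frozenset[str] = frozenset({"SINGLE PROTEIN"})
    excluded_comments: frozenset[str] = frozenset(
        {"not active", "not determined", "not soluble", "potential missing data"}
    )
    inactive_comments: frozenset[str] = frozenset({"not active"})
    reject_measured_above_ceiling: bool = True

    def __post_init__(self) -> None:
        if self.min_targets_per_compound < 1:
            raise CurationError("min_targets_per_compound must be >= 1")
        if self.potency_ceiling_nM <= 0:
            raise CurationError("potency_ceiling_nM must be > 0")
        object.__setattr__(
            self, "allowed_target_types", frozenset(self.allowed_target_types)
        )
        object.__setattr__(
            self,
            "excluded_comments",
            frozenset(s.lower() for s in self.excluded_comments),
        )
        object.__setattr__(
            self,
            "inactive_comments",
            frozenset(s.lower() for s in self.inactive_comments),
        )


@dataclass(frozen=True)
class InteractionMatrix:
    """The curated reference standard.

    ``positives`` holds the 1-cells of the compound (rows) by target
    (columns) binary matrix; ``known_inactives`` the pairs whose only
    evidence was an explicit "not active" annotation.  ``filtered`` records
    whether the minimum-targets-per-compound filter has been applied.
    """

    compounds: tuple[str, ...]
    targets: tuple[str, ...]
    positives: frozenset[tuple[str, str]]
    known_inactives: frozenset[tuple[str, str]] = frozenset()
    min_targets_per_compound: int = 15
    filtered: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", tuple(self.compounds))
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "known_inactives", frozenset(self.known_inactives))
        if self.positives & self.known_inactives:
            raise CurationError("positives and known_inactives overlap")
        cset, tset = set(self.compounds), set(self.targets)
        for c, t in self.positives | self.known_inactives:
            if c not in cset or t not in tset:
                raise CurationError(f"pair ({c}, {t}) outside the matrix universes")
        if self.filtered:
            per_compound: dict[str, int] = {}
            for c, _ in self.positives:
                per_compound[c] = per_compound.get(c, 0) + 1
            for c in self.compounds:
                if per_compound.get(c, 0) < self.min_targets_per_compound:
                    raise CurationError(
                        f"compound {c} has {per_compound.get(c, 0)} positives, "
                        f"below the minimum of {self.min_targets_per_compound}"
                    )

    @property
    def n_combinations(self) -> int:
        """Size of the full compound x target combination space."""
        return len(self.compounds) * len(self.targets)

    def profile(self, compound_id: str) -> frozenset[str]:
        """The set of targets a compound is known to bind."""
        return frozenset(t for c, t in self.positives if c == compound_id)


#: Logical field -> column name for the ChEMBL-style export dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "compound_id": "molecule_chembl_id",
    "target_id": "target_chembl_id",
    "target_type": "target_type",
    "assay_id": "assay_chembl_id",
    "activity_comment": "activity_comment",
    "potency_value": "standard_value",
    "potency_units": "standard_units",
    "potency_relation": "standard_relation",
    "assay_type": "assay_type",
    "organism": "target_organism",
}

_REQUIRED_FIELDS = ("compound_id", "target_id")


def read_bioactivity_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
) -> list[BioactivityRecord]:
    """Parse a tab-separated bioactivity table into records.

    ``column_map`` maps logical field names (the attributes of
    :class:`BioactivityRecord`) to physical column names; unmapped optional
    fields default to empty.  No filtering is performed here.  An unparsable
    potency cell is logged and treated as absent.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for logical, physical in column_map.items():
        if physical not in df.columns:
            raise CurationError(
                f"column {physical!r} (mapped from field {logical!r}) "
                f"not found in the input table"
            )
    for logical in _REQUIRED_FIELDS:
        if logical not in column_map:
            raise CurationError(f"column_map must map the {logical!r} field")

    records: list[BioactivityRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        values = dict(zip(df.columns, row))

        def cell(logical: str) -> str:
            physical = column_map.get(logical)
            return values[physical].strip() if physical else ""

        potency: float | None = None
        raw_potency = cell("potency_value")
        if raw_potency:
            try:
                potency = float(raw_potency)
            except ValueError:
                logger.warning(
                    "line %d: unparsable potency value %r, treated as absent",
                    idx,
                    raw_potency,
                )
        records.append(
            BioactivityRecord(
                compound_id=cell("compound_id"),
                target_id=cell("target_id"),
                target_type=cell("target_type") or "SINGLE PROTEIN",
                assay_id=cell("assay_id"),
                activity_comment=cell("activity_comment"),
                potency_value=potency,
                potency_units=cell("potency_units") or None,
                potency_relation=cell("potency_relation") or None,
                assay_type=cell("assay_type"),
                organism=cell("organism"),
            )
        )
    return records


def _is_inactive(record: BioactivityRecord, config: CurationConfig) -> bool:
    comment = record.activity_comment.lower()
    return any(sub in comment for sub in config.inactive_comments)


def cluster_assays_by_protein(
    records: Sequence[BioactivityRecord],
    config: CurationConfig | None = None,
) -> list[BioactivityRecord]:
    """Collapse assays measuring the same compound-target pair.

    Different bioassays against the same protein become one record per
    (compound, target, activity class), where the activity class separates
    explicitly-inactive evidence from everything else so downstream
    arbitration sees both.  Assay ids, assay types and organisms are
    concatenated (sorted, ``;``-joined) into the collapsed record's
    provenance fields.
    """
    config = config or CurationConfig()
    groups: dict[tuple[str, str, bool], list[BioactivityRecord]] = {}
    order: list[tuple[str, str, bool]] = []
    for rec in records:
        key = (rec.compound_id, rec.target_id, _is_inactive(rec, config))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    collapsed: list[BioactivityRecord] = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            collapsed.append(members[0])
            continue
        head = members[0]

        def joined(values: Iterable[str]) -> str:
            return ";".join(sorted({v for v in values if v}))

        # Strongest potency evidence wins the collapse (consistent with the
        # positive-over-inactive arbitration): one good measurement keeps
        # the pair even if another assay reported it weak.  Members without
        # comparable nM evidence sort in front so an uncommented potency is
        # never invented.
        def weakness(rec: BioactivityRecord) -> float:
            if rec.potency_value is None or rec.potency_units != "nM":
                return -1.0
            return rec.potency_value

        strongest_signal = min(members, key=weakness)
        collapsed.append(
            replace(
                head,
                assay_id=joined(m.assay_id for m in members),
                assay_type=joined(m.assay_type for m in members),
                organism=joined(m.organism for m in members),
                activity_comment=head.activity_comment
                or next((m.activity_comment for m in members if m.activity_comment), ""),
                potency_value=strongest_signal.potency_value,
                potency_units=strongest_signal.potency_units,
                potency_relation=strongest_signal.potency_relation,
            )
        )
    return collapsed


def _potency_rejection(
    record: BioactivityRecord, config: CurationConfig
) -> str | None:
    """Reason code if the potency evidence violates the ceiling, else None."""
    if record.potency_value is None:
        return None
    if record.potency_units is not None and record.potency_units != "nM":
        return REASON_UNIT_UNSUPPORTED
    relation = record.potency_relation or "="
    if relation in (">", ">=") and record.potency_value >= config.potency_ceiling_nM:
        return REASON_POTENCY_CEILING
    if (
        config.reject_measured_above_ceiling
        and record.potency_value > config.potency_ceiling_nM
    ):
        return REASON_POTENCY_CEILING
    return None


def curate_records(
    records: Sequence[BioactivityRecord],
    config: CurationConfig | None = None,
) -> tuple[
    set[tuple[str, str]],
    set[tuple[str, str]],
    list[tuple[BioactivityRecord, str]],
]:
    """Apply the filtering rules to collapsed records.

    Returns ``(positives, known_inactives, rejection_log)``.  A pair becomes
    a positive iff its target type is allowed, its activity comment matches
    no excluded substring and its potency evidence does not violate the
    ceiling.  A pair whose only evidence is an explicit inactive annotation
    becomes a known-inactive.  Every rejected record carries exactly one
    reason code.  A pair with both active and inactive evidence is arbitrated
    as positive (the inactive evidence is dropped and logged).
    """
    config = config or CurationConfig()
    positives: set[tuple[str, str]] = set()
    known_inactives: set[tuple[str, str]] = set()
    rejections: list[tuple[BioactivityRecord, str]] = []

    for rec in records:
        if rec.target_type not in config.allowed_target_types:
            rejections.append((rec, REASON_TARGET_TYPE))
            continue
        comment = rec.activity_comment.lower()
        if any(sub in comment for sub in config.excluded_comments):
            if _is_inactive(rec, config):
                known_inactives.add(rec.pair)
            rejections.append((rec, REASON_COMMENT_EXCLUDED))
            continue
        potency_reason = _potency_rejection(rec, config)
        if potency_reason is not None:
            rejections.append((rec, potency_reason))
            continue
        positives.add(rec.pair)

    # Pair-level arbitration: positive evidence wins over explicit inactivity.
    conflicts = positives & known_inactives
    for pair in sorted(conflicts):
        logger.info("pair %s has both active and inactive evidence; kept positive", pair)
    known_inactives -= conflicts
    return positives, known_inactives, rejections


def build_interaction_matrix(
    positives: Iterable[tuple[str, str]],
    known_inactives: Iterable[tuple[str, str]] = (),
    config: CurationConfig | None = None,
) -> InteractionMatrix:
    """Assemble the reference standard from curated pair sets.

    Compounds with fewer than ``min_targets_per_compound`` distinct positive
    targets are dropped (their pairs removed from both sets).  The surviving
    universes are sorted lexicographically.
    """
    config = config or CurationConfig()
    positives = set(positives)
    known_inactives = set(known_inactives) - positives

    per_compound: dict[str, set[str]] = {}
    for c, t in positives:
        per_compound.setdefault(c, set()).add(t)
    surviving = {
        c for c, ts in per_compound.items() if len(ts) >= config.min_targets_per_compound
    }
    if not surviving:
        raise EmptyReferenceStandardError(
            "no compound has enough targets to enter the reference standard"
        )
    kept_positives = {(c, t) for c, t in positives if c in surviving}
    targets = sorted({t for _, t in kept_positives})
    target_set = set(targets)
    kept_inactives = {
        (c, t) for c, t in known_inactives if c in surviving and t in target_set
    }
    return InteractionMatrix(
        compounds=tuple(sorted(surviving)),
        targets=tuple(targets),
        positives=frozenset(kept_positives),
        known_inactives=frozenset(kept_inactives),
        min_targets_per_compound=config.min_targets_per_compound,
        filtered=True,
    )


def build_reference_standard(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    config: CurationConfig | None = None,
) -> tuple[InteractionMatrix, list[tuple[BioactivityRecord, str]]]:
    """Full pipeline: parse, cluster, curate and build the matrix."""
    config = config or CurationConfig()
    records = read_bioactivity_table(source, column_map)
    collapsed = cluster_assays_by_protein(records, config)
    positives, inactives, rejections = curate_records(collapsed, config)
    matrix = build_interaction_matrix(positives, inactives, config)
    return matrix, rejections


def write_reference_standard(matrix: InteractionMatrix, path: str) -> None:
    """Write ``compound_id<TAB>target_id<TAB>status`` rows, sorted, LF endings."""
    rows = [(c, t, "positive") for c, t in matrix.positives]
    rows += [(c, t, "inactive") for c, t in matrix.known_inactives]
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("compound_id\ttarget_id\tstatus\n")
        for c, t, status in sorted(rows):
            fh.write(f"{c}\t{t}\t{status}\n")


def read_reference_standard(
    source: str | IO[str], config: CurationConfig | None = None
) -> InteractionMatrix:
    """Read a reference-standard TSV back into an :class:`InteractionMatrix`.

    The minimum-targets filter is re-applied, so re-curating a written
    standard is idempotent.
    """
    config = config or CurationConfig()
    df = pd.read_csv(source, sep="\t", dtype=str)
    positives = {
        (r.compound_id, r.target_id)
        for r in df.itertuples(index=False)
        if r.status == "positive"
    }
    inactives = {
        (r.compound_id, r.target_id)
        for r in df.itertuples(index=False)
        if r.status == "inactive"
    }
    return build_interaction_matrix(positives, inactives, config)


def write_rejections(
    rejections: Sequence[tuple[BioactivityRecord, str]], path: str
) -> None:
    """Write the rejection log (record fields + reason code), sorted."""
    header = [
        "compound_id",
        "target_id",
        "target_type",
        "assay_id",
        "activity_comment",
        "potency_value",
        "potency_units",
        "potency_relation",
        "assay_type",
        "organism",
        "reason",
    ]
    lines = []
    for rec, reason in rejections:
        lines.append(
            "\t".join(
                [
                    rec.compound_id,
                    rec.target_id,
                    rec.target_type,
                    rec.assay_id,
                    rec.activity_comment,
                    "" if rec.potency_value is None else repr(rec.potency_value),
                    rec.potency_units or "",
                    rec.potency_relation or "",
                    rec.assay_type,
                    rec.organism,
                    reason,
                ]
            )
        )
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for line in sorted(lines):
            fh.write(line + "\n")
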