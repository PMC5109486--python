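"""Curation of raw bioactivity records into the reference standard."""

import io

import pytest

from tipf.curation import (
    REASON_COMMENT_EXCLUDED,
    REASON_POTENCY_CEILING,
    REASON_TARGET_TYPE,
    REASON_UNIT_UNSUPPORTED,
    BioactivityRecord,
    CurationConfig,
    CurationError,
    EmptyReferenceStandardError,
    build_interaction_matrix,
    build_reference_standard,
    cluster_assays_by_protein,
    curate_records,
    read_bioactivity_table,
    read_reference_standard,
    write_reference_standard,
)
from conftest import frame_to_buffer

HEADER = (
    "molecule_chembl_id\ttarget_chembl_id\ttarget_type\tassay_chembl_id"
    "\tactivity_comment\tstandard_value\tstandard_units\tstandard_relation"
    "\tassay_type\ttarget_organism"
)


def table(*rows: str) -> io.StringIO:
    return io.StringIO("\n".join([HEADER, *rows]) + "\n")


class TestReadBioactivityTable:
    def test_identity_parse(self):
        src = table(
            "C1\tT1\tSINGLE PROTEIN\tA1\t\t100.0\tnM\t=\tB\tHomo sapiens",
            "C2\tT2\tSINGLE PROTEIN\tA2\tActive\t12.5\tnM\t<\tF\tHomo sapiens",
            "C3\tT3\tPROTEIN COMPLEX\tA3\t\t\t\t\tB\tRattus norvegicus",
        )
        records = read_bioactivity_table(src)
        assert len(records) == 3
        assert records[0] == BioactivityRecord(
            "C1", "T1", "SINGLE PROTEIN", "A1", "", 100.0, "nM", "=", "B", "Homo sapiens"
        )
        assert records[2].potency_value is None
        assert records[2].potency_relation is None

    def test_unparsable_potency_becomes_absent(self, caplog):
        src = table("C1\tT1\tSINGLE PROTEIN\tA1\t\tND\tnM\t=\tB\tHomo sapiens")
        with caplog.at_level("WARNING", logger="tipf.curation"):
            records = read_bioactivity_table(src)
        assert records[0].potency_value is None
        assert any("unparsable potency" in m for m in caplog.messages)

    def test_missing_mapped_column_is_configuration_error(self):
        src = io.StringIO("compound\ttarget\nC1\tT1\n")
        with pytest.raises(CurationError, match="molecule_chembl_id"):
            read_bioactivity_table(src)

    def test_round_trip_against_generator_truth(self, decorated_dataset):
        frame, _ = decorated_dataset
        records = read_bioactivity_table(frame_to_buffer(frame))
        assert len(records) == len(frame)
        got = {(r.compound_id, r.target_id, r.assay_id) for r in records}
        want = {
            (row.molecule_chembl_id, row.target_chembl_id, row.assay_chembl_id)
            for row in frame.itertuples(index=False)
        }
        assert got == want


class TestClusterAssays:
    def test_two_assays_same_pair_collapse(self):
        recs = [
            BioactivityRecord("C1", "T1", assay_id="A1", assay_type="B"),
            BioactivityRecord("C1", "T1", assay_id="A2", assay_type="F"),
        ]
        out = cluster_assays_by_protein(recs)
        assert len(out) == 1
        assert out[0].assay_id == "A1;A2"
        assert out[0].assay_type == "B;F"

    def test_singleton_unchanged(self):
        rec = BioactivityRecord("C1", "T1", assay_id="A1")
        assert cluster_assays_by_protein([rec]) == [rec]

    def test_mixed_evidence_hand_enumeration(self):
        # 12 records over 5 distinct pairs; (C1,T1) has both active and
        # explicitly inactive evidence and must collapse to two records.
        recs = [
            BioactivityRecord("C1", "T1", assay_id="A1"),
            BioactivityRecord("C1", "T1", assay_id="A2"),
            BioactivityRecord("C1", "T1", assay_id="A3", activity_comment="Not Active"),
            BioactivityRecord("C1", "T2", assay_id="A4"),
            BioactivityRecord("C1", "T2", assay_id="A5"),
            BioactivityRecord("C2", "T1", assay_id="A6"),
            BioactivityRecord("C2", "T1", assay_id="A7"),
            BioactivityRecord("C2", "T1", assay_id="A8"),
            BioactivityRecord("C2", "T2", assay_id="A9"),
            BioactivityRecord("C3", "T3", assay_id="A10"),
            BioactivityRecord("C3", "T3", assay_id="A11"),
            BioactivityRecord("C3", "T3", assay_id="A12"),
        ]
        out = cluster_assays_by_protein(recs)
        assert len(out) == 6
        pairs = sorted((r.compound_id, r.target_id) for r in out)
        assert pairs == [
            ("C1", "T1"),
            ("C1", "T1"),
            ("C1", "T2"),
            ("C2", "T1"),
            ("C2", "T2"),
            ("C3", "T3"),
        ]

    def test_strongest_potency_evidence_wins_collapse(self):
        # One good measurement keeps the pair; the weak assay is superseded.
        recs = [
            BioactivityRecord("C1", "T1", assay_id="A1", potency_value=10.0,
                              potency_units="nM", potency_relation="="),
            BioactivityRecord("C1", "T1", assay_id="A2", potency_value=60000.0,
                              potency_units="nM", potency_relation=">"),
        ]
        out = cluster_assays_by_protein(recs)
        assert len(out) == 1
        assert out[0].potency_value == 10.0
        positives, _, log = curate_records(out)
        assert positives == {("C1", "T1")}


class TestCurateRecords:
    @pytest.mark.parametrize(
        "record, reason",
        [
            (
                BioactivityRecord("C1", "T1", potency_value=50000.0,
                                  potency_units="nM", potency_relation=">"),
                REASON_POTENCY_CEILING,
            ),
            (
                BioactivityRecord("C1", "T1", potency_value=60000.0,
                                  potency_units="nM", potency_relation="="),
                REASON_POTENCY_CEILING,
            ),
            (
                BioactivityRecord("C1", "T1", target_type="PROTEIN COMPLEX"),
                REASON_TARGET_TYPE,
            ),
            (
                BioactivityRecord("C1", "T1", target_type="UNSPECIFIED"),
                REASON_TARGET_TYPE,
            ),
            (
                BioactivityRecord("C1", "T1", activity_comment="Not Determined"),
                REASON_COMMENT_EXCLUDED,
            ),
            (
                BioactivityRecord("C1", "T1", potency_value=10.0,
                                  potency_units="uM", potency_relation="="),
                REASON_UNIT_UNSUPPORTED,
            ),
        ],
    )
    def test_single_rejection_reason(self, record, reason):
        positives, inactives, log = curate_records([record])
        assert positives == set()
        assert [r for _, r in log] == [reason]

    def test_not_active_goes_to_known_inactives(self):
        rec = BioactivityRecord("C1", "T1", activity_comment="Not Active")
        positives, inactives, log = curate_records([rec])
        assert positives == set()
        assert inactives == {("C1", "T1")}
        assert [r for _, r in log] == [REASON_COMMENT_EXCLUDED]

    def test_measured_at_ceiling_is_kept(self):
        # "=" at exactly the ceiling does not exceed it.
        rec = BioactivityRecord("C1", "T1", potency_value=50000.0,
                                potency_units="nM", potency_relation="=")
        positives, _, log = curate_records([rec])
        assert positives == {("C1", "T1")}
        assert log == []

    def test_measured_above_ceiling_configurable_off(self):
        rec = BioactivityRecord("C1", "T1", potency_value=60000.0,
                                potency_units="nM", potency_relation="=")
        config = CurationConfig(reject_measured_above_ceiling=False)
        positives, _, log = curate_records([rec], config)
        assert positives == {("C1", "T1")}

    def test_conflicting_evidence_arbitrated_positive(self):
        recs = [
            BioactivityRecord("C1", "T1", assay_id="A1"),
            BioactivityRecord("C1", "T1", assay_id="A2", activity_comment="Not Active"),
        ]
        positives, inactives, _ = curate_records(cluster_assays_by_protein(recs))
        assert ("C1", "T1") in positives
        assert ("C1", "T1") not in inactives

    def test_every_input_pair_accounted_once(self, decorated_dataset):
        frame, _ = decorated_dataset
        records = read_bioactivity_table(frame_to_buffer(frame))
        collapsed = cluster_assays_by_protein(records)
        positives, inactives, log = curate_records(collapsed)
        rejected_pairs = {(r.compound_id, r.target_id) for r, _ in log}
        input_pairs = {(r.compound_id, r.target_id) for r in records}
        assert positives | inactives | rejected_pairs == input_pairs
        assert len(positives) + len(inactives) + len(rejected_pairs) >= len(
            input_pairs
        )
        # Exactly one reason per rejected record.
        assert len(log) == len([r for r, _ in log])


class TestBuildInteractionMatrix:
    def test_threshold_boundary(self):
        positives = (
            {("C1", f"T{i}") for i in range(16)}
            | {("C2", f"T{i}") for i in range(15)}
            | {("C3", f"T{i}") for i in range(3)}
        )
        matrix = build_interaction_matrix(positives)
        assert matrix.compounds == ("C1", "C2")

    def test_min_one_keeps_everything(self):
        positives = {("C1", "T1"), ("C2", "T2"), ("C3", "T1")}
        config = CurationConfig(min_targets_per_compound=1)
        matrix = build_interaction_matrix(positives, config=config)
        assert set(matrix.positives) == positives

    def test_survivors_match_brute_force_tally(self, clustered_matrix):
        # Independent per-compound tally from the raw standard.
        spec_positives = clustered_matrix.positives
        tally = {}
        for c, t in spec_positives:
            tally.setdefault(c, set()).add(t)
        assert all(len(ts) >= 15 for ts in tally.values())

    def test_empty_standard_raises(self):
        with pytest.raises(EmptyReferenceStandardError):
            build_interaction_matrix({("C1", "T1")})

    def test_universes_sorted(self, clustered_matrix):
        assert list(clustered_matrix.compounds) == sorted(clustered_matrix.compounds)
        assert list(clustered_matrix.targets) == sorted(clustered_matrix.targets)


class TestIdempotenceAndSerialization:
    def test_curation_idempotent_through_serialization(self, decorated_dataset, tmp_path):
        frame, _ = decorated_dataset
        matrix, _ = build_reference_standard(frame_to_buffer(frame))
        path = tmp_path / "standard.tsv"
        write_reference_standard(matrix, str(path))
        again = read_reference_standard(str(path))
        assert again.positives == matrix.positives
        assert again.known_inactives == matrix.known_inactives
        assert again.compounds == matrix.compounds
        assert again.targets == matrix.targets

    def test_rerun_byte_identical(self, decorated_dataset, tmp_path):
        frame, _ = decorated_dataset
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for out in (out1, out2):
            matrix, _ = build_reference_standard(frame_to_buffer(frame))
            write_reference_standard(matrix, str(out))
        assert out1.read_bytes() == out2.read_bytes()


def test_record_invariants_enforced():
    with pytest.raises(CurationError):
        BioactivityRecord("", "T1")
    with pytest.raises(CurationError):
        BioactivityRecord("C1", "T1", potency_value=-5.0)
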