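"""Curate a raw bioactivity table into a reference standard.

Generates a small synthetic assay table whose rows include every pathology
the curation rules handle — "Not Active" comments, potencies established
above the 50,000 nM ceiling, non-single-protein targets and duplicate
assays — then runs the full curation pipeline and prints what survived.
"""

import io

from tipf import (
    RecordDecorations,
    SyntheticSpec,
    build_reference_standard,
    generate,
)

spec = SyntheticSpec(
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
)
frame, truth = generate(spec)
print(f"raw table: {len(frame)} assay records")

matrix, rejections = build_reference_standard(
    io.StringIO(frame.to_csv(sep="\t", index=False))
)
print(
    f"reference standard: {len(matrix.compounds)} compounds x "
    f"{len(matrix.targets)} targets, {len(matrix.positives)} positive pairs, "
    f"{len(matrix.known_inactives)} known inactives"
)
print(f"rejected records: {len(rejections)}")
for record, reason in sorted(rejections, key=lambda r: (r[1], r[0].compound_id)):
    print(f"  {record.compound_id} x {record.target_id}: {reason}")

# Each rejection reason corresponds to one curation rule; duplicate assays
# are collapsed into single records rather than rejected, so the positive
# pair count matches the clean interactions exactly.
assert matrix.positives == truth.emitted_positives
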