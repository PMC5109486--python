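import io

import pytest

from tipf.curation import CurationConfig, build_reference_standard, build_interaction_matrix
from tipf.fingerprints import build_tipfs
from tipf.synthetic import RecordDecorations, SyntheticSpec, generate


def frame_to_buffer(frame):
    return io.StringIO(frame.to_csv(sep="\t", index=False))


@pytest.fixture(scope="session")
def decorated_dataset():
    """Raw table exercising every curation rule, with its truth."""
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
    return generate(spec)


@pytest.fixture(scope="session")
def clustered_matrix():
    """A 40-compound curated matrix with family structure and noise."""
    spec = SyntheticSpec(seed=7)
    frame, _ = generate(spec)
    matrix, _ = build_reference_standard(frame_to_buffer(frame))
    return matrix


@pytest.fixture(scope="session")
def clustered_tipfs(clustered_matrix):
    return build_tipfs(clustered_matrix)


@pytest.fixture
def tiny_matrix():
    """Two 3-compound families over disjoint 4-target blocks (unfiltered)."""
    positives = {
        (c, t)
        for c in ("C1", "C2", "C3")
        for t in ("T1", "T2", "T3", "T4")
    } | {
        (c, t)
        for c in ("C4", "C5", "C6")
        for t in ("T5", "T6", "T7", "T8")
    }
    config = CurationConfig(min_targets_per_compound=1)
    return build_interaction_matrix(positives, config=config)
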