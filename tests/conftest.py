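"""Shared fixtures: hand-built transcripts and labeled synthetic sets."""

import pytest
from hypothesis import settings

from nmdscreen.transcript_model import TranscriptModel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def build(sequence, exon_lengths=None, cds_start=None, cds_end=None, ident="T1"):
    """Construct a TranscriptModel with a single exon by default."""
    if exon_lengths is None:
        exon_lengths = (len(sequence),)
    return TranscriptModel(
        id=ident,
        sequence=sequence,
        exon_lengths=tuple(exon_lengths),
        cds_start=cds_start,
        cds_end=cds_end,
    )


@pytest.fixture
def simple_orf_transcript():
    """ATGAAATAG: one minimal ORF spanning the whole transcript."""
    return build("ATGAAATAG")


@pytest.fixture(scope="session")
def labeled_set():
    """A small balanced labeled set shared across tests (20 per class)."""
    from nmdscreen.synthetic_fixtures import make_transcript_set

    return make_transcript_set(n_per_label=20, seed=7)
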