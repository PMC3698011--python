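"""Shared fixtures: small synthetic read sets and a hand-written FASTQ."""

import numpy as np
import pytest

from qualcodec.synthetic import default_spec, generate_records, two_blob_spec

# The classic public example entry: a 26-base read on the Phred+33 scale.
SAMPLE_FASTQ = (
    "@SRR001666.1\n"
    "GATTTGGGGTTCAAAGCAGTGCAAGC\n"
    "+\n"
    "IIIHIIHABBBAA=2))!!!(!!!((\n"
)


@pytest.fixture
def sample_fastq_text():
    return SAMPLE_FASTQ


@pytest.fixture(scope="session")
def gaussian_records():
    """5000 Illumina-like reads of length 50, fixed seed (session-wide)."""
    records, _ = generate_records(default_spec(5000, 50, seed=123))
    return records


@pytest.fixture(scope="session")
def small_gaussian_records():
    """A lighter single-population set for per-test compression runs."""
    records, _ = generate_records(default_spec(800, 30, seed=42))
    return records


@pytest.fixture(scope="session")
def blob_records_and_labels():
    """Two well-separated quality populations (means 35 and 70)."""
    return generate_records(two_blob_spec(2000, 40, seed=5))
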