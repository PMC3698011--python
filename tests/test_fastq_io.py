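"""FASTQ parsing, quality decoding/encoding, and header-sorted output."""

import gzip
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qualcodec.fastq_io import (
    FastqFormatError,
    FastqRecord,
    QualityBlock,
    decode_qualities,
    encode_qualities,
    read_fastq,
    write_fastq_sorted,
)


class TestReadFastq:
    def test_sample_entry(self, sample_fastq_text):
        records = read_fastq(io.StringIO(sample_fastq_text))
        assert len(records) == 1
        rec = records[0]
        assert rec.header == "SRR001666.1"
        assert len(rec) == 26
        assert rec.sequence.startswith("GATTTGG")
        assert rec.quality_ascii.endswith("((")

    def test_empty_stream(self):
        assert read_fastq(io.StringIO("")) == []

    def test_write_read_round_trip(self, tmp_path):
        records = [
            FastqRecord("a/1", "ACGT", "+", "IIII"),
            FastqRecord("b/1", "TTTT", "+b/1", "!!!!"),
        ]
        path = tmp_path / "two.fastq"
        write_fastq_sorted(records, path)
        assert read_fastq(path) == records

    def test_gzip_round_trip(self, tmp_path):
        records = [FastqRecord("r1", "ACGTN", "+", "IIHH!")]
        path = tmp_path / "one.fastq.gz"
        write_fastq_sorted(records, path)
        assert read_fastq(path) == records

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("X1\nACGT\n+\nIIII\n", "@"),  # missing @ sigil
            ("@r1\nACGT\n-\nIIII\n", r"\+"),  # bad plus line
            ("@r1\nACGT\n+\nIII\n", "mismatch"),  # qual shorter than seq
            ("@r1\nACGT\n+\nIIII\n@r2\nACG\n+\nIII\n", "length 3"),  # ragged reads
            ("@r1\nACGT\n+\n", "truncated"),  # incomplete record
        ],
    )
    def test_malformed_input_rejected_with_position(self, text, fragment):
        with pytest.raises(FastqFormatError, match=fragment):
            read_fastq(io.StringIO(text))


class TestWriteSorted:
    def test_headers_ordered_bytewise(self):
        records = [
            FastqRecord("b", "A", "+", "I"),
            FastqRecord("a", "C", "+", "I"),
        ]
        out = io.StringIO()
        write_fastq_sorted(records, out)
        parsed = read_fastq(io.StringIO(out.getvalue()))
        assert [r.header for r in parsed] == ["a", "b"]

    def test_already_sorted_unchanged(self):
        records = [FastqRecord(h, "A", "+", "I") for h in ["a", "b", "c"]]
        out = io.StringIO()
        write_fastq_sorted(records, out)
        assert [r.header for r in read_fastq(io.StringIO(out.getvalue()))] == ["a", "b", "c"]

    def test_paired_files_share_ordering(self):
        # mates carry the same headers; sorting must agree across files
        headers = ["r3", "r1", "r2"]
        mate1 = [FastqRecord(h, "AC", "+", "II") for h in headers]
        mate2 = [FastqRecord(h, "GT", "+", "HH") for h in reversed(headers)]
        out1, out2 = io.StringIO(), io.StringIO()
        write_fastq_sorted(mate1, out1)
        write_fastq_sorted(mate2, out2)
        order1 = [r.header for r in read_fastq(io.StringIO(out1.getvalue()))]
        order2 = [r.header for r in read_fastq(io.StringIO(out2.getvalue()))]
        assert order1 == order2


class TestQualityCodec:
    def test_ascii_codes_are_the_scores(self):
        rec = FastqRecord("r", "AC", "+", "!I")
        block = decode_qualities([rec], offset=33)
        assert block.values.tolist() == [[33, 73]]

    def test_sample_read_leading_values(self, sample_fastq_text):
        records = read_fastq(io.StringIO(sample_fastq_text))
        block = decode_qualities(records, offset=33)
        assert block.values[0, :3].tolist() == [73, 73, 73]

    def test_n_mask_marks_unknown_bases(self):
        rec = FastqRecord("r", "ANGN", "+", "IIII")
        block = decode_qualities([rec], offset=33)
        assert block.n_mask.tolist() == [[False, True, False, True]]

    def test_character_below_offset_rejected(self):
        rec = FastqRecord("r", "AC", "+", "I ")  # space = 32 < 33
        with pytest.raises(ValueError, match="position 1"):
            decode_qualities([rec], offset=33)

    def test_encode_decode_inverse(self):
        rng = np.random.default_rng(0)
        values = rng.integers(33, 74, size=(10, 8))
        block = QualityBlock(values, 33, 33, 73)
        strings = encode_qualities(block)
        records = [FastqRecord(f"r{i}", "A" * 8, "+", s) for i, s in enumerate(strings)]
        assert np.array_equal(decode_qualities(records, 33).values, values)

    def test_all_bang_row(self):
        block = QualityBlock(np.full((2, 3), 33), 33, 33, 73)
        assert encode_qualities(block) == ["!!!", "!!!"]

    def test_value_above_qmax_rejected(self):
        block = QualityBlock(np.full((1, 2), 73), 33, 33, 73)
        block.values[0, 1] = 74  # mutate past validation
        with pytest.raises(ValueError, match="74"):
            encode_qualities(block)

    def test_matches_biopython_phred_decoding(self, sample_fastq_text):
        """Raw ASCII codes equal Biopython's Phred values plus the offset."""
        from Bio import SeqIO

        (bio_rec,) = SeqIO.parse(io.StringIO(sample_fastq_text), "fastq")
        ours = decode_qualities(read_fastq(io.StringIO(sample_fastq_text)), 33)
        expected = np.array(bio_rec.letter_annotations["phred_quality"]) + 33
        assert np.array_equal(ours.values[0], expected)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.text(st.characters(min_codepoint=48, max_codepoint=122), min_size=1, max_size=8),
            st.lists(st.sampled_from("ACGTN"), min_size=6, max_size=6),
            st.lists(st.integers(33, 73), min_size=6, max_size=6),
        ),
        min_size=0,
        max_size=6,
    )
)
def test_write_then_read_is_identity_on_sorted_lists(entries):
    """write_fastq_sorted then read_fastq returns the header-sorted records."""
    records = [
        FastqRecord(f"{i:02d}.{h}", "".join(seq), "+", "".join(chr(q) for q in quals))
        for i, (h, seq, quals) in enumerate(entries)
    ]
    out = io.StringIO()
    write_fastq_sorted(records, out)
    back = read_fastq(io.StringIO(out.getvalue()))
    assert back == sorted(records, key=lambda r: r.header.encode())
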