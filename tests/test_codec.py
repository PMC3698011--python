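"""End-to-end codec behavior: round trips, container format, rate accounting."""

import io

import numpy as np
import pytest

from qualcodec.codec import (
    CompressedContainer,
    ContainerFormatError,
    SequenceStub,
    compress,
    compress_file,
    decompress,
    decompress_file,
    effective_rate,
    read_container,
)
from qualcodec.fastq_io import FastqRecord, decode_qualities, read_fastq
from qualcodec.model_stats import round_half_away
from qualcodec.prng import SplitMix64
from qualcodec.rate_allocator import realize_allocations
from qualcodec.evaluation import mse


@pytest.fixture(scope="module")
def compressed(small_gaussian_records):
    container, stub = compress(small_gaussian_records, rate=0.5, clusters=2, seed=11)
    return small_gaussian_records, container, stub


class TestRoundTripConservation:
    def test_counts_headers_and_sequences_preserved(self, compressed):
        records, container, stub = compressed
        out = decompress(container, stub)
        assert len(out) == len(records)
        assert sorted(r.header for r in out) == sorted(r.header for r in records)
        originals = {r.header: r for r in records}
        for rec in out:
            src = originals[rec.header]
            assert rec.sequence == src.sequence
            assert rec.plus_line == src.plus_line
            assert len(rec.quality_ascii) == len(src.quality_ascii)

    def test_output_is_header_sorted(self, compressed):
        _, container, stub = compressed
        out = decompress(container, stub)
        headers = [r.header for r in out]
        assert headers == sorted(headers, key=str.encode)

    def test_decompress_is_deterministic(self, compressed):
        _, container, stub = compressed
        reparsed = CompressedContainer.from_bytes(container.to_bytes())
        assert decompress(container, stub) == decompress(reparsed, stub)

    def test_paired_files_decompress_in_identical_order(self, small_gaussian_records):
        mate1 = small_gaussian_records[:300]
        mate2 = [
            FastqRecord(r.header, r.sequence[::-1], r.plus_line, r.quality_ascii[::-1])
            for r in mate1
        ]
        out1 = decompress(*compress(mate1, 0.3, clusters=2, seed=3))
        out2 = decompress(*compress(mate2, 0.3, clusters=2, seed=99))
        assert [r.header for r in out1] == [r.header for r in out2]


class TestZeroRate:
    def test_payload_empty(self, small_gaussian_records):
        container, _ = compress(small_gaussian_records, rate=0.0, clusters=1, seed=0)
        assert container.payload == b""

    def test_reconstruction_is_rounded_cluster_mean(self, small_gaussian_records):
        container, stub = compress(small_gaussian_records, rate=0.0, clusters=1, seed=0)
        out = decompress(container, stub)
        mu = container.clusters[0].mu
        expected = np.clip(round_half_away(mu), container.qmin, container.qmax)
        by_header = {r.header: r for r in small_gaussian_records}
        for rec in out:
            got = np.frombuffer(rec.quality_ascii.encode(), dtype=np.uint8)
            n_pos = np.frombuffer(by_header[rec.header].sequence.encode(), np.uint8) == ord("N")
            assert np.array_equal(got[~n_pos], expected[~n_pos].astype(np.uint8))
            assert np.all(got[n_pos] == container.qmin)

    def test_all_n_read_gets_minimum_quality(self):
        records = [
            FastqRecord("allN", "NNNN", "+", "IIII"),
            FastqRecord("ok1", "ACGT", "+", "HHHH"),
            FastqRecord("ok2", "ACGT", "+", "IIHH"),
        ]
        container, stub = compress(records, rate=1.0, clusters=1, seed=0)
        out = {r.header: r for r in decompress(container, stub)}
        assert out["allN"].quality_ascii == chr(container.qmin) * 4


class TestContainerFormat:
    def test_serialization_is_bit_exact(self, compressed):
        _, container, _ = compressed
        data = container.to_bytes()
        assert CompressedContainer.from_bytes(data).to_bytes() == data

    def test_bad_magic_rejected(self, compressed):
        _, container, _ = compressed
        data = bytearray(container.to_bytes())
        data[:4] = b"NOPE"
        with pytest.raises(ContainerFormatError, match="magic"):
            CompressedContainer.from_bytes(bytes(data))

    def test_truncated_container_rejected(self, compressed):
        _, container, _ = compressed
        data = container.to_bytes()
        with pytest.raises(ContainerFormatError, match="truncated"):
            CompressedContainer.from_bytes(data[: len(data) // 2])

    def test_payload_length_mismatch_rejected(self, compressed):
        _, container, stub = compressed
        clipped = CompressedContainer.from_bytes(container.to_bytes())
        clipped.payload = clipped.payload[:-1]
        with pytest.raises(ContainerFormatError, match="payload"):
            decompress(clipped, stub)

    def test_stub_count_mismatch_rejected(self, compressed):
        _, container, stub = compressed
        short = SequenceStub(stub.headers[:-1], stub.sequences[:-1], stub.plus_lines[:-1])
        with pytest.raises(ContainerFormatError, match="reads"):
            decompress(container, short)

    def test_cluster_counts_sum_checked(self, compressed):
        _, container, _ = compressed
        data = bytearray(container.to_bytes())
        # count of cluster 0 sits right after the fixed header
        header_len = 4 + 1 + 4 + 8 + 1 + 1 + 1 + 1 + 8 + 8 + 2
        data[header_len] ^= 0xFF
        with pytest.raises(ContainerFormatError, match="counts"):
            CompressedContainer.from_bytes(bytes(data))


class TestRateAccounting:
    def test_effective_rate_is_container_bits_per_score(self, compressed):
        records, container, _ = compressed
        n_scores = len(records) * len(records[0])
        expected = len(container.to_bytes()) * 8 / n_scores
        assert effective_rate(container) == pytest.approx(expected)
        assert effective_rate(container) > container.rate

    def test_overhead_excludes_payload(self, compressed):
        _, container, _ = compressed
        assert (
            container.overhead_bytes + container.payload_bytes
            == len(container.to_bytes())
        )

    def test_payload_matches_realized_allocation(self, compressed):
        """Payload bit length equals the sum of the per-read integer budgets."""
        _, container, _ = compressed
        prng = SplitMix64(container.seed)
        total_bits = 0
        for c in container.clusters:
            if c.count:
                total_bits += int(realize_allocations(c.rho, c.count, prng).sum())
        assert len(container.payload) == (total_bits + 7) // 8


class TestEncoderDecoderSync:
    def test_decoder_replays_identical_rounding_draws(self, compressed):
        """The rho' sequence the decoder draws is bit-identical to the encoder's."""
        _, container, _ = compressed
        enc, dec = SplitMix64(container.seed), SplitMix64(container.seed)
        for c in container.clusters:
            if not c.count:
                continue
            assert np.array_equal(
                realize_allocations(c.rho, c.count, enc),
                realize_allocations(c.rho, c.count, dec),
            )
        assert enc.counter == dec.counter == sum(
            c.count for c in container.clusters
        ) * container.n


class TestFileLevelApi:
    def test_compress_decompress_files(self, tmp_path, small_gaussian_records):
        from qualcodec.fastq_io import write_fastq_sorted

        src = tmp_path / "in.fastq"
        write_fastq_sorted(small_gaussian_records, src)
        qc, qcs = compress_file(src, tmp_path / "out", rate=0.5, clusters=2, seed=1)
        assert qc.exists() and qcs.exists()
        dst = tmp_path / "back.fastq"
        decompress_file(qc, qcs, dst)
        back = read_fastq(dst)
        assert len(back) == len(small_gaussian_records)
        report = mse(small_gaussian_records, back, container=read_container(qc))
        assert report.mse >= 0
        assert report.rate_effective > 0.5

    def test_rate_above_cap_rejected(self, small_gaussian_records):
        with pytest.raises(ValueError, match="cap"):
            compress(small_gaussian_records, rate=16.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no reads"):
            compress([], rate=1.0)


def test_quality_only_changes_under_lossy_settings(small_gaussian_records):
    """Nucleotides and headers are never touched; only quality strings move."""
    container, stub = compress(small_gaussian_records, rate=0.2, clusters=1, seed=5)
    out = decompress(container, stub)
    src = {r.header: r for r in small_gaussian_records}
    changed = sum(r.quality_ascii != src[r.header].quality_ascii for r in out)
    assert all(r.sequence == src[r.header].sequence for r in out)
    assert changed > 0  # rate 0.2 is genuinely lossy on noisy input
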