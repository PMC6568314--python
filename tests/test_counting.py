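"""Read filtering, protospacer location and PAM counting, checked against
planted ground truth and a naive brute-force scanner."""

import numpy as np
import pandas as pd
import pytest

from pamscreen.counting import (
    FastqParseError,
    ManifestError,
    count_pams,
    count_sample,
    filter_read,
    filter_reads,
    locate_protospacer,
)
from pamscreen.pams import revcomp
from pamscreen.simulate import DEFAULT_FLANK3, DEFAULT_FLANK5, DEFAULT_PROTOSPACER

PROTO = DEFAULT_PROTOSPACER


def write_fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def amplicon(pam: str) -> str:
    return DEFAULT_FLANK5 + pam + PROTO + DEFAULT_FLANK3


class TestFilterRead:
    def test_short_high_quality_read_removed(self):
        assert filter_read("A" * 29, chr(40 + 33) * 29) == "length"

    def test_long_good_read_retained(self):
        seq, qual = "A" * 75, chr(37 + 33) * 75
        assert filter_read(seq, qual) == (seq, qual)

    def test_planted_low_quality_reads_are_exactly_removed(self):
        good = [("g%d" % i, "A" * 50, chr(37 + 33) * 50) for i in range(90)]
        bad = [("b%d" % i, "A" * 50, chr(10 + 33) * 50) for i in range(10)]
        kept = list(filter_reads(good + bad))
        assert len(kept) == 90
        assert all(r[0].startswith("g") for r in kept)

    def test_trailing_low_quality_tail_is_trimmed(self):
        seq = "A" * 40 + "C" * 10
        qual = chr(37 + 33) * 40 + chr(2 + 33) * 10
        out = filter_read(seq, qual)
        assert out == ("A" * 40, chr(37 + 33) * 40)

    def test_per_base_mode_is_stricter(self):
        # a mid-read Q20 base survives 3' trimming and the mean filter but
        # not the per-base interpretation
        qual = chr(37 + 33) * 25 + chr(33 + 20) + chr(37 + 33) * 24
        seq = "A" * 50
        assert isinstance(filter_read(seq, qual), tuple)
        assert filter_read(seq, qual, quality_mode="per_base") == "quality"

    def test_length_mismatch_raises(self):
        with pytest.raises(FastqParseError):
            filter_read("ACGT", "!!!")


class TestLocate:
    def test_constructed_positive_reports_pam(self):
        read = "GGGGGTAA" + PROTO + "CCCCC"
        m = locate_protospacer("r", read, PROTO)
        assert m.strand == "+"
        assert m.pam == "TAA"
        assert m.full_coverage

    def test_reverse_complement_is_orientation_normalized(self):
        read = "GGGGGTAA" + PROTO + "CCCCC"
        m = locate_protospacer("r", revcomp(read), PROTO)
        assert m.strand == "-"
        assert m.pam == "TAA"
        assert m.full_coverage

    def test_no_hit_returns_none(self):
        assert locate_protospacer("r", "ACGT" * 30, PROTO) is None

    def test_pam_truncated_at_read_start_is_not_covered(self):
        read = PROTO + "CCCCC"
        m = locate_protospacer("r", read, PROTO)
        assert not m.full_coverage and m.pam is None

    def test_disjoint_double_hit_is_ambiguous(self):
        read = "TAA" + PROTO + "G" + "TAA" + PROTO
        assert locate_protospacer("r", read, PROTO) == "ambiguous"

    def test_mismatch_budget_recovers_mutated_protospacer(self):
        mutated = "G" + PROTO[1:]
        read = "GGGGGTAA" + mutated + "CCCCC"
        assert locate_protospacer("r", read, PROTO) is None
        m = locate_protospacer("r", read, PROTO, max_mismatches=1)
        assert m.pam == "TAA" and m.mismatches == 1


class TestCountSample:
    def test_empty_fastq_gives_zero_row(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        vec, qc = count_sample(path, PROTO)
        assert vec.sum() == 0 and qc["reads_in"] == 0

    def test_n_in_pam_counts_as_ambiguous(self, tmp_path):
        path = tmp_path / "n.fastq"
        seq = DEFAULT_FLANK5 + "CNG" + PROTO + DEFAULT_FLANK3
        write_fastq(path, [("r1", seq, chr(70) * len(seq))])
        vec, qc = count_sample(path, PROTO)
        assert vec.sum() == 0 and qc["ambiguous"] == 1

    def test_doubling_a_file_doubles_counts(self, tmp_path, scenario):
        src = scenario["manifest"].iloc[0]["path"]
        doubled = tmp_path / "doubled.fastq"
        data = open(src).read()
        doubled.write_text(data + data)
        v1, _ = count_sample(src, PROTO)
        v2, _ = count_sample(doubled, PROTO)
        pd.testing.assert_series_equal(2 * v1, v2, check_names=False)

    def test_malformed_fastq_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n")
        with pytest.raises(FastqParseError):
            count_sample(path, PROTO)


class TestCountPams:
    def test_recovers_planted_counts(self, scenario):
        # at the default error rate, reads whose error hits the protospacer
        # go unmatched and errors in the PAM reshuffle a small number of
        # counts; everything else must match the planted multinomial draw
        counts = scenario["counts"]
        truth = scenario["truth_counts"]
        qc = scenario["qc"]
        n = scenario["cfg"].reads_per_sample
        assert (qc["reads_in"] == n).all()
        # per-sample recovered totals only lose error-struck reads
        assert (qc["retained"] / n > 0.95).all()
        rel = (counts - truth).abs().to_numpy().sum() / truth.to_numpy().sum()
        assert rel < 0.06

    def test_exact_recovery_without_errors(self, tmp_path):
        from pamscreen.simulate import default_config, emit_fastq, simulate_frequencies

        cfg = default_config(
            seed=13,
            reads_per_sample=1000,
            n_replicates=1,
            time_points=(0.0, 3.0),
            seq_error_rate=0.0,
        )
        freqs = simulate_frequencies(cfg)
        manifest, truth = emit_fastq(freqs, cfg, tmp_path)
        counts, qc = count_pams(manifest, cfg.protospacer)
        pd.testing.assert_frame_equal(
            counts.sort_index(), truth.sort_index(), check_dtype=False
        )
        assert (
            qc[["quality_filtered", "length_filtered", "unmatched", "ambiguous"]]
            .to_numpy()
            .sum()
            == 0
        )

    def test_qc_categories_partition_reads(self, scenario):
        qc = scenario["qc"]
        total = qc[
            ["retained", "quality_filtered", "length_filtered", "unmatched", "ambiguous"]
        ].sum(axis=1)
        assert (total == qc["reads_in"]).all()

    def test_strand_invariance_under_file_reverse_complement(self, tmp_path, scenario):
        src = scenario["manifest"].iloc[1]["path"]
        flipped = tmp_path / "rc.fastq"
        records = []
        from pamscreen.counting import iter_fastq

        for rid, seq, qual in iter_fastq(src):
            records.append((rid, revcomp(seq), qual[::-1]))
        write_fastq(flipped, records)
        v1, qc1 = count_sample(src, PROTO)
        v2, qc2 = count_sample(flipped, PROTO)
        pd.testing.assert_series_equal(v1, v2, check_names=False)
        assert qc1 == qc2

    def test_missing_sample_file_is_a_manifest_error(self, tmp_path):
        manifest = pd.DataFrame(
            [{"condition": "ON", "replicate": 1, "time": 0.0,
              "path": str(tmp_path / "nope.fastq")}]
        )
        with pytest.raises(ManifestError):
            count_pams(manifest, PROTO)


def naive_scan_oracle(path, proto):
    """Brute-force re-implementation of the per-read pipeline: explicit
    position-by-position substring comparison, no shared code paths."""
    from pamscreen.pams import ALL_PAMS

    counts = dict.fromkeys(ALL_PAMS, 0)
    lines = open(path).read().splitlines()
    rc = revcomp(proto)
    for i in range(0, len(lines), 4):
        seq, qual = lines[i + 1].upper(), lines[i + 3]
        while qual and (ord(qual[-1]) - 33) < 32:
            seq, qual = seq[:-1], qual[:-1]
        if len(seq) < 30:
            continue
        scores = [ord(c) - 33 for c in qual]
        if sum(scores) / len(scores) < 32:
            continue
        hits = []
        for query, strand in ((proto, "+"), (rc, "-")):
            for pos in range(len(seq) - len(query) + 1):
                if seq[pos : pos + len(query)] == query:
                    hits.append((pos, strand))
        if len(hits) != 1:
            positions = sorted(p for p, _ in hits)
            if len(hits) == 0 or any(
                b - a >= len(proto) for a, b in zip(positions, positions[1:])
            ):
                continue
            hits = [min(hits, key=lambda h: (h[0], h[1] != "+"))]
        pos, strand = hits[0]
        if strand == "+":
            if pos < 3 or pos + len(proto) > len(seq):
                continue
            pam = seq[pos - 3 : pos]
        else:
            if pos + len(proto) + 3 > len(seq):
                continue
            pam = revcomp(seq[pos + len(proto) : pos + len(proto) + 3])
        if pam in counts:
            counts[pam] += 1
    return pd.Series(counts)


def test_counting_equals_naive_scanner_on_small_fixture(scenario, tmp_path):
    src = scenario["manifest"].iloc[2]["path"]
    fixture = tmp_path / "first1000.fastq"
    with open(src) as fh:
        fixture.write_text("".join(line for line, _ in zip(fh, range(4000))))
    small = naive_scan_oracle(fixture, PROTO)
    vec, _ = count_sample(fixture, PROTO)
    pd.testing.assert_series_equal(vec, small, check_names=False)
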