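"""Amplicon read counting: from FASTQ to a per-sample 64-way PAM count table.

The amplicon is a short fixed construct (5' flank + PAM + protospacer +
3' flank), so alignment reduces to locating the known protospacer on either
strand of each read and reading off the three bases immediately 5' of it on
the protospacer-bearing strand.  Read-level filters mirror a standard
quality-trimming workflow: 3' bases below the quality threshold are trimmed,
reads whose mean quality stays below the threshold or that end up shorter
than the length cutoff are discarded, and only reads that fully cover the
PAM and protospacer (no end gaps) are counted.

Every read falls in exactly one QC bin::

    reads_in = retained + quality_filtered + length_filtered
               + unmatched + ambiguous
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .pams import ALL_PAMS, revcomp

QC_COLUMNS = (
    "reads_in",
    "quality_filtered",
    "length_filtered",
    "unmatched",
    "ambiguous",
    "retained",
)


class FastqParseError(ValueError):
    """Malformed FASTQ record, naming the file and offending record."""


class ManifestError(ValueError):
    """A sample manifest row points to a missing or invalid file."""


@dataclass(frozen=True)
class ProtospacerMatch:
    """Location of the protospacer on a read.

    ``protospacer_start`` is a 0-based offset in the read's forward
    orientation; ``strand`` is '+' when the read carries the protospacer
    directly and '-' when it carries its reverse complement.
    ``full_coverage`` is true when the three PAM bases and the whole
    protospacer lie within the read.
    """

    read_id: str
    strand: str
    protospacer_start: int
    pam: str | None
    full_coverage: bool
    mismatches: int = 0


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _qual_stats(qual: str) -> tuple[float, int, int]:
    """(mean phred, min phred, length) for a Phred+33 quality string."""
    scores = [ord(c) - 33 for c in qual]
    return (sum(scores) / len(scores), min(scores), len(scores))


@lru_cache(maxsize=4096)
def _trim_point(qual: str, threshold: int) -> int:
    """Length after trimming trailing bases with quality < threshold."""
    end = len(qual)
    cutoff = threshold + 33
    while end > 0 and ord(qual[end - 1]) < cutoff:
        end -= 1
    return end


def filter_read(
    sequence: str,
    qualities: str,
    min_mean_quality: int = 32,
    min_length: int = 30,
    quality_mode: str = "mean",
    trim: bool = True,
) -> tuple[str, str] | str:
    """Apply quality trimming and quality/length filters to one read.

    Returns the (possibly trimmed) ``(sequence, qualities)`` pair, or the
    rejection reason (``"quality"`` / ``"length"``).

    ``quality_mode`` selects how the threshold is applied after trimming:
    ``"mean"`` (default) requires mean read quality >= threshold,
    ``"per_base"`` requires every base >= threshold.
    """
    if len(sequence) != len(qualities):
        raise FastqParseError("sequence/quality length mismatch")
    if trim:
        end = _trim_point(qualities, min_mean_quality)
        sequence, qualities = sequence[:end], qualities[:end]
    if not qualities:
        return "length" if min_length > 0 else "quality"
    mean_q, min_q, length = _qual_stats(qualities)
    if length < min_length:
        return "length"
    check = mean_q if quality_mode == "mean" else min_q
    if check < min_mean_quality:
        return "quality"
    return sequence, qualities


def filter_reads(
    reads,
    min_mean_quality: int = 32,
    min_length: int = 30,
    quality_mode: str = "mean",
):
    """Filter an iterable of ``(id, sequence, qualities)`` triples; yields the
    retained (trimmed) triples."""
    for rid, seq, qual in reads:
        kept = filter_read(seq, qual, min_mean_quality, min_length, quality_mode)
        if isinstance(kept, tuple):
            yield rid, kept[0], kept[1]


# ---------------------------------------------------------------------------
# protospacer search
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def _hamming_hits(seq: str, proto: str, budget: int) -> list[tuple[int, int]]:
    """All (mismatches, position) with mismatches <= budget."""
    lp, hits = len(proto), []
    for pos in range(len(seq) - lp + 1):
        mm = 0
        window = seq[pos : pos + lp]
        for a, b in zip(window, proto):
            if a != b:
                mm += 1
                if mm > budget:
                    break
        else:
            hits.append((mm, pos))
    return hits


def _best_hit(
    sequence: str, proto: str, proto_rc: str, max_mismatches: int
) -> tuple[int, int, str] | None | str:
    """Best protospacer hit on a read: ``(mismatches, position, strand)``,
    ``None`` (no hit) or ``"ambiguous"`` (disjoint equal-score hits).

    Ties are broken by fewest mismatches, then leftmost position, then '+'
    strand; equally scored hits at disjoint (non-overlapping) positions
    cannot be attributed and make the read ambiguous.
    """
    lp = len(proto)
    if max_mismatches == 0:
        cands = [(0, p, "+") for p in _find_all(sequence, proto)]
        cands += [(0, p, "-") for p in _find_all(sequence, proto_rc)]
    else:
        cands = [
            (mm, p, "+") for mm, p in _hamming_hits(sequence, proto, max_mismatches)
        ]
        cands += [
            (mm, p, "-") for mm, p in _hamming_hits(sequence, proto_rc, max_mismatches)
        ]
    if not cands:
        return None
    best = min(mm for mm, _, _ in cands)
    top = [(p, s) for mm, p, s in cands if mm == best]
    if len(top) > 1:
        spans = sorted(p for p, _ in top)
        for a, b in zip(spans, spans[1:]):
            if b - a >= lp:
                return "ambiguous"
    pos, strand = min(top, key=lambda t: (t[0], t[1] != "+"))
    return (best, pos, strand)


def locate_protospacer(
    read_id: str,
    sequence: str,
    protospacer: str,
    max_mismatches: int = 0,
) -> ProtospacerMatch | None | str:
    """Locate the protospacer on a read (both orientations).

    Returns a :class:`ProtospacerMatch`, ``None`` when there is no hit within
    the mismatch budget, or the string ``"ambiguous"`` when several disjoint
    positions tie at the best score.
    """
    if not 20 <= len(protospacer) <= 40:
        raise ValueError("protospacer must be 20-40 nt")
    lp = len(protospacer)
    proto_rc = revcomp(protospacer)
    hit = _best_hit(sequence, protospacer, proto_rc, max_mismatches)
    if hit is None or hit == "ambiguous":
        return hit
    best, pos, strand = hit
    if strand == "+":
        covered = pos >= 3 and pos + lp <= len(sequence)
        pam = sequence[pos - 3 : pos] if covered else None
    else:
        covered = pos >= 0 and pos + lp + 3 <= len(sequence)
        pam = revcomp(sequence[pos + lp : pos + lp + 3]) if covered else None
    return ProtospacerMatch(
        read_id=read_id,
        strand=strand,
        protospacer_start=pos,
        pam=pam.upper() if pam else None,
        full_coverage=covered,
        mismatches=best,
    )


def extract_pam(match: ProtospacerMatch) -> str | None:
    """The trinucleotide immediately 5' of the protospacer on the
    protospacer-bearing strand; ``None`` when it contains a non-ACGT base."""
    if not match.full_coverage or match.pam is None:
        raise ValueError("extract_pam requires a fully covering match")
    return match.pam if match.pam in _PAM_SET else None


_PAM_SET = frozenset(ALL_PAMS)


# ---------------------------------------------------------------------------
# per-sample counting
# ---------------------------------------------------------------------------


def iter_fastq(path: str | Path):
    """Yield ``(id, sequence, qualities)`` from a Phred+33 FASTQ file."""
    try:
        with open(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield title.split(None, 1)[0], seq.upper(), qual
    except ValueError as exc:  # malformed record
        raise FastqParseError(f"{path}: {exc}") from exc


def count_sample(
    path: str | Path,
    protospacer: str,
    min_mean_quality: int = 32,
    min_length: int = 30,
    max_mismatches: int = 0,
    quality_mode: str = "mean",
) -> tuple[pd.Series, dict[str, int]]:
    """Count PAM occurrences in one FASTQ file.

    Returns a 64-entry count vector (zero-filled) and the QC tally.
    """
    counts = dict.fromkeys(ALL_PAMS, 0)
    qc = dict.fromkeys(QC_COLUMNS, 0)
    proto = protospacer.upper()
    proto_rc = revcomp(proto)
    lp = len(proto)
    for rid, seq, qual in iter_fastq(path):
        qc["reads_in"] += 1
        kept = filter_read(seq, qual, min_mean_quality, min_length, quality_mode)
        if not isinstance(kept, tuple):
            qc[f"{kept}_filtered"] += 1
            continue
        seq = kept[0]
        hit = _best_hit(seq, proto, proto_rc, max_mismatches)
        if hit is None:
            qc["unmatched"] += 1
            continue
        if hit == "ambiguous":
            qc["ambiguous"] += 1
            continue
        _, pos, strand = hit
        if strand == "+":
            if pos >= 3 and pos + lp <= len(seq):
                pam = seq[pos - 3 : pos]
            else:
                qc["unmatched"] += 1
                continue
        else:
            if pos + lp + 3 <= len(seq):
                pam = revcomp(seq[pos + lp : pos + lp + 3])
            else:
                qc["unmatched"] += 1
                continue
        if pam in counts:
            counts[pam] += 1
            qc["retained"] += 1
        else:  # degenerate base in the PAM
            qc["ambiguous"] += 1
    return pd.Series(counts, name=str(path)), qc


def count_pams(
    manifest: pd.DataFrame,
    protospacer: str,
    min_mean_quality: int = 32,
    min_length: int = 30,
    max_mismatches: int = 0,
    quality_mode: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count PAMs for every sample of a manifest.

    ``manifest`` needs columns ``condition, replicate, time, path``.  Returns
    ``(counts, qc)`` indexed by (condition, replicate, time); the count table
    always carries all 64 PAM columns.
    """
    required = {"condition", "replicate", "time", "path"}
    if not required.issubset(manifest.columns):
        raise ManifestError(f"manifest must have columns {sorted(required)}")
    for _, row in manifest.iterrows():
        if not Path(row["path"]).exists():
            raise ManifestError(
                f"missing FASTQ for sample ({row['condition']}, "
                f"rep {row['replicate']}, t={row['time']}): {row['path']}"
            )
    count_rows, qc_rows, index = [], [], []
    for _, row in manifest.iterrows():
        vec, qc = count_sample(
            row["path"],
            protospacer,
            min_mean_quality=min_mean_quality,
            min_length=min_length,
            max_mismatches=max_mismatches,
            quality_mode=quality_mode,
        )
        count_rows.append(vec)
        qc_rows.append(qc)
        index.append((row["condition"], int(row["replicate"]), float(row["time"])))
    midx = pd.MultiIndex.from_tuples(index, names=["condition", "replicate", "time"])
    counts = pd.DataFrame(count_rows)
    counts.index = midx
    qc = pd.DataFrame(qc_rows, index=midx)
    return counts.sort_index(), qc.sort_index()
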