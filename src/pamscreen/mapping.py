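"""Mapping acquired spacers onto the circular source plasmid.

Spacers excised during primed adaptation derive from the plasmid itself, so
exact matching on both strands with circular wrap-around suffices (a
1-mismatch rescue mode exists but is off by default).  A spacer's *position*
is always the 0-based start of its protospacer in plus-strand coordinates,
whatever strand it maps to, so profiles from both strands share one
coordinate axis.  Per-position start counts give the acquisition profile;
the trinucleotide immediately 5' of each uniquely mapped protospacer (on
the mapped strand) gives PAM usage, the quantity compared between naive and
primed adaptation datasets.

Bookkeeping invariant: ``mapped + multi_hit + unmapped + excluded`` equals
the number of input spacers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pams import ALL_PAMS, revcomp

_ACGT = frozenset("ACGT")


class MappingError(ValueError):
    pass


def _circular_hits(doubled: str, n: int, query: str) -> list[int]:
    """Start positions (mod n) of exact occurrences on a circular sequence."""
    hits, start = [], doubled.find(query)
    while start != -1 and start < n:
        hits.append(start)
        start = doubled.find(query, start + 1)
    return hits


def _hamming1_hits(doubled: str, n: int, query: str) -> list[int]:
    lq = len(query)
    out = []
    for pos in range(n):
        window = doubled[pos : pos + lq]
        mm = sum(a != b for a, b in zip(window, query))
        if mm <= 1:
            out.append(pos)
    return out


def map_spacer(
    spacer: str, plasmid: str, rescue_mismatch: bool = False
) -> list[tuple[int, str]]:
    """All (plus-strand start position, strand) hits of a spacer.

    The plasmid is treated as circular.  Spacers with non-ACGT bases raise
    :class:`MappingError` (tallied as excluded by :func:`build_profile`).
    """
    spacer = spacer.upper()
    if not set(spacer) <= _ACGT:
        raise MappingError(f"spacer contains non-ACGT base: {spacer}")
    if not 25 <= len(spacer) <= 40:
        raise MappingError(f"implausible spacer length {len(spacer)}")
    if len(spacer) > len(plasmid):
        raise MappingError("spacer longer than plasmid")
    plasmid = plasmid.upper()
    doubled = plasmid * 2
    n = len(plasmid)
    finder = _hamming1_hits if rescue_mismatch else _circular_hits
    hits = [(p, "+") for p in finder(doubled, n, spacer)]
    hits += [(p, "-") for p in finder(doubled, n, revcomp(spacer))]
    return sorted(hits)


@dataclass
class AcquisitionProfile:
    """Per-position, per-strand spacer start counts on a plasmid."""

    plasmid_name: str
    length: int
    counts: np.ndarray  # shape (2, length); rows '+', '-'
    n_input: int = 0
    n_mapped: int = 0
    n_multi_hit: int = 0
    n_unmapped: int = 0
    n_excluded: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise MappingError("empty profile has no frequencies")
        return self.counts / total

    def as_frame(self) -> pd.DataFrame:
        """Tidy (position, strand, count, frequency) table of nonzero bins."""
        strand_i, pos = np.nonzero(self.counts)
        freq = self.frequencies
        return pd.DataFrame(
            {
                "position": pos,
                "strand": np.where(strand_i == 0, "+", "-"),
                "count": self.counts[strand_i, pos],
                "frequency": freq[strand_i, pos],
            }
        )


def build_profile(
    spacers,
    plasmid: str,
    plasmid_name: str = "plasmid",
    rescue_mismatch: bool = False,
) -> AcquisitionProfile:
    """Map a spacer multiset and accumulate the acquisition profile.

    Multi-hit spacers are flagged and excluded from the profile; spacers
    with degenerate bases are excluded and tallied separately.
    """
    n = len(plasmid)
    counts = np.zeros((2, n), dtype=np.int64)
    prof = AcquisitionProfile(plasmid_name=plasmid_name, length=n, counts=counts)
    # memoize: draws from a profile repeat the same spacer many times
    cache: dict[str, list[tuple[int, str]] | None] = {}
    for spacer in spacers:
        prof.n_input += 1
        hits = cache.get(spacer, False)
        if hits is False:
            try:
                hits = map_spacer(spacer, plasmid, rescue_mismatch=rescue_mismatch)
            except MappingError:
                hits = None
            cache[spacer] = hits
        if hits is None:
            prof.n_excluded += 1
        elif len(hits) == 0:
            prof.n_unmapped += 1
        elif len(hits) > 1:
            prof.n_multi_hit += 1
        else:
            pos, strand = hits[0]
            counts["+-".index(strand), pos] += 1
            prof.n_mapped += 1
    return prof


def profile_correlation(a: AcquisitionProfile, b: AcquisitionProfile) -> float:
    """Pearson correlation of two acquisition profiles.

    Computed over per-(position, strand) frequencies, restricted to bins
    nonzero in at least one profile; profiles must share the coordinate
    system.
    """
    if a.length != b.length:
        raise MappingError("profiles are on different coordinate systems")
    fa, fb = a.frequencies.ravel(), b.frequencies.ravel()
    mask = (fa > 0) | (fb > 0)
    if mask.sum() < 2:
        raise MappingError("too few occupied positions for a correlation")
    r, _ = stats.pearsonr(fa[mask], fb[mask])
    return float(r)


def spacer_pam_usage(
    spacers,
    plasmid: str,
    groups: dict[str, str] | pd.Series | None = None,
    rescue_mismatch: bool = False,
) -> pd.DataFrame:
    """Trinucleotide (PAM) usage among uniquely mapped spacers.

    For each spacer the 3 nt immediately 5' of its protospacer on the mapped
    strand are extracted (circularly); frequencies are tabulated over all 64
    trinucleotides.  Returns a frame indexed by PAM with columns ``count``
    and ``frequency`` (and ``group`` when labels are given).
    """
    n = len(plasmid)
    doubled = (plasmid * 2).upper()
    usage = dict.fromkeys(ALL_PAMS, 0)
    cache: dict[str, str | None] = {}
    dropped = 0
    for spacer in spacers:
        pam = cache.get(spacer, False)
        if pam is False:
            try:
                hits = map_spacer(spacer, plasmid, rescue_mismatch=rescue_mismatch)
            except MappingError:
                hits = []
            if len(hits) != 1:
                pam = None
            else:
                pos, strand = hits[0]
                if strand == "+":
                    pam = doubled[pos - 3 + n : pos + n]  # 5' side, wraps
                else:
                    pam = revcomp(doubled[pos + len(spacer) : pos + len(spacer) + 3])
                if pam not in usage:
                    pam = None
            cache[spacer] = pam
        if pam is None:
            dropped += 1
        else:
            usage[pam] += 1
    total = sum(usage.values())
    table = pd.DataFrame(
        {"count": pd.Series(usage)},
    ).rename_axis("pam")
    table["frequency"] = table["count"] / total if total else 0.0
    table.attrs["n_dropped"] = dropped
    if groups is not None:
        table["group"] = pd.Series(dict(groups))
    return table


def mean_usage(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average PAM-usage frequencies over experimental replicates."""
    if not tables:
        raise MappingError("no usage tables to average")
    freq = pd.concat([t["frequency"] for t in tables], axis=1).mean(axis=1)
    count = pd.concat([t["count"] for t in tables], axis=1).mean(axis=1)
    return pd.DataFrame({"count": count, "frequency": freq}).rename_axis("pam")


def usage_comparison(
    naive: pd.DataFrame,
    primed: pd.DataFrame,
    groups: dict[str, str] | pd.Series | None = None,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """Join naive vs primed PAM usage for a log-log comparison.

    ``floor`` replaces zero frequencies before taking log10 so unused
    trinucleotides remain plottable.
    """
    out = pd.DataFrame(
        {
            "naive_frequency": naive["frequency"],
            "primed_frequency": primed["frequency"],
        }
    )
    out["log10_naive"] = np.log10(out["naive_frequency"].clip(lower=floor))
    out["log10_primed"] = np.log10(out["primed_frequency"].clip(lower=floor))
    if groups is not None:
        out["group"] = pd.Series(dict(groups))
    return out.rename_axis("pam")
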