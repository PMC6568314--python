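"""The 64 trinucleotide PAM variants and their kinetic reference grouping.

The *Escherichia coli* Type I-E Cascade effector requires a trinucleotide
protospacer adjacent motif (PAM) immediately 5' of the protospacer.  Pooled
plasmid-loss screens separate the 64 possible trinucleotides into three
kinetic classes:

``interfering``
    rapid plasmid loss after *cas* induction (includes the AAG/ATG consensus),
``stable``
    no detectable loss (includes CCG, the trinucleotide found at the
    corresponding position of the CRISPR repeat),
``intermediate``
    attenuated loss extending over many hours.

The reference grouping shipped here has the published class sizes
(17 interfering / 36 stable / 11 intermediate) and honors every class
membership stated in the text (consensus and repeat anchors, the PAMs shown
to acquire spacers, the AGN series, TAT, GAT...).  Members not individually
named in the text are a synthetic completion: the full 64-way listing exists
only as a figure panel, so the remainder was filled with plausible (A-rich
toward interfering) assignments.  Simulations plant this grouping as ground
truth, and classification is validated by recovering it, so none of the
package's guarantees depend on the unnamed assignments being the published
ones.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"

#: All 64 trinucleotides in lexicographic order.
ALL_PAMS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

#: Marker PAMs used to anchor cluster labels.
INTERFERING_ANCHORS = ("AAG", "ATG")
STABLE_ANCHOR = "CCG"
#: Reference PAM for hotspot score normalization.
REFERENCE_PAM = "CAA"
#: Bridge PAM present in both the general and the changed-context (AGN*) sets.
BRIDGE_PAM = "AGC"

GROUP_NAMES = ("stable", "interfering", "intermediate")

_INTERFERING = (
    "AAG", "ATG", "GAG", "TAG", "CAG", "AGG", "ATC",
    "AAA", "AAC", "AAT", "ATA", "ATT", "GAA", "TAC", "ACG", "GTA", "CAT",
)
_INTERMEDIATE = (
    "AGA", "AGC", "GAC", "CAA", "TAT", "TTG", "GTG", "TAA", "CTG", "ACA", "TGA",
)


def reference_groups() -> dict[str, str]:
    """Return the reference PAM -> kinetic group mapping (all 64 PAMs).

    Sizes are 17 interfering, 36 stable, 11 intermediate.
    """
    groups = {pam: "stable" for pam in ALL_PAMS}
    for pam in _INTERFERING:
        groups[pam] = "interfering"
    for pam in _INTERMEDIATE:
        groups[pam] = "intermediate"
    return groups


def group_sizes(groups: dict[str, str]) -> dict[str, int]:
    """Count members per kinetic group."""
    sizes = {name: 0 for name in GROUP_NAMES}
    for g in groups.values():
        sizes[g] += 1
    return sizes


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


# sanity at import time: the grouping is a partition with the published sizes
_sizes = group_sizes(reference_groups())
assert _sizes == {"stable": 36, "interfering": 17, "intermediate": 11}, _sizes
del _sizes
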