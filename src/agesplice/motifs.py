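"""RNA-binding-protein motif records and degenerate (IUPAC) motif matching.

Motifs are short degenerate nucleotide consensuses (DNA alphabet) each tied
to the splicing-factor gene whose product recognizes them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: IUPAC nucleotide codes -> the set of concrete bases each code stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifRecord:
    """A degenerate RNA motif and the splicing factor that binds it."""

    motif_id: str
    sf_gene: str
    consensus: str

    def __post_init__(self) -> None:
        validate_consensus(self.consensus)


def validate_consensus(consensus: str) -> None:
    if not consensus:
        raise ValueError("motif consensus must be non-empty")
    bad = sorted({c for c in consensus if c not in IUPAC_CODES})
    if bad:
        raise ValueError(
            f"invalid IUPAC symbol(s) {bad!r} in consensus {consensus!r} "
            "(uppercase IUPAC nucleotide codes only)"
        )


def iupac_regex(consensus: str) -> re.Pattern[str]:
    """Compile a consensus into a regex counting overlapping matches.

    An ``N`` in the *subject* sequence never matches: the character classes
    below contain concrete bases only.
    """
    validate_consensus(consensus)
    parts = []
    for c in consensus:
        bases = IUPAC_CODES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_occurrences(sequence: str, consensus: str) -> int:
    """Number of (possibly overlapping) positions where the consensus matches."""
    return sum(1 for _ in iupac_regex(consensus).finditer(sequence))
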