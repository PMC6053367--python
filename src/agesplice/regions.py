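"""Functional sequence regions flanking a cassette exon.

Seven windows around a skipped (cassette) exon are scanned for splicing-factor
motifs: the 3' end of the upstream exon, both ends of the upstream intron, the
cassette exon itself, both ends of the downstream intron, and the 5' end of
the downstream exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical order of the seven regions, 5' to 3' on the sense strand.
REGION_NAMES: tuple[str, ...] = (
    "upstream_exon_3p",
    "upstream_intron_5p",
    "upstream_intron_3p",
    "cassette_exon",
    "downstream_intron_5p",
    "downstream_intron_3p",
    "downstream_exon_5p",
)

#: Window lengths in nucleotides. Exact extents are a tunable convention:
#: exonic flanks 100 nt, intronic windows 200 nt, clipped to feature length.
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "upstream_exon_3p": 100,
    "upstream_intron_5p": 200,
    "upstream_intron_3p": 200,
    "cassette_exon": 100,
    "downstream_intron_5p": 200,
    "downstream_intron_3p": 200,
    "downstream_exon_5p": 100,
}

_VALID_SEQ = set("ACGTN")


@dataclass
class EventRegions:
    """The seven region sequences of one exon-skipping event."""

    event_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REGION_NAMES if r not in self.sequences]
        extra = [r for r in self.sequences if r not in REGION_NAMES]
        if missing or extra:
            raise ValueError(
                f"event {self.event_id}: regions must be exactly {REGION_NAMES}; "
                f"missing={missing}, unexpected={extra}"
            )
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_SEQ
            if bad:
                raise ValueError(
                    f"event {self.event_id}, region {name}: "
                    f"non-ACGTN characters {sorted(bad)!r}"
                )

    def __getitem__(self, region: str) -> str:
        return self.sequences[region]
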