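"""Core sequence containers.

A :class:`SequenceRecord` is one curated protein sequence; a
:class:`SequenceSet` is an ordered collection of them.  Order is significant
throughout the package: downstream alignments keep the order in which the
sequences were supplied, so every operation here preserves it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes tolerated in sequences (Asx, Glx, unknown,
#: selenocysteine, pyrrolysine).  They carry no physicochemical class, no
#: hydrophobicity value and no charge.
AMBIGUITY_AA = frozenset("BZXUO")

#: Full residue alphabet accepted in a SequenceRecord.
SEQUENCE_ALPHABET = STANDARD_AA | AMBIGUITY_AA

#: Gap character used in alignments (never allowed in unaligned records).
GAP = "-"


@dataclass
class SequenceRecord:
    """One protein sequence with its curation metadata.

    Parameters
    ----------
    accession
        Stable identifier (unique within a :class:`SequenceSet`).
    sequence
        Upper-case amino-acid string; no whitespace, no gaps.
    description
        Free-text definition line.
    organism
        Binomial or strain string from the source annotation.
    source_flags
        Curation tags, a subset of ``{"synthetic", "structure_derived",
        "partial", "duplicate", "nonstandard_residue"}``.
    """

    accession: str
    sequence: str
    description: str = ""
    organism: str = ""
    source_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: empty sequence")
        if any(c.isspace() or c == GAP for c in self.sequence):
            raise ValueError(
                f"record {self.accession!r}: sequence contains whitespace or gaps"
            )
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= SEQUENCE_ALPHABET:
            # Surface, do not reject: curation is the user's decision.
            self.source_flags.add("nonstandard_residue")

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceSet:
    """Ordered set of :class:`SequenceRecord` with unique accessions."""

    def __init__(self, records: list[SequenceRecord], provenance: str = ""):
        seen: set[str] = set()
        for rec in records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        self.records = list(records)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def get(self, accession: str) -> SequenceRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)
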