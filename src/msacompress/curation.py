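"""Sequence-set curation: filtering, deduplication, selection and trimming.

Automates the conservative part of assembling a coherent orthologue group
from homology-search output: dropping synthetic constructs, fragments and
exact duplicates, selecting sequences by accession list (``.cod`` file), and
trimming every sequence to a residue window before alignment.

Coordinates are 1-based inclusive throughout, matching the residue numbering
used in the structural literature (e.g. "Cys123").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .records import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

DEFAULT_DROP_KEYWORDS = ("synthetic", "artificial", "partial", "fragment", "chain ")


@dataclass
class CurationConfig:
    """Filtering rules for :func:`curate`.

    ``drop_keywords`` are lower-case substrings matched case-insensitively
    against the record description; the defaults cover the usual categories
    of non-natural entries in homology-search output (engineered variants,
    fragments, chains lifted from deposited structures).
    """

    min_length: int = 1
    max_length: int = 10_000
    drop_keywords: tuple[str, ...] = DEFAULT_DROP_KEYWORDS
    dedupe: bool = True
    trim_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        self.drop_keywords = tuple(k.lower() for k in self.drop_keywords)


@dataclass
class CurationReport:
    """Removal counts per reason, plus the accessions removed."""

    input_count: int = 0
    keyword: int = 0
    length: int = 0
    duplicates: int = 0
    removed_accessions: list[str] = field(default_factory=list)

    @property
    def retained(self) -> int:
        return self.input_count - self.keyword - self.length - self.duplicates

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            fh.write(f"input\t{self.input_count}\n")
            fh.write(f"keyword\t{self.keyword}\n")
            fh.write(f"length\t{self.length}\n")
            fh.write(f"duplicate\t{self.duplicates}\n")
            fh.write(f"retained\t{self.retained}\n")


def curate(seqset: SequenceSet, cfg: CurationConfig) -> tuple[SequenceSet, CurationReport]:
    """Filter a sequence set; returns the retained set (input order) and a report.

    Removal reasons are checked in order keyword → length → duplicate, so a
    record is counted once.  Duplicate means identical full sequence string;
    the first occurrence is kept.
    """
    if len(seqset) == 0:
        raise ValueError("cannot curate an empty set")
    report = CurationReport(input_count=len(seqset))
    kept: list[SequenceRecord] = []
    seen_sequences: set[str] = set()
    for rec in seqset:
        desc = rec.description.lower()
        if any(kw in desc for kw in cfg.drop_keywords):
            report.keyword += 1
            report.removed_accessions.append(rec.accession)
            continue
        if not (cfg.min_length <= len(rec) <= cfg.max_length):
            report.length += 1
            report.removed_accessions.append(rec.accession)
            continue
        if cfg.dedupe:
            if rec.sequence in seen_sequences:
                report.duplicates += 1
                report.removed_accessions.append(rec.accession)
                continue
            seen_sequences.add(rec.sequence)
        kept.append(rec)
    if not kept:
        logger.warning("curation removed every record")
    out = SequenceSet(kept, provenance=seqset.provenance + " | curated")
    if cfg.trim_window is not None:
        out = trim_to_window(out, cfg.trim_window)
    return out, report


def select_by_codes(seqset: SequenceSet, codes: list[str]) -> SequenceSet:
    """Select records by accession, in the order of ``codes``.

    Unknown accessions are reported via a logged warning and the returned
    set's ``missing`` attribute; no code matching at all is a hard error.
    """
    if not codes:
        raise ValueError("codes list is empty")
    by_acc = {rec.accession: rec for rec in seqset}
    picked: list[SequenceRecord] = []
    missing: list[str] = []
    for code in codes:
        rec = by_acc.get(code)
        if rec is None:
            missing.append(code)
        else:
            picked.append(rec)
    if not picked:
        raise ValueError("no accession in codes matches the set")
    if missing:
        logger.warning("%d code(s) not found: %s", len(missing), ", ".join(missing))
    out = SequenceSet(picked, provenance=seqset.provenance + " | selected")
    out.missing = missing  # type: ignore[attr-defined]
    return out


def read_codes(path: str | Path) -> list[str]:
    """Read a ``.cod`` file: one accession per line, blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def trim_to_window(seqset: SequenceSet, window: tuple[int, int]) -> SequenceSet:
    """Trim every sequence to a 1-based inclusive residue window.

    Sequences shorter than ``start`` are dropped (reported via the returned
    set's ``dropped`` attribute and a logged warning).
    """
    start, end = window
    if not (1 <= start <= end):
        raise ValueError("need 1 <= start <= end")
    kept: list[SequenceRecord] = []
    dropped: list[str] = []
    for rec in seqset:
        if len(rec) < start:
            dropped.append(rec.accession)
            continue
        kept.append(
            SequenceRecord(
                accession=rec.accession,
                sequence=rec.sequence[start - 1 : end],
                description=rec.description,
                organism=rec.organism,
                source_flags=set(rec.source_flags),
            )
        )
    if dropped:
        logger.warning(
            "%d sequence(s) shorter than window start %d dropped: %s",
            len(dropped), start, ", ".join(dropped),
        )
    out = SequenceSet(kept, provenance=seqset.provenance + f" | trimmed {start}:{end}")
    out.dropped = dropped  # type: ignore[attr-defined]
    return out
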