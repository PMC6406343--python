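"""GenBank flat-file ingest.

Converts the raw download of a protein homology search (concatenated GenBank
entries, ``LOCUS`` ... ``//``) into a clean :class:`~msacompress.records.SequenceSet`
and writes the three companion files used by the rest of the pipeline:

``.rem``
    one tab-separated summary line per record (accession, length, organism,
    description),
``.fas``
    the sequences in FASTA, accession as the first header token,
``.cod``
    one accession per line, in set order — the handle later selection steps
    use to pick sequences.

Input order is preserved everywhere: the alignments built downstream keep the
order in which the search returned the sequences.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .records import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

FASTA_WIDTH = 60  # output line width, common convention


def _split_entries(stream: IO[str]) -> list[str]:
    """Split concatenated flat-file text into LOCUS...// entry strings."""
    entries: list[str] = []
    current: list[str] = []
    for line in stream:
        current.append(line)
        if line.rstrip() == "//":
            entries.append("".join(current))
            current = []
    if any(l.strip() for l in current):  # trailing entry without terminator
        entries.append("".join(current) + "//\n")
    return entries


def parse_genbank_flat(stream: IO[str] | str | Path) -> SequenceSet:
    """Parse concatenated GenBank entries into a :class:`SequenceSet`.

    Entries are parsed one at a time so that a malformed record (no ORIGIN
    sequence body, no accession, unparseable header) is skipped with a
    logged warning rather than aborting the whole file; the number skipped
    is available on the returned set as ``skipped``.  Raises ``ValueError``
    if no record parses.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_genbank_flat(fh)

    records: list[SequenceRecord] = []
    skipped = 0
    for entry in _split_entries(stream):
        try:
            gb = SeqIO.read(io.StringIO(entry), "genbank")
            seq = str(gb.seq)
        except (ValueError, UndefinedSequenceError) as exc:
            skipped += 1
            logger.warning("skipping malformed GenBank entry: %s", exc)
            continue
        accession = gb.id if gb.id and gb.id != "<unknown id>" else ""
        # strip anything that is not a letter (digits/spaces are already
        # removed by the parser, but be defensive about odd bodies)
        seq = "".join(c for c in seq if c.isalpha()).upper()
        if not accession or not seq:
            skipped += 1
            logger.warning(
                "skipping malformed GenBank entry (accession=%r, %d residues)",
                accession or None,
                len(seq),
            )
            continue
        records.append(
            SequenceRecord(
                accession=accession,
                sequence=seq,
                description=gb.description or "",
                organism=str(gb.annotations.get("organism", "")),
            )
        )
    if not records:
        raise ValueError("no parseable GenBank record in input")
    out = SequenceSet(records, provenance="genbank flat file")
    out.skipped = skipped  # type: ignore[attr-defined]
    return out


def write_fasta(seqset: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, header = accession then description."""
    with open(path, "w") as fh:
        for rec in seqset:
            header = rec.accession
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), FASTA_WIDTH):
                fh.write(rec.sequence[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file back into a :class:`SequenceSet`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                accession=rec.id,
                sequence=str(rec.seq).replace("-", "").upper(),
                description=rec.description[len(rec.id) :].strip(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA record in {path}")
    return SequenceSet(records, provenance=str(path))


def write_companions(seqset: SequenceSet, basename: str | Path) -> dict[str, Path]:
    """Write the ``.rem`` / ``.fas`` / ``.cod`` companion files.

    Returns a mapping of extension to the path written.
    """
    if len(seqset) == 0:
        raise ValueError("cannot write companions for an empty set")
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {ext: base.with_suffix("." + ext) for ext in ("rem", "fas", "cod")}

    with open(paths["rem"], "w") as fh:
        for rec in seqset:
            fh.write(
                f"{rec.accession}\t{len(rec)}\t{rec.organism}\t{rec.description}\n"
            )
    write_fasta(seqset, paths["fas"])
    with open(paths["cod"], "w") as fh:
        for rec in seqset:
            fh.write(rec.accession + "\n")
    return paths
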