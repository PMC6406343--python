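"""Shared fixtures: all test inputs are built programmatically."""

from __future__ import annotations

import textwrap

import pytest

from msacompress import SequenceRecord, SequenceSet


def make_genbank_entry(
    accession: str,
    sequence: str | None,
    organism: str = "Escherichia coli",
    definition: str = "hypothetical protein",
) -> str:
    """Format one protein GenBank flat-file entry (LOCUS ... //)."""
    length = len(sequence) if sequence else 0
    lines = [
        f"LOCUS       {accession:<18}{length:>8} aa            linear   BCT 01-JAN-2019",
        f"DEFINITION  {definition}.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        "SOURCE      " + organism,
        "  ORGANISM  " + organism,
        "            Bacteria; Proteobacteria.",
    ]
    if sequence is not None:
        lines.append("ORIGIN      ")
        seq = sequence.lower()
        for i in range(0, len(seq), 60):
            chunk = seq[i : i + 60]
            spaced = " ".join(textwrap.wrap(chunk, 10))
            lines.append(f"{i + 1:>9} {spaced}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_record_flatfile() -> str:
    return make_genbank_entry("AAA00001", "MKV") + make_genbank_entry("AAA00002", "GGA")


@pytest.fixture
def small_set() -> SequenceSet:
    return SequenceSet(
        [
            SequenceRecord("P1", "MKVLWAAL", description="cyclophilin A",
                           organism="Homo sapiens"),
            SequenceRecord("P2", "MKVLWAAL", description="cyclophilin A-like",
                           organism="Mus musculus"),
            SequenceRecord("P3", "GGAGG", description="synthetic construct"),
            SequenceRecord("P4", "MKWDE", description="FKBP domain protein",
                           organism="Danio rerio"),
        ]
    )
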