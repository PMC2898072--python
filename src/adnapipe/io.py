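"""FASTA and TSV input/output helpers.

FASTA is read and written through Biopython's ``SeqIO`` with 60-column
wrapping; tabular files go through pandas.  All functions deal in plain
``(name, sequence)`` tuples so the rest of the package stays free of
Biopython types.
"""

from __future__ import annotations

import io as _stdlib_io
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(name, sequence), ...]`` (uppercased)."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def _records(entries: Iterable[tuple[str, str]]) -> list[SeqRecord]:
    return [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs as wrapped FASTA (60 columns)."""
    with open(path, "w") as handle:
        SeqIO.write(_records(entries), handle, "fasta")


def fasta_string(entries: Sequence[tuple[str, str]]) -> str:
    """Render entries as a FASTA-formatted string (for determinism checks)."""
    buf = _stdlib_io.StringIO()
    SeqIO.write(_records(entries), buf, "fasta")
    return buf.getvalue()
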