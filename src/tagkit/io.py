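"""FASTA and small-table I/O built on Biopython and pandas."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cloning_sim import NucleotideSequence


def read_fasta(path, topology: str = "linear") -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, str(rec.seq).upper(), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs or NucleotideSequence objects, wrapped
    at 60 columns, upper-case."""
    out = []
    for rec in records:
        if isinstance(rec, NucleotideSequence):
            out.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
        else:
            rid, seq = rec[0], rec[1]
            desc = rec[2] if len(rec) > 2 else ""
            out.append(SeqRecord(Seq(str(seq).upper()), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
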