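"""FASTA input/output.

Genomes and target sets are represented in memory as an ordered mapping
``{record_id: sequence}`` (uppercase DNA, possibly containing N).  Readers
accept plain or gzip-compressed multi-record FASTA.
"""

from __future__ import annotations

import gzip
import hashlib
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import ContractError

SequenceSet = Mapping[str, str]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into ``{id: sequence}``.

    Raises :class:`ContractError` on duplicate record identifiers or an
    empty file.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ContractError(f"duplicate FASTA record id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ContractError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: SequenceSet | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def as_sequence_set(genome: SequenceSet | Iterable[tuple[str, str]]) -> dict[str, str]:
    """Normalise a genome argument to an ordered dict, checking for duplicates."""
    if isinstance(genome, Mapping):
        return {rid: seq.upper() for rid, seq in genome.items()}
    out: dict[str, str] = {}
    for rid, seq in genome:
        if rid in out:
            raise ContractError(f"duplicate record id {rid!r}")
        out[rid] = seq.upper()
    return out


def genome_digest(genome: SequenceSet) -> str:
    """SHA-256 digest of a sequence set (ids and sequences, in order)."""
    h = hashlib.sha256()
    for rid, seq in genome.items():
        h.update(rid.encode())
        h.update(b"\0")
        h.update(seq.upper().encode())
        h.update(b"\n")
    return h.hexdigest()
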