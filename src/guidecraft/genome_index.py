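"""Genome-wide sgRNA uniqueness database.

Instead of shipping per-species references, a :class:`UniquenessIndex` is
built once from any genome sequence set: it counts, for every spacer
sequence, how many PAM-adjacent protospacer occurrences exist on either
strand of any record.  A guide whose spacer occurs exactly once is
classified unique; everything else is marked ``not_unique`` in reports.

Counting is done in guide orientation: a minus-strand protospacer
contributes to the key of its reverse-complemented (guide) spacer, so a
spacer and its reverse complement are distinct keys.

The on-disk format is a versioned, sorted, tab-separated text table with
a small header (format version, model name, spacer length, genome digest,
record count); an index is built once per genome and reused across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ContractError, IndexFormatError
from .io import SequenceSet, as_sequence_set, genome_digest
from .pam_models import PAMModel, enumerate_protospacers

FORMAT_VERSION = "guidecraft-index/1"


@dataclass
class UniquenessIndex:
    counts: dict[str, int]
    model_name: str
    spacer_length: int
    genome_digest: str
    n_records: int

    def occurrence_count(self, spacer: str) -> int:
        """Genome-wide PAM-adjacent occurrence count of ``spacer`` (0 if absent)."""
        spacer = spacer.upper()
        if len(spacer) != self.spacer_length:
            raise ContractError(
                f"spacer length {len(spacer)} != index spacer length {self.spacer_length}"
            )
        return self.counts.get(spacer, 0)

    def is_unique(self, spacer: str) -> bool:
        return self.occurrence_count(spacer) == 1

    @property
    def n_spacers(self) -> int:
        return len(self.counts)

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())


def build_index(genome: SequenceSet | Iterable[tuple[str, str]],
                model: PAMModel) -> UniquenessIndex:
    """Count every PAM-adjacent protospacer on both strands of every record."""
    records = as_sequence_set(genome)
    if not records:
        raise ContractError("cannot build an index from an empty genome")
    counts: dict[str, int] = {}
    for rid, seq in records.items():
        for cand in enumerate_protospacers(seq, model, both_strands=True, record_id=rid):
            counts[cand.spacer] = counts.get(cand.spacer, 0) + 1
    return UniquenessIndex(
        counts=counts,
        model_name=model.name,
        spacer_length=model.spacer_length,
        genome_digest=genome_digest(records),
        n_records=len(records),
    )


def save_index(index: UniquenessIndex, path: str | Path) -> None:
    """Write the index as a sorted, versioned TSV table."""
    with open(path, "w") as fh:
        fh.write(f"#format\t{FORMAT_VERSION}\n")
        fh.write(f"#model\t{index.model_name}\n")
        fh.write(f"#spacer_length\t{index.spacer_length}\n")
        fh.write(f"#genome_digest\t{index.genome_digest}\n")
        fh.write(f"#n_records\t{index.n_records}\n")
        fh.write(f"#n_spacers\t{len(index.counts)}\n")
        for spacer in sorted(index.counts):
            fh.write(f"{spacer}\t{index.counts[spacer]}\n")


def load_index(path: str | Path) -> UniquenessIndex:
    """Load an index written by :func:`save_index`, verifying format and size."""
    path = Path(path)
    header: dict[str, str] = {}
    counts: dict[str, int] = {}
    try:
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#format\t"):
                raise IndexFormatError(
                    f"{path}: not a guidecraft index (expected format tag {FORMAT_VERSION!r})"
                )
            version = first.split("\t", 1)[1]
            if version != FORMAT_VERSION:
                raise IndexFormatError(
                    f"{path}: format version {version!r}, expected {FORMAT_VERSION!r}"
                )
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, value = line[1:].split("\t", 1)
                    header[key] = value
                    continue
                spacer, count = line.split("\t")
                counts[spacer] = int(count)
    except (ValueError, IndexError) as exc:
        raise IndexFormatError(f"{path}: corrupt index file ({exc})") from exc
    for key in ("model", "spacer_length", "genome_digest", "n_records", "n_spacers"):
        if key not in header:
            raise IndexFormatError(f"{path}: missing header field {key!r}")
    if len(counts) != int(header["n_spacers"]):
        raise IndexFormatError(
            f"{path}: truncated index ({len(counts)} rows, header says {header['n_spacers']})"
        )
    return UniquenessIndex(
        counts=counts,
        model_name=header["model"],
        spacer_length=int(header["spacer_length"]),
        genome_digest=header["genome_digest"],
        n_records=int(header["n_records"]),
    )
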