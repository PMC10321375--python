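"""Small nucleotide-sequence helpers shared across modules.

All sequences handled by the package are plain Python ``str`` over the
DNA alphabet; coordinates are 0-based half-open on the forward strand
unless a function documents otherwise (reports convert to 1-based
inclusive at the boundary).
"""

from __future__ import annotations

from .errors import ContractError

#: IUPAC nucleotide codes -> the set of concrete bases each code matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DNA_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def validate_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Uppercase ``seq`` and check its alphabet; returns the uppercased string."""
    up = seq.upper()
    allowed = DNA_BASES | {"N"} if allow_n else DNA_BASES
    bad = set(up) - allowed
    if bad:
        raise ContractError(
            f"{what} contains non-DNA characters: {sorted(bad)!r}"
        )
    return up


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ContractError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
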