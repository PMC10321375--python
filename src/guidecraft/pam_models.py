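"""PAM recognition models and protospacer enumeration.

A :class:`PAMModel` names a Cas nuclease's PAM pattern (IUPAC string), the
side of the spacer it abuts (``three_prime`` for Cas9-family enzymes,
``five_prime`` for Cas12-family), the spacer length, and a nominal cut
offset.  The packaged registry ships twenty models covering the commonly
used Cas9 and Cas12 variants; it is a plain TSV users can replace.

:func:`enumerate_protospacers` scans a sequence on one or both strands and
returns every spacer of the model's length that sits immediately adjacent
to a PAM match.  Coordinates are 0-based half-open spans of the *spacer*
on the forward strand of the input; minus-strand candidates report the
spacer and PAM in guide orientation (reverse-complemented).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from ._seq import IUPAC_CODES, revcomp, validate_dna
from .errors import ContractError, RegistryError

_SIDES = ("three_prime", "five_prime")


@dataclass(frozen=True)
class PAMModel:
    """A named PAM recognition model."""

    name: str
    pattern: str          # IUPAC string, e.g. "NGG", "TTTV"
    side: str             # "three_prime": PAM 3' of the spacer; "five_prime": 5'
    spacer_length: int
    cut_offset: int       # nt from the PAM-proximal end of the spacer (signed)

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ContractError(f"PAM pattern {self.pattern!r} has non-IUPAC codes {sorted(bad)}")
        if self.side not in _SIDES:
            raise ContractError(f"side must be one of {_SIDES}, got {self.side!r}")
        if not 10 <= self.spacer_length <= 30:
            raise ContractError(f"spacer_length must be in [10, 30], got {self.spacer_length}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def pam_length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer occurrence: spacer + PAM in guide orientation.

    ``start``/``end`` delimit the spacer (not the PAM) as a 0-based
    half-open interval on the forward strand of the scanned sequence.
    """

    spacer: str
    pam: str
    start: int
    end: int
    strand: str                       # "+" or "-"
    record_id: str | None = None
    guide_id: str | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# registry

def _parse_registry(text: str, source: str) -> dict[str, PAMModel]:
    models: dict[str, PAMModel] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pattern, side, spacer_length, cut_offset = line.split("\t")
        if name in models:
            raise RegistryError(f"duplicate PAM model name {name!r} in {source}")
        models[name] = PAMModel(name, pattern, side, int(spacer_length), int(cut_offset))
    if not models:
        raise RegistryError(f"no PAM models found in {source}")
    return models


@lru_cache(maxsize=4)
def load_registry(path: str | None = None) -> dict[str, PAMModel]:
    """Load the PAM model registry (the packaged table, or a user TSV)."""
    if path is None:
        text = resources.files("guidecraft.data").joinpath("pam_models.tsv").read_text()
        return _parse_registry(text, "packaged registry")
    return _parse_registry(Path(path).read_text(), str(path))


def get_model(name: str, registry: dict[str, PAMModel] | None = None) -> PAMModel:
    """Look up a PAM model by name; unknown names raise a RegistryError
    listing every registered model."""
    reg = registry if registry is not None else load_registry()
    try:
        return reg[name]
    except KeyError:
        raise RegistryError(
            f"unknown PAM model {name!r}; available models: {', '.join(sorted(reg))}"
        ) from None


# ---------------------------------------------------------------------------
# matching and enumeration

def matches_pam(seq: str, model: PAMModel | str) -> bool:
    """True iff ``seq`` (concrete bases) matches the model's IUPAC pattern
    position by position."""
    pattern = model.pattern if isinstance(model, PAMModel) else model.upper()
    seq = validate_dna(seq, what="PAM sequence")
    if len(seq) != len(pattern):
        raise ContractError(
            f"PAM sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    return all(b in IUPAC_CODES[p] for b, p in zip(seq, pattern))


def pattern_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern into a regex finding overlapping matches."""
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in pattern.upper()
    )
    return re.compile(f"(?={body})")


def relaxed_pattern(pattern: str) -> str:
    """The pattern with its most 5'-proximal fixed (non-N) position set to N.

    Used by the off-target search to admit near-canonical PAMs, which the
    scoring table then down-weights.
    """
    chars = list(pattern.upper())
    for i, c in enumerate(chars):
        if c != "N":
            chars[i] = "N"
            return "".join(chars)
    return pattern.upper()


def _scan_forward(seq: str, model: PAMModel, pattern: str):
    """Yield (spacer, pam, start, end) for plus-orientation hits on ``seq``."""
    L = model.spacer_length
    plen = len(pattern)
    n = len(seq)
    rx = pattern_regex(pattern)
    for m in rx.finditer(seq):
        i = m.start()
        if model.side == "three_prime":
            s0, s1 = i - L, i
        else:
            s0, s1 = i + plen, i + plen + L
        if s0 < 0 or s1 > n:
            continue
        spacer = seq[s0:s1]
        if "N" in spacer:
            continue
        yield spacer, seq[i:i + plen], s0, s1


def enumerate_protospacers(
    seq: str,
    model: PAMModel,
    both_strands: bool = True,
    record_id: str | None = None,
    pattern: str | None = None,
) -> list[GuideCandidate]:
    """All PAM-adjacent protospacers in ``seq`` under ``model``.

    ``pattern`` overrides the model's PAM pattern (used internally for the
    relaxed off-target pattern).  Windows containing N are skipped.  Output
    is sorted by (start, strand).
    """
    seq = validate_dna(seq, allow_n=True, what="input sequence")
    pat = (pattern or model.pattern).upper()
    n = len(seq)
    out: list[GuideCandidate] = []
    for spacer, pam, s0, s1 in _scan_forward(seq, model, pat):
        out.append(GuideCandidate(spacer, pam, s0, s1, "+", record_id))
    if both_strands:
        rc = revcomp(seq)
        for spacer, pam, s0, s1 in _scan_forward(rc, model, pat):
            out.append(GuideCandidate(spacer, pam, n - s1, n - s0, "-", record_id))
    out.sort(key=lambda c: (c.start, c.strand))
    return out
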