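"""Auxiliary wet-lab helpers: verification-PCR primer design and
templated insertion of special sgRNA structures.

Primer design enumerates every (start, length) primer pair flanking a
requested amplicon window, filters on length, melting temperature, GC
fraction and a 3'-end cross-complementarity screen, and sorts by Tm
balance then product length.  Melting temperature uses the GC-fraction
closed form ``Tm = 64.9 + 41 * (GC_count - 16.4) / length`` -- a
deterministic, testable approximation; swap in your own Tm if you need
nearest-neighbor accuracy.

Special structures ("hairpin", "GOLD") ship as named sequence templates
in a user-editable config; the engine only performs the positional
insertion.  The packaged template sequences are synthetic placeholders
(see the config header) to be replaced with lab-validated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from ._seq import gc_count, validate_dna
from .errors import ContractError, RegistryError

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PrimerConstraints:
    length_bounds: tuple[int, int] = (18, 25)
    tm_bounds: tuple[float, float] = (55.0, 65.0)
    gc_bounds: tuple[float, float] = (0.4, 0.6)
    max_tm_diff: float = 3.0


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a template.

    ``forward_start`` is the 0-based template position of the forward
    primer's 5' end; ``reverse_start`` is the 0-based template position of
    the reverse primer's 5' end (the rightmost base of its binding site).
    ``product_length`` spans the two 5' ends inclusively.
    """

    forward_seq: str
    reverse_seq: str
    forward_start: int
    reverse_start: int
    product_length: int
    tm_forward: float
    tm_reverse: float


def melting_temp(seq: str) -> float:
    """GC-fraction closed form: ``64.9 + 41 * (GC - 16.4) / length`` (degC)."""
    s = validate_dna(seq, what="primer")
    if not s:
        raise ContractError("melting_temp of an empty sequence is undefined")
    return 64.9 + 41.0 * (gc_count(s) - 16.4) / len(s)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _three_prime_clash(a: str, b: str, tail: int = 5, threshold: int = 4) -> bool:
    """3'-end cross-dimer screen: align the 3' tail of one primer against
    the 3' tail of the other (antiparallel); >= ``threshold`` complementary
    pairs out of ``tail`` rejects the pair."""
    ta, tb = a[-tail:], b[-tail:]
    pairs = sum(1 for x, y in zip(ta, reversed(tb)) if _COMP[x] == y)
    return pairs >= threshold


def _primer_ok(seq: str, c: PrimerConstraints) -> float | None:
    """Tm if the primer satisfies the per-primer constraints, else None."""
    gc = gc_count(seq) / len(seq)
    if not c.gc_bounds[0] <= gc <= c.gc_bounds[1]:
        return None
    tm = melting_temp(seq)
    if not c.tm_bounds[0] <= tm <= c.tm_bounds[1]:
        return None
    return tm


def design_primers(
    template: str,
    amplicon_window: tuple[int, int],
    constraints: PrimerConstraints | None = None,
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """All constraint-satisfying primer pairs flanking ``amplicon_window``
    (0-based half-open on the template), sorted by |Tm_f - Tm_r| then
    product length.  Empty when nothing satisfies the constraints."""
    c = constraints or PrimerConstraints()
    t = validate_dna(template, what="template")
    ws, we = amplicon_window
    if not 0 <= ws < we <= len(t):
        raise ContractError(
            f"amplicon window [{ws}, {we}) outside template of length {len(t)}"
        )
    lmin, lmax = c.length_bounds

    forwards = []
    for fs in range(0, ws - lmin + 1):
        for flen in range(lmin, lmax + 1):
            if fs + flen > ws:
                break
            seq = t[fs:fs + flen]
            tm = _primer_ok(seq, c)
            if tm is not None:
                forwards.append((fs, seq, tm))
    reverses = []
    for rs in range(we, len(t) - lmin + 1):
        for rlen in range(lmin, lmax + 1):
            if rs + rlen > len(t):
                break
            seq = _revcomp(t[rs:rs + rlen])
            tm = _primer_ok(seq, c)
            if tm is not None:
                reverses.append((rs, rlen, seq, tm))

    pairs = []
    for fs, fseq, ftm in forwards:
        for rs, rlen, rseq, rtm in reverses:
            if abs(ftm - rtm) > c.max_tm_diff:
                continue
            if _three_prime_clash(fseq, rseq):
                continue
            pairs.append(PrimerPair(
                forward_seq=fseq, reverse_seq=rseq,
                forward_start=fs, reverse_start=rs + rlen - 1,
                product_length=rs + rlen - fs,
                tm_forward=ftm, tm_reverse=rtm,
            ))
    pairs.sort(key=lambda p: (abs(p.tm_forward - p.tm_reverse), p.product_length,
                              p.forward_start, p.reverse_start))
    return pairs[:max_pairs] if max_pairs is not None else pairs


# ---------------------------------------------------------------------------
# structure templates

@dataclass(frozen=True)
class StructureTemplate:
    """A named insertion applied to an assembled spacer + scaffold."""

    name: str
    insert_seq: str
    insert_position: str            # "five_prime" | "three_prime" | "internal"
    insert_offset: int | None = None   # required when insert_position == internal

    def __post_init__(self) -> None:
        if self.insert_position not in ("five_prime", "three_prime", "internal"):
            raise ContractError(
                f"invalid insert_position {self.insert_position!r}")
        if self.insert_position == "internal" and self.insert_offset is None:
            raise ContractError("internal templates require insert_offset")


@lru_cache(maxsize=4)
def load_structures(path: str | None = None) -> dict[str, StructureTemplate]:
    """Load structure templates from YAML (default: the packaged synthetic
    placeholder file)."""
    if path is None:
        text = resources.files("guidecraft.data").joinpath(
            "structures_synthetic.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.get("structures", {}).items():
        out[name] = StructureTemplate(
            name=name,
            insert_seq=str(spec.get("insert_seq", "")).upper(),
            insert_position=spec["insert_position"],
            insert_offset=spec.get("insert_offset"),
        )
    return out


def get_structure(name: str, registry: dict[str, StructureTemplate] | None = None
                  ) -> StructureTemplate:
    reg = registry if registry is not None else load_structures()
    try:
        return reg[name]
    except KeyError:
        raise RegistryError(
            f"unknown structure template {name!r}; available: {', '.join(sorted(reg))}"
        ) from None


def default_scaffold(path: str | None = None) -> str:
    """The default sgRNA scaffold sequence from the structure config."""
    if path is None:
        text = resources.files("guidecraft.data").joinpath(
            "structures_synthetic.yaml").read_text()
    else:
        text = Path(path).read_text()
    return str(yaml.safe_load(text).get("default_scaffold", "")).upper()


def add_structure(spacer: str, scaffold: str, template: StructureTemplate) -> str:
    """Assemble spacer + scaffold and place the template's insert at its
    declared position; length-additive and deterministic."""
    s = validate_dna(spacer, what="spacer")
    sc = validate_dna(scaffold, what="scaffold") if scaffold else ""
    body = s + sc
    ins = template.insert_seq
    if not ins:
        return body
    if template.insert_position == "five_prime":
        return ins + body
    if template.insert_position == "three_prime":
        return body + ins
    k = template.insert_offset
    if k is None or not 0 <= k <= len(body):
        raise ContractError(
            f"internal insert offset {k} out of bounds for assembled length {len(body)}"
        )
    return body[:k] + ins + body[k:]
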