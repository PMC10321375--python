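"""Per-guide quality metrics and flags.

Four properties are computed for every candidate guide:

* ``gc_content`` -- GC fraction of the spacer.
* ``polyTA_flag`` -- true when the spacer contains four or more consecutive
  T's or four or more consecutive A's.  A T4 run is the RNA polymerase III
  terminator motif and can truncate sgRNA transcription; flagged guides are
  reported with an exclamation mark, not dropped.
* ``hairpin_flag`` -- true when the sequence contains an inverted repeat
  (a stem of at least ``min_stem`` bases whose reverse complement recurs
  downstream with a loop of at least ``min_loop`` bases), i.e. it can fold
  back on itself.  Found by exhaustive substring scan, not thermodynamics.
* ``activity_score`` -- a pluggable linear on-target activity model over a
  fixed-length sequence context (flanks + spacer + PAM): an intercept plus
  positional single-nucleotide weights, positional dinucleotide weights,
  and a GC-count term.  The packaged default weights are synthetic
  stand-ins with the shape of published linear activity models (see the
  file header); activity is reported as missing when the required context
  is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from ._seq import gc_count, revcomp, validate_dna
from .errors import ConfigurationError, ContractError


@dataclass(frozen=True)
class GuideFlags:
    """Quality summary attached to each reported guide."""

    is_unique: bool
    polyTA_flag: bool
    hairpin_flag: bool
    gc_fraction: float
    activity: float | None
    specificity: float


def polyTA_flag(spacer: str) -> bool:
    """True iff the spacer contains a homopolymer run of >= 4 T's or >= 4 A's."""
    s = validate_dna(spacer, what="spacer")
    return "TTTT" in s or "AAAA" in s


def gc_content(spacer: str) -> float:
    """GC fraction (#G + #C) / length of a non-empty spacer."""
    s = validate_dna(spacer, what="spacer")
    if not s:
        raise ContractError("gc_content of an empty sequence is undefined")
    return gc_count(s) / len(s)


def hairpin_flag(seq: str, min_stem: int = 4, min_loop: int = 3) -> bool:
    """Exhaustive inverted-repeat scan.

    True iff some stem of length ``min_stem`` starting at i has its reverse
    complement starting at j with a gap of at least ``min_loop`` bases
    between the stem halves (j >= i + min_stem + min_loop).  Longer stems
    necessarily contain a qualifying stem of the minimum length, so only
    stems of exactly ``min_stem`` are scanned.
    """
    if min_stem < 3 or min_loop < 3:
        raise ContractError("min_stem and min_loop must both be >= 3")
    s = validate_dna(seq, allow_n=True, what="sequence")
    n = len(s)
    if n < 2 * min_stem + min_loop:
        return False
    for i in range(n - 2 * min_stem - min_loop + 1):
        stem = s[i:i + min_stem]
        if "N" in stem:
            continue
        if s.find(revcomp(stem), i + min_stem + min_loop) != -1:
            return True
    return False


# ---------------------------------------------------------------------------
# linear activity model

@dataclass(frozen=True)
class ActivityModel:
    """A linear on-target activity scorer over a fixed-length context."""

    intercept: float
    positional_weights: dict[tuple[int, str], float]      # (pos 1.., base) -> w
    dinucleotide_weights: dict[tuple[int, str], float]    # (pos 1.., dinuc) -> w
    gc_weights: tuple[float, float]                       # (low-GC, high-GC)
    context_length: int
    spacer_start: int         # 0-based offset of the spacer within the context
    spacer_length: int
    gc_optimum: int = 10      # GC count in the spacer with zero GC penalty
    source_tag: str = "unspecified"


@lru_cache(maxsize=8)
def load_activity_model(path: str | None = None) -> ActivityModel:
    """Load an activity model from YAML (default: the packaged synthetic one)."""
    if path is None:
        text = resources.files("guidecraft.data").joinpath(
            "activity_weights_synthetic.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        positional = {}
        for key, w in raw.get("positional", {}).items():
            pos, base = key.split(":")
            positional[(int(pos), base)] = float(w)
        dinuc = {}
        for key, w in raw.get("dinucleotide", {}).items():
            pos, pair = key.split(":")
            dinuc[(int(pos), pair)] = float(w)
        model = ActivityModel(
            intercept=float(raw["intercept"]),
            positional_weights=positional,
            dinucleotide_weights=dinuc,
            gc_weights=(float(raw["gc_low"]), float(raw["gc_high"])),
            context_length=int(raw["context_length"]),
            spacer_start=int(raw["spacer_start"]),
            spacer_length=int(raw["spacer_length"]),
            gc_optimum=int(raw.get("gc_optimum", 10)),
            source_tag=str(raw.get("source_tag", "unspecified")),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"invalid activity model file: {exc}") from exc
    for (pos, _), _w in model.positional_weights.items():
        if not 1 <= pos <= model.context_length:
            raise ConfigurationError(f"positional weight at invalid position {pos}")
    for (pos, _), _w in model.dinucleotide_weights.items():
        if not 1 <= pos <= model.context_length - 1:
            raise ConfigurationError(f"dinucleotide weight at invalid position {pos}")
    return model


def activity_score(context: str, model: ActivityModel) -> float:
    """Linear activity score of a full-length sequence context."""
    s = validate_dna(context, what="activity context")
    if len(s) != model.context_length:
        raise ConfigurationError(
            f"context length {len(s)} != model context length {model.context_length}"
        )
    score = model.intercept
    for i, base in enumerate(s, start=1):
        score += model.positional_weights.get((i, base), 0.0)
    for i in range(1, len(s)):
        score += model.dinucleotide_weights.get((i, s[i - 1:i + 1]), 0.0)
    gc = gc_count(s[model.spacer_start:model.spacer_start + model.spacer_length])
    low, high = model.gc_weights
    if gc < model.gc_optimum:
        score += low * (model.gc_optimum - gc)
    elif gc > model.gc_optimum:
        score += high * (gc - model.gc_optimum)
    return score
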