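"""Mismatch-bounded off-target search and CFD scoring.

Potential off-target sites are genomic protospacers whose Hamming
distance to the guide spacer is strictly below a user-settable bound
(default 5, i.e. 0-4 mismatches reported) and whose adjacent PAM matches
a *relaxed* form of the model's pattern: the most 5'-proximal fixed
position of the canonical pattern is degenerated to N (NGG -> NNG), and
non-canonical PAMs are down-weighted by the scoring table.  A switch
restricts the search to canonical PAMs only.

The search uses pigeonhole seed partitioning: the spacer is split into
``bound`` segments; any site with fewer than ``bound`` mismatches must
match at least one segment exactly, so exact segment occurrences are
located through a per-record k-mer position table and then verified in
full (spacer Hamming distance, PAM class, N-free window).

Each hit is scored with the cutting-frequency-determination (CFD) model:
the product, over mismatched positions, of an empirical per-position
penalty for the (guide base, genome base) pair, multiplied by a PAM
penalty; a perfect match with a canonical PAM scores 1.0.  The packaged
penalty tables are synthetic stand-ins with the published tables' shape
(see their headers); users supply their own tables for publication-grade
scores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import IUPAC_CODES, revcomp, validate_dna
from .errors import ConfigurationError, ContractError
from .io import SequenceSet, as_sequence_set
from .pam_models import GuideCandidate, PAMModel, relaxed_pattern

Interval = tuple[str, int, int]   # (record_id, start, end) 0-based half-open


@dataclass(frozen=True)
class OffTargetHit:
    record_id: str
    start: int                    # spacer span on the forward strand, 0-based
    end: int                      # half-open
    strand: str
    site_spacer: str              # genomic protospacer in guide orientation
    site_pam: str
    mismatch_count: int
    mismatch_detail: tuple[tuple[int, str, str], ...]   # (pos 1.., guide, genome)
    cfd: float


# ---------------------------------------------------------------------------
# penalty tables

@dataclass
class PenaltyTable:
    """CFD penalties for one PAM model.

    ``mismatch_penalty`` maps (position 1..spacer_length, guide_base,
    genome_base) to a multiplier in (0, 1); matches are never penalised.
    ``pam_penalty`` maps *masked* PAM keys -- the observed PAM with every
    position that is N in the canonical pattern masked back to N -- to a
    multiplier; the canonical PAM maps to 1.0.
    """

    mismatch_penalty: dict[tuple[int, str, str], float]
    pam_penalty: dict[str, float]
    pam_pattern: str
    source_tag: str

    def mismatch(self, position: int, guide_base: str, genome_base: str) -> float:
        try:
            return self.mismatch_penalty[(position, guide_base, genome_base)]
        except KeyError:
            raise ConfigurationError(
                "penalty table has no entry for position "
                f"{position}, guide base {guide_base!r}, genome base {genome_base!r}"
            ) from None

    def pam_key(self, pam_seq: str) -> str:
        return "".join(
            "N" if p == "N" else b for b, p in zip(pam_seq.upper(), self.pam_pattern)
        )

    def pam(self, pam_seq: str) -> float:
        if len(pam_seq) != len(self.pam_pattern):
            raise ContractError(
                f"PAM length {len(pam_seq)} != pattern length {len(self.pam_pattern)}"
            )
        key = self.pam_key(pam_seq)
        try:
            return self.pam_penalty[key]
        except KeyError:
            raise ConfigurationError(
                f"penalty table has no PAM entry for {key!r} (pattern {self.pam_pattern})"
            ) from None


def _read_packaged(name: str) -> str:
    return resources.files("guidecraft.data").joinpath(name).read_text()


@lru_cache(maxsize=32)
def load_penalty_table(
    model_name: str,
    pam_pattern: str,
    mismatch_path: str | None = None,
    pam_path: str | None = None,
) -> PenaltyTable:
    """Assemble the penalty table for one model from tabular config files.

    Defaults to the packaged synthetic tables
    (``cfd_mismatch_synthetic.tsv`` and ``pam_penalty_synthetic.tsv``).
    """
    mm_text = (Path(mismatch_path).read_text() if mismatch_path
               else _read_packaged("cfd_mismatch_synthetic.tsv"))
    pam_text = (Path(pam_path).read_text() if pam_path
                else _read_packaged("pam_penalty_synthetic.tsv"))

    mismatch: dict[tuple[int, str, str], float] = {}
    source_tag = "unspecified"
    for row in csv.reader(
        (l for l in mm_text.splitlines() if l and not l.startswith("#")), delimiter="\t"
    ):
        pos, g, d, pen = row
        mismatch[(int(pos), g, d)] = float(pen)
    for line in mm_text.splitlines():
        if line.startswith("#source"):
            source_tag = line.split("\t", 1)[1]

    pam: dict[str, float] = {}
    for row in csv.reader(
        (l for l in pam_text.splitlines() if l and not l.startswith("#")), delimiter="\t"
    ):
        model, key, pen = row
        if model == model_name:
            pam[key] = float(pen)
    if not pam:
        raise ConfigurationError(
            f"no PAM penalty entries for model {model_name!r} in the PAM penalty table"
        )
    return PenaltyTable(mismatch, pam, pam_pattern.upper(), source_tag)


def table_for_model(model: PAMModel) -> PenaltyTable:
    return load_penalty_table(model.name, model.pattern)


# ---------------------------------------------------------------------------
# scoring

def cfd_score(guide_spacer: str, hit_spacer: str, hit_pam: str,
              table: PenaltyTable) -> float:
    """CFD score: product of per-position mismatch penalties times the PAM
    penalty; 1.0 for a perfect match with a canonical PAM."""
    g = validate_dna(guide_spacer, what="guide spacer")
    h = validate_dna(hit_spacer, what="site spacer")
    if len(g) != len(h):
        raise ContractError("guide and site spacers must have equal length")
    score = table.pam(hit_pam)
    for i, (gb, hb) in enumerate(zip(g, h), start=1):
        if gb != hb:
            score *= table.mismatch(i, gb, hb)
    return score


def specificity_score(hits: Sequence[OffTargetHit] | Sequence[float]) -> float:
    """Aggregate per-guide specificity: ``1 / (1 + sum of off-target CFDs)``.

    1.0 when the guide has no off-target hits; strictly decreasing as any
    hit's CFD grows.  Hits must exclude the on-target site.
    """
    total = sum(h.cfd if isinstance(h, OffTargetHit) else float(h) for h in hits)
    return 1.0 / (1.0 + total)


# ---------------------------------------------------------------------------
# pigeonhole search

@lru_cache(maxsize=16)
def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer of ``seq`` (N-containing k-mers included;
    they are filtered during verification)."""
    table: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        table.setdefault(seq[i:i + k], []).append(i)
    return table


def _segments(length: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``parts`` near-equal contiguous segments."""
    base, extra = divmod(length, parts)
    bounds, start = [], 0
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _overlaps(record_id: str, start: int, end: int,
              exclude: Iterable[Interval]) -> bool:
    return any(r == record_id and start < e and end > s for r, s, e in exclude)


def find_offtargets(
    guide: GuideCandidate | str,
    genome: SequenceSet,
    model: PAMModel,
    max_diff_exclusive: int = 5,
    exclude: Sequence[Interval] = (),
    table: PenaltyTable | None = None,
    canonical_pam_only: bool = False,
) -> list[OffTargetHit]:
    """Every PAM-adjacent genomic site with spacer Hamming distance
    strictly below ``max_diff_exclusive`` to the guide, on either strand,
    outside the ``exclude`` intervals (the on-target loci).

    Output is sorted by (mismatch_count, descending CFD), with coordinates
    as the final tie-break for determinism.
    """
    spacer = guide.spacer if isinstance(guide, GuideCandidate) else guide
    spacer = validate_dna(spacer, what="guide spacer")
    if max_diff_exclusive < 1:
        raise ContractError("max_diff_exclusive must be >= 1")
    L = model.spacer_length
    if len(spacer) != L:
        raise ContractError(
            f"guide spacer length {len(spacer)} != model spacer length {L}"
        )
    records = as_sequence_set(genome)
    if table is None:
        table = table_for_model(model)

    pam_pat = model.pattern if canonical_pam_only else relaxed_pattern(model.pattern)
    pam_sets = [IUPAC_CODES[c] for c in pam_pat]
    plen = len(pam_pat)
    bound = max_diff_exclusive
    seg_bounds = _segments(L, min(bound, L))

    hits: list[OffTargetHit] = []
    for rid, seq in records.items():
        n = len(seq)
        seen: set[tuple[int, str]] = set()
        for strand in "+-":
            # In forward-strand coordinates a minus-strand site matches the
            # reverse complement of the spacer.
            target = spacer if strand == "+" else revcomp(spacer)
            for lo, hi in seg_bounds:
                k = hi - lo
                positions = _kmer_positions(seq, k).get(target[lo:hi])
                if not positions:
                    continue
                for p in positions:
                    w = p - lo
                    if w < 0 or w + L > n or (w, strand) in seen:
                        continue
                    window = seq[w:w + L]
                    mm = 0
                    for a, b in zip(window, target):
                        if a != b:
                            mm += 1
                            if mm >= bound:
                                break
                    if mm >= bound:
                        continue
                    # locate and check the PAM in forward coordinates
                    if (model.side == "three_prime") == (strand == "+"):
                        p0, p1 = w + L, w + L + plen
                    else:
                        p0, p1 = w - plen, w
                    if p0 < 0 or p1 > n:
                        continue
                    pam_fwd = seq[p0:p1]
                    site_pam = pam_fwd if strand == "+" else revcomp(pam_fwd)
                    if "N" in window or "N" in site_pam:
                        continue
                    if not all(b in s for b, s in zip(site_pam, pam_sets)):
                        continue
                    seen.add((w, strand))
                    if _overlaps(rid, w, w + L, exclude):
                        continue
                    site_spacer = window if strand == "+" else revcomp(window)
                    detail = tuple(
                        (i + 1, gb, hb)
                        for i, (gb, hb) in enumerate(zip(spacer, site_spacer))
                        if gb != hb
                    )
                    hits.append(OffTargetHit(
                        record_id=rid, start=w, end=w + L, strand=strand,
                        site_spacer=site_spacer, site_pam=site_pam,
                        mismatch_count=len(detail), mismatch_detail=detail,
                        cfd=cfd_score(spacer, site_spacer, site_pam, table),
                    ))
    hits.sort(key=lambda h: (h.mismatch_count, -h.cfd, h.record_id, h.start, h.strand))
    return hits


def locate_exact_sites(
    spacer: str, genome: SequenceSet, model: PAMModel,
) -> list[Interval]:
    """Spacer intervals of exact, canonical-PAM occurrences of ``spacer``
    in the genome (used to identify on-target loci in reference-free mode)."""
    table = table_for_model(model)
    sites = find_offtargets(spacer, genome, model, max_diff_exclusive=1,
                            table=table, canonical_pam_only=True)
    return [(h.record_id, h.start, h.end) for h in sites]
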