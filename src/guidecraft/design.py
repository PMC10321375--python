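"""Design orchestration: candidates -> uniqueness -> off-targets -> report.

The single-target workflow enumerates every PAM-adjacent candidate in the
target sequence, marks each spacer unique or not against the genome-wide
uniqueness index, searches the genome for off-target sites within the
mismatch bound (excluding the on-target locus), computes the quality
flags, and ranks the result.  Non-unique guides are *retained and marked*
(``not_unique``), never silently dropped; uniqueness acts as the leading
ranking key.

On-target exclusion in reference-free mode: when no locus is supplied,
exact full-length occurrences of the target sequence in the genome are
treated as the on-target loci; if the target sequence is not present at
all, each guide's exact canonical-PAM sites are excluded instead.

``shared_guides`` finds spacers that occur (with a valid PAM) in every
member of a gene group -- one guide for multiplex editing of polygenic
traits.  A shared guide is ideally represented exactly once per target
gene, so its uniqueness criterion is ``genome occurrence count == number
of target genes``; surplus occurrences surface as off-target hits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp, validate_dna
from .errors import ContractError, ProvenanceError
from .genome_index import UniquenessIndex
from .guide_features import (
    ActivityModel,
    GuideFlags,
    activity_score,
    gc_content,
    hairpin_flag,
    load_activity_model,
    polyTA_flag,
)
from .io import SequenceSet, as_sequence_set, genome_digest
from .offtarget import (
    Interval,
    OffTargetHit,
    PenaltyTable,
    find_offtargets,
    locate_exact_sites,
    specificity_score,
    table_for_model,
)
from .pam_models import GuideCandidate, PAMModel, enumerate_protospacers, get_model


@dataclass
class DesignParams:
    """Tunable knobs of the design workflow (defaults match the packaged
    SpCas9 setup: 20-nt spacer, NGG PAM, up to 4 mismatches reported)."""

    pam_model_name: str = "SpCas9-NGG"
    max_mismatch_inclusive: int = 4
    require_unique: bool = True       # rank non-unique guides last (still reported)
    gc_bounds: tuple[float, float] = (0.0, 1.0)
    top_k: int | None = None
    exclude_on_target: bool = True
    canonical_pam_only: bool = False
    scaffold: str = ""                # appended to the spacer for the hairpin scan
    min_stem: int = 4
    min_loop: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.gc_bounds
        if not 0.0 <= lo <= hi <= 1.0:
            raise ContractError(f"gc_bounds must satisfy 0 <= lo <= hi <= 1, got {self.gc_bounds}")
        if self.max_mismatch_inclusive < 0:
            raise ContractError("max_mismatch_inclusive must be >= 0")


@dataclass
class GuideReport:
    """One ranked candidate with its flags and off-target hit list."""

    candidate: GuideCandidate
    flags: GuideFlags
    hits: list[OffTargetHit]
    rank: int
    target_id: str = "target"
    # shared-guide mode: per-gene occurrence lists, keyed by gene id
    occurrences: dict[str, list[GuideCandidate]] | None = None


def _check_provenance(index: UniquenessIndex, genome: SequenceSet,
                      model: PAMModel) -> None:
    digest = genome_digest(genome)
    if index.genome_digest != digest:
        raise ProvenanceError(
            "uniqueness index was built from a different genome "
            f"(index digest {index.genome_digest[:12]}..., genome {digest[:12]}...)"
        )
    if index.model_name != model.name:
        raise ProvenanceError(
            f"uniqueness index was built with PAM model {index.model_name!r}, "
            f"design requested {model.name!r}"
        )


def _locate_target(target: str, genome: SequenceSet) -> list[Interval]:
    """Exact full-length occurrences of the target sequence (either strand)."""
    loci: list[Interval] = []
    rc = revcomp(target)
    for rid, seq in genome.items():
        for probe in (target, rc):
            pos = seq.find(probe)
            while pos != -1:
                iv = (rid, pos, pos + len(probe))
                if iv not in loci:
                    loci.append(iv)
                pos = seq.find(probe, pos + 1)
    return loci


def _activity_context(target: str, cand: GuideCandidate, model: PAMModel,
                      act: ActivityModel) -> str | None:
    """Cut the activity-model context (upstream flank + spacer + PAM +
    downstream flank) out of the target, or None near the edges or for
    PAM geometries the model was not built for."""
    if model.side != "three_prime" or model.spacer_length != act.spacer_length:
        return None
    up = act.spacer_start
    down = act.context_length - up - act.spacer_length - model.pam_length
    if down < 0:
        return None
    if cand.strand == "+":
        a, b = cand.start - up, cand.end + model.pam_length + down
        if a < 0 or b > len(target):
            return None
        return target[a:b]
    a, b = cand.start - model.pam_length - down, cand.end + up
    if a < 0 or b > len(target):
        return None
    return revcomp(target[a:b])


def _build_report(
    target: str, target_id: str, cand: GuideCandidate,
    index: UniquenessIndex, genome: SequenceSet, model: PAMModel,
    params: DesignParams, table: PenaltyTable, act: ActivityModel,
    exclude: Sequence[Interval],
) -> GuideReport:
    occ = index.occurrence_count(cand.spacer)
    if params.exclude_on_target and not exclude:
        exclude = locate_exact_sites(cand.spacer, genome, model)
    hits = find_offtargets(
        cand, genome, model,
        max_diff_exclusive=params.max_mismatch_inclusive + 1,
        exclude=exclude, table=table,
        canonical_pam_only=params.canonical_pam_only,
    )
    context = _activity_context(target, cand, model, act)
    flags = GuideFlags(
        is_unique=(occ == 1),
        polyTA_flag=polyTA_flag(cand.spacer),
        hairpin_flag=hairpin_flag(cand.spacer + params.scaffold,
                                  params.min_stem, params.min_loop),
        gc_fraction=gc_content(cand.spacer),
        activity=None if context is None else activity_score(context, act),
        specificity=specificity_score(hits),
    )
    return GuideReport(candidate=cand, flags=flags, hits=hits, rank=0,
                       target_id=target_id)


def _rank(reports: list[GuideReport], params: DesignParams) -> list[GuideReport]:
    """Deterministic total order: unique first (when require_unique),
    then specificity, activity, and position/strand as final tie-break."""

    def key(r: GuideReport):
        c = r.candidate
        return (
            (not r.flags.is_unique) if params.require_unique else False,
            -r.flags.specificity,
            -(r.flags.activity if r.flags.activity is not None else float("-inf")),
            c.record_id or "", c.start, c.strand,
        )

    ordered = sorted(reports, key=key)
    out = []
    for i, r in enumerate(ordered, start=1):
        r.rank = i
        r.candidate = replace(
            r.candidate, guide_id=r.candidate.guide_id or f"{r.target_id}_g{i:03d}")
        out.append(r)
    if params.top_k is not None:
        out = out[:params.top_k]
    return out


def design_for_sequence(
    target: str,
    target_locus: Interval | Sequence[Interval] | None,
    index: UniquenessIndex,
    genome: SequenceSet,
    params: DesignParams | None = None,
    target_id: str = "target",
) -> list[GuideReport]:
    """Design ranked sgRNAs for one target sequence against an indexed genome."""
    params = params or DesignParams()
    model = get_model(params.pam_model_name)
    genome = as_sequence_set(genome)
    _check_provenance(index, genome, model)
    target = validate_dna(target, allow_n=True, what="target sequence")
    table = table_for_model(model)
    act = load_activity_model()

    if target_locus is None:
        exclude: list[Interval] = _locate_target(target, genome) if params.exclude_on_target else []
    elif isinstance(target_locus, tuple) and len(target_locus) == 3 \
            and isinstance(target_locus[0], str):
        exclude = [target_locus]      # a single (record, start, end)
    else:
        exclude = list(target_locus)

    reports = []
    lo, hi = params.gc_bounds
    for cand in enumerate_protospacers(target, model):
        if not lo <= gc_content(cand.spacer) <= hi:
            continue
        reports.append(_build_report(target, target_id, cand, index, genome,
                                     model, params, table, act, exclude))
    return _rank(reports, params)


def shared_guides(
    targets: Mapping[str, str],
    index: UniquenessIndex,
    genome: SequenceSet,
    params: DesignParams | None = None,
) -> list[GuideReport]:
    """Guides whose spacer occurs (PAM-adjacent) in *every* target gene.

    Each report lists per-gene occurrence coordinates; uniqueness for a
    shared guide means its genome-wide count equals the number of target
    genes.  Off-target exclusion covers the loci of all target sequences.
    """
    if len(targets) < 2:
        raise ContractError("shared_guides requires at least 2 target sequences")
    params = params or DesignParams()
    model = get_model(params.pam_model_name)
    genome = as_sequence_set(genome)
    _check_provenance(index, genome, model)
    table = table_for_model(model)
    act = load_activity_model()

    per_gene: dict[str, dict[str, list[GuideCandidate]]] = {}
    for gid, seq in targets.items():
        cands: dict[str, list[GuideCandidate]] = {}
        for c in enumerate_protospacers(validate_dna(seq, allow_n=True), model):
            cands.setdefault(c.spacer, []).append(c)
        per_gene[gid] = cands

    gene_ids = list(targets)
    common = set(per_gene[gene_ids[0]])
    for gid in gene_ids[1:]:
        common &= set(per_gene[gid])

    exclude: list[Interval] = []
    if params.exclude_on_target:
        for seq in targets.values():
            exclude.extend(_locate_target(seq.upper(), genome))

    n_targets = len(targets)
    reports = []
    for spacer in sorted(common):
        first = per_gene[gene_ids[0]][spacer][0]
        occ = index.occurrence_count(spacer)
        hits = find_offtargets(
            first, genome, model,
            max_diff_exclusive=params.max_mismatch_inclusive + 1,
            exclude=exclude, table=table,
            canonical_pam_only=params.canonical_pam_only,
        )
        first_seq = targets[gene_ids[0]].upper()
        context = _activity_context(first_seq, first, model, act)
        flags = GuideFlags(
            is_unique=(occ == n_targets),
            polyTA_flag=polyTA_flag(spacer),
            hairpin_flag=hairpin_flag(spacer + params.scaffold,
                                      params.min_stem, params.min_loop),
            gc_fraction=gc_content(spacer),
            activity=None if context is None else activity_score(context, act),
            specificity=specificity_score(hits),
        )
        reports.append(GuideReport(
            candidate=first, flags=flags, hits=hits, rank=0, target_id="shared",
            occurrences={gid: list(per_gene[gid][spacer]) for gid in gene_ids},
        ))
    return _rank(reports, params)


def batch_design(
    targets: Mapping[str, str] | Iterable[tuple[str, str]],
    index: UniquenessIndex,
    genome: SequenceSet,
    params: DesignParams | None = None,
    target_loci: Mapping[str, Sequence[Interval]] | None = None,
) -> dict[str, list[GuideReport]]:
    """Run :func:`design_for_sequence` for every target, in input order."""
    items = list(targets.items()) if isinstance(targets, Mapping) else list(targets)
    if not items:
        raise ContractError("batch_design requires at least one target")
    seen = set()
    for tid, _ in items:
        if tid in seen:
            raise ContractError(f"duplicate target id {tid!r}")
        seen.add(tid)
    return {
        tid: design_for_sequence(
            seq,
            (target_loci or {}).get(tid),
            index, genome, params, target_id=tid,
        )
        for tid, seq in items
    }
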