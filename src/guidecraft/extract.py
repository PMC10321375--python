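"""Design-ready sequence extraction from genome + GFF3 annotation.

Many bench biologists have a genome FASTA and a GFF3 but no convenient
way to pull out the exact sequence to design against.  This module loads
gene models from GFF3 (1-based inclusive coordinates, converted to
0-based half-open internally) and extracts promoter, gene, mRNA, CDS and
UTR sequences in transcript orientation (minus-strand output is
reverse-complemented so it always reads 5'->3').

When a gene has several mRNA isoforms the longest one (by summed exon
length, ties broken by lexicographically smallest ID) is used unless a
transcript is named explicitly.  UTRs come from explicit
``five_prime_UTR``/``three_prime_UTR`` features when present and are
otherwise derived as exon minus CDS, so sparse annotations stay usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from ._seq import revcomp
from .errors import AnnotationError, ContractError
from .io import SequenceSet

Interval = tuple[int, int]

REGION_KINDS = ("promoter", "gene", "mRNA", "CDS", "UTR5", "UTR3")

DEFAULT_PROMOTER_LEN = 2000


@dataclass
class GeneModel:
    gene_id: str
    record_id: str
    strand: str
    gene_span: Interval
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    five_utr: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)
    transcript_id: str | None = None


def _to_intervals(features) -> list[Interval]:
    # GFF3 is 1-based inclusive; internal coordinates are 0-based half-open.
    iv = sorted((f.start - 1, f.end) for f in features)
    for (a0, a1), (b0, _b1) in zip(iv, iv[1:]):
        if b0 < a1:
            raise AnnotationError(f"overlapping features at {a0 + 1}-{a1} / {b0 + 1}")
    return iv


def _subtract(exons: list[Interval], cds: list[Interval]) -> list[Interval]:
    """Exonic intervals minus CDS intervals (all sorted, non-overlapping)."""
    out: list[Interval] = []
    for e0, e1 in exons:
        cur = e0
        for c0, c1 in cds:
            if c1 <= cur or c0 >= e1:
                continue
            if c0 > cur:
                out.append((cur, c0))
            cur = max(cur, c1)
        if cur < e1:
            out.append((cur, e1))
    return out


def load_annotation(gff_source: str | Path, genome: SequenceSet) -> dict[str, GeneModel]:
    """Parse GFF3 (a path, or raw GFF3 text containing newlines) into
    :class:`GeneModel` objects, one per gene, validated against the genome."""
    source = str(gff_source)
    from_string = "\n" in source
    try:
        db = gffutils.create_db(
            source, ":memory:", from_string=from_string,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:
        raise AnnotationError(f"failed to parse GFF3: {exc}") from exc

    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise AnnotationError(
                f"gene {gene.id!r} lies on record {gene.seqid!r}, "
                "which is absent from the genome"
            )
        reclen = len(genome[gene.seqid])
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise AnnotationError(f"gene {gene.id!r} has no mRNA child")

        def _exon_len(m) -> int:
            exons = list(db.children(m, featuretype="exon"))
            return sum(f.end - f.start + 1 for f in exons) if exons else m.end - m.start + 1

        mrnas.sort(key=lambda m: (-_exon_len(m), m.id))
        mrna = mrnas[0]
        exon_feats = list(db.children(mrna, featuretype="exon"))
        if not exon_feats:
            raise AnnotationError(f"mRNA {mrna.id!r} of gene {gene.id!r} has no exons")
        exons = _to_intervals(exon_feats)
        cds = _to_intervals(db.children(mrna, featuretype="CDS"))
        utr5 = _to_intervals(db.children(mrna, featuretype="five_prime_UTR"))
        utr3 = _to_intervals(db.children(mrna, featuretype="three_prime_UTR"))
        if cds and not (utr5 or utr3):
            non_cds = _subtract(exons, cds)
            cds_start, cds_end = cds[0][0], cds[-1][1]
            before = [iv for iv in non_cds if iv[1] <= cds_start]
            after = [iv for iv in non_cds if iv[0] >= cds_end]
            if gene.strand == "+":
                utr5, utr3 = before, after
            else:
                utr5, utr3 = after, before

        span = (gene.start - 1, gene.end)
        if span[0] < 0 or span[1] > reclen:
            raise AnnotationError(
                f"gene {gene.id!r} exceeds record {gene.seqid!r} bounds (length {reclen})"
            )
        for e0, e1 in exons:
            if e0 < span[0] or e1 > span[1] or e1 > reclen:
                raise AnnotationError(
                    f"exon {e0 + 1}-{e1} of gene {gene.id!r} is out of bounds"
                )
        models[gene.id] = GeneModel(
            gene_id=gene.id, record_id=gene.seqid, strand=gene.strand,
            gene_span=span, exons=exons, cds=cds,
            five_utr=utr5, three_utr=utr3, transcript_id=mrna.id,
        )
    if not models:
        raise AnnotationError("annotation contains no gene features")
    return models


def _splice(seq: str, intervals: list[Interval], strand: str) -> str:
    """Concatenate genomic slices in genomic order, then flip to transcript
    orientation for minus-strand genes."""
    joined = "".join(seq[a:b] for a, b in intervals)
    return joined if strand == "+" else revcomp(joined)


def extract_region(
    gene: GeneModel,
    genome: SequenceSet,
    kind: str,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
) -> str:
    """Extract one region kind for a gene, 5'->3' in transcript orientation.

    An annotated-but-absent feature set (e.g. a gene without a 5' UTR)
    yields the empty string, distinct from an error.
    """
    if kind not in REGION_KINDS:
        raise ContractError(f"kind must be one of {REGION_KINDS}, got {kind!r}")
    seq = genome[gene.record_id]
    if kind == "gene":
        return _splice(seq, [gene.gene_span], gene.strand)
    if kind == "mRNA":
        return _splice(seq, gene.exons, gene.strand)
    if kind == "CDS":
        return _splice(seq, gene.cds, gene.strand)
    if kind == "UTR5":
        return _splice(seq, gene.five_utr, gene.strand)
    if kind == "UTR3":
        return _splice(seq, gene.three_utr, gene.strand)
    # promoter: upstream of the transcription start, truncated at the record edge
    if promoter_len < 1:
        raise ContractError("promoter_len must be >= 1")
    if gene.strand == "+":
        tss = gene.exons[0][0]
        return seq[max(0, tss - promoter_len):tss]
    tss = gene.exons[-1][1]
    return revcomp(seq[tss:min(len(seq), tss + promoter_len)])


def region_intervals(
    gene: GeneModel,
    genome: SequenceSet,
    kind: str,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
) -> list[tuple[str, int, int]]:
    """Genomic intervals (record, start, end) covered by a region kind —
    the loci a design run should exclude as on-target."""
    if kind not in REGION_KINDS:
        raise ContractError(f"kind must be one of {REGION_KINDS}, got {kind!r}")
    rid = gene.record_id
    if kind == "gene":
        ivs = [gene.gene_span]
    elif kind == "mRNA":
        ivs = gene.exons
    elif kind == "CDS":
        ivs = gene.cds
    elif kind == "UTR5":
        ivs = gene.five_utr
    elif kind == "UTR3":
        ivs = gene.three_utr
    else:
        if gene.strand == "+":
            tss = gene.exons[0][0]
            ivs = [(max(0, tss - promoter_len), tss)]
        else:
            tss = gene.exons[-1][1]
            ivs = [(tss, min(len(genome[rid]), tss + promoter_len))]
    return [(rid, a, b) for a, b in ivs if b > a]
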