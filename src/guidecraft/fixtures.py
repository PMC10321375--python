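"""Deterministic synthetic data: genomes, planted sites, toy annotations.

Every generator is a pure function of its parameters and an explicit
seed, so any run is reproducible bit for bit and no download is ever
needed.  ``plant_sites`` writes protospacer cassettes (spacer variants +
PAM) into a background genome and returns an *exact* truth table: after
planting, every background window accidentally similar to the planted
spacer (within the cleaning distance, either strand) is re-randomised
away, so a brute-force scan of the final genome finds exactly the truth
entries.  Synthetic genomes have i.i.d. base composition; they emulate
sequence search conditions, not repeat structure or isochores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, validate_dna
from .errors import ContractError
from .extract import GeneModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(
    n_records: int,
    lengths: list[int],
    gc: float = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """Random genome with i.i.d. bases at the requested GC fraction.

    Records are named ``chr1``, ``chr2``, ...  Reproducible for a given
    seed; realized GC concentrates tightly around the target for long
    records.
    """
    if n_records < 1 or len(lengths) != n_records:
        raise ContractError("lengths must list one positive length per record")
    if any(n <= 0 for n in lengths):
        raise ContractError("record lengths must be positive")
    if not 0.0 < gc < 1.0:
        raise ContractError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for i, n in enumerate(lengths, start=1):
        draws = rng.choice(4, size=n, p=p)
        out[f"chr{i}"] = _BASES[draws].tobytes().decode()
    return out


@dataclass
class PlantSpec:
    """A set of planted protospacer sites derived from one reference spacer.

    ``positions`` places one cassette per entry; ``mismatch_edits`` (one
    list per position, 1-based spacer coordinates) mutates the planted
    spacer away from the reference to create near-match sites.
    """

    spacer: str
    pam: str
    positions: list[tuple[str, int, str]]            # (record, offset, strand)
    mismatch_edits: list[list[tuple[int, str]]] = field(default_factory=list)
    pam_side: str = "three_prime"

    def __post_init__(self) -> None:
        self.spacer = validate_dna(self.spacer, what="planted spacer")
        self.pam = validate_dna(self.pam, what="planted PAM")
        if not self.mismatch_edits:
            self.mismatch_edits = [[] for _ in self.positions]
        if len(self.mismatch_edits) != len(self.positions):
            raise ContractError("one edit list per planted position is required")
        for edits in self.mismatch_edits:
            for pos, base in edits:
                if not 1 <= pos <= len(self.spacer):
                    raise ContractError(f"edit position {pos} outside the spacer")
                if base == self.spacer[pos - 1]:
                    raise ContractError(
                        f"edit at position {pos} does not change the base ({base})"
                    )

    def cassette_length(self) -> int:
        return len(self.spacer) + len(self.pam)


def _edited_spacer(spacer: str, edits: list[tuple[int, str]]) -> str:
    chars = list(spacer)
    for pos, base in edits:
        chars[pos - 1] = base
    return "".join(chars)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _window_mismatches(arr: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Mismatch count of every window of len(probe) against the probe."""
    L = len(probe)
    if len(arr) < L:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    return (windows != probe).sum(axis=1)


def plant_sites(
    genome: dict[str, str],
    spec: PlantSpec,
    seed: int = 0,
    clean_distance: int = 5,
) -> tuple[dict[str, str], list[dict]]:
    """Plant the cassettes and return (edited genome, exact truth table).

    Truth rows carry ``record``, spacer ``start``/``end`` (forward strand,
    0-based half-open), ``strand``, ``mismatch_count``, ``site_spacer`` and
    ``site_pam`` (guide orientation).  After planting, any background
    window within ``clean_distance`` mismatches of the reference spacer on
    either strand is re-randomised so the truth table is exhaustive below
    that distance.
    """
    L = len(spec.spacer)
    clen = spec.cassette_length()
    plen = len(spec.pam)

    # check fit and overlap
    spans: dict[str, list[tuple[int, int]]] = {}
    for rid, off, strand in spec.positions:
        if rid not in genome:
            raise ContractError(f"planted record {rid!r} not in genome")
        if off < 0 or off + clen > len(genome[rid]):
            raise ContractError(f"cassette at {rid}:{off} does not fit the record")
        if strand not in "+-":
            raise ContractError(f"invalid strand {strand!r}")
        for a, b in spans.get(rid, []):
            if off < b and off + clen > a:
                raise ContractError(f"planted sites overlap on {rid} at {off}")
        spans.setdefault(rid, []).append((off, off + clen))

    arrays = {rid: bytearray(seq.encode()) for rid, seq in genome.items()}
    truth: list[dict] = []
    planted_spacer_spans: dict[str, list[tuple[int, int]]] = {}
    for (rid, off, strand), edits in zip(spec.positions, spec.mismatch_edits):
        site_spacer = _edited_spacer(spec.spacer, edits)
        if spec.pam_side == "three_prime":
            cassette = site_spacer + spec.pam
            sp_off = off if strand == "+" else off + plen
        else:
            cassette = spec.pam + site_spacer
            sp_off = off + plen if strand == "+" else off
        if strand == "-":
            cassette = revcomp(cassette)
        arrays[rid][off:off + clen] = cassette.encode()
        planted_spacer_spans.setdefault(rid, []).append((sp_off, sp_off + L))
        truth.append({
            "record": rid, "start": sp_off, "end": sp_off + L, "strand": strand,
            "mismatch_count": len(edits), "site_spacer": site_spacer,
            "site_pam": spec.pam,
        })

    # background cleaning: remove accidental near-matches on either strand
    rng = np.random.default_rng(seed)
    probe_f = _encode(spec.spacer)
    probe_r = _encode(revcomp(spec.spacer))
    protected = {
        rid: [(a, b) for a, b in spans.get(rid, [])] for rid in genome
    }
    for _ in range(20):
        dirty = False
        for rid, arr in arrays.items():
            a = np.frombuffer(bytes(arr), dtype=np.uint8)
            for probe, strand in ((probe_f, "+"), (probe_r, "-")):
                mm = _window_mismatches(a, probe)
                for w in np.flatnonzero(mm < clean_distance):
                    w = int(w)
                    if any(w < b and w + L > s
                           for s, b in planted_spacer_spans.get(rid, [])):
                        continue
                    # rewrite the window's unprotected bases
                    rewritten = False
                    for j in range(w, w + L):
                        if any(s <= j < b for s, b in protected.get(rid, [])):
                            continue
                        arr[j] = int(rng.choice(_BASES))
                        rewritten = True
                    if rewritten:
                        dirty = True
        if not dirty:
            break
    else:
        raise ContractError("background cleaning did not converge")

    return {rid: bytes(arr).decode() for rid, arr in arrays.items()}, truth


# ---------------------------------------------------------------------------
# toy annotation

def toy_annotation(
    genome: dict[str, str],
    n_genes: int,
    seed: int = 0,
) -> tuple[str, dict[str, GeneModel]]:
    """Emit a valid GFF3 string plus the matching truth GeneModels.

    Gene 1 is single-exon (gene == exon == CDS, no UTR rows: exactly four
    feature rows); later genes have two exons with explicit UTRs and a
    CDS length divisible by 3.  Strands alternate (+, -, +, ...); the seed
    jitters intergenic spacing.
    """
    if n_genes < 1:
        raise ContractError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    rid = next(iter(genome))
    reclen = len(genome[rid])

    lines = ["##gff-version 3"]
    models: dict[str, GeneModel] = {}
    cursor = 50
    for i in range(1, n_genes + 1):
        cursor += int(rng.integers(0, 150))
        strand = "+" if i % 2 == 1 else "-"
        gid, mid = f"gene{i}", f"mRNA{i}"
        single = i == 1
        glen = 300 if single else 600
        g0, g1 = cursor, cursor + glen
        if g1 + 50 > reclen:
            raise ContractError(
                f"record {rid!r} (length {reclen}) too short for {n_genes} genes"
            )

        def row(ftype: str, a: int, b: int, attrs: str) -> None:
            lines.append(
                f"{rid}\tguidecraft\t{ftype}\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}"
            )

        row("gene", g0, g1, f"ID={gid}")
        row("mRNA", g0, g1, f"ID={mid};Parent={gid}")
        if single:
            row("exon", g0, g1, f"ID=exon{i}.1;Parent={mid}")
            row("CDS", g0, g1, f"ID=cds{i};Parent={mid}")
            models[gid] = GeneModel(
                gene_id=gid, record_id=rid, strand=strand, gene_span=(g0, g1),
                exons=[(g0, g1)], cds=[(g0, g1)],
                five_utr=[], three_utr=[], transcript_id=mid,
            )
        else:
            exons = [(g0, g0 + 250), (g0 + 350, g1)]
            cds = [(g0 + 100, g0 + 250), (g0 + 350, g0 + 500)]   # 150+150 = 300 nt
            left_utr = [(g0, g0 + 100)]
            right_utr = [(g0 + 500, g1)]
            utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
            for j, (e0, e1) in enumerate(exons, start=1):
                row("exon", e0, e1, f"ID=exon{i}.{j};Parent={mid}")
            for j, (c0, c1) in enumerate(cds, start=1):
                row("CDS", c0, c1, f"ID=cds{i}.{j};Parent={mid}")
            for a, b in utr5:
                row("five_prime_UTR", a, b, f"ID=utr5.{i};Parent={mid}")
            for a, b in utr3:
                row("three_prime_UTR", a, b, f"ID=utr3.{i};Parent={mid}")
            models[gid] = GeneModel(
                gene_id=gid, record_id=rid, strand=strand, gene_span=(g0, g1),
                exons=exons, cds=cds, five_utr=utr5, three_utr=utr3,
                transcript_id=mid,
            )
        cursor = g1 + 200
    return "\n".join(lines) + "\n", models
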