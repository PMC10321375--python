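"""Regenerate the packaged default parameter tables in src/guidecraft/data/.

The PAM model registry lists twenty widely used Cas9/Cas12 PAM
configurations (public canonical motifs).  The CFD mismatch penalties,
PAM penalties and activity weights are SYNTHETIC stand-ins generated
here with a fixed seed: they reproduce the *shape* of the published
empirical tables (penalties shrink toward the PAM-proximal end,
transition mismatches are milder than transversions, near-canonical PAMs
are strongly down-weighted) but not the published numbers, which live in
supplementary material this package does not redistribute.  Users doing
publication-grade scoring should drop in their own tables; every loader
accepts a path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "guidecraft" / "data"

BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

PAM_MODELS = [
    # name, pattern, side, spacer_length, cut_offset
    ("SpCas9-NGG", "NGG", "three_prime", 20, -3),
    ("SpCas9-NAG", "NAG", "three_prime", 20, -3),
    ("SpCas9-NG", "NG", "three_prime", 20, -3),
    ("xCas9-NG", "NG", "three_prime", 20, -3),
    ("SpG-NGN", "NGN", "three_prime", 20, -3),
    ("SpRY-NRN", "NRN", "three_prime", 20, -3),
    ("ScCas9-NNG", "NNG", "three_prime", 20, -3),
    ("FnCas9-NGG", "NGG", "three_prime", 20, -3),
    ("SaCas9-NNGRRT", "NNGRRT", "three_prime", 21, -3),
    ("SaCas9KKH-NNNRRT", "NNNRRT", "three_prime", 21, -3),
    ("NmeCas9-NNNNGATT", "NNNNGATT", "three_prime", 24, -3),
    ("CjCas9-NNNNRYAC", "NNNNRYAC", "three_prime", 22, -3),
    ("StCas9-NNAGAAW", "NNAGAAW", "three_prime", 20, -3),
    ("Cas12a-TTTV", "TTTV", "five_prime", 23, 18),
    ("LbCas12a-TTTV", "TTTV", "five_prime", 23, 18),
    ("FnCas12a-TTN", "TTN", "five_prime", 23, 18),
    ("Cas12b-TTN", "TTN", "five_prime", 20, 17),
    ("Cas12e-TTCN", "TTCN", "five_prime", 20, 17),
    ("Cas12f-TTTR", "TTTR", "five_prime", 20, 17),
    ("CasMINI-TTTR", "TTTR", "five_prime", 20, 17),
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# penalty for a non-canonical base at the relaxed PAM position, by base
RELAXED_BASE_PENALTY = {"A": 0.26, "C": 0.11, "G": 0.20, "T": 0.07}


def write_pam_models() -> None:
    lines = ["# PAM model registry: name\tpattern\tside\tspacer_length\tcut_offset",
             "# cut_offset: nt from the PAM-proximal end of the spacer (nominal)"]
    for row in PAM_MODELS:
        lines.append("\t".join(str(x) for x in row))
    (DATA / "pam_models.tsv").write_text("\n".join(lines) + "\n")


def write_mismatch_table() -> None:
    rng = np.random.default_rng(20230504)
    lines = [
        "# SYNTHETIC CFD mismatch penalties: position\tguide_base\tgenome_base\tpenalty",
        "#source\tsynthetic-cfd-shape-v1 (generated by scripts/make_default_tables.py;"
        " not the published empirical table)",
        "# position 1 = 5' (PAM-distal for 3'-PAM models); penalties shrink toward",
        "# the 3' end; transition mismatches are milder than transversions.",
    ]
    for pos in range(1, 31):
        base_pen = 0.85 - 0.55 * (pos - 1) / 29.0
        for g in BASES:
            for d in BASES:
                if g == d:
                    continue
                mult = 1.25 if (g, d) in TRANSITIONS else 0.85
                jitter = rng.uniform(-0.05, 0.05)
                pen = float(np.clip(base_pen * mult + jitter, 0.02, 0.95))
                lines.append(f"{pos}\t{g}\t{d}\t{pen:.4f}")
    (DATA / "cfd_mismatch_synthetic.tsv").write_text("\n".join(lines) + "\n")


def write_pam_penalties() -> None:
    lines = [
        "# SYNTHETIC PAM penalties: model\tmasked_pam_key\tpenalty",
        "# keys mask positions that are N in the canonical pattern back to N;",
        "# canonical PAMs score 1.0, relaxed (first fixed position degenerated)",
        "# PAMs score the per-base penalty below.",
        "#source\tsynthetic-cfd-shape-v1",
    ]
    for name, pattern, _side, _L, _off in PAM_MODELS:
        chars = list(pattern)
        masked = ["N" if c == "N" else c for c in chars]
        # canonical keys: expand degenerate non-N codes to concrete bases
        canon_codes = ["N" if c == "N" else c for c in chars]
        for key in sorted(set(_expand_masked(canon_codes))):
            lines.append(f"{name}\t{key}\t1.0000")
        # relaxed keys: first non-N position takes each non-canonical base
        idx = next((i for i, c in enumerate(chars) if c != "N"), None)
        if idx is None:
            continue
        allowed = set(IUPAC[chars[idx]])
        for base in BASES:
            if base in allowed:
                continue
            codes = list(canon_codes)
            codes[idx] = base
            for key in sorted(set(_expand_masked(codes))):
                lines.append(f"{name}\t{key}\t{RELAXED_BASE_PENALTY[base]:.4f}")
    (DATA / "pam_penalty_synthetic.tsv").write_text("\n".join(lines) + "\n")


def _expand_masked(codes: list[str]) -> list[str]:
    """Expand degenerate codes to concrete bases, keeping N positions as N."""
    out = [""]
    for code in codes:
        opts = ["N"] if code == "N" else list(IUPAC[code])
        out = [p + b for p in out for b in opts]
    return out


def write_activity_weights() -> None:
    rng = np.random.default_rng(20230504 + 1)
    positional = {}
    for pos in rng.choice(np.arange(1, 31), size=18, replace=False):
        base = BASES[int(rng.integers(0, 4))]
        positional[f"{int(pos)}:{base}"] = round(float(rng.normal(0, 0.08)), 5)
    dinucleotide = {}
    for pos in rng.choice(np.arange(1, 30), size=10, replace=False):
        pair = BASES[int(rng.integers(0, 4))] + BASES[int(rng.integers(0, 4))]
        dinucleotide[f"{int(pos)}:{pair}"] = round(float(rng.normal(0, 0.05)), 5)
    lines = [
        "# SYNTHETIC linear activity model (generated by scripts/make_default_tables.py).",
        "# Shape of a published linear on-target model -- 30-nt context of",
        "# 4 nt upstream flank + 20-nt spacer + 3-nt PAM + 3 nt downstream --",
        "# with synthetic weights; replace with empirically fitted weights for",
        "# publication-grade activity prediction.",
        "source_tag: synthetic-linear-activity-v1",
        "context_length: 30",
        "spacer_start: 4",
        "spacer_length: 20",
        "gc_optimum: 10",
        "intercept: 0.59764",
        "gc_low: -0.20263",
        "gc_high: -0.16659",
        "positional:",
    ]
    for key in sorted(positional, key=lambda k: (int(k.split(":")[0]), k)):
        lines.append(f'  "{key}": {positional[key]}')
    lines.append("dinucleotide:")
    for key in sorted(dinucleotide, key=lambda k: (int(k.split(":")[0]), k)):
        lines.append(f'  "{key}": {dinucleotide[key]}')
    (DATA / "activity_weights_synthetic.yaml").write_text("\n".join(lines) + "\n")


def write_structures() -> None:
    text = """\
# Special-structure templates and the default sgRNA scaffold.
# The hairpin and GOLD insert sequences below are SYNTHETIC PLACEHOLDERS
# (self-complementary stem-loops of the right general shape); replace them
# with lab-validated sequences from the primary literature before use.
default_scaffold: GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
structures:
  identity:
    insert_seq: ""
    insert_position: three_prime
  hairpin:
    insert_seq: GGCGCGAAAGCGCC
    insert_position: five_prime
  GOLD:
    insert_seq: GCAGCCGAAAGGCTGC
    insert_position: three_prime
"""
    (DATA / "structures_synthetic.yaml").write_text(text)


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    write_pam_models()
    write_mismatch_table()
    write_pam_penalties()
    write_activity_weights()
    write_structures()
    print(f"wrote tables to {DATA}")
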