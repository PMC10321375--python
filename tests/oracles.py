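"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions alone -- position-by-
position scans over every window of both strands -- and deliberately
shares no code with the package's search machinery, so agreement between
the two is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pam_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq, pattern))


def brute_enumerate(seq: str, pattern: str, side: str, spacer_len: int,
                    both_strands: bool = True):
    """Every PAM-adjacent protospacer, by scanning each position of each
    strand: (spacer, pam, start, end, strand) with forward-strand spacer
    coordinates and guide-orientation sequences."""
    seq = seq.upper()
    n, plen = len(seq), len(pattern)
    out = []

    def scan(s, flip):
        for i in range(len(s) - plen + 1):
            if not pam_ok(s[i:i + plen], pattern):
                continue
            if side == "three_prime":
                a, b = i - spacer_len, i
            else:
                a, b = i + plen, i + plen + spacer_len
            if a < 0 or b > n:
                continue
            spacer = s[a:b]
            if "N" in spacer:
                continue
            if flip:
                out.append((spacer, s[i:i + plen], n - b, n - a, "-"))
            else:
                out.append((spacer, s[i:i + plen], a, b, "+"))

    scan(seq, False)
    if both_strands:
        scan(rc(seq), True)
    out.sort(key=lambda c: (c[2], c[4]))
    return out


def brute_index(genome: dict[str, str], pattern: str, side: str,
                spacer_len: int) -> dict[str, int]:
    """Spacer occurrence counts by exhaustive enumeration of every record."""
    counts: dict[str, int] = {}
    for seq in genome.values():
        for spacer, *_ in brute_enumerate(seq, pattern, side, spacer_len):
            counts[spacer] = counts.get(spacer, 0) + 1
    return counts


def brute_cfd(guide: str, site: str, pam_mult: float,
              mismatch_table: dict) -> float:
    """Positional-loop product of mismatch penalties times the PAM multiplier."""
    score = pam_mult
    for i in range(len(guide)):
        if guide[i] != site[i]:
            score = score * mismatch_table[(i + 1, guide[i], site[i])]
    return score


def brute_offtargets(guide: str, genome: dict[str, str], pattern: str,
                     side: str, bound: int):
    """Exhaustive scan of every PAM-adjacent window of both strands with
    direct Hamming counting; returns (record, start, strand, mismatches,
    site_spacer, site_pam) for every site below the bound.

    Window positions are located with a vectorised per-base comparison,
    then each candidate is re-verified base by base.
    """
    L = len(guide)
    out = []
    for rid, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand in "+-":
            probe = guide if strand == "+" else rc(guide)
            mm = (windows != np.frombuffer(probe.encode(), np.uint8)).sum(axis=1)
            for w in np.flatnonzero(mm < bound):
                w = int(w)
                window = seq[w:w + L]
                # independent recount
                d = sum(1 for a, b in zip(window, probe) if a != b)
                assert d == int(mm[w])
                plen = len(pattern)
                if (side == "three_prime") == (strand == "+"):
                    p0, p1 = w + L, w + L + plen
                else:
                    p0, p1 = w - plen, w
                if p0 < 0 or p1 > len(seq):
                    continue
                pam_f = seq[p0:p1]
                site_pam = pam_f if strand == "+" else rc(pam_f)
                if "N" in window or "N" in site_pam:
                    continue
                if not pam_ok(site_pam, pattern):
                    continue
                site_spacer = window if strand == "+" else rc(window)
                out.append((rid, w, strand, d, site_spacer, site_pam))
    return sorted(out)


def brute_activity(context: str, intercept, positional, dinucleotide,
                   gc_low, gc_high, spacer_start, spacer_length, gc_opt) -> float:
    """Term-by-term re-summation of the linear activity model."""
    total = intercept
    for i in range(len(context)):
        total += positional.get((i + 1, context[i]), 0.0)
    for i in range(len(context) - 1):
        total += dinucleotide.get((i + 1, context[i] + context[i + 1]), 0.0)
    gc = sum(1 for b in context[spacer_start:spacer_start + spacer_length]
             if b in "GC")
    if gc < gc_opt:
        total += gc_low * (gc_opt - gc)
    elif gc > gc_opt:
        total += gc_high * (gc - gc_opt)
    return total


def brute_hairpin(seq: str, min_stem: int, min_loop: int) -> bool:
    """Exhaustive check over every stem length and pair of positions."""
    n = len(seq)
    for stem_len in range(min_stem, n + 1):
        for i in range(n - stem_len + 1):
            stem = seq[i:i + stem_len]
            target = rc(stem)
            for j in range(i + stem_len + min_loop, n - stem_len + 1):
                if seq[j:j + stem_len] == target:
                    return True
    return False
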