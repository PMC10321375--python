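"""Report emission: guide table, off-target table, and position map.

Tables are tab-separated UTF-8 with Unix newlines and "." for missing
values; all coordinates are converted to 1-based inclusive at this
boundary, and floats are printed to 6 decimals so files diff cleanly.
The position map is a hand-assembled SVG (plus a plain-text fallback):
one arrow glyph per guide along the target axis, orientation showing
strand and fill showing uniqueness.  All writers are deterministic --
identical input yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .design import GuideReport
from .errors import ContractError

GUIDE_COLUMNS = (
    "guide_id", "target_id", "start", "end", "strand", "spacer", "pam",
    "unique", "gc", "polyTA", "hairpin", "activity", "specificity",
    "n_offtargets",
)

OFFTARGET_COLUMNS = (
    "guide_id", "record_id", "start", "end", "strand", "site_spacer",
    "site_pam", "mismatch_count", "mismatch_positions", "cfd",
)


def _fmt(x: float | None) -> str:
    return "." if x is None else f"{x:.6f}"


def write_guide_table(reports: Sequence[GuideReport], path: str | Path) -> None:
    """One row per ranked guide; non-unique guides carry the literal token
    ``not_unique`` and poly-T/A guides an exclamation mark."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(GUIDE_COLUMNS) + "\n")
        for r in reports:
            c, f = r.candidate, r.flags
            fh.write("\t".join((
                c.guide_id or f"{r.target_id}_g{r.rank:03d}",
                r.target_id,
                str(c.start + 1), str(c.end), c.strand,
                c.spacer, c.pam,
                "yes" if f.is_unique else "not_unique",
                _fmt(f.gc_fraction),
                "!" if f.polyTA_flag else "",
                "yes" if f.hairpin_flag else "no",
                _fmt(f.activity),
                _fmt(f.specificity),
                str(len(r.hits)),
            )) + "\n")


def write_offtarget_table(reports: Sequence[GuideReport], path: str | Path) -> None:
    """One row per (guide, off-target hit), with per-position mismatch
    detail as semicolon-joined ``pos:guide>genome`` entries."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(OFFTARGET_COLUMNS) + "\n")
        for r in reports:
            gid = r.candidate.guide_id or f"{r.target_id}_g{r.rank:03d}"
            for h in r.hits:
                detail = ";".join(f"{p}:{g}>{d}" for p, g, d in h.mismatch_detail)
                fh.write("\t".join((
                    gid, h.record_id, str(h.start + 1), str(h.end), h.strand,
                    h.site_spacer, h.site_pam, str(h.mismatch_count),
                    detail, f"{h.cfd:.6f}",
                )) + "\n")


# ---------------------------------------------------------------------------
# position map

_W, _H_BASE, _LANE_H, _MARGIN = 800, 60, 16, 40
_FILL_UNIQUE, _FILL_NOT = "#2b8cbe", "#d7301f"


def render_position_map(
    target_id: str,
    target_length: int,
    reports: Sequence[GuideReport],
    path: str | Path,
    text_path: str | Path | None = None,
) -> None:
    """Draw guides along the target axis as strand-oriented arrows (SVG),
    with an aligned plain-text fallback."""
    for r in reports:
        c = r.candidate
        if c.start < 0 or c.end > target_length:
            raise ContractError(
                f"guide at [{c.start}, {c.end}) outside target of length {target_length}"
            )
    scale = (_W - 2 * _MARGIN) / max(target_length, 1)
    axis_y = _H_BASE + len(reports) * _LANE_H
    height = axis_y + 40

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_W}" height="{height}" '
        f'viewBox="0 0 {_W} {height}">',
        f'<text x="{_MARGIN}" y="20" font-family="monospace" font-size="13">'
        f'{target_id} ({target_length} bp)</text>',
        f'<line x1="{_MARGIN}" y1="{axis_y}" x2="{_W - _MARGIN}" y2="{axis_y}" '
        'stroke="black" stroke-width="2"/>',
        f'<text x="{_MARGIN}" y="{axis_y + 18}" font-family="monospace" '
        'font-size="10">1</text>',
        f'<text x="{_W - _MARGIN}" y="{axis_y + 18}" font-family="monospace" '
        f'font-size="10" text-anchor="end">{target_length}</text>',
    ]
    for i, r in enumerate(reports):
        c = r.candidate
        x0 = _MARGIN + c.start * scale
        x1 = _MARGIN + c.end * scale
        y = _H_BASE + i * _LANE_H
        fill = _FILL_UNIQUE if r.flags.is_unique else _FILL_NOT
        head = min(6.0, x1 - x0)
        if c.strand == "+":
            pts = (f"{x0:.2f},{y - 4:.2f} {x1 - head:.2f},{y - 4:.2f} "
                   f"{x1:.2f},{y:.2f} {x1 - head:.2f},{y + 4:.2f} {x0:.2f},{y + 4:.2f}")
        else:
            pts = (f"{x1:.2f},{y - 4:.2f} {x0 + head:.2f},{y - 4:.2f} "
                   f"{x0:.2f},{y:.2f} {x0 + head:.2f},{y + 4:.2f} {x1:.2f},{y + 4:.2f}")
        gid = c.guide_id or f"{r.target_id}_g{r.rank:03d}"
        lines.append(f'<polygon points="{pts}" fill="{fill}"/>')
        lines.append(
            f'<text x="{x1 + 4:.2f}" y="{y + 4:.2f}" font-family="monospace" '
            f'font-size="9">{gid}</text>'
        )
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines) + "\n")

    if text_path is None:
        text_path = str(path) + ".txt"
    width = 80
    tscale = width / max(target_length, 1)
    rows = [f"{target_id} ({target_length} bp)", "1" + " " * (width - len(str(target_length)) - 1) + str(target_length), "=" * width]
    for r in reports:
        c = r.candidate
        a = min(int(c.start * tscale), width - 1)
        b = max(min(int(c.end * tscale), width), a + 1)
        glyph = ">" if c.strand == "+" else "<"
        mark = "u" if r.flags.is_unique else "x"
        row = [" "] * width
        for j in range(a, b):
            row[j] = glyph
        gid = c.guide_id or f"{r.target_id}_g{r.rank:03d}"
        rows.append("".join(row) + f"  {gid} [{mark}]")
    Path(text_path).write_text("\n".join(rows) + "\n")
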