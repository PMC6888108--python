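"""Human-readable reports: per-column call tracks and an annotated alignment.

The text track writes one symbol per column under the alignment: ``U`` for
universally conserved, ``S`` for clade-shared, ``C`` for clade-specific
(numbered consecutively on a second track, matching the site table), and
``V`` for variable.  The HTML report highlights the same three conserved
classes in green / yellow / turquoise.
"""

from __future__ import annotations

import html
from typing import Optional, Sequence

from .alignment import LabeledAlignment
from .classify import (
    CLADE_SHARED,
    CLADE_SPECIFIC,
    CODE_CLASSES,
    UNIVERSAL,
    ColumnCall,
    SiteTable,
)

_COLORS = {UNIVERSAL: "#7ccd7c", CLADE_SHARED: "#ffe066", CLADE_SPECIFIC: "#40e0d0"}

_BLOCK = 60


def class_track(calls: Sequence[ColumnCall]) -> str:
    """One class-code character per column."""
    return "".join(c.code for c in calls)


def parse_class_track(track: str) -> list[str]:
    """Class names per column, inverse of :func:`class_track`."""
    return [CODE_CLASSES[ch] for ch in track]


def site_number_track(calls: Sequence[ColumnCall], table: SiteTable) -> str:
    """Site numbers under clade-specific columns ('.' elsewhere).

    Multi-digit numbers extend rightwards; overlaps favour the leftmost.
    """
    track = ["."] * len(calls)
    for row in table.rows:
        s = str(row.site)
        start = row.column - 1
        for i, ch in enumerate(s):
            if start + i < len(track) and track[start + i] == ".":
                track[start + i] = ch
    return "".join(track)


def render_text(aln: LabeledAlignment, calls: Sequence[ColumnCall],
                table: SiteTable, block: int = _BLOCK) -> str:
    """Plain-text annotated alignment in blocks, class + site tracks below."""
    classes = class_track(calls)
    numbers = site_number_track(calls, table)
    width = max(len(sid) for sid in aln.seq_ids) + 2
    out: list[str] = []
    for start in range(0, aln.n_columns, block):
        stop = min(start + block, aln.n_columns)
        out.append(f"{'':{width}}{start + 1}")
        for sid, row in aln.records:
            out.append(f"{sid:{width}}{row[start:stop]}")
        out.append(f"{'class':{width}}{classes[start:stop]}")
        out.append(f"{'site':{width}}{numbers[start:stop]}")
        out.append("")
    return "\n".join(out)


def render_html(aln: LabeledAlignment, calls: Sequence[ColumnCall],
                table: SiteTable, title: str = "Conserved-site report") -> str:
    """HTML report: colour-highlighted alignment plus the site table."""
    classes = [c.site_class for c in calls]
    rows_html = []
    for sid, row in aln.records:
        cells = []
        for j, ch in enumerate(row):
            color = _COLORS.get(classes[j])
            cells.append(
                f'<span style="background:{color}">{html.escape(ch)}</span>'
                if color else html.escape(ch)
            )
        rows_html.append(
            f"<tr><td class='id'>{html.escape(sid)} "
            f"<small>({html.escape(aln.clade_of[sid])})</small></td>"
            f"<td class='seq'>{''.join(cells)}</td></tr>"
        )
    site_rows = "".join(
        f"<tr><td>{r.site}</td><td>{html.escape(r.clade)}</td>"
        f"<td>{html.escape(r.domain)}</td>"
        f"<td>{'NA' if r.position is None else r.position}</td>"
        f"<td>{html.escape(r.conserved_aa)}</td>"
        f"<td>{html.escape(r.other_aa)}</td></tr>"
        for r in table.rows
    )
    legend = " ".join(
        f'<span style="background:{c}">&nbsp;{html.escape(lab.replace("_", "-").lower())}&nbsp;</span>'
        for lab, c in _COLORS.items()
    )
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{html.escape(title)}</title>
<style>
 body {{ font-family: sans-serif; }}
 td.seq {{ font-family: monospace; white-space: nowrap; letter-spacing: 1px; }}
 td.id {{ padding-right: 1em; }}
 table.sites td, table.sites th {{ border: 1px solid #999; padding: 2px 6px; }}
</style></head><body>
<h1>{html.escape(title)}</h1>
<p>Legend: {legend}</p>
<table>{''.join(rows_html)}</table>
<h2>Clade-specific conserved sites</h2>
<table class="sites">
<tr><th>site</th><th>clade</th><th>domain</th><th>position</th>
<th>conserved AA</th><th>AA in other clades</th></tr>
{site_rows}
</table>
</body></html>
"""
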