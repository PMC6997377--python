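"""Contrast-alignment rendering and molecular-viewer highlight scripts."""

from __future__ import annotations

import html as _html
from dataclasses import dataclass

from .alphabet import AA20, CLASS_OF, RESIDUE_CLASSES
from .bpps import HierarchyNode, selective_pressure_heights
from .msa_io import Alignment, ColumnProfile, frequency_digit


@dataclass(frozen=True)
class ResidueColorClass:
    name: str
    members: frozenset[str]
    foreground: str        # hex font color
    highlight: str | None  # hex background highlight, or None


# Eight classes partition the 20 amino acids; hex values fixed by config.
COLOR_CLASSES: dict[str, ResidueColorClass] = {
    "nonpolar": ResidueColorClass("nonpolar", frozenset("AVILMWFY"), "#FF0000", "#FFFF00"),
    "cysteine": ResidueColorClass("cysteine", frozenset("C"), "#0000FF", "#FFFF00"),
    "acidic": ResidueColorClass("acidic", frozenset("DE"), "#FF0000", None),
    "basic": ResidueColorClass("basic", frozenset("KR"), "#00FFFF", None),
    "polar": ResidueColorClass("polar", frozenset("STNQ"), "#FF00FF", None),
    "glycine": ResidueColorClass("glycine", frozenset("G"), "#008000", None),
    "histidine": ResidueColorClass("histidine", frozenset("H"), "#0000FF", None),
    "proline": ResidueColorClass("proline", frozenset("P"), "#000000", None),
}

UNCLASSIFIED = ResidueColorClass("unclassified", frozenset("-X"), "#808080", None)


def classify_residue(aa: str) -> ResidueColorClass:
    """Biochemical color class of a residue; gaps and ambiguity are gray."""
    if aa in CLASS_OF:
        return COLOR_CLASSES[CLASS_OF[aa]]
    if aa in UNCLASSIFIED.members:
        return UNCLASSIFIED
    raise ValueError(f"not an amino acid: {aa!r}")


def _select_representatives(
    node: HierarchyNode, aln: Alignment, weights=None, max_rows: int = 10
) -> tuple[list, list]:
    """Query first, then highest-weight foreground rows, then contrast rows
    from the background, capped."""
    recs = {r.id: r for r in aln.records}
    w = {r.id: (weights[i] if weights is not None else 1.0)
         for i, r in enumerate(aln.records)}
    fg = [recs[i] for i in sorted(node.foreground, key=lambda i: (-w[i], i))
          if i in recs]
    fg = [recs[aln.query_id]] + [r for r in fg if r.id != aln.query_id]
    bg = [recs[i] for i in sorted(node.background, key=lambda i: (-w[i], i))
          if i in recs]
    n_fg = max(1, max_rows - min(len(bg), max_rows // 2))
    return fg[:n_fg], bg[: max_rows - min(len(fg), n_fg)]


def render_contrast_alignment(
    node: HierarchyNode,
    aln: Alignment,
    profile: ColumnProfile,
    weights=None,
    out_format: str = "text",
    max_rows: int = 10,
) -> str:
    """Render a contrast alignment for one hierarchy node.

    Pattern columns are colored by biochemical class for residues matching
    the pattern residue set and shown gray otherwise; below the rows come a
    selective-pressure bar row (0-9), the characteristic residue row, and
    its conservation digits in integer tenths.
    """
    if not node.pattern:
        banner = f"[no pattern] node {node.node_id}: no subgroup signal"
        return banner if out_format == "text" else f"<p>{_html.escape(banner)}</p>"

    pattern_by_col = {p.column: p for p in node.pattern}
    heights = dict(selective_pressure_heights(node))
    ncol = aln.n_columns
    fg_rows, bg_rows = _select_representatives(node, aln, weights, max_rows)

    bar_row = "".join(
        str(min(9, int(round(9 * heights.get(c, 0.0))))) if c in pattern_by_col else " "
        for c in range(1, ncol + 1)
    )
    char_row = []
    digit_row = []
    for c in range(1, ncol + 1):
        if c in pattern_by_col:
            p = pattern_by_col[c]
            aa = max(p.residue_set, key=lambda a: profile.frequencies[c - 1, AA20.index(a)])
            char_row.append(aa)
            digit_row.append(str(frequency_digit(float(profile.frequencies[c - 1, AA20.index(aa)]))))
        else:
            char_row.append(" ")
            digit_row.append(" ")
    char_row = "".join(char_row)
    digit_row = "".join(digit_row)

    name_w = max(len(r.id) for r in fg_rows + bg_rows) + 2
    pad = name_w + 1  # id field + group label + space

    if out_format == "text":
        lines = [f"# node {node.node_id} contrast alignment"]
        lines.append(" " * pad + bar_row)
        for label, rows in (("fg", fg_rows), ("bg", bg_rows)):
            for rec in rows:
                lines.append(f"{rec.id:<{name_w - 2}}{label} {rec.row}")
        lines.append(" " * pad + char_row)
        lines.append(" " * pad + digit_row)
        return "\n".join(lines) + "\n"

    if out_format != "html":
        raise ValueError(f"unknown output format: {out_format!r}")

    def span(ch: str, col: int) -> str:
        esc = _html.escape(ch)
        p = pattern_by_col.get(col)
        if p is not None and ch in p.residue_set:
            cls = classify_residue(ch)
            bg = f"background:{cls.highlight};" if cls.highlight else ""
            return f'<span style="color:{cls.foreground};{bg}">{esc}</span>'
        return f'<span style="color:#808080">{esc}</span>'

    out = [f"<pre><b>node {_html.escape(node.node_id)}</b>"]
    out.append(" " * pad + _html.escape(bar_row))
    for label, rows in (("fg", fg_rows), ("bg", bg_rows)):
        for rec in rows:
            cells = "".join(span(ch, c + 1) for c, ch in enumerate(rec.row))
            out.append(f"{_html.escape(rec.id):<{name_w - 2}}{label} " + cells)
    out.append(" " * pad + _html.escape(char_row))
    out.append(" " * pad + _html.escape(digit_row))
    out.append("</pre>")
    return "\n".join(out) + "\n"


_NODE_COLORS = ["red", "blue", "orange", "green", "purple", "teal"]


def write_viewer_script(
    structure,
    cmap,
    pattern_residues_by_node: dict[str, list[int]],
    dc_pairs: list[tuple[int, int]] | None = None,
    specific_pairs: set[tuple[int, int]] | None = None,
    cluster_center: int | None = None,
    dialect: str = "pymol",
) -> str:
    """Emit a molecular-viewer command script highlighting the constraints.

    Colors each node's pattern residues with a distinct color, draws a rod
    per DC pair (lineage-specific pairs on the 'magenta' channel, others
    'gray'), and labels the cluster center. Residues are addressed by
    author numbering of the mapped structure residues; inputs are column
    numbers, translated through ``cmap``; unmapped entries are skipped.
    """
    if dialect not in ("pymol", "chimerax"):
        raise ValueError(f"unknown viewer dialect: {dialect!r}")
    specific_pairs = {tuple(sorted(p)) for p in (specific_pairs or set())}
    chain = structure.chain_id

    def auth(col: int) -> int | None:
        ri = cmap.column_to_residue.get(col)
        return None if ri is None else structure.residues[ri].auth_number

    lines = [f"# rescon constraint highlights for {structure.structure_id} chain {chain}"]
    for ni, (node_id, cols) in enumerate(sorted(pattern_residues_by_node.items())):
        color = _NODE_COLORS[ni % len(_NODE_COLORS)]
        for col in sorted(cols):
            a = auth(col)
            if a is None:
                lines.append(f"# warning: column {col} (node {node_id}) unmapped; skipped")
                continue
            if dialect == "pymol":
                lines.append(f"color {color}, chain {chain} and resi {a}")
            else:
                lines.append(f"color /{chain}:{a} {color}")
    for k, (ci, cj) in enumerate(sorted(dc_pairs or [])):
        ai, aj = auth(ci), auth(cj)
        if ai is None or aj is None:
            lines.append(f"# warning: DC pair ({ci},{cj}) unmapped; skipped")
            continue
        color = "magenta" if (min(ci, cj), max(ci, cj)) in specific_pairs else "gray"
        if dialect == "pymol":
            lines.append(
                f"distance dc{k}, chain {chain} and resi {ai} and name CA, "
                f"chain {chain} and resi {aj} and name CA"
            )
            lines.append(f"color {color}, dc{k}")
        else:
            lines.append(f"distance /{chain}:{ai}@CA /{chain}:{aj}@CA color {color}")
    if cluster_center is not None:
        a = auth(cluster_center)
        if a is not None:
            if dialect == "pymol":
                lines.append(f'label chain {chain} and resi {a} and name CA, "center"')
            else:
                lines.append(f"label /{chain}:{a} text center")
    return "\n".join(lines) + "\n"
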