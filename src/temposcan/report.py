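"""Tabular summaries of a scan.

Writes the per-node summary table as TSV (tab-delimited, LF, UTF-8) with a
JSON twin holding identical values, in two modes: ``significant-only``
(nodes with temporal signal, mirroring the summary table a user inspects)
and ``all-nodes`` (every internal node, with eligibility diagnostics).

Column order: node_id, n_tips, p_value, slope, adj_r2, x_intercept,
significant; ``all-nodes`` appends ineligibility_reason. Floats are written
in shortest round-trip form so re-running on the same inputs yields
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from ._errors import ValidationError
from .scan import ScanResult
from .tree_io import DatedTree

__all__ = ["write_summary", "summary_rows", "write_node_scatter"]

_COLUMNS = ["node_id", "n_tips", "p_value", "slope", "adj_r2", "x_intercept",
            "significant"]


def summary_rows(scan: ScanResult, mode: str = "significant-only") -> list[dict]:
    """Rows of the summary table as dicts, preorder by node_id.

    Ineligible nodes (all-nodes mode only) have None statistics and carry
    their ineligibility reason. The JSON twin serializes exactly these rows.
    """
    if mode not in ("significant-only", "all-nodes"):
        raise ValidationError(f"unknown summary mode: {mode!r}")
    rows = []
    for rep in scan.reports:
        if mode == "significant-only" and not rep.significant:
            continue
        row: dict = {
            "node_id": rep.node_id,
            "n_tips": rep.n_tips,
            "p_value": rep.fit.p_value if rep.fit else None,
            "slope": rep.fit.slope if rep.fit else None,
            "adj_r2": rep.fit.adj_r2 if rep.fit else None,
            "x_intercept": rep.fit.x_intercept if rep.fit else None,
            "significant": rep.significant,
            "anchor": rep.anchor,
        }
        if mode == "all-nodes":
            row["ineligibility_reason"] = rep.ineligibility_reason
        rows.append(row)
    return rows


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_summary(
    scan: ScanResult, path: str | Path, mode: str = "significant-only"
) -> None:
    """Write the summary TSV at *path* and its JSON twin at ``<path>.json``
    (or with a ``.json`` suffix replacing ``.tsv``)."""
    path = Path(path)
    rows = summary_rows(scan, mode=mode)
    columns = list(_COLUMNS) + (
        ["ineligibility_reason"] if mode == "all-nodes" else []
    ) + ["anchor"]

    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_cell(row.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n")

    json_path = (
        path.with_suffix(".json") if path.suffix == ".tsv"
        else Path(str(path) + ".json")
    )
    payload = {
        "mode": mode,
        "alpha": scan.config.alpha,
        "correction": scan.config.correction,
        "tree_fingerprint": scan.tree_fingerprint,
        "rows": rows,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")


def write_node_scatter(
    tree: DatedTree, node_id: int, path: str | Path
) -> None:
    """Export (tip, date, distance) triples for one node's regression as TSV,
    for plotting in external tools."""
    from .scan import node_to_tip_distances

    if tree.tip_dates is None:
        raise ValidationError("tree has no tip dates")
    dmap = node_to_tip_distances(tree, node_id)
    tips = tree.descendant_tip_labels(node_id)
    lines = ["tip\tdate\tdistance"]
    for t in tips:
        lines.append(f"{t}\t{tree.tip_dates[t]!r}\t{dmap[t]!r}")
    Path(path).write_text("\n".join(lines) + "\n")
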