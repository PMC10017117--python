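"""Reading, validating and writing rooted dated trees.

Trees come in as Newick or Nexus (TRANSLATE tables resolved) with branch
lengths in substitutions/site. Sampling dates are decimal years embedded in
the tip labels — either as a delimited field (default: last ``_``-separated
token) or via a regex capture group. Before-common-era dates are plain
negative decimals (e.g. ``-400.5``).

A :class:`DatedTree` wraps a :class:`dendropy.Tree` and adds

* stable integer ``node_id``\\ s assigned in a deterministic preorder
  traversal (the order children appear in the file), so the same file always
  yields the same ids;
* a ``tip_dates`` mapping from tip label to decimal year.

Annotated output is Nexus with FigTree-style ``[&key=value,...]`` comments
per internal node carrying the scan statistics, so the file can be opened in
standard tree viewers and re-read losslessly.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import dendropy

from ._errors import TreeParseError, ValidationError

__all__ = [
    "DatedTree",
    "DateParseSpec",
    "read_tree",
    "parse_tip_dates",
    "write_annotated_tree",
    "calendar_to_decimal_year",
]

_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


@dataclass
class DateParseSpec:
    """How to pull a decimal-year date out of a tip label.

    Exactly one of the two modes is active: ``delimiter-field`` splits the
    label on ``delimiter`` and takes token ``field_index`` (negative counts
    from the end; the default ``-1`` is the last field), while ``regex``
    applies a pattern whose first capture group is the date.
    """

    mode: str = "delimiter-field"
    delimiter: str = "_"
    field_index: int = -1
    regex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("delimiter-field", "regex"):
            raise ValidationError(f"unknown date-parse mode: {self.mode!r}")
        if self.mode == "regex" and not self.regex:
            raise ValidationError("regex mode requires a pattern")
        if self.mode == "delimiter-field" and self.regex is not None:
            raise ValidationError(
                "delimiter-field mode and a regex pattern are mutually exclusive"
            )

    def parse(self, label: str) -> Optional[float]:
        """Return the decimal-year date in *label*, or None if unparsable."""
        if self.mode == "regex":
            m = re.search(self.regex, label)  # type: ignore[arg-type]
            if m is None or not m.groups():
                return None
            token = m.group(1)
        else:
            parts = label.split(self.delimiter)
            try:
                token = parts[self.field_index]
            except IndexError:
                return None
        try:
            value = float(token)
        except ValueError:
            return None
        return value if math.isfinite(value) else None


@dataclass
class DatedTree:
    """A rooted tree with branch lengths in substitutions/site and, once
    :func:`parse_tip_dates` has run, a decimal-year date per tip.

    ``node_id`` 0 is always the root; ids increase in preorder following the
    child order of the source file.
    """

    tree: dendropy.Tree
    tip_dates: Optional[dict[str, float]] = None
    _id_to_node: dict[int, dendropy.Node] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._id_to_node:
            self._assign_node_ids()

    # -- structure ---------------------------------------------------------

    def _assign_node_ids(self) -> None:
        self._id_to_node = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            node.node_id = i
            self._id_to_node[i] = node

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node(self, node_id: int) -> dendropy.Node:
        try:
            return self._id_to_node[node_id]
        except KeyError:
            raise ValidationError(f"no node with id {node_id}") from None

    def preorder_nodes(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_node_iter()

    def internal_node_ids(self) -> list[int]:
        return [n.node_id for n in self.preorder_nodes() if not n.is_leaf()]

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def descendant_tip_labels(self, node_id: int) -> list[str]:
        """Labels of tips below *node_id*, in tree (left-to-right) order."""
        node = self.node(node_id)
        if node.is_leaf():
            raise ValidationError(f"node {node_id} is a tip, not an internal node")
        return [leaf.taxon.label for leaf in node.leaf_iter()]

    def mrca_id(self, labels: list[str]) -> int:
        """node_id of the most recent common ancestor of the given tips."""
        known = set(self.tip_labels)
        missing = [t for t in labels if t not in known]
        if missing:
            raise ValidationError(f"tips not in tree: {', '.join(sorted(missing))}")
        if len(labels) < 2:
            raise ValidationError("MRCA needs at least two tip labels")
        node = self.tree.mrca(taxon_labels=labels)
        return node.node_id

    # -- dates -------------------------------------------------------------

    def date_of(self, label: str) -> float:
        if self.tip_dates is None:
            raise ValidationError("tip dates have not been parsed yet")
        return self.tip_dates[label]

    def with_dates(self, dates: dict[str, float]) -> "DatedTree":
        """A view of the same topology with a different date assignment."""
        return DatedTree(self.tree, dict(dates), dict(self._id_to_node))

    # -- serialization -----------------------------------------------------

    def as_newick(self) -> str:
        return _newick_string(self.root) + ";"

    def fingerprint(self) -> str:
        """Hash of topology + branch lengths + dates (hex digest)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.as_newick().encode())
        if self.tip_dates:
            for label in sorted(self.tip_dates):
                h.update(f"{label}={self.tip_dates[label]!r};".encode())
        return h.hexdigest()


def _newick_string(node: dendropy.Node, comment: Optional[dict] = None) -> str:
    """Plain Newick for the subtree at *node*; shortest-round-trip floats."""
    if node.is_leaf():
        core = _quote_label(node.taxon.label)
    else:
        core = "(" + ",".join(_newick_string(c) for c in node.child_nodes()) + ")"
    if node.edge.length is not None:
        core += f":{node.edge.length!r}"
    return core


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`<>+-]|^$")


def _quote_label(label: str) -> str:
    # '-' appears in negative dates embedded in labels; Newick tolerates it
    # unquoted in practice, but quote anything else that is structural.
    if re.search(r"[\s()\[\]{},;:='\"]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_tree(path: str | Path, format: str = "auto") -> DatedTree:
    """Read a rooted tree from a Newick or Nexus file.

    Returns a :class:`DatedTree` without tip dates (run
    :func:`parse_tip_dates` next). Underscores in labels are preserved
    verbatim, never turned into spaces. A root with three or more children is
    accepted but triggers a warning, since such a basal polytomy usually
    means the rooting is arbitrary.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"tree file not found: {path}")
    if format not in ("newick", "nexus", "auto"):
        raise ValidationError(f"unknown tree format: {format!r}")
    if format == "auto":
        head = path.read_text(errors="replace").lstrip()[:6].upper()
        format = "nexus" if head.startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=format,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeParseError(f"cannot parse {path} as {format}: {exc}") from exc
    return _validate_structure(tree)


def _validate_structure(tree: dendropy.Tree) -> DatedTree:
    tree.is_rooted = True
    missing, negative = [], []
    root = tree.seed_node
    skip_edges = {root.edge}
    if len(root.child_nodes()) == 1:
        # leftover root edge (collapsed below, once lengths are validated):
        # its child's edge length may legitimately be absent
        skip_edges.add(root.child_nodes()[0].edge)
    for node in tree.preorder_node_iter():
        if node.edge in skip_edges:
            continue
        edge_name = node.taxon.label if node.is_leaf() else "internal node"
        if node.edge.length is None:
            missing.append(edge_name)
        elif node.edge.length < 0:
            negative.append(f"{edge_name} ({node.edge.length})")
    if missing:
        raise ValidationError(
            f"{len(missing)} edge(s) without a branch length "
            f"(edges above: {', '.join(missing)})"
        )
    if negative:
        raise ValidationError(
            f"negative branch length(s) on edge(s) above: {', '.join(negative)}"
        )

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    dups = sorted({x for x in labels if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"duplicate tip labels: {', '.join(dups)}")

    n_children = len(root.child_nodes())
    if n_children == 1:
        if root.child_nodes()[0].is_leaf():
            raise ValidationError("tree has fewer than two lineages at the root")
        tree.suppress_unifurcations()
        tree.seed_node.edge.length = None
        n_children = len(tree.seed_node.child_nodes())
    if n_children < 2:
        raise ValidationError("tree has fewer than two lineages at the root")
    if n_children >= 3:
        warnings.warn(
            f"root has {n_children} children (basal polytomy): the rooting "
            "may be arbitrary; interpret root-level statistics with care",
            UserWarning,
            stacklevel=2,
        )
    return DatedTree(tree)


def parse_tip_dates(
    tree: DatedTree,
    spec: Optional[DateParseSpec] = None,
    on_missing: str = "error",
) -> DatedTree:
    """Extract decimal-year sampling dates from tip labels.

    With ``on_missing='error'`` (default) any tip whose label yields no
    finite date aborts with a message listing every offender. With
    ``on_missing='prune'`` such tips are removed and the resulting
    unifurcations collapsed (branch lengths summed), so root-to-tip distances
    of the remaining tips are unchanged; the pruned labels are reported in a
    warning.
    """
    if spec is None:
        spec = DateParseSpec()
    if on_missing not in ("error", "prune"):
        raise ValidationError(f"unknown on_missing policy: {on_missing!r}")

    dates: dict[str, float] = {}
    undated: list[str] = []
    for label in tree.tip_labels:
        value = spec.parse(label)
        if value is None:
            undated.append(label)
        else:
            dates[label] = value

    if undated:
        if on_missing == "error":
            raise ValidationError(
                "no parsable sampling date in tip label(s): "
                + ", ".join(undated)
            )
        if len(dates) < 3:
            raise ValidationError(
                f"pruning {len(undated)} undated tip(s) would leave "
                f"{len(dates)} dated tips; at least 3 are required"
            )
        warnings.warn(
            f"pruned {len(undated)} undated tip(s): {', '.join(undated)}",
            UserWarning,
            stacklevel=2,
        )
        pruned = tree.tree.clone(depth=1)
        taxa = [t for t in pruned.taxon_namespace if t.label in set(undated)]
        pruned.prune_taxa(taxa, suppress_unifurcations=True)
        # prune_taxa can leave a root edge behind; drop it.
        if pruned.seed_node.edge.length is not None:
            pruned.seed_node.edge.length = None
        return DatedTree(pruned, dates)

    return DatedTree(tree.tree, dates, dict(tree._id_to_node))


def calendar_to_decimal_year(year: int, month: int, day: int) -> float:
    """Convert a calendar date to a decimal year.

    The day is placed at its midpoint: ``year + (day_of_year - 0.5) / days``.
    """
    import datetime

    d = datetime.date(year, month, day)
    day_of_year = d.timetuple().tm_yday
    days = 366 if d.year % 4 == 0 and (d.year % 100 != 0 or d.year % 400 == 0) else 365
    return year + (day_of_year - 0.5) / days


# -- annotated Nexus output ------------------------------------------------


def write_annotated_tree(tree: DatedTree, scan, path: str | Path) -> None:
    """Write a Nexus file whose internal nodes carry the scan statistics.

    Each internal node gets a FigTree-style comment
    ``[&node_id=..,anchor=..,signal=..,p=..,slope=..,adj_r2=..,x_intercept=..]``
    placed after its closing parenthesis; ineligible nodes carry ``signal=0``
    and their ineligibility reason instead of statistics. Branch lengths are
    written with shortest-round-trip floats, so re-reading recovers them
    bit-identically.
    """
    from .scan import ScanResult  # local import to avoid a cycle

    if not isinstance(scan, ScanResult):
        raise ValidationError("write_annotated_tree expects a ScanResult")
    if scan.tree_fingerprint != tree.fingerprint():
        raise ValidationError("scan result was not produced from this tree")

    by_id = {r.node_id: r for r in scan.reports}

    def annotate(node: dendropy.Node) -> str:
        if node.is_leaf():
            core = _quote_label(node.taxon.label)
        else:
            core = "(" + ",".join(annotate(c) for c in node.child_nodes()) + ")"
            rep = by_id.get(node.node_id)
            if rep is not None:
                fields = [f"node_id={rep.node_id}", f"anchor={rep.anchor}"]
                if rep.eligible and rep.fit is not None:
                    fields += [
                        f"signal={1 if rep.significant else 0}",
                        f"p={rep.fit.p_value!r}",
                        f"slope={rep.fit.slope!r}",
                        f"adj_r2={rep.fit.adj_r2!r}",
                    ]
                    if rep.fit.x_intercept is not None:
                        fields.append(f"x_intercept={rep.fit.x_intercept!r}")
                else:
                    fields += ["signal=0", f"ineligible={rep.ineligibility_reason}"]
                core += "[&" + ",".join(fields) + "]"
        if node.edge.length is not None:
            core += f":{node.edge.length!r}"
        return core

    labels = tree.tip_labels
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(labels)};",
        "    TAXLABELS",
        *[f"        {_quote_label(t)}" for t in labels],
        "    ;",
        "END;",
        "BEGIN TREES;",
        f"    TREE scan = [&R] {annotate(tree.root)};",
        "END;",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_annotations(path: str | Path) -> dict[int, dict[str, float]]:
    """Recover the per-node statistics written by :func:`write_annotated_tree`.

    Returns a mapping node_id -> {key: value} for every annotated internal
    node, with numeric values parsed back to floats.
    """
    tree = dendropy.Tree.get(
        path=str(path),
        schema="nexus",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        extract_comment_metadata=True,
    )
    out: dict[int, dict] = {}
    for node in tree.preorder_node_iter():
        meta = {a.name: a.value for a in node.annotations}
        if "node_id" in meta:
            parsed = {}
            for k, v in meta.items():
                try:
                    parsed[k] = float(v)
                except (TypeError, ValueError):
                    parsed[k] = v
            out[int(parsed["node_id"])] = parsed
    return out
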