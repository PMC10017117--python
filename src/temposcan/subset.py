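"""Clade sub-alignment extraction restricted to variant sites.

Once a clade with temporal signal has been identified, the natural next step
is a tip-dating run on just that clade. This module pulls the descendant
tips of a chosen node out of a nucleotide alignment and keeps only the
columns that are variant *within the clade* — a column that varies across
the full alignment but is constant among the clade's sequences is dropped.

A column is variant when it shows at least two distinct unambiguous
nucleotide states (A, C, G, T after upper-casing; U is treated as T). Gaps
(``-``, ``.``) and IUPAC ambiguity codes (N, R, Y, S, W, K, M, B, D, H, V)
are ignored by default, so missing data never creates spurious variation;
``gaps_as_state=True`` opts in to counting the gap as a fifth state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence
import warnings

from Bio import SeqIO

from ._errors import ValidationError
from .tree_io import DatedTree

__all__ = [
    "Alignment",
    "SubAlignment",
    "read_fasta",
    "match_alignment_to_tree",
    "variant_columns",
    "make_subset_fasta",
]

_REAL_STATES = frozenset("ACGT")
_IGNORED = frozenset("-.NRYSWKMBDHV?")
_GAPS = frozenset("-.")


@dataclass
class Alignment:
    """An in-memory nucleotide alignment: ordered name -> sequence map.

    Sequences are upper-cased on load, with U folded to T. All sequences
    must have identical length and names must be unique.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise ValidationError(
                f"alignment sequences have unequal lengths: {sorted(lengths)}"
            )
        self.records = {
            name: seq.upper().replace("U", "T") for name, seq in self.records.items()
        }

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values()))) if self.records else 0

    @property
    def names(self) -> list[str]:
        return list(self.records)


@dataclass
class SubAlignment:
    """Descendant-tip sequences restricted to variant columns.

    ``kept_columns`` are the original 0-based column indices, ascending;
    ``variant_rule`` records how variance was defined.
    """

    records: dict[str, str]
    kept_columns: list[int]
    variant_rule: str


def read_fasta(path: str | Path) -> Alignment:
    """Load a FASTA alignment (multi-line or single-line records)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"alignment file not found: {path}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate record name in alignment: {rec.id}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return Alignment(records)


def match_alignment_to_tree(
    aln: Alignment, tree: DatedTree
) -> tuple[list[str], list[str], list[str]]:
    """Exact-string matching of tip labels against record names.

    Returns (matched, tips_missing_from_alignment, alignment_only_extras).
    Any tree tip without an alignment record is an error; extra alignment
    records only produce a warning.
    """
    tips = tree.tip_labels
    names = set(aln.records)
    matched = [t for t in tips if t in names]
    missing = [t for t in tips if t not in names]
    extras = sorted(names - set(tips))
    if missing:
        raise ValidationError(
            "tree tip(s) absent from alignment: " + ", ".join(missing)
        )
    if extras:
        warnings.warn(
            f"alignment has {len(extras)} record(s) not in the tree: "
            + ", ".join(extras),
            UserWarning,
            stacklevel=2,
        )
    return matched, missing, extras


def variant_columns(
    seqs: Sequence[str], gaps_as_state: bool = False
) -> list[int]:
    """0-based indices of columns with >= 2 distinct states, ascending.

    States counted are A/C/G/T; with ``gaps_as_state`` the gap characters
    ``-`` and ``.`` count as one additional state. Ambiguity codes never
    count.
    """
    if len(seqs) < 2:
        raise ValidationError("variant-column detection needs at least 2 sequences")
    if len({len(s) for s in seqs}) > 1:
        raise ValidationError("sequences have unequal lengths")
    seqs = [s.upper().replace("U", "T") for s in seqs]
    out: list[int] = []
    for col in range(len(seqs[0])):
        states = set()
        for s in seqs:
            c = s[col]
            if c in _REAL_STATES:
                states.add(c)
            elif gaps_as_state and c in _GAPS:
                states.add("-")
            if len(states) >= 2:
                break
        if len(states) >= 2:
            out.append(col)
    return out


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width)) or ""


def make_subset_fasta(
    aln: Alignment,
    tree: DatedTree,
    node_id: int,
    out: str | Path,
    gaps_as_state: bool = False,
) -> SubAlignment:
    """Write the variant-sites FASTA for the clade at *node_id*.

    The output contains exactly the descendant tips of the node, in tree
    (left-to-right) order, with sequences restricted to the columns variant
    within that subset. A sidecar ``<out>.sites.txt`` lists the kept columns
    1-based for human cross-reference along with the variance rule used.
    """
    match_alignment_to_tree(aln, tree)
    tips = tree.descendant_tip_labels(node_id)
    present = [t for t in tips if t in aln.records]
    if len(present) < 2:
        raise ValidationError(
            f"node {node_id} has {len(present)} descendant tip(s) in the "
            "alignment; at least 2 are required"
        )

    seqs = [aln.records[t] for t in present]
    cols = variant_columns(seqs, gaps_as_state=gaps_as_state)
    if not cols:
        warnings.warn(
            f"clade at node {node_id} has no variant sites; writing "
            "empty-length records",
            UserWarning,
            stacklevel=2,
        )
    rule = (
        ">=2 distinct states among A,C,G,T plus gap" if gaps_as_state
        else ">=2 distinct states among A,C,G,T; gaps and ambiguity codes ignored"
    )
    records = {t: "".join(aln.records[t][c] for c in cols) for t in present}

    out = Path(out)
    chunks = []
    for name, seq in records.items():
        body = _wrap(seq)
        chunks.append(f">{name}\n{body}\n" if body else f">{name}\n")
    out.write_text("".join(chunks))

    sidecar = out.with_suffix(out.suffix + ".sites.txt")
    lines = [
        f"# variant sites kept for node {node_id} ({len(present)} sequences)",
        f"# rule: {rule}",
        "# columns are 1-based positions in the original alignment",
        *[str(c + 1) for c in cols],
        "",
    ]
    sidecar.write_text("\n".join(lines))

    return SubAlignment(records=records, kept_columns=cols, variant_rule=rule)
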