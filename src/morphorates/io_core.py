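"""Shared data model and readers/writers for the pipeline's input formats.

The pipeline touches four kinds of input: a discrete character matrix
(NEXUS or TNT ``xread``), a rooted tree in Newick, a stratigraphic range
table (CSV/TSV with first/last appearance dates), and a time-bin table.
Everything is validated into the small set of types defined here.

Conventions used throughout the package: ages are Ma before present,
durations are Myr, both as floats.  A character cell is either a single
state (small non-negative integer), a set of states (polymorphism or
uncertainty), or missing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

#: Sentinel for a missing / inapplicable cell.
MISSING = None

Cell = "frozenset[int] | None"


class ParseError(ValueError):
    """A file failed validation against its declared format."""


class LabelMismatchError(ValueError):
    """Tip labels and matrix taxon labels do not agree."""


# ---------------------------------------------------------------------------
# CharacterMatrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters, with missing cells and polymorphisms.

    Parameters
    ----------
    taxon_labels
        Ordered, unique taxon names (rows).
    cells
        ``cells[i][j]`` is a ``frozenset`` of integer states for taxon *i*,
        character *j*, or ``None`` when the cell is missing.  A singleton
        set is an ordinary coded state; a larger set is a polymorphism.
    ordering
        Per-character flag, ``"ordered"`` or ``"unordered"``.  Defaults to
        all-unordered, the treatment used for equally weighted cladistic
        characters.
    weights
        Per-character non-negative weights; default all 1.
    """

    taxon_labels: list[str]
    cells: list[list["frozenset[int] | None"]]
    ordering: list[str] = field(default_factory=list)
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ParseError("taxon labels are not unique")
        if len(self.cells) != len(self.taxon_labels):
            raise ParseError(
                f"{len(self.taxon_labels)} labels but {len(self.cells)} rows"
            )
        lengths = {len(row) for row in self.cells}
        if len(lengths) > 1:
            raise ParseError(f"ragged matrix: row lengths {sorted(lengths)}")
        n = self.n_characters
        if not self.ordering:
            self.ordering = ["unordered"] * n
        if len(self.ordering) != n:
            raise ParseError("ordering flags do not match character count")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,) or np.any(self.weights < 0):
            raise ParseError("weights must be per-character and non-negative")
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell is not None and (len(cell) == 0 or min(cell) < 0):
                    raise ParseError(
                        f"invalid cell for taxon {self.taxon_labels[i]!r}, "
                        f"character {j + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    @property
    def state_counts(self) -> list[int]:
        """Number of distinct observed states per character."""
        counts = []
        for j in range(self.n_characters):
            observed: set[int] = set()
            for row in self.cells:
                if row[j] is not None:
                    observed |= row[j]
            counts.append(len(observed))
        return counts

    def alphabet_sizes(self) -> list[int]:
        """Per-character alphabet size (max observed state + 1, min 1)."""
        sizes = []
        for j in range(self.n_characters):
            mx = -1
            for row in self.cells:
                if row[j] is not None:
                    mx = max(mx, max(row[j]))
            sizes.append(max(mx + 1, 1))
        return sizes

    def scored_mask(self) -> np.ndarray:
        """Boolean (taxa x characters) array, True where the cell is coded."""
        return np.array(
            [[cell is not None for cell in row] for row in self.cells], dtype=bool
        )

    def row(self, label: str) -> list["frozenset[int] | None"]:
        return self.cells[self.taxon_labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_labels.index(l) for l in labels]
        return CharacterMatrix(
            taxon_labels=list(labels),
            cells=[self.cells[i] for i in idx],
            ordering=list(self.ordering),
            weights=self.weights.copy(),
        )


# ---------------------------------------------------------------------------
# Stratigraphic ranges and time bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratRange:
    """Observed stratigraphic range of one taxon.

    ``fad`` is the first-appearance date and ``lad`` the last-appearance
    date, both in Ma before present, so ``fad >= lad > 0``.
    """

    taxon: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad):
            raise ValueError(
                f"taxon {self.taxon!r}: fad ({self.fad}) < lad ({self.lad})"
            )
        if self.lad <= 0:
            raise ValueError(f"taxon {self.taxon!r}: lad must be positive Ma")


@dataclass
class TimeBins:
    """Ordered, non-overlapping time intervals.

    Each bin is ``(label, start, end)`` with ``start > end`` in Ma (start is
    the older boundary).  Bins are ordered oldest first.
    """

    bins: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, start, end in self.bins:
            if not start > end:
                raise ValueError(f"bin {label!r}: start ({start}) <= end ({end})")
        for (la, sa, ea), (lb, sb, eb) in zip(self.bins, self.bins[1:]):
            if ea < sb:
                raise ValueError(f"bins {la!r} and {lb!r} overlap or are unordered")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    @property
    def durations(self) -> np.ndarray:
        return np.array([s - e for _, s, e in self.bins])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for _, s, e in self.bins])

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)


#: Default disparity bins: eleven Late Permian - Early Jurassic stage /
#: substage intervals, boundaries anchored at the Permo-Triassic boundary
#: (252 Ma) and consistent with the stated interval durations (Myr):
#: WUC-CH 5, IND-OLE 7, ANS 4, LAD 6, CRN 7, early NOR 4, mid NOR 12,
#: late NOR-RHT 10, HET 5, SIN 7, PLB 7.
DEFAULT_TIME_BINS = TimeBins(
    [
        ("t1 Wuchiapingian-Changhsingian", 257.0, 252.0),
        ("t2 Induan-Olenekian", 252.0, 245.0),
        ("t3 Anisian", 245.0, 241.0),
        ("t4 Ladinian", 241.0, 235.0),
        ("t5 Carnian", 235.0, 228.0),
        ("t6 Early Norian", 228.0, 224.0),
        ("t7 Middle Norian", 224.0, 212.0),
        ("t8 Late Norian-Rhaetian", 212.0, 202.0),
        ("t9 Hettangian", 202.0, 197.0),
        ("t10 Sinemurian", 197.0, 190.0),
        ("t11 Pliensbachian", 190.0, 183.0),
    ]
)

#: Default rate bins: the disparity bins up to the Rhaetian, with the three
#: Jurassic stages pooled into one interval (few branches realize rates
#: there), giving nine intervals in all.
DEFAULT_RATE_BINS = TimeBins(
    list(DEFAULT_TIME_BINS.bins[:8]) + [("t9-t11 Jurassic", 202.0, 183.0)]
)


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------


@dataclass
class DatedTree:
    """A rooted tree whose edge lengths are branch durations in Myr.

    ``root_age`` (Ma) anchors the tree in absolute time; node ages are
    ``root_age`` minus root-to-node path length.  A topology-only tree
    (no branch lengths) has ``root_age = None``.
    """

    tree: dendropy.Tree
    root_age: "float | None" = None

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def has_lengths(self) -> bool:
        return all(
            e.length is not None
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Node age (Ma) for every node; requires branch lengths + root_age."""
        if self.root_age is None:
            raise ValueError("tree has no root age; calibrate it first")
        ages: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                ages[node] = self.root_age
            else:
                ages[node] = ages[node.parent_node] - (node.edge.length or 0.0)
        return ages

    def branches(self) -> list[dendropy.Edge]:
        """All edges with a parent (i.e. excluding the root's stub edge)."""
        return [
            e
            for e in self.tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        ]

    def label_of(self, node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or f"node{id(node)}"

    def check_against_matrix(self, m: CharacterMatrix) -> None:
        missing = set(self.tip_labels) - set(m.taxon_labels)
        if missing:
            raise LabelMismatchError(
                f"tips absent from character matrix: {sorted(missing)}"
            )

    def clone(self) -> "DatedTree":
        return DatedTree(self.tree.clone(depth=1), self.root_age)


# ---------------------------------------------------------------------------
# Character matrix I/O
# ---------------------------------------------------------------------------

_STATE_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"


def _symbol_to_state(sym: str) -> int:
    sym = sym.upper()
    if sym not in _STATE_SYMBOLS:
        raise ParseError(f"unknown state symbol {sym!r}")
    return _STATE_SYMBOLS.index(sym)


def _parse_row_symbols(line: str, taxon: str) -> list["frozenset[int] | None"]:
    """Parse one row of compact state symbols into cells."""
    cells: list["frozenset[int] | None"] = []
    i = 0
    while i < len(line):
        c = line[i]
        if c.isspace():
            i += 1
            continue
        if c in "?-":
            cells.append(MISSING)
            i += 1
        elif c in "({[":
            closer = {"(": ")", "{": "}", "[": "]"}[c]
            j = line.find(closer, i)
            if j < 0:
                raise ParseError(f"taxon {taxon!r}: unclosed polymorphism {line[i:]!r}")
            members = frozenset(
                _symbol_to_state(s) for s in line[i + 1 : j] if not s.isspace()
            )
            if not members:
                raise ParseError(f"taxon {taxon!r}: empty polymorphism")
            cells.append(members)
            i = j + 1
        else:
            try:
                cells.append(frozenset([_symbol_to_state(c)]))
            except ParseError as exc:
                raise ParseError(
                    f"taxon {taxon!r}, character {len(cells) + 1}: {exc}"
                ) from None
            i += 1
    return cells


def _read_nexus_matrix(path: "str | Path") -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block via dendropy."""
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"NEXUS parse failure in {path}: {exc}") from exc
    labels: list[str] = []
    cells: list[list["frozenset[int] | None"]] = []
    declared = None
    FUNDAMENTAL = 0  # dendropy StateAlphabet denominations
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        row: list["frozenset[int] | None"] = []
        for state in seq:
            if state.state_denomination == FUNDAMENTAL:
                if state.symbol in ("?", "-"):
                    row.append(MISSING)
                else:
                    row.append(frozenset([_symbol_to_state(state.symbol)]))
                continue
            # ambiguous ('?', '{..}') or polymorphic ('(..)') state
            syms = {s.symbol for s in (state.member_states or ())}
            if not syms or "?" in syms or "-" in syms:
                row.append(MISSING)
            else:
                row.append(frozenset(_symbol_to_state(s) for s in syms))
        labels.append(taxon.label)
        if declared is None:
            declared = len(row)
        elif len(row) != declared:
            raise ParseError(
                f"taxon {taxon.label!r}: {len(row)} characters, expected {declared}"
            )
        cells.append(row)
    return CharacterMatrix(taxon_labels=labels, cells=cells)


def _read_tnt_matrix(path: "str | Path") -> CharacterMatrix:
    """Read a TNT ``xread`` block (hand parser; no library reads TNT)."""
    text = Path(path).read_text()
    # strip comments in single quotes after xread, and TNT 'comments' blocks
    m = re.search(r"xread\b", text, flags=re.IGNORECASE)
    if not m:
        raise ParseError(f"{path}: no xread block found")
    rest = text[m.end() :]
    # optional quoted title
    rest = re.sub(r"^\s*'[^']*'", "", rest, count=1)
    header = re.match(r"\s*(\d+)\s+(\d+)", rest)
    if not header:
        raise ParseError(f"{path}: xread header (nchar ntax) not found")
    nchar, ntax = int(header.group(1)), int(header.group(2))
    body = rest[header.end() :]
    stop = body.find(";")
    if stop >= 0:
        body = body[:stop]
    labels: list[str] = []
    cells: list[list["frozenset[int] | None"]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line or line.startswith("&"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"{path}: malformed xread row {line!r}")
        taxon, states = parts
        row = _parse_row_symbols(states, taxon)
        if len(row) != nchar:
            raise ParseError(
                f"taxon {taxon!r}: {len(row)} characters, header declares {nchar}"
            )
        labels.append(taxon)
        cells.append(row)
    if len(labels) != ntax:
        raise ParseError(f"{path}: {len(labels)} taxa, header declares {ntax}")
    return CharacterMatrix(taxon_labels=labels, cells=cells)


def read_character_matrix(path: "str | Path", dialect: str = "nexus") -> CharacterMatrix:
    """Read a discrete character matrix.

    ``?`` and ``-`` are treated as missing; ``(ab)`` / ``{ab}`` as
    polymorphisms.  ``dialect`` is ``"nexus"`` (canonical) or ``"tnt"``.
    """
    if dialect == "nexus":
        return _read_nexus_matrix(path)
    if dialect == "tnt":
        return _read_tnt_matrix(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'nexus' or 'tnt')")


def _format_cell(cell: "frozenset[int] | None") -> str:
    if cell is None:
        return "?"
    if len(cell) == 1:
        return _STATE_SYMBOLS[next(iter(cell))]
    return "(" + "".join(_STATE_SYMBOLS[s] for s in sorted(cell)) + ")"


def write_character_matrix(
    m: CharacterMatrix, path: "str | Path", dialect: str = "nexus"
) -> None:
    """Write a matrix in NEXUS (CHARACTERS block) or TNT xread format."""
    out = io.StringIO()
    name_w = max(len(l) for l in m.taxon_labels) + 2
    if dialect == "nexus":
        symbols = " ".join(_STATE_SYMBOLS[: max(max(m.alphabet_sizes()), 2)])
        out.write("#NEXUS\n\nBEGIN DATA;\n")
        out.write(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};\n")
        out.write(
            f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
        )
        out.write("  MATRIX\n")
        for label, row in zip(m.taxon_labels, m.cells):
            states = "".join(_format_cell(c) for c in row)
            out.write(f"    {label.replace(' ', '_'):<{name_w}}{states}\n")
        out.write("  ;\nEND;\n")
    elif dialect == "tnt":
        out.write(f"xread\n{m.n_characters} {m.n_taxa}\n")
        for label, row in zip(m.taxon_labels, m.cells):
            states = "".join(_format_cell(c) for c in row)
            out.write(f"{label.replace(' ', '_'):<{name_w}}{states}\n")
        out.write(";\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text(out.getvalue())


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------


def read_tree(
    path: "str | Path",
    matrix: "CharacterMatrix | None" = None,
    root_age: "float | None" = None,
) -> DatedTree:
    """Read a rooted Newick tree.

    Branch lengths, when present, are interpreted as durations in Myr.
    If ``matrix`` is given, tip labels are checked against its taxa.
    If ``root_age`` is omitted but lengths are present, the root age is set
    so that the shallowest tip sits at age 0 (relative chronology).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise ParseError(f"Newick parse failure in {path}: {exc}") from exc
    dated = DatedTree(tree=tree, root_age=None)
    if matrix is not None:
        dated.check_against_matrix(matrix)
    if dated.has_lengths:
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        dated.root_age = root_age if root_age is not None else float(max(depths))
    return dated


def write_tree(t: DatedTree, path: "str | Path") -> None:
    """Write Newick with branch lengths = durations (Myr) when present."""
    t.tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_from_newick(newick: str, root_age: "float | None" = None) -> DatedTree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    dated = DatedTree(tree=tree, root_age=root_age)
    if root_age is None and dated.has_lengths:
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        dated.root_age = float(max(depths))
    return dated


# ---------------------------------------------------------------------------
# Range table I/O
# ---------------------------------------------------------------------------


def read_ranges(path: "str | Path") -> list[StratRange]:
    """Read a delimited table with columns ``taxon``, ``fad``, ``lad``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"taxon", "fad", "lad"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: range table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    ranges = []
    for rec in df.itertuples(index=False):
        try:
            ranges.append(
                StratRange(taxon=str(rec.taxon), fad=float(rec.fad), lad=float(rec.lad))
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from None
    return ranges


def write_ranges(ranges: Iterable[StratRange], path: "str | Path") -> None:
    pd.DataFrame(
        [(r.taxon, r.fad, r.lad) for r in ranges], columns=["taxon", "fad", "lad"]
    ).to_csv(path, index=False)
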