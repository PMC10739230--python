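"""Labeled +/- compatibility matrices: parsing, writing, and forward prediction.

A :class:`CrossTable` stores the outcome of mon--mon and/or di--mon crosses
as a labeled matrix over {PLUS, MINUS, MISSING}.  Published crossing tables
are transcribed into CSV/TSV with the first column holding the row label;
en-dash and em-dash minus signs (as typeset in journals) are accepted on
input and ASCII "-" is emitted on output.

Matrices are stored as written (ordered), so asymmetric experimental
records can be represented; symmetry is an invariant *check*
(:meth:`CrossTable.symmetry_violations`), never a silent fix.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .mating import Dikaryon, MatingGenotype, compatible, dimon_compatible

__all__ = [
    "Cell",
    "RowKind",
    "CrossTable",
    "PanelSpec",
    "CrossTableParseError",
    "parse_cross_table",
    "write_cross_table",
    "predict_table",
]


class Cell(enum.Enum):
    PLUS = "+"
    MINUS = "-"
    MISSING = "?"


class RowKind(enum.Enum):
    MONOKARYON = "monokaryon"
    DIKARYON = "dikaryon"


_PLUS_SYMBOLS = {"+"}
_MINUS_SYMBOLS = {"-", "–", "—"}  # ASCII hyphen, en dash, em dash
_MISSING_SYMBOLS = {"?", ""}
# Footnote markers sometimes decorate published cells ("+*", "-**"); they
# carry no quantitative meaning in the available text and are stripped.
_FOOTNOTE_CHARS = "*"


class CrossTableParseError(ValueError):
    """Parse failure with row/column coordinates in the message."""


@dataclass
class CrossTable:
    """Labeled matrix of cross outcomes.

    ``row_kinds[i]`` says whether row ``i`` is a monokaryon (mon--mon cross
    against the columns) or a dikaryon (di--mon cross).  Columns are always
    monokaryons.
    """

    row_labels: list[str]
    col_labels: list[str]
    entries: list[list[Cell]]
    row_kinds: list[RowKind] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_kinds:
            self.row_kinds = [RowKind.MONOKARYON] * len(self.row_labels)
        if len(self.entries) != len(self.row_labels):
            raise ValueError("entry rows do not match row labels")
        for i, row in enumerate(self.entries):
            if len(row) != len(self.col_labels):
                raise ValueError(f"row {self.row_labels[i]!r} has {len(row)} cells, "
                                 f"expected {len(self.col_labels)}")
        if len(self.row_kinds) != len(self.row_labels):
            raise ValueError("row_kinds do not match row labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")

    def get(self, row: str, col: str) -> Cell:
        return self.entries[self.row_labels.index(row)][self.col_labels.index(col)]

    def count(self, cell: Cell) -> int:
        return sum(row.count(cell) for row in self.entries)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def subtable(self, rows: Sequence[str], cols: Sequence[str]) -> "CrossTable":
        ri = [self.row_labels.index(r) for r in rows]
        ci = [self.col_labels.index(c) for c in cols]
        return CrossTable(
            row_labels=list(rows),
            col_labels=list(cols),
            entries=[[self.entries[i][j] for j in ci] for i in ri],
            row_kinds=[self.row_kinds[i] for i in ri],
        )

    def symmetry_violations(self) -> list[tuple[str, str]]:
        """Pairs (r, c) where both orientations are scored and disagree.

        Only meaningful for mon--mon rows whose label also appears as a
        column.  Diagonal PLUS cells are also reported (self-compatibility
        is impossible under the tetrapolar model).
        """
        bad: list[tuple[str, str]] = []
        col_index = {c: j for j, c in enumerate(self.col_labels)}
        row_index = {r: i for i, r in enumerate(self.row_labels)}
        for i, r in enumerate(self.row_labels):
            if self.row_kinds[i] is not RowKind.MONOKARYON:
                continue
            for j, c in enumerate(self.col_labels):
                v = self.entries[i][j]
                if v is Cell.MISSING:
                    continue
                if r == c and v is Cell.PLUS:
                    bad.append((r, c))
                    continue
                if c in row_index and r in col_index:
                    w = self.entries[row_index[c]][col_index[r]]
                    if w is not Cell.MISSING and w is not v and r < c:
                        bad.append((r, c))
        return bad

    def to_text(self, dialect: str = "csv") -> str:
        return write_cross_table(self, dialect=dialect)


@dataclass
class PanelSpec:
    """A four-tester panel derived from one dikaryotic isolate.

    The testers are the four monobasidiospore mating types of the isolate,
    in the conventional order (AxBx, AxBy, AyBx, AyBy): testers 1 and 2
    share the first A allele, 3 and 4 the second; 1 and 3 share the first
    B allele, 2 and 4 the second.  Genotypes are optional (known only for
    fully typed panels).
    """

    isolate: str
    testers: list[str]
    genotypes: Optional[list[MatingGenotype]] = None

    def __post_init__(self) -> None:
        if len(self.testers) != 4:
            raise ValueError(f"panel {self.isolate!r} must have exactly 4 testers")
        if self.genotypes is not None:
            if len(self.genotypes) != 4:
                raise ValueError(f"panel {self.isolate!r}: need 4 genotypes")
            g = self.genotypes
            ok = (g[0].a == g[1].a and g[2].a == g[3].a and g[0].a != g[2].a
                  and g[0].b == g[2].b and g[1].b == g[3].b and g[0].b != g[1].b)
            if not ok:
                raise ValueError(
                    f"panel {self.isolate!r}: genotypes {[str(x) for x in g]} are not "
                    "a valid meiotic tester set (AxBx, AxBy, AyBx, AyBy)")


def _classify_symbol(raw: str, row: int, col: int) -> Cell:
    sym = raw.strip().strip(_FOOTNOTE_CHARS).strip()
    if sym in _PLUS_SYMBOLS:
        return Cell.PLUS
    if sym in _MINUS_SYMBOLS:
        return Cell.MINUS
    if sym in _MISSING_SYMBOLS:
        return Cell.MISSING
    raise CrossTableParseError(
        f"unknown cell symbol {raw!r} at data row {row}, column {col}")


def parse_cross_table(
    source: Union[str, Path],
    dialect: str = "auto",
    row_kinds: Union[RowKind, Mapping[str, RowKind], None] = None,
) -> CrossTable:
    """Parse a CSV/TSV compatibility matrix.

    ``source`` is a path or the raw text itself.  The header row carries
    the column labels; the first field of each data row is the row label.
    Cells: "+" -> PLUS; ASCII hyphen / en dash / em dash -> MINUS;
    "?" or blank -> MISSING; anything else is an error naming the cell.
    Footnote markers (``*``) are stripped.

    ``row_kinds`` may be a single :class:`RowKind` for all rows or a
    mapping from row label to kind (default: monokaryon).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)

    if dialect == "auto":
        dialect = "tsv" if "\t" in text.splitlines()[0] else "csv"
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise ValueError(f"unknown dialect {dialect!r}")

    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim)
            if any(f.strip() for f in r)]
    if not rows:
        raise CrossTableParseError("empty table")
    header = rows[0]
    col_labels = [h.strip() for h in header[1:]]
    if len(set(col_labels)) != len(col_labels):
        raise CrossTableParseError("duplicate column labels in header")

    row_labels: list[str] = []
    entries: list[list[Cell]] = []
    for i, row in enumerate(rows[1:], start=1):
        label = row[0].strip()
        if not label:
            raise CrossTableParseError(f"missing row label at data row {i}")
        if label in row_labels:
            raise CrossTableParseError(f"duplicate row label {label!r} at data row {i}")
        cells = row[1:]
        # Trailing blank fields may be omitted in hand-edited files; pad.
        if len(cells) < len(col_labels):
            cells = cells + [""] * (len(col_labels) - len(cells))
        if len(cells) > len(col_labels):
            raise CrossTableParseError(
                f"ragged row {label!r} (data row {i}): {len(cells)} cells for "
                f"{len(col_labels)} columns")
        row_labels.append(label)
        entries.append([_classify_symbol(c, i, j + 1) for j, c in enumerate(cells)])

    if row_kinds is None:
        kinds = [RowKind.MONOKARYON] * len(row_labels)
    elif isinstance(row_kinds, RowKind):
        kinds = [row_kinds] * len(row_labels)
    else:
        kinds = [row_kinds.get(r, RowKind.MONOKARYON) for r in row_labels]

    return CrossTable(row_labels, col_labels, entries, kinds)


def write_cross_table(table: CrossTable, dialect: str = "csv") -> str:
    """Serialize a table; MINUS is always emitted as ASCII "-", MISSING as blank."""
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    out = io.StringIO()
    writer = csv.writer(out, delimiter=delim, lineterminator="\n")
    writer.writerow([""] + table.col_labels)
    symbol = {Cell.PLUS: "+", Cell.MINUS: "-", Cell.MISSING: ""}
    for label, row in zip(table.row_labels, table.entries):
        writer.writerow([label] + [symbol[c] for c in row])
    return out.getvalue()


def predict_table(
    rows: Mapping[str, Union[MatingGenotype, Dikaryon]],
    cols: Mapping[str, MatingGenotype],
) -> CrossTable:
    """Forward model: predict every cross outcome from assigned genotypes.

    Rows may mix monokaryons (mon--mon rule: heteroallelic at both loci)
    and dikaryons (di--mon rule: either nucleus compatible).  Deterministic.
    """
    row_labels = list(rows)
    col_labels = list(cols)
    entries: list[list[Cell]] = []
    kinds: list[RowKind] = []
    for r in row_labels:
        obj = rows[r]
        if isinstance(obj, Dikaryon):
            kinds.append(RowKind.DIKARYON)
            entries.append([Cell.PLUS if dimon_compatible(obj, cols[c]) else Cell.MINUS
                            for c in col_labels])
        else:
            kinds.append(RowKind.MONOKARYON)
            entries.append([Cell.PLUS if compatible(obj, cols[c]) else Cell.MINUS
                            for c in col_labels])
    return CrossTable(row_labels, col_labels, entries, kinds)
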