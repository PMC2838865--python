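"""Reading and writing tab-delimited spot tables.

Input tables are generic TSV exports of image-quantification software
(one header row, one row per spot) carrying normalized,
background-compensated intensities for both channels.  A
:class:`ColumnMap` tells the reader which columns hold what and how to
recognize control spots; the :data:`CHIPSKIPPER` preset covers the
ChipSkipper export dialect.
"""

from __future__ import annotations

import enum
import fnmatch
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "Category",
    "ColumnMap",
    "SpotRecord",
    "ConfigurationError",
    "EmptyInputError",
    "read_array_table",
    "write_table",
    "CHIPSKIPPER",
    "PRESETS",
]


class Category(str, enum.Enum):
    """Design category of a spot."""

    GENE = "gene"
    SPIKE_IN = "spike_in"
    BACKGROUND = "background"
    NEGATIVE_CONTROL = "negative_control"
    SPECIFICITY_CONTROL = "specificity_control"


#: Categories that act as controls (excluded from gene-level grouping).
CONTROL_CATEGORIES = frozenset(
    {
        Category.SPIKE_IN,
        Category.BACKGROUND,
        Category.NEGATIVE_CONTROL,
        Category.SPECIFICITY_CONTROL,
    }
)


class ConfigurationError(ValueError):
    """A column mapping does not match the input table."""


class EmptyInputError(ValueError):
    """The input table contains no data rows."""


#: Default case-insensitive glob patterns used to recognize control spots
#: from the category-source column (clone names / type flags).
DEFAULT_CATEGORY_PATTERNS: dict[Category, tuple[str, ...]] = {
    Category.SPIKE_IN: ("spike*",),
    Category.BACKGROUND: ("bg*", "background*", "blank*", "buffer*", "empty*"),
    Category.NEGATIVE_CONTROL: ("neg*",),
    Category.SPECIFICITY_CONTROL: ("spec*",),
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from table columns to spot fields.

    Parameters
    ----------
    spot_id, clone_id, gene_name, category_source, signal_ch1, signal_ch2
        Header names of the respective columns.  ``category_source`` is the
        column whose values are matched against ``category_patterns`` (with
        ``gene_name`` as fallback) to classify control spots.
    block, row, col
        Optional grid-coordinate columns; read through but not interpreted.
    comment
        Optional free-text column.
    category_patterns
        Case-insensitive glob patterns per control category; a spot whose
        category-source value matches no pattern is a regular gene spot.
    """

    spot_id: str
    clone_id: str
    gene_name: str
    category_source: str
    signal_ch1: str
    signal_ch2: str
    block: str | None = None
    row: str | None = None
    col: str | None = None
    comment: str | None = None
    category_patterns: dict[Category, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PATTERNS)
    )

    def __post_init__(self) -> None:
        names = [
            self.spot_id,
            self.clone_id,
            self.gene_name,
            self.category_source,
            self.signal_ch1,
            self.signal_ch2,
        ]
        optional = [self.block, self.row, self.col, self.comment]
        names += [n for n in optional if n is not None]
        # clone/gene/category source may legitimately share a column;
        # the two signal channels never may.
        if self.signal_ch1 == self.signal_ch2:
            raise ConfigurationError("signal_ch1 and signal_ch2 must differ")
        if len({self.signal_ch1, self.signal_ch2} & {self.spot_id}) > 0:
            raise ConfigurationError("signal columns cannot double as spot_id")
        patterns = {
            Category(k): tuple(v) for k, v in self.category_patterns.items()
        }
        for cat, pats in patterns.items():
            if len(pats) == 0:
                raise ConfigurationError(f"category {cat.value} has no patterns")
        object.__setattr__(self, "category_patterns", patterns)

    @property
    def required_columns(self) -> list[str]:
        cols = [
            self.spot_id,
            self.clone_id,
            self.gene_name,
            self.category_source,
            self.signal_ch1,
            self.signal_ch2,
        ]
        # dedupe, keep order
        return list(dict.fromkeys(cols))

    def classify(self, *values: str) -> Category:
        """First matching pattern wins; unmatched values are gene spots."""
        lowered = [v.strip().lower() for v in values if v]
        for cat, pats in self.category_patterns.items():
            for pat in pats:
                p = pat.lower()
                if any(fnmatch.fnmatchcase(v, p) for v in lowered):
                    return cat
        return Category.GENE


#: Column mapping for the ChipSkipper normalized-export dialect.
CHIPSKIPPER = ColumnMap(
    spot_id="Spot",
    clone_id="Clone",
    gene_name="Name",
    category_source="Type",
    signal_ch1="Signal Ch1",
    signal_ch2="Signal Ch2",
    block="Block",
    row="Row",
    col="Column",
    comment="Comment",
)

#: Mapping used by :mod:`spotcall.simulate` output tables.
SIMULATED = ColumnMap(
    spot_id="spot_id",
    clone_id="clone_id",
    gene_name="gene_name",
    category_source="clone_id",
    signal_ch1="signal_ch1",
    signal_ch2="signal_ch2",
    comment="comment",
)

PRESETS: dict[str, ColumnMap] = {
    "chipskipper": CHIPSKIPPER,
    "simulated": SIMULATED,
}


@dataclass
class SpotRecord:
    """One spot: identity, design category and two channel intensities.

    Signals are normalized, background-compensated intensities on the
    linear scale (arbitrary fluorescence units).  A spot whose signals
    could not be parsed, or are negative, is kept with ``valid=False``
    and an annotated comment — never silently dropped.
    """

    spot_id: str
    clone_id: str
    gene_name: str
    category: Category
    signal_ch1: float
    signal_ch2: float
    comment: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.category, Category):
            self.category = Category(self.category)
        if self.valid:
            for s in (self.signal_ch1, self.signal_ch2):
                if not math.isfinite(s) or s < 0:
                    self.valid = False
                    break

    @property
    def usable_signals(self) -> bool:
        """True when both signals are finite and strictly positive."""
        return (
            self.valid
            and math.isfinite(self.signal_ch1)
            and math.isfinite(self.signal_ch2)
            and self.signal_ch1 > 0
            and self.signal_ch2 > 0
        )


def _parse_signal(raw: object) -> tuple[float, bool]:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        return math.nan, False
    if not math.isfinite(value) or value < 0:
        return value, False
    return value, True


def read_array_table(source: IO[str] | str, cmap: ColumnMap) -> list[SpotRecord]:
    """Parse a tab-delimited spot table into :class:`SpotRecord` objects.

    One record is produced per data row, in file order.  Rows with
    non-numeric or negative signals are retained with ``valid=False``
    and the problem noted in the comment field.

    Raises
    ------
    ConfigurationError
        If a mapped column is missing from the header.
    EmptyInputError
        If the table has no data rows.
    """
    try:
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError("input table is empty") from None
    missing = [c for c in cmap.required_columns if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            "input table lacks mapped column(s): " + ", ".join(missing)
        )
    if len(frame) == 0:
        raise EmptyInputError("input table contains no data rows")

    records: list[SpotRecord] = []
    has_comment = cmap.comment is not None and cmap.comment in frame.columns
    for tup in frame.itertuples(index=False):
        row = dict(zip(frame.columns, tup))
        clone = str(row[cmap.clone_id]).strip()
        gene = str(row[cmap.gene_name]).strip()
        if not clone:
            clone = gene  # grouping needs a non-empty key
        category = cmap.classify(str(row[cmap.category_source]), gene)
        s1, ok1 = _parse_signal(row[cmap.signal_ch1])
        s2, ok2 = _parse_signal(row[cmap.signal_ch2])
        comment = str(row[cmap.comment]) if has_comment else ""
        valid = ok1 and ok2
        if not valid:
            bad = []
            if not ok1:
                bad.append(f"ch1={row[cmap.signal_ch1]!r}")
            if not ok2:
                bad.append(f"ch2={row[cmap.signal_ch2]!r}")
            note = "invalid signal: " + ", ".join(bad)
            comment = f"{comment}; {note}" if comment else note
        records.append(
            SpotRecord(
                spot_id=str(row[cmap.spot_id]),
                clone_id=clone,
                gene_name=gene,
                category=category,
                signal_ch1=s1,
                signal_ch2=s2,
                comment=comment,
                valid=valid,
            )
        )
    return records


def _format_cell(value: object) -> str:
    if isinstance(value, float):
        return repr(value)  # round-trips exactly (>= 17 significant digits)
    if isinstance(value, enum.Enum):
        return str(value.value)
    if value is None:
        return ""
    if isinstance(value, (tuple, list)):
        return ",".join(_format_cell(v) for v in value)
    return str(value)


def write_table(records: Sequence[object], dest: IO[str] | str) -> None:
    """Write homogeneous dataclass records as a tab-delimited table.

    Floats are written with full precision so a write/read round trip
    preserves values exactly.  An empty record list yields a header-only
    file when the element type can be inferred, otherwise an empty file.
    """
    records = list(records)
    if records:
        first = type(records[0])
        if any(type(r) is not first for r in records):
            raise TypeError("records must be homogeneous")
        names = [f.name for f in dc_fields(first)]
    else:
        names = []

    lines: list[str] = []
    if names:
        lines.append("\t".join(names))
    for rec in records:
        lines.append("\t".join(_format_cell(getattr(rec, n)) for n in names))
    text = "\n".join(lines) + ("\n" if lines else "")

    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    else:
        dest.write(text)


def spot_header() -> list[str]:
    return [f.name for f in dc_fields(SpotRecord)]


def write_spot_table(records: Iterable[SpotRecord], dest: IO[str] | str) -> None:
    """Write SpotRecords with an explicit header even when empty."""
    records = list(records)
    if records:
        write_table(records, dest)
        return
    text = "\t".join(spot_header()) + "\n"
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    else:
        dest.write(text)
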