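"""Parsimony-informative sites and lineage-aware classification of polymorphic columns.

The central question: at which alignment columns do two lineages (say dicots
and monocots) carry different amino acids, and is each lineage fixed or
variable there? Columns are labelled:

* ``invariant`` -- one residue across all sequences;
* ``non_informative`` -- a lineage has no unambiguous residue at the column
  (the between-lineage contrast is undefined there);
* ``overlapping`` -- the two lineages share at least one residue;
* ``disjoint`` -- no shared residue, both lineages variable;
* ``fixed_variable`` -- no shared residue, one lineage fixed for a single
  residue while the other varies;
* ``strictly_dimorphic`` -- both lineages fixed, for different residues (the
  pattern of the F/Y active-site dimorphism).

A column is parsimony-informative when at least two distinct non-gap,
non-ambiguous states each occur in at least two sequences. By default only
parsimony-informative columns are classified, mirroring how such site tables
are usually reported.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .seq_core import AMINO_ACIDS, GAP, NUCLEOTIDES, CodonAlignment, ProteinAlignment


class SiteCategory(str, Enum):
    INVARIANT = "invariant"
    NON_INFORMATIVE = "non_informative"
    OVERLAPPING = "overlapping"
    DISJOINT = "disjoint"
    FIXED_VARIABLE = "fixed_variable"
    STRICTLY_DIMORPHIC = "strictly_dimorphic"


#: categories that indicate lineage-differential polymorphism (the Table-4 style set)
POLYMORPHIC_CATEGORIES = (
    SiteCategory.OVERLAPPING,
    SiteCategory.DISJOINT,
    SiteCategory.FIXED_VARIABLE,
    SiteCategory.STRICTLY_DIMORPHIC,
)


@dataclass(frozen=True)
class LineagePartition:
    """Mapping of sequence id -> lineage label; exactly two lineages."""

    mapping: tuple  # tuple of (id, label) pairs, kept hashable

    def __init__(self, mapping) -> None:
        if isinstance(mapping, dict):
            items = tuple(mapping.items())
        else:
            items = tuple(tuple(x) for x in mapping)
        object.__setattr__(self, "mapping", items)
        labels = sorted({lab for _, lab in items})
        if len(labels) != 2:
            raise ValueError(f"partition must define exactly two lineages, got {labels}")
        for lab in labels:
            n = sum(1 for _, l in items if l == lab)
            if n < 2:
                raise ValueError(f"lineage {lab!r} has {n} sequence(s); need at least 2")
        ids = [sid for sid, _ in items]
        if len(set(ids)) != len(ids):
            raise ValueError("partition lists a sequence id more than once")

    @property
    def labels(self) -> tuple:
        """The two lineage labels, sorted alphabetically."""
        return tuple(sorted({lab for _, lab in self.mapping}))

    def label_of(self, seq_id: str) -> str:
        for sid, lab in self.mapping:
            if sid == seq_id:
                return lab
        raise KeyError(seq_id)

    def group(self, label: str) -> list:
        return [sid for sid, lab in self.mapping if lab == label]

    def swapped(self) -> "LineagePartition":
        """Same grouping with the two labels exchanged (for symmetry checks)."""
        a, b = self.labels
        flip = {a: b, b: a}
        return LineagePartition([(sid, flip[lab]) for sid, lab in self.mapping])

    @classmethod
    def read_tsv(cls, path) -> "LineagePartition":
        items = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"partition lines must be 'id<TAB>lineage', got {line!r}")
            items.append((parts[0], parts[1]))
        return cls(items)

    def write_tsv(self, path) -> None:
        Path(path).write_text(
            "".join(f"{sid}\t{lab}\n" for sid, lab in self.mapping)
        )


@dataclass
class SiteClassification:
    """Verdict for one alignment column (1-based, original coordinates)."""

    column: int
    informative: bool
    residues: dict  # lineage label -> Counter of non-gap residues
    category: SiteCategory
    fixed_lineage: str = None  # for FIXED_VARIABLE: the lineage fixed at one residue
    variable_lineage: str = None

    def residue_string(self, label: str) -> str:
        """Residues of one lineage, most frequent first, ties alphabetical."""
        counter = self.residues[label]
        ordered = sorted(counter, key=lambda r: (-counter[r], r))
        return ", ".join(ordered)

    def label(self) -> str:
        if self.category is SiteCategory.FIXED_VARIABLE:
            return f"fixed_in_{self.fixed_lineage}_variable_in_{self.variable_lineage}"
        return self.category.value


def _column_states(alignment) -> tuple:
    """(rows, valid-state alphabet) for a protein or nucleotide view."""
    if isinstance(alignment, CodonAlignment):
        return alignment.nucleotide_rows(), set(NUCLEOTIDES)
    if isinstance(alignment, ProteinAlignment):
        return [row for _, row in alignment.records], set(AMINO_ACIDS)
    # plain nucleotide rows
    return list(alignment), set(NUCLEOTIDES)


def parsimony_informative_sites(alignment) -> list:
    """1-based columns with >= 2 distinct states each present in >= 2 sequences.

    Accepts a :class:`ProteinAlignment`, a :class:`CodonAlignment` (scanned as
    nucleotide columns) or a plain list of equal-length nucleotide strings.
    Gaps and ambiguous characters are never counted as states. Requires at
    least 4 sequences.
    """
    rows, valid = _column_states(alignment)
    if len(rows) < 4:
        raise ValueError(f"parsimony informativeness needs >= 4 sequences, got {len(rows)}")
    length = len(rows[0])
    out = []
    for j in range(length):
        counts = Counter(row[j] for row in rows if row[j] in valid)
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append(j + 1)
    return out


def classify_lineage_sites(
    alignment: ProteinAlignment,
    partition: LineagePartition,
    sites: str = "informative",
) -> list:
    """Classify alignment columns by their between-lineage residue pattern.

    ``sites="informative"`` (default) restricts the report to
    parsimony-informative columns; ``sites="all"`` classifies every column.
    Reported column numbers use ``alignment.original_columns`` so coordinates
    survive partial deletion.
    """
    if sites not in ("informative", "all"):
        raise ValueError(f"sites must be 'informative' or 'all', got {sites!r}")
    for sid in alignment.ids:
        partition.label_of(sid)  # raises if uncovered
    label_a, label_b = partition.labels
    rows_by_label = {
        lab: [alignment.row(sid) for sid in alignment.ids if partition.label_of(sid) == lab]
        for lab in (label_a, label_b)
    }
    informative = set(parsimony_informative_sites(alignment))
    columns = range(1, alignment.length + 1)
    if sites == "informative":
        columns = sorted(informative)

    out = []
    valid = set(AMINO_ACIDS)
    for col in columns:
        j = col - 1
        residues = {
            lab: Counter(row[j] for row in rows_by_label[lab] if row[j] in valid)
            for lab in (label_a, label_b)
        }
        set_a, set_b = set(residues[label_a]), set(residues[label_b])
        fixed = variable = None
        if not set_a or not set_b:
            warnings.warn(
                f"column {alignment.original_columns[j]}: one lineage has no "
                "unambiguous residues; classified non_informative",
                stacklevel=2,
            )
            category = SiteCategory.NON_INFORMATIVE
        elif len(set_a | set_b) == 1:
            category = SiteCategory.INVARIANT
        elif set_a & set_b:
            category = SiteCategory.OVERLAPPING
        elif len(set_a) == 1 and len(set_b) == 1:
            category = SiteCategory.STRICTLY_DIMORPHIC
        elif len(set_a) == 1:
            category = SiteCategory.FIXED_VARIABLE
            fixed, variable = label_a, label_b
        elif len(set_b) == 1:
            category = SiteCategory.FIXED_VARIABLE
            fixed, variable = label_b, label_a
        else:
            category = SiteCategory.DISJOINT
        out.append(
            SiteClassification(
                column=alignment.original_columns[j],
                informative=col in informative,
                residues=residues,
                category=category,
                fixed_lineage=fixed,
                variable_lineage=variable,
            )
        )
    return out


def column_to_residue_number(alignment: ProteinAlignment, seq_id: str, column: int) -> int:
    """1-based residue number within the ungapped sequence at a 1-based column.

    ``column`` refers to the alignment's original coordinates (so the lookup
    works on partially deleted alignments too). Raises if the sequence has a
    gap at that column.
    """
    try:
        j = alignment.original_columns.index(column)
    except ValueError:
        raise IndexError(f"column {column} is not present in this alignment") from None
    row = alignment.row(seq_id)
    if row[j] == GAP:
        raise ValueError(f"{seq_id} has a gap at column {column}")
    return sum(1 for ch in row[: j + 1] if ch != GAP)


def classification_table(classifications, partition: LineagePartition) -> pd.DataFrame:
    """Tabular (TSV-ready) view of site classifications."""
    label_a, label_b = partition.labels
    rows = []
    for sc in classifications:
        rows.append(
            {
                "column": sc.column,
                "informative": sc.informative,
                label_a: sc.residue_string(label_a),
                label_b: sc.residue_string(label_b),
                "category": sc.label(),
            }
        )
    return pd.DataFrame(rows, columns=["column", "informative", label_a, label_b, "category"])


def residue_number_table(
    alignment: ProteinAlignment, classifications, categories=None
) -> pd.DataFrame:
    """Per-isoform residue numbers for selected columns (Table-5 style report)."""
    if categories is None:
        categories = (SiteCategory.STRICTLY_DIMORPHIC, SiteCategory.FIXED_VARIABLE)
    rows = []
    for sc in classifications:
        if sc.category not in categories:
            continue
        entry = {"column": sc.column, "category": sc.label()}
        for sid in alignment.ids:
            j = alignment.original_columns.index(sc.column)
            ch = alignment.row(sid)[j]
            if ch == GAP:
                entry[sid] = ""
            else:
                entry[sid] = f"{ch}{column_to_residue_number(alignment, sid, sc.column)}"
        rows.append(entry)
    return pd.DataFrame(rows, columns=["column", "category", *alignment.ids])
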