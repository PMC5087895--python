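"""Sequence records, FASTA I/O, translation, pairwise identity and codon alignments.

Everything downstream (family classification, site classification, selection
statistics) operates on the containers defined here:

* :class:`SequenceRecord` -- a single protein or CDS sequence.
* :class:`ProteinAlignment` -- a gapped amino-acid alignment (pre-aligned input
  is consumed as-is; this package never re-aligns).
* :class:`CodonAlignment` -- the protein alignment back-translated onto its
  coding sequences, with one gapped codon ("---") per protein gap.

Gap handling follows the "partial deletion" convention: alignment columns are
dropped when the fraction of non-gap sequences falls below a coverage cutoff
(0.95 by default in the pipeline), and the surviving columns remember their
original 1-based positions so reports keep the coordinates of the full
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"

#: the 20 standard amino acids, alphabetical by one-letter code
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad ids, stops, length mismatches)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; ``kind`` is "protein" or "cds"."""

    id: str
    seq: str
    kind: Literal["protein", "cds"] = "protein"

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise SequenceError(f"sequence id {self.id!r} is empty or contains whitespace")
        object.__setattr__(self, "seq", self.seq.upper())

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table; stops map to ``"*"``.

    Built from the NCBI translation tables (default 1, the standard code).
    """

    id: int
    table: dict  # codon -> one-letter amino acid, "*" for stop

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise SequenceError(f"genetic code must map all 64 codons, got {len(self.table)}")

    @staticmethod
    def from_ncbi_id(table_id: int = 1) -> "GeneticCode":
        return _genetic_code(table_id)

    def translate_codon(self, codon: str) -> str:
        """Amino acid for ``codon``; "X" for codons with ambiguous bases."""
        return self.table.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in sorted(self.table) if self.table[c] != "*")

    @property
    def stop_codons(self) -> tuple:
        return tuple(c for c in sorted(self.table) if self.table[c] == "*")

    def synonymous_families(self) -> dict:
        """amino acid -> sorted list of its sense codons."""
        fams: dict = {}
        for codon, aa in self.table.items():
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        return {aa: sorted(cods) for aa, cods in fams.items()}


@lru_cache(maxsize=None)
def _genetic_code(table_id: int) -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return GeneticCode(id=table_id, table=table)


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path, kind: Literal["protein", "cds"] = "protein") -> list:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; gap characters are preserved (so aligned FASTA
    round-trips). Duplicate ids and empty files raise :class:`SequenceError`.
    """
    path = Path(path)
    records = [SequenceRecord(r.id, str(r.seq), kind) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seen: dict = {}
    dups = []
    for rec in records:
        if rec.id in seen:
            dups.append(rec.id)
        seen[rec.id] = True
    if dups:
        raise SequenceError(f"duplicate sequence ids in {path}: {sorted(set(dups))}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, Path(path), "fasta")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate(record: SequenceRecord, code: GeneticCode = STANDARD_CODE) -> SequenceRecord:
    """Translate a CDS record; a terminal stop codon is dropped.

    Raises :class:`SequenceError` if the length is not a multiple of 3 or an
    internal stop codon is found (the error names the 1-based codon index).
    """
    seq = record.seq
    if len(seq) % 3:
        raise SequenceError(
            f"{record.id}: CDS length {len(seq)} is not a multiple of 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    aas = []
    for i, codon in enumerate(codons):
        aa = code.translate_codon(codon)
        if aa == "*":
            if i == len(codons) - 1:
                break  # terminal stop dropped
            raise SequenceError(
                f"{record.id}: internal stop codon {codon} at codon {i + 1}"
            )
        aas.append(aa)
    return SequenceRecord(record.id, "".join(aas), "protein")


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    return aligner


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: Literal["aligned", "shorter"] = "aligned",
) -> float:
    """Percent identity from a global alignment of two proteins.

    Identity is ``100 * matches / denominator`` where the default denominator
    is the number of aligned columns after stripping terminal-gap overhangs
    (``denominator="shorter"`` switches to the shorter ungapped length).
    Ambiguous residues (X) never match. The result is symmetric: the pair is
    canonicalized before aligning so that tie-breaking among co-optimal
    alignments cannot depend on argument order.
    """
    for rec in (a, b):
        if not rec.ungapped():
            raise SequenceError(f"cannot align empty sequence {rec.id!r}")
    sa, sb = a.ungapped(), b.ungapped()
    if (sb, b.id) < (sa, a.id):
        sa, sb = sb, sa
    aln = _aligner(matrix, gap_open, gap_extend).align(sa, sb)[0]
    row_a, row_b = aln[0], aln[1]
    # strip columns inside terminal-gap runs of either row
    start = max(len(row_a) - len(row_a.lstrip(GAP)), len(row_b) - len(row_b.lstrip(GAP)))
    end = min(len(row_a.rstrip(GAP)), len(row_b.rstrip(GAP)))
    matches = sum(
        1
        for x, y in zip(row_a[start:end], row_b[start:end])
        if x == y and x != GAP and x != "X"
    )
    if denominator == "shorter":
        denom = min(len(sa), len(sb))
    else:
        denom = end - start
    if denom == 0:
        raise SequenceError(f"no aligned columns between {a.id!r} and {b.id!r}")
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _check_rows(records: Sequence, unit: int = 1) -> int:
    if not records:
        raise SequenceError("alignment has no rows")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("alignment rows have duplicate ids")
    lengths = {len(row) for _, row in records}
    if len(lengths) != 1:
        raise SequenceError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    if length % unit:
        raise SequenceError(f"alignment length {length} is not a multiple of {unit}")
    return length


@dataclass
class ProteinAlignment:
    """A gapped protein alignment; columns are reported 1-based."""

    records: list  # list of (id, gapped sequence)
    original_columns: list = field(default=None)  # 1-based positions in the unfiltered alignment
    column_mask: list = field(default=None)  # kept flags over the pre-filter columns

    def __post_init__(self) -> None:
        length = _check_rows(self.records)
        if self.original_columns is None:
            self.original_columns = list(range(1, length + 1))
        elif len(self.original_columns) != length:
            raise SequenceError("original_columns does not match alignment length")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list:
        return [rid for rid, _ in self.records]

    def row(self, seq_id: str) -> str:
        for rid, row in self.records:
            if rid == seq_id:
                return row
        raise KeyError(seq_id)

    def column(self, index: int) -> str:
        """Residues at 0-based column ``index``, one per row."""
        return "".join(row[index] for _, row in self.records)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "ProteinAlignment":
        return cls([(r.id, r.seq) for r in records])

    def to_records(self) -> list:
        return [SequenceRecord(rid, row, "protein") for rid, row in self.records]


@dataclass
class CodonAlignment:
    """A codon alignment: gapped nucleotide rows, three columns per codon.

    Row length is ``3 * n_codon_columns``; each protein gap appears as "---".
    """

    records: list  # list of (id, gapped codon string)
    original_columns: list = field(default=None)  # 1-based codon columns pre-filter
    column_mask: list = field(default=None)

    def __post_init__(self) -> None:
        length = _check_rows(self.records, unit=3)
        n = length // 3
        if self.original_columns is None:
            self.original_columns = list(range(1, n + 1))
        elif len(self.original_columns) != n:
            raise SequenceError("original_columns does not match codon column count")

    @property
    def n_codon_columns(self) -> int:
        return len(self.records[0][1]) // 3

    @property
    def ids(self) -> list:
        return [rid for rid, _ in self.records]

    def row(self, seq_id: str) -> str:
        for rid, row in self.records:
            if rid == seq_id:
                return row
        raise KeyError(seq_id)

    def codon(self, row_index: int, column: int) -> str:
        """Codon at 0-based row and 0-based codon column."""
        return self.records[row_index][1][3 * column : 3 * column + 3]

    def nucleotide_rows(self) -> list:
        return [row for _, row in self.records]

    def to_protein(self, code: GeneticCode = STANDARD_CODE) -> ProteinAlignment:
        rows = []
        for rid, row in self.records:
            aas = []
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                aas.append(GAP if GAP in codon else code.translate_codon(codon))
            rows.append((rid, "".join(aas)))
        return ProteinAlignment(rows, original_columns=list(self.original_columns))


def back_translate(
    alignment: ProteinAlignment,
    cds_records: Iterable[SequenceRecord],
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Map a protein alignment onto its coding sequences, codon by codon.

    Every aligned protein row must equal the translation of its CDS (terminal
    stop ignored); mismatches raise :class:`SequenceError` naming the id and
    the first offending residue.
    """
    cds_map = {}
    for rec in cds_records:
        if rec.id in cds_map:
            raise SequenceError(f"duplicate CDS id {rec.id!r}")
        cds_map[rec.id] = rec
    rows = []
    for rid, gapped in alignment.records:
        if rid not in cds_map:
            raise SequenceError(f"no CDS provided for aligned sequence {rid!r}")
        cds = cds_map[rid]
        protein = translate(cds, code).seq
        ungapped = gapped.replace(GAP, "")
        if len(protein) != len(ungapped):
            raise SequenceError(
                f"{rid}: CDS translates to {len(protein)} residues but aligned "
                f"protein has {len(ungapped)}"
            )
        for i, (x, y) in enumerate(zip(protein, ungapped)):
            if x != y:
                raise SequenceError(
                    f"{rid}: CDS translation disagrees with protein at residue "
                    f"{i + 1} ({x!r} vs {y!r})"
                )
        out = []
        k = 0
        for ch in gapped:
            if ch == GAP:
                out.append("---")
            else:
                out.append(cds.seq[3 * k : 3 * k + 3])
                k += 1
        rows.append((rid, "".join(out)))
    return CodonAlignment(rows)


def partial_deletion(alignment, coverage: float):
    """Drop alignment columns whose non-gap fraction is below ``coverage``.

    Codon columns of a :class:`CodonAlignment` are treated atomically (a codon
    containing any gap character counts as a gap). Ambiguous residues/bases
    count as non-gap. Returns the same alignment type; ``original_columns``
    maps surviving columns back to pre-filter 1-based positions and
    ``column_mask`` records the kept/removed flags.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    n_rows = len(alignment.records)
    if isinstance(alignment, CodonAlignment):
        n_cols = alignment.n_codon_columns
        def is_gap(row, j):
            return GAP in row[3 * j : 3 * j + 3]
    else:
        n_cols = alignment.length
        def is_gap(row, j):
            return row[j] == GAP
    keep = []
    for j in range(n_cols):
        non_gap = sum(1 for _, row in alignment.records if not is_gap(row, j))
        keep.append(non_gap / n_rows >= coverage)
    kept_idx = [j for j, k in enumerate(keep) if k]
    if not kept_idx:
        warnings.warn("partial deletion removed every column", stacklevel=2)
    original = [alignment.original_columns[j] for j in kept_idx]
    if isinstance(alignment, CodonAlignment):
        rows = [
            (rid, "".join(row[3 * j : 3 * j + 3] for j in kept_idx))
            for rid, row in alignment.records
        ]
        return CodonAlignment(rows, original_columns=original, column_mask=keep)
    rows = [(rid, "".join(row[j] for j in kept_idx)) for rid, row in alignment.records]
    return ProteinAlignment(rows, original_columns=original, column_mask=keep)
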