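"""Nucleotide composition by codon position, amino-acid content, t-tests, and RSCU.

Frequencies are computed per sequence (each vector sums to 100% within its
codon position, or over the 20 amino acids), then contrasted between the two
lineages with a pooled-variance Student's t-test per cell. Reports carry the
group mean with its standard error (SE = SD/sqrt(n)); the SD is retained as
well. Restricting to parsimony-informative sites -- nucleotide-level columns
for the codon-position table, residue-level for the amino-acid table -- is the
default, since invariant positions carry no lineage contrast.

RSCU (relative synonymous codon usage) is a codon's observed count divided by
the mean count of its synonymous family; 1.0 means unbiased usage. Stop codons
and single-codon families (Met, Trp in the standard code) are excluded, and a
family never observed yields NaN entries (flagged) rather than 0/0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import (
    AMINO_ACIDS,
    GAP,
    NUCLEOTIDES,
    STANDARD_CODE,
    CodonAlignment,
    GeneticCode,
    ProteinAlignment,
)
from .site_polymorphism import LineagePartition, parsimony_informative_sites

#: composition contrasts are highlighted as significant below this p-value
SIGNIFICANCE_LEVEL = 1e-3


def students_t(group_a, group_b) -> tuple:
    """Pooled-variance two-sample t-test; returns (t, two-sided p).

    Degenerate inputs: zero pooled variance with equal means gives (0, 1);
    zero pooled variance with unequal means gives (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), a.size + b.size - 2)
    return float(t), float(p)


@dataclass
class CompositionTable:
    """Per-sequence frequency vectors with lineage means, spreads and t-tests."""

    per_sequence: pd.DataFrame  # rows: sequence ids; columns: cells (percent)
    lineage_of: pd.Series  # sequence id -> lineage label
    mean: pd.DataFrame  # rows: lineages
    se: pd.DataFrame
    sd: pd.DataFrame
    t: pd.Series
    p: pd.Series
    n_sites: dict  # cells-group (codon position or "aa") -> number of columns used

    @property
    def significant(self) -> pd.Series:
        return self.p < SIGNIFICANCE_LEVEL

    def summary_frame(self) -> pd.DataFrame:
        """Table-style summary: one row per cell, mean +/- SE per lineage, p."""
        rows = []
        for cell in self.per_sequence.columns:
            entry = {"cell": cell}
            for lab in self.mean.index:
                entry[lab] = f"{self.mean.loc[lab, cell]:.2f} ± {self.se.loc[lab, cell]:.2f}"
            entry["t"] = round(self.t[cell], 4)
            entry["p"] = self.p[cell]
            entry["significant"] = bool(self.significant[cell])
            rows.append(entry)
        return pd.DataFrame(rows)


def _group_stats(per_seq: pd.DataFrame, partition: LineagePartition) -> CompositionTable:
    labels = partition.labels
    lineage_of = pd.Series({sid: partition.label_of(sid) for sid in per_seq.index})
    mean = pd.DataFrame(index=list(labels), columns=per_seq.columns, dtype=float)
    se = mean.copy()
    sd = mean.copy()
    t_vals, p_vals = {}, {}
    for lab in labels:
        sub = per_seq.loc[lineage_of == lab]
        mean.loc[lab] = sub.mean()
        sd.loc[lab] = sub.std(ddof=1)
        se.loc[lab] = sub.std(ddof=1) / math.sqrt(len(sub))
    a_rows = per_seq.loc[lineage_of == labels[0]]
    b_rows = per_seq.loc[lineage_of == labels[1]]
    for cell in per_seq.columns:
        t_vals[cell], p_vals[cell] = students_t(a_rows[cell], b_rows[cell])
    return CompositionTable(
        per_sequence=per_seq,
        lineage_of=lineage_of,
        mean=mean,
        se=se,
        sd=sd,
        t=pd.Series(t_vals),
        p=pd.Series(p_vals),
        n_sites={},
    )


def codon_position_composition(
    codon_alignment: CodonAlignment,
    partition: LineagePartition,
    site_filter: str = "informative",
) -> CompositionTable:
    """Base frequencies (percent) at codon positions 1/2/3, per sequence.

    ``site_filter="informative"`` keeps only parsimony-informative nucleotide
    columns of the codon alignment; ``"all"`` keeps every column. Gaps and
    ambiguous bases are excluded from numerator and denominator. Cells are
    named ``T-1 ... G-3`` (base, codon position).
    """
    if site_filter not in ("informative", "all"):
        raise ValueError(f"site_filter must be 'informative' or 'all', got {site_filter!r}")
    rows = codon_alignment.nucleotide_rows()
    length = len(rows[0])
    if site_filter == "informative":
        kept = [c - 1 for c in parsimony_informative_sites(codon_alignment)]
    else:
        kept = list(range(length))
    if not kept:
        raise ValueError("site filter left no nucleotide columns")
    by_position = {p: [j for j in kept if j % 3 == p] for p in range(3)}
    cells = [f"{base}-{pos + 1}" for pos in range(3) for base in "TCAG"]
    data = {}
    for sid, row in zip(codon_alignment.ids, rows):
        vec = {}
        for pos in range(3):
            counts = {b: 0 for b in NUCLEOTIDES}
            for j in by_position[pos]:
                if row[j] in counts:
                    counts[row[j]] += 1
            total = sum(counts.values())
            for base in "TCAG":
                vec[f"{base}-{pos + 1}"] = 100.0 * counts[base] / total if total else np.nan
        data[sid] = vec
    per_seq = pd.DataFrame.from_dict(data, orient="index")[cells]
    table = _group_stats(per_seq, partition)
    table.n_sites = {f"position_{p + 1}": len(by_position[p]) for p in range(3)}
    return table


def amino_acid_composition(
    alignment: ProteinAlignment,
    partition: LineagePartition,
    site_filter: str = "informative",
) -> CompositionTable:
    """Amino-acid frequencies (percent over the 20 standard residues) per sequence."""
    if site_filter not in ("informative", "all"):
        raise ValueError(f"site_filter must be 'informative' or 'all', got {site_filter!r}")
    if site_filter == "informative":
        kept = [c - 1 for c in parsimony_informative_sites(alignment)]
    else:
        kept = list(range(alignment.length))
    if not kept:
        raise ValueError("site filter left no alignment columns")
    data = {}
    for sid, row in alignment.records:
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for j in kept:
            if row[j] in counts:
                counts[row[j]] += 1
        total = sum(counts.values())
        data[sid] = {
            aa: (100.0 * counts[aa] / total if total else np.nan) for aa in AMINO_ACIDS
        }
    per_seq = pd.DataFrame.from_dict(data, orient="index")[list(AMINO_ACIDS)]
    table = _group_stats(per_seq, partition)
    table.n_sites = {"aa": len(kept)}
    return table


@dataclass
class RSCUTable:
    """Codon counts and RSCU values for one set of coding sequences."""

    table: pd.DataFrame  # columns: codon, amino_acid, count, rscu
    zero_families: list  # amino acids whose whole family was unobserved (rscu NaN)

    def rscu_of(self, codon: str) -> float:
        row = self.table.loc[self.table["codon"] == codon, "rscu"]
        if row.empty:
            raise KeyError(codon)
        return float(row.iloc[0])


def rscu(cds_records, code: GeneticCode = STANDARD_CODE) -> RSCUTable:
    """Relative synonymous codon usage over a set of CDS records.

    RSCU(c) = count(c) / mean count over c's synonymous family. Stop codons
    and single-codon families are excluded. Families with zero total count are
    reported with NaN and listed in ``zero_families``.
    """
    counts = {c: 0 for c in code.sense_codons}
    for rec in cds_records:
        seq = rec.seq.replace(GAP, "")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    rows = []
    zero_families = []
    for aa, codons in sorted(code.synonymous_families().items()):
        if len(codons) < 2:
            continue  # Met, Trp: RSCU undefined
        total = sum(counts[c] for c in codons)
        if total == 0:
            zero_families.append(aa)
        mean_count = total / len(codons)
        for c in codons:
            val = counts[c] / mean_count if total else np.nan
            rows.append({"codon": c, "amino_acid": aa, "count": counts[c], "rscu": val})
    if zero_families:
        warnings.warn(
            f"no codons observed for amino acid(s) {''.join(zero_families)}; RSCU undefined there",
            stacklevel=2,
        )
    return RSCUTable(pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "rscu"]), zero_families)
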