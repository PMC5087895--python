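import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lineagediv as ld
from lineagediv.composition import (
    amino_acid_composition,
    codon_position_composition,
    rscu,
    students_t,
)
from lineagediv.site_polymorphism import LineagePartition

from oracles import pooled_t


def _two_group_codon_alignment(rows_a, rows_b):
    records = [(f"a{i}", s) for i, s in enumerate(rows_a)]
    records += [(f"b{i}", s) for i, s in enumerate(rows_b)]
    aln = ld.CodonAlignment(records)
    part = LineagePartition(
        [(rid, "dicot" if rid.startswith("a") else "monocot") for rid, _ in records]
    )
    return aln, part


# --- Student's t ------------------------------------------------------------

def test_t_identical_groups():
    assert students_t([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)


def test_t_zero_variance_unequal_means():
    t, p = students_t([0, 0, 0, 0], [1, 1, 1, 1])
    assert math.isinf(t) and p == 0.0


def test_t_matches_textbook_formula():
    from scipy import stats

    rng = random.Random(13)
    for _ in range(25):
        a = [rng.gauss(0, 1) for _ in range(rng.randint(2, 8))]
        b = [rng.gauss(0.5, 2) for _ in range(rng.randint(2, 8))]
        t, p = students_t(a, b)
        t_ref, df = pooled_t(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df), abs=1e-10)


def test_t_antisymmetric_in_group_order():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0]
    t_ab, p_ab = students_t(a, b)
    t_ba, p_ba = students_t(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)


# --- codon-position composition ---------------------------------------------

def test_single_sequence_two_codons():
    aln, part = _two_group_codon_alignment(["ATGGCA", "ATGGCA"], ["ATGGCA", "ATGGCA"])
    table = codon_position_composition(aln, part, site_filter="all")
    row = table.per_sequence.loc["a0"]
    assert row["A-1"] == 50.0 and row["G-1"] == 50.0
    assert row["T-2"] == 50.0 and row["C-2"] == 50.0
    assert row["G-3"] == 50.0 and row["A-3"] == 50.0


def test_identical_lineages_give_null_tests():
    aln, part = _two_group_codon_alignment(
        ["ATGGCAAAA", "ATGGCAAAA"], ["ATGGCAAAA", "ATGGCAAAA"]
    )
    table = codon_position_composition(aln, part, site_filter="all")
    assert (table.t == 0).all()
    assert (table.p == 1).all()


def test_per_sequence_rows_normalize_per_position(simulated_dataset):
    codon_aln, _, partition, _ = simulated_dataset
    table = codon_position_composition(codon_aln, partition, site_filter="informative")
    for pos in (1, 2, 3):
        cells = [f"{b}-{pos}" for b in "TCAG"]
        sums = table.per_sequence[cells].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)


def test_gc3_contrast_detected_in_simulation(simulated_dataset):
    """Lineages simulated with different GC3 should differ significantly at
    third positions but not at second positions."""
    codon_aln, _, partition, _ = simulated_dataset
    table = codon_position_composition(codon_aln, partition, site_filter="informative")
    assert table.p["G-3"] < 1e-3 and table.p["C-3"] < 1e-3


def test_filter_leaving_no_columns_errors():
    aln, part = _two_group_codon_alignment(
        ["ATGGCA", "ATGGCA"], ["ATGGCA", "ATGGCA"]
    )
    with pytest.raises(ValueError):
        codon_position_composition(aln, part, site_filter="informative")


# --- amino-acid composition -------------------------------------------------

def test_amino_acid_frequencies_simple():
    rows = [("a0", "MMKK"), ("a1", "MMKK"), ("b0", "MMKK"), ("b1", "MMKK")]
    aln = ld.ProteinAlignment(rows)
    part = LineagePartition(
        [(rid, "dicot" if rid.startswith("a") else "monocot") for rid, _ in rows]
    )
    table = amino_acid_composition(aln, part, site_filter="all")
    assert table.per_sequence.loc["a0", "M"] == 50.0
    assert table.per_sequence.loc["a0", "K"] == 50.0
    assert table.per_sequence.loc["a0"].sum() == pytest.approx(100.0, abs=1e-9)


def test_group_mean_agrees_with_pooled_counting():
    """With gap-free equal-length sequences, the mean of per-sequence
    frequencies must equal the pooled count frequency."""
    rng = random.Random(21)
    rows = [(f"a{i}", "".join(rng.choice("MKVA") for _ in range(30))) for i in range(3)]
    rows += [(f"b{i}", "".join(rng.choice("MKVA") for _ in range(30))) for i in range(3)]
    aln = ld.ProteinAlignment(rows)
    part = LineagePartition(
        [(rid, "dicot" if rid.startswith("a") else "monocot") for rid, _ in rows]
    )
    table = amino_acid_composition(aln, part, site_filter="all")
    for label, prefix in (("dicot", "a"), ("monocot", "b")):
        pooled = "".join(s for rid, s in rows if rid.startswith(prefix))
        for aa in "MKVA":
            expected = 100.0 * pooled.count(aa) / len(pooled)
            assert table.mean.loc[label, aa] == pytest.approx(expected)


# --- RSCU -------------------------------------------------------------------

def test_rscu_hand_example():
    # Ala counts GCT=2, GCC=1, GCA=1, GCG=0 -> RSCU 2, 1, 1, 0
    rec = ld.SequenceRecord("x", "GCTGCTGCCGCA", "cds")
    with pytest.warns(UserWarning):
        table = rscu([rec])
    assert table.rscu_of("GCT") == pytest.approx(2.0)
    assert table.rscu_of("GCC") == pytest.approx(1.0)
    assert table.rscu_of("GCA") == pytest.approx(1.0)
    assert table.rscu_of("GCG") == pytest.approx(0.0)
    assert "A" not in table.zero_families
    assert "K" in table.zero_families
    assert math.isnan(table.rscu_of("AAA"))


def test_rscu_uniform_usage_is_one():
    code = ld.STANDARD_CODE
    seq = "".join("".join(codons) for codons in code.synonymous_families().values())
    table = rscu([ld.SequenceRecord("x", seq, "cds")])
    observed = table.table.dropna(subset=["rscu"])
    assert np.allclose(observed["rscu"], 1.0)


def test_rscu_family_mean_is_one_and_duplication_invariant(simulated_dataset):
    codon_aln, _, _, _ = simulated_dataset
    cds = [ld.SequenceRecord(rid, row.replace("-", ""), "cds") for rid, row in codon_aln.records]
    table = rscu(cds)
    for aa, group in table.table.groupby("amino_acid"):
        if group["count"].sum() > 0:
            assert group["rscu"].mean() == pytest.approx(1.0, abs=1e-9)
    doubled = rscu(cds + cds)
    assert np.allclose(doubled.table["rscu"], table.table["rscu"], equal_nan=True)


def test_rscu_excludes_single_codon_families_and_stops():
    table = rscu([ld.SequenceRecord("x", "ATGTGG", "cds")])
    assert "ATG" not in set(table.table["codon"])
    assert "TGG" not in set(table.table["codon"])
    assert "TAA" not in set(table.table["codon"])
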