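import itertools
import math
import random

import numpy as np
import pytest

import lineagediv as ld
from lineagediv.selection import (
    codon_z_test,
    group_divergence,
    jukes_cantor,
    nei_gojobori_pair,
    pairwise_nucleotide_distance,
    per_site_dnds,
    tajima_coefficients,
    tajimas_d,
)
from lineagediv.site_polymorphism import LineagePartition

from oracles import nei_gojobori_sites, nucleotide_differences, tajima_d_direct


# --- pairwise nucleotide distance -------------------------------------------

def test_distance_identical_rows():
    assert pairwise_nucleotide_distance("ACGT", "ACGT", "p") == 0.0
    assert pairwise_nucleotide_distance("ACGT", "ACGT", "jc") == 0.0


def test_distance_counting_and_pairwise_deletion():
    # 2 mismatches over 10 compared sites; gaps excluded from both counts
    a = "AAAAAAAAAA-C"
    b = "AAAAAAAACC-C"
    assert pairwise_nucleotide_distance(a, b, "p") == pytest.approx(2 / 11)
    assert pairwise_nucleotide_distance(a[:10], b[:10], "p") == pytest.approx(0.2)


def test_jc_closed_form():
    assert jukes_cantor(0.2) == pytest.approx(-0.75 * math.log(1 - 0.26666666666666666))
    assert math.isnan(jukes_cantor(0.8))


# --- Nei-Gojobori pair counts ------------------------------------------------

def test_ng_identical_rows():
    ng = nei_gojobori_pair("GGGAAA", "GGGAAA")
    assert (ng.Sd, ng.Nd, ng.dS, ng.dN) == (0.0, 0.0, 0.0, 0.0)


def test_ng_hand_worked_pair():
    """GGG+AAA vs GGA+AAA: stop-codon exclusion at AAA/GGA first positions
    gives S = 4/3 per sequence, one synonymous difference, pS = 0.75."""
    ng = nei_gojobori_pair("GGGAAA", "GGAAAA")
    assert ng.S == pytest.approx(4 / 3)
    assert ng.N == pytest.approx(14 / 3)
    assert ng.Sd == pytest.approx(1.0)
    assert ng.Nd == pytest.approx(0.0)
    assert ng.pS == pytest.approx(0.75)
    assert ng.pN == pytest.approx(0.0)
    jc = nei_gojobori_pair("GGGAAA", "GGAAAA", correction="jc")
    assert math.isnan(jc.dS) and jc.flags  # pS >= 0.75: JC undefined, flagged


def test_ng_site_counts_match_enumeration_oracle():
    code = ld.STANDARD_CODE
    from lineagediv.selection import _codon_tables

    tables = _codon_tables(1)
    for codon in code.sense_codons:
        assert tables.syn_sites[tables.index[codon]] == pytest.approx(
            nei_gojobori_sites(codon)
        )


def test_ng_differences_equal_raw_mismatches_on_random_pairs():
    """Sd + Nd equals the raw nucleotide difference count, and S + N equals
    3 x compared codons, for random sense-codon rows."""
    rng = random.Random(17)
    sense = list(ld.STANDARD_CODE.sense_codons)
    for _ in range(30):
        n = rng.randint(1, 20)
        a = "".join(rng.choice(sense) for _ in range(n))
        b = "".join(rng.choice(sense) for _ in range(n))
        ng = nei_gojobori_pair(a, b)
        assert ng.Sd + ng.Nd == pytest.approx(nucleotide_differences(a, b))
        assert ng.S + ng.N == pytest.approx(3 * ng.n_codons, abs=1e-9)


def test_ng_symmetric():
    rng = random.Random(19)
    sense = list(ld.STANDARD_CODE.sense_codons)
    for _ in range(10):
        a = "".join(rng.choice(sense) for _ in range(8))
        b = "".join(rng.choice(sense) for _ in range(8))
        x, y = nei_gojobori_pair(a, b), nei_gojobori_pair(b, a)
        assert (x.S, x.N, x.Sd, x.Nd) == (y.S, y.N, y.Sd, y.Nd)


def test_ng_excludes_gapped_and_stop_columns():
    ng = nei_gojobori_pair("GGG---AAA", "GGGAAATAA")  # gap column + stop column
    assert ng.n_codons == 1


# --- group divergence -------------------------------------------------------

def test_group_divergence_identical_sequences():
    rows = [("a0", "ATGGCT"), ("a1", "ATGGCT"), ("b0", "ATGGCT"), ("b1", "ATGGCT")]
    aln = ld.CodonAlignment(rows)
    part = LineagePartition([(r, "dicot" if r.startswith("a") else "monocot") for r, _ in rows])
    div = group_divergence(aln, part, "p", n_boot=200, seed=0)
    assert div.within["dicot"][0] == 0.0
    assert div.within["monocot"][0] == 0.0
    assert div.between[0] == 0.0


def test_group_divergence_averages_enumerated_pairs():
    # within-pair p-distance 0.1 in each lineage (1 diff / 10 sites);
    # between pairs average hand-computable
    a0 = "AAAAAAAAAA"
    a1 = "AAAAAAAAAC"  # 1 diff from a0
    b0 = "GGGGGGGGGG"
    b1 = "GGGGGGGGGC"
    rows = [("a0", a0 + "AA"), ("a1", a1 + "AA"), ("b0", b0 + "GG"), ("b1", b1 + "GG")]
    aln = ld.CodonAlignment(rows)
    part = LineagePartition([(r, "dicot" if r.startswith("a") else "monocot") for r, _ in rows])
    div = group_divergence(aln, part, "p", n_boot=200, seed=0)
    assert div.within["dicot"][0] == pytest.approx(1 / 12)
    assert div.within["monocot"][0] == pytest.approx(1 / 12)
    pairs = [(a0 + "AA", b0 + "GG"), (a0 + "AA", b1 + "GG"), (a1 + "AA", b0 + "GG"), (a1 + "AA", b1 + "GG")]
    expected = np.mean([nucleotide_differences(x, y) / 12 for x, y in pairs])
    assert div.between[0] == pytest.approx(expected)


def test_simulated_within_less_than_between(simulated_dataset):
    codon_aln, _, partition, _ = simulated_dataset
    div = group_divergence(codon_aln, partition, "p", n_boot=200, seed=1)
    assert div.within["dicot"][0] < div.between[0]
    assert div.within["monocot"][0] < div.between[0]


# --- codon Z-test -----------------------------------------------------------

def test_z_test_no_variation_flagged():
    rows = [(f"s{i}", "ATGGCTAAA") for i in range(4)]
    aln = ld.CodonAlignment(rows)
    result = codon_z_test(aln, n_boot=100, seed=0)
    assert result.flagged and result.p == 1.0


def test_z_test_detects_purifying_selection():
    """Strongly purifying simulations should reject neutrality nearly always."""
    rejected = 0
    for seed in range(10):
        cfg = ld.SimulationConfig(
            n_per_lineage=(3, 3), n_codons=300, omega=0.1,
            n_dimorphic_sites=0, n_fixed_variable_sites=0, seed=seed,
        )
        codon_aln, _, partition, _ = ld.simulate(cfg)
        result = codon_z_test(codon_aln, partition, "purifying", n_boot=300, seed=seed)
        if result.p < 0.05:
            rejected += 1
    assert rejected >= 9


def test_z_test_seed_reproducible(simulated_dataset):
    codon_aln, _, partition, _ = simulated_dataset
    r1 = codon_z_test(codon_aln, partition, "purifying", n_boot=200, seed=5)
    r2 = codon_z_test(codon_aln, partition, "purifying", n_boot=200, seed=5)
    assert (r1.z, r1.p) == (r2.z, r2.p)


# --- per-site dN/dS ---------------------------------------------------------

def test_per_site_categories_on_engineered_columns():
    """Two nonsynonymous-only columns and eight synonymous-only columns."""
    syn_a, syn_b = "GGT", "GGC"  # Gly: synonymous pair
    non_a, non_b = "AAA", "GAA"  # Lys vs Glu: nonsynonymous (Sd = 0 -> undefined)
    row1 = syn_a * 8 + non_a * 2
    row2 = syn_b * 8 + non_b * 2
    row3 = syn_a * 8 + non_a * 2
    aln = ld.CodonAlignment([("s1", row1), ("s2", row2), ("s3", row3)])
    summary = per_site_dnds(aln)
    assert summary.counts["lt1"] == 8
    # nonsynonymous-only columns have Sd = 0: the ratio is undefined, not gt1
    assert summary.counts["undefined"] == 2
    cats = summary.per_site["category"].tolist()
    assert cats[:8] == ["lt1"] * 8 and cats[8:] == ["undefined"] * 2


def test_per_site_counts_sum_to_columns(simulated_dataset):
    codon_aln, _, _, _ = simulated_dataset
    summary = per_site_dnds(codon_aln)
    assert sum(summary.counts.values()) == codon_aln.n_codon_columns
    assert summary.counts["lt1"] > summary.counts["gt1"]  # purifying simulation


def test_per_site_requires_three_sequences():
    with pytest.raises(ValueError):
        per_site_dnds(ld.CodonAlignment([("a", "AAA"), ("b", "AAA")]))


# --- Tajima's D -------------------------------------------------------------

def test_tajima_identical_sequences_undefined():
    result = tajimas_d(["ACGT"] * 4)
    assert result.S == 0 and result.flagged and math.isnan(result.D)
    assert result.pi == 0.0 and result.theta_w == 0.0


def test_tajima_hand_worked_example():
    """n=4, rows AAAA/AAAA/AAAT/AATT: S=2, mean pairwise difference 7/6,
    a1=11/6; D ~ +0.5916 (verified against the direct-formula oracle)."""
    rows = ["AAAA", "AAAA", "AAAT", "AATT"]
    S, k, D_oracle = tajima_d_direct(rows)
    assert (S, k) == (2, pytest.approx(7 / 6))
    result = tajimas_d(rows)
    assert result.S == 2
    assert result.k == pytest.approx(7 / 6)
    assert result.a1 == pytest.approx(11 / 6)
    assert result.theta_w == pytest.approx((12 / 11) / 4)
    assert result.D == pytest.approx(D_oracle)
    assert result.D == pytest.approx(0.59158, abs=1e-4)


def test_tajima_matches_oracle_on_random_alignments():
    rng = random.Random(23)
    for _ in range(20):
        n, L = rng.randint(4, 10), rng.randint(5, 50)
        rows = ["".join(rng.choice("ACGT") for _ in range(L)) for _ in range(n)]
        S, k, D_oracle = tajima_d_direct(rows)
        result = tajimas_d(rows)
        assert result.S == S and result.k == pytest.approx(k)
        if D_oracle is None:
            assert math.isnan(result.D)
        else:
            assert result.D == pytest.approx(D_oracle)


def test_tajima_sign_matches_pi_theta_difference():
    rng = random.Random(29)
    signs = set()
    for _ in range(30):
        n, L = rng.randint(4, 8), rng.randint(10, 40)
        rows = ["".join(rng.choice("AC") for _ in range(L)) for _ in range(n)]
        result = tajimas_d(rows)
        if result.S > 0 and result.D != 0:
            assert math.copysign(1, result.D) == math.copysign(1, result.pi - result.theta_w)
            signs.add(math.copysign(1, result.D))
    assert signs  # the property was actually exercised


def test_tajima_complete_deletion_drops_gapped_columns():
    rows = ["AC-T", "ACGT", "ACGA", "ACGA"]
    result = tajimas_d(rows, "complete")
    assert result.L == 3  # gapped column removed
    assert result.S == 1


def test_tajima_coefficients_positive_for_n_ge_4():
    for n in range(4, 30):
        coef = tajima_coefficients(n)
        assert all(v > 0 for v in coef.values())


def test_tajima_requires_four_sequences():
    with pytest.raises(ValueError):
        tajimas_d(["ACGT"] * 3)
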