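"""Divergence, Nei-Gojobori dN/dS counting, the codon-based Z-test, and Tajima's D.

Nei-Gojobori (1986) counting: each codon position contributes a synonymous
"site fraction" equal to the proportion of its possible single-base changes
(changes creating stop codons excluded from the denominator) that leave the
amino acid unchanged; a codon's synonymous sites S_c is the sum over its three
positions, and S for a sequence pair averages the two sequences. Observed
differences between two codons are decomposed into synonymous (Sd) and
nonsynonymous (Nd) fractions by averaging over all minimal mutational pathways
between them, excluding pathways that pass through a stop codon (if every
pathway does, all pathways are used and stop-crossing steps count as
nonsynonymous, keeping Sd+Nd equal to the raw nucleotide difference count).
Proportions pS = Sd/S and pN = Nd/N may be Jukes-Cantor corrected,
d = -(3/4) ln(1 - 4p/3), undefined (flagged) at p >= 3/4.

The codon-based Z-test contrasts mean dS and mean dN over sequence pairs,
with variances estimated by bootstrap over codon columns:
Z = (mean dS - mean dN) / sqrt(Var(dS) + Var(dN)). One-tailed alternatives
"purifying" (dS > dN) and "positive" (dN > dS) use the normal upper tail.

Tajima's D contrasts the mean pairwise difference count (k) with the
segregating-site estimate S/a1, normalized by the usual coefficients
(a1, a2, b1, b2, c1, c2, e1, e2); its sign equals the sign of pi - theta_W.
Complete deletion (dropping any column containing a gap or ambiguity) is the
default for D, matching the usual convention for that statistic; pair
statistics instead exclude unusable codon columns pairwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import GAP, NUCLEOTIDES, STANDARD_CODE, CodonAlignment, GeneticCode
from .site_polymorphism import LineagePartition


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differences; NaN at p >= 0.75."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pairwise nucleotide distance
# ---------------------------------------------------------------------------

def pairwise_nucleotide_distance(row_a: str, row_b: str, model: str = "p") -> float:
    """p-distance or JC distance between two gapped nucleotide rows.

    Columns where either row is a gap or an ambiguous base are excluded
    (pairwise deletion). JC is NaN (flagged via the return value) at p >= 0.75.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    if model not in ("p", "jc"):
        raise ValueError(f"model must be 'p' or 'jc', got {model!r}")
    valid = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x in NUCLEOTIDES and y in NUCLEOTIDES:
            valid += 1
            if x != y:
                mismatch += 1
    if valid == 0:
        raise ValueError("no shared non-gap columns")
    p = mismatch / valid
    return p if model == "p" else jukes_cantor(p)


# ---------------------------------------------------------------------------
# Nei-Gojobori codon tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _CodonTables:
    codons: tuple  # sense codons
    index: dict  # codon -> array index
    syn_sites: np.ndarray  # per-codon synonymous site count
    sd: np.ndarray  # pairwise synonymous difference fractions
    nd: np.ndarray  # pairwise nonsynonymous difference fractions


def _path_steps(c1: str, c2: str, code: GeneticCode):
    """(syn, nonsyn, hits_stop) step counts along one mutational pathway order."""
    syn = nonsyn = 0
    hits_stop = False
    current = c1
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    for pos in diff_pos:
        nxt = current[:pos] + c2[pos] + current[pos + 1 :]
        if code.is_stop(nxt) or code.is_stop(current):
            hits_stop = True
        if code.translate_codon(current) == code.translate_codon(nxt):
            syn += 1
        else:
            nonsyn += 1
        current = nxt
    return syn, nonsyn, hits_stop


@lru_cache(maxsize=4)
def _codon_tables(code_id: int) -> _CodonTables:
    code = GeneticCode.from_ncbi_id(code_id)
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    n = len(codons)

    syn_sites = np.zeros(n)
    for c, i in index.items():
        total = 0.0
        for pos in range(3):
            syn = non_stop = 0
            for base in NUCLEOTIDES:
                if base == c[pos]:
                    continue
                mut = c[:pos] + base + c[pos + 1 :]
                if code.is_stop(mut):
                    continue
                non_stop += 1
                if code.translate_codon(mut) == code.translate_codon(c):
                    syn += 1
            if non_stop:
                total += syn / non_stop
        syn_sites[i] = total

    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for c1, i in index.items():
        for c2, j in index.items():
            if i >= j:
                continue
            diff_pos = [k for k in range(3) if c1[k] != c2[k]]
            if not diff_pos:
                continue
            results = []
            for order in itertools.permutations(diff_pos):
                target = c1
                syn = nonsyn = 0
                blocked = False
                current = c1
                for pos in order:
                    nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                    if code.is_stop(nxt):
                        blocked = True
                    if code.translate_codon(current) == code.translate_codon(nxt):
                        syn += 1
                    else:
                        nonsyn += 1
                    current = nxt
                results.append((syn, nonsyn, blocked))
            open_paths = [(s, ns) for s, ns, b in results if not b]
            if not open_paths:  # every pathway crosses a stop; keep them all
                open_paths = [(s, ns) for s, ns, _ in results]
            sd[i, j] = sd[j, i] = sum(s for s, _ in open_paths) / len(open_paths)
            nd[i, j] = nd[j, i] = sum(ns for _, ns in open_paths) / len(open_paths)
    return _CodonTables(codons, index, syn_sites, sd, nd)


def _encode(codon_rows, code: GeneticCode) -> np.ndarray:
    """Codon-index matrix (n_seq x n_codon_columns); -1 marks gap/stop/ambiguous."""
    tables = _codon_tables(code.id)
    n_cols = len(codon_rows[0]) // 3
    out = np.full((len(codon_rows), n_cols), -1, dtype=np.int64)
    for r, row in enumerate(codon_rows):
        for j in range(n_cols):
            out[r, j] = tables.index.get(row[3 * j : 3 * j + 3], -1)
    return out


# ---------------------------------------------------------------------------
# Pairwise Nei-Gojobori
# ---------------------------------------------------------------------------

@dataclass
class NeiGojoboriPair:
    """Synonymous/nonsynonymous site and difference counts for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons: int  # codon columns compared (both sequences usable)
    correction: str
    flags: list = field(default_factory=list)


def nei_gojobori_pair(
    codon_row_a: str,
    codon_row_b: str,
    code: GeneticCode = STANDARD_CODE,
    correction: str = "none",
) -> NeiGojoboriPair:
    """Nei-Gojobori counts between two aligned codon rows.

    Codon columns containing a gap, stop or ambiguous base in either sequence
    are excluded. ``correction`` is "none" (proportions) or "jc".
    """
    if len(codon_row_a) != len(codon_row_b) or len(codon_row_a) % 3:
        raise ValueError("codon rows must have equal length divisible by 3")
    if correction not in ("none", "jc"):
        raise ValueError(f"correction must be 'none' or 'jc', got {correction!r}")
    tables = _codon_tables(code.id)
    enc = _encode([codon_row_a, codon_row_b], code)
    a, b = enc[0], enc[1]
    valid = (a >= 0) & (b >= 0)
    av, bv = a[valid], b[valid]
    n_codons = int(valid.sum())
    S = float((tables.syn_sites[av].sum() + tables.syn_sites[bv].sum()) / 2.0)
    N = 3.0 * n_codons - S
    Sd = float(tables.sd[av, bv].sum())
    Nd = float(tables.nd[av, bv].sum())
    flags = []
    if S == 0.0 and Sd > 0.0:
        raise ValueError("inconsistent counts: synonymous differences with zero synonymous sites")
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    if correction == "jc":
        dS, dN = jukes_cantor(pS), jukes_cantor(pN)
        if math.isnan(dS):
            flags.append("dS undefined: pS >= 0.75")
        if math.isnan(dN):
            flags.append("dN undefined: pN >= 0.75")
    else:
        dS, dN = pS, pN
    return NeiGojoboriPair(S, N, Sd, Nd, pS, pN, dS, dN, n_codons, correction, flags)


# ---------------------------------------------------------------------------
# Pair matrices shared by the Z-test and per-site counting
# ---------------------------------------------------------------------------

def _pair_matrices(enc: np.ndarray, pairs, code_id: int):
    """Per-pair, per-column Sd/Nd/S/N matrices (zeros at unusable columns)."""
    tables = _codon_tables(code_id)
    n_pairs, n_cols = len(pairs), enc.shape[1]
    SD = np.zeros((n_pairs, n_cols))
    ND = np.zeros((n_pairs, n_cols))
    Sm = np.zeros((n_pairs, n_cols))
    Nm = np.zeros((n_pairs, n_cols))
    for k, (i, j) in enumerate(pairs):
        a, b = enc[i], enc[j]
        valid = (a >= 0) & (b >= 0)
        av, bv = a[valid], b[valid]
        SD[k, valid] = tables.sd[av, bv]
        ND[k, valid] = tables.nd[av, bv]
        Sm[k, valid] = (tables.syn_sites[av] + tables.syn_sites[bv]) / 2.0
        Nm[k, valid] = 3.0 - Sm[k, valid]
    return SD, ND, Sm, Nm


def _pair_list(ids, partition: LineagePartition = None, scope: str = "within"):
    """Index pairs: all pairs, or only within-lineage pairs when partitioned."""
    idx = range(len(ids))
    if partition is None:
        return list(itertools.combinations(idx, 2))
    labels = {i: partition.label_of(ids[i]) for i in idx}
    pairs = [(i, j) for i, j in itertools.combinations(idx, 2)]
    if scope == "within":
        return [(i, j) for i, j in pairs if labels[i] == labels[j]]
    if scope == "between":
        return [(i, j) for i, j in pairs if labels[i] != labels[j]]
    return pairs


# ---------------------------------------------------------------------------
# Group divergence
# ---------------------------------------------------------------------------

@dataclass
class GroupDivergence:
    within: dict  # lineage label -> (mean, SE)
    between: tuple  # (mean, SE)
    model: str
    n_boot: int
    seed: int


def group_divergence(
    codon_alignment: CodonAlignment,
    partition: LineagePartition,
    model: str = "p",
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupDivergence:
    """Mean within- and between-lineage nucleotide divergence with bootstrap SEs.

    Distances use pairwise deletion of gapped/ambiguous columns; SEs come from
    resampling nucleotide columns (``n_boot`` replicates, seeded).
    """
    rows = codon_alignment.nucleotide_rows()
    ids = codon_alignment.ids
    length = len(rows[0])
    base_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    enc = np.full((len(rows), length), -1, dtype=np.int64)
    for r, row in enumerate(rows):
        for j, ch in enumerate(row):
            enc[r, j] = base_idx.get(ch, -1)

    def transform(p):
        return jukes_cantor(p) if model == "jc" else p

    pairs_all = list(itertools.combinations(range(len(ids)), 2))
    valid = np.zeros((len(pairs_all), length))
    diff = np.zeros((len(pairs_all), length))
    for k, (i, j) in enumerate(pairs_all):
        ok = (enc[i] >= 0) & (enc[j] >= 0)
        valid[k] = ok
        diff[k] = ok & (enc[i] != enc[j])

    label_a, label_b = partition.labels
    labels = [partition.label_of(s) for s in ids]
    groups = {
        label_a: [k for k, (i, j) in enumerate(pairs_all) if labels[i] == labels[j] == label_a],
        label_b: [k for k, (i, j) in enumerate(pairs_all) if labels[i] == labels[j] == label_b],
        "between": [k for k, (i, j) in enumerate(pairs_all) if labels[i] != labels[j]],
    }

    rng = np.random.default_rng(seed)
    W = rng.multinomial(length, np.full(length, 1.0 / length), size=n_boot).T  # L x B
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = diff.sum(axis=1) / valid.sum(axis=1)
        p_boot = (diff @ W) / (valid @ W)  # pairs x B

    def stats_for(keys):
        mean = float(np.mean([transform(p) for p in p_obs[keys]]))
        reps = np.array(
            [np.mean([transform(p) for p in p_boot[keys, b]]) for b in range(n_boot)]
        )
        return mean, float(np.nanstd(reps, ddof=1))

    within = {lab: stats_for(groups[lab]) for lab in (label_a, label_b)}
    between = stats_for(groups["between"])
    return GroupDivergence(within, between, model, n_boot, seed)


# ---------------------------------------------------------------------------
# Codon-based Z-test
# ---------------------------------------------------------------------------

@dataclass
class ZTestResult:
    z: float
    p: float
    alternative: str
    mean_dS: float
    mean_dN: float
    var_dS: float
    var_dN: float
    n_pairs: int
    n_boot: int
    seed: int
    flagged: bool = False
    note: str = ""


def codon_z_test(
    codon_alignment: CodonAlignment,
    partition: LineagePartition = None,
    alternative: str = "purifying",
    n_boot: int = 1000,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> ZTestResult:
    """Codon-based Z-test of selection (null: strict neutrality, dS = dN).

    With a partition, only within-lineage pairs enter the averages; without,
    all pairs do. Variances of mean dS and mean dN come from a seeded bootstrap
    over codon columns. Alternatives: "purifying" (dS > dN, one-tailed),
    "positive" (dN > dS, one-tailed), "neutral" (two-sided).
    """
    if alternative not in ("purifying", "positive", "neutral"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ids = codon_alignment.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    enc = _encode(codon_alignment.nucleotide_rows(), code)
    pairs = _pair_list(ids, partition, scope="within")
    if not pairs:
        raise ValueError("partition leaves no within-lineage pairs")
    SD, ND, Sm, Nm = _pair_matrices(enc, pairs, code.id)

    if SD.sum() + ND.sum() == 0.0:
        return ZTestResult(
            math.nan, 1.0, alternative, 0.0, 0.0, 0.0, 0.0,
            len(pairs), n_boot, seed, flagged=True, note="no variation",
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        dS_pairs = SD.sum(axis=1) / Sm.sum(axis=1)
        dN_pairs = ND.sum(axis=1) / Nm.sum(axis=1)
    mean_dS = float(np.nanmean(dS_pairs))
    mean_dN = float(np.nanmean(dN_pairs))

    rng = np.random.default_rng(seed)
    L = enc.shape[1]
    W = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T  # L x B
    with np.errstate(divide="ignore", invalid="ignore"):
        dS_boot = np.nanmean((SD @ W) / (Sm @ W), axis=0)
        dN_boot = np.nanmean((ND @ W) / (Nm @ W), axis=0)
    var_dS = float(np.nanvar(dS_boot, ddof=1))
    var_dN = float(np.nanvar(dN_boot, ddof=1))
    se = math.sqrt(var_dS + var_dN)
    if se == 0.0:
        return ZTestResult(
            math.nan, 1.0, alternative, mean_dS, mean_dN, var_dS, var_dN,
            len(pairs), n_boot, seed, flagged=True, note="zero bootstrap variance",
        )
    if alternative == "purifying":
        z = (mean_dS - mean_dN) / se
        p = float(stats.norm.sf(z))
    elif alternative == "positive":
        z = (mean_dN - mean_dS) / se
        p = float(stats.norm.sf(z))
    else:
        z = (mean_dS - mean_dN) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ZTestResult(float(z), p, alternative, mean_dS, mean_dN, var_dS, var_dN,
                       len(pairs), n_boot, seed)


# ---------------------------------------------------------------------------
# Per-site dN/dS
# ---------------------------------------------------------------------------

@dataclass
class SelectionSummary:
    per_site: pd.DataFrame  # column, Sd, Nd, S, N, ratio, category
    counts: dict  # category -> number of codon columns

    @property
    def n_sites(self) -> int:
        return len(self.per_site)


def per_site_dnds(
    codon_alignment: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> SelectionSummary:
    """Per-codon-column dN/dS categories from pairwise Nei-Gojobori counts.

    For each codon column, Sd/Nd/S/N are summed over all usable sequence pairs
    (pairwise deletion). ratio = (Nd/N)/(Sd/S); a column is "gt1" when the
    ratio exceeds 1, "lt1" when at most 1, and "undefined" when there is no
    variation or no synonymous difference to scale by (Sd = 0).
    """
    ids = codon_alignment.ids
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    enc = _encode(codon_alignment.nucleotide_rows(), code)
    pairs = list(itertools.combinations(range(len(ids)), 2))
    SD, ND, Sm, Nm = _pair_matrices(enc, pairs, code.id)
    sd_col, nd_col = SD.sum(axis=0), ND.sum(axis=0)
    s_col, n_col = Sm.sum(axis=0), Nm.sum(axis=0)
    rows = []
    counts = {"gt1": 0, "lt1": 0, "undefined": 0}
    for j in range(enc.shape[1]):
        if sd_col[j] + nd_col[j] == 0.0 or sd_col[j] == 0.0 or s_col[j] == 0.0:
            category, ratio = "undefined", math.nan
        else:
            ratio = (nd_col[j] / n_col[j]) / (sd_col[j] / s_col[j])
            category = "gt1" if ratio > 1.0 else "lt1"
        counts[category] += 1
        rows.append(
            {
                "column": codon_alignment.original_columns[j],
                "Sd": sd_col[j],
                "Nd": nd_col[j],
                "S": s_col[j],
                "N": n_col[j],
                "ratio": ratio,
                "category": category,
            }
        )
    return SelectionSummary(pd.DataFrame(rows), counts)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaResult:
    n: int
    L: int  # analyzed sites after deletion
    S: int  # segregating sites
    k: float  # mean pairwise differences
    pi: float  # k / L, per site
    theta_w: float  # S / (a1 * L), per site
    D: float  # NaN when S == 0
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    flagged: bool = False


def tajima_coefficients(n: int) -> dict:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment, deletion: str = "complete") -> TajimaResult:
    """Tajima's D over a nucleotide alignment (rows or a :class:`CodonAlignment`).

    ``deletion="complete"`` (default) drops every column containing a gap or
    ambiguous base before counting segregating sites and pairwise differences.
    ``deletion="pairwise"`` counts a column as segregating when it holds two
    unambiguous states, and averages pairwise differences over each pair's
    usable columns scaled to the full analyzed length.
    """
    if isinstance(alignment, CodonAlignment):
        rows = alignment.nucleotide_rows()
    else:
        rows = list(alignment)
    n = len(rows)
    if n < 4:
        raise ValueError(f"Tajima's D needs >= 4 sequences, got {n}")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"deletion must be 'complete' or 'pairwise', got {deletion!r}")
    length = len(rows[0])
    valid_cols = [
        j for j in range(length) if all(row[j] in NUCLEOTIDES for row in rows)
    ]
    if deletion == "complete":
        cols = valid_cols
        mat = [[row[j] for j in cols] for row in rows]
        L = len(cols)
        if L == 0:
            raise ValueError("complete deletion removed every column")
        S = sum(1 for j in range(L) if len({r[j] for r in mat}) > 1)
        total = 0
        n_pairs = 0
        for i, j in itertools.combinations(range(n), 2):
            total += sum(1 for a, b in zip(mat[i], mat[j]) if a != b)
            n_pairs += 1
        k = total / n_pairs
    else:
        L = length
        S = 0
        for j in range(length):
            states = {row[j] for row in rows if row[j] in NUCLEOTIDES}
            if len(states) > 1:
                S += 1
        ps = []
        for i, j in itertools.combinations(range(n), 2):
            ps.append(pairwise_nucleotide_distance(rows[i], rows[j], "p"))
        k = float(np.mean(ps)) * L

    coef = tajima_coefficients(n)
    theta_w = S / (coef["a1"] * L)
    pi = k / L
    if S == 0:
        return TajimaResult(n, L, S, k, 0.0, 0.0, math.nan, flagged=True, **coef)
    var = coef["e1"] * S + coef["e2"] * S * (S - 1.0)
    D = (k - S / coef["a1"]) / math.sqrt(var)
    return TajimaResult(n, L, S, k, pi, theta_w, float(D), **coef)
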