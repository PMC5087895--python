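"""Independent brute-force oracles used to cross-check the library.

These deliberately share no code with the package: plain recursion and
counting, fast only at tiny problem sizes.
"""

from __future__ import annotations

import itertools
from collections import Counter
from functools import lru_cache


def affine_alignment_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score with affine gaps by exhaustive recursion.

    ``score(x, y)`` gives the substitution score. ``gap_open`` is the cost of
    the first gapped position, ``gap_extend`` of each further one (both
    positive costs).
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "x" else gap_open
            options.append(-cost + best(i + 1, j, "x"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "y" else gap_open
            options.append(-cost + best(i, j + 1, "y"))
        return max(options)

    return best(0, 0, "m")


def informative_columns(rows, valid_states) -> list:
    """1-based parsimony-informative columns by direct counting."""
    out = []
    for j in range(len(rows[0])):
        counts = Counter(r[j] for r in rows if r[j] in valid_states)
        if len([s for s, c in counts.items() if c >= 2]) >= 2:
            out.append(j + 1)
    return out


def connected_components(ids, edge) -> list:
    """Components by repeated merging; ``edge(x, y)`` says whether linked."""
    groups = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for g1, g2 in itertools.combinations(list(groups), 2):
            if g1 in groups and g2 in groups and any(
                edge(x, y) for x in g1 for y in g2
            ):
                groups.remove(g1)
                groups.remove(g2)
                groups.append(g1 | g2)
                changed = True
                break
    return sorted((sorted(g) for g in groups), key=lambda g: g[0])


def nucleotide_differences(row_a: str, row_b: str) -> int:
    """Raw nucleotide differences over columns where both rows are ACGT."""
    return sum(
        1
        for x, y in zip(row_a, row_b)
        if x in "ACGT" and y in "ACGT" and x != y
    )


def tajima_d_direct(rows):
    """Tajima's D from first principles on gap-free equal-length rows.

    Returns (S, k_mean, D or None).
    """
    n = len(rows)
    L = len(rows[0])
    S = sum(1 for j in range(L) if len({r[j] for r in rows}) > 1)
    pairs = list(itertools.combinations(range(n), 2))
    k = sum(
        sum(1 for x, y in zip(rows[i], rows[j]) if x != y) for i, j in pairs
    ) / len(pairs)
    if S == 0:
        return S, k, None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i / i for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 / a1
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    D = (k - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5
    return S, k, D


def pooled_t(a, b):
    """Textbook pooled two-sample t statistic and df."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / (sp2 * (1.0 / na + 1.0 / nb)) ** 0.5
    return t, df


STANDARD_TABLE = {}


def _build_standard_table():
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                STANDARD_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_standard_table()


def nei_gojobori_sites(codon: str) -> float:
    """Synonymous sites of one codon by direct enumeration (standard code)."""
    total = 0.0
    aa = STANDARD_TABLE[codon]
    for pos in range(3):
        syn = non_stop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if STANDARD_TABLE[mut] == "*":
                continue
            non_stop += 1
            if STANDARD_TABLE[mut] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total
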