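"""Seeded two-lineage codon-alignment simulator with known ground truth.

The generator emulates the structure of a two-lineage (e.g. dicot vs monocot)
gene subfamily alignment: a shared ancestral coding sequence splits into two
lineages, each evolving as a star phylogeny (a lineage ancestor plus
independent tips). Substitutions are single-base events per codon whose
relative weights encode

* purifying selection: nonsynonymous changes carry weight ``omega`` relative
  to synonymous ones, so the realized dN/dS tracks ``omega``;
* stop avoidance: changes creating stop codons have weight zero, so no
  simulated CDS ever contains an internal stop;
* lineage-specific GC3 bias: third-position choices are weighted toward each
  lineage's target GC3, and at the lineage split all third positions are
  synonymously re-drawn under that bias (representing the mutational pressure
  acting since divergence), so realized GC3 converges on the target.

``depth`` values are expected *realized* substitutions per codon (every event
substitutes; omega shapes the synonymous/nonsynonymous composition of events,
not their total number).

On top of the neutral backbone, a configurable number of lineage-diagnostic
amino-acid sites is injected by overwriting columns after evolution:
strictly dimorphic sites (each lineage fixed for a different residue) and
fixed-variable sites (one lineage fixed, the other carrying 2-4 disjoint
residues). The injected truth is returned for classifier evaluation.

Defaults mirror the study conditions the package targets: 8 + 15 sequences,
423 codons, omega = 0.1, GC3 targets 0.41 (dicot-like) and 0.87
(monocot-like), one strictly dimorphic and three fixed-variable sites.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .seq_core import (
    AMINO_ACIDS,
    STANDARD_CODE,
    CodonAlignment,
    GeneticCode,
    ProteinAlignment,
)
from .site_polymorphism import LineagePartition, SiteCategory


@dataclass(frozen=True)
class SimulationConfig:
    n_per_lineage: tuple = (8, 15)
    n_codons: int = 423
    split_depth: float = 0.75  # substitutions/codon, root -> lineage ancestor
    tip_depth: float = 0.6  # substitutions/codon, lineage ancestor -> each tip
    omega: float = 0.1
    gc3_target: tuple = (0.41, 0.87)
    n_dimorphic_sites: int = 1
    n_fixed_variable_sites: int = 3
    seed: int = 0
    lineage_labels: tuple = ("dicot", "monocot")

    def __post_init__(self) -> None:
        n = self.n_per_lineage
        if isinstance(n, int):
            object.__setattr__(self, "n_per_lineage", (n, n))
        if any(x < 2 for x in self.n_per_lineage):
            raise ValueError("need at least 2 sequences per lineage")
        if self.n_codons < 1 or self.n_dimorphic_sites < 0 or self.n_fixed_variable_sites < 0:
            raise ValueError("counts must be non-negative and n_codons >= 1")
        if self.n_dimorphic_sites + self.n_fixed_variable_sites > self.n_codons:
            raise ValueError("more injected sites than codon columns")
        for g in self.gc3_target:
            if not 0.0 < g < 1.0:
                raise ValueError(f"gc3_target must be in (0, 1), got {g}")
        if not 0.0 <= self.omega:
            raise ValueError("omega must be non-negative")


@dataclass
class SimulationTruth:
    ancestor: str  # root coding sequence
    injected: dict  # 1-based column -> {"category", "residues": {label: [residues]}}
    substitutions: dict  # lineage label -> {"synonymous": int, "nonsynonymous": int}
    config: SimulationConfig

    def columns(self, category: SiteCategory) -> list:
        return sorted(
            col for col, info in self.injected.items() if info["category"] == category.value
        )

    def to_json(self) -> str:
        payload = {
            "ancestor": self.ancestor,
            "injected": {
                str(col): {
                    "category": info["category"],
                    "residues": info["residues"],
                }
                for col, info in sorted(self.injected.items())
            },
            "substitutions": self.substitutions,
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# --- substitution machinery -------------------------------------------------

def _neighbors(code: GeneticCode):
    """codon -> list of (new codon, position, is_synonymous); stops excluded."""
    out = {}
    for codon in code.sense_codons:
        lst = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if code.is_stop(mut):
                    continue
                lst.append((mut, pos, code.translate_codon(mut) == code.translate_codon(codon)))
        out[codon] = lst
    return out


def _gc_weight(base: str, gc3: float) -> float:
    return gc3 if base in "GC" else 1.0 - gc3


def _weight_table(neighbors, omega: float, gc3: float):
    """Per-codon substitution options with cumulative weights, plus the
    uniformization constant C (the largest total exit weight).

    Weights: synonymous 1, nonsynonymous ``omega``, third-position changes
    additionally scaled by the GC3 preference of the *target* base. Because a
    move's weight depends only on its target's third base, every edge satisfies
    detailed balance against pi(codon) proportional to that GC weight, so the
    chain's stationary GC3 matches the target.
    """
    table = {}
    for codon, opts in neighbors.items():
        weights = np.empty(len(opts))
        for k, (mut, pos, is_syn) in enumerate(opts):
            w = 1.0 if is_syn else omega
            if pos == 2:
                w *= 2.0 * _gc_weight(mut[2], gc3)
            weights[k] = w
        table[codon] = (opts, np.cumsum(weights), float(weights.sum()))
    C = max(t[2] for t in table.values())
    return table, C


def _substitute(codons, depth, table, C, rng, tally) -> list:
    """Evolve a codon list by a uniformized substitution chain.

    Each codon receives Poisson events; an event substitutes with probability
    (total exit weight)/C and otherwise self-loops, which keeps the stationary
    distribution weight-proportional. The event rate is scaled so ``depth``
    remains the expected number of *realized* substitutions per codon.
    """
    out = list(codons)
    if depth <= 0.0 or C <= 0.0:
        return out
    w_bar = float(np.mean([table[c][2] for c in out]))
    if w_bar <= 0.0:
        return out
    n_events = rng.poisson(depth * C / w_bar, size=len(out))
    for idx in np.nonzero(n_events)[0]:
        for _ in range(n_events[idx]):
            opts, cumw, total = table[out[idx]]
            u = rng.random() * C
            if u >= total:
                continue  # self-loop
            choice = int(np.searchsorted(cumw, u, side="right"))
            mut, _, is_syn = opts[choice]
            out[idx] = mut
            tally["synonymous" if is_syn else "nonsynonymous"] += 1
    return out


def _resample_third_positions(codons, gc3, code, rng) -> list:
    """Synonymously redraw each codon's third base under the GC3 target."""
    out = []
    for codon in codons:
        options = [codon]
        for base in "ACGT":
            if base == codon[2]:
                continue
            mut = codon[:2] + base
            if not code.is_stop(mut) and code.translate_codon(mut) == code.translate_codon(codon):
                options.append(mut)
        weights = np.array([_gc_weight(c[2], gc3) for c in options])
        out.append(options[rng.choice(len(options), p=weights / weights.sum())])
    return out


def _draw_ancestor(n_codons, gc3_mid, code, rng) -> list:
    sense = list(code.sense_codons)
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    return _resample_third_positions(codons, gc3_mid, code, rng)


def _codon_for(residue, code, rng) -> str:
    options = code.synonymous_families()[residue]
    return options[rng.integers(0, len(options))]


def simulate(config: SimulationConfig, code: GeneticCode = STANDARD_CODE):
    """Run one simulation.

    Returns ``(codon_alignment, protein_alignment, partition, truth)``. The
    output is byte-identical for identical configs (single seeded generator,
    fixed evaluation order).
    """
    rng = np.random.default_rng(config.seed)
    neighbors = _neighbors(code)
    label_a, label_b = config.lineage_labels
    gc3 = dict(zip((label_a, label_b), config.gc3_target))
    n_seqs = dict(zip((label_a, label_b), config.n_per_lineage))

    ancestor = _draw_ancestor(config.n_codons, float(np.mean(config.gc3_target)), code, rng)

    tips = {}
    lineage_of = {}
    tallies = {}
    for label in (label_a, label_b):
        tally = {"synonymous": 0, "nonsynonymous": 0}
        table, C = _weight_table(neighbors, config.omega, gc3[label])
        if config.split_depth > 0.0:
            # cumulative third-position bias along the split branch; a
            # zero-length branch accumulates none
            lineage_root = _resample_third_positions(ancestor, gc3[label], code, rng)
            lineage_root = _substitute(
                lineage_root, config.split_depth, table, C, rng, tally
            )
        else:
            lineage_root = list(ancestor)
        for i in range(n_seqs[label]):
            tip = _substitute(
                lineage_root, config.tip_depth, table, C, rng, tally
            )
            sid = f"{label}_{i + 1}"
            tips[sid] = tip
            lineage_of[sid] = label
        tallies[label] = tally

    # inject lineage-diagnostic sites
    n_inject = config.n_dimorphic_sites + config.n_fixed_variable_sites
    injected: dict = {}
    if n_inject:
        columns = rng.choice(config.n_codons, size=n_inject, replace=False)
        aa_pool = list(AMINO_ACIDS)
        for rank, col in enumerate(columns):
            col = int(col)
            if rank < config.n_dimorphic_sites:
                res_a, res_b = (aa_pool[i] for i in rng.choice(20, size=2, replace=False))
                codon_a = _codon_for(res_a, code, rng)
                codon_b = _codon_for(res_b, code, rng)
                for sid in tips:
                    tips[sid][col] = codon_a if lineage_of[sid] == label_a else codon_b
                injected[col + 1] = {
                    "category": SiteCategory.STRICTLY_DIMORPHIC.value,
                    "residues": {label_a: [res_a], label_b: [res_b]},
                }
            else:
                fixed_label = (label_a, label_b)[int(rng.integers(0, 2))]
                var_label = label_b if fixed_label == label_a else label_a
                n_var = n_seqs[var_label]
                k_hi = min(4, max(2, n_var - 1))
                k = int(rng.integers(2, k_hi + 1))
                picks = rng.choice(20, size=k + 1, replace=False)
                fixed_res = aa_pool[picks[0]]
                var_res = [aa_pool[i] for i in picks[1:]]
                fixed_codon = _codon_for(fixed_res, code, rng)
                var_codons = [_codon_for(r, code, rng) for r in var_res]
                var_ids = [sid for sid in tips if lineage_of[sid] == var_label]
                for sid in tips:
                    if lineage_of[sid] == fixed_label:
                        tips[sid][col] = fixed_codon
                for i, sid in enumerate(var_ids):
                    tips[sid][col] = var_codons[i % k]
                injected[col + 1] = {
                    "category": SiteCategory.FIXED_VARIABLE.value,
                    "fixed_lineage": fixed_label,
                    "residues": {fixed_label: [fixed_res], var_label: sorted(var_res)},
                }

    records = [(sid, "".join(codons)) for sid, codons in tips.items()]
    codon_alignment = CodonAlignment(records)
    protein_alignment = codon_alignment.to_protein(code)
    partition = LineagePartition([(sid, lineage_of[sid]) for sid in tips])
    truth = SimulationTruth("".join(ancestor), injected, tallies, config)
    return codon_alignment, protein_alignment, partition, truth


def evaluate_detection(truth: SimulationTruth, detected) -> dict:
    """Precision/recall of detected site categories against the injected truth.

    ``detected`` is a list of :class:`SiteClassification`. Returns
    ``{category value: {"precision", "recall", "tp", "detected", "truth"}}``
    for the injected categories. Empty detected and empty truth give 1.0/1.0.
    """
    out = {}
    for category in (SiteCategory.STRICTLY_DIMORPHIC, SiteCategory.FIXED_VARIABLE):
        truth_cols = set(truth.columns(category))
        detected_cols = {sc.column for sc in detected if sc.category is category}
        tp = len(truth_cols & detected_cols)
        precision = tp / len(detected_cols) if detected_cols else (1.0 if not truth_cols else 0.0)
        recall = tp / len(truth_cols) if truth_cols else 1.0
        out[category.value] = {
            "precision": precision,
            "recall": recall,
            "tp": tp,
            "detected": len(detected_cols),
            "truth": len(truth_cols),
        }
    return out


def realized_gc3(codon_alignment: CodonAlignment, ids=None) -> float:
    """Fraction of G/C at third codon positions over the given sequences."""
    if ids is None:
        ids = codon_alignment.ids
    gc = total = 0
    for sid in ids:
        row = codon_alignment.row(sid)
        for j in range(2, len(row), 3):
            if row[j] in "ACGT":
                total += 1
                if row[j] in "GC":
                    gc += 1
    return gc / total if total else float("nan")
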