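"""Identity-threshold gene-family assignment and family frequency ratios.

Follows the ALDH Gene Nomenclature Committee convention: proteins sharing more
than 40% amino-acid identity belong to one family, more than 60% to one
subfamily. Pairwise identities come from global alignments
(:func:`lineagediv.seq_core.pairwise_identity`); clusters are the connected
components of the thresholded identity graph (single linkage, the weakest
consistent reading of the pairwise rule), so subfamilies always refine
families. Cluster numbering is deterministic: clusters are ordered by their
lexicographically smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .seq_core import SequenceRecord, pairwise_identity


@dataclass(frozen=True)
class AGNCThresholds:
    """Percent-identity cutoffs; membership requires strictly greater identity."""

    family_min_identity: float = 40.0
    subfamily_min_identity: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.family_min_identity < self.subfamily_min_identity <= 100.0:
            raise ValueError(
                "thresholds must satisfy 0 < family < subfamily <= 100, got "
                f"{self.family_min_identity} / {self.subfamily_min_identity}"
            )


@dataclass
class FamilyAssignment:
    """Per-sequence family/subfamily cluster labels plus the identity matrix used."""

    assignments: dict  # id -> (family_id, subfamily_id), both 1-based ints
    families: dict  # family_id -> sorted list of ids
    subfamilies: dict  # (family_id, subfamily_id) -> sorted list of ids
    identity: pd.DataFrame
    thresholds: AGNCThresholds

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": sid, "family_cluster": fam, "subfamily_cluster": sub}
            for sid, (fam, sub) in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["id", "family_cluster", "subfamily_cluster"])


def identity_matrix(records, **kwargs) -> pd.DataFrame:
    """Symmetric percent-identity matrix over all pairs (diagonal 100)."""
    ids = [r.id for r in records]
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(records[i], records[j], **kwargs)
    return pd.DataFrame(mat, index=ids, columns=ids)


def _components(ids, adjacency: np.ndarray) -> list:
    """Connected components as lists of ids, ordered by smallest member id."""
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    groups: dict = {}
    for sid, lab in zip(ids, labels):
        groups.setdefault(lab, []).append(sid)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def assign_families(
    records,
    thresholds: AGNCThresholds = AGNCThresholds(),
    identity: pd.DataFrame = None,
    **identity_kwargs,
) -> FamilyAssignment:
    """Cluster protein records into families and nested subfamilies.

    ``identity`` may be supplied to reuse a precomputed matrix; otherwise all
    pairwise global alignments are computed. Order of input records never
    affects cluster membership or numbering.
    """
    records = list(records)
    if not records:
        raise ValueError("assign_families requires at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if identity is None:
        identity = identity_matrix(records, **identity_kwargs)
    identity = identity.loc[ids, ids]
    mat = identity.to_numpy()

    fam_adj = mat > thresholds.family_min_identity
    families = _components(ids, fam_adj)

    assignments: dict = {}
    fam_map: dict = {}
    sub_map: dict = {}
    for fam_id, members in enumerate(families, start=1):
        fam_map[fam_id] = members
        idx = [ids.index(m) for m in members]
        sub_adj = mat[np.ix_(idx, idx)] > thresholds.subfamily_min_identity
        subfams = _components(members, sub_adj)
        for sub_id, sub_members in enumerate(subfams, start=1):
            sub_map[(fam_id, sub_id)] = sub_members
            for sid in sub_members:
                assignments[sid] = (fam_id, sub_id)
    return FamilyAssignment(assignments, fam_map, sub_map, identity, thresholds)


def family_frequencies(assignment: FamilyAssignment) -> pd.Series:
    """Ratio of genes per family to the total gene count; sums to 1."""
    total = len(assignment.assignments)
    if total == 0:
        raise ValueError("empty assignment")
    counts = {fam: len(members) for fam, members in assignment.families.items()}
    freq = pd.Series(counts, name="frequency").sort_index() / total
    freq.index.name = "family_cluster"
    return freq
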