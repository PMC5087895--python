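"""End-to-end pipeline: codon alignment -> filtered statistics -> report bundle.

Stages (each optional piece of the bundle mirrors one report table):

1. read aligned protein FASTA + CDS FASTA + two-lineage partition;
2. back-translate to a codon alignment;
3. partial deletion at the configured coverage (codon columns atomic);
4. parsimony-informative sites (nucleotide and residue level);
5. lineage site classification + per-isoform residue numbering;
6. codon-position composition, amino-acid composition, per-lineage RSCU;
7. within/between divergence, codon Z-test, per-site dN/dS, Tajima's D;
8. optional family/subfamily classification of the input proteins.

All outputs are TSV/JSON plus a manifest recording parameters and seeds, so
every number is reproducible by calling the underlying function with the
manifest's values. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import amino_acid_composition, codon_position_composition, rscu
from .family_classify import AGNCThresholds, assign_families, family_frequencies
from .seq_core import (
    STANDARD_CODE,
    GeneticCode,
    ProteinAlignment,
    back_translate,
    partial_deletion,
    read_fasta,
)
from .selection import codon_z_test, group_divergence, per_site_dnds, tajimas_d
from .site_polymorphism import (
    LineagePartition,
    classification_table,
    classify_lineage_sites,
    parsimony_informative_sites,
    residue_number_table,
)


@dataclass
class PipelineConfig:
    aligned_fasta: str
    cds_fasta: str
    partition: str
    outdir: str
    coverage: float = 0.95
    family_identity: float = 40.0
    subfamily_identity: float = 60.0
    model: str = "p"  # nucleotide distance model: p | jc
    n_boot: int = 1000
    seed: int = 0
    genetic_code: int = 1
    site_scope: str = "informative"
    classify_families: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")
        for name in ("aligned_fasta", "cds_fasta", "partition"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_tsv(frame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns a manifest dict (also written as ``manifest.json``). On any stage
    failure the partially written bundle is removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list = []
    stage = "setup"
    try:
        stage = "read inputs"
        code = GeneticCode.from_ncbi_id(config.genetic_code)
        aligned = ProteinAlignment.from_records(read_fasta(config.aligned_fasta, "protein"))
        cds = read_fasta(config.cds_fasta, "cds")
        partition = LineagePartition.read_tsv(config.partition)

        stage = "back-translation"
        codon_aln = back_translate(aligned, cds, code)

        stage = "partial deletion"
        codon_aln = partial_deletion(codon_aln, config.coverage)
        protein_aln = codon_aln.to_protein(code)

        stage = "informative sites"
        nt_sites = parsimony_informative_sites(codon_aln)
        aa_sites = parsimony_informative_sites(protein_aln)
        sites_frame = pd.DataFrame(
            {
                "level": ["nucleotide"] * len(nt_sites) + ["residue"] * len(aa_sites),
                "column": nt_sites + aa_sites,
            }
        )
        path = outdir / "informative_sites.tsv"
        _write_tsv(sites_frame, path, "parsimony-informative columns (post partial deletion coordinates)")
        written.append(path)

        stage = "site classification"
        classifications = classify_lineage_sites(protein_aln, partition, sites=config.site_scope)
        cls_frame = classification_table(classifications, partition)
        path = outdir / "site_classification.tsv"
        _write_tsv(cls_frame, path, "lineage polymorphism classification per alignment column")
        written.append(path)
        res_frame = residue_number_table(protein_aln, classifications)
        path = outdir / "residue_numbers.tsv"
        _write_tsv(res_frame, path, "per-isoform residue numbers at lineage-diagnostic columns")
        written.append(path)

        stage = "composition"
        nt_comp = codon_position_composition(codon_aln, partition, config.site_scope)
        path = outdir / "composition_nucleotide.tsv"
        _write_tsv(nt_comp.summary_frame(), path, "base frequency (%) by codon position, mean ± SE per lineage")
        written.append(path)
        aa_comp = amino_acid_composition(protein_aln, partition, config.site_scope)
        path = outdir / "composition_amino_acid.tsv"
        _write_tsv(aa_comp.summary_frame(), path, "amino-acid frequency (%), mean ± SE per lineage")
        written.append(path)

        stage = "RSCU"
        cds_by_id = {rec.id: rec for rec in cds}
        rscu_frames = []
        for label in partition.labels:
            table = rscu([cds_by_id[sid] for sid in partition.group(label) if sid in cds_by_id], code)
            frame = table.table.copy()
            frame.insert(0, "lineage", label)
            rscu_frames.append(frame)
        path = outdir / "rscu.tsv"
        _write_tsv(pd.concat(rscu_frames, ignore_index=True), path, "relative synonymous codon usage per lineage")
        written.append(path)

        stage = "selection statistics"
        divergence = group_divergence(
            codon_aln, partition, config.model, config.n_boot, config.seed
        )
        z_within = codon_z_test(
            codon_aln, partition, "purifying", config.n_boot, config.seed, code
        )
        per_site = per_site_dnds(codon_aln, code)
        path = outdir / "per_site_dnds.tsv"
        _write_tsv(per_site.per_site, path, "per-codon-column Nei-Gojobori counts and dN/dS category")
        written.append(path)
        tajima = tajimas_d(codon_aln, "complete")
        selection_summary = {
            "divergence": {
                "model": divergence.model,
                "within": {lab: {"mean": m, "se": s} for lab, (m, s) in divergence.within.items()},
                "between": {"mean": divergence.between[0], "se": divergence.between[1]},
            },
            "z_test": {
                "alternative": z_within.alternative,
                "z": _json_float(z_within.z),
                "p": z_within.p,
                "mean_dS": z_within.mean_dS,
                "mean_dN": z_within.mean_dN,
                "n_pairs": z_within.n_pairs,
                "flagged": z_within.flagged,
            },
            "per_site_dnds": per_site.counts,
            "tajima": {
                "D": _json_float(tajima.D),
                "S": tajima.S,
                "n": tajima.n,
                "L": tajima.L,
                "pi": tajima.pi,
                "theta_w": tajima.theta_w,
            },
        }
        path = outdir / "selection.json"
        path.write_text(json.dumps(selection_summary, indent=2, sort_keys=True))
        written.append(path)

        if config.classify_families:
            stage = "family classification"
            proteins = [
                rec
                for rec in (
                    dataclasses.replace(r, seq=r.seq.replace("-", ""))
                    for r in aligned.to_records()
                )
            ]
            assignment = assign_families(
                proteins,
                AGNCThresholds(config.family_identity, config.subfamily_identity),
            )
            path = outdir / "families.tsv"
            _write_tsv(assignment.to_frame(), path, "identity-threshold family/subfamily clusters")
            written.append(path)
            freq = family_frequencies(assignment).reset_index()
            path = outdir / "family_frequencies.json"
            path.write_text(
                json.dumps(
                    {str(int(r.family_cluster)): r.frequency for r in freq.itertuples()},
                    indent=2,
                    sort_keys=True,
                )
            )
            written.append(path)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "n_sequences": len(codon_aln.ids),
            "n_codon_columns": codon_aln.n_codon_columns,
            "kept_columns": codon_aln.original_columns,
            "outputs": [p.name for p in written],
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _json_float(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x
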