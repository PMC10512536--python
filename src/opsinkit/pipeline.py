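"""End-to-end orchestration: simulate -> curate -> annotate -> introns
-> reconcile -> expression, all stages communicating via on-disk
standard formats so any stage can be replaced independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import PipelineError
from . import intron_projection, locus_curation, reconciliation
from .io_core import SeqRecord, write_fasta, write_gff_gene_models, write_newick
from .site_annotation import annotation_table
from .expression_summary import calls_to_frame, peak_stage, sex_bias_flags
from .synthetic_data import ArtifactSpec, ExpressionSpec, SimConfig, simulate_study

_KNOWN_KEYS = {"seed", "outdir", "sim", "curation", "expression", "log_level"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_ARTIFACT_KEYS = {f.name for f in dataclasses.fields(ArtifactSpec)}
_EXPR_KEYS = {f.name for f in dataclasses.fields(ExpressionSpec)}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int
    outdir: Path
    sim: SimConfig = None  # built in __post_init__ when absent
    curation: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = dict(raw.get("sim", {}))
        unknown = set(sim_raw) - _SIM_KEYS
        if unknown:
            raise PipelineError(f"unknown sim config keys: {sorted(unknown)}")
        if "artifact" in sim_raw:
            bad = set(sim_raw["artifact"]) - _ARTIFACT_KEYS
            if bad:
                raise PipelineError(f"unknown artifact keys: {sorted(bad)}")
            sim_raw["artifact"] = ArtifactSpec(**sim_raw["artifact"])
        if "expression" in sim_raw:
            bad = set(sim_raw["expression"]) - _EXPR_KEYS
            if bad:
                raise PipelineError(f"unknown expression keys: {sorted(bad)}")
            sim_raw["expression"] = ExpressionSpec(**sim_raw["expression"])
        sim_raw.setdefault("seed", raw["seed"])
        return cls(
            seed=raw["seed"],
            outdir=raw.get("outdir", "opsinkit_run"),
            sim=SimConfig(**sim_raw),
            curation=raw.get("curation", {}),
            expression=raw.get("expression", {}),
            log_level=raw.get("log_level", "INFO"),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one simulated study; returns the summary dict.

    Stage outputs land under ``config.outdir``; a stage failure raises
    :class:`PipelineError` naming the stage.  Reruns with the same
    config and seed are byte-identical.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("simulate")
    def sim_result():
        family, emitted, assemblies, matrix, sheet = simulate_study(config.sim)
        write_fasta(
            [SeqRecord(id=c, seq=s, moltype="dna")
             for c, s in assemblies.genome.items()], out / "genome.fasta")
        write_fasta(
            [SeqRecord(id=c, seq=s, moltype="dna")
             for c, s in assemblies.second_genome.items()],
            out / "genome_asm2.fasta")
        write_gff_gene_models(assemblies.models, out / "models.gff3")
        write_gff_gene_models(assemblies.second_models, out / "models_asm2.gff3")
        write_fasta(emitted.proteins, out / "proteins.fasta")
        write_fasta(assemblies.cds, out / "cds.fasta")
        write_newick(family.gene_tree, out / "gene_tree.nwk")
        write_newick(family.species_tree, out / "species_tree.nwk")
        family.truth.to_tsv(out / "truth.tsv")
        matrix.to_csv(out / "tpm.tsv", sep="\t")
        sheet.to_csv(out / "samples.tsv", sep="\t")
        return family, emitted, assemblies, matrix, sheet

    family, emitted, assemblies, matrix, sheet = sim_result

    @stage("curate")
    def curation_report():
        report = locus_curation.curate_repertoire(
            assemblies.cds,
            assemblies.models,
            assemblies.genome,
            second_genome=assemblies.second_genome,
            second_models=assemblies.second_models,
            flank_len=config.curation.get(
                "flank_len", config.sim.artifact.flank_window),
            **{k: v for k, v in config.curation.items() if k != "flank_len"},
        )
        report.to_tsv(out / "curation.tsv")
        return report

    summary["final_locus_count"] = len(curation_report.retained)
    summary["removed"] = len(curation_report.removals)

    @stage("annotate")
    def annotation():
        table = annotation_table(emitted.proteins)
        table.to_csv(out / "annotation.tsv", sep="\t")
        return table

    summary["n_annotated"] = len(annotation)
    summary["n_with_K296"] = int((annotation["K296"] == True).sum())  # noqa: E712

    @stage("introns")
    def intron_report():
        rows = []
        per_gene = {}
        for model in emitted.models:
            if not model.complete:
                continue
            bounds = intron_projection.cds_intron_phases(model)
            protein = next(p.seq for p in emitted.proteins if p.id == model.gene_id)
            bounds = intron_projection.project_to_alignment(bounds, protein)
            per_gene[model.gene_id] = bounds
            rows += [{
                "gene_id": b.gene_id, "intron_index": b.intron_index,
                "phase": b.phase, "residue_index": b.residue_index,
                "alignment_column": b.alignment_column,
            } for b in bounds]
        pd.DataFrame(rows).to_csv(out / "introns.tsv", sep="\t", index=False)
        return per_gene

    summary["n_intron_boundaries"] = sum(len(v) for v in intron_report.values())

    @stage("reconcile")
    def reconcile_result():
        rec = reconciliation.lca_reconcile(family.gene_tree, family.species_tree)
        (out / "reconciled_gene_tree.nwk").write_text(
            rec.annotated_gene_tree_newick() + "\n")
        rows = [{
            "species_node": node.name or "+".join(sorted(node.leaf_names())),
            "implied_count": rec.implied_counts[node],
            "losses_on_branch_above": rec.losses_per_branch[node],
        } for node in family.species_tree.postorder()]
        pd.DataFrame(rows).to_csv(out / "ancestral_counts.tsv", sep="\t",
                                  index=False)
        return rec

    summary["duplications"] = reconcile_result.duplications_total
    summary["losses"] = reconcile_result.losses_total
    summary["root_count"] = reconcile_result.implied_counts[
        family.species_tree.root]

    @stage("expression")
    def expression_calls():
        peaks = peak_stage(matrix, sheet)
        biases = sex_bias_flags(matrix, sheet, **config.expression)
        frame = calls_to_frame(peaks, biases)
        frame.to_csv(out / "expression_calls.tsv", sep="\t")
        return frame

    summary["n_sex_biased"] = int(
        (expression_calls["sex_bias"] != "none").sum())
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
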