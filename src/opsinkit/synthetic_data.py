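"""Synthetic genomes, gene families and expression matrices with a
ground-truth log.

The generator emulates the structure of an anthozoan opsin study
without any external data: gene families evolve by birth-death along a
fixed seven-taxon anthozoan-like species tree; every gene carries a
GPCR-scaffold coding sequence derived from the bovine rhodopsin
reference with configurable residues planted at the canonical
functional sites; duplicates arising by retrotransposition are
intronless; assembly artifacts are injected as near-identical adjacent
locus copies (optionally split by an N-run and absent from a second
assembly); and stage/sex expression matrices carry designated peak
stages and sex-biased transcripts under log-normal noise.

Everything downstream is tested against the :class:`TruthLog` the
generator emits, never against intermediate pipeline state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import OpsinkitError
from .io_core import GeneModel, SeqRecord, Tree, TreeNode, parse_newick
from .site_annotation import default_frame

# Seven-taxon anthozoan-like species tree: two sea anemone lineages,
# stony corals + corallimorphs, zoanthids, tube anemones, soft corals.
DEFAULT_SPECIES_TREE = (
    "(((((Actiniaria_A:1,Actiniaria_B:1):0.5,"
    "(Scleractinia:1,Corallimorpharia:1):0.5):0.5,"
    "Zoantharia:2):1,Ceriantharia:3):1,Octocorallia:4);"
)

STAGES = ("blastula", "gastrula", "planula", "polyp", "adult_male", "adult_female")

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"
_AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ArtifactSpec:
    n_artifacts: int = 2
    cds_identity: float = 99.0            # percent, injected copy vs original
    flank_identity: float = 99.5          # percent
    n_run_length: int = 100               # 0 disables the N-run
    n_true_tandem: int = 1                # genuine tandem paralogs (negative controls)
    true_tandem_flank_identity: float = 70.0
    flank_window: int = 400               # nt of flank copied with each locus


@dataclass
class ExpressionSpec:
    n_replicates: int = 2
    base_tpm: float = 20.0
    peak_fold: float = 8.0
    sex_fold: float = 10.0
    frac_sex_biased: float = 0.25
    noise_sigma: float = 0.25


@dataclass
class SimConfig:
    """All knobs of the generator; the seed is mandatory."""

    seed: int
    species_tree_newick: str = DEFAULT_SPECIES_TREE
    dup_rate: float = 0.25                # duplications per gene per unit time
    loss_rate: float = 0.1
    retro_prob: float = 0.3               # duplicate copies CDS without introns
    n_introns: int = 3
    intron_len: int = 90
    intergenic_len: int = 600
    aa_mutation_rate: float = 0.05        # per-site, outside the catalog
    randomize_sites: bool = False         # plant random states at catalog sites
    intron_positions: tuple[int, ...] | None = None  # CDS nt offsets, shared by all genes
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    retry_cap: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise OpsinkitError("SimConfig.seed is mandatory")
        if min(self.dup_rate, self.loss_rate) < 0 or not 0 <= self.retro_prob <= 1:
            raise OpsinkitError("rates must be >= 0 and retro_prob in [0,1]")


# Alternative residues planted at catalog sites when randomize_sites is on.
# Keys are reference positions; values the state choices (canonical first).
SITE_CHOICES: dict[int, str] = {
    83: "DNC", 94: "TE", 110: "CS", 113: "EQ", 181: "EQ", 187: "CS",
    292: "AS", 296: "KH",
    134: "DEG", 135: "RKL", 136: "YWF",
    302: "NS", 303: "PA", 306: "YF",
    310: "NH", 311: "KM", 312: "QK", 313: "FL", 314: "RG",
}


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    kind: str                  # {duplication, loss}
    species_branch: str        # label of the species node below the branch
    mechanism: str = "tandem"  # {tandem, retro} for duplications


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    true_counts: dict[str, int] = field(default_factory=dict)   # species-node label -> count
    planted_sites: dict[str, dict[int, str]] = field(default_factory=dict)
    planted_introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    artifact_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    expression: dict[str, dict] = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")

    def to_tsv(self, path) -> None:
        rows = [{"record": "event", "key": e.kind,
                 "value": f"{e.species_branch}:{e.mechanism}"} for e in self.events]
        rows += [{"record": "count", "key": k, "value": v}
                 for k, v in self.true_counts.items()]
        rows += [{"record": "sites", "key": g, "value": json.dumps(v)}
                 for g, v in self.planted_sites.items()]
        rows += [{"record": "introns", "key": g, "value": json.dumps(v)}
                 for g, v in self.planted_introns.items()]
        rows += [{"record": "artifact", "key": a, "value": f"{b}:{kind}"}
                 for a, b, kind in self.artifact_pairs]
        rows += [{"record": "expression", "key": t, "value": json.dumps(v)}
                 for t, v in self.expression.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Birth-death gene family simulation
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("children", "retro", "name")

    def __init__(self, retro: bool = False):
        self.children: list[_Lineage] = []
        self.retro = retro
        self.name: str | None = None


@dataclass
class GeneFamily:
    gene_tree: Tree
    genes_by_species: dict[str, list[str]]
    retro_genes: set[str]
    truth: TruthLog
    species_tree: Tree


def _node_label(node: TreeNode) -> str:
    return node.name or "+".join(sorted(node.leaf_names()))


def simulate_gene_family(config: SimConfig, rng: np.random.Generator | None = None
                         ) -> GeneFamily:
    """Evolve one gene family by birth-death along the species tree.

    Each gene lineage duplicates at rate ``dup_rate`` and dies at rate
    ``loss_rate`` along every species branch; at speciations surviving
    lineages enter both daughter species.  New duplicates are
    retrotransposed (intronless, heritable) with probability
    ``retro_prob``.  Leaves are labeled ``Species__gN``.  If the family
    goes extinct the simulation retries up to ``retry_cap`` times.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    species_tree = parse_newick(config.species_tree_newick)
    lam, mu = config.dup_rate, config.loss_rate

    for _attempt in range(config.retry_cap):
        truth = TruthLog()
        counter = {"g": 0}

        def evolve(lin: _Lineage, t: float, branch_label: str) -> list[_Lineage]:
            total = lam + mu
            while True:
                dt = rng.exponential(1.0 / total) if total > 0 else np.inf
                if dt >= t:
                    return [lin]
                t -= dt
                if rng.random() < lam / total:
                    retro = bool(rng.random() < config.retro_prob)
                    truth.events.append(TruthEvent(
                        "duplication", branch_label,
                        "retro" if retro else "tandem"))
                    a = _Lineage(retro=lin.retro)
                    b = _Lineage(retro=lin.retro or retro)
                    lin.children = [a, b]
                    out = evolve(a, t, branch_label)
                    out += evolve(b, t, branch_label)
                    return out
                truth.events.append(TruthEvent("loss", branch_label))
                return []

        def descend(sp_node: TreeNode, incoming: list[_Lineage]) -> None:
            truth.true_counts[_node_label(sp_node)] = len(incoming)
            if sp_node.is_leaf:
                for lin in incoming:
                    counter["g"] += 1
                    lin.name = f"{sp_node.name}__g{counter['g']}"
                return
            for child in sp_node.children:
                branch_survivors: list[_Lineage] = []
                for lin in incoming:
                    stub = _Lineage(retro=lin.retro)
                    lin.children.append(stub)
                    branch_survivors.extend(
                        evolve(stub, child.length or 1.0, _node_label(child))
                    )
                descend(child, branch_survivors)

        root_lin = _Lineage()
        descend(species_tree.root, [root_lin])

        def to_tree(lin: _Lineage) -> TreeNode | None:
            if lin.name is not None:
                return TreeNode(name=lin.name)
            kids = [t for t in (to_tree(c) for c in lin.children) if t is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = TreeNode(children=[kids[0], kids[1]])
            for extra in kids[2:]:
                node = TreeNode(children=[node, extra])
            return node

        root = to_tree(root_lin)
        if root is None:
            continue

        retro_genes = set()

        def collect_retro(lin: _Lineage) -> None:
            if lin.name is not None and lin.retro:
                retro_genes.add(lin.name)
            for c in lin.children:
                collect_retro(c)

        collect_retro(root_lin)
        gene_tree = Tree(root)
        genes_by_species: dict[str, list[str]] = {
            sp: [] for sp in species_tree.leaf_names()
        }
        for name in gene_tree.leaf_names():
            genes_by_species[name.split("__")[0]].append(name)
        return GeneFamily(
            gene_tree=gene_tree, genes_by_species=genes_by_species,
            retro_genes=retro_genes, truth=truth, species_tree=species_tree,
        )
    raise OpsinkitError(
        f"gene family went extinct in all {config.retry_cap} attempts"
    )


# ---------------------------------------------------------------------------
# Sequence emission
# ---------------------------------------------------------------------------

def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution with 2:1 transition bias."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        base = out[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < 0.5:
            out[i] = _TRANSITION[base]
        else:
            choices = [b for b in _BASES if b != base and b != _TRANSITION[base]]
            out[i] = choices[int(rng.integers(2))]
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][int(rng.integers(len(_CODONS[a])))] for a in protein)


def plant_protein(
    rng: np.random.Generator,
    planted: Mapping[int, str] | None = None,
    randomize: bool = False,
    aa_mutation_rate: float = 0.05,
) -> tuple[str, dict[int, str]]:
    """A rhodopsin-scaffold protein with chosen residues at catalog sites.

    Returns the protein and the exact residue planted at every catalog
    position (the per-gene truth record).
    """
    frame = default_frame()
    ref = list(frame.record.seq)
    catalog_positions = sorted(set(frame.all_positions()))
    states: dict[int, str] = {}
    for pos in catalog_positions:
        if planted and pos in planted:
            states[pos] = planted[pos]
        elif randomize and pos in SITE_CHOICES:
            choices = SITE_CHOICES[pos]
            states[pos] = choices[int(rng.integers(len(choices)))]
        else:
            states[pos] = ref[pos - 1]
        ref[pos - 1] = states[pos]
    protected = set(catalog_positions)
    for i in range(len(ref)):
        if (i + 1) in protected:
            continue
        if rng.random() < aa_mutation_rate:
            ref[i] = _AAS[int(rng.integers(len(_AAS)))]
    return "".join(ref), states


@dataclass
class EmittedGenome:
    genome: dict[str, str]
    models: list[GeneModel]
    proteins: list[SeqRecord]
    cds: list[SeqRecord]


def emit_sequences(family: GeneFamily, config: SimConfig,
                   rng: np.random.Generator | None = None) -> EmittedGenome:
    """Give every simulated gene a coding sequence, structure and locus.

    Each gene is a mutated rhodopsin-scaffold CDS with its planted
    catalog-site states recorded in the truth log.  Non-retro genes get
    introns (at the configured shared CDS offsets, or at random
    per-gene offsets); retroduplicates are intronless.  One chromosome
    per species, genes separated by random intergenic spacers.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    proteins: list[SeqRecord] = []
    cds_records: list[SeqRecord] = []

    for species in sorted(family.genes_by_species):
        genes = family.genes_by_species[species]
        chrom = f"chr_{species}"
        parts: list[str] = [_random_dna(config.intergenic_len, rng)]
        offset = config.intergenic_len
        for gene in genes:
            protein, states = plant_protein(
                rng, randomize=config.randomize_sites,
                aa_mutation_rate=config.aa_mutation_rate,
            )
            family.truth.planted_sites[gene] = states
            cds = _back_translate(protein, rng) + "TAA"
            intronless = gene in family.retro_genes
            if intronless or config.n_introns == 0:
                offsets: list[int] = []
            elif config.intron_positions is not None:
                offsets = sorted(config.intron_positions)
            else:
                lo, hi = 30, len(cds) - 30
                offsets = sorted(
                    int(x) for x in rng.choice(
                        np.arange(lo, hi), size=config.n_introns, replace=False)
                )
            family.truth.planted_introns[gene] = [
                (off // 3 + 1, off % 3) for off in offsets
            ]
            exons: list[tuple[int, int]] = []
            pos = offset
            prev = 0
            for off in offsets:
                exons.append((pos, pos + (off - prev)))
                pos += (off - prev) + config.intron_len
                prev = off
            exons.append((pos, pos + (len(cds) - prev)))
            gene_seq_parts = []
            prev = 0
            for off in offsets:
                gene_seq_parts.append(cds[prev:off])
                gene_seq_parts.append(_random_dna(config.intron_len, rng))
                prev = off
            gene_seq_parts.append(cds[prev:])
            gene_seq = "".join(gene_seq_parts)
            parts.append(gene_seq)
            models.append(GeneModel(
                gene_id=gene, chrom=chrom, strand="+", exons=exons,
            ))
            proteins.append(SeqRecord(id=gene, seq=protein, moltype="protein"))
            cds_records.append(SeqRecord(id=gene, seq=cds, moltype="dna"))
            spacer = _random_dna(config.intergenic_len, rng)
            parts.append(spacer)
            offset = exons[-1][1] + len(spacer)
        genome[chrom] = "".join(parts)
    return EmittedGenome(genome=genome, models=models, proteins=proteins,
                         cds=cds_records)


# ---------------------------------------------------------------------------
# Assembly-artifact injection
# ---------------------------------------------------------------------------

@dataclass
class TwoAssemblies:
    genome: dict[str, str]
    models: list[GeneModel]
    second_genome: dict[str, str]
    second_models: list[GeneModel]
    cds: list[SeqRecord]


def _insert_segment(genome: dict[str, str], models: list[GeneModel],
                    chrom: str, at: int, segment: str) -> None:
    genome[chrom] = genome[chrom][:at] + segment + genome[chrom][at:]
    shift = len(segment)
    for i, m in enumerate(models):
        if m.chrom == chrom and m.span[0] >= at:
            models[i] = GeneModel(
                gene_id=m.gene_id, chrom=m.chrom, strand=m.strand,
                exons=[(s + shift, e + shift) for s, e in m.exons],
                complete=m.complete,
            )


def _copy_locus(genome: dict[str, str], model: GeneModel, window: int,
                cds_rate: float, flank_rate: float,
                rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """A mutated copy of a locus plus its flanks; exons in copy coordinates."""
    lo, hi = model.span
    chrom_seq = genome[model.chrom]
    left = chrom_seq[max(0, lo - window):lo]
    middle = chrom_seq[lo:hi]
    right = chrom_seq[hi:hi + window]
    mutated_middle = list(middle)
    exonic = np.zeros(len(middle), dtype=bool)
    for s, e in model.exons:
        exonic[s - lo:e - lo] = True
    for i in range(len(middle)):
        rate = cds_rate if exonic[i] else flank_rate
        if rng.random() < rate:
            base = middle[i]
            if base in _TRANSITION:
                if rng.random() < 0.5:
                    mutated_middle[i] = _TRANSITION[base]
                else:
                    choices = [b for b in _BASES if b != base and b != _TRANSITION[base]]
                    mutated_middle[i] = choices[int(rng.integers(2))]
    segment = (_mutate_dna(left, flank_rate, rng) + "".join(mutated_middle)
               + _mutate_dna(right, flank_rate, rng))
    exons = [(len(left) + s - lo, len(left) + e - lo) for s, e in model.exons]
    return segment, exons


def inject_assembly_artifacts(
    emitted: EmittedGenome, family: GeneFamily, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TwoAssemblies:
    """Plant haplotype-artifact copies and true tandem paralogs.

    Artifact copies (near-identical CDS *and* flanks, optionally split
    by an N-run) go into the first assembly only; true tandem paralogs
    (near-identical CDS, divergent flanks) go into both assemblies.
    The truth log records each pair with its kind.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    spec = config.artifact
    genome = dict(emitted.genome)
    models = list(emitted.models)
    genome2 = dict(emitted.genome)
    models2 = list(emitted.models)
    cds_records = list(emitted.cds)
    truth = family.truth

    eligible = [m.gene_id for m in emitted.models]
    n_targets = spec.n_true_tandem + spec.n_artifacts
    if n_targets > len(eligible):
        raise OpsinkitError("more injections requested than loci available")
    picked = [eligible[i] for i in
              rng.choice(len(eligible), size=n_targets, replace=False)]
    tandem_targets = picked[:spec.n_true_tandem]
    artifact_targets = picked[spec.n_true_tandem:]

    def inject(target_id: str, kind: str) -> None:
        cds_rate = (100.0 - spec.cds_identity) / 100.0
        if kind == "true_tandem":
            flank_rate = (100.0 - spec.true_tandem_flank_identity) / 100.0
            n_run = ""
        else:
            flank_rate = (100.0 - spec.flank_identity) / 100.0
            n_run = "N" * spec.n_run_length
        model = next(m for m in models if m.gene_id == target_id)
        segment, exons = _copy_locus(genome, model, spec.flank_window,
                                     cds_rate, flank_rate, rng)
        copy_id = f"{target_id}_copy"
        at = model.span[1] + min(50, config.intergenic_len // 4)
        full_segment = n_run + segment
        _insert_segment(genome, models, model.chrom, at, full_segment)
        copy_model = GeneModel(
            gene_id=copy_id, chrom=model.chrom, strand=model.strand,
            exons=[(at + len(n_run) + s, at + len(n_run) + e) for s, e in exons],
        )
        models.append(copy_model)
        copy_cds = "".join(
            genome[model.chrom][s:e] for s, e in copy_model.exons
        )
        cds_records.append(SeqRecord(id=copy_id, seq=copy_cds, moltype="dna"))
        if kind == "true_tandem":
            # a real paralog exists in the second assembly too
            model2 = next(m for m in models2 if m.gene_id == target_id)
            _insert_segment(genome2, models2, model2.chrom,
                            model2.span[1] + min(50, config.intergenic_len // 4),
                            segment)
            at2 = model2.span[1] + min(50, config.intergenic_len // 4)
            models2.append(GeneModel(
                gene_id=copy_id, chrom=model2.chrom, strand=model2.strand,
                exons=[(at2 + s, at2 + e) for s, e in exons],
            ))
        truth.artifact_pairs.append((target_id, copy_id, kind))

    for t in tandem_targets:
        inject(t, "true_tandem")
    for t in artifact_targets:
        inject(t, "artifact")
    return TwoAssemblies(genome=genome, models=models, second_genome=genome2,
                         second_models=models2, cds=cds_records)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def make_expression_matrix(
    config: SimConfig,
    transcripts: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A TPM matrix (transcripts x stage/sex replicates) plus sample sheet.

    Each transcript gets a designated peak stage (TPM ``peak_fold`` times
    the base level there) and, with probability ``frac_sex_biased``, a
    male or female bias of ``sex_fold`` between the adult samples.  TPM
    values carry multiplicative log-normal noise of ``noise_sigma``;
    sigma 0 reproduces the planted means exactly.  The planted truth is
    appended to the family truth log by the caller via the returned
    metadata, or read from ``config``-driven TruthLog entries.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    spec = config.expression
    samples = [f"{stage}_r{i + 1}" for stage in STAGES
               for i in range(spec.n_replicates)]
    sheet = pd.DataFrame({
        "sample": samples,
        "stage": [s.rsplit("_r", 1)[0] for s in samples],
        "sex": ["male" if s.startswith("adult_male")
                else "female" if s.startswith("adult_female") else "none"
                for s in samples],
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    }).set_index("sample")

    rows = {}
    truth: dict[str, dict] = {}
    for t in transcripts:
        peak = STAGES[int(rng.integers(len(STAGES)))]
        bias = "none"
        if rng.random() < spec.frac_sex_biased:
            bias = "female" if rng.random() < 0.5 else "male"
        means = {}
        for stage in STAGES:
            m = spec.base_tpm
            if stage == peak:
                m *= spec.peak_fold
            means[stage] = m
        if bias != "none":
            low = "adult_male" if bias == "female" else "adult_female"
            if peak in ("adult_male", "adult_female"):
                # keep the planted peak on the favoured sex
                favoured = "adult_female" if bias == "female" else "adult_male"
                means[favoured] = spec.base_tpm * spec.peak_fold
                other = "adult_male" if favoured == "adult_female" else "adult_female"
                means[other] = means[favoured] / spec.sex_fold
                peak = favoured
            else:
                means[low] = means[low] / spec.sex_fold
        vals = []
        for s in samples:
            stage = sheet.loc[s, "stage"]
            m = means[stage]
            if spec.noise_sigma > 0:
                m = m * float(np.exp(rng.normal(0.0, spec.noise_sigma)
                                     - spec.noise_sigma ** 2 / 2))
            vals.append(m)
        rows[t] = vals
        fold = spec.sex_fold if bias != "none" else 1.0
        if bias == "none" and peak in ("adult_male", "adult_female"):
            # a peak in one adult sex is itself a sex bias of peak_fold
            bias = "male" if peak == "adult_male" else "female"
            fold = spec.peak_fold
        truth[t] = {"peak": peak, "sex_bias": bias, "fold": fold}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix.index.name = "transcript"
    matrix.attrs["truth"] = truth
    return matrix, sheet


# ---------------------------------------------------------------------------
# Annotation-recovery corpus
# ---------------------------------------------------------------------------

def simulate_annotated_proteins(
    n: int, seed: int, aa_mutation_rate: float = 0.05,
) -> tuple[list[SeqRecord], dict[str, dict[int, str]]]:
    """N rhodopsin-scaffold proteins with randomized planted site states.

    A light-weight corpus for site-annotation recovery tests: returns
    the records and the exact planted residue at every catalog position.
    """
    rng = np.random.default_rng([seed, 5])
    records = []
    truth = {}
    for i in range(n):
        protein, states = plant_protein(
            rng, randomize=True, aa_mutation_rate=aa_mutation_rate)
        rec = SeqRecord(id=f"sim_opsin_{i + 1}", seq=protein, moltype="protein")
        records.append(rec)
        truth[rec.id] = states
    return records, truth


def simulate_study(config: SimConfig) -> tuple[GeneFamily, EmittedGenome,
                                               TwoAssemblies, pd.DataFrame,
                                               pd.DataFrame]:
    """Full generator run: family, sequences, artifacts, expression."""
    family = simulate_gene_family(config)
    emitted = emit_sequences(family, config)
    assemblies = inject_assembly_artifacts(emitted, family, config)
    transcripts = [m.gene_id for m in emitted.models]
    matrix, sheet = make_expression_matrix(config, transcripts)
    family.truth.expression = matrix.attrs["truth"]
    return family, emitted, assemblies, matrix, sheet
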