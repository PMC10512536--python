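"""Candidate deduplication and haplotype/assembly-artifact filtering.

Chromosome-level assemblies of heterozygous genomes frequently carry
both haplotypes of a locus as a pair of adjacent, near-identical
"tandem duplicates".  True recent paralogs share high coding identity
too, so coding identity alone cannot separate them; the giveaways for
an artifact are (a) near-identical *non-coding* flanks (haplotypes
diverge little anywhere, paralogs diverge fast outside exons), (b) an
assembly-gap N-run splitting the pair, and (c) a second, independent
assembly that contains only one copy.  This module implements exactly
that decision rule, with every threshold configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from .errors import OpsinkitError
from .io_core import GeneModel, SeqRecord, extract_cds_and_flanks

VERDICT_ARTIFACT = "artifact"
VERDICT_DISTINCT = "distinct_paralogs"

CORROBORATION_COLLAPSED = "collapsed"
CORROBORATION_BOTH = "both_present"
CORROBORATION_UNKNOWN = "unknown"


@dataclass
class LocusRecord:
    locus_id: str
    chrom: str
    span: tuple[int, int]          # 0-based half-open genomic span
    cds_seq: str
    left_flank: str = ""
    right_flank: str = ""
    assembly_id: str = "asm1"


@dataclass
class ArtifactCall:
    pair: tuple[str, str]
    cds_identity: float
    flank_identity: float | None   # None when no flank sequence available
    n_run_between: bool = False
    n_run_length: int = 0
    corroborated_by_second_assembly: str = CORROBORATION_UNKNOWN
    verdict: str = VERDICT_DISTINCT


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------

@dataclass
class Removal:
    seq_id: str
    reason: str                    # {identical_duplicate, fragment, assembly_artifact}
    detail: str = ""


def dedup_candidates(seqs: Sequence[SeqRecord]) -> tuple[list[SeqRecord], list[Removal]]:
    """Collapse exact duplicates and drop exact-substring fragments.

    The first occurrence (input order) is the retained representative.
    Idempotent: running it on its own output changes nothing.
    """
    removals: list[Removal] = []
    by_seq: dict[str, str] = {}
    unique: list[SeqRecord] = []
    for rec in seqs:
        if rec.seq in by_seq:
            removals.append(Removal(rec.id, "identical_duplicate", f"same as {by_seq[rec.seq]}"))
        else:
            by_seq[rec.seq] = rec.id
            unique.append(rec)
    # fragments: exact substrings of a strictly longer retained sequence
    retained: list[SeqRecord] = []
    for rec in unique:
        host = next(
            (o for o in unique
             if o.id != rec.id and len(o.seq) > len(rec.seq) and rec.seq in o.seq),
            None,
        )
        if host is not None:
            removals.append(Removal(rec.id, "fragment", f"substring of {host.id}"))
        else:
            retained.append(rec)
    return retained, removals


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def pairwise_identity(a: str | SeqRecord, b: str | SeqRecord) -> float:
    """Percent identity from a global nucleotide alignment.

    Matches over aligned columns, excluding terminal gap runs (so a
    length difference at the ends does not count against identity).
    Symmetric in its arguments.
    """
    if isinstance(a, SeqRecord):
        a = a.seq
    if isinstance(b, SeqRecord):
        b = b.seq
    if not a or not b:
        raise OpsinkitError("pairwise_identity: empty sequence")
    if a == b:
        return 100.0
    aln = _dna_aligner().align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    start = 0
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    end = n
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != "-")
    return 100.0 * matches / (end - start)


def longest_n_run(seq: str) -> int:
    best = run = 0
    for ch in seq:
        if ch == "N":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


# ---------------------------------------------------------------------------
# Artifact flagging
# ---------------------------------------------------------------------------

def _flank_identity(a: LocusRecord, b: LocusRecord) -> float | None:
    vals = []
    if a.left_flank and b.left_flank:
        vals.append(pairwise_identity(a.left_flank, b.left_flank))
    if a.right_flank and b.right_flank:
        vals.append(pairwise_identity(a.right_flank, b.right_flank))
    return sum(vals) / len(vals) if vals else None


def flag_assembly_artifacts(
    loci: Sequence[LocusRecord],
    cds_id_threshold: float = 97.0,
    flank_id_threshold: float = 97.0,
    flank_len: int = 2000,
    min_n_run: int = 50,
    genome: dict[str, str] | None = None,
    same_chromosome_only: bool = True,
) -> list[ArtifactCall]:
    """Flag near-identical locus pairs as likely haplotype artifacts.

    Only pairs whose CDS identity exceeds ``cds_id_threshold`` are
    reported at all.  Among those, a pair is called an artifact when its
    flanks are also near-identical (> ``flank_id_threshold``) or when an
    assembly-gap N-run of at least ``min_n_run`` separates the loci;
    otherwise it is kept as distinct paralogs.  By default only
    same-chromosome ("tandem") pairs are considered; lift that with
    ``same_chromosome_only=False`` for fragmented assemblies.
    """
    calls: list[ArtifactCall] = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if same_chromosome_only and a.chrom != b.chrom:
                continue
            cds_id = pairwise_identity(a.cds_seq, b.cds_seq)
            if cds_id <= cds_id_threshold:
                continue
            flank_id = _flank_identity(a, b)
            n_len = 0
            if a.chrom == b.chrom and genome is not None and a.chrom in genome:
                lo = min(a.span[1], b.span[1])
                hi = max(a.span[0], b.span[0])
                if hi > lo:
                    n_len = longest_n_run(genome[a.chrom][lo:hi])
            else:
                # fall back to the flanks facing the partner locus
                first, second = (a, b) if a.span <= b.span else (b, a)
                n_len = max(longest_n_run(first.right_flank),
                            longest_n_run(second.left_flank))
            has_n = n_len >= min_n_run
            artifact = (flank_id is not None and flank_id > flank_id_threshold) or has_n
            calls.append(ArtifactCall(
                pair=(a.locus_id, b.locus_id),
                cds_identity=cds_id,
                flank_identity=flank_id,
                n_run_between=has_n,
                n_run_length=n_len,
                verdict=VERDICT_ARTIFACT if artifact else VERDICT_DISTINCT,
            ))
    return calls


def cross_assembly_corroborate(
    calls: Sequence[ArtifactCall],
    loci: Sequence[LocusRecord],
    second_assembly_loci: Sequence[LocusRecord],
    min_hit_identity: float = 90.0,
) -> list[ArtifactCall]:
    """Check flagged pairs against an independent assembly.

    If both members of a pair best-match the *same* locus of the second
    assembly, the pair was collapsed there — corroborating the artifact
    call.  If they match two distinct loci, both copies exist
    independently and the verdict is overridden to distinct paralogs.
    No hit above ``min_hit_identity`` leaves the call unchanged as
    ``unknown``.
    """
    by_id = {l.locus_id: l for l in loci}

    def best_match(locus: LocusRecord) -> str | None:
        best_id, best_val = None, min_hit_identity
        for cand in second_assembly_loci:
            ident = pairwise_identity(locus.cds_seq, cand.cds_seq)
            if ident >= best_val:
                best_id, best_val = cand.locus_id, ident
        return best_id

    out = []
    for call in calls:
        call = ArtifactCall(**vars(call))
        a, b = (by_id.get(x) for x in call.pair)
        if a is None or b is None or not second_assembly_loci:
            out.append(call)
            continue
        ma, mb = best_match(a), best_match(b)
        if ma is None or mb is None:
            call.corroborated_by_second_assembly = CORROBORATION_UNKNOWN
        elif ma == mb:
            call.corroborated_by_second_assembly = CORROBORATION_COLLAPSED
        else:
            call.corroborated_by_second_assembly = CORROBORATION_BOTH
            call.verdict = VERDICT_DISTINCT
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# Full curation
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    retained: list[SeqRecord]
    removals: list[Removal]
    artifact_calls: list[ArtifactCall] = field(default_factory=list)

    @property
    def final_ids(self) -> list[str]:
        return [r.id for r in self.retained]

    def to_tsv(self, path) -> None:
        import pandas as pd
        rows = [{"seq_id": r.id, "status": "retained", "reason": "", "detail": ""}
                for r in self.retained]
        rows += [{"seq_id": r.seq_id, "status": "removed", "reason": r.reason,
                  "detail": r.detail} for r in self.removals]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_locus_records(
    gene_models: Sequence[GeneModel],
    genome: dict[str, str],
    flank_len: int = 2000,
    assembly_id: str = "asm1",
) -> list[LocusRecord]:
    records = []
    for m in gene_models:
        ext = extract_cds_and_flanks(genome, m, flank_len=flank_len)
        records.append(LocusRecord(
            locus_id=m.gene_id, chrom=m.chrom, span=m.span, cds_seq=ext.cds,
            left_flank=ext.left_flank, right_flank=ext.right_flank,
            assembly_id=assembly_id,
        ))
    return records


def curate_repertoire(
    candidates: Sequence[SeqRecord],
    gene_models: Sequence[GeneModel],
    genome: dict[str, str],
    second_genome: dict[str, str] | None = None,
    second_models: Sequence[GeneModel] | None = None,
    cds_id_threshold: float = 97.0,
    flank_id_threshold: float = 97.0,
    flank_len: int = 2000,
    min_n_run: int = 50,
) -> CurationReport:
    """Dedup -> artifact filter -> cross-assembly corroboration.

    ``candidates`` are CDS sequences whose ids match gene-model ids.
    Every removal carries a reason code; of each artifact pair the
    first-listed locus is retained.
    """
    retained, removals = dedup_candidates(candidates)
    retained_ids = {r.id for r in retained}
    models = {m.gene_id: m for m in gene_models}
    loci = build_locus_records(
        [models[r.id] for r in retained if r.id in models], genome, flank_len=flank_len
    )
    calls = flag_assembly_artifacts(
        loci, cds_id_threshold=cds_id_threshold, flank_id_threshold=flank_id_threshold,
        flank_len=flank_len, min_n_run=min_n_run, genome=genome,
    )
    if second_genome is not None and second_models is not None:
        second_loci = build_locus_records(
            second_models, second_genome, flank_len=flank_len, assembly_id="asm2"
        )
        calls = cross_assembly_corroborate(calls, loci, second_loci)
    to_remove: dict[str, str] = {}
    for call in calls:
        if call.verdict == VERDICT_ARTIFACT:
            keep, drop = call.pair
            if keep in to_remove:          # keep already removed; spare drop
                continue
            to_remove.setdefault(drop, f"haplotype copy of {keep}")
    final = [r for r in retained if r.id not in to_remove]
    removals += [Removal(x, "assembly_artifact", d) for x, d in to_remove.items()]
    return CurationReport(retained=final, removals=removals, artifact_calls=calls)
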