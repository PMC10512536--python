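"""Dedup, identity, and haplotype/assembly-artifact filtering."""

import numpy as np
import pytest

from opsinkit.io_core import SeqRecord, revcomp
from opsinkit.locus_curation import (
    ArtifactCall,
    CORROBORATION_BOTH,
    CORROBORATION_COLLAPSED,
    CORROBORATION_UNKNOWN,
    LocusRecord,
    VERDICT_ARTIFACT,
    VERDICT_DISTINCT,
    cross_assembly_corroborate,
    curate_repertoire,
    dedup_candidates,
    flag_assembly_artifacts,
    pairwise_identity,
)
from opsinkit.synthetic_data import (
    ArtifactSpec,
    SimConfig,
    emit_sequences,
    inject_assembly_artifacts,
    simulate_gene_family,
)


def _dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, n_subs, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestDedup:
    def test_identical_sequences_collapse_to_first(self):
        seqs = [SeqRecord("a", "ACGTACGT", "dna"), SeqRecord("b", "ACGTACGT", "dna")]
        retained, removals = dedup_candidates(seqs)
        assert [r.id for r in retained] == ["a"]
        assert removals[0].reason == "identical_duplicate"

    def test_exact_substring_removed_as_fragment(self):
        long = _dna(600, 1)
        seqs = [SeqRecord("full", long, "dna"),
                SeqRecord("frag", long[100:340], "dna")]
        retained, removals = dedup_candidates(seqs)
        assert [r.id for r in retained] == ["full"]
        assert removals[0].reason == "fragment" and "full" in removals[0].detail

    def test_high_similarity_but_distinct_sequences_both_kept(self):
        a = _dna(500, 2)
        b = _mutate(a, 25, 3)  # 95% identity
        retained, removals = dedup_candidates(
            [SeqRecord("a", a, "dna"), SeqRecord("b", b, "dna")])
        assert len(retained) == 2 and not removals

    def test_dedup_is_idempotent(self):
        seqs = [SeqRecord("a", "ACGTACGTAA", "dna"),
                SeqRecord("b", "ACGTACGTAA", "dna"),
                SeqRecord("c", "GTACG", "dna")]
        once, _ = dedup_candidates(seqs)
        twice, removals = dedup_candidates(once)
        assert [r.id for r in twice] == [r.id for r in once] and not removals


class TestPairwiseIdentity:
    def test_identical_sequences_are_100(self):
        s = _dna(500, 4)
        assert pairwise_identity(s, s) == 100.0

    def test_ten_substitutions_in_500_is_98(self):
        a = _dna(500, 5)
        b = _mutate(a, 10, 6)
        assert pairwise_identity(a, b) == pytest.approx(98.0)

    def test_reverse_complement_is_not_special_cased(self):
        a = _dna(400, 7)
        assert pairwise_identity(a, revcomp(a)) < 70.0

    def test_symmetric(self):
        a, b = _dna(300, 8), _dna(300, 9)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def _locus(lid, cds, left="", right="", chrom="chr1", span=(0, 1)):
    return LocusRecord(locus_id=lid, chrom=chrom, span=span, cds_seq=cds,
                       left_flank=left, right_flank=right)


class TestArtifactFlagging:
    def setup_method(self):
        self.cds = _dna(900, 10)
        self.cds_similar = _mutate(self.cds, 13, 11)       # ~98.6%
        self.flank = _dna(800, 12)
        self.flank_similar = _mutate(self.flank, 8, 13)    # 99%
        self.flank_diverged = _mutate(self.flank, 320, 14) # ~60%

    def test_near_identical_cds_and_flanks_is_artifact(self):
        calls = flag_assembly_artifacts([
            _locus("a", self.cds, self.flank, self.flank, span=(0, 900)),
            _locus("b", self.cds_similar, self.flank_similar,
                   self.flank_similar, span=(2000, 2900)),
        ])
        assert len(calls) == 1 and calls[0].verdict == VERDICT_ARTIFACT

    def test_divergent_flanks_keep_distinct_paralogs(self):
        calls = flag_assembly_artifacts([
            _locus("a", self.cds, self.flank, self.flank, span=(0, 900)),
            _locus("b", self.cds_similar, self.flank_diverged,
                   self.flank_diverged, span=(2000, 2900)),
        ])
        assert len(calls) == 1 and calls[0].verdict == VERDICT_DISTINCT

    def test_n_run_between_loci_is_artifact_without_flanks(self):
        genome = {"chr1": _dna(900, 15) + "N" * 500 + _dna(900, 16)}
        calls = flag_assembly_artifacts(
            [_locus("a", self.cds, span=(0, 900)),
             _locus("b", self.cds_similar, span=(1400, 2300))],
            genome=genome)
        assert calls[0].n_run_between and calls[0].n_run_length == 500
        assert calls[0].verdict == VERDICT_ARTIFACT

    def test_pairs_below_cds_threshold_never_reported(self):
        far = _mutate(self.cds, 90, 17)  # 90%
        calls = flag_assembly_artifacts([
            _locus("a", self.cds, self.flank, self.flank, span=(0, 900)),
            _locus("b", far, self.flank_similar, self.flank_similar,
                   span=(2000, 2900)),
        ])
        assert calls == []

    def test_different_chromosomes_skipped_by_default(self):
        calls = flag_assembly_artifacts([
            _locus("a", self.cds, chrom="chr1", span=(0, 900)),
            _locus("b", self.cds_similar, chrom="chr2", span=(0, 900)),
        ])
        assert calls == []
        lifted = flag_assembly_artifacts([
            _locus("a", self.cds, self.flank, self.flank, chrom="chr1",
                   span=(0, 900)),
            _locus("b", self.cds_similar, self.flank_similar,
                   self.flank_similar, chrom="chr2", span=(0, 900)),
        ], same_chromosome_only=False)
        assert len(lifted) == 1

    def test_raising_cds_threshold_never_adds_calls(self):
        loci = [
            _locus("a", self.cds, self.flank, self.flank, span=(0, 900)),
            _locus("b", self.cds_similar, self.flank_similar,
                   self.flank_similar, span=(2000, 2900)),
            _locus("c", _mutate(self.cds, 25, 18), self.flank_diverged,
                   self.flank_diverged, span=(4000, 4900)),
        ]
        previous = None
        for threshold in (90.0, 95.0, 97.0, 99.0):
            n = len(flag_assembly_artifacts(loci, cds_id_threshold=threshold))
            if previous is not None:
                assert n <= previous
            previous = n


class TestCorroboration:
    def _call(self):
        return ArtifactCall(pair=("a", "b"), cds_identity=99.0,
                            flank_identity=99.0, verdict=VERDICT_ARTIFACT)

    def test_both_members_matching_one_locus_is_collapsed(self):
        cds = _dna(900, 20)
        loci = [_locus("a", cds), _locus("b", _mutate(cds, 10, 21))]
        second = [_locus("s1", _mutate(cds, 5, 22))]
        (out,) = cross_assembly_corroborate([self._call()], loci, second)
        assert out.corroborated_by_second_assembly == CORROBORATION_COLLAPSED
        assert out.verdict == VERDICT_ARTIFACT

    def test_two_distinct_matches_override_to_distinct(self):
        cds = _dna(900, 23)
        cds_b = _mutate(cds, 10, 24)
        loci = [_locus("a", cds), _locus("b", cds_b)]
        second = [_locus("s1", _mutate(cds, 2, 25)),
                  _locus("s2", _mutate(cds_b, 2, 26))]
        (out,) = cross_assembly_corroborate([self._call()], loci, second)
        assert out.corroborated_by_second_assembly == CORROBORATION_BOTH
        assert out.verdict == VERDICT_DISTINCT

    def test_no_hit_above_threshold_is_unknown(self):
        loci = [_locus("a", _dna(900, 27)), _locus("b", _dna(900, 28))]
        second = [_locus("s1", _dna(900, 29))]
        (out,) = cross_assembly_corroborate([self._call()], loci, second)
        assert out.corroborated_by_second_assembly == CORROBORATION_UNKNOWN


class TestCurateRepertoire:
    def test_simulated_artifacts_and_fragments_removed_with_reasons(self):
        cfg = SimConfig(seed=77, dup_rate=0.25, loss_rate=0.0,
                        artifact=ArtifactSpec(n_artifacts=2, n_true_tandem=1,
                                              flank_window=400))
        fam = simulate_gene_family(cfg)
        emitted = emit_sequences(fam, cfg)
        asm = inject_assembly_artifacts(emitted, fam, cfg)
        candidates = list(asm.cds)
        # add two exact fragments of real CDSs
        candidates.append(SeqRecord("frag1", asm.cds[0].seq[30:300], "dna"))
        candidates.append(SeqRecord("frag2", asm.cds[1].seq[90:420], "dna"))
        report = curate_repertoire(
            candidates, asm.models, asm.genome,
            second_genome=asm.second_genome, second_models=asm.second_models,
            flank_len=400)
        truth_artifacts = {b for _, b, kind in fam.truth.artifact_pairs
                           if kind == "artifact"}
        removed = {r.seq_id: r.reason for r in report.removals}
        assert removed["frag1"] == "fragment"
        assert removed["frag2"] == "fragment"
        assert {k for k, v in removed.items() if v == "assembly_artifact"} \
            == truth_artifacts
        expected_final = {c.id for c in asm.cds} - truth_artifacts
        assert set(report.final_ids) == expected_final

    def test_no_artifacts_planted_preserves_input(self):
        cfg = SimConfig(seed=78, dup_rate=0.2, loss_rate=0.0,
                        artifact=ArtifactSpec(n_artifacts=0, n_true_tandem=0))
        fam = simulate_gene_family(cfg)
        emitted = emit_sequences(fam, cfg)
        asm = inject_assembly_artifacts(emitted, fam, cfg)
        report = curate_repertoire(asm.cds, asm.models, asm.genome,
                                   flank_len=400)
        assert set(report.final_ids) == {c.id for c in asm.cds}

    def test_all_candidates_identical_keeps_one(self):
        cds = _dna(900, 30)
        candidates = [SeqRecord(f"c{i}", cds, "dna") for i in range(4)]
        report = curate_repertoire(candidates, [], {}, flank_len=400)
        assert report.final_ids == ["c0"]
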