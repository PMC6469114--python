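import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan import generate_genome
from hgtscan.detect import (
    DetectParams,
    Junction,
    JunctionVerdict,
    CandidateInsertion,
    SimilarityBlock,
    anchor_chain_align,
    call_hgt,
    corroborate_junction,
    junction_depth_test,
    overlap_genes,
    segment_candidate,
    transcribed_subset,
    transposase_proximity,
)
from hgtscan.simulate import derive_strain, shred_assembly
from hgtscan.types import DepthTrack, FeatureRecord, GenomicInterval

from _oracles import brute_force_blocks


def _block(start, end, bin_, ident=1.0, sid="sc"):
    return SimilarityBlock(
        interval=GenomicInterval(sid, start, end),
        taxon_bin=bin_,
        identity=ident,
        anchor_count=max(1, end - start - 20),
    )


class TestAnchorChainAlign:
    def test_exact_copy_gives_one_covering_block(self):
        ref = generate_genome(50_000, 0.36, seed=0)
        query = generate_genome(2_000, 0.36, seed=1) + ref[10_000:15_000] \
            + generate_genome(2_000, 0.36, seed=2)
        blocks = anchor_chain_align(query, ref)
        sym = [b for b in blocks if b.interval.length >= 4000]
        assert len(sym) == 1
        b = sym[0]
        assert b.interval.start == pytest.approx(2_000, abs=25)
        assert b.interval.end == pytest.approx(7_000, abs=25)
        assert b.interval.length >= 0.99 * 5_000
        assert b.identity >= 0.9
        assert b.ref_interval.start == pytest.approx(10_000, abs=25)

    def test_unrelated_sequences_give_nothing(self):
        a = generate_genome(3_000, 0.36, seed=3)
        b = generate_genome(3_000, 0.36, seed=4)
        assert anchor_chain_align(a, b) == []

    def test_survives_one_percent_divergence(self):
        ref = generate_genome(40_000, 0.36, seed=5)
        copy, _pos = derive_strain(ref[5_000:10_000], 0.01, seed=6)
        query = generate_genome(1_000, 0.36, seed=7) + copy
        blocks = anchor_chain_align(query, ref)
        assert len(blocks) == 1
        assert blocks[0].interval.start == pytest.approx(1_000, abs=60)
        assert blocks[0].interval.length >= 0.95 * 5_000

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            anchor_chain_align("ACGT" * 10, "ACGT" * 10, k=5)

    def test_matches_brute_force_on_mixed_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(8):
            n = int(rng.integers(200, 1200))
            ref = generate_genome(n, 0.4, seed=int(rng.integers(2**31)))
            if trial % 2 == 0:
                query = generate_genome(n, 0.4, seed=int(rng.integers(2**31)))
            else:
                a = int(rng.integers(0, n // 2))
                b = int(rng.integers(a + 50, n))
                query = (
                    generate_genome(100, 0.4, seed=int(rng.integers(2**31)))
                    + ref[a:b]
                )
            got = [
                (b_.interval.start, b_.interval.end,
                 b_.ref_interval.start, b_.ref_interval.end, b_.anchor_count)
                for b_ in anchor_chain_align(query, ref, k=11, min_block=50)
            ]
            expected = brute_force_blocks(query, ref, k=11, min_block=50)
            assert got == expected


class TestSegmentCandidate:
    def test_interleaved_blocks_yield_one_candidate(self):
        blocks = [
            _block(0, 10_000, "host"),
            _block(10_000, 24_190, "symbiont"),
            _block(24_190, 30_000, "host"),
        ]
        (cand,) = segment_candidate(blocks, 30_000)
        assert (cand.interval.start, cand.interval.end) == (10_000, 24_190)
        assert cand.interval.length == 14_190
        kinds = [j.kind for j in cand.junctions]
        assert kinds == ["internal", "internal"]

    def test_scaffold_edge_insert_has_one_internal_junction(self):
        blocks = [
            _block(0, 38_814, "symbiont"),
            _block(38_814, 60_000, "host"),
        ]
        (cand,) = segment_candidate(blocks, 60_000)
        assert cand.interval.start == 0
        kinds = sorted(j.kind for j in cand.junctions)
        assert kinds == ["edge", "internal"]

    def test_only_host_blocks_give_no_candidates(self):
        blocks = [_block(0, 10_000, "host"), _block(12_000, 30_000, "host")]
        assert segment_candidate(blocks, 30_000) == []

    def test_overlap_resolved_by_higher_identity(self):
        blocks = [
            _block(0, 12_000, "host", ident=0.80),
            _block(10_000, 24_000, "symbiont", ident=0.99),
            _block(24_000, 30_000, "host", ident=0.99),
        ]
        (cand,) = segment_candidate(blocks, 30_000)
        # host block trimmed back to 10_000, junction at the midpoint
        assert cand.interval.start == 10_000

    def test_symbiont_runs_merged_across_small_gaps(self):
        blocks = [
            _block(0, 10_000, "host"),
            _block(10_000, 14_000, "symbiont"),
            _block(14_300, 20_000, "symbiont"),
            _block(20_000, 30_000, "host"),
        ]
        (cand,) = segment_candidate(blocks, 30_000, max_gap=500)
        assert (cand.interval.start, cand.interval.end) == (10_000, 20_000)
        assert cand.n_symbiont_blocks == 2


class TestJunctionDepthTest:
    def test_constant_depth_continuous(self):
        t = DepthTrack("s", np.full(3_000, 47.0))
        v = junction_depth_test(t, 1_500)
        assert v.verdict == "continuous"
        assert v.log2_ratio == 0.0

    def test_step_detected(self):
        values = np.concatenate([np.full(1_500, 47.0), np.full(1_500, 120.0)])
        v = junction_depth_test(DepthTrack("s", values), 1_500)
        assert v.verdict == "step_change"
        assert v.log2_ratio == pytest.approx(math.log2(47.5 / 120.5), abs=1e-9)

    def test_near_edge_indeterminate(self):
        t = DepthTrack("s", np.full(3_000, 47.0))
        assert junction_depth_test(t, 50).verdict == "indeterminate"

    def test_dropout_window_indeterminate(self):
        values = np.concatenate([np.zeros(1_500), np.full(1_500, 47.0)])
        v = junction_depth_test(DepthTrack("s", values), 1_500)
        assert v.verdict == "indeterminate"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(700, 2_300))
    def test_mirror_symmetry(self, seed, pos):
        rng = np.random.default_rng(seed)
        values = rng.poisson(40, size=3_000).astype(float)
        fwd = junction_depth_test(DepthTrack("s", values), pos)
        rev = junction_depth_test(DepthTrack("s", values[::-1].copy()),
                                  len(values) - pos)
        assert fwd.verdict == rev.verdict


class TestCorroboration:
    def _scaffold(self):
        return generate_genome(6_000, 0.36, seed=20)

    def test_exact_copy_corroborates(self):
        seq = self._scaffold()
        assert corroborate_junction(seq, 3_000, [[("c1", seq)]]) == 1

    def test_breakpoint_at_junction_does_not(self):
        seq = self._scaffold()
        broken = [("c1", seq[:3_000]), ("c2", seq[3_000:])]
        assert corroborate_junction(seq, 3_000, [broken]) == 0

    def test_empty_assembly_set(self):
        assert corroborate_junction(self._scaffold(), 3_000, []) == 0

    def test_counts_multiple_assemblies(self):
        seq = self._scaffold()
        shred = shred_assembly(seq, 3_000, seed=1, avoid=[(2_400, 3_600)])
        assert corroborate_junction(seq, 3_000, [[("c", seq)], shred]) == 2


class TestAnnotation:
    CAND = GenomicInterval("sc83", 2_271_642, 2_272_117)

    def _tnp(self, start, end):
        return FeatureRecord(
            "sc83", GenomicInterval("sc83", start, end), "transposase", "t1"
        )

    def test_transposase_inside_insert(self):
        assert transposase_proximity(self.CAND, [self._tnp(2_271_642, 2_272_117)]) == 0

    def test_gap_measured(self):
        f = self._tnp(2_272_117 + 1_200, 2_272_117 + 1_500)
        assert transposase_proximity(self.CAND, [f], max_dist=2_000) == 1_200

    def test_beyond_max_dist_absent(self):
        f = self._tnp(2_272_117 + 2_500, 2_272_117 + 2_800)
        assert transposase_proximity(self.CAND, [f], max_dist=2_000) is None

    def test_gene_overlap_half_open(self):
        inside = FeatureRecord(
            "sc83", GenomicInterval("sc83", 2_271_700, 2_271_900), "gene", "g_in"
        )
        abutting = FeatureRecord(
            "sc83", GenomicInterval("sc83", 2_272_117, 2_272_300), "gene", "g_out"
        )
        assert overlap_genes(self.CAND, [inside, abutting]) == ["g_in"]
        assert overlap_genes(self.CAND, []) == []

    def test_transcribed_subset_thresholds(self):
        fpkm = {"a": 1.6, "b": 0.04, "c": 0.0}
        assert transcribed_subset(["a", "b", "c"], fpkm, 0.01) == ["a", "b"]
        assert transcribed_subset(["a", "b", "c"], fpkm, 1.0) == ["a"]
        assert transcribed_subset([], {}, 0.01) == []


class TestCallVerdicts:
    def _cand(self):
        return CandidateInsertion(
            scaffold_id="sc",
            interval=GenomicInterval("sc", 10_000, 24_190),
            junctions=(Junction(10_000, "internal"), Junction(24_190, "internal")),
            n_symbiont_blocks=1,
            mean_identity=0.99,
        )

    def _verdicts(self, kind="continuous"):
        return [
            JunctionVerdict(10_000, 47.0, 47.5, 0.01, kind),
            JunctionVerdict(24_190, 47.5, 47.0, -0.01, "continuous"),
        ]

    def test_positive_control_is_hgt(self):
        (call,) = call_hgt([(self._cand(), self._verdicts(), 1)])
        assert call.verdict == "hgt"
        assert call.length == 14_190

    def test_depth_step_is_chimera_suspect(self):
        verdicts = [
            JunctionVerdict(10_000, 47.0, 120.0, -1.34, "step_change"),
            self._verdicts()[1],
        ]
        (call,) = call_hgt([(self._cand(), verdicts, 1)])
        assert call.verdict == "chimera_suspect"

    def test_no_corroboration_is_unresolved(self):
        (call,) = call_hgt([(self._cand(), self._verdicts(), 0)])
        assert call.verdict == "unresolved"

    def test_edge_indeterminate_does_not_block(self):
        verdicts = [
            JunctionVerdict(0, math.nan, math.nan, math.nan, "indeterminate", "edge"),
            JunctionVerdict(24_190, 47.0, 47.5, 0.01, "continuous"),
        ]
        (call,) = call_hgt([(self._cand(), verdicts, 1)])
        assert call.verdict == "hgt"

    def test_internal_indeterminate_blocks(self):
        verdicts = [
            JunctionVerdict(10_000, math.nan, math.nan, math.nan,
                            "indeterminate", "internal"),
            self._verdicts()[1],
        ]
        (call,) = call_hgt([(self._cand(), verdicts, 1)])
        assert call.verdict == "unresolved"
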