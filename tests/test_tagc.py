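import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan import generate_genome
from hgtscan.tagc import (
    ScaffoldRecord,
    TagcParams,
    assign_taxon_coverage,
    classify_assembly,
    classify_scaffold,
    compute_gc,
    mean_depth,
)
from hgtscan.types import DepthTrack, GenomicInterval, TabularHit

from _oracles import brute_force_union


def _hit(start, end, bin_="symbiont", ident=98.0, sid="sc1"):
    return TabularHit(
        query_id=sid,
        subject_id="ref",
        taxon_bin=bin_,
        percent_identity=ident,
        query_interval=GenomicInterval(sid, start, end),
        subject_interval=GenomicInterval("ref", start, end),
        bitscore=float(end - start),
    )


class TestComputeGc:
    def test_simple(self):
        assert compute_gc("ATGC") == 0.5

    def test_ambiguity_excluded(self):
        assert compute_gc("AANN") == 0.0
        assert compute_gc("NNNN") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_gc("")

    def test_simulated_symbiont_gc(self):
        seq = generate_genome(100_000, 0.3513, seed=0)
        assert compute_gc(seq) == pytest.approx(0.3513, abs=0.005)


class TestMeanDepth:
    def test_constant(self):
        t = DepthTrack("s", np.full(100, 47.0))
        assert mean_depth(t) == 47.0

    def test_mixed(self):
        t = DepthTrack("s", [0, 0, 10, 10])
        assert mean_depth(t) == 5.0

    def test_interval(self):
        t = DepthTrack("s", [0, 0, 10, 10])
        assert mean_depth(t, GenomicInterval("s", 2, 4)) == 10.0

    def test_empty_interval_rejected(self):
        t = DepthTrack("s", [1.0, 1.0])
        with pytest.raises(ValueError):
            t.mean(2, 2)


class TestTaxonCoverage:
    def test_single_hit(self):
        assert assign_taxon_coverage([_hit(0, 1000)], 2000) == (1000, 0)

    def test_overlap_union_not_sum(self):
        hits = [_hit(0, 600), _hit(400, 1000)]
        assert assign_taxon_coverage(hits, 2000) == (1000, 0)

    def test_short_run_below_min_block(self):
        assert assign_taxon_coverage([_hit(0, 200)], 2000, min_block=300) == (0, 0)

    def test_hit_beyond_scaffold_rejected(self):
        with pytest.raises(ValueError):
            assign_taxon_coverage([_hit(0, 3000)], 2000)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 400)), min_size=0,
            max_size=12,
        )
    )
    def test_union_matches_per_base_oracle(self, raw):
        ivs = [(s, s + l) for s, l in raw]
        hits = [_hit(s, e) for s, e in ivs]
        got, _ = assign_taxon_coverage(hits, 2000, min_block=300)
        assert got == brute_force_union(ivs, min_run=300)


class TestClassifyScaffold:
    REFS = (47.0, 120.0)

    def test_pure_symbiont(self):
        r = ScaffoldRecord("w1", 10_000, 0.35, 118.0)
        c = classify_scaffold(r, (9_800, 0), self.REFS)
        assert (c.label, c.depth_cluster) == ("symbiont", "symbiont-like")

    def test_interleaved_candidate_at_host_depth(self):
        r = ScaffoldRecord("sc5", 30_000, 0.36, 48.0)
        c = classify_scaffold(r, (14_000, 15_000), self.REFS)
        assert (c.label, c.depth_cluster) == ("hgt_candidate", "host-like")

    def test_no_hits_unassigned(self):
        r = ScaffoldRecord("x", 5_000, 0.4, 47.0)
        c = classify_scaffold(r, (0, 0), self.REFS)
        assert c.label == "unassigned"

    def test_host(self):
        r = ScaffoldRecord("h", 5_000, 0.36, 47.0)
        c = classify_scaffold(r, (0, 4_900), self.REFS)
        assert c.label == "host"

    def test_intermediate_depth_band(self):
        r = ScaffoldRecord("m", 5_000, 0.36, 80.0)
        refs = (70.0, 90.0)
        c = classify_scaffold(r, (0, 4_900), refs)
        assert c.depth_cluster == "intermediate"


class TestClassifyAssembly:
    def _records_and_hits(self):
        records = [
            ScaffoldRecord("h1", 10_000, 0.36, 47.0),
            ScaffoldRecord("h2", 10_000, 0.36, 49.0),
            ScaffoldRecord("w1", 8_000, 0.35, 120.0),
            ScaffoldRecord("c1", 10_000, 0.36, 48.0),
            ScaffoldRecord("u1", 2_000, 0.40, 5.0),
        ]
        hits = {
            "h1": [_hit(0, 9_900, "host", sid="h1")],
            "h2": [_hit(0, 9_800, "host", sid="h2")],
            "w1": [_hit(0, 7_900, "symbiont", sid="w1")],
            "c1": [
                _hit(0, 4_000, "host", sid="c1"),
                _hit(4_000, 6_000, "symbiont", sid="c1"),
                _hit(6_000, 10_000, "host", sid="c1"),
            ],
            "u1": [],
        }
        return records, hits

    def test_partition_property(self):
        records, hits = self._records_and_hits()
        out = classify_assembly(records, hits)
        assert len(out) == len(records)
        labels = {c.scaffold_id: c.label for c in out}
        assert labels == {
            "h1": "host", "h2": "host", "w1": "symbiont",
            "c1": "hgt_candidate", "u1": "unassigned",
        }
        clusters = {c.scaffold_id: c.depth_cluster for c in out}
        assert clusters["c1"] == "host-like"
        assert clusters["w1"] == "symbiont-like"

    def test_invariant_to_hit_order_and_splitting(self):
        records, hits = self._records_and_hits()
        base = classify_assembly(records, hits)
        # shuffle hit order
        shuffled = {k: list(reversed(v)) for k, v in hits.items()}
        assert classify_assembly(records, shuffled) == base
        # split one hit into two abutting hits
        split = dict(hits)
        h = hits["h1"][0]
        mid = 5_000
        split["h1"] = [_hit(0, mid, "host", sid="h1"), _hit(mid, 9_900, "host", sid="h1")]
        assert classify_assembly(records, split) == base
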