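import numpy as np
import pytest

from hgtscan import (
    SimulationConfig,
    derive_strain,
    generate_genome,
    make_chimera,
    plant_insertions,
    shred_assembly,
    simulate_reads,
    simulate_study,
)
from hgtscan.detect import junction_depth_test
from hgtscan.tagc import compute_gc

from conftest import small_config


class TestGenerateGenome:
    def test_gc_hits_target(self):
        seq = generate_genome(100_000, 0.36, seed=0)
        assert compute_gc(seq) == pytest.approx(0.36, abs=0.01)

    def test_deterministic(self):
        assert generate_genome(500, 0.5, seed=7) == generate_genome(500, 0.5, seed=7)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            generate_genome(10, gc, seed=0)


class TestDeriveStrain:
    def test_zero_divergence_identity(self):
        g = generate_genome(1000, 0.4, seed=1)
        v, pos = derive_strain(g, 0.0, seed=2)
        assert v == g and pos.size == 0

    def test_site_count_binomial(self):
        g = generate_genome(100_000, 0.4, seed=1)
        _v, pos = derive_strain(g, 0.01, seed=2)
        assert 900 <= pos.size <= 1100  # 1000 +/- ~3 sd

    def test_substituted_base_differs(self):
        g = generate_genome(5000, 0.4, seed=1)
        v, pos = derive_strain(g, 0.05, seed=2)
        assert all(v[p] != g[p] for p in pos)
        untouched = sorted(set(range(len(g))) - set(int(p) for p in pos))
        assert all(v[p] == g[p] for p in untouched)


class TestPlantInsertions:
    def test_no_insertions_is_identity(self):
        host = generate_genome(10_000, 0.36, seed=3)
        sym = generate_genome(5_000, 0.35, seed=4)
        mod, truth = plant_insertions(host, sym, 0, (500, 1000), seed=5)
        assert mod == host and truth == []

    def test_single_475bp_insertion(self):
        host = generate_genome(20_000, 0.36, seed=3)
        sym = generate_genome(5_000, 0.35, seed=4)
        mod, truth = plant_insertions(host, sym, 1, (475, 475), seed=5)
        assert len(mod) == len(host) + 475
        (ins,) = truth
        assert ins.length == 475
        assert mod[ins.site.start : ins.site.end] == \
            sym[ins.source.start : ins.source.end]

    def test_truth_intervals_disjoint_and_sequences_match(self):
        host = generate_genome(60_000, 0.36, seed=3)
        sym = generate_genome(30_000, 0.35, seed=4)
        mod, truth = plant_insertions(host, sym, 4, (500, 3000), seed=5)
        ivs = sorted((t.site.start, t.site.end) for t in truth)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        for t in truth:
            assert mod[t.site.start : t.site.end] == \
                sym[t.source.start : t.source.end]


class TestSimulateReads:
    def test_exact_read_count_and_mean_depth(self):
        seq = generate_genome(10_000, 0.5, seed=6)
        sim = simulate_reads([("r", seq, 10.0)], read_length=100, seed=7)
        assert sim.placements["r"].size == 1000
        assert sim.tracks["r"].mean() == pytest.approx(10.0, abs=0.5)

    def test_track_is_exact_for_known_placement(self):
        seq = "A" * 300
        sim = simulate_reads([("r", seq, 100 / 300)], read_length=100, seed=0)
        (start,) = sim.placements["r"]
        v = sim.tracks["r"].values
        assert (v[start : start + 100] == 1).all()
        assert v.sum() == 100

    def test_fastq_deterministic(self, tmp_path):
        seq = generate_genome(2_000, 0.4, seed=8)
        out = []
        for run in range(2):
            sim = simulate_reads([("r", seq, 3.0)], read_length=100, seed=9)
            p = tmp_path / f"r{run}.fastq"
            sim.to_fastq(p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_zero_reads_warns(self):
        with pytest.warns(UserWarning, match="zero reads"):
            simulate_reads([("r", "ACGT" * 100, 0.01)], read_length=100, seed=0)


class TestMakeChimera:
    def test_depth_steps_at_junction(self):
        h = generate_genome(5_000, 0.36, seed=10)
        s = generate_genome(4_000, 0.35, seed=11)
        seq, track, junction = make_chimera(h, s, 47.0, 120.0, 100, seed=12)
        assert junction == len(h)
        assert len(seq) == len(h) + len(s)
        left = track.values[junction - 600 : junction - 100].mean()
        right = track.values[junction + 100 : junction + 600].mean()
        assert right / left == pytest.approx(120 / 47, rel=0.15)
        verdict = junction_depth_test(track, junction)
        assert verdict.verdict == "step_change"

    def test_equal_depths_look_continuous(self):
        h = generate_genome(5_000, 0.36, seed=10)
        s = generate_genome(4_000, 0.35, seed=11)
        _seq, track, junction = make_chimera(h, s, 47.0, 47.0, 100, seed=12)
        assert junction_depth_test(track, junction).verdict == "continuous"


class TestShredAssembly:
    def test_mean_equal_to_length_gives_single_contig(self):
        g = generate_genome(5_000, 0.4, seed=13)
        frags = shred_assembly(g, len(g), seed=14)
        assert frags == [("alt_00000", g)]

    def test_fragments_tile_genome(self):
        g = generate_genome(100_000, 0.4, seed=13)
        frags = shred_assembly(g, 10_000, seed=14)
        assert "".join(seq for _n, seq in sorted(frags)) == g
        assert 3 <= len(frags) <= 25  # Poisson(9) cuts

    def test_avoid_windows_respected(self):
        g = generate_genome(50_000, 0.4, seed=15)
        avoid = [(10_000, 12_000), (30_000, 33_000)]
        for seed in range(5):
            frags = shred_assembly(g, 2_000, seed=seed, avoid=avoid)
            starts = np.cumsum([0] + [len(s) for _n, s in sorted(frags)])[:-1]
            for cut in starts[1:]:
                assert not any(a <= cut < b for a, b in avoid)


class TestStudyBundle:
    def test_truth_matches_planted_sequences(self, small_bundle):
        b = small_bundle
        sym = "".join(seq for _sid, seq in b.symbiont_ref)
        for ins in b.truth.insertions:
            planted = b.scaffolds[ins.site.scaffold_id][ins.site.start : ins.site.end]
            assert planted == sym[ins.source.start : ins.source.end]

    def test_depth_regimes(self, small_bundle):
        b = small_bundle
        for sid in b.host_scaffold_ids:
            assert b.tracks[sid].mean() == pytest.approx(
                b.config.host_depth, rel=0.05
            )
        for sid in b.symbiont_scaffold_ids:
            assert b.tracks[sid].mean() == pytest.approx(
                b.config.symbiont_depth, rel=0.05
            )

    def test_chimera_junction_recorded(self, small_bundle):
        b = small_bundle
        (cid, pos) = b.truth.chimera_junctions[0]
        assert pos == b.config.chimera_host_len
        assert len(b.scaffolds[cid]) == (
            b.config.chimera_host_len + b.config.chimera_symbiont_len
        )

    def test_deterministic_bundle(self):
        b1 = simulate_study(small_config(seed=42))
        b2 = simulate_study(small_config(seed=42))
        assert b1.scaffolds == b2.scaffolds
        assert [i.site for i in b1.truth.insertions] == \
            [i.site for i in b2.truth.insertions]
        assert all(
            (b1.tracks[s].values == b2.tracks[s].values).all() for s in b1.tracks
        )

    def test_two_strain_bundle_emits_variants(self):
        b = simulate_study(small_config(seed=21, n_strains=2))
        assert len(b.variant_sites) > 100
        sym = dict(b.symbiont_ref)
        for v in b.variant_sites[:50]:
            assert sym[v.scaffold_id][v.position] == v.ref_base
            assert v.alt_base != v.ref_base
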