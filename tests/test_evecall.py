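"""Pairing, spliced-leader scanning, neighbors, and the coverage screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from dinoeve.core import InputError, Scaffold
from dinoeve.evecall import (
    DEFAULT_SL_SEQUENCE,
    EveCall,
    EveMember,
    SLQuery,
    annotate_neighbors,
    call_eves,
    coverage_uniformity,
    scan_dinoSL,
    scan_sl_region,
)
from dinoeve.orfs import annotate_orfs, find_orfs
from dinoeve.synthio import (
    EveSpec,
    plant_eve,
    random_background,
)


def _member(gene_class, start, end, sid="s"):
    return EveMember(sid, gene_class, start, end, "+", "src")


class TestCallEves:
    def test_pair_within_threshold_is_genomic(self):
        calls = call_eves([_member("MCP", 1000, 2000), _member("RdRp", 3200, 4700)])
        assert [c.type for c in calls] == ["genomic"]
        assert calls[0].gap == 1200

    def test_gap_1500_is_genomic_but_1501_is_not(self):
        at = call_eves([_member("MCP", 0, 2000), _member("RdRp", 3500, 5000)])
        assert at[0].type == "genomic" and at[0].gap == 1500
        over = call_eves([_member("MCP", 0, 2000), _member("RdRp", 3501, 5000)])
        assert sorted(c.type for c in over) == ["single_MCP", "single_RdRp"]

    def test_two_pairs_separated_do_not_cross(self):
        """Two planted genome copies 2,501 nt apart pair internally."""
        members = [
            _member("MCP", 0, 1000),
            _member("RdRp", 1400, 2900),
            _member("MCP", 5401, 6400),  # 2501 nt after first pair ends
            _member("RdRp", 6800, 8300),
        ]
        calls = call_eves(members)
        genomic = [c for c in calls if c.type == "genomic"]
        assert len(genomic) == 2
        for c in genomic:
            assert c.gap == 400

    def test_order_invariance(self, rng):
        members = [
            _member("MCP", 0, 1000),
            _member("RdRp", 1200, 2700),
            _member("RdRp", 5000, 6500),
            _member("MCP", 7000, 8000),
        ]
        base = call_eves(members)
        for _ in range(5):
            rng.shuffle(members)
            assert call_eves(list(members)) == base

    @given(
        st.lists(
            st.tuples(st.sampled_from(["MCP", "RdRp"]), st.integers(0, 30)),
            min_size=0,
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_genomic_count_bounded_and_partition(self, raw):
        members = [
            _member(gc, 1000 * p, 1000 * p + 600) for gc, p in raw
        ]
        calls = call_eves(members)
        n_mcp = sum(m.gene_class == "MCP" for m in members)
        n_rdrp = sum(m.gene_class == "RdRp" for m in members)
        genomic = [c for c in calls if c.type == "genomic"]
        assert len(genomic) <= min(n_mcp, n_rdrp)
        # every member in exactly one EVE
        assert sum(len(c.members) for c in calls) == len(members)

    def test_non_viral_member_rejected(self):
        with pytest.raises(InputError):
            call_eves([EveMember("s", "cellular", 0, 10, "+", "x")])


class TestScanDinoSL:
    def _eve(self, start, end, sid="s"):
        return EveCall(sid, "single_RdRp", (EveMember(sid, "RdRp", start, end, "+", "x"),))

    def test_exact_planted_leader_at_minus_100(self, rng):
        bg = random_background(rng, 3000, 0.5)
        start = 1000
        sl_start = start - 100 - 22
        seq = bg[:sl_start] + DEFAULT_SL_SEQUENCE + bg[sl_start + 22 : ]
        hits = scan_dinoSL(Scaffold("s", seq), self._eve(start, 2500))
        exact = [h for h in hits if h.matches == 22]
        assert len(exact) == 1
        assert exact[0].offset == -100
        assert exact[0].identity == pytest.approx(100.0)

    def test_leader_outside_window_not_reported(self, rng):
        bg = random_background(rng, 3000, 0.5)
        start = 1200
        sl_start = start - 600 - 22
        seq = bg[:sl_start] + DEFAULT_SL_SEQUENCE + bg[sl_start + 22 :]
        hits = scan_dinoSL(Scaffold("s", seq), self._eve(start, 2500), window_nt=500)
        assert all(h.matches < 22 for h in hits)

    def test_no_shared_word_means_no_hit(self, rng):
        """A copy mutated every 8 positions shares no clean 9-mer."""
        q = SLQuery()
        sl = list(DEFAULT_SL_SEQUENCE)
        for i in (2, 10, 18):  # non-ambiguous positions, max run 7 < 9
            sl[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sl[i]]
        region = random_background(rng, 200, 0.5) + "".join(sl) + random_background(rng, 200, 0.5)
        assert scan_sl_region(region, q, word=9, min_matches=18) == \
            oracles.sl_scan_bruteforce(region, q.sequence, set(q.ambiguous), 9, 18)

    def test_agrees_with_bruteforce_on_random_cases(self, rng):
        """Seeded scan equals all-positions comparison on 1,000 cases."""
        q = SLQuery()
        for _ in range(1000):
            region = list(random_background(rng, 120, 0.5))
            # plant a mutated leader copy at a random spot
            n_mut = int(rng.integers(0, 8))
            sl = list(DEFAULT_SL_SEQUENCE)
            for pos in rng.choice(22, size=n_mut, replace=False):
                sl[pos] = "ACGT"[rng.integers(4)]
            p = int(rng.integers(0, 120 - 22))
            region[p : p + 22] = sl
            region = "".join(region)
            got = scan_sl_region(region, q, word=9, min_matches=18)
            want = oracles.sl_scan_bruteforce(
                region, q.sequence, set(q.ambiguous), 9, 18
            )
            assert sorted(got) == sorted(want)

    def test_ambiguous_positions_do_not_count_as_mismatch(self, rng):
        q = SLQuery()
        sl = list(DEFAULT_SL_SEQUENCE)
        for a in q.ambiguous:
            sl[a] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sl[a]]
        region = random_background(rng, 100, 0.5) + "".join(sl) + random_background(rng, 100, 0.5)
        hits = scan_sl_region(region, q, word=9, min_matches=22)
        assert any(h[2] == 22 for h in hits)

    def test_benchmark_rdrp_eves_carry_leaders(self, bench, scan_result):
        """All planted-leader EVEs on the benchmark report a perfect SL."""
        truth_sl_scaffolds = {
            r.scaffold_id
            for r in bench.manifest.records
            if r.feature == "dinoSL"
        }
        called_sl_scaffolds = {
            c.scaffold_id for c in scan_result.calls if any(h.matches == 22 for h in c.sl_hits)
        }
        assert truth_sl_scaffolds == called_sl_scaffolds


class TestAnnotateNeighbors:
    def test_line_at_95_bp_downstream(self, rng, viral_panel, cellular_panel):
        sc = Scaffold("s", random_background(rng, 4000, 0.5))
        sc, records = plant_eve(
            sc,
            EveSpec(kind="single_RdRp", divergence=0.0, line_offset=95, strand="+"),
            rng, viral_panel, cellular_panel,
        )
        rdrp = next(r for r in records if r.feature == "RdRp")
        orfs = annotate_orfs(find_orfs(sc, 60), viral_panel, cellular_panel)
        eve = EveCall(
            "s", "single_RdRp",
            (EveMember("s", "RdRp", rdrp.start, rdrp.end, "+", rdrp.source_id),),
        )
        neighbors = annotate_neighbors(eve, orfs)
        retro = [n for n in neighbors if n.gene_class == "retroelement"]
        assert retro and retro[0].distance == 95
        assert retro[0].side == "downstream"

    def test_no_annotated_orfs_no_neighbors(self):
        eve = EveCall("s", "single_MCP", (EveMember("s", "MCP", 0, 900, "+", "x"),))
        assert annotate_neighbors(eve, []) == []

    def test_benchmark_retroelement_fraction_matches_plants(self, bench, scan_result):
        """The planted LINE fraction is recovered call-by-call."""
        line_scaffolds = {
            r.scaffold_id for r in bench.manifest.records if r.feature == "LINE"
        }
        for c in scan_result.calls:
            if c.scaffold_id in line_scaffolds:
                assert c.has_retroelement_neighbor


class TestDepthInput:
    def test_sam_reads_accumulate_per_base(self, tmp_path):
        from dinoeve.evecall import read_depth_sam

        sam = tmp_path / "reads.sam"
        body = "A" * 50
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:sc1\tLN:100\n"
            f"r1\t0\tsc1\t1\t60\t50M\t*\t0\t0\t{body}\t*\n"
            f"r2\t0\tsc1\t41\t60\t50M\t*\t0\t0\t{body}\t*\n"
        )
        depth = read_depth_sam(sam, {"sc1": 100})["sc1"]
        assert depth[0] == 1 and depth[45] == 2 and depth[95] == 0

    def test_depth_tsv_round_trip(self, tmp_path, bench):
        from dinoeve.evecall import read_depth_tsv
        from dinoeve.synthio import write_benchmark

        write_benchmark(bench, tmp_path)
        lengths = {s.id: len(s.seq) for s in bench.scaffolds}
        back = read_depth_tsv(tmp_path / "depth.tsv", lengths)
        sid = bench.scaffolds[0].id
        assert (back[sid] == bench.depth[sid]).all()


class TestCoverageUniformity:
    def test_constant_depth_passes_with_zero_statistic(self):
        res = coverage_uniformity(np.full(5000, 30), (2000, 3000))
        assert res.status == "pass"
        assert res.contrast == pytest.approx(0.0)
        assert res.cv == pytest.approx(0.0)

    def test_depth_discontinuity_fails(self):
        depth = np.concatenate([np.full(2500, 30), np.zeros(2500)])
        res = coverage_uniformity(depth, (2000, 3000))
        assert res.status == "fail"

    def test_all_zero_depth_fails_with_reason(self):
        res = coverage_uniformity(np.zeros(4000), (1000, 2000))
        assert res.status == "fail"
        assert "zero coverage" in res.reason

    def test_bad_interval_rejected(self):
        with pytest.raises(InputError):
            coverage_uniformity(np.full(100, 10), (50, 200))

    def test_classification_accuracy_on_mixed_profiles(self, rng):
        """25 uniform (Poisson 30x) + 25 chimeric profiles classified
        perfectly by the default thresholds."""
        correct = 0
        for k in range(50):
            if k < 25:
                depth = rng.poisson(30, size=5000)
                want = "pass"
            else:
                j = int(rng.integers(2200, 2800))
                depth = np.concatenate([rng.poisson(30, size=j), np.zeros(5000 - j)])
                want = "fail"
            got = coverage_uniformity(depth, (2000, 3000)).status
            correct += got == want
        assert correct == 50

    def test_all_benchmark_chimeras_flagged(self, scan_result):
        for c in scan_result.calls:
            if c.scaffold_id.startswith("chi_"):
                assert c.coverage_status == "fail"
            elif c.scaffold_id.startswith("sc_"):
                assert c.coverage_status == "pass"
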