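"""Identity, codon back-alignment, NG86 dN/dS, neighbor joining."""

import warnings

import numpy as np
import pandas as pd
import pytest

import oracles
from dinoeve.core import InputError
from dinoeve.evolution import (
    CodonAlignment,
    codon_backalign,
    dnds_matrix,
    identity_distance_matrix,
    ng86_dnds,
    nj_tree,
    pairwise_identity,
)
from dinoeve.synthio import (
    _random_protein,
    back_translate,
    mutate_cds_synonymous,
    mutate_sequence_neutral,
)

warnings.filterwarnings("ignore", category=Warning, module="Bio")


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == pytest.approx(100.0)

    def test_single_substitution_over_100(self):
        a = "A" * 50 + "C" * 50
        b = "A" * 50 + "C" * 49 + "G"
        assert pairwise_identity(a, b) == pytest.approx(99.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            pairwise_identity("", "ACGT")

    def test_matches_independent_dp(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 80))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            assert pairwise_identity(a, b) == pytest.approx(
                oracles.needleman_wunsch_identity(a, b)
            )

    def test_symmetry_of_distance_matrix(self, rng):
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(4)
        }
        d = identity_distance_matrix(seqs)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)


class TestCodonBackalign:
    def test_gapless_alignment_concatenates_codons(self, rng):
        prot = _random_protein(rng, 20)
        cds = back_translate(prot, 0.5, rng)
        ca = codon_backalign(["a"], [prot], {"a": cds})
        assert ca.rows[0] == cds

    def test_protein_gap_becomes_codon_gap(self, rng):
        prot = _random_protein(rng, 10)
        cds = back_translate(prot, 0.5, rng)
        gapped = prot[:5] + "-" + prot[5:]
        ca = codon_backalign(["a"], [gapped], {"a": cds})
        assert ca.rows[0] == cds[:15] + "---" + cds[15:]

    def test_round_trip_reproduces_protein_alignment(self, rng):
        from dinoeve.homology import translate_frame

        for _ in range(5):
            prot = _random_protein(rng, 30)
            cds = back_translate(prot, 0.5, rng)
            cols = sorted(rng.choice(31, size=3, replace=False))
            gapped = prot
            for c in reversed(cols):
                gapped = gapped[:c] + "-" + gapped[c:]
            ca = codon_backalign(["a"], [gapped], {"a": cds})
            regapped = "".join(
                "-" if ca.rows[0][i : i + 3] == "---" else
                translate_frame(ca.rows[0][i : i + 3], 1)
                for i in range(0, len(ca.rows[0]), 3)
            )
            assert regapped == gapped
            assert ca.rows[0].replace("-", "") == cds

    def test_translation_mismatch_names_row_and_position(self, rng):
        prot = _random_protein(rng, 10)
        cds = back_translate(prot, 0.5, rng)
        wrong = "TTT" + cds[3:] if not prot.startswith("F") else "GGG" + cds[3:]
        with pytest.raises(InputError, match="position 0"):
            codon_backalign(["rowx"], [prot], {"rowx": wrong})

    def test_trailing_stop_tolerated(self, rng):
        prot = _random_protein(rng, 12)
        cds = back_translate(prot, 0.5, rng) + "TAA"
        ca = codon_backalign(["a"], [prot], {"a": cds})
        assert len(ca.rows[0]) == 36


class TestNG86:
    def test_identical_rows_have_no_differences(self, rng):
        cds = back_translate(_random_protein(rng, 50), 0.5, rng)
        r = ng86_dnds(CodonAlignment(("a", "b"), (cds, cds)))
        assert r.nd == 0 and r.sd == 0
        assert r.dn == 0.0 and r.ds == 0.0
        assert r.omega is None  # undefined at dS = 0

    def test_synonymous_single_codon_change(self):
        r = ng86_dnds(CodonAlignment(("a", "b"), ("TTTATG", "TTCATG")))
        assert r.sd == pytest.approx(1.0)
        assert r.nd == pytest.approx(0.0)
        assert r.dn == pytest.approx(0.0)
        # ps = Sd / S_sites saturates on a 2-codon toy (p >= 3/4), so the
        # Jukes-Cantor correction is undefined and flagged as None
        assert r.ds is None and r.omega is None

    def test_sites_sum_to_three_per_codon(self, rng):
        cds = back_translate(_random_protein(rng, 40), 0.5, rng)
        mut = mutate_sequence_neutral(cds, 0.05, rng)
        r = ng86_dnds(CodonAlignment(("a", "b"), (cds, mut)))
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.codons_compared)

    def test_multi_substitution_codons_match_pathway_enumeration(self, rng):
        """Pathway-averaged Nd/Sd equal explicit enumeration, including a
        toy pair whose middle codon differs at two positions."""
        a = "TTTATGGCGAAACCC"
        b = "TTTATGGGTAAACCC"  # GCG -> GGT: two substitutions
        r = ng86_dnds(CodonAlignment(("a", "b"), (a, b)))
        sd = nd = 0.0
        for i in range(0, 15, 3):
            s_, n_ = oracles.ng86_codon_diffs(a[i : i + 3], b[i : i + 3])
            sd += s_
            nd += n_
        assert r.sd == pytest.approx(sd)
        assert r.nd == pytest.approx(nd)
        # and on random pairs with many multi-hit codons
        for _ in range(5):
            cds = back_translate(_random_protein(rng, 60), 0.5, rng)
            mut = mutate_sequence_neutral(cds, 0.25, rng)
            rr = ng86_dnds(CodonAlignment(("a", "b"), (cds, mut)))
            sd = nd = 0.0
            for i in range(0, len(cds), 3):
                c1, c2 = cds[i : i + 3], mut[i : i + 3]
                if "TAA" in (c1, c2) or "TAG" in (c1, c2) or "TGA" in (c1, c2):
                    continue
                s_, n_ = oracles.ng86_codon_diffs(c1, c2)
                sd += s_
                nd += n_
            assert rr.sd == pytest.approx(sd)
            assert rr.nd == pytest.approx(nd)

    def test_agrees_with_biopython_reference(self, rng):
        """dN and dS match Bio.codonalign's NG86 on stop-free pairs."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        stops = {"TAA", "TAG", "TGA"}
        for seed in range(3):
            r2 = np.random.default_rng(seed)
            cds = back_translate(_random_protein(r2, 150), 0.5, r2)
            mut = mutate_sequence_neutral(cds, 0.08, r2)
            keep_a, keep_b = [], []
            for i in range(0, len(cds), 3):
                if cds[i : i + 3] in stops or mut[i : i + 3] in stops:
                    continue
                keep_a.append(cds[i : i + 3])
                keep_b.append(mut[i : i + 3])
            a, b = "".join(keep_a), "".join(keep_b)
            mine = ng86_dnds(CodonAlignment(("a", "b"), (a, b)))
            dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.dn == pytest.approx(dn_ref, rel=1e-9)
            assert mine.ds == pytest.approx(ds_ref, rel=1e-9)

    def test_symmetric_in_row_order_and_column_permutation(self, rng):
        cds = back_translate(_random_protein(rng, 60), 0.5, rng)
        mut = mutate_sequence_neutral(cds, 0.1, rng)
        r_ab = ng86_dnds(CodonAlignment(("a", "b"), (cds, mut)))
        r_ba = ng86_dnds(CodonAlignment(("b", "a"), (mut, cds)))
        assert r_ab.sd == pytest.approx(r_ba.sd)
        assert r_ab.nd == pytest.approx(r_ba.nd)
        perm = rng.permutation(len(cds) // 3)
        a_p = "".join(cds[3 * i : 3 * i + 3] for i in perm)
        b_p = "".join(mut[3 * i : 3 * i + 3] for i in perm)
        r_perm = ng86_dnds(CodonAlignment(("a", "b"), (a_p, b_p)))
        assert r_perm.sd == pytest.approx(r_ab.sd)
        assert r_perm.nd == pytest.approx(r_ab.nd)

    def test_gap_codons_skipped(self):
        r = ng86_dnds(CodonAlignment(("a", "b"), ("TTT---ATG", "TTCAAAATG")))
        assert r.codons_compared == 2

    def test_synonymous_only_degradation_gives_zero_dn(self, rng):
        cds = back_translate(_random_protein(rng, 100), 0.5, rng)
        syn = mutate_cds_synonymous(cds, 0.6, rng)
        r = ng86_dnds(CodonAlignment(("a", "b"), (cds, syn)))
        assert r.nd == 0.0 and r.dn == 0.0
        assert r.sd > 0

    def test_neutral_degradation_recovers_omega_near_one(self):
        """Median omega over 50 seeded neutral replicates lies in
        [0.8, 1.2], the neutral regime the statistic should report."""
        rng = np.random.default_rng(7)
        omegas = []
        for _ in range(50):
            cds = back_translate(_random_protein(rng, 400), 0.5, rng)
            mut = mutate_sequence_neutral(cds, 0.05, rng)
            r = ng86_dnds(CodonAlignment(("a", "b"), (cds, mut)))
            if r.omega is not None:
                omegas.append(r.omega)
        assert len(omegas) >= 45
        assert 0.8 <= float(np.median(omegas)) <= 1.2

    def test_dnds_matrix_reports_pairwise_and_mean(self, rng):
        cds = back_translate(_random_protein(rng, 80), 0.5, rng)
        rows = (cds,
                mutate_sequence_neutral(cds, 0.05, rng),
                mutate_sequence_neutral(cds, 0.1, rng))
        mat, mean = dnds_matrix(CodonAlignment(("a", "b", "c"), rows))
        assert mat.shape == (3, 3)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        upper = [mat.iloc[i, j] for i in range(3) for j in range(i + 1, 3)]
        finite = [v for v in upper if np.isfinite(v)]
        assert mean == pytest.approx(float(np.mean(finite)))


class TestNJTree:
    def test_three_taxa_closed_form(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> branch lengths a=1, b=2, c=4
        d = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        newick = nj_tree(d)
        from skbio import TreeNode
        from io import StringIO

        t = TreeNode.read(StringIO(newick))
        dist = {x.name: x.length for x in t.tips()}
        assert dist["a"] == pytest.approx(1.0)
        assert dist["b"] == pytest.approx(2.0)
        assert dist["c"] == pytest.approx(4.0)

    def test_additive_matrix_recovers_tree_metric(self):
        """Tip-to-tip distances of the NJ tree reproduce an additive
        5-taxon matrix exactly."""
        from io import StringIO

        from skbio import TreeNode

        src = TreeNode.read(StringIO("((a:2,b:3):1,(c:1,d:4):2,e:5);"))
        ids = ["a", "b", "c", "d", "e"]
        d = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    d[i, j] = d[j, i] = src.find(x).distance(src.find(y))
        newick = nj_tree(pd.DataFrame(d, index=ids, columns=ids))
        out = TreeNode.read(StringIO(newick))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert out.find(x).distance(out.find(y)) == pytest.approx(d[i, j])

    def test_taxon_order_permutation_keeps_topology(self):
        from io import StringIO

        from skbio import TreeNode

        ids = ["a", "b", "c", "d", "e"]
        src = TreeNode.read(StringIO("((a:2,b:3):1,(c:1,d:4):2,e:5);"))
        d = pd.DataFrame(0.0, index=ids, columns=ids)
        for x in ids:
            for y in ids:
                if x != y:
                    d.loc[x, y] = src.find(x).distance(src.find(y))
        perm = ["d", "a", "e", "b", "c"]
        t1 = TreeNode.read(StringIO(nj_tree(d)))
        t2 = TreeNode.read(StringIO(nj_tree(d.loc[perm, perm])))
        assert t1.compare_rfd(t2) == 0.0

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InputError):
            nj_tree(bad, ids=["a", "b"])
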