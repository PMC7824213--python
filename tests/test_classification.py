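import random

import pytest

from trlocus.classify import (
    VGene,
    assign_alleles,
    assign_gene_names,
    assign_subgroup_numbers,
    cluster_subgroups,
    pairwise_identity,
)
from oracles import components_bfs, hamming_identity, nw_score


def mutate_at(seq: str, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("A" * 300, "A" * 300) == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_symmetric(self, rng):
        a = "".join(rng.choice("ACGT") for _ in range(80))
        b = "".join(rng.choice("ACGT") for _ in range(75))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_alignment_score_matches_dp_oracle(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1, open_gap_score=-2, extend_gap_score=-2)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            assert aligner.score(a, b) == nw_score(a, b)

    def test_substitution_only_pairs_equal_hamming(self, rng):
        # equal length, few substitutions: gaps cost more than they gain, so
        # the optimal alignment is the diagonal and identity is exact
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(60))
            b = mutate_at(a, rng.sample(range(60), 9), rng)
            assert pairwise_identity(a, b) == pytest.approx(hamming_identity(a, b))

    def test_single_gap_case(self):
        # deleting one base: 59 matches over 60 columns
        a = "ACGT" * 15
        assert pairwise_identity(a, a[:30] + a[31:]) == pytest.approx(100 * 59 / 60)


class TestClustering:
    def test_single_gene_is_singleton(self):
        (sg,) = cluster_subgroups([VGene("g1", "ACGTACGTACGT" * 5, 100)])
        assert [g.gene_id for g in sg.members] == ["g1"]

    def test_single_linkage_chain(self, rng):
        a = "".join(rng.choice("ACGT") for _ in range(100))
        pos_ab = rng.sample(range(100), 20)
        b = mutate_at(a, pos_ab, rng)
        c = list(b)
        for p in pos_ab[:10]:  # third base, diverging from both a and b
            c[p] = next(x for x in "ACGT" if x not in (a[p], b[p]))
        for p in [q for q in rng.sample(range(100), 40) if q not in pos_ab][:10]:
            c[p] = rng.choice([x for x in "ACGT" if x != b[p]])
        c = "".join(c)
        assert pairwise_identity(a, b) == 80.0
        assert pairwise_identity(b, c) == 80.0
        assert pairwise_identity(a, c) == 70.0
        clusters = cluster_subgroups([VGene("A", a, 1), VGene("B", b, 2), VGene("C", c, 3)])
        assert len(clusters) == 1  # A~B and B~C connect all three

    def test_exact_threshold_tie_does_not_join(self):
        a = "AAAA" * 25
        b = mutate_at(a, list(range(25)), random.Random(0))  # exactly 75% identity
        assert pairwise_identity(a, b) == 75.0
        assert len(cluster_subgroups([VGene("A", a, 1), VGene("B", b, 2)])) == 2

    def test_two_simulated_families_recovered(self, rng):
        from trlocus.simulate import make_v_family, make_v_instance

        f1 = make_v_instance(rng, (6, 6, 3), gene_id="F1")
        f2 = make_v_instance(rng, (7, 4, 4), gene_id="F2")
        genes = []
        for fam, founder in (("a", f1), ("b", f2)):
            for i, m in enumerate(make_v_family(founder, 5, 0.05, rng)):
                lo, hi = m.parts["V-REGION"]
                genes.append(VGene(f"{fam}{i}", m.seq[lo - 1 : hi], len(genes) * 1000 + 1))
        clusters = cluster_subgroups(genes)
        got = {frozenset(g.gene_id for g in sg.members) for sg in clusters}
        want = {frozenset(f"a{i}" for i in range(5)), frozenset(f"b{i}" for i in range(5))}
        assert got == want

    def test_matches_bruteforce_components_oracle(self, small_annotated):
        genes = [
            VGene(a.truth.gene_id, a.unit.core_seq, a.unit.parts["V-REGION"][0])
            for a in small_annotated
            if a.unit.gene_type == "V" and a.truth is not None
        ]
        by_id = {g.gene_id: g.core for g in genes}
        clusters = cluster_subgroups(genes)
        got = {frozenset(g.gene_id for g in sg.members) for sg in clusters}
        oracle = components_bfs(
            list(by_id), lambda x, y: pairwise_identity(by_id[x], by_id[y]) > 75.0
        )
        assert got == oracle

    def test_partition_invariant_under_input_permutation(self, rng):
        from trlocus.simulate import make_v_family, make_v_instance

        founder = make_v_instance(rng, (6, 6, 3))
        genes = []
        for i, m in enumerate(make_v_family(founder, 6, 0.05, rng)):
            lo, hi = m.parts["V-REGION"]
            genes.append(VGene(f"g{i}", m.seq[lo - 1 : hi], (i + 1) * 10))
        ref = cluster_subgroups(genes)
        shuffled = genes[::-1]
        assert [[g.gene_id for g in sg.members] for sg in cluster_subgroups(shuffled)] == [
            [g.gene_id for g in sg.members] for sg in ref
        ]


class TestSubgroupNumbers:
    REF = None

    @pytest.fixture(autouse=True)
    def _reference(self, rng):
        self.rng = random.Random(7)
        self.ref_seqs = {
            str(i): "".join(self.rng.choice("ACGT") for _ in range(120)) for i in (4, 8, 42)
        }
        self.reference = list(self.ref_seqs.items())

    def _cluster(self, seq, pos=1):
        return cluster_subgroups([VGene(f"x{pos}", seq, pos)])[0]

    def test_match_adopts_reference_id(self):
        near8 = mutate_at(self.ref_seqs["8"], list(range(20)), self.rng)  # ~83%
        clusters = assign_subgroup_numbers([self._cluster(near8)], self.reference)
        assert clusters[0].subgroup_id == "8"

    def test_no_match_founds_new_subgroup_after_max(self):
        novel = "".join(self.rng.choice("ACGT") for _ in range(120))
        clusters = assign_subgroup_numbers([self._cluster(novel)], self.reference)
        assert clusters[0].subgroup_id == "43"

    def test_conflicting_claims_resolved_best_identity_wins(self):
        close = mutate_at(self.ref_seqs["4"], list(range(12)), self.rng)  # 90%
        farther = mutate_at(self.ref_seqs["4"], list(range(25)), self.rng)  # ~79%
        a, b = self._cluster(close, pos=10), self._cluster(farther, pos=20)
        clusters = assign_subgroup_numbers([a, b], self.reference)
        assert a.subgroup_id == "4"
        assert b.subgroup_id == "43"  # loser founds a new subgroup

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroup_numbers([], [])


class TestGeneNames:
    def _subgroups(self, positions):
        genes = [VGene(f"g{i}", "ACGT" * 30, p) for i, p in enumerate(positions)]
        sg = cluster_subgroups(genes)
        for s in sg:
            s.subgroup_id = "9"
        return sg

    def test_multi_member_numbering_follows_position(self):
        names = assign_gene_names(self._subgroups([10_000, 50_000, 90_000]), prefix="TRAV")
        assert [names[f"g{i}"].gene for i in range(3)] == ["TRAV9-1", "TRAV9-2", "TRAV9-3"]

    def test_singleton_has_no_hyphen(self):
        names = assign_gene_names(self._subgroups([10_000]), prefix="TRAV")
        assert names["g0"].gene == "TRAV9"
        assert str(names["g0"]) == "TRAV9*01"

    def test_new_five_prime_member_renumbers_the_rest(self):
        before = assign_gene_names(self._subgroups([50_000, 90_000]), prefix="TRAV")
        after = assign_gene_names(self._subgroups([50_000, 90_000, 1_000]), prefix="TRAV")
        assert before["g0"].gene == "TRAV9-1"
        assert after["g2"].gene == "TRAV9-1"  # the new 5'-most member
        assert after["g0"].gene == "TRAV9-2"
        assert after["g1"].gene == "TRAV9-3"

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_gene_names(self._subgroups([5, 5]))


class TestAlleles:
    def test_identical_instances_share_star_01(self):
        out = assign_alleles({"TRAV9-1": [("locusA", "ACGT"), ("locusB", "ACGT")]})
        assert out == {"locusA": 1, "locusB": 1}

    def test_core_substitution_creates_star_02(self):
        out = assign_alleles({"TRAV9-1": [("ref", "ACGT"), ("alt", "ACTT"), ("third", "ACGT")]})
        assert out == {"ref": 1, "alt": 2, "third": 1}

    def test_reference_instance_is_star_01(self):
        out = assign_alleles({"g": [("reference_locus", "AAAA"), ("other", "AAAT")]})
        assert out["reference_locus"] == 1
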