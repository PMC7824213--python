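import pytest

from trlocus.simulate import (
    SimConfig,
    inject_defect,
    make_cdr2less_v,
    make_v_family,
    make_v_instance,
    simulate_locus,
)
from trlocus.evaluation import translate_in_frame
from oracles import hamming_identity


def v_region(inst):
    lo, hi = inst.parts["V-REGION"]
    return inst.seq[lo - 1 : hi]


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=77, n_subgroups=4, genes_per_subgroup=(2, 3), n_nonlocalized=1)
        a, b = simulate_locus(cfg), simulate_locus(SimConfig(**{**cfg.__dict__}))
        assert a.locus.sequence == b.locus.sequence
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
        assert [t.parts for t in a.truth] == [t.parts for t in b.truth]

    def test_different_seed_differs(self):
        a = simulate_locus(SimConfig(seed=1, n_subgroups=3, genes_per_subgroup=(2, 2)))
        b = simulate_locus(SimConfig(seed=2, n_subgroups=3, genes_per_subgroup=(2, 2)))
        assert a.locus.sequence != b.locus.sequence


class TestStructure:
    def test_defect_free_locus_is_all_functional_by_construction(self, small_sim):
        assert all(t.intended_functionality == "F" for t in small_sim.truth)
        assert all(t.defect is None for t in small_sim.truth)

    def test_j_cassette_duplication(self):
        sim = simulate_locus(SimConfig(seed=5, n_subgroups=2, genes_per_subgroup=(2, 2), j_block=(5, 2)))
        aj = [t for t in sim.truth if t.gene_id.startswith("AJ")]
        assert len(aj) == 10  # two tandem cassettes of the 5-set block
        per_set = {}
        for t in aj:
            per_set[t.intended_subgroup] = per_set.get(t.intended_subgroup, 0) + 1
        assert set(per_set.values()) == {2}

    def test_gap_runs_planted(self, small_sim):
        assert len(small_sim.locus.gap_runs) == small_sim.config.gap_runs

    def test_nonlocalized_genes_on_contigs(self, small_sim):
        nl = [t for t in small_sim.truth if not t.localized]
        assert len(nl) == 2
        assert all(t.contig != small_sim.locus.locus_id for t in nl)

    def test_infeasible_cdr_capacity_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_locus(SimConfig(seed=0, cdr1_range=(4, 13)))

    def test_bad_defect_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_locus(SimConfig(seed=0, defect_rates={"stop_codon": 1.5}))


class TestVFamily:
    def test_zero_divergence_members_identical(self, rng):
        founder = make_v_instance(rng, (6, 6, 3))
        members = make_v_family(founder, 4, 0.0, rng)
        assert all(m.seq == founder.seq for m in members)

    def test_within_family_identity_above_threshold(self, rng):
        founder = make_v_instance(rng, (6, 6, 3))
        members = make_v_family(founder, 6, 0.05, rng)
        regions = [v_region(m) for m in members]
        # substitution-only divergence: per-site identity is exact by Hamming
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                assert hamming_identity(regions[i], regions[j]) > 75.0

    def test_cross_family_identity_below_threshold(self, rng):
        base = make_v_instance(rng, (6, 6, 3))
        with pytest.warns(UserWarning):
            f1, f2 = make_v_family(base, 2, 0.40, rng)
        fam1 = [v_region(m) for m in make_v_family(f1, 4, 0.05, rng)]
        fam2 = [v_region(m) for m in make_v_family(f2, 4, 0.05, rng)]
        for a in fam1:
            for b in fam2:
                assert hamming_identity(a, b) < 75.0

    def test_high_divergence_warns(self, rng):
        founder = make_v_instance(rng, (6, 6, 3))
        with pytest.warns(UserWarning, match="subgroup integrity"):
            make_v_family(founder, 1, 0.30, rng)

    def test_protected_motifs_never_mutated(self, rng):
        founder = make_v_instance(rng, (8, 5, 4))
        for m in make_v_family(founder, 10, 0.20, rng):
            assert m.seq[:3] == "ATG"
            ilo, ihi = m.parts["V-INTRON"]
            assert m.seq[ilo - 1 : ilo + 1] == "GT" and m.seq[ihi - 2 : ihi] == "AG"
            aa = translate_in_frame(v_region(m))
            assert "*" not in aa


class TestInjectDefect:
    @pytest.fixture
    def founder(self, rng):
        return make_v_instance(rng, (6, 6, 3))

    def test_stop_codon_marks_pseudogene(self, founder, rng):
        mutated = inject_defect(founder, "stop_codon", rng)
        assert mutated.functionality == "P"
        assert "*" in translate_in_frame(v_region(mutated))

    def test_frameshift_breaks_frame(self, founder, rng):
        mutated = inject_defect(founder, "frameshift", rng)
        assert mutated.functionality == "P"
        assert len(v_region(mutated)) == len(v_region(founder)) - 1
        assert len(v_region(mutated)) % 3 != 0

    def test_splice_break_changes_donor(self, founder, rng):
        mutated = inject_defect(founder, "splice_break", rng)
        ilo = mutated.parts["V-INTRON"][0]
        assert mutated.seq[ilo - 1 : ilo + 1] == "GC"
        assert mutated.functionality == "ORF"

    def test_rss_break_hits_critical_heptamer_bases(self, founder, rng):
        mutated = inject_defect(founder, "rss_break", rng)
        _, hept, _ = mutated.rss_layout[0]
        assert mutated.seq[hept[0] - 1] != "C"
        assert mutated.functionality == "ORF"

    def test_conserved_aa_change_keeps_frame(self, founder, rng):
        mutated = inject_defect(founder, "conserved_aa_change", rng)
        aa = translate_in_frame(v_region(mutated))
        assert "*" not in aa and mutated.functionality == "ORF"

    def test_unknown_kind_rejected(self, founder, rng):
        with pytest.raises(ValueError, match="unknown defect kind"):
            inject_defect(founder, "inversion", rng)

    def test_double_injection_rejected(self, founder, rng):
        once = inject_defect(founder, "stop_codon", rng)
        with pytest.raises(ValueError, match="already carries"):
            inject_defect(once, "stop_codon", rng)

    def test_inapplicable_kind_rejected(self, rng):
        from trlocus.simulate import make_d_instance

        with pytest.raises(ValueError, match="not applicable"):
            inject_defect(make_d_instance(rng), "stop_codon", rng)


class TestCdr2Less:
    def test_removes_nine_codons_in_frame(self, rng):
        founder = make_v_instance(rng, (7, 3, 4))
        shorter = make_cdr2less_v(founder)
        assert len(shorter.seq) == len(founder.seq) - 27
        aa_full = translate_in_frame(v_region(founder))
        aa_short = translate_in_frame(v_region(shorter))
        assert aa_short is not None and "*" not in aa_short
        assert len(aa_short) == len(aa_full) - 9

    def test_applied_twice_rejected(self, rng):
        shorter = make_cdr2less_v(make_v_instance(rng, (7, 3, 4)))
        with pytest.raises(ValueError, match="already absent"):
            make_cdr2less_v(shorter)
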