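import numpy as np
import pytest

from duxevo._codon import STOP_CODONS, translate
from duxevo.family_sim import (Event, FamilySimConfig, apply_event,
                               build_ancestor, evolve_sequence,
                               simulate_family)

STAR_TREE = "(w:0.0,x:0.0,y:0.0,z:0.0);"


class TestEvolveSequence:
    def test_zero_branch_length_is_identity(self):
        seq = "ACGT" * 250
        assert evolve_sequence(seq, 0.0, rng=np.random.default_rng(1)) == seq

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -0.1)

    def test_jc69_expected_divergence(self):
        # closed form: E[p] = (3/4)(1 - exp(-4t/3))
        t, L = 0.3, 100_000
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[rng.integers(0, 4)] for _ in range(L))
        out = evolve_sequence(seq, t, "JC69", np.random.default_rng(8))
        p_obs = sum(a != b for a, b in zip(seq, out)) / L
        p_exp = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_k2p_expected_divergence(self):
        t, L, kappa = 0.3, 100_000, 3.0
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[rng.integers(0, 4)] for _ in range(L))
        out = evolve_sequence(seq, t, "K2P", np.random.default_rng(10),
                              kappa=kappa)
        p_obs = sum(a != b for a, b in zip(seq, out)) / L
        from duxevo.family_sim import _k2p_matrix
        p_exp = 1.0 - _k2p_matrix(t, kappa)[0, 0]
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_same_seed_same_output(self):
        seq = "ACGT" * 500
        a = evolve_sequence(seq, 0.2, rng=np.random.default_rng(3))
        b = evolve_sequence(seq, 0.2, rng=np.random.default_rng(3))
        assert a == b

    def test_length_preserved_and_n_inert(self):
        seq = "ACGTN" * 200
        out = evolve_sequence(seq, 0.5, rng=np.random.default_rng(4))
        assert len(out) == len(seq)
        assert all(b == "N" for i, b in enumerate(out) if seq[i] == "N")


class TestApplyEvent:
    @pytest.fixture()
    def ancestor(self):
        cfg = FamilySimConfig(species_tree=STAR_TREE, families=["DUX"], seed=1)
        genome, _ = build_ancestor("DUX", cfg, np.random.default_rng(1))
        return genome, cfg

    def test_pseudogenize_stop_places_one_stop(self, ancestor):
        genome, cfg = ancestor
        ev = Event("w", "DUX", "pseudogenize_stop",
                   {"exon": "exon4", "codon": 10})
        before = genome.get("DUX.exon4").seq
        apply_event(genome, ev, cfg, np.random.default_rng(2))
        after = genome.get("DUX.exon4").seq
        assert translate(after)[10] == "*"
        # everything else unchanged
        assert after[:30] == before[:30]
        assert after[33:] == before[33:]

    def test_retrotranspose_conserves_exon_content(self, ancestor):
        genome, cfg = ancestor
        exon_len = sum(len(s.seq) for s in genome.segments
                       if s.gene == "DUX" and s.kind == "exon")
        total_before = len(genome.sequence())
        apply_event(genome, Event("w", "DUX", "retrotranspose"), cfg,
                    np.random.default_rng(2))
        retro = genome.get("DUX.retro")
        assert len(retro.seq) == exon_len
        assert len(genome.sequence()) == total_before + exon_len

    def test_delete_exon_removes_exact_segment(self, ancestor):
        genome, cfg = ancestor
        ln = len(genome.get("DUX.exon3").seq)
        before = len(genome.sequence())
        apply_event(genome, Event("w", "DUX", "delete_exon",
                                  {"exon": "exon3"}), cfg,
                    np.random.default_rng(2))
        assert len(genome.sequence()) == before - ln
        with pytest.raises(KeyError):
            genome.get("DUX.exon3")

    def test_event_on_deleted_gene_is_an_error(self, ancestor):
        genome, cfg = ancestor
        apply_event(genome, Event("w", "DUX", "delete_gene"), cfg,
                    np.random.default_rng(2))
        with pytest.raises((KeyError, ValueError)):
            apply_event(genome, Event("w", "DUX", "delete_exon",
                                      {"exon": "exon2"}), cfg,
                        np.random.default_rng(2))


class TestSimulateFamily:
    def test_star_tree_no_events_identical_genomes(self):
        cfg = FamilySimConfig(species_tree=STAR_TREE, families=["DUX"], seed=3)
        sim = simulate_family(cfg)
        seqs = {sp: g.sequence() for (sp, _), g in sim.genomes.items()}
        assert len(set(seqs.values())) == 1
        assert set(sim.truth.table.status) == {"intact"}

    def test_reciprocal_loss_truth_pattern(self):
        tree = "((m:0.05,r:0.05)rodents:0.03,(h:0.04,q:0.04)primates:0.04);"
        events = [Event("rodents", "DUXB", "delete_gene"),
                  Event("primates", "DUXBL", "delete_gene")]
        cfg = FamilySimConfig(species_tree=tree, families=["DUXB", "DUXBL"],
                              events=events, seed=4)
        truth = simulate_family(cfg).truth
        assert truth.status("m", "DUXB") == "absent"
        assert truth.status("r", "DUXB") == "absent"
        assert truth.status("h", "DUXB") == "intact"
        assert truth.status("h", "DUXBL") == "absent"
        assert truth.status("m", "DUXBL") == "intact"

    def test_same_seed_byte_identical(self):
        tree = "((a:0.1,b:0.1):0.05,c:0.15);"
        cfg = FamilySimConfig(species_tree=tree, families=["DUX"],
                              events=[Event("a", "DUX", "tandem_duplicate")],
                              seed=6)
        s1 = simulate_family(cfg)
        s2 = simulate_family(cfg)
        for key in s1.genomes:
            assert s1.genomes[key].sequence() == s2.genomes[key].sequence()
        assert s1.truth.table.equals(s2.truth.table)

    def test_intact_orfs_are_stop_free(self, small_sim):
        for (sp, fam), genome in small_sim.genomes.items():
            if small_sim.truth.status(sp, fam) != "intact":
                continue
            prot = translate(genome.gene_cds(fam))
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_truth_domains_are_60_residues(self, small_sim):
        assert small_sim.truth.hd_proteins
        for prot in small_sim.truth.hd_proteins.values():
            assert len(prot) == 60
            assert "*" not in prot

    def test_unknown_event_branch_rejected(self):
        cfg = FamilySimConfig(
            species_tree=STAR_TREE, families=["DUX"],
            events=[Event("nope", "DUX", "delete_gene")], seed=1)
        with pytest.raises(ValueError, match="unknown branch"):
            simulate_family(cfg)

    def test_splice_signals_conserved(self, small_sim):
        for (sp, fam), genome in small_sim.genomes.items():
            for seg in genome.segments:
                if seg.kind == "intron":
                    assert seg.seq.startswith("GT")
                    assert seg.seq.endswith("AG")
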