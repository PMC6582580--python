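import numpy as np
import pytest

from gulotrace.core_io import NucSeq
from gulotrace.orthocall import (
    ABSENT, CONTAMINATION, INCONCLUSIVE, PRESENT, PROTOSTOMIA_CLADOGRAM,
    PROTOSTOMIA_STATES, SpeciesCall, call_lineage, call_species, dollo_losses,
    dollo_losses_bruteforce, lossmap_newick, render_callogram,
    screen_contamination,
)
from gulotrace.synthgen import backtranslate, contaminate, synth_absent_genome
from gulotrace.tsearch import HSP


class TestContaminationScreen:
    def test_bacterial_copy_flagged(self, panel):
        gt = synth_absent_genome(2000, seed=0)
        ct = contaminate(gt, panel["bacterial"][0], seed=1)
        copy = ct.scaffolds[-1]
        v = screen_contamination(copy, panel)
        assert v["positive"]

    def test_planted_animal_gene_not_flagged(self, query, panel):
        rng = np.random.default_rng(2)
        cds = NucSeq("c", backtranslate(query.residues, rng))
        assert not screen_contamination(cds, panel)["positive"]

    def test_empty_panel_rejected(self, query):
        rng = np.random.default_rng(3)
        cds = NucSeq("c", backtranslate(query.residues, rng))
        with pytest.raises(ValueError):
            screen_contamination(cds, {"animal": [], "bacterial": []})


def _hsp(sid, qs, qe, s=0, e=None):
    e = e if e is not None else s + 3 * (qe - qs)
    return HSP(sid, 1, qs, qe, s, e, 100, 50.0, 1e-10, 1.0)


class TestCallSpecies:
    def test_no_hits_absent(self):
        call = call_species("sp", [], [], 180)
        assert call.status == ABSENT

    def test_residual_homology_absent(self):
        hsps = [_hsp("s1", 0, 20)]  # 11% of a 180-aa query
        assert call_species("sp", [], hsps, 180).status == ABSENT

    def test_scattered_hits_inconclusive(self):
        hsps = [_hsp("s1", 0, 60), _hsp("s2", 60, 120), _hsp("s3", 120, 180)]
        assert call_species("sp", [], hsps, 180).status == INCONCLUSIVE

    def test_substantial_single_scaffold_homology_without_model(self):
        hsps = [_hsp("s1", 0, 120)]
        assert call_species("sp", [], hsps, 180).status == INCONCLUSIVE

    def test_pure_function_of_evidence(self):
        hsps = [_hsp("s1", 0, 60), _hsp("s2", 60, 120), _hsp("s3", 120, 180)]
        a = call_species("sp", [], hsps, 180)
        b = call_species("sp", [], list(reversed(hsps)), 180)
        assert a.status == b.status


class TestCallLineage:
    def _calls(self, status, n):
        return [SpeciesCall(f"s{i}", status) for i in range(n)]

    def test_four_absent_species_make_lineage_absent(self):
        assert call_lineage("L", self._calls(ABSENT, 4)).status == ABSENT

    def test_two_absent_insufficient(self):
        assert call_lineage("L", self._calls(ABSENT, 2)).status == INCONCLUSIVE

    def test_single_present_overrides(self):
        calls = self._calls(ABSENT, 2) + [SpeciesCall("g", PRESENT)]
        assert call_lineage("L", calls).status == PRESENT

    def test_contamination_neither_present_nor_absent(self):
        calls = self._calls(ABSENT, 2) + [SpeciesCall("r", CONTAMINATION)]
        assert call_lineage("L", calls).status == INCONCLUSIVE

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            call_lineage("L", [])


class TestDollo:
    def test_sister_pair_loss(self):
        lm = dollo_losses("((A,B),(C,D));",
                          {"A": "present", "B": "present",
                           "C": "absent", "D": "absent"})
        assert lm.n_losses == 1 and lm.loss_clades == [frozenset({"C", "D"})]

    def test_all_present_no_losses(self):
        lm = dollo_losses("((A,B),(C,D));", {x: "present" for x in "ABCD"})
        assert lm.n_losses == 0

    def test_unknown_tips_unconstrained(self):
        lm = dollo_losses("((A,B),(C,D));",
                          {"A": "present", "C": "absent"})
        assert lm.n_losses == 1

    def test_unknown_tip_never_increases_losses(self):
        base = dollo_losses("((A,(B,E)),(C,D));",
                            {"A": "present", "B": "present", "C": "absent",
                             "D": "absent", "E": "absent"})
        relaxed = dollo_losses("((A,(B,E)),(C,D));",
                               {"A": "present", "B": "present", "C": "absent",
                                "D": "absent", "E": "unknown"})
        assert relaxed.n_losses <= base.n_losses

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            dollo_losses("((A,B),C);", {"Z": "absent"})

    def _random_case(self, rng):
        import test_core_io
        n = int(rng.integers(4, 10))
        nwk = test_core_io._random_tree_newick(rng, n)
        states = {f"t{i}": ["present", "absent", "unknown"][rng.integers(0, 3)]
                  for i in range(n)}
        return nwk, states

    @pytest.mark.parametrize("seed", range(10))
    def test_minimality_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            nwk, states = self._random_case(rng)
            lm = dollo_losses(nwk, states)
            assert lm.n_losses == dollo_losses_bruteforce(nwk, states)
            # structural invariants: absent tips below exactly one loss,
            # present tips below none
            for tip, st in states.items():
                cover = sum(tip in c for c in lm.loss_clades)
                if st == "absent":
                    assert cover == 1
                elif st == "present":
                    assert cover == 0

    def test_protostomia_pattern_four_independent_losses(self):
        lm = dollo_losses(PROTOSTOMIA_CLADOGRAM, PROTOSTOMIA_STATES)
        assert lm.n_losses == 4
        assert lm.n_losses == dollo_losses_bruteforce(PROTOSTOMIA_CLADOGRAM,
                                                      PROTOSTOMIA_STATES)
        lost = set().union(*lm.loss_clades)
        assert {"Pancrustacea", "Nematoda", "Platyhelminthes",
                "Bivalvia"} <= lost
        assert not lost & {"Araneae", "Acari", "Priapulida", "Annelida",
                           "Brachiopoda", "Gastropoda"}

    def test_lossmap_newick_tags_losses(self):
        lm = dollo_losses("((A,B),(C,D));",
                          {"A": "present", "B": "present",
                           "C": "absent", "D": "absent"})
        assert "[&loss]" in lossmap_newick(lm)


class TestRender:
    # a 16-species mite cladogram: two superorders, ticks with one presumed
    # contamination and one scatter-inconclusive genome, one lineage of four
    # absences (synthetic stand-in mirroring the published call pattern)
    ACARI_TREE = ("(((Isc,(Rmi,Iri)),(Gocc,(Vde,(Vja,Tme)))),"
                  "((Tur,(Ttr,Dpt)),(Pov,(Dfa,(Ema,(Ssc,(Tme2,Cle)))))));")
    ACARI_CALLS = {
        "Isc": PRESENT, "Rmi": CONTAMINATION, "Iri": INCONCLUSIVE,
        "Gocc": ABSENT, "Vde": ABSENT, "Vja": ABSENT, "Tme": ABSENT,
        "Tur": PRESENT, "Ttr": PRESENT, "Dpt": PRESENT, "Pov": PRESENT,
        "Dfa": PRESENT, "Ema": PRESENT, "Ssc": PRESENT, "Tme2": PRESENT,
        "Cle": INCONCLUSIVE,
    }

    def test_colour_assignment_matches_calls(self):
        calls = [SpeciesCall(s, st) for s, st in self.ACARI_CALLS.items()]
        fig, table = render_callogram(self.ACARI_TREE, calls)
        import matplotlib.pyplot as plt
        rows = dict(l.split("\t")[:2] for l in table.splitlines()[1:])
        assert rows == {s: st for s, st in self.ACARI_CALLS.items()}
        colours = [l.split("\t")[2] for l in table.splitlines()[1:]]
        assert set(colours) == {"green", "red", "blue", "orange"}
        plt.close(fig)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            render_callogram("((A,B),C);", [])

    def test_missing_tip_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            render_callogram("((A,B),C);", [SpeciesCall("A", PRESENT)])


class TestEndToEndCalls:
    def test_confusion_matrix_diagonal(self, intact_corpus, fragmented_corpus,
                                       contaminated_corpus, absent_corpus):
        """Across the four synthetic cohorts the call matches the planted
        mode in >= 95% of genomes."""
        expected = {
            PRESENT: intact_corpus,
            INCONCLUSIVE: fragmented_corpus,
            CONTAMINATION: contaminated_corpus,
            ABSENT: absent_corpus,
        }
        total = correct = 0
        for status, corpus in expected.items():
            for e in corpus:
                total += 1
                correct += e.result.call.status == status
        assert correct / total >= 0.95

    def test_fragmented_never_present(self, fragmented_corpus):
        assert all(e.result.call.status != PRESENT for e in fragmented_corpus)

    def test_contaminated_only_never_present(self, contaminated_corpus):
        assert all(e.result.call.status != PRESENT
                   for e in contaminated_corpus)
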