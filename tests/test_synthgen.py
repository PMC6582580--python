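import re

import numpy as np
import pytest

from gulotrace.core_io import ProtSeq, revcomp, translate_cds
from gulotrace.synthgen import (
    PlantSpec, contaminate, default_query, fragment_assembly, random_protein,
    synth_absent_genome, synth_chromatogram, synth_genome,
)


def _introns(gt):
    """Intron sequences of the (single) planted gene, transcription order."""
    gene = gt.genes[0]
    scaffold = next(s for s in gt.scaffolds if s.id == gene.scaffold_id)
    seq = scaffold.residues if gene.strand == "+" else revcomp(scaffold.residues)
    L = len(seq)
    if gene.strand == "+":
        ex = gene.exons
    else:
        ex = [(L - e, L - s) for s, e in gene.exons]
    return [seq[ex[i][1]:ex[i + 1][0]] for i in range(len(ex) - 1)]


class TestPlantSpec:
    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            PlantSpec(protein=ProtSeq("p", "MHWAK*LL"))

    def test_motif_count_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            PlantSpec(protein=ProtSeq("p", "MAAAAAAA"), motif_variant="HWAK")
        with pytest.raises(ValueError, match="HWxK"):
            PlantSpec(protein=random_protein(60, 0, "HWAK"),
                      motif_variant="none")

    def test_intron_bounds(self):
        with pytest.raises(ValueError, match="intron"):
            PlantSpec(protein=random_protein(60, 0), intron_length_range=(5, 50))


class TestSynthGenome:
    @pytest.mark.parametrize("seed,ec,strand", [
        (0, 1, "+"), (1, 3, "+"), (2, 3, "-"), (3, 5, "-"),
    ])
    def test_truth_invariants(self, seed, ec, strand):
        q = default_query()
        spec = PlantSpec(protein=q, exon_count=ec, strand=strand,
                         intron_length_range=(50, 300))
        gt = synth_genome(spec, background_length=8000, seed=seed)
        gene = gt.genes[0]
        assert len(gene.exons) == ec
        assert translate_cds(gene.cds) == q.residues
        for intron in _introns(gt):
            assert intron.startswith("GT") and intron.endswith("AG")
            assert len(intron) >= 50
        # concatenated exon sequence equals the CDS
        scaffold = gt.scaffolds[0].residues
        if strand == "+":
            cat = "".join(scaffold[s:e] for s, e in gene.exons)
        else:
            cat = "".join(revcomp(scaffold[s:e]) for s, e in gene.exons)
        assert cat == gene.cds

    def test_single_exon_translates_to_protein(self):
        q = default_query()
        gt = synth_genome(PlantSpec(protein=q, exon_count=1),
                          background_length=2000, seed=5)
        g = gt.genes[0]
        s, e = g.exons[0]
        assert translate_cds(gt.scaffolds[0].residues[s:e]) == q.residues

    def test_lone_atg_first_exon(self):
        q = default_query()
        gt = synth_genome(PlantSpec(protein=q, exon_count=2, lone_atg_first=True),
                          background_length=8000, seed=7)
        g = gt.genes[0]
        s, e = g.exons[0]
        assert e - s == 3 and g.has_start_codon
        assert gt.scaffolds[0].residues[s:e] == "ATG"

    def test_determinism_byte_identical(self):
        q = default_query()
        spec = PlantSpec(protein=q, exon_count=3)
        a = synth_genome(spec, background_length=8000, seed=11)
        b = synth_genome(spec, background_length=8000, seed=11)
        assert a.fasta() == b.fasta() and a.gff3() == b.gff3()

    def test_impossible_packing(self):
        q = default_query()
        with pytest.raises(ValueError, match="background_length"):
            synth_genome(PlantSpec(protein=q, exon_count=1),
                         background_length=100, seed=0)


class TestFragmentAndContaminate:
    def _intact(self, seed=0, ec=3):
        return synth_genome(PlantSpec(protein=default_query(), exon_count=ec,
                                      intron_length_range=(100, 500)),
                            background_length=10000, seed=seed)

    def test_exons_scattered_over_three_scaffolds(self):
        fr = fragment_assembly(self._intact(), pieces=3, seed=1)
        assert fr.mode == "fragmented"
        assert len(set(fr.genes[0].exon_scaffolds)) == 3
        # no fragment scaffold carries the complete CDS
        for sc in fr.scaffolds:
            assert fr.genes[0].cds not in sc.residues
            assert revcomp(fr.genes[0].cds) not in sc.residues

    def test_fragment_preconditions(self):
        with pytest.raises(ValueError, match="pieces"):
            fragment_assembly(self._intact(), pieces=2, seed=0)
        with pytest.raises(ValueError, match="exons"):
            fragment_assembly(self._intact(ec=3), pieces=4, seed=0)
        fr = fragment_assembly(self._intact(), pieces=3, seed=0)
        with pytest.raises(ValueError, match="intact"):
            fragment_assembly(fr, pieces=3, seed=0)

    def test_fragment_determinism(self):
        a = fragment_assembly(self._intact(), pieces=3, seed=4)
        b = fragment_assembly(self._intact(), pieces=3, seed=4)
        assert a.fasta() == b.fasta()

    def test_contaminate_appends_near_copy(self, panel):
        gt = self._intact()
        ref = panel["bacterial"][0]
        ct = contaminate(gt, ref, seed=2)
        assert ct.mode == "contaminated"
        assert len(ct.scaffolds) == len(gt.scaffolds) + 1
        # originals untouched
        for a, b in zip(gt.scaffolds, ct.scaffolds):
            assert a.residues == b.residues
        copy = ct.scaffolds[-1].residues
        ident = sum(a == b for a, b in zip(copy, ref.residues)) / len(ref)
        assert ident >= 0.98
        # third-position mutations keep the protein nearly intact and the
        # HWGK motif untouched
        pa, pb = translate_cds(copy), translate_cds(ref.residues)
        aa_ident = sum(a == b for a, b in zip(pa, pb)) / len(pb)
        assert aa_ident >= 0.97
        assert re.search(r"HW[^X*]K", pa)


class TestChromatograms:
    def test_area_equals_response_times_concentration(self):
        ct = synth_chromatogram([(180.0, 50.0)], response=2.0, noise_sd=0.0,
                                seed=0)
        mask = (ct.times > 150) & (ct.times < 210)
        base = np.polynomial.polynomial.polyval(ct.times[mask],
                                                np.asarray(ct.baseline))
        area = np.trapezoid(ct.signal[mask] - base, ct.times[mask])
        assert area == pytest.approx(100.0, rel=0.01)

    def test_zero_concentration_flat_baseline(self):
        ct = synth_chromatogram([(180.0, 0.0)], response=2.0, noise_sd=0.0,
                                seed=0)
        base = np.polynomial.polynomial.polyval(ct.times,
                                                np.asarray(ct.baseline))
        assert np.allclose(ct.signal, base)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            synth_chromatogram([(180.0, -1.0)], seed=0)

    def test_mean_planted_area_unbiased_over_seeds(self):
        # noise averages out: mean integrated area over seeds within 2 s.e.
        areas = []
        for seed in range(100):
            ct = synth_chromatogram([(180.0, 30.0)], response=2.0,
                                    noise_sd=0.05, seed=seed)
            mask = (ct.times > 150) & (ct.times < 210)
            base = np.polynomial.polynomial.polyval(
                ct.times[mask], np.asarray(ct.baseline))
            areas.append(np.trapezoid(ct.signal[mask] - base, ct.times[mask]))
        se = np.std(areas, ddof=1) / np.sqrt(len(areas))
        assert abs(np.mean(areas) - 60.0) <= 2 * se + 1e-6

    def test_tsv_round_trip(self):
        from gulotrace.ascorbquant import Chromatogram
        ct = synth_chromatogram([(120.0, 10.0)], seed=3, noise_sd=0.01)
        c = Chromatogram.from_tsv(ct.tsv())
        assert np.allclose(c.times, ct.times)
        assert np.allclose(c.signal, np.round(ct.signal, 6), atol=1e-6)


def test_absent_genome_has_no_genes():
    gt = synth_absent_genome(6000, seed=1, n_scaffolds=3)
    assert gt.mode == "absent" and gt.genes == []
    assert sum(len(s) for s in gt.scaffolds) == 6000
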