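import numpy as np
import pytest

from gulotrace.core_io import NucSeq, leaf_labels
from gulotrace.codonphylo import (
    CodonAlignment, MCMCConfig, align_codons, burnin_count, column_support,
    nj_tree, p_distance_matrix, place_and_classify, psrf,
)
from gulotrace.synthgen import backtranslate, default_query, random_protein


def _cds(pid, prot, seed):
    rng = np.random.default_rng(seed)
    return NucSeq(pid, backtranslate(prot, rng))


def _mutate(prot, frac, rng, keep="HWK"):
    out = list(prot)
    alphabet = "ACDEFGHIKLMNPQRSTVY"
    for s in rng.choice(len(out), size=int(frac * len(out)), replace=False):
        if out[s] not in keep:
            out[s] = alphabet[rng.integers(0, len(alphabet))]
    return "".join(out)


class TestAlignCodons:
    def test_identical_cds_align_gap_free(self):
        a = _cds("a", "MHWAKDEFGHIK", 0)
        b = NucSeq("b", a.residues)
        aln = align_codons([a, b])
        assert aln.cds_rows[0] == aln.cds_rows[1] == a.residues

    def test_degap_identity(self):
        rng = np.random.default_rng(1)
        for trial in range(15):
            prots = []
            base = random_protein(40, 100 + trial).residues
            for i in range(int(rng.integers(2, 5))):
                p = _mutate(base, 0.15, rng)
                if rng.random() < 0.4:  # random in-frame indel
                    pos = int(rng.integers(5, 30))
                    p = p[:pos] + p[pos + 2:]
                prots.append(p)
            cds = [_cds(f"s{i}", p, 200 + i) for i, p in enumerate(prots)]
            aln = align_codons(cds)
            for i, rec in enumerate(cds):
                assert aln.degap(i) == rec.residues
                assert len(aln.cds_rows[i]) == 3 * len(aln.protein_rows[i])

    def test_clean_insertion_yields_triplet_gap(self):
        base = "MHWAKDEFGHIKLMNPQRST"
        ins = base[:10] + "AAA" + base[10:]
        aln = align_codons([_cds("a", base, 2), _cds("b", ins, 3)])
        assert aln.cds_rows[0].count("-") == 9
        run = aln.protein_rows[0].index("-")
        assert aln.protein_rows[0][run:run + 3] == "---"

    def test_internal_stop_rejected(self):
        bad = NucSeq("bad", "ATGTAAATGATG")
        with pytest.raises(ValueError, match="bad"):
            align_codons([bad, _cds("ok", "MHWAK", 1)])

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            align_codons([NucSeq("x", "ATGC")])


class TestColumnSupport:
    def test_identical_records_full_support(self):
        cds = [_cds(f"s{i}", "MHWAKDEFG", 5) for i in range(4)]
        for i, c in enumerate(cds):
            cds[i] = NucSeq(f"s{i}", cds[0].residues)
        aln = align_codons(cds)
        sup, filt = column_support(aln)
        assert sup == [9] * 9
        assert filt.protein_rows == aln.protein_rows

    def test_discordant_column_dropped(self):
        # column 2 pairwise-mismatching with negative BLOSUM62 scores
        rows = ["MKDIE", "MKWIE", "MKPIE", "MKGIE"]
        cds = [_cds(f"s{i}", r, 10 + i) for i, r in enumerate(rows)]
        aln = align_codons(cds)
        sup, filt = column_support(aln)
        assert sup[2] <= 2
        assert len(filt.protein_rows[0]) == 4

    def test_filtering_idempotent(self):
        rng = np.random.default_rng(3)
        base = random_protein(30, 42).residues
        cds = [_cds(f"s{i}", _mutate(base, 0.3, rng), 30 + i) for i in range(4)]
        _, once = column_support(align_codons(cds))
        sup2, twice = column_support(once)
        assert twice.protein_rows == once.protein_rows

    def test_needs_three_records(self):
        cds = [_cds("a", "MHWAK", 1), _cds("b", "MHWAK", 2)]
        with pytest.raises(ValueError):
            column_support(align_codons(cds))


class TestNeighborJoining:
    def test_three_point_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = nj_tree((d, ["A", "B", "C"]))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_topology_recovered(self, seed):
        import dendropy
        import test_core_io
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        nwk = test_core_io._random_tree_newick(rng, n)
        ref = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = ref.phylogenetic_distance_matrix()
        taxa = sorted(ref.taxon_namespace, key=lambda t: t.label)
        d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        tree = nj_tree((d, [t.label for t in taxa]))
        # compare unrooted bipartitions
        def biparts(t, labels):
            out = set()
            for node in t.preorder_node_iter():
                s = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(s) < len(labels) - 1:
                    out.add(min(s, frozenset(labels) - s, key=sorted))
            return out
        labels = {t.label for t in taxa}
        assert biparts(tree, labels) == biparts(ref, labels)

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        ids = ["d", "c", "b", "a"]
        t1 = nj_tree((d.copy(), list(ids)))
        t2 = nj_tree((d.copy(), list(reversed(ids))))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            nj_tree((np.zeros((2, 2)), ["a", "b"]))


class TestPlacement:
    def _dataset(self):
        rng = np.random.default_rng(7)
        query = default_query().residues
        animals = [_cds(f"animal_{i}", _mutate(query, 0.08, rng), 70 + i)
                   for i in range(3)]
        fungi = [_cds(f"fungus_{i}", _mutate(query, 0.28, rng), 80 + i)
                 for i in range(2)]
        near = _cds("near_query", _mutate(query, 0.04, rng), 90)
        far = _cds("diverged", _mutate(query, 0.55, rng), 91)
        return animals, fungi, near, far

    def test_near_copy_confirmed_and_outlier_external(self):
        animals, fungi, near, far = self._dataset()
        aln = align_codons(animals + fungi + [near, far])
        tree = nj_tree(p_distance_matrix(aln))
        v = place_and_classify(tree, ["near_query", "diverged"],
                               [a.id for a in animals],
                               [f.id for f in fungi])
        assert v == {"near_query": True, "diverged": False}

    def test_missing_outgroup_rejected(self):
        animals, fungi, near, far = self._dataset()
        aln = align_codons(animals + [near])
        tree = nj_tree(p_distance_matrix(aln))
        with pytest.raises(ValueError):
            place_and_classify(tree, ["near_query"],
                               [a.id for a in animals], ["nope1", "nope2"])


class TestMcmcDiagnostics:
    @pytest.mark.parametrize("gens,every,frac,expected", [
        (5_000_000, 100, 0.25, 12_500),
        (1000, 10, 0.25, 25),
        (1000, 10, 0.0, 0),
    ])
    def test_burnin_arithmetic(self, gens, every, frac, expected):
        cfg = MCMCConfig(generations=gens, sample_every=every,
                         burnin_frac=frac)
        assert burnin_count(cfg) == expected

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(generations=5, sample_every=10)
        with pytest.raises(ValueError):
            MCMCConfig(burnin_frac=1.0)

    def test_constant_identical_chains_unity(self):
        assert psrf([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]]) == 1.0

    def test_hand_computed_value(self):
        # two identical chains [1,2,3,4]: B = 0, W > 0
        # => psrf = sqrt((n-1)/n) = sqrt(3/4)
        assert psrf([[1, 2, 3, 4], [1, 2, 3, 4]]) == \
               pytest.approx(np.sqrt(0.75))

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(10, 1, 1000)
        assert psrf([a, b]) > 1.1

    def test_iid_samplers_near_unity(self):
        ok = 0
        for seed in range(20):
            rng1 = np.random.default_rng(10_000 + seed)
            rng2 = np.random.default_rng(20_000 + seed)
            r = psrf([rng1.normal(size=10_000), rng2.normal(size=10_000)])
            ok += 0.99 <= r <= 1.01
        assert ok / 20 >= 0.95

    def test_chain_validation(self):
        with pytest.raises(ValueError):
            psrf([[1.0, 2.0]])
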