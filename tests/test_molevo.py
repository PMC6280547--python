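"""Distance phylogenetics, NG86 Ka/Ks and the branch-model LRT."""

import itertools
import math

import numpy as np
import pytest

from crossoil import molevo, synthetic_data as sd


class TestDistances:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAA", "AAAT", 0.25),
            ("AA-A", "AATA", 0.0),  # gap column dropped, 0/3
        ],
    )
    def test_p_distance(self, a, b, expected):
        assert molevo.p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            molevo.p_distance("--", "AA")

    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0.0), (0.1, -math.log(0.9))]
    )
    def test_poisson(self, p, expected):
        assert molevo.poisson_distance(p) == pytest.approx(expected)

    def test_poisson_monotone_and_dominates_p(self):
        ps = np.linspace(0, 0.95, 30)
        ds = [molevo.poisson_distance(p) for p in ps]
        assert all(a < b for a, b in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, ps))
        with pytest.raises(ValueError):
            molevo.poisson_distance(1.0)


def _tree_distances(tree):
    tips = list(tree.tips())
    return {
        frozenset((a.name, b.name)): a.distance(b)
        for a, b in itertools.combinations(tips, 2)
    }


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3.0, 5.0], [3.0, 0, 4.0], [5.0, 4.0, 0]])
        tree = molevo.neighbor_joining(d, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas
        assert lengths["a"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["b"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["c"] == pytest.approx((5 + 4 - 3) / 2)

    def test_additive_four_taxon_matrix_reproduced(self):
        # tree ((A:2,B:3):1,C:4,D:5) gives an additive matrix
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            float,
        )
        tree = molevo.neighbor_joining(d, list("ABCD"))
        got = _tree_distances(tree)
        ids = list("ABCD")
        for i, j in itertools.combinations(range(4), 2):
            assert got[frozenset((ids[i], ids[j]))] == pytest.approx(d[i, j])
        # sister structure: A and B share an internal parent
        parents = {t.name: t.parent for t in tree.tips()}
        assert parents["A"] is parents["B"]

    @pytest.mark.parametrize("n_taxa", [5, 8])
    def test_additive_random_trees_reproduced(self, n_taxa):
        # build a random binary tree, read off its additive matrix, and
        # require NJ to reproduce all path lengths (oracle: skbio paths)
        rng = np.random.default_rng(n_taxa)
        from skbio import TreeNode

        names = [f"t{i}" for i in range(n_taxa)]
        nodes = [TreeNode(name=n) for n in names]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            a, b = nodes[j], nodes[i]
            parent = TreeNode()
            a.length = float(rng.uniform(0.5, 3))
            b.length = float(rng.uniform(0.5, 3))
            parent.extend([a, b])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        true = nodes[0]
        d = np.zeros((n_taxa, n_taxa))
        tips = {t.name: t for t in true.tips()}
        for x, y in itertools.combinations(range(n_taxa), 2):
            d[x, y] = d[y, x] = tips[names[x]].distance(tips[names[y]])
        rebuilt = molevo.neighbor_joining(d, names)
        got = _tree_distances(rebuilt)
        for x, y in itertools.combinations(range(n_taxa), 2):
            assert got[frozenset((names[x], names[y]))] == pytest.approx(d[x, y])

    def test_agrees_with_skbio_nj_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        base = rng.uniform(1, 5, (6, 6))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"s{i}" for i in range(6)]
        mine = molevo.neighbor_joining(d, names)
        ref = skbio_nj(DistanceMatrix(d, names))
        assert mine.compare_subsets(ref) == pytest.approx(0.0)

    def test_ultrametric_quartet_sisters(self):
        # balanced quartet: (a,b) and (c,d) at height 1, root at height 3
        d = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            float,
        )
        tree = molevo.neighbor_joining(d, list("abcd"))
        parents = {t.name: t.parent for t in tree.tips()}
        assert parents["a"] is parents["b"]
        assert parents["c"] is parents["d"]

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            molevo.neighbor_joining(d, list("abc"))


def _two_clade_alignment(seed=1, length=300, clade_sep=80, within=6):
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"

    def mutate(s, k):
        s = list(s)
        for i in rng.choice(len(s), k, replace=False):
            s[i] = aas[rng.integers(20)]
        return "".join(s)

    base = "".join(aas[i] for i in rng.integers(0, 20, length))
    other = mutate(base, clade_sep)
    rows = [mutate(base, within) for _ in range(3)] + [
        mutate(other, within) for _ in range(3)
    ]
    return molevo.ProteinAlignment([f"x{i}" for i in range(6)], rows)


class TestBootstrap:
    def test_clear_clades_high_support(self):
        aln = _two_clade_alignment(seed=1)
        tree = molevo.bootstrap_support(aln, n_reps=100, seed=1)
        # the bipartition separating the two planted clades
        clade = frozenset(["x0", "x1", "x2"])
        supports = {}
        all_tips = frozenset(aln.ids)
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            supports[min(side, all_tips - side, key=sorted)] = node.support
        key = min(clade, all_tips - clade, key=sorted)
        assert supports[key] >= 95

    def test_single_replicate_support_binary(self):
        aln = _two_clade_alignment(seed=2)
        tree = molevo.bootstrap_support(aln, n_reps=1, seed=3)
        for node in tree.non_tips():
            assert node.support in (0.0, 100.0)

    def test_deterministic_given_seed(self):
        aln = _two_clade_alignment(seed=4)
        t1 = molevo.bootstrap_support(aln, n_reps=25, seed=9)
        t2 = molevo.bootstrap_support(aln, n_reps=25, seed=9)
        s1 = sorted(n.support for n in t1.non_tips())
        s2 = sorted(n.support for n in t2.non_tips())
        assert s1 == s2

    def test_taxon_order_invariance(self):
        aln = _two_clade_alignment(seed=5)
        perm = [3, 1, 5, 0, 4, 2]
        shuffled = molevo.ProteinAlignment(
            [aln.ids[i] for i in perm], [aln.rows[i] for i in perm]
        )
        def support_map(tree, ids):
            all_tips = frozenset(ids)
            out = {}
            for node in tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                out[min(side, all_tips - side, key=sorted)] = node.support
            return out

        m1 = support_map(molevo.bootstrap_support(aln, 50, seed=2), aln.ids)
        m2 = support_map(molevo.bootstrap_support(shuffled, 50, seed=2), aln.ids)
        # same bipartitions recovered; supports are resampling-order
        # dependent only through the seed, so allow sampling slack
        assert set(m1) == set(m2)
        for k in m1:
            assert abs(m1[k] - m2[k]) <= 15


class TestNg86:
    def test_identical_sequences_zero(self):
        seq = "ATGGCTGCTAAA" * 10
        est = molevo.ng86_ka_ks(seq, seq)
        assert est.ka == 0.0 and est.ks == 0.0 and est.omega is None

    def test_single_synonymous_change(self):
        # GGT -> GGC is synonymous (both glycine): Ka stays 0
        a = "GGT" + "ATGGCTAAAGCT" * 75
        b = "GGC" + "ATGGCTAAAGCT" * 75
        est = molevo.ng86_ka_ks(a, b)
        assert est.ka == 0.0
        assert est.ks > 0.0
        assert est.n_diffs == 0.0 and est.s_diffs == 1.0

    def test_single_nonsynonymous_change(self):
        a = "ATG" + "GCT" * 100
        b = "ATG" + "GCT" * 99 + "GAT"  # Ala -> Asp at the last codon
        est = molevo.ng86_ka_ks(a, b)
        assert est.s_diffs == 0.0 and est.n_diffs == 1.0
        assert est.ks == 0.0 and est.omega is None

    def test_agrees_with_independent_ng86(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        aln, _ = sd.simulate_codon_alignment(
            sd.SimConfig(seed=1, n_codons=400),
            "(A:0.08,B:0.08,C:0.02);",
            default_omega=0.5,
        )
        est = molevo.ng86_ka_ks(aln["A"], aln["B"])
        dn, ds = cal_dn_ds(CodonSeq(aln["A"]), CodonSeq(aln["B"]), method="NG86")
        assert est.ka == pytest.approx(dn, abs=5e-3)
        assert est.ks == pytest.approx(ds, abs=5e-3)

    def test_recovers_neutral_omega(self):
        aln, _ = sd.simulate_codon_alignment(
            sd.SimConfig(seed=1, n_codons=3000),
            "(A:0.1,B:0.1,C:0.02);",
            default_omega=1.0,
        )
        est = molevo.ng86_ka_ks(aln["A"], aln["B"])
        assert 0.7 <= est.omega <= 1.4

    def test_omega_ordering_preserved(self):
        aln, _ = sd.simulate_codon_alignment(
            sd.SimConfig(seed=1, n_codons=2000),
            "(A:0.1,B:0.1,C:0.1);",
            {"A": 0.1, "B": 1.0},
        )
        purifying = molevo.ng86_ka_ks(aln["A"], aln["C"])
        neutral = molevo.ng86_ka_ks(aln["B"], aln["C"])
        assert purifying.omega < neutral.omega

    def test_length_validation(self):
        with pytest.raises(ValueError):
            molevo.ng86_ka_ks("ATGG", "ATGG")


class TestBranchLrt:
    def test_published_branch_model_comparison(self):
        res = molevo.branch_lrt(-2343.655, -2361.163, 6)
        assert res.statistic == pytest.approx(35.016, abs=1e-9)
        assert res.p_value == pytest.approx(4.278e-06, rel=1e-3)
        assert res.label_swap  # the freer model printed the lower lnL

    def test_equal_likelihoods(self):
        res = molevo.branch_lrt(-100.0, -100.0, 3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_df2_closed_form(self):
        res = molevo.branch_lrt(-50.0, -46.2, 2)
        assert res.p_value == pytest.approx(math.exp(-res.statistic / 2))

    def test_df6_series_closed_form(self):
        # chi-square upper tail at even df has a finite Poisson series
        res = molevo.branch_lrt(-2343.655, -2361.163, 6)
        x = res.statistic / 2
        series = math.exp(-x) * (1 + x + x * x / 2)
        assert res.p_value == pytest.approx(series, abs=1e-9)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            molevo.branch_lrt(-1.0, -2.0, 0)
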