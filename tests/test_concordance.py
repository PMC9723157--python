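"""Gene/site concordance factors, ILS equality tests, quartet frequencies and
the polytomy test."""

import numpy as np
import pytest

from phyloconcord.alignments import Alignment
from phyloconcord.concordance import (
    QuartetFrequencies,
    concordance_table,
    equality_test,
    gene_concordance_factors,
    polytomy_test,
    quartet_frequencies,
    quartet_topology_frequencies,
    site_concordance_factors,
)
from phyloconcord.simulate import (
    SimulationConfig,
    SpeciesTreeModel,
    simulate_jc_alignment,
    simulate_msc_gene_trees,
)
from phyloconcord.trees import (
    GeneTreeCategory,
    classify_gene_tree,
    parse_newick,
    reference_branches,
)

from conftest import random_binary_tree

REF5 = "(((A1,A2),B),(C,D));"
# gene-tree topologies with known categories at the {C,D} branch of REF5
# (blocks A={A1,A2}, B={B}, C={C}, D={D})
GENE_CONCORDANT = "(((A1,A2),B),(C,D));"
GENE_DF1 = "(((A1,A2),C),(B,D));"
GENE_DF2 = "(((A1,A2),D),(B,C));"
GENE_PARA = "((A1,C),((A2,D),B));"


def make_gene_set(n_con, n_df1, n_df2, n_para=0):
    trees = []
    for nwk, n in [(GENE_CONCORDANT, n_con), (GENE_DF1, n_df1),
                   (GENE_DF2, n_df2), (GENE_PARA, n_para)]:
        trees.extend(parse_newick(nwk) for _ in range(n))
    return trees


class TestEqualityTest:
    def test_symmetric_counts(self):
        res = equality_test(50, 50)
        assert res.chi2 == 0
        assert res.p == 1.0

    def test_one_sided_extreme(self):
        res = equality_test(25, 0)
        assert res.chi2 == pytest.approx(25.0)
        assert res.p == pytest.approx(5.733e-7, rel=1e-3)

    def test_moderate_asymmetry(self):
        res = equality_test(49, 73)
        assert res.chi2 == pytest.approx(576 / 122)
        assert res.p == pytest.approx(0.0298, abs=0.0005)

    def test_both_zero_undefined(self):
        assert equality_test(0, 0) is None

    def test_matches_binomial_monte_carlo(self):
        # under H0 each of n = n1+n2 genes picks a side fairly; the rejection
        # rate of the chi-square at the observed statistic's threshold must
        # match the simulated binomial tail
        rng = np.random.default_rng(8)
        n = 122
        stat = lambda k: (2 * k - n) ** 2 / n
        crit = equality_test(49, 73).chi2
        sims = rng.binomial(n, 0.5, size=20000)
        mc_p = np.mean(stat(sims) >= crit - 1e-9)
        assert equality_test(49, 73).p == pytest.approx(mc_p, abs=0.01)


class TestGeneConcordanceFactors:
    def test_all_identical_gene_trees(self, balanced_tree):
        gts = [parse_newick(balanced_tree.write_newick(lengths=False))
               for _ in range(10)]
        for rec in gene_concordance_factors(balanced_tree, gts):
            assert rec.gcf == 100.0
            assert rec.gdf1 == rec.gdf2 == rec.gdfp == 0.0
            assert rec.gn == 10

    def test_constructed_counts(self):
        ref = parse_newick(REF5)
        gts = make_gene_set(5, 3, 2)
        recs = {r.branch_id: r for r in gene_concordance_factors(ref, gts)}
        rec = recs["C,D"]
        assert (rec.gcf, rec.gdf1, rec.gdf2, rec.gdfp) == (50.0, 30.0, 20.0, 0.0)
        assert rec.gn == 10

    def test_paraphyly_complement(self):
        ref = parse_newick(REF5)
        gts = make_gene_set(266, 189, 58, 487)
        rec = {r.branch_id: r for r in gene_concordance_factors(ref, gts)}["C,D"]
        assert rec.gcf == pytest.approx(26.6)
        assert rec.gdf1 == pytest.approx(18.9)
        assert rec.gdf2 == pytest.approx(5.8)
        assert rec.gdfp == pytest.approx(100 - 26.6 - 18.9 - 5.8)  # = 48.7

    def test_conservation_identity_every_branch(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            ref = random_binary_tree(labels, rng)
            gts = []
            for _ in range(int(rng.integers(2, 12))):
                keep = [l for l in labels if rng.random() > 0.25] or labels
                gts.append(random_binary_tree(keep, rng))
            for rec in gene_concordance_factors(ref, gts):
                if rec.gn > 0:
                    assert rec.gcf + rec.gdf1 + rec.gdf2 + rec.gdfp == \
                        pytest.approx(100.0)
                else:
                    assert rec.gcf is None  # undefined, never zero

    def test_undefined_branch_reported_null(self):
        ref = parse_newick("((A,B),((C,D),(E,F)));")
        gts = [parse_newick("((A,B),(C,D));")]  # misses E and F entirely
        recs = {r.branch_id: r for r in gene_concordance_factors(ref, gts)}
        assert recs["E,F"].gcf is None
        assert recs["E,F"].gn == 0

    def test_nonbinary_reference_rejected(self):
        ref = parse_newick("((A,B),(C,D,E),F);")
        with pytest.raises(ValueError, match="binary"):
            gene_concordance_factors(ref, [parse_newick("((A,B),(C,D));")])

    def test_matches_bruteforce_on_random_instances(self):
        # oracle: per-branch category counting via exhaustive bipartition
        # listing, reusing the independently tested classifier path
        from test_trees import _oracle_classify

        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            ref = random_binary_tree(labels, rng)
            gts = []
            for _ in range(int(rng.integers(2, 15))):
                keep = [l for l in labels if rng.random() > 0.25]
                gts.append(random_binary_tree(keep if len(keep) >= 4 else labels, rng))
            recs = gene_concordance_factors(ref, gts)
            for br, rec in zip(reference_branches(ref), recs):
                cats = [
                    _oracle_classify(gt.write_newick(), br.quadripartition)
                    for gt in gts
                ]
                want_gn = sum(c is not GeneTreeCategory.NOT_DECISIVE for c in cats)
                assert rec.gn == want_gn
                assert rec.n_concordant == sum(
                    c is GeneTreeCategory.CONCORDANT for c in cats
                )
                assert rec.n_df1 == sum(c is GeneTreeCategory.DF1 for c in cats)
                assert rec.n_df2 == sum(c is GeneTreeCategory.DF2 for c in cats)


class TestQuartetFrequencies:
    def test_all_concordant(self):
        ref = parse_newick(REF5)
        qf = quartet_frequencies(ref, {"C", "D"}, make_gene_set(10, 0, 0))
        assert (qf.q_main, qf.q_alt1, qf.q_alt2) == (1.0, 0.0, 0.0)

    def test_paraphyly_excluded_from_denominator(self):
        ref = parse_newick(REF5)
        qf = quartet_frequencies(ref, {"C", "D"}, make_gene_set(45, 29, 26, 100))
        assert qf.q_main == pytest.approx(0.45)
        assert qf.q_alt1 == pytest.approx(0.29)
        assert qf.q_alt2 == pytest.approx(0.26)
        assert qf.n_decisive == 100

    def test_frequencies_sum_to_one(self):
        ref = parse_newick(REF5)
        qf = quartet_frequencies(ref, {"C", "D"}, make_gene_set(3, 4, 5, 2))
        assert qf.q_main + qf.q_alt1 + qf.q_alt2 == pytest.approx(1.0)

    def test_no_resolving_trees_undefined(self):
        ref = parse_newick(REF5)
        qf = quartet_frequencies(ref, {"C", "D"}, make_gene_set(0, 0, 0, 5))
        assert qf.q_main is None
        assert qf.n_decisive == 0

    def test_msc_simulation_matches_closed_form(self):
        T = 0.6
        ref = parse_newick(f"((A:1.0,B:1.0):{T},(C:{1 + T},D:{1 + T}):0.0);")
        gts = simulate_msc_gene_trees(
            SpeciesTreeModel(ref), SimulationConfig(2000, seed=31)
        )
        qf = quartet_topology_frequencies(ref, {"A", "B"}, gts)
        expected = 1 - (2 / 3) * np.exp(-T)  # 0.634
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(qf.q_main - expected) < 3 * se
        alt = (1 / 3) * np.exp(-T)  # 0.183
        se_alt = np.sqrt(alt * (1 - alt) / 2000)
        assert abs(qf.q_alt1 - alt) < 3 * se_alt
        assert abs(qf.q_alt2 - alt) < 3 * se_alt


class TestPolytomyTest:
    def test_near_uniform_not_rejected(self):
        res = polytomy_test(QuartetFrequencies.from_counts(34, 33, 33))
        assert res.chi2 == pytest.approx(0.02)
        assert res.p == pytest.approx(0.99, abs=0.005)
        assert not res.rejects()

    def test_skewed_rejected(self):
        res = polytomy_test(QuartetFrequencies.from_counts(60, 20, 20))
        assert res.chi2 == pytest.approx(32.0)
        assert res.p == pytest.approx(1.125e-7, rel=1e-2)
        assert res.rejects()

    def test_extreme_rejection(self):
        res = polytomy_test(QuartetFrequencies.from_counts(100, 0, 0))
        assert res.p < 1e-15

    def test_undefined_without_data(self):
        with pytest.raises(ValueError):
            polytomy_test(QuartetFrequencies.from_counts(0, 0, 0))


def _exhaustive_scf_oracle(ref, aln, split):
    """Naive per-quartet enumeration with pure-python counting."""
    from phyloconcord.trees import quadripartition

    q = quadripartition(ref, split)
    idx = {t: i for i, t in enumerate(aln.taxa)}
    fracs, ns = [], []
    for a in sorted(q.a):
        for b in sorted(q.b):
            for c in sorted(q.c):
                for d in sorted(q.d):
                    n_main = n1 = n2 = 0
                    for col in zip(*(aln.sequences[idx[x]] for x in (a, b, c, d))):
                        if any(ch not in "ACGT" for ch in col):
                            continue
                        w, x, y, z = col
                        if w == x and y == z and w != y:
                            n_main += 1
                        elif w == y and x == z and w != x:
                            n1 += 1
                        elif w == z and x == y and w != x:
                            n2 += 1
                    tot = n_main + n1 + n2
                    if tot:
                        fracs.append(100 * n_main / tot)
                        ns.append(tot)
    return (np.mean(fracs) if fracs else None), (np.mean(ns) if ns else None)


class TestSiteConcordanceFactors:
    def test_long_internal_branches_give_high_scf(self):
        nwk = "(((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4):0.05,(E:0.1,F:0.1):0.45);"
        ref = parse_newick(nwk)
        aln = simulate_jc_alignment(ref, 3000, seed=4)
        for rec in site_concordance_factors(ref, aln, exhaustive=True):
            assert rec.scf > 75

    def test_exhaustive_matches_independent_oracle(self):
        nwk = "(((A:0.2,B:0.3):0.2,(C:0.2,D:0.25):0.2):0.1,(E:0.3,F:0.2):0.2);"
        ref = parse_newick(nwk)
        aln = simulate_jc_alignment(ref, 500, seed=12)
        recs = site_concordance_factors(ref, aln, exhaustive=True)
        for rec in recs:
            want_scf, want_sn = _exhaustive_scf_oracle(ref, aln, rec.split)
            assert rec.scf == pytest.approx(want_scf)
            assert rec.sn == pytest.approx(want_sn)

    def test_sampled_estimate_near_exhaustive(self):
        nwk = "(((A:0.2,B:0.3):0.2,(C:0.2,D:0.25):0.2):0.1,(E:0.3,F:0.2):0.2);"
        ref = parse_newick(nwk)
        aln = simulate_jc_alignment(ref, 800, seed=19)
        ex = {r.branch_id: r for r in site_concordance_factors(ref, aln, exhaustive=True)}
        sm = {r.branch_id: r for r in
              site_concordance_factors(ref, aln, n_quartets=2000, seed=3)}
        for bid in ex:
            assert sm[bid].scf == pytest.approx(ex[bid].scf, abs=3.0)

    def test_invariant_sites_undefined(self, balanced_tree):
        aln = Alignment(sorted(balanced_tree.leaf_labels), ["AAAA"] * 6)
        for rec in site_concordance_factors(balanced_tree, aln, n_quartets=5, seed=0):
            assert rec.scf is None

    def test_conservation_identity(self):
        nwk = "(((A:0.2,B:0.3):0.2,(C:0.2,D:0.25):0.2):0.1,(E:0.3,F:0.2):0.2);"
        ref = parse_newick(nwk)
        aln = simulate_jc_alignment(ref, 400, seed=2)
        for rec in site_concordance_factors(ref, aln, n_quartets=300, seed=5):
            assert rec.scf + rec.sdf1 + rec.sdf2 == pytest.approx(100.0)

    def test_missing_block_taxon_reported_undefined(self, balanced_tree):
        aln = simulate_jc_alignment(
            parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"), 100, seed=1
        )
        recs = site_concordance_factors(balanced_tree, aln, n_quartets=10, seed=0)
        assert any(r.scf is None for r in recs)

    def test_seeded_determinism(self):
        nwk = "(((A:0.2,B:0.3):0.2,(C:0.2,D:0.25):0.2):0.1,(E:0.3,F:0.2):0.2);"
        ref = parse_newick(nwk)
        aln = simulate_jc_alignment(ref, 300, seed=6)
        a = site_concordance_factors(ref, aln, n_quartets=100, seed=9)
        b = site_concordance_factors(ref, aln, n_quartets=100, seed=9)
        assert [(r.scf, r.sdf1, r.sdf2, r.sn) for r in a] == \
            [(r.scf, r.sdf1, r.sdf2, r.sn) for r in b]


class TestIlsCalibration:
    def test_gcf_monotone_in_branch_length(self):
        """Mean gene concordance rises strictly with the focal branch's
        coalescent length."""
        means = []
        for T in (0.1, 0.5, 1.0, 2.0, 5.0):
            ref = parse_newick(
                f"((A:1.0,B:1.0):{T},(C:{1 + T},D:{1 + T}):0.0);"
            )
            gts = simulate_msc_gene_trees(
                SpeciesTreeModel(ref), SimulationConfig(2000, seed=101)
            )
            rec = {
                r.branch_id: r for r in gene_concordance_factors(ref, gts)
            }["C,D"]
            means.append(rec.gcf)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_equality_test_type_one_error(self, caterpillar_tree):
        """Under pure ILS the two alternatives are symmetric: the gEF test at
        alpha = 0.05 rejects in about 5% of replicate simulations."""
        model = SpeciesTreeModel(caterpillar_tree)
        n_rep = 200
        rejections = 0
        tests = 0
        for rep in range(n_rep):
            gts = simulate_msc_gene_trees(
                model, SimulationConfig(150, seed=20_000 + rep)
            )
            for rec in gene_concordance_factors(caterpillar_tree, gts):
                if rec.gef is not None:
                    tests += 1
                    rejections += rec.gef.p < 0.05
        rate = rejections / tests
        # 99% binomial envelope around 0.05 at n = 600 tests
        assert 0.027 < rate < 0.073


class TestConcordanceTable:
    def test_gene_and_site_fields_merged(self):
        nwk = "(((A:0.2,B:0.3):0.2,(C:0.2,D:0.25):0.2):0.1,(E:0.3,F:0.2):0.2);"
        ref = parse_newick(nwk)
        gts = simulate_msc_gene_trees(
            SpeciesTreeModel(parse_newick(
                "(((A:1,B:1):0.5,(C:1,D:1):0.5):0.5,(E:1.5,F:1.5):0.5);"
            )),
            SimulationConfig(30, seed=1),
        )
        aln = simulate_jc_alignment(ref, 300, seed=2)
        recs = concordance_table(ref, gts, aln, n_quartets=100, seed=3)
        assert len(recs) == 3
        for rec in recs:
            assert rec.gcf is not None
            assert rec.scf is not None
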