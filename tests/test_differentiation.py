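import numpy as np
import pandas as pd
import pytest

from palmpop import (
    GeneticMap,
    SimConfig,
    allele_counts,
    exclude_lg,
    fisher_scan,
    fit_admixture,
    fixed_differences,
    lg_enrichment,
    simulate_dataset,
    weir_cockerham_fst,
    window_density,
)
from palmpop.differentiation import differentiation_table, private_alleles
from palmpop.genmap import UNMAPPED
from palmpop.matrix import MISSING

from _oracles import brute_private, fisher_two_sided, wc_fst_summaries
from conftest import make_matrix

TWO_GROUPS = {"West": ["W"], "East": ["E"]}


def _labels(n_west, n_east):
    return ["W"] * n_west + ["E"] * n_east


class TestAlleleCounts:
    def test_het_plus_homalt(self):
        gm = make_matrix([[1], [2], [0], [0]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        assert counts.ref[0, 0] == 1 and counts.alt[0, 0] == 3
        assert counts.ref[1, 0] == 4 and counts.alt[1, 0] == 0

    def test_missing_tallied_separately(self):
        gm = make_matrix([[MISSING], [MISSING], [1], [1]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        assert counts.ref[0, 0] == 0 and counts.alt[0, 0] == 0
        assert counts.missing[0, 0] == 2

    def test_empty_group_rejected(self):
        gm = make_matrix([[1], [1]])
        with pytest.raises(ValueError, match="no samples"):
            allele_counts(gm, ["W", "W"], TWO_GROUPS)

    def test_matches_brute_force(self, rng):
        dosage = rng.integers(-1, 3, size=(20, 60))
        labels = _labels(9, 11)
        counts = allele_counts(make_matrix(dosage), labels, TWO_GROUPS)
        masks = [np.array(labels) == "W", np.array(labels) == "E"]
        flags = brute_private(dosage, masks)
        priv = private_alleles(counts)
        assert list(priv["nonref_private"]) == [f[0] for f in flags]
        assert list(priv["ref_private"]) == [f[1] for f in flags]


class TestPrivateAlleles:
    def test_definitions(self):
        # locus 0: alt only in West; locus 1: alt in both, ref only in East;
        # locus 2: both alleles in both groups
        gm = make_matrix([[1, 2, 1], [0, 2, 1], [0, 1, 1], [0, 1, 0]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        priv = private_alleles(counts)
        assert priv.loc[0, "nonref_private"] and priv.loc[0, "nonref_private_group"] == "West"
        assert not priv.loc[1, "nonref_private"]
        assert priv.loc[1, "ref_private"] and priv.loc[1, "ref_private_group"] == "East"
        assert not priv.loc[2, "nonref_private"] and not priv.loc[2, "ref_private"]


class TestWeirCockerham:
    def test_fixed_difference_gives_theta_one(self):
        gm = make_matrix([[0], [0], [2], [2]])
        res = weir_cockerham_fst(gm, _labels(2, 2), TWO_GROUPS)
        assert res.a[0] == pytest.approx(0.5, abs=1e-12)
        assert res.b[0] == pytest.approx(0.0, abs=1e-12)
        assert res.c[0] == pytest.approx(0.0, abs=1e-12)
        assert res.per_locus[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_locus_excluded(self):
        gm = make_matrix([[0, 1], [0, 2], [0, 0], [0, 1]])
        res = weir_cockerham_fst(gm, _labels(2, 2), TWO_GROUPS)
        assert res.n_excluded == 1
        assert np.isnan(res.per_locus[0])

    def test_all_degenerate_rejected(self):
        gm = make_matrix([[0], [0], [0], [0]])
        with pytest.raises(ValueError, match="no informative"):
            weir_cockerham_fst(gm, _labels(2, 2), TWO_GROUPS)

    def test_single_locus_weighted_equals_mean(self, rng):
        dosage = rng.integers(0, 3, size=(12, 1))
        res = weir_cockerham_fst(make_matrix(dosage), _labels(6, 6), TWO_GROUPS)
        assert res.weighted_fst == pytest.approx(res.mean_fst, abs=1e-12)

    def test_matches_independent_oracle_per_locus(self, rng):
        dosage = rng.integers(-1, 3, size=(24, 80))
        labels = _labels(10, 14)
        res = weir_cockerham_fst(make_matrix(dosage), labels, TWO_GROUPS)
        masks = [np.array(labels) == "W", np.array(labels) == "E"]
        mean_o, weighted_o, thetas_o = wc_fst_summaries(dosage, masks)
        got = res.per_locus[res.informative]
        np.testing.assert_allclose(got, thetas_o, atol=1e-12)
        assert res.mean_fst == pytest.approx(mean_o, abs=1e-12)
        assert res.weighted_fst == pytest.approx(weighted_o, abs=1e-12)

    def test_monotone_in_simulated_divergence(self):
        estimates = []
        for f in (0.05, 0.2, 0.35):
            cfg = SimConfig(
                n_loci=800, n_per_pop=(30, 30), n_admixed=0, n_outgroup=0,
                n_duplicates=0, private_rate=0.0, missing_rate=0.0,
                fst_true=f, seed=99,
            )
            gm, sheet, *_ = simulate_dataset(cfg)
            labels = ["W" if r == "North_Africa" else "E" for r in sheet.table["region"]]
            estimates.append(weir_cockerham_fst(gm, labels, TWO_GROUPS).weighted_fst)
        assert estimates[0] < estimates[1] < estimates[2]


class TestFisherScan:
    def test_identical_counts_give_p_one(self):
        gm = make_matrix([[1], [1], [1], [1]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        scan = fisher_scan(counts)
        assert scan.loc[0, "p"] == pytest.approx(1.0)

    def test_extreme_table(self):
        # allele counts [[10, 0], [0, 10]]: p = 2 / C(20, 10)
        gm = make_matrix([[0] * 1, [0], [0], [0], [0], [2], [2], [2], [2], [2]])
        counts = allele_counts(gm, _labels(5, 5), TWO_GROUPS)
        scan = fisher_scan(counts)
        assert scan.loc[0, "p"] == pytest.approx(1.0825e-5, rel=1e-3)
        assert scan.loc[0, "p"] == pytest.approx(fisher_two_sided(10, 0, 0, 10), rel=1e-9)

    def test_bonferroni_single_locus_identity(self):
        gm = make_matrix([[0], [2], [1], [1]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        scan = fisher_scan(counts)
        assert scan.loc[0, "p_adj"] == pytest.approx(scan.loc[0, "p"])

    def test_uncalled_group_excluded_from_m(self):
        gm = make_matrix([[1, 1], [1, 1], [MISSING, 1], [MISSING, 1]])
        counts = allele_counts(gm, _labels(2, 2), TWO_GROUPS)
        scan = fisher_scan(counts)
        assert not scan.loc[0, "tested"]
        assert scan.loc[1, "p_adj"] == pytest.approx(scan.loc[1, "p"])  # m == 1


class TestFixedDifferences:
    def test_examples(self):
        # locus 0 fixed; locus 1 one West het; locus 2 East uncalled
        gm = make_matrix(
            [[2, 2, 2], [2, 1, 2], [0, 0, MISSING], [0, 0, MISSING]]
        )
        fixed = fixed_differences(allele_counts(gm, _labels(2, 2), TWO_GROUPS))
        assert list(fixed) == [True, False, False]

    def test_fixed_implies_nonref_private(self, rng):
        dosage = rng.integers(-1, 3, size=(16, 120))
        counts = allele_counts(make_matrix(dosage), _labels(8, 8), TWO_GROUPS)
        fixed = fixed_differences(counts)
        priv = private_alleles(counts)
        assert (priv.loc[fixed, "nonref_private"]).all()


def _toy_map():
    return GeneticMap(
        pd.DataFrame(
            {
                "lg": ["LG1", "LG1", "LG2"],
                "contig": ["c1", "c2", "c3"],
                "order": [1, 2, 1],
                "length": [100, 200, 150],
            }
        )
    )


class TestArtificialChromosomes:
    def test_offsets(self):
        gmap = _toy_map()
        assert gmap.locate("c2", 50) == ("LG1", 150)  # 100 + 50
        assert gmap.locate("c1", 1) == ("LG1", 1)
        assert gmap.locate("zzz", 7) == (UNMAPPED, 7)

    def test_duplicate_contig_rejected(self):
        tab = _toy_map().table[["lg", "contig", "order", "length"]]
        bad = pd.concat([tab, tab.iloc[[0]].assign(order=9)])
        with pytest.raises(ValueError, match="more than once"):
            GeneticMap(bad)


class TestEnrichment:
    def test_threefold_example(self):
        # genome: 1000 SNPs, 50 significant; LG1: 100 SNPs, 15 significant
        gmap = GeneticMap(
            pd.DataFrame(
                {"lg": ["LG1", "LG2"], "contig": ["c1", "c2"], "order": [1, 1],
                 "length": [10_000, 100_000]}
            )
        )
        table = pd.DataFrame(
            {
                "contig": ["c1"] * 100 + ["c2"] * 900,
                "pos": list(range(1, 101)) + list(range(1, 901)),
                "significant": [True] * 15 + [False] * 85 + [True] * 35 + [False] * 865,
            }
        )
        enr = lg_enrichment(table, gmap).set_index("lg")
        assert enr.loc["LG1", "fold"] == pytest.approx(3.0)

    def test_lg_without_hits_gets_fold_zero(self):
        gmap = _toy_map()
        table = pd.DataFrame(
            {"contig": ["c1", "c3"], "pos": [5, 10], "significant": [True, False]}
        )
        enr = lg_enrichment(table, gmap).set_index("lg")
        assert enr.loc["LG2", "fold"] == 0.0

    def test_window_counts_sum_to_lg_totals(self, two_pop_sim):
        gm, sheet, gmap, *_ = two_pop_sim
        labels = ["W" if r in ("North_Africa", "Central", "Outgroup") else "E"
                  for r in sheet.table["region"]]
        table, _ = differentiation_table(gm, labels, TWO_GROUPS)
        dens = window_density(table, gmap, window_bp=100_000)
        per_lg = dens.groupby("lg")["n_snps"].sum()
        coords = gmap.locate_frame(gm.loci)
        expected = coords.groupby("lg").size()
        for lg in expected.index:
            assert per_lg[lg] == expected[lg]
        with pytest.raises(ValueError, match="positive"):
            window_density(table, gmap, window_bp=0)


class TestExcludeLg:
    def test_removes_exactly_the_lg_loci(self, two_pop_sim):
        gm, _, gmap, *_ = two_pop_sim
        lg = gmap.linkage_groups[0]
        contigs = set(gmap.contigs_of(lg))
        k = int(gm.loci["contig"].isin(contigs).sum())
        out = exclude_lg(gm, gmap, lg)
        assert out.n_loci == gm.n_loci - k
        assert not out.loci["contig"].isin(contigs).any()

    def test_unknown_lg_rejected(self, two_pop_sim):
        gm, _, gmap, *_ = two_pop_sim
        with pytest.raises(ValueError, match="unknown linkage group"):
            exclude_lg(gm, gmap, "LG999")

    def test_excluded_matrix_feeds_admixture(self, two_pop_sim):
        gm, _, gmap, *_ = two_pop_sim
        out = exclude_lg(gm, gmap, gmap.linkage_groups[0])
        run = fit_admixture(out.take_loci(np.arange(min(50, out.n_loci))), K=2,
                            burn_in=10, n_reps=20, seed=1)
        assert run.Q.shape[1] == 2
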