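"""Genotype container and population-genetic statistics, checked against
slow enumeration / scalar oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riverpopgen import popgen as pg
from riverpopgen.synthetic import SyntheticGenotypeConfig, island_model_genotypes

from conftest import make_genotypes


def rarefaction_oracle(copies, g):
    """Mean number of distinct alleles over all C(N, g) subsets."""
    vals = [
        len(set(sub)) for sub in itertools.combinations(copies, g)
    ]
    return sum(vals) / len(vals)


class TestTableIO:
    def test_read_write_round_trip(self, tmp_path, toy_genotypes):
        pg.write_genotypes(toy_genotypes, tmp_path / "g.tsv")
        back = pg.read_genotypes(tmp_path / "g.tsv")
        assert back.n_individuals == 4
        pd.testing.assert_frame_equal(
            back.data[sorted(back.data.columns)],
            toy_genotypes.data[sorted(toy_genotypes.data.columns)],
        )

    def test_missing_round_trip(self, tmp_path):
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(120, 122), None]),
                ("i2", "N", "A", [(120, 120), (100, 100)]),
            ]
        )
        pg.write_genotypes(gt, tmp_path / "g.tsv")
        back = pg.read_genotypes(tmp_path / "g.tsv")
        assert back.data.loc[0, "locus2_a1"] == pg.MISSING

    def test_half_missing_call_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "individual_id": ["i1"],
                "node_id": ["N"],
                "species": ["A"],
                "locus1_a1": [120],
                "locus1_a2": [""],
            }
        )
        df.to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        with pytest.raises(pg.GenotypeValidationError, match="half-missing"):
            pg.read_genotypes(tmp_path / "g.tsv")

    def test_duplicate_individual_rejected(self):
        with pytest.raises(pg.GenotypeValidationError, match="duplicate"):
            make_genotypes(
                [
                    ("i1", "N", "A", [(1, 1), (1, 1)]),
                    ("i1", "N", "A", [(1, 2), (1, 1)]),
                ]
            )

    def test_genepop_import_matches_tsv(self, tmp_path, toy_genotypes):
        # same four individuals in 3-digit genepop encoding
        lines = ["toy data", "locus1", "locus2", "pop"]
        for _, row in toy_genotypes.data.iterrows():
            calls = " ".join(
                f"{row[f'{loc}_a1']:03d}{row[f'{loc}_a2']:03d}"
                for loc in ("locus1", "locus2")
            )
            lines.append(f"L1 , {calls}")
        (tmp_path / "toy.gen").write_text("\n".join(lines) + "\n")
        back = pg.read_genepop(tmp_path / "toy.gen", species="A")
        for loc in ("locus1", "locus2"):
            for a in ("_a1", "_a2"):
                np.testing.assert_array_equal(
                    back.data[loc + a].to_numpy(),
                    toy_genotypes.data[loc + a].to_numpy(),
                )


class TestFilter:
    def test_threshold_keeps_only_large_groups(self):
        rows = []
        for node, n in (("N14", 14), ("N15", 15), ("N16", 16)):
            for i in range(n):
                rows.append((f"{node}_i{i}", node, "A", [(1, 2), (1, 1)]))
        gt = make_genotypes(rows)
        kept = pg.filter_nodes(gt, min_n=15)
        assert set(kept.data["node_id"]) == {"N15", "N16"}
        assert pg.filter_nodes(gt, min_n=1).n_individuals == gt.n_individuals

    def test_empty_result_flagged(self, toy_genotypes):
        with pytest.raises(pg.GenotypeValidationError):
            pg.filter_nodes(toy_genotypes, min_n=100)


class TestFrequencies:
    def test_monomorphic(self):
        gt = make_genotypes([("i1", "N", "A", [(120, 120), (1, 1)])])
        assert pg.allele_frequencies(gt, "N", "A", "locus1") == {120: 1.0}

    def test_hand_counts(self):
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(120, 122), (1, 1)]),
                ("i2", "N", "A", [(120, 120), (1, 1)]),
            ]
        )
        freqs = pg.allele_frequencies(gt, "N", "A", "locus1")
        assert freqs == {120: 0.75, 122: 0.25}

    def test_frequencies_sum_to_one(self):
        gt = island_model_genotypes(
            SyntheticGenotypeConfig(n_pops=3, n_per_pop=20, seed=1)
        )
        for loc in gt.loci:
            s = sum(pg.allele_frequencies(gt, "pop01", "synthetic", loc).values())
            assert s == pytest.approx(1.0)


class TestAllelicRichness:
    def test_monomorphic_copies(self):
        assert pg._rarefied_richness([4], 2) == pytest.approx(1.0)

    def test_three_one_split_matches_enumeration(self):
        # copies {1,1,1,2}: C(4,2)=6 subsets, mean distinct = (3*1 + 3*2)/6
        assert pg._rarefied_richness([3, 1], 2) == pytest.approx(1.5)
        assert rarefaction_oracle([1, 1, 1, 2], 2) == pytest.approx(1.5)

    @pytest.mark.parametrize("counts", [[3, 1], [2, 2, 2], [5, 2, 1], [1, 1, 1, 1]])
    @pytest.mark.parametrize("g", [2, 3, 4])
    def test_matches_subset_enumeration(self, counts, g):
        copies = [a for a, c in enumerate(counts) for _ in range(c)]
        if g > len(copies):
            pytest.skip("g exceeds copies")
        expected = rarefaction_oracle(copies, g)
        assert pg._rarefied_richness(counts, g) == pytest.approx(expected)

    def test_full_sample_equals_allele_count(self):
        counts = [3, 2, 1, 4]
        assert pg._rarefied_richness(counts, sum(counts)) == pytest.approx(4.0)

    def test_monotone_in_g(self):
        counts = [5, 3, 2]
        vals = [pg._rarefied_richness(counts, g) for g in range(2, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_table_level_defaults_and_errors(self, toy_genotypes):
        tab, g = pg.allelic_richness(toy_genotypes)
        assert g == 8  # 2 x 4 fully observed individuals
        with pytest.raises(ValueError, match="exceeds"):
            pg.allelic_richness(toy_genotypes, g=10)
        with pytest.raises(ValueError, match=">= 2"):
            pg.allelic_richness(toy_genotypes, g=1)


class TestHeterozygosity:
    def test_observed_hand_values(self):
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(1, 2), (1, 1)]),
                ("i2", "N", "A", [(1, 1), (1, 1)]),
                ("i3", "N", "A", [(2, 2), (1, 1)]),
                ("i4", "N", "A", [(1, 1), (1, 1)]),
            ]
        )
        ho = pg.observed_heterozygosity(gt)
        assert ho.loc[("N", "A"), "Ho_locus1"] == pytest.approx(0.25)
        assert ho.loc[("N", "A"), "Ho_locus2"] == 0.0

    def test_expected_monomorphic_zero(self):
        gt = make_genotypes(
            [("i1", "N", "A", [(1, 1), (1, 1)]), ("i2", "N", "A", [(1, 1), (1, 1)])]
        )
        for unbiased in (True, False):
            he = pg.expected_heterozygosity(gt, unbiased=unbiased)
            assert he.loc[("N", "A"), "He"] == 0.0

    def test_two_heterozygotes_scalar_case(self):
        # both individuals 1/2: plain 0.5; unbiased (2/1)(1 - 0.5 - 1/4) = 0.5
        gt = make_genotypes(
            [("i1", "N", "A", [(1, 2), (1, 1)]), ("i2", "N", "A", [(1, 2), (1, 1)])]
        )
        plain = pg.expected_heterozygosity(gt, unbiased=False)
        unb = pg.expected_heterozygosity(gt, unbiased=True)
        assert plain.loc[("N", "A"), "He_locus1"] == pytest.approx(0.5)
        assert unb.loc[("N", "A"), "He_locus1"] == pytest.approx(0.5)

    def test_plain_gene_diversity_formula(self):
        # frequencies (0.25, 0.25, 0.5) -> 1 - sum p^2 = 0.625
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(1, 2), (1, 1)]),
                ("i2", "N", "A", [(3, 3), (1, 1)]),
            ]
        )
        plain = pg.expected_heterozygosity(gt, unbiased=False)
        assert plain.loc[("N", "A"), "He_locus1"] == pytest.approx(0.625)

    def test_unbiased_single_individual_raises(self):
        gt = make_genotypes([("i1", "N", "A", [(1, 2), (1, 1)])])
        with pytest.raises(ValueError):
            pg.expected_heterozygosity(gt, unbiased=True)


class TestFis:
    def test_ho_equals_hs_gives_zero(self):
        gt = island_model_genotypes(
            SyntheticGenotypeConfig(n_pops=1, n_per_pop=500, seed=4, target_fst=0.0)
        )
        f = pg.fis(gt)
        assert abs(f.iloc[0]) < 0.05  # HWE by construction

    def test_no_heterozygotes_gives_one(self):
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(1, 1), (1, 1)]),
                ("i2", "N", "A", [(2, 2), (1, 1)]),
            ]
        )
        assert pg.fis(gt).loc[("N", "A")] == pytest.approx(1.0)

    def test_ratio_of_locus_means_scalar_oracle(self):
        gt = make_genotypes(
            [
                ("i1", "N", "A", [(1, 2), (1, 1)]),
                ("i2", "N", "A", [(1, 1), (1, 2)]),
                ("i3", "N", "A", [(2, 2), (2, 2)]),
            ]
        )
        # scalar oracle: mean Ho and mean unbiased Hs per locus
        ho = []
        hs = []
        for loc in ("locus1", "locus2"):
            a1 = gt.data[f"{loc}_a1"].to_numpy()
            a2 = gt.data[f"{loc}_a2"].to_numpy()
            het = np.mean(a1 != a2)
            copies = np.concatenate([a1, a2])
            _, cnt = np.unique(copies, return_counts=True)
            p = cnt / 6
            n = 3
            hs.append(n / (n - 1) * (1 - np.sum(p**2) - het / (2 * n)))
            ho.append(het)
        expected = 1 - np.mean(ho) / np.mean(hs)
        assert pg.fis(gt).loc[("N", "A")] == pytest.approx(expected)


class TestNeiFst:
    def _two_pop_table(self, genos_a, genos_b):
        rows = []
        for i, g in enumerate(genos_a):
            rows.append((f"a{i}", "P1", "A", [g, (1, 1)]))
        for i, g in enumerate(genos_b):
            rows.append((f"b{i}", "P2", "A", [g, (1, 1)]))
        return make_genotypes(rows)

    def test_fixed_different_alleles_gives_one(self):
        gt = self._two_pop_table([(1, 1)] * 50, [(2, 2)] * 50)
        fst = pg.pairwise_nei_fst(gt)
        assert fst.loc["P1", "P2"] == pytest.approx(1.0)

    def test_identical_monomorphic_pair_undefined(self):
        gt = self._two_pop_table([(1, 1)] * 10, [(1, 1)] * 10)
        fst = pg.pairwise_nei_fst(gt)
        assert np.isnan(fst.loc["P1", "P2"])

    def test_identical_frequency_spectra_near_zero(self):
        rng = np.random.default_rng(0)
        draws_a = rng.choice([1, 2, 3], size=(100, 2), p=[0.5, 0.3, 0.2])
        draws_b = rng.choice([1, 2, 3], size=(100, 2), p=[0.5, 0.3, 0.2])
        gt = self._two_pop_table(
            [tuple(x) for x in draws_a], [tuple(x) for x in draws_b]
        )
        fst = pg.pairwise_nei_fst(gt)
        assert abs(fst.loc["P1", "P2"]) < 0.02

    def test_matrix_symmetric_zero_diagonal(self):
        gt = island_model_genotypes(
            SyntheticGenotypeConfig(n_pops=4, n_per_pop=30, seed=9, target_fst=0.1)
        )
        fst = pg.pairwise_nei_fst(gt)
        np.testing.assert_allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0.0)
        assert np.nanmax(fst.values) <= 1.0

    def test_scalar_oracle_on_printed_table(self):
        # hand-evaluated Nei (1987) on a small two-population table
        gt = self._two_pop_table([(1, 1), (1, 2), (2, 2)], [(1, 2), (2, 2), (2, 2)])
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([1, 2, 2, 2, 2, 2])
        n = 3
        ho_a, ho_b = 1 / 3, 1 / 3
        p_a = {al: np.mean(a == al) for al in (1, 2)}
        p_b = {al: np.mean(b == al) for al in (1, 2)}
        sum_p2 = np.mean(
            [sum(v**2 for v in p_a.values()), sum(v**2 for v in p_b.values())]
        )
        ho_bar = (ho_a + ho_b) / 2
        hs = n / (n - 1) * (1 - sum_p2 - ho_bar / (2 * n))
        pbar2 = sum(((p_a[al] + p_b[al]) / 2) ** 2 for al in (1, 2))
        ht = 1 - pbar2 + hs / (2 * n) - ho_bar / (4 * n)
        expected = (ht - hs) / ht
        fst = pg.pairwise_nei_fst(gt)
        assert fst.loc["P1", "P2"] == pytest.approx(expected)


class TestMRatio:
    def test_contiguous_ladder_gives_one(self):
        gt = make_genotypes(
            [("i1", "N", "A", [(10, 11), (1, 1)]), ("i2", "N", "A", [(12, 12), (1, 1)])]
        )
        m = pg.m_ratio(gt)
        assert m.loc[("N", "A"), "M_locus1"] == pytest.approx(1.0)

    def test_gapped_ladder(self):
        gt = make_genotypes(
            [("i1", "N", "A", [(10, 14), (1, 1)]), ("i2", "N", "A", [(10, 10), (1, 1)])]
        )
        m = pg.m_ratio(gt)
        assert m.loc[("N", "A"), "M_locus1"] == pytest.approx(2 / 5)

    def test_monomorphic_convention(self):
        gt = make_genotypes([("i1", "N", "A", [(10, 10), (1, 1)])])
        m = pg.m_ratio(gt)
        assert m.loc[("N", "A"), "M_locus1"] == pytest.approx(1.0)


class TestMantel:
    def _random_dist(self, rng, k):
        m = rng.random((k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(1)
        m = self._random_dist(rng, 6)
        r, p = pg.mantel_test(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_reversal_gives_r_minus_one(self):
        rng = np.random.default_rng(2)
        m = self._random_dist(rng, 6)
        r, _ = pg.mantel_test(m, 10.0 - m, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_p_matches_exhaustive_enumeration(self):
        import itertools as it

        rng = np.random.default_rng(3)
        m1 = self._random_dist(rng, 5)
        m2 = self._random_dist(rng, 5)
        iu = np.triu_indices(5, k=1)
        v1 = m1[iu]
        r_obs = np.corrcoef(v1, m2[iu])[0, 1]
        count = sum(
            np.corrcoef(v1, m2[np.ix_(perm, perm)][iu])[0, 1] >= r_obs
            for perm in it.permutations(range(5))
        )
        exact = count / 120
        r, p = pg.mantel_test(m1, m2, n_perm=4000, seed=7)
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(exact, abs=0.05)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        m1 = self._random_dist(rng, 8)
        m2 = m1 + 0.3 * self._random_dist(rng, 8)
        r, _ = pg.mantel_test(m1, m2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(m1, m2, permutations=0)
        assert r == pytest.approx(float(r_ref))

    def test_zero_variance_raises(self):
        m = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pg.mantel_test(m, m, n_perm=9, seed=0)


class TestSubsample:
    def test_subsample_sizes_and_determinism(self):
        gt = island_model_genotypes(
            SyntheticGenotypeConfig(n_pops=3, n_per_pop=30, seed=5)
        )
        sub1 = pg.subsample(gt, {"pop01": 10, "pop02": 50}, seed=1)
        sizes = sub1.sample_sizes()
        assert sizes[("pop01", "synthetic")] == 10
        assert sizes[("pop02", "synthetic")] == 30  # capped at group size
        sub2 = pg.subsample(gt, {"pop01": 10, "pop02": 50}, seed=1)
        pd.testing.assert_frame_equal(sub1.data, sub2.data)
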