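"""Population statistics vs independent brute-force/textbook oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igklocus.errors import ValidationError
from igklocus.locus import GenomicInterval
from igklocus.popgen import (
    allele_freq_skew,
    bh_adjust,
    density_contrast,
    fisher_exact_2x2,
    fisher_group_test,
    ibs_cluster,
    ibs_dissimilarity,
    pca_genotypes,
    snv_density,
    windowed_density,
)
from igklocus.variants import CohortGenotypes


def _cohort(hap_gt, positions, contig="c"):
    hap_gt = np.asarray(hap_gt, dtype=np.int8)
    n_haps = hap_gt.shape[0]
    assert n_haps % 2 == 0
    sites = pd.DataFrame(
        {"pos": positions, "ref": "A", "alt": "G", "feature": "intergenic"}
    )
    hap_ids = [f"s{i // 2}_h{i % 2 + 1}" for i in range(n_haps)]
    sample_map = {f"s{i}": (f"s{i}_h1", f"s{i}_h2") for i in range(n_haps // 2)}
    return CohortGenotypes(sites, hap_gt, hap_ids, sample_map, contig)


class TestSnvDensity:
    def test_heterozygous_sites_arithmetic(self):
        # 4 het sites in 10 kb -> 4 / 20000
        gt = np.zeros((2, 4), dtype=np.int8)
        gt[0, :] = 1
        cg = _cohort(gt, [100, 200, 300, 400])
        d = snv_density(cg, "s0", GenomicInterval("c", 0, 10_000))
        assert d == pytest.approx(2.0e-4)

    def test_no_variants_is_zero(self):
        cg = _cohort(np.zeros((2, 1), dtype=np.int8), [5])
        assert snv_density(cg, "s0", GenomicInterval("c", 0, 1_000)) == 0.0

    def test_homozygous_alt_dosage(self):
        # 10 hom-alt sites in 10 kb -> 20 / 20000
        gt = np.ones((2, 10), dtype=np.int8)
        cg = _cohort(gt, list(range(0, 1000, 100)))
        d = snv_density(cg, "s0", GenomicInterval("c", 0, 10_000))
        assert d == pytest.approx(1.0e-3)

    def test_zero_length_interval_unrepresentable(self):
        # the interval type itself forbids zero length, so the density
        # denominator can never be zero
        with pytest.raises(ValidationError):
            GenomicInterval("c", 3, 3)

    def test_tiling_sums_to_length_weighted_union(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 2, size=(4, 50)).astype(np.int8)
        pos = sorted(rng.choice(10_000, size=50, replace=False).tolist())
        cg = _cohort(gt, pos)
        whole = GenomicInterval("c", 0, 10_000)
        tiles = [GenomicInterval("c", s, s + 2_000) for s in range(0, 10_000, 2_000)]
        total = snv_density(cg, "s1", whole)
        weighted = sum(
            snv_density(cg, "s1", t) * t.length() for t in tiles
        ) / whole.length()
        assert weighted == pytest.approx(total)


class TestWindowedDensity:
    def test_50kb_region_gives_five_windows(self):
        cg = _cohort(np.zeros((2, 1), dtype=np.int8), [5])
        track = windowed_density(cg, GenomicInterval("c", 0, 50_000), 10_000)
        assert len(track.windows) == 5

    def test_partial_final_window_normalized_by_true_length(self):
        gt = np.ones((2, 1), dtype=np.int8)
        cg = _cohort(gt, [10_500])
        track = windowed_density(cg, GenomicInterval("c", 0, 11_000), 10_000)
        assert track.windows[-1].length() == 1_000
        assert track.values.loc["s0", 1] == pytest.approx(2 / (1_000 * 2))

    def test_uniform_density_estimated_unbiased(self, small_locus):
        # Poisson oracle through the simulator
        from igklocus.pipeline import run_pipeline
        from igklocus.simulate import SimConfig, simulate_cohort

        locus, ref = small_locus
        cfg = SimConfig(seed=29, n_alleles_per_gene=1,
                        snv_density_proximal=2e-3, snv_density_distal=2e-3)
        cfg.feature_density_multipliers = {}
        cfg.conversion_freq = {k: 0.0 for k in cfg.conversion_freq}
        cfg.sv_deletion_freq = {k: 0.0 for k in cfg.sv_deletion_freq}
        cfg.inversion_freq = 0.0
        cohort = simulate_cohort(locus, ref, cfg)
        res = run_pipeline(cohort, annotate=False)
        track = windowed_density(
            res.cohort_genotypes, locus.proximal, 2_000
        )
        grand_mean = track.values.to_numpy().mean()
        # per-haplotype rate 2e-3 -> diploid-normalized expectation 2e-3
        n_obs = track.values.size
        se = math.sqrt(2e-3 / (2_000 * 2) / n_obs) * 2  # loose Poisson SE
        assert grand_mean == pytest.approx(2e-3, abs=4 * se)


class TestDensityContrast:
    def _track(self, values):
        df = pd.DataFrame(values)
        wins = [GenomicInterval("c", i * 10, i * 10 + 10) for i in range(df.shape[1])]
        from igklocus.popgen import DensityTrack

        return DensityTrack(windows=wins, values=df)

    def test_identical_tracks_zero_differences(self):
        v = {0: {"a": 1.0, "b": 2.0}, 1: {"a": 3.0, "b": 1.0}}
        diff, p, degenerate = density_contrast(self._track(v), self._track(v))
        assert (diff == 0).all() and p == 1.0 and degenerate

    def test_twofold_distal_density_detected_at_n36(self, desk_cohort, desk_result):
        from igklocus.pipeline import population_summary

        summary = population_summary(desk_result, desk_cohort)
        assert summary["density_diff"].mean() > 0
        assert summary["density_wilcoxon_p"] < 0.05

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        a = {j: {f"s{i}": rng.random() for i in range(8)} for j in range(4)}
        b = {j: {f"s{i}": rng.random() for i in range(8)} for j in range(4)}
        d1, p1, _ = density_contrast(self._track(a), self._track(b))
        d2, p2, _ = density_contrast(self._track(b), self._track(a))
        assert np.allclose(d1, -d2) and p1 == pytest.approx(p2)

    def test_wilcoxon_matches_sign_flip_enumeration(self):
        # exact-null oracle: enumerate all 2^n sign assignments
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 9
            d = rng.normal(0.5, 1.0, n)
            while len(np.unique(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(0.5, 1.0, n)
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = []
            for signs in itertools.product([0, 1], repeat=n):
                dist.append(sum(r for s, r in zip(signs, ranks) if s))
            dist = np.array(dist)
            cdf = (dist <= w_obs).mean()
            sf = (dist >= w_obs).mean()
            p_oracle = min(1.0, 2 * min(cdf, sf))
            p_scipy = stats.wilcoxon(d, alternative="two-sided").pvalue
            assert p_scipy == pytest.approx(p_oracle, abs=1e-12)


class TestChiSquareSkew:
    @staticmethod
    def _textbook_chi2(table):
        table = np.asarray(table, dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        dof = (table.shape[0] - 1) * (table.shape[1] - 1)
        return chi2, stats.chi2.sf(chi2, dof)

    def test_matches_textbook_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            table = rng.integers(1, 30, size=shape)
            tables = {"G": pd.DataFrame(table)}
            out = allele_freq_skew(tables).iloc[0]
            chi2, p = self._textbook_chi2(table)
            assert abs(out["chi2"] - chi2) < 1e-9
            assert abs(out["p"] - p) < 1e-9

    def test_identical_distributions_not_significant(self):
        table = pd.DataFrame([[10, 10], [10, 10]])
        out = allele_freq_skew({"G": table}).iloc[0]
        assert out["p"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_fixed_private_alleles_closed_form(self):
        # two populations each fixed for a private allele, 20 haplotypes
        # each: chi-square equals N = 40 for the 2x2 of fixed counts
        table = pd.DataFrame([[20, 0], [0, 20]])
        out = allele_freq_skew({"G": table}).iloc[0]
        assert out["chi2"] == pytest.approx(40.0)
        assert out["p"] == pytest.approx(stats.chi2.sf(40.0, 1))

    def test_single_allele_gene_untestable(self):
        tables = {
            "G1": pd.DataFrame({"a": [20, 20]}),
            "G2": pd.DataFrame({"a": [20, 5], "b": [0, 15]}),
        }
        out = allele_freq_skew(tables).set_index("gene")
        assert not out.loc["G1", "testable"]
        assert out.loc["G2", "testable"]
        assert np.isnan(out.loc["G1", "p_adj"])


class TestBenjaminiHochberg:
    def test_worked_step_up_example(self):
        adj = bh_adjust(np.array([0.001, 0.02, 0.8]))
        assert np.allclose(adj, [0.003, 0.03, 0.8])

    def test_matches_step_up_formula_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = rng.random(int(rng.integers(2, 40)))
            n = len(p)
            order = np.argsort(p)
            adj_sorted = p[order] * n / np.arange(1, n + 1)
            adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
            oracle = np.empty(n)
            oracle[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(bh_adjust(p), oracle, atol=1e-12)

    def test_adjustment_preserves_p_ordering(self):
        rng = np.random.default_rng(17)
        p = rng.random(25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFisherExact:
    @staticmethod
    def _enumerate_p(table):
        (a, b), (c, d) = table
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2

        def prob(x):
            return (
                math.comb(r1, x)
                * math.comb(r2, c1 - x)
                / math.comb(n, c1)
            )

        lo, hi = max(0, c1 - r2), min(r1, c1)
        p_obs = prob(a)
        return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))

    def test_reconstructed_deletion_table_significant(self):
        # AFR 8/16 deleted vs non-AFR 46/54 deleted
        _odds, p, _ = fisher_exact_2x2([[8, 8], [46, 8]])
        assert p <= 0.01

    def test_balanced_table_p_one(self):
        _odds, p, _ = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_row_swap_leaves_p_unchanged(self):
        t = [[3, 9], [12, 2]]
        assert fisher_exact_2x2(t)[1] == pytest.approx(
            fisher_exact_2x2(t[::-1])[1]
        )

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            table = rng.integers(0, 31, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _odds, p, _ = fisher_exact_2x2(table)
            assert p == pytest.approx(self._enumerate_p(table.tolist()), abs=1e-9)

    def test_zero_margin_flagged(self):
        _odds, p, degenerate = fisher_exact_2x2([[0, 0], [5, 5]])
        assert p == 1.0 and degenerate

    def test_group_interface_builds_table(self):
        states = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        groups = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        _odds, p, _ = fisher_group_test(states, groups)
        assert p == pytest.approx(1.0)


class TestPca:
    def test_two_backgrounds_separate_on_ev1(self):
        rng = np.random.default_rng(23)
        n_sites = 60
        bg1 = rng.integers(0, 2, n_sites).astype(np.int8)
        bg2 = rng.integers(0, 2, n_sites).astype(np.int8)
        haps = []
        for i in range(20):
            bg = bg1 if i < 10 else bg2
            hap = bg.copy()
            flip = rng.random(n_sites) < 0.05
            hap[flip] = 1 - hap[flip]
            haps.append(hap)
        cg = _cohort(np.array(haps), sorted(rng.choice(5_000, n_sites, replace=False)))
        coords, _evals = pca_genotypes(cg)
        labels = np.array([0] * 5 + [1] * 5)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords[["EV1"]], labels) > 0.5

    def test_duplicated_samples_duplicate_coordinates(self):
        rng = np.random.default_rng(29)
        gt = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        cg1 = _cohort(gt, sorted(rng.choice(2_000, 30, replace=False)))
        dup = np.vstack([gt, gt])
        pos = cg1.sites["pos"].tolist()
        cg2 = _cohort(dup, pos)
        c1, _ = pca_genotypes(cg1)
        c2, _ = pca_genotypes(cg2)
        half = len(c2) // 2
        assert np.allclose(
            c2.iloc[:half].to_numpy(), c2.iloc[half:].to_numpy(), atol=1e-9
        )

    def test_monomorphic_only_rejected(self):
        cg = _cohort(np.ones((4, 3), dtype=np.int8), [1, 2, 3])
        with pytest.raises(ValidationError):
            pca_genotypes(cg)

    def test_conversion_genotype_groups_separate(self, desk_cohort, desk_result):
        locus = desk_cohort.locus
        filtered = desk_result.filtered_genotypes
        win = locus.conversion_window
        region = filtered.restrict(win)
        if region.n_sites < 2:
            pytest.skip("too few window sites after filtering")
        coords, _ = pca_genotypes(region)
        conv_dosage = {}
        for h in desk_cohort.haplotypes:
            s = h.truth.sample
            conv_dosage[s] = conv_dosage.get(s, 0) + (
                h.truth.conversion_state == "converted"
            )
        groups = pd.Series(conv_dosage).loc[coords.index]
        centers = coords.groupby(groups)["EV1"].mean()
        spread = coords.groupby(groups)["EV1"].std().max()
        assert centers.max() - centers.min() > spread


class TestIbs:
    def test_identical_samples_zero_dissimilarity(self):
        gt = np.tile(np.array([[1], [0]], dtype=np.int8), (2, 5))
        cg = _cohort(gt, list(range(5)))
        dis, flagged = ibs_dissimilarity(cg)
        assert dis.loc["s0", "s1"] == pytest.approx(0.0)
        assert not flagged

    def test_opposite_homozygotes_full_dissimilarity(self):
        gt = np.array([[1] * 5, [1] * 5, [0] * 5, [0] * 5], dtype=np.int8)
        cg = _cohort(gt, list(range(5)))
        dis, _ = ibs_dissimilarity(cg)
        assert dis.loc["s0", "s1"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        gt = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
        cg = _cohort(gt, sorted(rng.choice(900, 40, replace=False)))
        dis, _ = ibs_dissimilarity(cg)
        D = cg.dosage().to_numpy()
        for i, si in enumerate(cg.samples):
            for j, sj in enumerate(cg.samples):
                if i >= j:
                    continue
                per_site = [
                    1 - (2 - abs(a - b)) / 2 for a, b in zip(D[i], D[j])
                ]
                assert dis.loc[si, sj] == pytest.approx(np.mean(per_site))

    def test_three_planted_backgrounds_recovered(self):
        rng = np.random.default_rng(37)
        n_sites = 80
        backgrounds = [rng.integers(0, 2, n_sites) for _ in range(3)]
        haps, truth = [], []
        for i in range(30):
            bg = backgrounds[i // 10]
            for _h in range(2):
                hap = bg.copy()
                flip = rng.random(n_sites) < 0.03
                hap[flip] = 1 - hap[flip]
                haps.append(hap.astype(np.int8))
            truth.append(i // 10)
        cg = _cohort(np.array(haps), sorted(rng.choice(9_000, n_sites, replace=False)))
        _dis, _Z, labels = ibs_cluster(cg, k=3)
        from sklearn.metrics import adjusted_rand_score

        truth_by_sample = pd.Series(truth, index=cg.samples).loc[labels.index]
        assert adjusted_rand_score(truth_by_sample, labels) > 0.9
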