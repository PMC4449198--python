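import numpy as np
import pandas as pd
import pytest

from aviqtl.genoprob import calc_genoprob
from aviqtl.scan import (
    forward_select,
    lod_support_interval,
    pca_covariates,
    permutation_maxima,
    permutation_threshold,
    scanone,
    scantwo,
    select_egg_covariate,
)
from aviqtl.simulate import QtlEffect, SimConfig, make_map, nearest_locus, simulate_ail, simulate_traits

from conftest import make_cross, tiny_map


def _eight_individual_fixture():
    """Worked fixture: 8 individuals, 3 markers, fixed trait values."""
    gmap = tiny_map([("m1", 1, 0.0), ("m2", 1, 10.0), ("m3", 1, 25.0)])
    geno = np.array(
        [
            [0, 0, 1],
            [1, 1, 1],
            [2, 2, 2],
            [0, 1, 1],
            [2, 1, 0],
            [1, 0, 0],
            [2, 2, 1],
            [0, 0, 0],
        ],
        dtype=float,
    )
    trait = [1.2, 2.1, 3.3, 1.0, 2.2, 1.9, 3.1, 0.8]
    weight = [1.0, 2.0, 1.5, 1.1, 2.2, 0.9, 1.8, 1.3]
    return make_cross(
        gmap, geno, phenotypes={"t": trait}, covariates={"body_weight": weight}
    )


def _oracle_lod(y, C, x, z):
    """Independent LOD: two explicit least-squares fits."""
    n = len(y)
    b0, *_ = np.linalg.lstsq(C, y, rcond=None)
    rss0 = np.sum((y - C @ b0) ** 2)
    D = np.column_stack([C, x, z])
    b1, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss1 = np.sum((y - D @ b1) ** 2)
    return (n / 2) * np.log10(rss0 / rss1)


class TestScanone:
    def test_matches_hand_computed_rss_ratio(self):
        cross = _eight_individual_fixture()
        probs = calc_genoprob(cross, step_cM=5.0)
        res = scanone(probs, cross, "t", ["body_weight"])
        y = cross.phenotypes["t"].to_numpy()
        C = np.column_stack([np.ones(8), cross.covariates["body_weight"].to_numpy()])
        for j in range(probs.n_positions):
            expected = _oracle_lod(y, C, probs.x[:, j], probs.z[:, j])
            assert res.lod[j] == pytest.approx(expected, abs=1e-10)

    def test_lod_nonnegative(self, demo_dataset):
        cross, _, _ = demo_dataset
        probs = calc_genoprob(cross, step_cM=2.0)
        res = scanone(probs, cross, "bone_density", ["sex", "batch", "body_weight"])
        assert (res.lod >= -1e-12).all()

    def test_perfect_fit_capped_and_flagged(self):
        gmap = tiny_map([("m1", 1, 0.0), ("m2", 1, 50.0)])
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(40, 2)).astype(float)
        x = geno[:, 0] - 1
        cross = make_cross(gmap, geno, phenotypes={"t": x})
        probs = calc_genoprob(cross, step_cM=0.0)
        res = scanone(probs, cross, "t")
        assert np.isfinite(res.lod).all()
        assert res.perfect[0]
        assert res.lod[0] <= (40 / 2) * 16 + 1e-9

    def test_listwise_deletion_counts(self):
        cross = _eight_individual_fixture()
        cross.phenotypes.loc["i3", "t"] = np.nan
        cross.covariates.loc["i5", "body_weight"] = np.nan
        probs = calc_genoprob(cross, step_cM=0.0)
        res = scanone(probs, cross, "t", ["body_weight"])
        assert res.n_used == 6

    def test_rank_deficient_covariates_named(self):
        cross = _eight_individual_fixture()
        cross.covariates["dup"] = cross.covariates["body_weight"] * 2.0
        probs = calc_genoprob(cross, step_cM=0.0)
        with pytest.raises(ValueError, match="dup"):
            scanone(probs, cross, "t", ["body_weight", "dup"])

    def test_constant_trait_rejected(self):
        cross = _eight_individual_fixture()
        cross.phenotypes["flat"] = 1.0
        probs = calc_genoprob(cross, step_cM=0.0)
        with pytest.raises(ValueError, match="constant"):
            scanone(probs, cross, "flat")

    def test_adding_covariate_never_increases_fit_rss(self):
        # nested-model invariant checked through the oracle identity
        cross = _eight_individual_fixture()
        probs = calc_genoprob(cross, step_cM=0.0)
        y = cross.phenotypes["t"].to_numpy()
        C0 = np.ones((8, 1))
        C1 = np.column_stack([C0, cross.covariates["body_weight"].to_numpy()])
        for j in range(probs.n_positions):
            D0 = np.column_stack([C0, probs.x[:, j], probs.z[:, j]])
            D1 = np.column_stack([C1, probs.x[:, j], probs.z[:, j]])
            r0 = np.sum((y - D0 @ np.linalg.lstsq(D0, y, rcond=None)[0]) ** 2)
            r1 = np.sum((y - D1 @ np.linalg.lstsq(D1, y, rcond=None)[0]) ** 2)
            assert r1 <= r0 + 1e-9


@pytest.fixture(scope="module")
def pair_scan():
    gmap = make_map(SimConfig(n_markers=12, n_chromosomes=2))
    pos1 = nearest_locus(gmap, "1", 30.0)
    pos2 = nearest_locus(gmap, "2", 60.0)
    cfg = SimConfig(
        n_markers=12, n_chromosomes=2, n_individuals_final=250,
        generations=4, pop_per_generation=80, seed=5,
        qtl_spec=[
            QtlEffect("1", pos1, 0.7, 0.0, "t"),
            QtlEffect("2", pos2, 0.6, 0.0, "t"),
        ],
        geno_missing_rate=0.0, pheno_missing_rate=0.0,
    )
    cross, truth, _ = simulate_ail(cfg)
    cross = simulate_traits(cross, cfg, truth)
    probs = calc_genoprob(cross, step_cM=0.0)
    return cross, probs, scantwo(probs, cross, "t", ["sex"]), (pos1, pos2)


class TestScantwo:

    def test_same_locus_pairs_excluded(self, pair_scan):
        _, probs, res, _ = pair_scan
        same = (res.table["chrom1"] == res.table["chrom2"]) & (
            res.table["pos1"] == res.table["pos2"]
        )
        assert not same.any()
        n = probs.n_positions
        assert len(res.table) == n * (n - 1) // 2

    def test_interaction_lod_is_difference(self, pair_scan):
        _, _, res, _ = pair_scan
        np.testing.assert_allclose(
            res.table["lod_int"], res.table["lod_full"] - res.table["lod_add"], atol=1e-9
        )
        assert (res.table["lod_int"] <= res.table["lod_full"] + 1e-9).all()

    def test_additive_lod_dominates_single_scans(self, pair_scan):
        cross, probs, res, _ = pair_scan
        one = scanone(probs, cross, "t", ["sex"])
        lod1 = {(r["chrom"], r["pos_cM"]): r["lod"] for _, r in one.table.iterrows()}
        for _, row in res.table.sample(50, random_state=0).iterrows():
            m = max(lod1[(row["chrom1"], row["pos1"])], lod1[(row["chrom2"], row["pos2"])])
            assert row["lod_add"] >= m - 1e-6

    def test_pure_interaction_recovered(self):
        # effect only through the product term x1*x2
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            gmap = make_map(SimConfig(n_markers=12, n_chromosomes=2))
            pos1 = nearest_locus(gmap, "1", 40.0)
            pos2 = nearest_locus(gmap, "2", 40.0)
            from aviqtl.simulate import EpistasisEffect

            cfg = SimConfig(
                n_markers=12, n_chromosomes=2, n_individuals_final=300,
                generations=3, pop_per_generation=80, seed=seed,
                epistasis_spec=[EpistasisEffect("1", pos1, "2", pos2, 1.2, "t")],
                trait_noise_sd={"t": 0.7},
                geno_missing_rate=0.0, pheno_missing_rate=0.0,
            )
            cross, truth, _ = simulate_ail(cfg)
            cross = simulate_traits(cross, cfg, truth)
            probs = calc_genoprob(cross, step_cM=0.0)
            res = scantwo(probs, cross, "t")
            _, best = res.max_int()
            d1 = abs(best["pos1"] - pos1) if best["chrom1"] == "1" else np.inf
            d2 = abs(best["pos2"] - pos2) if best["chrom2"] == "2" else np.inf
            if d1 <= 15 and d2 <= 15:
                hits += 1
        assert hits >= int(0.8 * n_seeds) - 1


class TestPermutationThreshold:
    def test_alpha_zero_is_max(self, demo_dataset):
        cross, _, _ = demo_dataset
        probs = calc_genoprob(cross, step_cM=5.0)
        maxima = permutation_maxima(probs, cross, "bone_density", ["sex"], n_perm=100, seed=1)
        thr = permutation_threshold(
            probs, cross, "bone_density", ["sex"], n_perm=100, alpha=0.0, seed=1
        )
        assert thr == pytest.approx(maxima.max())

    def test_seed_stability(self, demo_dataset):
        cross, _, _ = demo_dataset
        probs = calc_genoprob(cross, step_cM=5.0)
        t1 = permutation_threshold(probs, cross, "bone_density", ["sex"], n_perm=1000, seed=1)
        t2 = permutation_threshold(probs, cross, "bone_density", ["sex"], n_perm=1000, seed=2)
        assert abs(t1 - t2) / t1 < 0.10

    def test_minimum_permutations_enforced(self, demo_dataset):
        cross, _, _ = demo_dataset
        probs = calc_genoprob(cross, step_cM=5.0)
        with pytest.raises(ValueError):
            permutation_threshold(probs, cross, "bone_density", n_perm=50)


class TestPcaCovariates:
    def test_k_zero_no_columns(self, demo_dataset):
        cross, _, _ = demo_dataset
        assert pca_covariates(cross, 0).shape[1] == 0

    def test_scores_orthogonal(self, demo_dataset):
        cross, _, _ = demo_dataset
        pcs = pca_covariates(cross, 4)
        corr = np.corrcoef(pcs.to_numpy().T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_k_too_large_rejected(self, demo_dataset):
        cross, _, _ = demo_dataset
        with pytest.raises(ValueError):
            pca_covariates(cross, cross.n_individuals)

    def test_two_subpopulations_separated_by_pc1(self):
        rng = np.random.default_rng(7)
        gmap = tiny_map([(f"m{j}", 1, float(j * 5)) for j in range(40)])
        # two families with different allele frequencies
        n_half = 60
        pa = rng.beta(0.5, 0.5, size=40)
        pb = np.clip(pa + rng.choice([-0.5, 0.5], size=40), 0.05, 0.95)
        ga = rng.binomial(2, pa, size=(n_half, 40)).astype(float)
        gb = rng.binomial(2, pb, size=(n_half, 40)).astype(float)
        cross = make_cross(gmap, np.vstack([ga, gb]))
        pcs = pca_covariates(cross, 1)
        group = np.repeat([0.0, 1.0], n_half)
        r = np.corrcoef(pcs["PC1"], group)[0, 1]
        assert abs(r) > 0.9


class TestEggCovariate:
    def _female_cross(self, slope, seed=0, n=120):
        rng = np.random.default_rng(seed)
        gmap = tiny_map([("m1", 1, 0.0), ("m2", 1, 20.0)])
        eggs = np.clip(rng.normal(10, 3, n), 0, None)
        weight = rng.normal(1800, 100, n)
        trait = slope * eggs + 0.001 * weight + rng.normal(0, 1, n)
        return make_cross(
            gmap,
            rng.integers(0, 3, size=(n, 2)).astype(float),
            phenotypes={"bone": trait},
            covariates={"sex": ["F"] * n, "eggs": eggs, "body_weight": weight},
        )

    def test_strong_association_included(self):
        decision = select_egg_covariate(self._female_cross(2.0), "bone")
        assert decision.include and decision.covariates == ["eggs"]

    def test_males_rejected(self):
        cross = self._female_cross(0.0)
        cross.covariates.loc[cross.individuals[0], "sex"] = "M"
        with pytest.raises(ValueError, match="female"):
            select_egg_covariate(cross, "bone")

    def test_all_missing_eggs_skipped_with_notice(self):
        cross = self._female_cross(0.0)
        cross.covariates["eggs"] = np.nan
        decision = select_egg_covariate(cross, "bone")
        assert not decision.include and decision.covariates == []

    def test_null_inclusion_rate_near_alpha(self):
        included = sum(
            select_egg_covariate(self._female_cross(0.0, seed=s), "bone").include
            for s in range(100)
        )
        assert included <= 13  # ~5% expected under the null


class TestForwardSelect:
    def test_null_trait_empty_model(self):
        rng = np.random.default_rng(12)
        cfg = SimConfig(
            n_markers=30, n_chromosomes=3, n_individuals_final=200,
            generations=3, pop_per_generation=60, seed=3,
            geno_missing_rate=0.0, pheno_missing_rate=0.0,
        )
        cross, truth, _ = simulate_ail(cfg)
        cross = simulate_traits(cross, cfg, truth)  # trait1 is pure noise + covariates
        probs = calc_genoprob(cross, step_cM=5.0)
        thr = permutation_threshold(probs, cross, "trait1", ["sex"], n_perm=250, seed=1)
        model = forward_select(probs, cross, "trait1", ["sex"], threshold=thr)
        assert model.loci == [] and model.lod == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_loci(self):
        gmap = make_map(SimConfig(n_markers=45, n_chromosomes=3))
        targets = [
            ("1", nearest_locus(gmap, "1", 30.0), 0.7),
            ("2", nearest_locus(gmap, "2", 70.0), 0.6),
            ("3", nearest_locus(gmap, "3", 50.0), 0.6),
        ]
        cfg = SimConfig(
            n_markers=45, n_chromosomes=3, n_individuals_final=450,
            generations=6, pop_per_generation=100, seed=17,
            qtl_spec=[QtlEffect(c, p, a, 0.0, "t") for c, p, a in targets],
            geno_missing_rate=0.0, pheno_missing_rate=0.0,
        )
        cross, truth, _ = simulate_ail(cfg)
        cross = simulate_traits(cross, cfg, truth)
        probs = calc_genoprob(cross, step_cM=2.5)
        model = forward_select(probs, cross, "t", ["sex"], threshold=3.5)
        recovered = 0
        for chrom, pos, _ in targets:
            if any(q["chrom"] == chrom and abs(q["pos_cM"] - pos) <= 20 for q in model.loci):
                recovered += 1
        assert recovered >= 2

    def test_refit_reproduces_stored_lod(self, demo_dataset):
        cross, _, _ = demo_dataset
        probs = calc_genoprob(cross, step_cM=5.0)
        model = forward_select(probs, cross, "bone_density", ["sex"], threshold=3.0)
        if model.loci:
            assert model.refit(probs, cross, ["sex"]) == pytest.approx(model.lod, abs=1e-6)

    def test_detects_planted_epistasis(self):
        from aviqtl.simulate import EpistasisEffect

        gmap = make_map(SimConfig(n_markers=20, n_chromosomes=2))
        p1 = nearest_locus(gmap, "1", 50.0)
        p2 = nearest_locus(gmap, "2", 50.0)
        cfg = SimConfig(
            n_markers=20, n_chromosomes=2, n_individuals_final=400,
            generations=4, pop_per_generation=100, seed=23,
            qtl_spec=[
                QtlEffect("1", p1, 0.8, 0.0, "t"),
                QtlEffect("2", p2, 0.7, 0.0, "t"),
            ],
            epistasis_spec=[EpistasisEffect("1", p1, "2", p2, 0.9, "t")],
            geno_missing_rate=0.0, pheno_missing_rate=0.0,
        )
        cross, truth, _ = simulate_ail(cfg)
        cross = simulate_traits(cross, cfg, truth)
        probs = calc_genoprob(cross, step_cM=0.0)
        model = forward_select(
            probs, cross, "t", ["sex"], threshold=3.5, pair_threshold=2.0
        )
        assert len(model.loci) >= 2
        assert len(model.pairs) >= 1
        assert model.pve > 0


class TestSupportInterval:
    def _scan_from_curve(self, positions, lods, markers=None):
        gmap = tiny_map(markers or [(f"m{j}", 1, p) for j, p in enumerate(positions)])
        table = pd.DataFrame(
            {
                "chrom": "1",
                "pos_cM": positions,
                "name": [f"p{j}" for j in range(len(positions))],
                "is_marker": True,
                "lod": lods,
            }
        )
        from aviqtl.scan import ScanResult

        return ScanResult("t", table, [], 100), gmap

    def test_drop_exactly_at_markers(self):
        pos = [0, 10, 20, 30, 40, 50, 60]
        lod = [0.5, 1.0, 3.2, 5.0, 3.2, 1.0, 0.5]
        scan, gmap = self._scan_from_curve(pos, lod)
        si = lod_support_interval(scan, gmap, drop=1.8)
        assert (si.interval.start, si.interval.end) == (20, 40)
        assert si.interval.start <= si.peak_pos <= si.interval.end

    def test_flat_curve_whole_chromosome_flagged(self):
        pos = [0, 10, 20, 30]
        scan, gmap = self._scan_from_curve(pos, [2.0] * 4)
        si = lod_support_interval(scan, gmap, peak=("1", 10.0))
        assert si.degenerate
        assert (si.interval.start, si.interval.end) == (0, 30)

    def test_boundary_peak_truncated(self):
        pos = [0, 10, 20, 30]
        scan, gmap = self._scan_from_curve(pos, [5.0, 2.0, 1.0, 0.5])
        si = lod_support_interval(scan, gmap)
        assert si.truncated_left and not si.truncated_right
        assert si.interval.start == 0

    def test_expansion_to_flanking_markers(self):
        # pseudomarker endpoints move outward to real markers
        gmap = tiny_map([("m1", 1, 0.0), ("m2", 1, 30.0), ("m3", 1, 60.0)])
        positions = [0, 10, 20, 30, 40, 50, 60]
        lod = [0.1, 0.2, 3.0, 4.0, 3.0, 0.2, 0.1]
        table = pd.DataFrame(
            {
                "chrom": "1",
                "pos_cM": positions,
                "name": "x",
                "is_marker": [True, False, False, True, False, False, True],
                "lod": lod,
            }
        )
        from aviqtl.scan import ScanResult

        si = lod_support_interval(ScanResult("t", table, [], 100), gmap, drop=1.8)
        assert (si.interval.start, si.interval.end) == (0.0, 60.0)
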