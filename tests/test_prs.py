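"""PRS oracles: pruning vs exhaustive oracle, scoring vs a double loop,
threshold nesting, mixing-weight recovery, stratified folds, odds-ratio
arithmetic, and pooled-R^2 hand calculations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaprs import prs
from metaprs.containers import GenotypeMatrix
from metaprs.ld import pairwise_r2


def _geno(dosages, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        dosages, variants, pd.Index([f"s{i}" for i in range(n)])
    )


def _sumstats(ids, betas, ps, eaf=0.4):
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": np.arange(len(ids)) * 1000 + 1000,
            "effect_allele": "G",
            "other_allele": "A",
            "eaf": eaf,
            "beta": betas,
            "se": 0.05,
            "p": ps,
            "n": 1000,
            "stratum": "REF",
        }
    )


class TestLdPrune:
    def test_duplicate_variant_one_retained(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.5, 300).astype(float)
        geno = _geno(np.column_stack([col, col]))
        ss = _sumstats(["v0", "v1"], [0.1, 0.1], [0.01, 0.001])
        kept, audit = prs.ld_prune(ss, geno)
        assert kept == ["v1"]  # smaller p wins
        assert audit["n_out"] == 1

    def test_independent_set_all_retained(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, rng.uniform(0.3, 0.7, 8), (500, 8)).astype(float)
        ss = _sumstats([f"v{j}" for j in range(8)], 0.1, rng.random(8))
        kept, _ = prs.ld_prune(ss, _geno(g))
        assert sorted(kept) == sorted(ss["variant_id"])

    def test_matches_exhaustive_oracle_on_block_fixture(self):
        rng = np.random.default_rng(2)
        n = 500
        base = rng.binomial(1, 0.5, (n, 2, 3)).astype(float)
        cols = []
        for j in range(12):
            blk, k = divmod(j, 4)
            hap = base[:, :, blk].copy()
            flip = rng.random((n, 2)) < 0.05 * (k + 1)
            hap = np.where(flip, rng.binomial(1, 0.5, (n, 2)), hap)
            cols.append(hap.sum(axis=1))
        geno = _geno(np.column_stack(cols))
        ss = _sumstats([f"v{j}" for j in range(12)], 0.1, rng.random(12))
        kept, _ = prs.ld_prune(ss, geno, r2_cutoff=0.5)
        # oracle: explicit loop respecting the same priority and rule
        order = ss.sort_values(["p", "pos", "variant_id"], kind="mergesort")
        r2 = pairwise_r2(geno, list(order["variant_id"]))
        oracle = []
        for i in range(len(order)):
            if all(r2[i, j] < 0.5 for j in oracle):
                oracle.append(i)
        want = list(order["variant_id"].iloc[oracle])
        assert sorted(kept) == sorted(want)

    def test_absent_from_panel_retained(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, (200, 2)).astype(float)
        ss = _sumstats(["v0", "v1", "zzz"], 0.1, [0.1, 0.2, 0.3])
        kept, audit = prs.ld_prune(ss, _geno(g))
        assert "zzz" in kept
        assert audit["n_no_panel"] == 1


class TestDerivePrsWeights:
    def test_null_sumstats_tight_threshold_empty(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.5, (100, 50)).astype(float)
        ss = _sumstats([f"v{j}" for j in range(50)], 0.0,
                       rng.uniform(0.01, 1, 50))
        model = prs.derive_prs_weights(ss, 1e-8, _geno(g))
        assert model.n_variants == 0

    def test_loose_threshold_independent_variants_keeps_all(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, rng.uniform(0.3, 0.7, 20), (500, 20)).astype(float)
        ss = _sumstats([f"v{j}" for j in range(20)], 0.1,
                       rng.uniform(0, 0.99, 20))
        model = prs.derive_prs_weights(ss, 1.0, _geno(g))
        assert model.n_variants == 20

    def test_model_size_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, rng.uniform(0.3, 0.7, 100), (400, 100)).astype(float)
        ss = _sumstats([f"v{j}" for j in range(100)], 0.1,
                       10 ** rng.uniform(-9, 0, 100))
        sizes = [
            prs.derive_prs_weights(ss, thr, _geno(g)).n_variants
            for thr in prs.PRS_THRESHOLDS
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_retained_pairs_below_r2_cutoff(self):
        rng = np.random.default_rng(7)
        col = rng.binomial(2, 0.5, 400).astype(float)
        g = np.column_stack([col, col, rng.binomial(2, 0.5, 400)])
        geno = _geno(g.astype(float))
        ss = _sumstats(["v0", "v1", "v2"], 0.1, [0.001, 0.002, 0.003])
        model = prs.derive_prs_weights(ss, 0.5, geno)
        r2 = pairwise_r2(geno, list(model.weights["variant_id"]))
        off = r2[~np.eye(len(r2), dtype=bool)]
        assert np.all(off < 0.5)


class TestScore:
    def test_zero_dosages_zero_score(self):
        geno = _geno(np.zeros((3, 2)))
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": ["v0", "v1"], "effect_allele": "G",
                          "weight": [0.3, -0.2], "source_p": 0.01,
                          "eaf": [0.4, 0.4]}),
        )
        assert np.allclose(prs.score(model, geno), 0.0)

    def test_single_variant_arithmetic(self):
        geno = _geno(np.array([[2.0]]))
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["G"],
                          "weight": [0.3], "source_p": [0.01], "eaf": [0.4]}),
        )
        assert prs.score(model, geno).iloc[0] == pytest.approx(0.6)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        dos = rng.uniform(0, 2, (5, 8))
        geno = _geno(dos)
        w = rng.normal(0, 0.3, 8)
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": [f"v{j}" for j in range(8)],
                          "effect_allele": "G", "weight": w,
                          "source_p": 0.01, "eaf": 0.4}),
        )
        got = prs.score(model, geno)
        for i in range(5):
            want = sum(dos[i, j] * w[j] for j in range(8))
            assert got.iloc[i] == pytest.approx(want, rel=1e-12)

    def test_swapped_effect_allele_reflects_dosage(self):
        geno = _geno(np.array([[2.0], [0.0]]))
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["A"],
                          "weight": [0.5], "source_p": [0.01], "eaf": [0.4]}),
        )
        got = prs.score(model, geno)
        assert got.iloc[0] == pytest.approx(0.0)
        assert got.iloc[1] == pytest.approx(1.0)

    def test_missing_dosage_mean_imputed(self):
        dos = np.array([[np.nan], [1.0]])
        geno = _geno(dos)
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["G"],
                          "weight": [1.0], "source_p": [0.01], "eaf": [0.3]}),
        )
        got = prs.score(model, geno)
        assert got.iloc[0] == pytest.approx(0.6)  # 2 * eaf

    def test_unmappable_fraction_errors(self):
        geno = _geno(np.zeros((2, 1)))
        model = prs.PrsModel(
            "t", "s", 0.1,
            pd.DataFrame({"variant_id": ["v0", "x1", "x2"],
                          "effect_allele": "G", "weight": 0.1,
                          "source_p": 0.01, "eaf": 0.4}),
        )
        with pytest.raises(ValueError, match="unmappable"):
            prs.score(model, geno)

    def test_linearity_in_dosage_perturbation(self):
        rng = np.random.default_rng(9)
        dos = rng.uniform(0, 1, (4, 6))
        delta = rng.uniform(0, 1, (4, 6))
        w = rng.normal(0, 0.5, 6)
        weights = pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(6)], "effect_allele": "G",
             "weight": w, "source_p": 0.01, "eaf": 0.4}
        )
        model = prs.PrsModel("t", "s", 0.1, weights)
        s1 = prs.score(model, _geno(dos))
        s2 = prs.score(model, _geno(delta))
        s12 = prs.score(model, _geno(dos + delta))
        assert np.allclose(s12, s1 + s2)


class TestMultiethnicCombine:
    def test_exact_fit(self):
        rng = np.random.default_rng(10)
        idx = pd.Index([f"s{i}" for i in range(50)])
        s1 = pd.Series(rng.normal(size=50), index=idx)
        s2 = pd.Series(rng.normal(size=50), index=idx)
        fit = prs.multiethnic_combine(s1, s2, s1.copy())
        assert fit["alpha1"] == pytest.approx(1.0, abs=1e-10)
        assert fit["alpha2"] == pytest.approx(0.0, abs=1e-10)
        assert fit["r2_incremental"] == pytest.approx(1.0, abs=1e-10)

    def test_noise_second_score_near_zero_alpha2(self):
        rng = np.random.default_rng(11)
        n = 3000
        idx = pd.Index([f"s{i}" for i in range(n)])
        s1 = pd.Series(rng.normal(size=n), index=idx)
        s2 = pd.Series(rng.normal(size=n), index=idx)
        y = 0.5 * s1 + pd.Series(rng.normal(size=n), index=idx)
        fit = prs.multiethnic_combine(s1, s2, y)
        single = prs.multiethnic_combine(
            s1, pd.Series(0.0, index=idx), y
        )
        assert abs(fit["alpha2"]) < 0.05
        assert abs(fit["adjusted_r2"] - single["adjusted_r2"]) < 0.01

    def test_planted_mixing_weights_recovered(self):
        rng = np.random.default_rng(12)
        n = 3000
        idx = pd.Index([f"s{i}" for i in range(n)])
        s1 = pd.Series(rng.normal(size=n), index=idx)
        s2 = pd.Series(rng.normal(size=n), index=idx)
        y = 0.6 * s1 + 0.8 * s2 + pd.Series(rng.normal(size=n), index=idx)
        fit = prs.multiethnic_combine(s1, s2, y)
        assert fit["alpha1"] == pytest.approx(0.6, abs=0.1)
        assert fit["alpha2"] == pytest.approx(0.8, abs=0.1)

    def test_collinear_scores_fall_back(self):
        rng = np.random.default_rng(13)
        idx = pd.Index([f"s{i}" for i in range(100)])
        s1 = pd.Series(rng.normal(size=100), index=idx)
        fit = prs.multiethnic_combine(s1, s1 * 2.0, s1 + 0.1)
        assert fit["collinear_fallback"]
        assert np.isnan(fit["alpha2"])

    def test_incremental_r2_nonnegative_in_sample(self):
        rng = np.random.default_rng(14)
        n = 200
        idx = pd.Index([f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"c": rng.normal(size=n)}, index=idx)
        s1 = pd.Series(rng.normal(size=n), index=idx)
        s2 = pd.Series(rng.normal(size=n), index=idx)
        y = pd.Series(rng.normal(size=n), index=idx)
        fit = prs.multiethnic_combine(s1, s2, y, covariates=cov)
        assert fit["r2_incremental"] >= 0.0


class TestStratifiedFolds:
    def test_case_ratio_preserved(self):
        rng = np.random.default_rng(15)
        labels = pd.Series(
            (rng.random(500) < 0.2).astype(int),
            index=[f"s{i}" for i in range(500)],
        )
        folds = prs.stratified_folds(labels, 10, seed=1, stratify=True)
        per_fold_cases = labels.groupby(folds).sum()
        assert per_fold_cases.max() - per_fold_cases.min() <= 1
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 2

    def test_deterministic_under_seed(self):
        labels = pd.Series([0, 1] * 50, index=[f"s{i}" for i in range(100)])
        a = prs.stratified_folds(labels, 5, seed=3, stratify=True)
        b = prs.stratified_folds(labels, 5, seed=3, stratify=True)
        pd.testing.assert_series_equal(a, b)


class TestRiskStratification:
    def test_hand_computed_odds_ratio(self):
        # top 50 of 1000; 10 cases in top, 100 cases overall
        n = 1000
        scores = pd.Series(
            np.arange(n, dtype=float)[::-1], index=[f"s{i}" for i in range(n)]
        )
        disease = pd.Series(0, index=scores.index)
        disease.iloc[:10] = 1          # 10 cases inside the top 50
        disease.iloc[200:290] = 1      # 90 cases outside
        res = prs.risk_stratification(scores, disease, top_fractions=(0.05,))
        row = res.iloc[0]
        assert row["cases_top"] == 10 and row["controls_top"] == 40
        assert row["odds_ratio"] == pytest.approx((10 * 860) / (40 * 90))
        assert row["ci_lo"] < row["odds_ratio"] < row["ci_hi"]

    def test_zero_cell_corrected(self):
        scores = pd.Series(
            np.arange(100, dtype=float), index=[f"s{i}" for i in range(100)]
        )
        disease = pd.Series(0, index=scores.index)
        disease.iloc[95:] = 1  # all cases in the top 5%
        res = prs.risk_stratification(scores, disease, top_fractions=(0.05,))
        row = res.iloc[0]
        assert row["corrected"]
        assert np.isfinite(row["odds_ratio"])

    def test_no_cases_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            prs.risk_stratification(scores, pd.Series([0, 0], index=["a", "b"]))

    def test_or_increases_with_heritability(self):
        """Liability-threshold simulation: top-5% OR rises with h^2."""
        rng = np.random.default_rng(16)
        n = 4000
        idx = pd.Index([f"s{i}" for i in range(n)])
        mean_or = []
        for h2 in (0.0, 0.2, 0.5, 0.8):
            ors = []
            for _ in range(5):
                g = rng.normal(size=n)
                liab = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.normal(size=n)
                d = (liab > np.quantile(liab, 1 - 0.17)).astype(int)
                res = prs.risk_stratification(
                    pd.Series(g, index=idx), pd.Series(d, index=idx),
                    top_fractions=(0.05,),
                )
                ors.append(res["odds_ratio"].iloc[0])
            mean_or.append(np.mean(ors))
        rho, _ = stats.spearmanr([0.0, 0.2, 0.5, 0.8], mean_or)
        assert rho > 0
        assert mean_or[0] == pytest.approx(1.0, abs=0.35)

    def test_fdr_column_spans_scores_and_fractions(self):
        rng = np.random.default_rng(17)
        n = 500
        idx = pd.Index([f"s{i}" for i in range(n)])
        scores = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)}, index=idx
        )
        disease = pd.Series((rng.random(n) < 0.2).astype(int), index=idx)
        res = prs.risk_stratification(scores, disease)
        assert len(res) == 2 * len(prs.TOP_FRACTIONS)
        ok = res["fdr_adjusted_p"].notna()
        assert (res.loc[ok, "fdr_adjusted_p"] >= res.loc[ok, "p"] - 1e-12).all()


class TestMetaPrsR2:
    def test_identical_strata(self):
        marg = pd.DataFrame({"beta": [0.2, 0.2], "se": [0.05, 0.05]})
        out = prs.meta_prs_r2(marg)
        assert out["pooled_beta"] == pytest.approx(0.2)
        assert out["r2"] == pytest.approx(0.04)

    def test_two_stratum_hand_calculation(self):
        # w = (400, 100): pooled = (400*0.3 + 100*0.1)/500 = 0.26
        marg = pd.DataFrame({"beta": [0.3, 0.1], "se": [0.05, 0.1]})
        out = prs.meta_prs_r2(marg)
        assert out["pooled_beta"] == pytest.approx(0.26)
        assert out["r2"] == pytest.approx(0.26**2)

    def test_single_stratum_and_zero(self):
        assert prs.meta_prs_r2(
            pd.DataFrame({"beta": [0.4], "se": [0.1]})
        )["r2"] == pytest.approx(0.16)
        assert prs.meta_prs_r2(
            pd.DataFrame({"beta": [0.0, 0.0], "se": [0.1, 0.2]})
        )["r2"] == 0.0


@pytest.fixture(scope="module")
def cohort_setup():
    from metaprs import synthgen

    pop = synthgen.PopulationSpec(
        n_variants=200, n_blocks=40, block_size=5, within_block_r2=0.3
    )
    traits = [synthgen.TraitSpec(name="y", n_causal=30, h2=0.4,
                                 ancestry_effect_corr=0.3)]
    sc = synthgen.simulate_cohort(pop, traits, {"EA": 200, "AA": 600},
                                  seed=21)
    eff = sc.truth[sc.truth["trait"] == "y"].rename(
        columns={"beta_EA": "beta"})[["variant_id", "beta"]]
    ref = synthgen.simulate_reference_sumstats(
        sc.genotypes, eff, 0.4, 200000, 22
    )
    return sc, ref


class TestCrossvalMultiethnic:

    def test_deterministic_under_seed(self, cohort_setup):
        sc, ref = cohort_setup
        a = prs.crossval_multiethnic(
            sc.genotypes, sc.cohort, ref, "y", k=4, seed=5, n_pcs=2
        )
        b = prs.crossval_multiethnic(
            sc.genotypes, sc.cohort, ref, "y", k=4, seed=5, n_pcs=2
        )
        pd.testing.assert_frame_equal(a.cv, b.cv)

    def test_records_reference_only_baseline(self, cohort_setup):
        sc, ref = cohort_setup
        out = prs.crossval_multiethnic(
            sc.genotypes, sc.cohort, ref, "y", k=4, seed=5, n_pcs=2
        )
        assert {"fold", "alpha1", "alpha2", "r2_multi", "r2_ea_only"} <= set(
            out.cv.columns
        )
        assert len(out.cv) == 4
        assert np.isfinite(out.mean_adjusted_r2)

    def test_binary_fold_without_cases_errors(self):
        from metaprs import synthgen

        pop = synthgen.PopulationSpec(
            n_variants=50, n_blocks=10, block_size=5
        )
        traits = [synthgen.TraitSpec(name="d", kind="binary", n_causal=10,
                                     h2=0.3, prevalence=0.02)]
        sc = synthgen.simulate_cohort(pop, traits, {"EA": 30, "AA": 60},
                                      seed=23)
        eff = sc.truth[sc.truth["trait"] == "d"].rename(
            columns={"beta_EA": "beta"})[["variant_id", "beta"]]
        ref = synthgen.simulate_reference_sumstats(
            sc.genotypes, eff, 0.3, 50000, 24
        )
        with pytest.raises(ValueError, match="fold"):
            prs.crossval_multiethnic(
                sc.genotypes, sc.cohort, ref, "d", k=10, seed=1,
                binary=True, n_pcs=0,
            )


class TestPrsPhenotypeMatrix:
    def test_shape_and_diagonal_signal(self):
        from metaprs import synthgen

        pop = synthgen.PopulationSpec(
            n_variants=100, n_blocks=20, block_size=5
        )
        traits = [
            synthgen.TraitSpec(name="a", n_causal=20, h2=0.5),
            synthgen.TraitSpec(name="b", n_causal=20, h2=0.5),
        ]
        sc = synthgen.simulate_cohort(pop, traits, {"EA": 400, "AA": 400},
                                      seed=25)
        models = {}
        for t in ("a", "b"):
            eff = sc.truth[sc.truth["trait"] == t].rename(
                columns={"beta_EA": "beta"})[["variant_id", "beta"]]
            ref = synthgen.simulate_reference_sumstats(
                sc.genotypes, eff, 0.5, 200000, 26
            )
            for thr in (1e-2, 1e-4):
                models[(t, thr)] = prs.derive_prs_weights(
                    ref, thr, sc.genotypes, trait=t
                )
        out = prs.prs_phenotype_matrix(
            models, sc.genotypes, sc.cohort, ["a", "b"]
        )
        assert len(out) == 4 * 2  # (2 traits x 2 thresholds) x 2 phenotypes
        pivot = out.pivot_table(index=["prs_trait", "threshold"],
                                columns="phenotype", values="z")
        # own-trait cells dominate cross-trait cells
        assert pivot.loc["a"].loc[:, "a"].abs().max() > \
            pivot.loc["a"].loc[:, "b"].abs().max()
        assert pivot.loc["b"].loc[:, "b"].abs().max() > \
            pivot.loc["b"].loc[:, "a"].abs().max()
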