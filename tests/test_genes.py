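"""Gene pipeline tests: NB exact test against exhaustive enumeration and the
Poisson limit, candidate restriction, HR-gated retention arithmetic, leakage
guards, frozen-cutpoint validation, NNLS deconvolution."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmesig import (FeatureMatrix, GenePipelineConfig, GeneSetLibrary,
                    SurvivalData, estimate_common_dispersion,
                    finalize_gene_signature, multivariable_adjustment,
                    nb_exact_test, nnls_deconvolve, normalize_counts,
                    restrict_genes, retain_genes, run_gene_splits,
                    validate_gene_signature)
from tmesig.genes import SplitRecord, _exact_nb_pvalue, binary_outcome_at
from tmesig.celltype import evaluate_signature, score_patients

from conftest import make_cohort, random_survival


def enumeration_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Brute-force conditional two-sided p in linear space."""
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi < 1e-8:
        pr = stats.binom.pmf(a, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        ra, rb = n_a / phi, n_b / phi
        pr = (stats.nbinom.pmf(a, ra, ra / (ra + n_a * mu))
              * stats.nbinom.pmf(t - a, rb, rb / (rb + n_b * mu)))
    pr = pr / pr.sum()
    obs = pr[sum_a]
    return float(min(1.0, pr[pr <= obs * (1 + 1e-10)].sum()))


class TestNBExactTest:
    def test_identical_groups_p_one(self):
        counts = pd.DataFrame(np.arange(12).reshape(4, 3),
                              columns=["g1", "g2", "g3"])
        p = nb_exact_test(counts.iloc[:2], counts.iloc[:2].copy(),
                          dispersion_estimate=0.1)
        assert (p == 1.0).all()

    def test_zero_total_gene_p_one(self):
        a = pd.DataFrame({"g": [0, 0]})
        b = pd.DataFrame({"g": [0, 0, 0]})
        assert nb_exact_test(a, b, dispersion_estimate=0.2).iloc[0] == 1.0

    @pytest.mark.parametrize("phi", [0.05, 0.3, 1.0])
    def test_matches_enumeration_small_totals(self, phi):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n_a, n_b = rng.integers(2, 6, 2)
            sa = int(rng.integers(0, 16))
            sb = int(rng.integers(0, 31 - sa))
            mine = _exact_nb_pvalue(sa, sb, n_a, n_b, phi)
            oracle = enumeration_oracle(sa, sb, n_a, n_b, phi)
            assert abs(mine - oracle) < 1e-10

    def test_dispersion_zero_limit_is_binomial(self):
        # vanishing dispersion: the conditional law is exactly binomial
        for sa, sb, na, nb in [(3, 9, 2, 4), (10, 2, 3, 3), (0, 5, 2, 2)]:
            mine = _exact_nb_pvalue(sa, sb, na, nb, 1e-12)
            oracle = enumeration_oracle(sa, sb, na, nb, 0.0)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_small_dispersion_continuous_with_poisson_limit(self):
        p_small = _exact_nb_pvalue(20, 50, 3, 3, 1e-4)
        p_limit = _exact_nb_pvalue(20, 50, 3, 3, 0.0)
        assert p_small == pytest.approx(p_limit, abs=1e-3)

    def test_shifted_gene_detected_among_nulls(self):
        rng = np.random.default_rng(5)
        nulls = {f"n{i}": rng.poisson(20, 16) for i in range(20)}
        df = pd.DataFrame({"up": np.r_[rng.poisson(60, 8),
                                       rng.poisson(20, 8)], **nulls})
        p = nb_exact_test(df.iloc[:8], df.iloc[8:], dispersion_estimate=0.05)
        assert p["up"] < 0.01
        assert np.median(p.drop("up")) > 0.1

    def test_common_dispersion_estimate_order_of_magnitude(self):
        rng = np.random.default_rng(6)
        phi = 0.3
        r = 1 / phi
        mu = 30.0
        counts = rng.negative_binomial(r, r / (r + mu), size=(10, 200))
        est = estimate_common_dispersion(counts[:5], counts[5:])
        assert 0.15 < est < 0.6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(pd.DataFrame({"g": [-1]}), pd.DataFrame({"g": [1]}))


class TestRestrictGenes:
    def setup_method(self):
        self.lib = GeneSetLibrary({"vessel": ["VA", "VB"],
                                   "granulocyte": ["GA", "GB", "GC"]})
        df = pd.DataFrame(np.arange(10).reshape(2, 5),
                          columns=["VA", "VB", "GA", "GB", "GC"],
                          index=["p0", "p1"])
        self.expr = FeatureMatrix(df, kind="counts")

    def test_single_type_returns_exactly_its_list(self):
        out = restrict_genes(self.expr, self.lib, ["vessel"])
        assert out.feature_names == ["VA", "VB"]

    def test_union_is_sorted(self):
        out = restrict_genes(self.expr, self.lib, ["granulocyte", "vessel"])
        assert out.feature_names == sorted(["VA", "VB", "GA", "GB", "GC"])

    def test_unmeasured_type_error_names_genes(self):
        lib = GeneSetLibrary({"vessel": ["VA"], "tcell": ["TX", "TY"]})
        with pytest.raises(KeyError, match="TX"):
            restrict_genes(self.expr, lib, ["vessel", "tcell"])

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(KeyError, match="missing from library"):
            restrict_genes(self.expr, self.lib, ["nope"])


class TestRetainGenes:
    def rec(self, i, coefs, hr):
        return SplitRecord(i, [f"t{i}"], [f"v{i}"], list(coefs),
                           list(coefs), coefs, hr)

    def test_hand_built_support_arithmetic(self):
        cfg = GenePipelineConfig(direction="resistance", retain_frac=0.5)
        records = [
            self.rec(0, {"a": 1.0, "b": 0.5, "c": 0.2}, 2.0),
            self.rec(1, {"a": 0.9, "b": 0.4}, 3.0),
            self.rec(2, {"a": 0.8, "c": 0.0}, 1.8),
            self.rec(3, {"d": 1.0}, 1.0),  # fails HR gate
        ]
        genes, tbl = retain_genes(records, cfg)
        sup = tbl.set_index("gene")["support"]
        assert sup["a"] == pytest.approx(1.0)
        assert sup["b"] == pytest.approx(2 / 3)
        assert sup["c"] == pytest.approx(1 / 3)
        assert "d" not in sup
        assert genes == ["a", "b"]

    def test_gene_in_every_gated_record_retained(self):
        cfg = GenePipelineConfig(direction="resistance")
        records = [self.rec(i, {"x": 0.5, f"n{i}": 0.1}, 2.0)
                   for i in range(10)]
        genes, _ = retain_genes(records, cfg)
        assert "x" in genes

    def test_cap_at_max_genes(self):
        cfg = GenePipelineConfig(direction="resistance", retain_frac=0.05)
        coefs = {f"g{i:02d}": 1.0 - 0.01 * i for i in range(12)}
        records = [self.rec(i, coefs, 2.0) for i in range(4)]
        genes, _ = retain_genes(records, cfg)
        assert len(genes) == 10

    def test_response_gate_uses_low_hr(self):
        cfg = GenePipelineConfig(direction="response")
        records = [self.rec(0, {"a": -1.0}, 0.5),
                   self.rec(1, {"b": -1.0}, 1.2)]
        genes, tbl = retain_genes(records, cfg)
        assert genes == ["a"]

    def test_no_gated_records_is_error(self):
        cfg = GenePipelineConfig(direction="resistance")
        with pytest.raises(ValueError, match="HR gate"):
            retain_genes([self.rec(0, {"a": 1.0}, 1.2)], cfg)


def small_gene_cohort(n=80, n_genes=30, n_planted=4, seed=3, beta=1.0):
    """Counts with planted survival-associated genes."""
    from tmesig import (CohortSpec, ExpressionSpec, simulate_cell_fractions,
                        simulate_expression, simulate_survival)
    spec = CohortSpec(n_patients=n, seed=seed, baseline_hazard=0.04)
    fr = simulate_cell_fractions(spec)["tumor"]
    lib = {"vessel": [f"V{i:02d}" for i in range(n_genes)]}
    espec = ExpressionSpec(gene_set_library=lib, seed=seed)
    expr = simulate_expression(fr, espec)
    planted = [f"V{i:02d}" for i in range(n_planted)]
    norm = normalize_counts(expr)
    z = (norm.data[planted] - norm.data[planted].mean()) / norm.data[planted].std()
    surv = simulate_survival(beta * z.mean(axis=1).to_numpy() * np.sqrt(n_planted),
                             spec)
    return expr, surv, planted, GeneSetLibrary(lib)


class TestGeneSplits:
    @pytest.fixture(scope="class")
    def small(self):
        expr, surv, planted, lib = small_gene_cohort(beta=2.0)
        cfg = GenePipelineConfig(n_splits=3, n_seeds_per_split=2,
                                 direction="resistance", seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = run_gene_splits(expr, surv, cfg)
        return expr, surv, planted, cfg, records

    def test_deterministic_records(self, small):
        expr, surv, planted, cfg, records = small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = run_gene_splits(expr, surv, cfg)
        for r1, r2 in zip(records, again):
            assert r1.train_ids == r2.train_ids
            assert r1.union_genes == r2.union_genes
            assert r1.coefficients == r2.coefficients
            assert (r1.test_hr == r2.test_hr
                    or (np.isnan(r1.test_hr) and np.isnan(r2.test_hr)))

    def test_train_test_disjoint_and_sized(self, small):
        expr, _, _, cfg, records = small
        n = len(expr.data)
        for r in records:
            assert not set(r.train_ids) & set(r.test_ids)
            assert len(r.train_ids) + len(r.test_ids) == n
            assert len(r.train_ids) == pytest.approx(0.8 * n, abs=2)

    def test_no_leakage_from_test_outcomes(self, small):
        # with the partition held fixed, rewriting the held-out half's
        # outcomes must not change anything computed on the training half
        from tmesig.genes import _run_one_split, binary_outcome_at
        expr, surv, planted, cfg, records = small
        r0 = records[0]
        tr = np.flatnonzero(np.isin(surv.patient_id, r0.train_ids))
        te = np.flatnonzero(np.isin(surv.patient_id, r0.test_ids))
        time2, event2 = surv.time.copy(), surv.event.copy()
        rng = np.random.default_rng(0)
        time2[te] = rng.exponential(5.0, te.size)
        event2[te] = rng.integers(0, 2, te.size)
        surv2 = SurvivalData(time2, event2, surv.patient_id)
        norm = normalize_counts(expr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec2 = _run_one_split(expr, norm, surv2,
                                  binary_outcome_at(surv2, 24.0), tr, te,
                                  cfg, 0)
        assert rec2.de_genes == r0.de_genes
        assert rec2.union_genes == r0.union_genes
        assert rec2.coefficients == r0.coefficients
        assert rec2.test_hr != r0.test_hr  # the held-out HR does change

    def test_planted_genes_reach_split_unions(self, small):
        expr, surv, planted, cfg, records = small
        hit = np.mean([len(set(r.union_genes) & set(planted)) / len(planted)
                       for r in records])
        assert hit >= 0.5

    def test_impossible_de_alpha_yields_empty_records(self):
        expr, surv, _, _ = small_gene_cohort(seed=5)
        cfg = GenePipelineConfig(n_splits=1, n_seeds_per_split=1,
                                 de_alpha=1e-12, direction="resistance",
                                 seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = run_gene_splits(expr, surv, cfg)
        assert records[0].union_genes == []
        assert np.isnan(records[0].test_hr)


class TestFinalizeAndValidate:
    @pytest.fixture(scope="class")
    def trained(self):
        expr, surv, planted, lib = small_gene_cohort(seed=7)
        model = finalize_gene_signature(expr, surv, planted, "resistance")
        return expr, surv, planted, model

    def test_resistance_coefficients_nonnegative(self, trained):
        _, _, _, model = trained
        assert all(b >= 0 for b in model.coefficients.values())

    def test_response_coefficients_nonpositive(self):
        expr, surv, planted, _ = small_gene_cohort(seed=8, beta=-1.0)
        model = finalize_gene_signature(expr, surv, planted, "response")
        assert all(b <= 0 for b in model.coefficients.values())

    def test_single_noise_gene_still_valid_model(self):
        expr, surv, _, _ = small_gene_cohort(seed=9, beta=0.0)
        model = finalize_gene_signature(expr, surv, ["V29"], "resistance")
        assert model.features == ["V29"]
        assert np.isfinite(model.cutpoint_value)

    def test_identical_cohort_reproduces_training_evaluation(self, trained):
        expr, surv, _, model = trained
        res_val = validate_gene_signature(model, expr, surv, sided="two")
        scores = score_patients(model, normalize_counts(expr))
        res_tr = evaluate_signature(scores, surv, model, sided="two")
        assert res_val.hr == pytest.approx(res_tr.hr)
        assert res_val.p == pytest.approx(res_tr.p)

    def test_too_many_missing_genes_hard_error(self, trained):
        expr, surv, _, model = trained
        keep = [g for g in expr.data.columns if g not in model.features[:2]]
        crippled = FeatureMatrix(expr.data[keep].copy(), kind="counts")
        with pytest.raises(KeyError, match="missing"):
            validate_gene_signature(model, crippled, surv)

    def test_few_missing_genes_warns_and_proceeds(self):
        expr, surv, planted, _ = small_gene_cohort(seed=10, n_planted=6)
        model = finalize_gene_signature(expr, surv, planted, "resistance")
        keep = [g for g in expr.data.columns if g != model.features[0]]
        reduced = FeatureMatrix(expr.data[keep].copy(), kind="counts")
        with pytest.warns(UserWarning, match="no imputation"):
            res = validate_gene_signature(model, reduced, surv)
        # a valid evaluation object comes back; with a large-coefficient
        # gene dropped, all scores may fall below the frozen cutpoint, in
        # which case the result is flagged rather than imputed
        assert res.n_high + res.n_low == len(surv)


class TestMultivariable:
    def test_empty_covariates_match_univariable(self, rng):
        surv = random_survival(150, rng)
        high = rng.integers(0, 2, 150)
        tbl = multivariable_adjustment(high, pd.DataFrame(), surv)
        from tmesig import hazard_ratio
        hr, _, _, _ = hazard_ratio(surv, high)
        assert tbl.loc[0, "hr"] == pytest.approx(hr, rel=1e-6)

    def test_independent_covariates_leave_hr_unchanged(self, rng):
        n = 400
        high = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * high)))
        surv = SurvivalData(t, np.ones(n, int),
                            np.array([f"p{i}" for i in range(n)]))
        cov = pd.DataFrame({"age": rng.normal(65, 8, n),
                            "sex": rng.choice(["m", "f"], n)})
        tbl = multivariable_adjustment(high, cov, surv).set_index("term")
        from tmesig import hazard_ratio
        hr, _, _, _ = hazard_ratio(surv, high)
        assert tbl.loc["signature_high", "hr"] == pytest.approx(hr, rel=0.1)

    def test_collinear_covariate_dropped_with_warning(self, rng):
        surv = random_survival(100, rng)
        high = rng.integers(0, 2, 100)
        cov = pd.DataFrame({"dup": high.astype(float)})
        with pytest.warns(UserWarning, match="unidentifiable"):
            tbl = multivariable_adjustment(high, cov, surv)
        assert list(tbl["term"]) == ["signature_high"]


class TestNNLS:
    def make_B(self, rng):
        B = pd.DataFrame(rng.uniform(0, 10, size=(40, 3)),
                         index=[f"g{i}" for i in range(40)],
                         columns=["ctA", "ctB", "ctC"])
        return B

    def test_exact_mixture_recovered(self, rng):
        B = self.make_B(rng)
        f = np.array([0.5, 0.3, 0.2])
        frac, resid = nnls_deconvolve(B, B.to_numpy() @ f)
        np.testing.assert_allclose(frac, f, atol=1e-6)
        assert resid < 1e-8

    def test_pure_profile_gives_indicator(self, rng):
        B = self.make_B(rng)
        frac, _ = nnls_deconvolve(B, B["ctB"].to_numpy())
        np.testing.assert_allclose(frac, [0, 1, 0], atol=1e-6)

    def test_noisy_mixture_small_error(self, rng):
        B = self.make_B(rng)
        f = np.array([0.6, 0.1, 0.3])
        clean = B.to_numpy() @ f
        errs = []
        for _ in range(30):
            noisy = clean + rng.normal(0, 0.05 * clean.mean(), size=40)
            frac, _ = nnls_deconvolve(B, noisy)
            errs.append(np.abs(frac - f).mean())
        assert np.mean(errs) <= 0.05

    def test_gene_matching_by_symbol(self, rng):
        B = self.make_B(rng)
        f = np.array([0.2, 0.5, 0.3])
        M = pd.Series(B.to_numpy() @ f, index=B.index).sample(frac=1.0,
                                                              random_state=1)
        frac, _ = nnls_deconvolve(B, M)
        np.testing.assert_allclose(frac, f, atol=1e-6)

    def test_no_shared_genes_rejected(self, rng):
        B = self.make_B(rng)
        with pytest.raises(ValueError, match="shared"):
            nnls_deconvolve(B, pd.Series([1.0], index=["other"]))


class TestBinaryOutcome:
    def test_classification_rules(self):
        surv = SurvivalData(np.array([10.0, 30.0, 10.0, 24.0, 30.0]),
                            np.array([1, 1, 0, 1, 0]),
                            np.array(list("abcde")))
        out = binary_outcome_at(surv, 24.0)
        assert out["a"] == 1          # event before horizon
        assert out["b"] == 0          # event after horizon: event-free at 24
        assert np.isnan(out["c"])     # censored early: unknown
        assert out["d"] == 1          # event exactly at horizon
        assert out["e"] == 0          # censored after horizon
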