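import numpy as np
import pandas as pd
import pytest

import mrgps
from mrgps.signature_fit import FitError

from helpers import harrell_c_bruteforce  # noqa: F401


def simulate_indicator_cohort(
    n, betas, n_null=0, censoring=0.2, seed=0, baseline=0.02, p_plus=0.5
):
    """Indicators drawn iid ±1, exponential PH survival from the first pairs."""
    rng = np.random.default_rng(seed)
    k = len(betas) + n_null
    values = np.where(rng.uniform(size=(k, n)) < p_plus, 1, -1).astype(np.int8)
    pairs = [("METTL3", f"T{i}") for i in range(k)]
    eta = np.asarray(betas) @ values[: len(betas)].astype(float)
    t = rng.exponential(1.0 / (baseline * np.exp(eta)))
    if censoring > 0:
        c = rng.uniform(0, np.quantile(t, 1 - censoring) * 2.2, size=n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
    else:
        obs, ev = t, np.ones(n, dtype=int)
    ids = [f"S{i}" for i in range(n)]
    ind = mrgps.PairIndicatorMatrix(pairs, ids, values)
    clin = mrgps.ClinicalTable(pd.DataFrame({
        "sample_id": ids, "time_months": np.maximum(obs, 1e-6),
        "event": ev, "grade": ["LGG"] * n,
    }))
    return ind, clin


class TestPublishedSignature:
    def test_five_pairs_with_printed_coefficients(self):
        sig = mrgps.published_mrgps()
        assert len(sig) == 5
        assert sig.provenance == "published"
        coefs = dict(sig.entries)
        assert coefs[("EIF3A", "AK2")] == -0.204
        assert coefs[("EIF3A", "EMP3")] == -0.266
        assert coefs[("YTHDC1", "IGFBP2")] == -0.439
        assert coefs[("YTHDC1", "TUBA1C")] == -0.140
        assert coefs[("IGF2BP3", "CYP17A1")] == 0.647

    def test_coefficient_sum(self):
        assert mrgps.published_mrgps().coefficients.sum() == pytest.approx(-0.402)

    def test_json_round_trip(self, tmp_path):
        sig = mrgps.published_mrgps()
        sig.save(tmp_path / "sig.json")
        back = mrgps.PairSignature.load(tmp_path / "sig.json")
        assert back.entries == sig.entries
        assert back.provenance == "published"


class TestRiskScore:
    def _indicators(self, fill):
        sig = mrgps.published_mrgps()
        values = np.full((5, 4), fill, dtype=np.int8)
        return sig, mrgps.PairIndicatorMatrix(
            sig.pairs, [f"S{i}" for i in range(4)], values)

    def test_all_plus_one_gives_sum_of_coefficients(self):
        sig, ind = self._indicators(1)
        rs = mrgps.risk_score(sig, ind)
        assert rs.score == pytest.approx(np.full(4, -0.402))

    def test_all_minus_one_negates(self):
        sig, ind = self._indicators(-1)
        rs = mrgps.risk_score(sig, ind)
        assert rs.score == pytest.approx(np.full(4, 0.402))

    def test_zero_coefficients_zero_scores(self):
        sig = mrgps.PairSignature([(p, 0.0) for p in mrgps.published_mrgps().pairs])
        _, ind = self._indicators(1)
        rs = mrgps.risk_score(sig, ind)
        assert (rs.score == 0).all()
        assert rs.group == ["low"] * 4  # ties at the median go to low risk

    def test_linearity_and_sign_flip(self):
        rng = np.random.default_rng(7)
        pairs = [("M", f"G{i}") for i in range(3)]
        values = np.where(rng.uniform(size=(3, 20)) < 0.5, 1, -1)
        ind = mrgps.PairIndicatorMatrix(pairs, [f"S{i}" for i in range(20)], values)
        coefs = [0.5, -1.2, 0.3]
        s1 = mrgps.risk_score(mrgps.PairSignature(list(zip(pairs, coefs))), ind)
        s2 = mrgps.risk_score(
            mrgps.PairSignature([(p, 2.0 * c) for p, c in zip(pairs, coefs)]), ind)
        assert s2.score == pytest.approx(2.0 * s1.score)
        flipped = mrgps.PairIndicatorMatrix(
            pairs, [f"S{i}" for i in range(20)], -values)
        s3 = mrgps.risk_score(mrgps.PairSignature(list(zip(pairs, coefs))), flipped)
        assert s3.score == pytest.approx(-s1.score)

    def test_median_split_balance(self):
        # with a multi-level score (5 weighted pairs), the tie count at the
        # median bounds the group imbalance; ties themselves go to low
        rng = np.random.default_rng(8)
        pairs = [("M", f"G{i}") for i in range(5)]
        coefs = [0.9, -0.55, 0.3, -0.17, 0.08]
        for n in (9, 10, 51, 100):
            values = np.where(rng.uniform(size=(5, n)) < 0.5, 1, -1)
            ind = mrgps.PairIndicatorMatrix(pairs, [f"S{i}" for i in range(n)], values)
            rs = mrgps.risk_score(mrgps.PairSignature(list(zip(pairs, coefs))), ind)
            med = np.median(rs.score)
            ties = int((rs.score == med).sum())
            n_high = rs.group.count("high")
            n_low = rs.group.count("low")
            # ties all land in "low", so imbalance is bounded by 2*ties - 1
            assert abs(n_high - n_low) <= max(2 * ties - 1, 1)
            for s, g in zip(rs.score, rs.group):
                if s == med:
                    assert g == "low"

    def test_missing_pair_is_hard_error(self):
        sig = mrgps.published_mrgps()
        ind = mrgps.PairIndicatorMatrix(
            sig.pairs[:4], ["S0", "S1"], np.ones((4, 2), dtype=np.int8))
        with pytest.raises(KeyError, match="CYP17A1"):
            mrgps.risk_score(sig, ind)


class TestLassoCoxSelect:
    def test_planted_prognostic_pair_selected_among_nulls(self):
        ind, clin = simulate_indicator_cohort(
            n=400, betas=(1.0,), n_null=20, seed=42)
        selected = mrgps.lasso_cox_select(ind, clin, folds=5, seed=1)
        assert ("METTL3", "T0") in selected

    def test_huge_penalty_selects_nothing(self):
        ind, clin = simulate_indicator_cohort(n=100, betas=(1.0,), n_null=3, seed=0)
        assert mrgps.lasso_cox_select(ind, clin, alpha=1e6) == []

    def test_zero_penalty_matches_unpenalized_cox(self):
        ind, clin = simulate_indicator_cohort(n=800, betas=(0.8, -0.5), seed=3)
        selected, coefs = mrgps.lasso_cox_select(
            ind, clin, alpha=0.0, return_coefficients=True)
        assert set(selected) == {("METTL3", "T0"), ("METTL3", "T1")}
        sig = mrgps.cox_refit(selected, ind, clin)
        refit = dict(sig.entries)
        for pair in selected:
            assert coefs[pair] == pytest.approx(refit[pair], abs=5e-3)

    def test_seeded_reproducibility(self):
        ind, clin = simulate_indicator_cohort(n=300, betas=(0.7,), n_null=10, seed=5)
        a = mrgps.lasso_cox_select(ind, clin, folds=5, seed=11)
        b = mrgps.lasso_cox_select(ind, clin, folds=5, seed=11)
        assert a == b

    def test_no_events_is_error(self):
        ind, clin = simulate_indicator_cohort(n=50, betas=(1.0,), n_null=2, seed=0)
        df = clin.data.copy()
        df["event"] = 0
        with pytest.raises(FitError, match="events"):
            mrgps.lasso_cox_select(ind, mrgps.ClinicalTable(df), folds=3, seed=0)

    def test_constant_feature_dropped_with_warning(self):
        ind, clin = simulate_indicator_cohort(n=100, betas=(1.0,), n_null=2, seed=1)
        values = ind.values.copy()
        values[2] = 1
        ind2 = mrgps.PairIndicatorMatrix(ind.pairs, ind.sample_ids, values)
        with pytest.warns(UserWarning, match="constant"):
            selected = mrgps.lasso_cox_select(ind2, clin, folds=3, seed=0)
        assert ("METTL3", "T2") not in selected


class TestCoxRefit:
    def test_recovers_true_coefficients(self):
        ind, clin = simulate_indicator_cohort(n=1000, betas=(0.8, -0.5), seed=10)
        sig = mrgps.cox_refit([("METTL3", "T0"), ("METTL3", "T1")], ind, clin)
        fitted = dict(sig.entries)
        assert fitted[("METTL3", "T0")] == pytest.approx(0.8, abs=0.15)
        assert fitted[("METTL3", "T1")] == pytest.approx(-0.5, abs=0.15)
        assert sig.global_p < 1e-10

    def test_null_pair_has_small_coefficient(self):
        ind, clin = simulate_indicator_cohort(n=1000, betas=(0.8,), n_null=1, seed=12)
        sig = mrgps.cox_refit([("METTL3", "T1")], ind, clin)
        assert abs(dict(sig.entries)[("METTL3", "T1")]) < 0.15
        assert sig.hazard_ratios["p"].iloc[0] > 0.01

    def test_hazard_ratio_is_exp_of_coefficient(self):
        ind, clin = simulate_indicator_cohort(n=300, betas=(0.6,), seed=13, n_null=1)
        sig = mrgps.cox_refit(list(ind.pairs), ind, clin)
        for (pair, coef), hr in zip(sig.entries, sig.hazard_ratios["HR"]):
            assert hr == pytest.approx(np.exp(coef), rel=1e-10)

    def test_collinear_columns_rejected(self):
        ind, clin = simulate_indicator_cohort(n=100, betas=(0.5,), n_null=1, seed=14)
        values = ind.values.copy()
        values[1] = values[0]
        ind2 = mrgps.PairIndicatorMatrix(ind.pairs, ind.sample_ids, values)
        with pytest.raises(FitError, match="collinear"):
            mrgps.cox_refit(list(ind2.pairs), ind2, clin)

    def test_empty_selection_is_error(self):
        ind, clin = simulate_indicator_cohort(n=50, betas=(0.5,), seed=15)
        with pytest.raises(FitError, match="no pairs"):
            mrgps.cox_refit([], ind, clin)


class TestCombineClinical:
    def _cohort_with_age_effect(self, n=1500, beta_age=0.05, seed=21):
        rng = np.random.default_rng(seed)
        pairs = [("M", "G0"), ("M", "G1")]
        values = np.where(rng.uniform(size=(2, n)) < 0.5, 1, -1)
        age = rng.uniform(20, 80, n)
        eta = 0.5 * values[0] + beta_age * (age - 50.0)
        t = rng.exponential(1.0 / (0.02 * np.exp(eta)))
        ids = [f"S{i}" for i in range(n)]
        clin = mrgps.ClinicalTable(pd.DataFrame({
            "sample_id": ids, "time_months": np.maximum(t, 1e-6),
            "event": np.ones(n, dtype=int), "grade": ["LGG"] * n,
            "age": age,
            "radiotherapy": rng.choice(["yes", "no"], n),
        }))
        ind = mrgps.PairIndicatorMatrix(pairs, ids, values)
        sig = mrgps.PairSignature([(pairs[0], 0.5), (pairs[1], 0.0)])
        return sig, ind, clin

    def test_age_hazard_ratio_recovered(self):
        sig, ind, clin = self._cohort_with_age_effect()
        model = mrgps.combine_clinical(sig, ind, clin, covariates=("age",))
        hr = model.hazard_ratios.loc["age"]
        assert hr["HR_lower95"] <= np.exp(0.05) <= hr["HR_upper95"]
        assert hr["HR"] == pytest.approx(np.exp(0.05), abs=0.02)

    def test_no_covariates_reduces_to_refit(self):
        sig, ind, clin = self._cohort_with_age_effect(n=400)
        combined = mrgps.combine_clinical(sig, ind, clin, covariates=())
        refit = mrgps.cox_refit(sig.pairs, ind, clin)
        for pair, coef in refit.entries:
            assert combined.hazard_ratios.loc[f"{pair[0]}|{pair[1]}", "coef"] == (
                pytest.approx(coef, abs=1e-8))

    def test_constant_covariate_rejected(self):
        sig, ind, clin = self._cohort_with_age_effect(n=100)
        df = clin.data.copy()
        df["radiotherapy"] = "yes"
        with pytest.raises(mrgps.ValidationError, match="constant"):
            mrgps.combine_clinical(sig, ind, mrgps.ClinicalTable(df),
                                   covariates=("radiotherapy",))

    def test_covariate_identical_to_pair_is_collinear(self):
        sig, ind, clin = self._cohort_with_age_effect(n=100)
        df = clin.data.copy()
        df["twin"] = ind.values[0].astype(float)
        with pytest.raises(FitError, match="collinear"):
            mrgps.combine_clinical(sig, ind, mrgps.ClinicalTable(df),
                                   covariates=("twin",))


class TestBaselineGeneSignature:
    def _expression_cohort(self, n=500, n_genes=100, seed=31):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n_genes, n))
        genes = [f"GENE{i}" for i in range(n_genes)]
        eta = 1.0 * vals[0] - 1.0 * vals[1]
        t = rng.exponential(1.0 / (0.02 * np.exp(eta)))
        ids = [f"S{i}" for i in range(n)]
        expr = mrgps.ExpressionMatrix(genes, ids, vals)
        clin = mrgps.ClinicalTable(pd.DataFrame({
            "sample_id": ids, "time_months": np.maximum(t, 1e-6),
            "event": np.ones(n, dtype=int), "grade": ["LGG"] * n,
        }))
        return expr, clin

    def test_prognostic_genes_selected(self):
        expr, clin = self._expression_cohort()
        sig, scores = mrgps.baseline_gene_signature(expr, clin, n_target=20,
                                                    folds=5, seed=2)
        assert "GENE0" in sig.genes
        assert "GENE1" in sig.genes
        assert len(scores.sample_ids) == 500

    def test_huge_penalty_gives_empty_signature(self):
        expr, clin = self._expression_cohort(n=100, n_genes=20)
        sig, _ = mrgps.baseline_gene_signature(expr, clin, alpha=1e6)
        assert sig.genes == []

    def test_scores_invariant_to_gene_level_offset(self):
        expr, clin = self._expression_cohort(n=200, n_genes=30)
        sig, scores = mrgps.baseline_gene_signature(expr, clin, n_target=5,
                                                    folds=3, seed=4)
        shifted_vals = expr.values.copy()
        shifted_vals[0] += 100.0  # constant offset removed by standardization
        shifted = mrgps.ExpressionMatrix(expr.gene_ids, expr.sample_ids, shifted_vals)
        sig2, scores2 = mrgps.baseline_gene_signature(shifted, clin, n_target=5,
                                                      folds=3, seed=4)
        assert sig2.genes == sig.genes
        assert scores2.score == pytest.approx(scores.score, abs=1e-8)
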