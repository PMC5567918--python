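import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import agq_logistic_loglik, dyad_days_bruteforce
from atsea import dyad_inference as di
from atsea._laplace import GlmmControl, build_random_design, laplace_loglik

# Published model-ranking weights used as worked-example inputs for the
# weight/averaging algebra (descending AICc order; the remaining 11
# candidate models share the residual mass).
TABLE_WEIGHTS = [0.26, 0.20, 0.10, 0.10, 0.09, 0.08, 0.07, 0.04, 0.04]
# which of the nine ranked models contain the sex-pairing term
SEX_IN_MODEL = [True, False, True, True, True, False, False, True, True]


def _full_weight_vector():
    rest = 1.0 - sum(TABLE_WEIGHTS)
    return np.array(TABLE_WEIGHTS + [rest / 11] * 11)


def simulate_dyad_obs(seed, n_birds=29, n_days=5, b0=2.78, b1=-0.38,
                      sd_dyad=0.5, sd_bird=0.5, dep_sd_min=35.0):
    """Observation-level simulation of the dyadic association process."""
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n_birds), 2))
    u = rng.normal(0, sd_dyad, len(pairs))
    v = rng.normal(0, sd_bird, n_birds)
    sex = rng.integers(0, 2, n_birds)
    rows = []
    for day in range(n_days):
        dep = rng.normal(0, dep_sd_min * 60.0, n_birds)
        for k, (i, j) in enumerate(pairs):
            gap_min = abs(dep[i] - dep[j]) / 60.0
            x = np.log(gap_min + 1.0)
            eta = b0 + b1 * x + u[k] + v[i] + v[j]
            rows.append({
                "bird_a": f"B{i:02d}", "bird_b": f"B{j:02d}", "day": day,
                "associated": int(rng.uniform() < 1 / (1 + np.exp(-eta))),
                "gap_minutes": gap_min, "log_dt_depart": x,
                "sex_pair": "same" if sex[i] == sex[j] else "different",
                "nest_dist": float(rng.uniform(2, 40)),
                "d_condition": float(abs(rng.normal(0, 0.5))),
            })
    return pd.DataFrame(rows)


class TestEnumerateModels:
    def test_twenty_models(self):
        assert len(di.enumerate_models()) == 20

    def test_matches_marginality_filtered_power_set(self):
        all_terms = [*di.MAIN_TERMS, di.TERM_INTERACTION]
        expected = set()
        for r in range(len(all_terms) + 1):
            for combo in itertools.combinations(all_terms, r):
                s = frozenset(combo)
                if di.TERM_INTERACTION in s and not (
                    di.TERM_LOGT in s and di.TERM_SEX in s
                ):
                    continue
                expected.add(s)
        assert {m.terms for m in di.enumerate_models()} == expected

    def test_interaction_without_mains_rejected(self):
        with pytest.raises(ValueError, match="interaction"):
            di.ModelSpec(frozenset({di.TERM_INTERACTION, di.TERM_LOGT}))

    def test_formula_rendering(self):
        spec = di.ModelSpec(frozenset({di.TERM_LOGT, di.TERM_SEX,
                                       di.TERM_INTERACTION}))
        assert spec.formula() == "logT + sexPair + logT:sexPair"
        assert di.ModelSpec().formula() == "1"


class TestAicc:
    def test_direct_formula(self):
        assert di.aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert di.aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            di.aicc(-5.0, 5, 6)

    def test_published_rows_imply_consistent_n(self):
        # two ranked models with (logLik, df, AICc) printed to 0.1; invert
        # the small-sample correction for each and check the implied
        # observation counts overlap
        def n_range(loglik, k, aicc_lo, aicc_hi):
            base = -2 * loglik + 2 * k
            lo = 2 * k * (k + 1) / (aicc_hi - base)
            hi = 2 * k * (k + 1) / (aicc_lo - base)
            return lo + k + 1, hi + k + 1

        r1 = n_range(-155.72, 8, 328.05, 328.15)
        r2 = n_range(-157.03, 7, 328.55, 328.65)
        lo = max(r1[0], r2[0])
        hi = min(r1[1], r2[1])
        assert lo < hi
        assert 200 < lo and hi < 240


class TestWeights:
    def test_equal_aicc_uniform(self):
        w = di.akaike_weights([100.0] * 4)
        assert np.allclose(w, 0.25)

    def test_sum_to_one(self):
        rng = np.random.default_rng(0)
        w = di.akaike_weights(rng.uniform(300, 340, 20))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_delta_ratio(self):
        w = di.akaike_weights([328.1, 328.58])
        assert w[0] / w[1] == pytest.approx(np.exp(0.24))


class TestConfidenceSet:
    def test_single_model(self):
        assert di.confidence_set([1.0]) == 1

    def test_published_weights_keep_nine(self):
        assert di.confidence_set(_full_weight_vector()) == 9

    def test_twenty_equal_weights_keep_nineteen(self):
        assert di.confidence_set(np.full(20, 0.05)) == 19

    def test_empty(self):
        assert di.confidence_set([]) == 0


def _dummy_fit(terms, betas, ses, aicc_val=330.0):
    names = ["(Intercept)", *terms]
    return di.FitResult(
        spec=di.ModelSpec(frozenset(terms)),
        beta=pd.Series(betas, index=names),
        se=pd.Series(ses, index=names),
        sigma_dyad=0.5, sigma_bird=0.5, loglik=-160.0, k=len(names) + 2,
        n=220, aicc=aicc_val, converged=True,
    )


class TestModelAverage:
    def test_single_model_reproduced(self):
        fit = _dummy_fit([di.TERM_LOGT], [2.0, -0.4], [1.0, 0.1])
        out = di.model_average([fit], np.array([1.0])).set_index("term")
        assert out.loc[di.TERM_LOGT, "estimate"] == pytest.approx(-0.4)
        assert out.loc[di.TERM_LOGT, "unconditional_se"] == pytest.approx(0.1)
        assert out.loc[di.TERM_LOGT, "importance"] == pytest.approx(1.0)

    def test_hand_arithmetic_two_models(self):
        f1 = _dummy_fit([di.TERM_LOGT], [0.0, 1.0], [0.5, 0.5])
        f2 = _dummy_fit([di.TERM_LOGT], [0.0, 3.0], [0.5, 0.5])
        out = di.model_average([f1, f2], np.array([0.75, 0.25]),
                               threshold=1.0).set_index("term")
        assert out.loc[di.TERM_LOGT, "estimate"] == pytest.approx(1.5)
        expected_se = 0.75 * np.sqrt(0.25 + 0.25) + 0.25 * np.sqrt(0.25 + 2.25)
        assert out.loc[di.TERM_LOGT, "unconditional_se"] == pytest.approx(
            expected_se)

    def test_published_importances_recovered(self):
        fits = [
            _dummy_fit([di.TERM_LOGT, di.TERM_SEX] if has_sex else [di.TERM_LOGT],
                       [2.8, -0.4, -0.7][: 3 if has_sex else 2],
                       [1.0, 0.15, 1.0][: 3 if has_sex else 2])
            for has_sex in SEX_IN_MODEL
        ] + [_dummy_fit([], [2.8], [1.0]) for _ in range(11)]
        out = di.model_average(fits, _full_weight_vector()).set_index("term")
        assert out.loc[di.TERM_SEX, "importance"] == pytest.approx(0.64, abs=0.005)
        assert out.loc[di.TERM_SEX, "n_models"] == 6
        assert out.loc[di.TERM_LOGT, "importance"] == pytest.approx(1.0)
        assert out.loc[di.TERM_LOGT, "n_models"] == 9

    def test_identical_betas_have_no_spread_term(self):
        f1 = _dummy_fit([di.TERM_LOGT], [2.0, -0.4], [1.0, 0.2])
        f2 = _dummy_fit([di.TERM_LOGT, di.TERM_SEX], [2.0, -0.4, 0.1],
                        [1.0, 0.2, 0.5])
        out = di.model_average([f1, f2], np.array([0.6, 0.4]),
                               threshold=1.0).set_index("term")
        assert out.loc[di.TERM_LOGT, "estimate"] == pytest.approx(-0.4)
        assert out.loc[di.TERM_LOGT, "unconditional_se"] == pytest.approx(0.2)


class TestPredict:
    def _avg(self, b0=2.78, b1=-0.38, s0=1.01, s1=0.14):
        return pd.DataFrame({
            "term": ["(Intercept)", di.TERM_LOGT],
            "estimate": [b0, b1],
            "unconditional_se": [s0, s1],
        })

    def test_hand_value_at_point_estimates(self):
        out = di.predict_probability(self._avg(), [30.0])
        expected = 1 / (1 + np.exp(-(2.78 - 0.38 * np.log(31.0))))
        assert out["probability"].iloc[0] == pytest.approx(expected)

    def test_negative_slope_monotone_decreasing(self):
        out = di.predict_probability(self._avg(), np.arange(0, 120, 5))
        assert (np.diff(out["probability"]) < 0).all()

    def test_zero_slope_constant(self):
        out = di.predict_probability(self._avg(b1=0.0), [0, 10, 100])
        assert out["probability"].nunique() == 1

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            di.predict_probability(self._avg(), [-1.0])

    def test_band_contains_point_estimate(self):
        out = di.predict_probability(self._avg(), [5.0, 50.0])
        assert (out["ci_lower"] < out["probability"]).all()
        assert (out["probability"] < out["ci_upper"]).all()


class TestBuildDyadTable:
    def _trips(self, rows):
        return pd.DataFrame(rows, columns=["bird_id", "trip_index", "t_start",
                                           "t_end", "departure_time"])

    def _deployments(self, birds):
        return pd.DataFrame({
            "bird_id": birds, "colony_id": "LB", "stage": "guard",
            "clutch": 1, "sex": (["F", "M"] * len(birds))[:len(birds)],
            "mass": 1200.0, "flipper": 117.0,
            "nest_lat": -38.55, "nest_lon": 142.92,
            "colony_lat": -38.55, "colony_lon": 142.92,
        })

    def test_single_bird_empty(self):
        trips = self._trips([("a", 0, 1000, 40000, 1000)])
        out = di.build_dyad_table(trips, pd.DataFrame(columns=[
            "bird_a", "bird_b", "t_start", "t_end"]),
            self._deployments(["a"]))
        assert len(out) == 0

    def test_three_birds_one_day_three_rows(self):
        trips = self._trips([(b, 0, 1000, 40000, 1000) for b in "abc"])
        out = di.build_dyad_table(trips, pd.DataFrame(columns=[
            "bird_a", "bird_b", "t_start", "t_end"]),
            self._deployments(list("abc")))
        assert len(out) == 3
        assert set(zip(out["bird_a"], out["bird_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")}

    def test_randomised_schedule_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        rows = []
        for b in [f"b{i}" for i in range(6)]:
            for k in range(rng.integers(1, 4)):
                day = int(rng.integers(0, 5))
                t0 = day * 86400 + int(rng.integers(0, 20000))
                rows.append((b, k, t0, t0 + int(rng.integers(20000, 90000)), t0))
        trips = self._trips(rows)
        out = di.build_dyad_table(trips, pd.DataFrame(columns=[
            "bird_a", "bird_b", "t_start", "t_end"]),
            self._deployments([f"b{i}" for i in range(6)]))
        got = set(zip(out["bird_a"], out["bird_b"], out["day"]))
        assert got == dyad_days_bruteforce(trips)

    def test_association_flag_from_event_intersection(self):
        trips = self._trips([("a", 0, 1000, 40000, 1000),
                             ("b", 0, 2000, 41000, 2000)])
        events = pd.DataFrame([("a", "b", 5000, 6000, 900.0, 100.0)],
                              columns=["bird_a", "bird_b", "t_start", "t_end",
                                       "duration_in_criterion", "mean_distance"])
        out = di.build_dyad_table(trips, events, self._deployments(list("ab")))
        assert out["associated"].iloc[0] == 1
        # departure gap ln(|1000-2000|/60 + 1)
        assert out["log_dt_depart"].iloc[0] == pytest.approx(
            np.log(1000 / 60 + 1))

    def test_orphan_event_bird_rejected(self):
        trips = self._trips([("a", 0, 1000, 40000, 1000)])
        events = pd.DataFrame([("a", "zz", 5000, 6000, 900.0, 100.0)],
                              columns=["bird_a", "bird_b", "t_start", "t_end",
                                       "duration_in_criterion", "mean_distance"])
        with pytest.raises(ValueError, match="zz"):
            di.build_dyad_table(trips, events, self._deployments(["a"]))

    def test_dyad_unit_collapses_days(self):
        trips = self._trips([("a", 0, 1000, 40000, 1000),
                             ("a", 1, 87400, 126400, 87400),
                             ("b", 0, 2000, 41000, 2000),
                             ("b", 1, 88400, 127400, 88400)])
        out = di.build_dyad_table(trips, pd.DataFrame(columns=[
            "bird_a", "bird_b", "t_start", "t_end"]),
            self._deployments(list("ab")), unit="dyad")
        assert len(out) == 1


class TestFitGlmm:
    def test_degenerate_limit_matches_logistic_oracle(self):
        import statsmodels.api as sm

        table = simulate_dyad_obs(0, n_birds=12, n_days=3)
        spec = di.ModelSpec(frozenset({di.TERM_LOGT}))
        fit = di.fit_glmm(table, spec,
                          control=GlmmControl(fix_sigma_dyad=0.0,
                                              fix_sigma_bird=0.0))
        X, _ = di.design_matrix(table, spec)
        ref = sm.Logit(table["associated"].to_numpy(dtype=float), X).fit(disp=0)
        np.testing.assert_allclose(fit.beta.to_numpy(), ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_laplace_close_to_adaptive_quadrature(self):
        rng = np.random.default_rng(5)
        n_groups, m = 10, 5
        groups = np.repeat(np.arange(n_groups), m)
        X = np.column_stack([np.ones(n_groups * m),
                             rng.normal(size=n_groups * m)])
        u = rng.normal(0, 0.8, n_groups)
        eta = 0.3 + 0.6 * X[:, 1] + u[groups]
        y = (rng.uniform(size=n_groups * m) < 1 / (1 + np.exp(-eta))).astype(float)
        Z = build_random_design(groups, np.zeros(len(y), dtype=int),
                                np.zeros(len(y), dtype=int), n_groups, 1)
        for beta, sigma in [((0.3, 0.6), 0.8), ((0.0, 0.5), 0.4),
                            ((-0.2, 0.8), 0.6)]:
            lap = laplace_loglik(y, X, Z, n_groups, sigma, 0.0, np.array(beta))
            agq = agq_logistic_loglik(y, X, groups, np.array(beta), sigma)
            assert lap == pytest.approx(agq, abs=0.1)

    def test_k_counts_fixed_effects_plus_variances(self):
        table = simulate_dyad_obs(1, n_birds=10, n_days=2)
        spec = di.ModelSpec(frozenset({di.TERM_LOGT, di.TERM_SEX}))
        fit = di.fit_glmm(table, spec)
        assert fit.k == 3 + 2

    def test_loglik_never_decreases_with_added_term(self):
        table = simulate_dyad_obs(2, n_birds=14, n_days=3)
        base = di.fit_glmm(table, di.ModelSpec(frozenset({di.TERM_LOGT})))
        bigger = di.fit_glmm(table, di.ModelSpec(
            frozenset({di.TERM_LOGT, di.TERM_COND})))
        assert bigger.loglik >= base.loglik - 1e-4


class TestColonyLmm:
    def _counts(self, seed, contrast=-1.17, sd_bird=0.5, sd_e=1.0,
                n_birds=15, n_trips=4):
        rng = np.random.default_rng(seed)
        rows = []
        for colony, shift in (("LB", 0.0), ("GI", contrast)):
            for i in range(n_birds):
                bird = f"{colony}{i}"
                u = rng.normal(0, sd_bird)
                for k in range(n_trips):
                    rows.append({
                        "bird_id": bird, "colony_id": colony,
                        "n_partners": 2.0 + shift + u + rng.normal(0, sd_e)})
        return pd.DataFrame(rows)

    def test_zero_bird_variance_matches_group_means(self):
        df = self._counts(0, sd_bird=0.0, sd_e=0.3)
        contrast, se, F, p = di.fit_lmm_colony(df)
        means = df.groupby("colony_id")["n_partners"].mean()
        # contrast is the second sorted colony (LB) relative to the first (GI)
        assert contrast == pytest.approx(means["LB"] - means["GI"], abs=0.02)

    def test_contrast_recovered_over_seeds(self):
        # generator puts GI 1.17 associations per trip below LB
        ests = [di.fit_lmm_colony(self._counts(s))[0] for s in range(50)]
        assert np.mean(ests) == pytest.approx(1.17, abs=0.1)

    def test_null_rejection_rate_calibrated(self):
        # permute colony labels at the bird level; the Wald test should
        # reject at roughly its nominal level
        rng = np.random.default_rng(3)
        df = self._counts(1, contrast=0.0)
        birds = df["bird_id"].unique()
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            relabel = dict(zip(birds, rng.permutation(
                df.groupby("bird_id")["colony_id"].first().to_numpy())))
            perm = df.assign(colony_id=df["bird_id"].map(relabel))
            if perm["colony_id"].nunique() < 2:
                continue
            _, _, _, p = di.fit_lmm_colony(perm)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_perm <= 0.07

    def test_single_colony_rejected(self):
        df = self._counts(0)
        with pytest.raises(ValueError):
            di.fit_lmm_colony(df[df["colony_id"] == "LB"])
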