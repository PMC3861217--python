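"""Survival, multiple-comparison, clustering, correlation and growth-model
statistics, each checked against an independent oracle where feasible."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from symbiovar.pheno_stats import (
    HazardEstimates,
    cld_from_significance,
    cluster_variants,
    correlate,
    fit_growth,
    fit_hazard_ratios,
    fit_log_group_effect,
    pairwise_comparisons,
    rank_tests,
    tukey_cld,
    zscale,
)
from symbiovar.synthgen import GrowthConfig, SurvivalConfig, simulate_growth, simulate_survival


# --------------------------------------------------------------------------
# Cox hazard ratios
# --------------------------------------------------------------------------


def _breslow_loglik(beta: float, time, x, event) -> float:
    """Brute-force Cox partial log likelihood (Breslow; exact on tie-free data)."""
    ll = 0.0
    order = np.argsort(time)
    time, x, event = time[order], x[order], event[order]
    for i in range(len(time)):
        if not event[i]:
            continue
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
    return ll


class TestCox:
    def test_null_recovery_within_three_se(self, rng):
        cfg = SurvivalConfig(group_lnhr={"base": 0.0, "other": 0.0}, n_vials=10)
        est = fit_hazard_ratios(simulate_survival(cfg, rng), "base")
        assert abs(est.lnhr[1]) <= 3 * est.se[1]

    def test_planted_ln2_recovery(self, rng):
        cfg = SurvivalConfig(group_lnhr={"base": 0.0, "fast": np.log(2)}, n_vials=10)
        est = fit_hazard_ratios(simulate_survival(cfg, rng), "base")
        assert abs(est.lnhr[1] - np.log(2)) <= 3 * est.se[1]

    def test_matches_brute_force_partial_likelihood(self):
        """On a 20-observation tie-free instance the fitted lnHR agrees with a
        direct maximization of the (Breslow = Efron) partial likelihood."""
        rng = np.random.default_rng(3)
        n = 20
        x = np.repeat([0.0, 1.0], n // 2)
        time = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        assert len(np.unique(time)) == n  # tie-free
        event = np.ones(n, dtype=int)
        records = pd.DataFrame(
            {
                "line": np.where(x > 0, "b", "a"),
                "vial": [f"v{i}" for i in range(n)],
                "experiment": 1,
                "day": time,
                "event": event,
            }
        )
        est = fit_hazard_ratios(records, "a", cluster_policy="none")
        res = minimize_scalar(
            lambda b: -_breslow_loglik(b, time, x, event), bounds=(-5, 5), method="bounded"
        )
        assert est.lnhr[1] == pytest.approx(res.x, abs=1e-3)

    def test_line_without_events_flagged_inestimable(self, rng):
        cfg = SurvivalConfig(group_lnhr={"base": 0.0, "other": 0.0}, n_vials=4)
        rec = simulate_survival(cfg, rng)
        immortal = pd.DataFrame(
            {
                "line": "immortal",
                "vial": "immortal.v1",
                "experiment": 1,
                "day": 60,
                "event": 0,
            },
            index=range(10),
        )
        est = fit_hazard_ratios(pd.concat([rec, immortal], ignore_index=True), "base")
        assert est.inestimable == ["immortal"]
        assert "immortal" not in est.lines

    def test_baseline_without_events_rejected(self, rng):
        cfg = SurvivalConfig(group_lnhr={"base": 0.0, "b": 0.0}, horizon=0, n_vials=2)
        rec = simulate_survival(cfg, rng)
        with pytest.raises(ValueError, match="no events"):
            fit_hazard_ratios(rec, "base")


# --------------------------------------------------------------------------
# compact letter display
# --------------------------------------------------------------------------


def _estimates(lnhr: list[float], se: float = 0.1) -> HazardEstimates:
    k = len(lnhr)
    cov = np.zeros((k, k))
    cov[1:, 1:] = np.eye(k - 1) * se**2
    return HazardEstimates(
        baseline="g0",
        lines=[f"g{i}" for i in range(k)],
        lnhr=np.array(lnhr),
        se=np.sqrt(np.diag(cov)),
        covariance=cov,
    )


class TestCld:
    def test_two_separated_groups_get_distinct_letters(self):
        est = _estimates([0.0, 0.05, 2.0, 2.05], se=0.05)
        letters = tukey_cld(est)
        assert letters["g0"] == letters["g1"]
        assert letters["g2"] == letters["g3"]
        assert set(letters["g0"]) & set(letters["g2"]) == set()

    def test_identical_estimates_share_one_letter(self):
        est = _estimates([0.0, 0.0, 0.0], se=0.5)
        assert set(tukey_cld(est).values()) == {"a"}

    def test_letters_reproduce_significance_matrix(self):
        """Exhaustive consistency on random <=8-group problems: two groups
        share a letter iff their adjusted comparison is non-significant."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 9))
            est = _estimates(list(rng.normal(0, 1.0, size=k)), se=float(rng.uniform(0.05, 0.6)))
            comps = pairwise_comparisons(est)
            letters = tukey_cld(est)
            for row in comps.itertuples(index=False):
                share = bool(set(letters[row.line_1]) & set(letters[row.line_2]))
                assert share != bool(row.significant), (seed, row)

    def test_mc_adjustment_agrees_with_equicorrelation(self):
        """The one-factor approximation should track the exact-correlation
        Monte-Carlo adjustment closely and yield the same decisions."""
        est = _estimates([0.0, 0.4, 1.5], se=0.3)
        eq = pairwise_comparisons(est, method="equicorrelation")
        mc = pairwise_comparisons(est, method="mc")
        assert np.abs(eq["p_adjusted"] - mc["p_adjusted"]).max() < 0.1
        assert (eq["significant"] == mc["significant"]).all()

    def test_adjusted_p_not_smaller_than_raw(self):
        est = _estimates([0.0, 0.3, 0.9, 1.4], se=0.25)
        comps = pairwise_comparisons(est)
        raw = 2 * stats.norm.sf(np.abs(comps["z"]))
        assert (comps["p_adjusted"] >= raw - 1e-12).all()

    def test_insert_absorb_on_hand_built_matrix(self):
        groups = ["a", "b", "c"]
        sig = {("a", "c"): True, ("a", "b"): False, ("b", "c"): False}
        letters = cld_from_significance(groups, sig)
        assert set(letters["a"]) & set(letters["c"]) == set()
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------


class TestRankTests:
    def test_holm_adjustment_dominates_raw(self, rng):
        groups = {g: rng.normal(0, 1, 12) for g in "abcd"}
        out = rank_tests(groups)
        assert (out["pairwise"]["p_holm"] >= out["pairwise"]["p_raw"] - 1e-12).all()
        ordered = out["pairwise"].sort_values("p_raw")
        assert ordered["p_holm"].is_monotonic_increasing

    def test_three_sd_shift_detected(self, rng):
        out = rank_tests({"a": rng.normal(0, 1, 10), "b": rng.normal(3, 1, 10)})
        assert out["two_group_p"] < 0.01

    def test_two_group_p_matches_mann_whitney(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        out = rank_tests({"a": a, "b": b})
        assert out["two_group_p"] == pytest.approx(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests({"a": np.array([1.0]), "b": np.array([])})


# --------------------------------------------------------------------------
# scaling, clustering, correlation
# --------------------------------------------------------------------------


class TestScaleClusterCorrelate:
    def test_zscale_simple_column(self):
        out = zscale(pd.DataFrame({"c": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["c"], [-1.0, 0.0, 1.0])

    def test_zscale_idempotent_and_centered(self, rng):
        m = pd.DataFrame(rng.normal(3, 5, size=(10, 4)), columns=list("wxyz"))
        z1 = zscale(m)
        z2 = zscale(z1)
        assert np.allclose(z1, z2)
        assert np.abs(z1.mean()).max() < 1e-12
        assert np.allclose(z1.std(ddof=1), 1.0)

    def test_zscale_zero_variance_names_column(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscale(m)

    def test_planted_partition_recovered_exactly(self):
        """Two 5-SD-separated phenotype groups are recovered at k=2; verified
        against the exhaustive best 2-partition by max within-group distance."""
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(0, 1, size=(8, 4)), index=[f"v{i}" for i in range(8)])
        m.iloc[4:] += 5.0
        scaled = zscale(m)
        _link, labels = cluster_variants(scaled, k=2)
        got = {frozenset(labels[labels == c].index) for c in (1, 2)}
        # exhaustive search over all 2-partitions, complete-linkage criterion
        rows = list(scaled.index)
        best, best_cost = None, np.inf
        X = scaled.to_numpy()
        for mask in range(1, 2 ** len(rows) - 1):
            part = [{r for i, r in enumerate(rows) if (mask >> i) & 1}]
            part.append(set(rows) - part[0])
            cost = 0.0
            for grp in part:
                idx = [rows.index(r) for r in grp]
                for i, j in itertools.combinations(idx, 2):
                    cost = max(cost, np.linalg.norm(X[i] - X[j]))
            if cost < best_cost:
                best_cost, best = cost, {frozenset(p) for p in part}
        assert got == best
        assert got == {frozenset({"v0", "v1", "v2", "v3"}), frozenset({"v4", "v5", "v6", "v7"})}

    def test_k_equals_n_gives_singletons(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(5, 3)))
        _link, labels = cluster_variants(m, k=5)
        assert labels.nunique() == 5

    def test_column_order_invariance_and_monotone_heights(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(7, 4)), columns=list("abcd"))
        link1, lab1 = cluster_variants(m, k=3)
        link2, lab2 = cluster_variants(m[list("dcba")], k=3)
        assert (lab1 == lab2).all()
        heights = link1[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_correlation_perfect_line(self):
        x = np.arange(10.0)
        out = correlate(x, 2 * x, family_size=4)
        assert out["r"] == pytest.approx(1.0)

    def test_bonferroni_cap_at_one(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        out = correlate(x, y, family_size=1000)
        assert out["p_bonferroni"] <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))

    def test_bonferroni_type_one_error_controlled(self):
        """Independent vectors, family of 4: the adjusted test stays below the
        nominal level across simulations."""
        hits = 0
        n_runs = 1000
        rng = np.random.default_rng(7)
        for _ in range(n_runs):
            x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
            hits += correlate(x, y, family_size=4)["p_bonferroni"] < 0.05
        assert hits / n_runs <= 0.05


# --------------------------------------------------------------------------
# growth models
# --------------------------------------------------------------------------


class TestGrowth:
    def test_noise_free_exponential_closed_form(self, rng):
        cfg = GrowthConfig(
            model="exponential",
            params={"pop": (0.0, 0.204)},
            noise_sd=0.0,
            timepoints=(2, 4, 6, 8, 10, 12),
        )
        fit = fit_growth(simulate_growth(cfg, rng))
        assert fit.preferred == "exponential"
        assert fit.doubling_times["pop"] == pytest.approx(np.log(2) / 0.204, rel=1e-6)

    def test_noise_free_linear_preferred(self, rng):
        cfg = GrowthConfig(model="linear", params={"s": (1.0, 0.1)}, noise_sd=0.0)
        data = simulate_growth(cfg, rng)
        # exact zero residuals break OLS AIC; add negligible jitter
        data["titre"] += rng.normal(0, 1e-6, len(data))
        fit = fit_growth(data)
        assert fit.preferred == "linear"

    def test_flat_series_has_undefined_doubling_time(self, rng):
        cfg = GrowthConfig(model="exponential", params={"s": (1.0, 0.0)}, noise_sd=0.0)
        data = simulate_growth(cfg, rng)
        data["titre"] += rng.normal(0, 1e-9, len(data))
        fit = fit_growth(data)
        assert fit.doubling_times["s"] == np.inf

    def test_slope_contrast_recovery(self, rng):
        """Two-strain linear design with a planted 0.115/day slope contrast is
        recovered within 3 SE of the interaction estimate."""
        cfg = GrowthConfig(
            model="linear",
            params={"mel": (0.72, 0.017), "cs": (1.1, 0.132)},
            noise_sd=0.2,
            timepoints=(0, 10, 20, 30, 40, 50),
            n_replicates=5,
        )
        fit = fit_growth(simulate_growth(cfg, rng), reference_group="mel")
        key = "age:C(group, Treatment('mel'))[T.cs]"
        est = fit.linear.params[key]
        se = fit.linear.bse[key]
        assert abs(est - 0.115) <= 3 * se

    def test_nonpositive_titre_rejected(self):
        df = pd.DataFrame({"strain": "s", "day": [1, 2, 3], "titre": [1.0, -0.5, 2.0]})
        with pytest.raises(ValueError):
            fit_growth(df)


class TestLogGroupEffect:
    def test_twofold_difference_recovered(self, rng):
        rows = []
        for grp, lines in (("mel", list("mnop")), ("cs", list("wxyz"))):
            for ln in lines:
                mu = np.log(2.0) if grp == "mel" else 0.0
                for _ in range(4):
                    rows.append(
                        {"group": grp, "line": ln, "value": float(np.exp(mu + rng.normal(0, 0.3)))}
                    )
        out = fit_log_group_effect(pd.DataFrame(rows))
        assert out["estimator"] == "mixedlm-reml"
        assert abs(out["contrast"] - np.log(2)) <= 3 * out["se"]

    def test_single_replicate_falls_back_to_ols(self, rng):
        rows = [
            {"group": g, "line": f"{g}{i}", "value": float(np.exp(rng.normal()))}
            for g in ("a", "b")
            for i in range(4)
        ]
        with pytest.warns(UserWarning, match="single replicate"):
            out = fit_log_group_effect(pd.DataFrame(rows))
        assert out["estimator"] == "ols"

    def test_null_type_one_error_calibrated(self):
        """Identical groups: the REML group test rejects at roughly the nominal
        rate."""
        rej = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            rows = [
                {"group": g, "line": f"{g}{i}", "value": float(np.exp(rng.normal(0, 0.3)))}
                for g in ("a", "b")
                for i in range(4)
                for _ in range(4)
            ]
            out = fit_log_group_effect(pd.DataFrame(rows))
            rej += out["p"] < 0.05
        assert rej / n_runs <= 0.10
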