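import math

import numpy as np
import pandas as pd
import pytest

from oculokit.stats_classification import (
    GroupModelSpec,
    classify_impairment,
    cohens_d,
    fit_group_model,
    interaction_test,
    multi_metric_impairment_rate,
    pairwise_correlations,
    roc_best_cutoff,
)


def long_rows(rng, n_per_group=12, trials=6, shift=0.0, age_effect=0.0,
              group_ages=(60.0, 60.0), overlap_penalty=(0.0, 0.0)):
    """Two-group long-format fixture with participant-level clustering."""
    rows = []
    for gi, group in enumerate(("a", "b")):
        for p in range(n_per_group):
            age = rng.normal(group_ages[gi], 5.0)
            base = rng.normal(gi * shift + age_effect * age, 1.0)
            for tr in range(trials):
                cond = "gap" if tr % 2 == 0 else "overlap"
                value = base + rng.normal(0.0, 0.5)
                if cond == "overlap":
                    value += overlap_penalty[gi]
                rows.append({
                    "participant_id": f"{group}{p}", "group": group, "age": age,
                    "condition": cond, "value": value,
                })
    return pd.DataFrame(rows)


class TestGroupModel:
    def test_identical_groups_null(self, rng):
        df = long_rows(rng, shift=0.0)
        res = fit_group_model(df, GroupModelSpec(metric_name="m"))
        row = res.contrasts.iloc[0]
        assert abs(row["estimate"]) < 0.5
        assert row["p"] > 0.05

    def test_large_shift_detected(self, rng):
        hits = 0
        for seed in range(30):
            df = long_rows(np.random.default_rng(seed), shift=2.0)
            res = fit_group_model(df, GroupModelSpec(metric_name="m"))
            if res.contrasts.iloc[0]["p"] < 0.05:
                hits += 1
        assert hits >= 29  # ~2 pooled SD shift, n=12/group

    def test_age_confounded_null_adjusted_away(self):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            # metric depends only on age; groups differ in age by 8 years
            df = long_rows(r, n_per_group=40, shift=0.0, age_effect=0.3,
                           group_ages=(58.0, 66.0))
            res = fit_group_model(df, GroupModelSpec(metric_name="m"))
            if res.contrasts.iloc[0]["p"] >= 0.05:
                hits += 1
        assert hits >= 27  # non-significant in >= 90% of replicates

    def test_requires_two_groups(self, rng):
        df = long_rows(rng)
        df = df[df["group"] == "a"]
        with pytest.raises(ValueError, match="2 groups"):
            fit_group_model(df, GroupModelSpec(metric_name="m"))

    def test_rank_deficiency_reported(self, rng):
        df = long_rows(rng)
        df["age2"] = df["age"]  # perfectly collinear copy
        spec = GroupModelSpec(metric_name="m", covariates=("age", "age2"))
        with pytest.raises(ValueError, match="collinear"):
            fit_group_model(df, spec)

    def test_sqrt_transform_applied(self, rng):
        df = long_rows(rng, shift=0.0)
        df["value"] = (df["value"] - df["value"].min() + 1.0) ** 2
        res = fit_group_model(df, GroupModelSpec(metric_name="m", transform="sqrt"))
        assert res.model is not None


class TestInteraction:
    def test_null_interaction_type_one_error(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            df = long_rows(r, overlap_penalty=(0.8, 0.8))  # equal penalty
            res = interaction_test(df, GroupModelSpec(metric_name="m"))
            if res.interaction_pvalue < 0.05:
                hits += 1
        assert hits <= 8  # roughly alpha-level false positives

    def test_differential_penalty_detected(self):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            df = long_rows(r, overlap_penalty=(0.2, 1.6))
            res = interaction_test(df, GroupModelSpec(metric_name="m"))
            if res.interaction_pvalue < 0.05:
                hits += 1
        assert hits >= 27

    def test_label_swap_symmetry(self, rng):
        df = long_rows(rng, overlap_penalty=(0.2, 1.2))
        res1 = interaction_test(df, GroupModelSpec(metric_name="m"))
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"a": "b", "b": "a"})
        res2 = interaction_test(swapped, GroupModelSpec(metric_name="m"))
        c1 = res1.interaction_contrasts.iloc[0]
        c2 = res2.interaction_contrasts.iloc[0]
        assert c1["estimate"] == pytest.approx(-c2["estimate"], rel=1e-6)
        assert c1["p"] == pytest.approx(c2["p"], rel=1e-6)

    def test_empty_cell_reported(self, rng):
        df = long_rows(rng)
        df = df[~((df["group"] == "b") & (df["condition"] == "overlap"))]
        with pytest.raises(ValueError, match="empty design cell"):
            interaction_test(df, GroupModelSpec(metric_name="m"))


class TestCorrelations:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        m = pd.DataFrame({"x": x})
        s = pd.DataFrame({"y": x})
        out = pairwise_correlations(m, s)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r1 = pairwise_correlations(pd.DataFrame({"x": x}),
                                   pd.DataFrame({"y": y}))["r"].iloc[0]
        r2 = pairwise_correlations(pd.DataFrame({"x": 3.0 * x - 7.0}),
                                   pd.DataFrame({"y": -0.5 * y + 2.0}))["r"].iloc[0]
        assert abs(r1) == pytest.approx(abs(r2))

    def test_zero_variance_missing(self, rng):
        m = pd.DataFrame({"x": np.ones(10)})
        s = pd.DataFrame({"y": rng.normal(size=10)})
        out = pairwise_correlations(m, s)
        assert math.isnan(out["r"].iloc[0])

    def test_bonferroni_controls_family_error(self):
        # 12 independent null tests per replicate; family-wise error <= alpha
        fw_errors = 0
        n_rep = 300
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(r.normal(size=(20, 3)), columns=list("abc"))
            s = pd.DataFrame(r.normal(size=(20, 4)), columns=list("wxyz"))
            out = pairwise_correlations(m, s)
            assert len(out) == 12
            if out["significant"].any():
                fw_errors += 1
        assert fw_errors / n_rep <= 0.08


class TestCohensD:
    def test_identical_groups(self, rng):
        x = rng.normal(size=30)
        assert cohens_d(x, x) == 0.0

    def test_unit_difference(self):
        a = np.array([-1.0, 0.0, 1.0])
        b = a + 1.0
        assert cohens_d(b, a) == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30).item())
            b = rng.normal(loc=0.4, size=rng.integers(5, 30).item())
            na, nb = len(a), len(b)
            pooled = math.sqrt(((na - 1) * np.var(a, ddof=1)
                                + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
            assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_zero_pooled_sd_missing(self):
        assert math.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestImpairment:
    CONTROL = {"latency_ms": (200.0, 25.0), "longest_fixation_ms": (5000.0, 1000.0)}

    def test_higher_is_worse(self):
        flags = classify_impairment({"latency_ms": 260.0}, self.CONTROL)
        assert flags["latency_ms"]

    def test_lower_is_worse(self):
        flags = classify_impairment({"longest_fixation_ms": 2500.0}, self.CONTROL)
        assert flags["longest_fixation_ms"]

    def test_exactly_two_sd_not_impaired(self):
        flags = classify_impairment({"latency_ms": 250.0}, self.CONTROL)
        assert not flags["latency_ms"]

    def test_missing_control_stats_error(self):
        with pytest.raises(KeyError):
            classify_impairment({"pursuit_gain": 0.2}, self.CONTROL)

    def test_control_false_positive_rate(self, rng):
        # one-sided 2 SD flags ~2.3% of control-distributed scores
        scores = rng.normal(200.0, 25.0, size=10_000)
        flags = [
            classify_impairment({"latency_ms": s}, self.CONTROL)["latency_ms"]
            for s in scores
        ]
        rate = np.mean(flags)
        assert 0.015 < rate < 0.032  # binomial tolerance around 0.0228

    def test_multi_metric_rate(self):
        flags = pd.DataFrame({
            "a": [True] * 12 + [False] * 3,
            "b": [True] * 12 + [True] * 3,
        })
        assert multi_metric_impairment_rate(flags) == pytest.approx(0.80)

    def test_single_impairment_not_counted(self):
        flags = pd.DataFrame({"a": [True, False], "b": [False, False]})
        assert multi_metric_impairment_rate(flags) == 0.0


def brute_force_roc(scores, labels):
    """Exhaustive sweep over every threshold/direction pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best_acc, best_sens = -1.0, -1.0
    candidates = np.concatenate((
        [-np.inf, np.inf],
        (np.sort(np.unique(scores))[:-1] + np.sort(np.unique(scores))[1:]) / 2.0,
    ))
    for direction in ("greater", "less"):
        for c in candidates:
            pred = scores > c if direction == "greater" else scores < c
            acc = (pred == labels).mean()
            sens = pred[labels].mean()
            if acc > best_acc + 1e-12 or (
                abs(acc - best_acc) <= 1e-12 and sens > best_sens
            ):
                best_acc, best_sens = acc, sens
    return best_acc, best_sens


class TestROC:
    def test_separable(self):
        scores = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        labels = [True, True, True, False, False, False]
        r = roc_best_cutoff(scores, labels)
        assert r.accuracy == 1.0
        assert 3.0 < r.cutoff < 5.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_identical_distributions(self):
        scores = [1.0, 2.0, 3.0] * 2
        labels = [True] * 3 + [False] * 3
        r = roc_best_cutoff(scores, labels)
        assert r.accuracy >= 0.5  # majority-class floor

    def test_accuracy_at_least_prevalence(self, rng):
        for _ in range(50):
            n = rng.integers(4, 30).item()
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc_best_cutoff(scores, labels)
            prevalence = max(labels.mean(), 1 - labels.mean())
            assert r.accuracy >= prevalence - 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = rng.integers(4, 25).item()
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            r = roc_best_cutoff(scores, labels)
            acc, sens = brute_force_roc(scores, labels)
            assert r.accuracy == pytest.approx(acc)
            assert r.sensitivity == pytest.approx(sens)

    def test_one_class_empty_error(self):
        with pytest.raises(ValueError):
            roc_best_cutoff([1.0, 2.0], [True, True])
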