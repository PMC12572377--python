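"""Censored evaluation statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mammorisk.evaluation import (
    age_adjusted_auc,
    bootstrap_ci,
    cohort_filter,
    delong_test,
    horizon_auc,
    km_strata,
    uno_c_index,
    windowed_auc,
)


def records_from(score, event, time, age=None, patient=None, birads=None,
                 biopsy=None):
    n = len(score)
    return pd.DataFrame({
        "patient_id": patient if patient is not None else [f"P{i}" for i in range(n)],
        "exam_id": [f"E{i}" for i in range(n)],
        "score": score,
        "event": np.asarray(event, dtype=bool),
        "time_years": time,
        "age": age if age is not None else np.full(n, 55.0),
        "birads": birads if birads is not None else np.ones(n, dtype=int),
        "prior_bc": np.zeros(n, dtype=bool),
        "biopsy_benign_within_90d": biopsy if biopsy is not None else np.zeros(n, dtype=bool),
    })


def random_cohort(rng, n=None):
    n = n or int(rng.integers(10, 51))
    score = rng.choice(np.round(rng.random(8), 3), size=n)  # forced score ties
    event = rng.random(n) < 0.4
    time = rng.uniform(0.2, 14.0, n)
    return records_from(score, event, time)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def auc_oracle(records, j):
    """O(n^2) pairwise comparison with ties counted 1/2."""
    ev = records["event"].to_numpy(bool)
    t = records["time_years"].to_numpy(float)
    s = records["score"].to_numpy(float)
    pos = np.where(ev & (t <= j))[0]
    neg = np.where(~(ev & (t <= j)) & (t >= j))[0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for i in pos:
        for k in neg:
            wins += 1.0 if s[i] > s[k] else (0.5 if s[i] == s[k] else 0.0)
    return wins / (len(pos) * len(neg))


def km_oracle(time, event, grid):
    """Product-limit estimator by explicit looping."""
    out = []
    surv = 1.0
    prev = 0.0
    times = np.sort(np.unique(time[event]))
    for g in grid:
        surv = 1.0
        for u in times[times <= g]:
            d = np.sum((time == u) & event)
            at_risk = np.sum(time >= u)
            if at_risk > 0:
                surv *= 1.0 - d / at_risk
        out.append(surv)
    return np.array(out)


def uno_oracle(records, tau):
    """Weighted-pair loop: IPCW concordance with KM censoring weights G(t),
    squared weights on pairs anchored at event times below tau."""
    ev = records["event"].to_numpy(bool)
    t = records["time_years"].to_numpy(float)
    s = records["score"].to_numpy(float)
    # KM of the censoring distribution (events are "censored" observations
    # of the censoring time, so the roles flip)
    n = len(t)

    def G(x):
        surv = 1.0
        for u in np.sort(np.unique(t[~ev])):
            if u > x:
                break
            d = np.sum((t == u) & ~ev)
            at_risk = np.sum(t >= u)
            if at_risk > 0:
                surv *= 1.0 - d / at_risk
        return surv

    num = den = 0.0
    for i in range(n):
        if not ev[i] or t[i] >= tau:
            continue
        w = G(t[i]) ** -2
        for k in range(n):
            if t[k] > t[i]:
                den += w
                if s[i] > s[k]:
                    num += w
                elif s[i] == s[k]:
                    num += 0.5 * w
    return num / den if den > 0 else None


# ---------------------------------------------------------------------------
# horizon / windowed AUC
# ---------------------------------------------------------------------------

class TestHorizonAuc:
    def test_perfect_ranking(self):
        df = records_from([0.9, 0.8, 0.1], [True, False, False],
                          [0.5, 12.0, 11.0])
        assert horizon_auc(df, 10) == 1.0

    def test_all_ties_give_half(self):
        df = records_from([0.5] * 6, [True, True, False, False, False, False],
                          [1.0, 2.0, 12, 12, 12, 12])
        assert horizon_auc(df, 10) == 0.5

    def test_undefined_reported_absent(self):
        df = records_from([0.1, 0.2], [False, False], [12.0, 13.0])
        assert horizon_auc(df, 10) is None

    def test_censored_before_horizon_excluded(self):
        # censored at 3y w/o event: not a valid 10y control
        df = records_from([0.9, 0.95, 0.1], [True, False, False],
                          [2.0, 3.0, 12.0])
        assert horizon_auc(df, 10) == 1.0

    def test_matches_pairwise_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(200):
            df = random_cohort(rng)
            for j in (2, 5, 10):
                expect = auc_oracle(df, j)
                got = horizon_auc(df, j)
                if expect is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expect, abs=1e-12)
                    checked += 1
        assert checked > 300

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        df = random_cohort(rng, n=40)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert horizon_auc(df, 5) == pytest.approx(horizon_auc(shuffled, 5), abs=1e-12)


class TestWindowedAuc:
    def test_zero_lower_edge_reduces_to_horizon(self):
        rng = np.random.default_rng(5)
        df = random_cohort(rng, n=40)
        assert windowed_auc(df, 0, 5) == pytest.approx(horizon_auc(df, 5), abs=1e-15)

    def test_only_case_inside_window_dropped_gives_undefined(self):
        df = records_from([0.9, 0.2, 0.3], [True, False, False],
                          [0.5, 8.0, 9.0])
        assert windowed_auc(df, 1, 5) is None

    def test_matches_filter_then_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            df = random_cohort(rng)
            a = 1.0
            keep = ~(df["event"] & (df["time_years"] <= a))
            expect = auc_oracle(df.loc[keep], 5)
            got = windowed_auc(df, a, 5)
            if expect is None:
                assert got is None
            else:
                assert got == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# Uno's C
# ---------------------------------------------------------------------------

class TestUnoC:
    def test_anticoncordant_scores_give_zero(self):
        df = records_from([0.1, 0.2, 0.3, 0.4], [True] * 4, [1, 2, 3, 4])
        assert uno_c_index(df, tau=10).cindex == pytest.approx(0.0)

    def test_matches_weighted_pair_loop_oracle(self):
        rng = np.random.default_rng(41)
        n_checked = 0
        for _ in range(30):
            df = random_cohort(rng, n=50)
            # continuous times avoid convention differences on exact ties
            df["time_years"] = rng.uniform(0.2, 14.0, len(df))
            expect = uno_oracle(df, tau=10.0)
            if expect is None:
                continue
            got = uno_c_index(df, tau=10.0)
            assert got.ipcw
            assert got.cindex == pytest.approx(expect, abs=1e-10)
            n_checked += 1
        assert n_checked >= 20

    def test_permutation_null_is_half(self):
        rng = np.random.default_rng(2)
        df = random_cohort(rng, n=60)
        df["time_years"] = rng.uniform(0.2, 14.0, len(df))
        vals = []
        for _ in range(100):
            d2 = df.copy()
            d2["score"] = rng.permutation(d2["score"].to_numpy())
            vals.append(uno_c_index(d2, tau=10.0).cindex)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_censoring_falls_back_to_harrell(self):
        # no events at all -> IPCW estimator undefined
        df = records_from([0.5, 0.4, 0.3], [False] * 3, [5.0, 6.0, 7.0])
        with pytest.raises(ValueError):
            uno_c_index(df, tau=10)


# ---------------------------------------------------------------------------
# age-adjusted AUC
# ---------------------------------------------------------------------------

class TestAgeAdjustedAuc:
    def test_constant_age_reduces_to_plain_auc(self):
        rng = np.random.default_rng(6)
        df = random_cohort(rng, n=60)
        aauc = age_adjusted_auc(df, 10)
        auc = horizon_auc(df, 10)
        assert aauc == pytest.approx(auc, abs=1e-6)

    def test_age_confounded_score_adjusts_to_chance(self):
        """score = age + noise and hazard driven by age alone: the plain AUC
        is inflated, the adjusted AUC sits near 0.5."""
        rng = np.random.default_rng(0)
        plain, adjusted = [], []
        for _ in range(10):
            n = 400
            age = rng.uniform(40, 75, n)
            score = age / 100 + rng.normal(0, 0.02, n)
            p_event = (age - 30) / 90
            event = rng.random(n) < p_event
            time = np.where(event, rng.uniform(0.5, 9.5, n), rng.uniform(10.5, 15, n))
            df = records_from(score, event, time, age=age)
            plain.append(horizon_auc(df, 10))
            adjusted.append(age_adjusted_auc(df, 10))
        assert np.mean(plain) > 0.55
        assert abs(np.mean(adjusted) - 0.5) < 0.05

    def test_perfect_within_age_separation_gives_one(self):
        n = 60
        rng = np.random.default_rng(1)
        age = np.repeat([45.0, 60.0], n // 2)
        event = np.tile([True, False, False], n // 3)
        score = age / 100 + np.where(event, 0.5, 0.0)
        time = np.where(event, 1.0, 12.0)
        df = records_from(score, event, time, age=age)
        assert age_adjusted_auc(df, 10) == pytest.approx(1.0)

    def test_too_few_controls_refused(self):
        df = records_from([0.5, 0.1, 0.2], [True, False, False], [1.0, 12, 12])
        with pytest.raises(ValueError, match="controls"):
            age_adjusted_auc(df, 10)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        delta, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_swap_negates_delta_keeps_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(80), rng.random(80)
        y = (rng.random(80) < 0.5).astype(int)
        d1, p1 = delong_test(a, b, y)
        d2, p2 = delong_test(b, a, y)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_agrees_with_paired_bootstrap_reference(self):
        """DeLong p vs a large paired-bootstrap null on n=100 paired scores."""
        rng = np.random.default_rng(7)
        n = 100
        y = np.array([1] * 40 + [0] * 60)
        latent = rng.normal(size=n) + 0.8 * y
        a = latent + rng.normal(0, 0.8, n)
        b = latent + rng.normal(0, 1.1, n)
        delta, p = delong_test(a, b, y)

        n_boot = 100_000
        idx = rng.integers(0, n, size=(n_boot, n))
        from scipy.stats import rankdata
        deltas = np.empty(n_boot)
        kept = 0
        for i in range(n_boot):
            ii = idx[i]
            yy = y[ii]
            m = yy.sum()
            if m == 0 or m == n:
                continue
            ra = rankdata(a[ii])
            rb = rankdata(b[ii])
            auc_a = (ra[yy == 1].sum() - m * (m + 1) / 2) / (m * (n - m))
            auc_b = (rb[yy == 1].sum() - m * (m + 1) / 2) / (m * (n - m))
            deltas[kept] = auc_a - auc_b
            kept += 1
        deltas = deltas[:kept]
        # bootstrap two-sided p: is 0 in the tail of the resampled deltas?
        frac = min(np.mean(deltas <= 0), np.mean(deltas >= 0))
        p_boot = 2 * frac
        se = 2 * np.sqrt(frac * (1 - frac) / kept)
        # agreement within the Monte-Carlo CI plus estimator slack
        assert abs(p - p_boot) < max(5 * se, 0.25 * max(p, p_boot), 0.02)


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        df = records_from([0.1, 0.2, 0.3], [True, False, False], [1, 12, 12])
        lo, hi = bootstrap_ci(lambda d: 7.25, df, n_boot=50, seed=0)
        assert lo == hi == 7.25

    def test_auc_interval_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        df = random_cohort(rng, n=80)
        df["score"] = df["score"] + df["event"] * 0.3  # informative scores
        point = horizon_auc(df, 10)
        lo, hi = bootstrap_ci(lambda d: horizon_auc(d, 10), df,
                              n_boot=300, seed=1)
        assert lo <= point <= hi

    def test_normal_mean_matches_closed_form(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(3.0, 1.0, n)
        df = records_from(x, np.zeros(n, bool), np.full(n, 12.0))
        lo, hi = bootstrap_ci(lambda d: d["score"].mean(), df,
                              n_boot=1000, seed=2)
        se = x.std(ddof=1) / np.sqrt(n)
        lo_cf, hi_cf = x.mean() - 1.96 * se, x.mean() + 1.96 * se
        assert (hi - lo) == pytest.approx(hi_cf - lo_cf, rel=0.05)

    def test_mostly_undefined_statistic_refused(self):
        df = records_from([0.1, 0.2, 0.3], [True, False, False], [1, 12, 12])
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(lambda d: None, df, n_boot=20, seed=0)

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(10)
        df = random_cohort(rng, n=40)
        f = lambda d: horizon_auc(d, 5)
        assert bootstrap_ci(f, df, n_boot=100, seed=4) == \
            bootstrap_ci(f, df, n_boot=100, seed=4)


# ---------------------------------------------------------------------------
# KM percentile strata
# ---------------------------------------------------------------------------

class TestKmStrata:
    def test_group_sizes_on_distinct_uniform_scores(self):
        rng = np.random.default_rng(11)
        score = rng.permutation(np.linspace(0.01, 0.99, 100))
        event = rng.random(100) < 0.3
        time = np.where(event, rng.uniform(0.5, 9.5, 100), rng.uniform(1, 15, 100))
        df = records_from(score, event, time)
        out = km_strata(df)
        assert [g["n"] for g in out["groups"]] == [10, 40, 40, 10]

    def test_pct_of_all_cancers_sums_to_hundred(self):
        rng = np.random.default_rng(12)
        df = random_cohort(rng, n=80)
        if not (df["event"] & (df["time_years"] <= 10)).any():
            df.loc[0, "event"] = True
            df.loc[0, "time_years"] = 2.0
        out = km_strata(df)
        assert sum(g["pct_of_all_cancers"] for g in out["groups"]) == pytest.approx(100.0)

    def test_no_events_gives_flat_km(self):
        rng = np.random.default_rng(13)
        score = rng.random(30)
        df = records_from(score, np.zeros(30, bool), np.full(30, 12.0))
        out = km_strata(df)
        for g in out["groups"]:
            np.testing.assert_allclose(g["km_survival"], 1.0)

    def test_km_matches_product_limit_oracle(self):
        rng = np.random.default_rng(14)
        df = random_cohort(rng, n=30)
        out = km_strata(df)
        event = df.sort_values(["score", "patient_id", "exam_id"],
                               kind="mergesort").reset_index(drop=True)
        # group 2 covers rows 3..14 (10%..50% of 30)
        lo, hi = round(0.1 * 30), round(0.5 * 30)
        t = event["time_years"].to_numpy(float)[lo:hi]
        e = event["event"].to_numpy(bool)[lo:hi]
        e10 = e & (t <= 10.0)
        t10 = np.minimum(t, 10.0)
        g = out["groups"][1]
        expect = km_oracle(t10, e10, g["km_times"])
        np.testing.assert_allclose(g["km_survival"], expect, atol=1e-12)

    def test_tie_handling_is_deterministic(self):
        score = np.full(20, 0.5)
        rng = np.random.default_rng(15)
        event = rng.random(20) < 0.3
        time = rng.uniform(0.5, 14, 20)
        df = records_from(score, event, time)
        a = km_strata(df)
        b = km_strata(df.sample(frac=1.0, random_state=3).reset_index(drop=True))
        assert [g["n_cancers"] for g in a["groups"]] == \
            [g["n_cancers"] for g in b["groups"]]

    def test_too_few_records_rejected(self):
        df = records_from([0.1] * 5, [False] * 5, [12.0] * 5)
        with pytest.raises(ValueError):
            km_strata(df)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

class TestCohortFilter:
    def make(self):
        df = records_from(
            score=[0.1, 0.2, 0.3, 0.4],
            event=[False] * 4,
            time=[12.0] * 4,
            age=[30.0, 50.0, 80.0, 60.0],
            birads=[4, 1, 2, 0],
            biopsy=[True, False, False, False],
        )
        df.loc[3, "prior_bc"] = True
        return df

    def test_definitions(self):
        df = self.make()
        s1 = cohort_filter(df, "screening1")
        # BI-RADS 4 + benign biopsy within 90d is included in screening1...
        assert "E0" in set(s1["exam_id"])
        # ...but excluded from screening2 (BI-RADS 0/1/2 only)
        s2 = cohort_filter(df, "screening2")
        assert "E0" not in set(s2["exam_id"])
        assert set(s2["exam_id"]) == {"E1", "E2", "E3"}
        rec = cohort_filter(df, "recurrence")
        assert set(rec["exam_id"]) == {"E3"}
        bcsc = cohort_filter(df, "bcsc_eligible")
        # age 30 and 80 out of range; prior-BC row excluded
        assert set(bcsc["exam_id"]) == {"E1"}

    def test_idempotent(self):
        df = self.make()
        for which in ("screening1", "screening2", "recurrence", "bcsc_eligible"):
            once = cohort_filter(df, which)
            twice = cohort_filter(once, which)
            pd.testing.assert_frame_equal(once, twice)

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_filter(self.make(), "nope")
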