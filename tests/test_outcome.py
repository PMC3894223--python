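"""Burden groups, Kaplan–Meier/log-rank, Cox screening, covariate tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnaburden as cb
from oracles import fisher_2x2_two_sided, logrank_chi2, quantile_type6


def _survival_table(times, events, groups):
    return pd.DataFrame({"time": times, "event": events, "group": groups})


# ---------------------------------------------------------------------------
# burden groups
# ---------------------------------------------------------------------------

def test_quartile_toy_example():
    counts = pd.Series([1, 2, 3, 4], index=list("abcd"))
    g = cb.assign_burden_groups(counts).set_index("sample_id")["group"]
    assert g["a"] == "low" and g["d"] == "high"
    assert g["b"] == g["c"] == "intermediate"


def test_41_distinct_counts_split_10_21_10(rng):
    counts = pd.Series(rng.permutation(np.arange(1, 42) * 7 + 11),
                       index=[f"S{i}" for i in range(41)])
    groups = cb.assign_burden_groups(counts)
    sizes = groups["group"].value_counts()
    assert (sizes["low"], sizes["intermediate"], sizes["high"]) == (10, 21, 10)


@pytest.mark.parametrize("seed", range(20))
def test_group_assignment_matches_rank_oracle(seed):
    rng = np.random.default_rng(seed)
    counts = pd.Series(rng.integers(5, 400, size=rng.integers(5, 60)))
    counts.index = [f"S{i}" for i in range(len(counts))]
    if counts.nunique() == 1:
        return
    groups = cb.assign_burden_groups(counts)
    q1 = quantile_type6(counts.to_numpy(), 0.25)
    q3 = quantile_type6(counts.to_numpy(), 0.75)
    assert groups["q1"].iloc[0] == pytest.approx(q1)
    assert groups["q3"].iloc[0] == pytest.approx(q3)
    for _, row in groups.iterrows():
        c = row["total_cna_count"]
        expected = "low" if c <= q1 else ("high" if c >= q3 else "intermediate")
        assert row["group"] == expected


def test_group_assignment_shift_invariant(rng):
    counts = pd.Series(rng.integers(10, 300, size=41),
                       index=[f"S{i}" for i in range(41)])
    if counts.nunique() == 1:
        counts.iloc[0] += 1
    a = cb.assign_burden_groups(counts).set_index("sample_id")["group"]
    b = cb.assign_burden_groups(counts + 1000).set_index("sample_id")["group"]
    assert (a == b).all()


def test_degenerate_groupings_rejected():
    with pytest.raises(ValueError, match="identical"):
        cb.assign_burden_groups(pd.Series([5, 5, 5, 5]))
    with pytest.raises(ValueError, match="at least 4"):
        cb.assign_burden_groups(pd.Series([1, 2, 3]))


# ---------------------------------------------------------------------------
# endpoint preparation
# ---------------------------------------------------------------------------

def test_perioperative_deaths_excluded_from_os_only():
    groups = pd.Series(["low"] * 10 + ["intermediate"] * 21 + ["high"] * 10,
                       index=[f"S{i:02d}" for i in range(41)])
    clinical = cb.simulate_clinical(groups, cb.SurvivalSpec(), seed=17)
    os_tab = cb.prepare_survival(clinical, "os")
    rec_tab = cb.prepare_survival(clinical, "recurrence")
    assert len(os_tab) == 39
    assert len(rec_tab) == 41
    clean = cb.simulate_clinical(groups, cb.SurvivalSpec(n_perioperative=0),
                                 seed=17)
    assert len(cb.prepare_survival(clean, "os")) == 41


def test_negative_times_rejected():
    groups = pd.Series(["low", "high", "low", "high"], index=list("abcd"))
    clinical = cb.simulate_clinical(groups, seed=3)
    clinical.loc[0, "os_time"] = -1.0
    with pytest.raises(ValueError, match="negative"):
        cb.prepare_survival(clinical, "os")


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank
# ---------------------------------------------------------------------------

def test_km_steps_without_censoring():
    """With n distinct event times and no censoring, KM drops by 1/n."""
    tab2 = _survival_table([1, 2, 3, 4, 5, 9], [1] * 6, ["g"] * 3 + ["h"] * 3)
    res = cb.km_logrank(tab2)
    curve = res.curves["g"]
    surv = curve.set_index("time")["survival"]
    np.testing.assert_allclose(surv.loc[[1, 2, 3]], [2 / 3, 1 / 3, 0.0])


def test_logrank_matches_expected_event_accounting():
    """Two-group toy (1,2,3 vs 2,4,6, all events) against the hand oracle."""
    tab = _survival_table([1, 2, 3, 2, 4, 6], [1] * 6,
                          ["a"] * 3 + ["b"] * 3)
    res = cb.km_logrank(tab)
    expected = logrank_chi2([1, 2, 3], [1, 1, 1], [2, 4, 6], [1, 1, 1])
    assert res.logrank_stat == pytest.approx(expected, abs=1e-8)
    assert expected == pytest.approx(2.24433, abs=1e-4)   # frozen from the oracle
    assert res.logrank_df == 1


def test_logrank_invariant_under_monotone_time_transform(rng):
    times = rng.exponential(10, 40).round(3) + 0.01
    events = rng.uniform(size=40) < 0.7
    groups = np.where(rng.uniform(size=40) < 0.5, "a", "b")
    t1 = _survival_table(times, events.astype(int), groups)
    t2 = _survival_table(times ** 2, events.astype(int), groups)
    r1, r2 = cb.km_logrank(t1), cb.km_logrank(t2)
    assert r1.logrank_stat == pytest.approx(r2.logrank_stat)


def test_km_matches_exponential_closed_form(rng):
    lam = 0.05
    n = 2000
    death = rng.exponential(1 / lam, n)
    censor = rng.uniform(5, 40, n)
    tab = _survival_table(np.minimum(death, censor),
                          (death <= censor).astype(int), ["g"] * n)
    res = cb.km_logrank(pd.concat([
        tab, _survival_table([1.0], [1], ["h"])], ignore_index=True))
    curve = res.curves["g"]
    for t in (5.0, 10.0, 20.0):
        s_hat = curve.loc[curve["time"] <= t, "survival"].iloc[-1]
        assert abs(s_hat - np.exp(-lam * t)) < 0.03


def test_intermediate_group_has_worst_curve_in_most_replicates():
    """Default hazards, 10/21/10 split: the intermediate KM curve sits lowest
    at the typical follow-up time in >= 80% of replicates."""
    groups = pd.Series(["low"] * 10 + ["intermediate"] * 21 + ["high"] * 10,
                       index=[f"S{i:02d}" for i in range(41)])
    wins = 0
    n_rep = 60
    for rep in range(n_rep):
        clinical = cb.simulate_clinical(groups, cb.SurvivalSpec(), seed=5000 + rep)
        tab = cb.prepare_survival(clinical, "os")
        tab = tab.merge(groups.rename("group"), left_on="sample_id",
                        right_index=True)
        res = cb.km_logrank(tab)
        at_46 = {}
        for g, curve in res.curves.items():
            below = curve[curve["time"] <= 46.0]
            at_46[g] = below["survival"].iloc[-1] if len(below) else 1.0
        wins += at_46["intermediate"] <= min(at_46.values()) + 1e-12
    assert wins >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def test_cox_null_indicator_recovers_unity(rng):
    groups = pd.Series(["low"] * 1000 + ["intermediate"] * 1000,
                       index=[f"S{i}" for i in range(2000)])
    clinical = cb.simulate_clinical(groups, cb.SurvivalSpec(
        hr_intermediate=1.0, n_perioperative=0, censor_window=(100., 140.)),
        seed=77)
    tab = cb.prepare_survival(clinical, "os")
    tab["intermediate"] = (groups.to_numpy() == "intermediate").astype(int)
    res = cb.cox_model(tab, covariates=())
    assert 0.7 < res.univariate["intermediate"].hr < 1.4


def test_cox_recovers_true_hazard_ratio_large_n():
    groups = pd.Series(["low"] * 2000 + ["intermediate"] * 2000,
                       index=[f"S{i}" for i in range(4000)])
    clinical = cb.simulate_clinical(groups, cb.SurvivalSpec(
        n_perioperative=0, censor_window=(100., 140.)), seed=42)
    tab = cb.prepare_survival(clinical, "os")
    tab["intermediate"] = (groups.to_numpy() == "intermediate").astype(int)
    res = cb.cox_model(tab, covariates=())
    term = res.univariate["intermediate"]
    assert abs(term.hr - 3.7) / 3.7 < 0.10
    assert term.ci_low < 3.7 < term.ci_high


def test_cox_screening_keeps_only_small_p_covariates(rng):
    n = 400
    x_signal = rng.uniform(size=n)
    x_noise = rng.uniform(size=n)
    death = rng.exponential(1 / (0.02 * np.exp(1.5 * x_signal)))
    censor = np.full(n, 80.0)
    tab = pd.DataFrame({
        "time": np.minimum(death, censor),
        "event": (death <= censor).astype(int),
        "flag": rng.integers(0, 2, n),
        "x_signal": x_signal, "x_noise": x_noise,
    })
    res = cb.cox_model(tab, indicator="flag",
                       covariates=("x_signal", "x_noise"))
    scr = res.screening.set_index("covariate")
    assert bool(scr.loc["x_signal", "retained"])
    assert scr.loc["x_signal", "univariate_p"] < 0.2
    assert "x_signal" in res.multivariate


def test_cox_rejects_non_binary_indicator():
    tab = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [1, 0, 1, 1],
                        "flag": [0, 1, 2, 1]})
    with pytest.raises(ValueError, match="binary"):
        cb.cox_model(tab, indicator="flag", covariates=())


# ---------------------------------------------------------------------------
# group-covariate tests and correlations
# ---------------------------------------------------------------------------

def test_identical_group_distributions_are_not_flagged():
    """Literally identical covariate distributions across groups -> p ~ 1."""
    base = cb.simulate_clinical(
        pd.Series(["low"] * 50, index=[f"A{i}" for i in range(50)]), seed=9)
    frames = []
    for g, prefix in (("low", "A"), ("intermediate", "B"), ("high", "C")):
        f = base.copy()
        f["sample_id"] = [f"{prefix}{i}" for i in range(50)]
        frames.append(f.assign(_group=g))
    clinical = pd.concat(frames, ignore_index=True)
    groups = clinical[["sample_id", "_group"]].rename(columns={"_group": "group"})
    res = cb.group_covariate_tests(clinical.drop(columns="_group"), groups)
    informative = res[res["test"].isin(["chi2", "kruskal"])]
    assert (informative["p"] > 0.9).all()


def test_exact_2x2_equals_hypergeometric_enumeration():
    clinical = cb.simulate_clinical(
        pd.Series(["low"] * 8 + ["high"] * 8, index=[f"S{i}" for i in range(16)]),
        seed=21)
    groups = pd.DataFrame({"sample_id": clinical["sample_id"],
                           "group": ["low"] * 8 + ["high"] * 8})
    res = cb.group_covariate_tests(clinical, groups).set_index("covariate")
    row = res.loc["angioinvasion"]
    assert row["test"] == "fisher_exact"
    tab = pd.crosstab(groups["group"], clinical["angioinvasion"]).to_numpy()
    assert row["p"] == pytest.approx(fisher_2x2_two_sided(tab))


def test_covariates_independent_of_group_rarely_significant():
    groups = pd.Series(["low"] * 10 + ["intermediate"] * 21 + ["high"] * 10,
                       index=[f"S{i:02d}" for i in range(41)])
    sig = 0
    n_tests = 0
    for rep in range(15):
        clinical = cb.simulate_clinical(groups, cb.SurvivalSpec(), seed=300 + rep)
        gdf = pd.DataFrame({"sample_id": clinical["sample_id"],
                            "group": groups.to_numpy()})
        res = cb.group_covariate_tests(clinical, gdf, seed=rep)
        main = res[res["test"].isin(["chi2", "fisher_exact", "exact_mc", "kruskal"])]
        sig += (main["p"] < 0.05).sum()
        n_tests += main["p"].notna().sum()
    assert sig / n_tests < 0.12          # ~5% expected under independence


def test_correlation_identity_and_zero_variance_flag():
    tab = pd.DataFrame({"total_cna_count": [3, 7, 11, 20],
                        "gain_count": [3, 7, 11, 20],
                        "loss_count": [0, 0, 0, 0]})
    res = cb.correlate_counts(tab).set_index("variable")
    assert res.loc["gain_count", "pearson_r"] == pytest.approx(1.0)
    assert np.isnan(res.loc["loss_count", "pearson_r"])
    assert "zero variance" in res.loc["loss_count", "note"]


def test_correlation_matches_covariance_formula(rng):
    total = rng.integers(10, 400, 30).astype(float)
    other = total * 0.6 + rng.normal(0, 20, 30)
    tab = pd.DataFrame({"total_cna_count": total, "gain_count": other})
    res = cb.correlate_counts(tab).set_index("variable")
    x, y = total, other
    r_manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert res.loc["gain_count", "pearson_r"] == pytest.approx(r_manual)


def test_simulated_cohort_counts_correlate_with_direction_counts():
    cohort = cb.simulate_cohort(cb.CohortSpec(n_tumors=41, count_range=(11, 200),
                                              recurrent_loci=[]),
                                cb.toy_genome(0.5), seed=31)
    events = cb.call_cnas(cohort.segments,
                          chromosomes=tuple(cohort.genome.chrom_lengths))
    burden = cb.burden_table(events)
    tab = burden.set_index("sample_id")[["total_cna_count", "gain_count",
                                         "loss_count"]]
    res = cb.correlate_counts(tab).set_index("variable")
    assert res.loc["gain_count", "pearson_r"] > 0.8
    assert res.loc["loss_count", "pearson_r"] > 0.8
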