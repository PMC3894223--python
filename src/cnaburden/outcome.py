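"""Burden-group stratification and survival / covariate analyses.

Tumors are split by their total CNA count into three groups — low (lowest
quartile), high (highest quartile) and intermediate (middle two quartiles) —
and the groups are compared by Kaplan–Meier curves with the log-rank test
and by Cox proportional-hazards models. The Cox analysis is built around a
binary intermediate-vs-rest indicator (the non-monotonic burden–outcome
pattern: intermediate burden carries the elevated hazard); candidate
covariates are screened into the multivariate model by their own univariate
p-value < 0.2.

Quartile cuts use the SPSS-style weighted-average empirical quantile
(Hyndman–Fan type 6); with ties crossing a cut, assignment is
boundary-inclusive (count <= Q1 -> low, count >= Q3 -> high). On a 41-sample
vector of distinct counts this rule yields the 10 / 21 / 10 split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

GROUP_ORDER = ("low", "intermediate", "high")

#: Candidate Cox covariates screened at p < 0.2 (numeric encodings).
DEFAULT_COX_CANDIDATES = ("age", "n_positive", "angioinvasion_flag",
                          "tumor_size", "grade_pd", "ln_resected")


# ---------------------------------------------------------------------------
# Burden groups
# ---------------------------------------------------------------------------

def assign_burden_groups(counts: pd.Series,
                         quantile_method: str = "weibull") -> pd.DataFrame:
    """Assign low / intermediate / high burden groups by count quartiles.

    ``quantile_method`` is a numpy quantile method name; the default
    ("weibull", Hyndman–Fan type 6) matches SPSS's weighted-average rule.
    Raises when all counts are identical (grouping undefined) or n < 4.
    """
    if len(counts) < 4:
        raise ValueError("need at least 4 samples to form quartile groups")
    vals = counts.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all counts identical; burden grouping undefined")
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=quantile_method)
    group = np.where(vals <= q1, "low", np.where(vals >= q3, "high", "intermediate"))
    return pd.DataFrame({
        "sample_id": counts.index.astype(str),
        "total_cna_count": counts.to_numpy(),
        "group": group, "q1": q1, "q3": q3,
    })


# ---------------------------------------------------------------------------
# Survival preparation
# ---------------------------------------------------------------------------

def encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add numeric covariate encodings used by the Cox models."""
    out = clinical.copy()
    out["n_positive"] = (out["n_stage"] != "N0").astype(int)
    out["grade_pd"] = (out["grade"] == "PD").astype(int)
    out["angioinvasion_flag"] = out["angioinvasion"].astype(int)
    out["t1b_plus"] = (out["t_stage"] != "T1a").astype(int)
    return out


def prepare_survival(clinical: pd.DataFrame, endpoint: str = "os",
                     burden: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Build the analysis table for one endpoint.

    ``os``: time/event from overall survival; patients flagged as
    perioperative deaths within 3 months of surgery are excluded.
    ``recurrence``: time to first recurrence, censored at the last clinical
    evaluation; the perioperative exclusion does not apply.
    Merges burden-group assignments when given.
    """
    if endpoint not in ("os", "recurrence"):
        raise ValueError("endpoint must be 'os' or 'recurrence'")
    df = encode_covariates(clinical)
    if (df["os_time"] < 0).any() or (df["rec_time"] < 0).any():
        raise ValueError("negative survival times")
    if endpoint == "os":
        keep = ~(df["perioperative_death"] & (df["os_time"] <= 3.0))
        df = df[keep].copy()
        df["time"] = df["os_time"]
        df["event"] = df["os_event"].astype(int)
    else:
        df = df.copy()
        df["time"] = df["rec_time"]
        df["event"] = df["rec_event"].astype(int)
    if burden is not None:
        df = df.merge(burden[["sample_id", "group", "total_cna_count"]],
                      on="sample_id", how="inner")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    """KM curves per group plus the k-group log-rank test."""
    curves: dict[str, pd.DataFrame]       # group -> (time, at_risk, survival)
    logrank_stat: float
    logrank_df: int
    logrank_p: float


def km_logrank(table: pd.DataFrame, group_col: str = "group",
               time_col: str = "time", event_col: str = "event") -> SurvivalResult:
    """Product-limit curves per group and the k-group log-rank chi-square."""
    groups_present = [g for g in GROUP_ORDER if g in set(table[group_col])]
    groups_present += [g for g in sorted(set(table[group_col]))
                       if g not in groups_present]
    curves = {}
    used = []
    for g in groups_present:
        sub = table[table[group_col] == g]
        if len(sub) == 0:
            warnings.warn(f"group {g!r} has no subjects; dropped")
            continue
        used.append(g)
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[g] = pd.DataFrame({
            "time": tab.index.to_numpy(float),
            "at_risk": tab["at_risk"].to_numpy(int),
            "survival": surv.reindex(tab.index).to_numpy(float),
        })
    if len(used) < 2:
        raise ValueError("need at least 2 non-empty groups for the log-rank test")
    sub = table[table[group_col].isin(used)]
    if int(sub[event_col].sum()) < 1:
        raise ValueError("need at least one event for the log-rank test")
    res = multivariate_logrank_test(sub[time_col], sub[group_col], sub[event_col])
    return SurvivalResult(curves=curves,
                          logrank_stat=float(res.test_statistic),
                          logrank_df=len(used) - 1,
                          logrank_p=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards with covariate screening
# ---------------------------------------------------------------------------

@dataclass
class CoxTerm:
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    """Univariate and covariate-adjusted Cox fits of a binary indicator."""
    univariate: dict[str, CoxTerm]
    screening: pd.DataFrame               # covariate, univariate_p, retained
    multivariate: dict[str, CoxTerm] = field(default_factory=dict)
    converged: bool = True
    message: str = ""


def _wald_terms(cph: CoxPHFitter) -> dict[str, CoxTerm]:
    z = stats.norm.ppf(0.975)
    out = {}
    for term in cph.params_.index:
        beta = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        # exponent clipped so a near-singular fit yields a huge finite bound
        out[term] = CoxTerm(
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(np.clip(beta - z * se, -700.0, 700.0))),
            ci_high=float(np.exp(np.clip(beta + z * se, -700.0, 700.0))),
            p=float(2 * stats.norm.sf(abs(beta / se))),
        )
    return out


def _fit_cox(df: pd.DataFrame, cols: Sequence[str],
             time_col: str, event_col: str) -> CoxPHFitter:
    use = df[[time_col, event_col, *cols]].astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(use, duration_col=time_col, event_col=event_col)
    return cph


def cox_model(table: pd.DataFrame, indicator: str = "intermediate",
              covariates: Sequence[str] = DEFAULT_COX_CANDIDATES,
              screening_p: float = 0.2,
              time_col: str = "time", event_col: str = "event") -> CoxResult:
    """Univariate fit of a binary indicator, then a screened multivariate fit.

    Each candidate covariate is screened by the p-value of its own univariate
    Cox fit; covariates with p < ``screening_p`` join the indicator in the
    multivariate model. HRs are exp(coefficient) with Wald 95% CIs. On
    non-convergence the partial results are withheld and ``converged`` is
    False.
    """
    df = table.copy()
    if indicator == "intermediate" and "intermediate" not in df.columns:
        df["intermediate"] = (df["group"] == "intermediate").astype(int)
    if set(df[indicator].unique()) - {0, 1}:
        raise ValueError(f"indicator {indicator!r} must be binary 0/1")

    try:
        uni = _fit_cox(df, [indicator], time_col, event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        return CoxResult(univariate={}, screening=pd.DataFrame(),
                         converged=False, message=str(exc))
    univariate = _wald_terms(uni)

    screen_rows = []
    retained = []
    for cov in covariates:
        if cov not in df.columns:
            continue
        if df[cov].astype(float).nunique() < 2:
            screen_rows.append({"covariate": cov, "univariate_p": np.nan,
                                "retained": False, "note": "constant"})
            continue
        try:
            fit = _fit_cox(df, [cov], time_col, event_col)
            p = _wald_terms(fit)[cov].p
        except Exception:
            screen_rows.append({"covariate": cov, "univariate_p": np.nan,
                                "retained": False, "note": "did not converge"})
            continue
        keep = bool(p < screening_p)
        if keep:
            retained.append(cov)
        screen_rows.append({"covariate": cov, "univariate_p": p,
                            "retained": keep, "note": ""})
    screening = pd.DataFrame(screen_rows,
                             columns=["covariate", "univariate_p", "retained", "note"])

    multivariate: dict[str, CoxTerm] = {}
    converged, message = True, ""
    if retained:
        try:
            multi = _fit_cox(df, [indicator, *retained], time_col, event_col)
            multivariate = _wald_terms(multi)
        except Exception as exc:
            converged, message = False, f"multivariate fit failed: {exc}"
    else:
        multivariate = dict(univariate)
    return CoxResult(univariate=univariate, screening=screening,
                     multivariate=multivariate, converged=converged,
                     message=message)


# ---------------------------------------------------------------------------
# Group-covariate association tests
# ---------------------------------------------------------------------------

def _exact_rxc_p(tab: np.ndarray, rng: np.random.Generator,
                 n_perm: int = 5000) -> float:
    """Monte-Carlo permutation p for an r x c table (chi-square statistic)."""
    rows = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1))
    cols = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0))
    obs = stats.chi2_contingency(tab, correction=False)[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(tab)
        np.add.at(t, (rows, perm), 1)
        stat = stats.chi2_contingency(t, correction=False)[0] \
            if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all() \
            else 0.0
        hits += stat >= obs - 1e-12
    return (1 + hits) / (1 + n_perm)


DEFAULT_CATEGORICAL = ("t_stage", "n_stage", "m_stage", "grade", "angioinvasion")
DEFAULT_CONTINUOUS = ("tumor_size", "ln_resected", "age")

_COLLAPSE = {
    "t_stage": lambda s: np.where(s == "T1a", "T1a", "T1b+"),
    "n_stage": lambda s: np.where(s == "N0", "N0", "N1+"),
}


def group_covariate_tests(clinical: pd.DataFrame, groups: pd.DataFrame,
                          categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                          continuous: Sequence[str] = DEFAULT_CONTINUOUS,
                          seed: int = 0) -> pd.DataFrame:
    """Test each covariate for association with the burden group.

    Categorical covariates: chi-square, switching to an exact test when any
    expected cell count is below 5 (Fisher for 2x2; Monte-Carlo permutation
    otherwise, seeded). Continuous covariates: Kruskal–Wallis across the
    three groups plus pairwise Mann–Whitney comparisons against the low
    group. Constant covariates are skipped with a note.
    """
    df = clinical.merge(groups[["sample_id", "group"]], on="sample_id")
    rng = np.random.default_rng(seed)
    rows = []
    for cov in categorical:
        vals = df[cov]
        if cov in _COLLAPSE:
            vals = pd.Series(_COLLAPSE[cov](vals), index=vals.index)
        if vals.nunique() < 2:
            rows.append({"covariate": cov, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "constant covariate"})
            continue
        tab = pd.crosstab(df["group"], vals).to_numpy()
        chi2, p, _dof, expected = stats.chi2_contingency(tab, correction=False)
        if (expected < 5).any():
            if tab.shape == (2, 2):
                _odds, p = stats.fisher_exact(tab)
                rows.append({"covariate": cov, "test": "fisher_exact",
                             "statistic": np.nan, "p": p, "note": ""})
            else:
                p = _exact_rxc_p(tab, rng)
                rows.append({"covariate": cov, "test": "exact_mc",
                             "statistic": chi2, "p": p,
                             "note": "Monte-Carlo permutation"})
        else:
            rows.append({"covariate": cov, "test": "chi2", "statistic": chi2,
                         "p": p, "note": ""})
    for cov in continuous:
        by_group = [df.loc[df["group"] == g, cov].to_numpy()
                    for g in GROUP_ORDER if (df["group"] == g).any()]
        if np.ptp(df[cov].to_numpy(float)) == 0:
            rows.append({"covariate": cov, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "constant covariate"})
            continue
        stat, p = stats.kruskal(*by_group)
        rows.append({"covariate": cov, "test": "kruskal", "statistic": stat,
                     "p": p, "note": ""})
        low = df.loc[df["group"] == "low", cov].to_numpy()
        for g in ("intermediate", "high"):
            other = df.loc[df["group"] == g, cov].to_numpy()
            if len(low) and len(other):
                stat, p = stats.mannwhitneyu(low, other, alternative="two-sided")
                rows.append({"covariate": cov, "test": f"mannwhitney_low_vs_{g}",
                             "statistic": stat, "p": p, "note": ""})
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p", "note"])


# ---------------------------------------------------------------------------
# Count correlations
# ---------------------------------------------------------------------------

def correlate_counts(table: pd.DataFrame, total_col: str = "total_cna_count",
                     columns: Optional[Sequence[str]] = None,
                     spearman: bool = True) -> pd.DataFrame:
    """Correlate the total CNA count with other per-sample count columns.

    Pearson r (and optionally Spearman rho) with two-sided p-values between
    ``total_col`` and each requested column (default: every other numeric
    column). Zero-variance columns yield NaN with a note.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 samples to correlate")
    total = table[total_col].to_numpy(float)
    if columns is None:
        columns = [c for c in table.columns
                   if c != total_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        y = table[col].to_numpy(float)
        row = {"variable": col, "pearson_r": np.nan, "pearson_p": np.nan,
               "spearman_rho": np.nan, "spearman_p": np.nan, "note": ""}
        if np.ptp(y) == 0 or np.ptp(total) == 0:
            row["note"] = "zero variance; correlation undefined"
        else:
            r, p = stats.pearsonr(total, y)
            row.update(pearson_r=float(r), pearson_p=float(p))
            if spearman:
                rho, sp = stats.spearmanr(total, y)
                row.update(spearman_rho=float(rho), spearman_p=float(sp))
        rows.append(row)
    return pd.DataFrame(rows)
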