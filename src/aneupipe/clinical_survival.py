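"""Prognostic and clinical association layer.

Univariable Cox proportional-hazards fits, Kaplan-Meier analysis on a
median split of a genomic score with a log-rank test, and the clinical
test battery that relates the score to age, stage and grade: Spearman for
continuous variables, Wilcoxon rank-sum for two-level categories,
Kruskal-Wallis for multi-level ones, and Fisher's exact test on the
score-group x category contingency table (exact for 2x2, seeded
Monte-Carlo for larger tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class SurvivalFit:
    """One univariable proportional-hazards fit."""

    endpoint: str
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int


def cox_univariable(time, event, x, endpoint: str = "pfi",
                    covariate: str = "score",
                    min_events: int = 10) -> SurvivalFit:
    """Univariable Cox fit; HR = exp(coefficient) with Wald CI and p.

    Requires a finite, non-constant covariate and at least ``min_events``
    observed events.
    """
    df = pd.DataFrame({
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=int),
        "x": np.asarray(x, dtype=float),
    }).dropna()
    if not np.isfinite(df["x"]).all():
        raise ValueError("cox_univariable: non-finite covariate")
    if df["x"].nunique() <= 1:
        raise ValueError("cox_univariable: constant covariate")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("cox_univariable: no events")
    if n_events < min_events:
        raise ValueError(
            f"cox_univariable: only {n_events} events (< {min_events})")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = stats.norm.ppf(0.975)
    return SurvivalFit(
        endpoint=endpoint, covariate=covariate,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p=float(cph.summary.loc["x", "p"]),
        n=len(df), events=n_events,
    )


def km_median_split(time, event, score, endpoint: str = "pfi"):
    """Kaplan-Meier comparison of score <= median versus > median.

    Ties at the median go to the lower group.  Returns the log-rank
    result, a Cox HR on the group indicator, and the per-group KM curve
    points (time, at-risk, survival).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    s = np.asarray(score, dtype=float)
    med = float(np.median(s))
    higher = s > med
    n_low, n_high = int((~higher).sum()), int(higher.sum())
    if n_low == 0 or n_high == 0:
        raise ValueError("km_median_split: median split leaves a group empty"
                         " (all scores tied)")
    logger.info("km_median_split: median=%g, lower n=%d, higher n=%d",
                med, n_low, n_high)
    lr = logrank_test(t[~higher], t[higher], e[~higher], e[higher])
    fit = cox_univariable(t, e, higher.astype(float), endpoint=endpoint,
                          covariate="higher_group", min_events=1)
    curves = []
    for name, mask in (("lower", ~higher), ("higher", higher)):
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask], label=name)
        ev = km.event_table
        curve = pd.DataFrame({
            "group": name,
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "survival": km.survival_function_[name]
            .reindex(ev.index).to_numpy(dtype=float),
        })
        curves.append(curve)
    return {
        "median": med,
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "fit": fit,
        "curves": pd.concat(curves, ignore_index=True),
    }


# ---------------------------------------------------------------------------
# Fisher's exact test, 2x2 and Monte-Carlo RxC
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    Uses the probability-mass ordering convention: the p-value sums the
    null probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact_2x2: table must be 2x2")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def _log_table_prob_term(table: np.ndarray) -> float:
    """The table-dependent part of the multivariate hypergeometric
    log-probability (margins fixed): -sum log(n_ij!)."""
    return -float(gammaln(table + 1.0).sum())


def fisher_exact_montecarlo(table, n_draws: int = 100_000,
                            seed: int = 0) -> float:
    """Seeded Monte-Carlo Fisher exact p for an RxC contingency table.

    Tables are sampled from the null (fixed margins) by permuting the
    column labels of the reconstructed individual-level data, which draws
    tables with their multivariate hypergeometric probabilities.  The
    p-value is the add-one-corrected fraction of sampled tables whose
    probability is at most the observed one (probability ordering, the
    same convention as the exact 2x2 test).
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("fisher_exact_montecarlo: negative counts")
    r, c = table.shape
    n = int(table.sum())
    if n == 0:
        raise ValueError("fisher_exact_montecarlo: empty table")
    row_of = np.repeat(np.arange(r), table.sum(axis=1))
    col_of = np.repeat(
        np.concatenate([np.arange(c)] * r),
        table.reshape(-1))
    obs_term = _log_table_prob_term(table)
    rng = np.random.default_rng(seed)
    worse = 0
    chunk = max(1, min(n_draws, 2_000_000 // max(n, 1)))
    done = 0
    ncell = r * c
    while done < n_draws:
        b = min(chunk, n_draws - done)
        perms = rng.permuted(np.tile(col_of, (b, 1)), axis=1)
        flat = (np.arange(b)[:, None] * ncell
                + row_of[None, :] * c + perms).reshape(-1)
        counts = np.bincount(flat, minlength=b * ncell).reshape(b, ncell)
        terms = -gammaln(counts + 1.0).sum(axis=1)
        worse += int((terms <= obs_term + 1e-9).sum())
        done += b
    return (1.0 + worse) / (1.0 + n_draws)


def anova_from_summary(ns, means, sds) -> tuple[float, float]:
    """One-way ANOVA F and p from per-group n / mean / SD summaries.

    Lets printed cohort summary tables be tested directly, without raw
    values.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = len(ns)
    n = ns.sum()
    grand = (ns * means).sum() / n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds ** 2).sum()
    df1, df2 = k - 1, n - k
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# clinical battery
# ---------------------------------------------------------------------------

def _group_table(groups: np.ndarray, categories: pd.Series) -> np.ndarray:
    """Category x group count table, dropping empty category levels."""
    levels = [l for l in pd.unique(categories) if pd.notna(l)]
    levels.sort(key=str)
    tab = np.array([
        [int(((categories == l) & (groups == g)).sum()) for g in (0, 1)]
        for l in levels])
    keep = tab.sum(axis=1) > 0
    if (~keep).any():
        logger.warning("clinical battery: dropping %d empty level(s)",
                       int((~keep).sum()))
    return tab[keep]


def clinical_battery(score: pd.Series, clinical: pd.DataFrame,
                     continuous: tuple[str, ...] = ("age",),
                     categorical: tuple[str, ...] = (
                         "t_stage", "n_stage", "m_stage",
                         "gleason_primary", "gleason_secondary"),
                     mc_draws: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Associations between a per-sample score and clinical variables.

    Continuous variables: Spearman correlation with the score, plus a
    one-way ANOVA across the median-split score groups.  Categorical
    variables: Wilcoxon rank-sum of the score across two levels or
    Kruskal-Wallis across more, plus Fisher's exact test on the
    score-group x category table (exact 2x2, Monte-Carlo beyond).
    """
    common = [s for s in clinical.index if s in score.index]
    sc = score.loc[common].astype(float)
    clin = clinical.loc[common]
    med = float(np.median(sc))
    group = (sc > med).astype(int).to_numpy()  # ties to the lower group

    rows = []
    for var in continuous:
        v = clin[var].astype(float)
        ok = v.notna()
        rho, p = stats.spearmanr(sc[ok], v[ok])
        rows.append({"variable": var, "test": "spearman",
                     "statistic": float(rho), "p": float(p)})
        g_ns, g_means, g_sds = [], [], []
        for g in (0, 1):
            vals = v[ok & (group == g)]
            g_ns.append(len(vals))
            g_means.append(float(vals.mean()))
            g_sds.append(float(vals.std(ddof=1)))
        f, p_a = anova_from_summary(g_ns, g_means, g_sds)
        summary = (f"n={g_ns}, mean={list(np.round(g_means, 2))}, "
                   f"sd={list(np.round(g_sds, 2))}")
        rows.append({"variable": var, "test": "anova",
                     "statistic": f, "p": p_a, "group_summary": summary})
    for var in categorical:
        v = clin[var]
        ok = v.notna()
        levels = pd.unique(v[ok])
        samples_by_level = [sc[ok & (v == l)].to_numpy() for l in levels]
        samples_by_level = [s for s in samples_by_level if len(s)]
        if len(samples_by_level) < 2:
            logger.warning("clinical battery: %s has < 2 levels, skipped",
                           var)
            continue
        if len(samples_by_level) == 2:
            u, p = stats.mannwhitneyu(*samples_by_level,
                                      alternative="two-sided")
            rows.append({"variable": var, "test": "wilcoxon",
                         "statistic": float(u), "p": float(p)})
        else:
            h, p = stats.kruskal(*samples_by_level)
            rows.append({"variable": var, "test": "kruskal_wallis",
                         "statistic": float(h), "p": float(p)})
        tab = _group_table(group[ok.to_numpy()], v[ok])
        if tab.shape == (2, 2):
            odds, p_f = fisher_exact_2x2(tab)
            stat = odds
        else:
            p_f = fisher_exact_montecarlo(tab, n_draws=mc_draws, seed=seed)
            stat = float("nan")
        rows.append({"variable": var, "test": "fisher_exact",
                     "statistic": stat, "p": p_f,
                     "group_summary": "x".join(map(str, tab.shape))})
    return pd.DataFrame(rows)
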