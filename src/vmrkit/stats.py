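"""Cohort-level inference: responder classification, the competition
regression, ANCOVA with de-correlated measures, and thin wrappers for the
group tests used throughout the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM, anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class CompetitionFit:
    """OLS fit of implicit learning on explicit strategy.

    Under the competition model x_i = p_i (r - x_e) the regression of
    implicit on explicit has slope -p_i and intercept p_i * r, so the
    intercept-to-rotation ratio should match the slope magnitude;
    ``p_i_hat`` is |slope| and ``intercept_over_r`` the consistency check.
    """

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    p_i_hat: float
    r_deg: float
    intercept_over_r: float
    n: int
    r_squared: float


def competition_regression(implicit, explicit, r_deg: float = 30.0) -> CompetitionFit:
    """Regress implicit learning on explicit strategy across participants."""
    y = np.asarray(implicit, dtype=float)
    x = np.asarray(explicit, dtype=float)
    if len(x) != len(y):
        raise ValueError("implicit and explicit must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 participants")
    if np.isclose(np.var(x), 0.0):
        raise ValueError("explicit strategy has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    slope = float(model.params[1])
    intercept = float(model.params[0])
    return CompetitionFit(
        slope=slope,
        intercept=intercept,
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
        p_i_hat=abs(slope),
        r_deg=r_deg,
        intercept_over_r=intercept / r_deg,
        n=len(x),
        r_squared=float(model.rsquared),
    )


@dataclass
class ResponderLabels:
    """Outcome of Gaussian-mixture responder sorting."""

    labels: list[str]
    n_components_selected: int
    aic: dict[int, float]
    means: dict[str, float] = field(default_factory=dict)


def classify_responders(
    adaptation_scores, seed: int = 0, n_restarts: int = 10, max_components: int = 2
) -> ResponderLabels:
    """Sort participants into responsive / unresponsive subgroups.

    Fits 1- and 2-component Gaussian mixtures to the adaptation feature
    (conventionally the mean angle over the last 10 rotation epochs),
    selects the component count by AIC, and assigns labels by maximum
    posterior; with 2 components the higher-mean component is 'responsive'.
    Multiple restarts with a fixed seed make the fit reproducible.
    """
    x = np.asarray(adaptation_scores, dtype=float).reshape(-1, 1)
    if len(x) < 4:
        raise ValueError("need at least 4 participants")
    aic: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, n_init=n_restarts, random_state=seed, reg_covar=1e-6
        ).fit(x)
        aic[k] = float(gm.aic(x))
        fits[k] = gm
    k_best = min(aic, key=aic.get)
    gm = fits[k_best]
    if k_best == 1:
        labels = ["responsive"] * len(x)
        means = {"responsive": float(gm.means_[0, 0])}
    else:
        comp = gm.predict(x)
        order = np.argsort(gm.means_[:, 0])  # low mean = unresponsive
        name = {int(order[0]): "unresponsive", int(order[1]): "responsive"}
        labels = [name[int(c)] for c in comp]
        means = {name[int(i)]: float(gm.means_[i, 0]) for i in range(2)}
    return ResponderLabels(
        labels=labels, n_components_selected=k_best, aic=aic, means=means
    )


def partial_eta_squared(anova_table: pd.DataFrame) -> pd.Series:
    """Partial eta-squared per effect from a Type-II ANOVA table."""
    ss_err = float(anova_table.loc["Residual", "sum_sq"])
    effects = anova_table.drop(index="Residual")
    return effects["sum_sq"] / (effects["sum_sq"] + ss_err)


def ancova_implicit(implicit, explicit, group_labels) -> dict:
    """ANCOVA: implicit learning as the outcome, explicit strategy as the
    covariate and group as the fixed factor (Type-II sums of squares).

    Use de-correlated implicit / explicit measures (disjoint epoch sets) so
    shared motor noise does not inflate the covariate effect.  Returns the
    F, p and partial eta-squared for the group factor and the covariate.
    """
    df = pd.DataFrame(
        {
            "implicit": np.asarray(implicit, dtype=float),
            "explicit": np.asarray(explicit, dtype=float),
            "group": list(group_labels),
        }
    )
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    model = smf.ols("implicit ~ explicit + C(group)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    table = anova_lm(model, typ=2)
    eta = partial_eta_squared(table)
    return {
        "F_group": float(table.loc["C(group)", "F"]),
        "p_group": float(table.loc["C(group)", "PR(>F)"]),
        "partial_eta2_group": float(eta["C(group)"]),
        "F_covariate": float(table.loc["explicit", "F"]),
        "p_covariate": float(table.loc["explicit", "PR(>F)"]),
        "partial_eta2_covariate": float(eta["explicit"]),
        "n": len(df),
    }


# ---------------------------------------------------------------------------
# Group-test wrappers.  Each returns a plain dict (test, statistic, df, p,
# effect size, n) so results drop straight into a tidy report.


def _cohen_d(x, y=None) -> float:
    x = np.asarray(x, dtype=float)
    if y is None:
        return float(np.mean(x) / np.std(x, ddof=1))
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    )
    return float((np.mean(x) - np.mean(y)) / pooled)


def one_sample_t(x, popmean: float = 0.0) -> dict:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    res = sps.ttest_1samp(x, popmean)
    return {
        "test": "one_sample_t",
        "statistic": float(res.statistic),
        "df": len(x) - 1,
        "p": float(res.pvalue),
        "effect_size": _cohen_d(x - popmean),
        "n": len(x),
    }


def paired_t(x, y) -> dict:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired t-test needs equal-length samples, n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0.0 and np.mean(d) == 0.0:
        # identical vectors: zero difference with zero variance
        return {"test": "paired_t", "statistic": 0.0, "df": len(x) - 1,
                "p": 1.0, "effect_size": 0.0, "n": len(x)}
    res = sps.ttest_rel(x, y)
    eff = float(np.mean(d) / np.std(d, ddof=1)) if np.std(d, ddof=1) > 0 else 0.0
    return {
        "test": "paired_t",
        "statistic": float(res.statistic),
        "df": len(x) - 1,
        "p": float(res.pvalue),
        "effect_size": eff,
        "n": len(x),
    }


def unpaired_t(x, y) -> dict:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValueError("unpaired t-test needs n >= 2 per group")
    res = sps.ttest_ind(x, y)
    return {
        "test": "unpaired_t",
        "statistic": float(res.statistic),
        "df": len(x) + len(y) - 2,
        "p": float(res.pvalue),
        "effect_size": _cohen_d(x, y),
        "n": (len(x), len(y)),
    }


def wilcoxon_rank_sum(x, y) -> dict:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValueError("rank-sum test needs n >= 2 per group")
    res = sps.ranksums(x, y)
    return {
        "test": "wilcoxon_rank_sum",
        "statistic": float(res.statistic),
        "df": None,
        "p": float(res.pvalue),
        "effect_size": float(res.statistic / np.sqrt(len(x) + len(y))),
        "n": (len(x), len(y)),
    }


def shapiro_wilk(x) -> dict:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    res = sps.shapiro(x)
    return {
        "test": "shapiro_wilk",
        "statistic": float(res.statistic),
        "df": None,
        "p": float(res.pvalue),
        "effect_size": None,
        "n": len(x),
    }


def one_way_anova(groups: dict, tukey: bool = True) -> dict:
    """One-way between-subjects ANOVA with optional post-hoc Tukey HSD.

    ``groups`` maps a group name to its sample.
    """
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("one-way ANOVA needs >= 2 groups of n >= 2")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    res = sps.f_oneway(*samples)
    k = len(samples)
    n_tot = sum(map(len, samples))
    grand = np.mean(np.concatenate(samples))
    ss_between = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ss_total = float(np.sum((np.concatenate(samples) - grand) ** 2))
    out = {
        "test": "one_way_anova",
        "statistic": float(res.statistic),
        "df": (k - 1, n_tot - k),
        "p": float(res.pvalue),
        "effect_size": ss_between / ss_total if ss_total > 0 else 0.0,
        "n": n_tot,
    }
    if tukey:
        values = np.concatenate(samples)
        labels = np.concatenate([[name] * len(s) for name, s in zip(groups, samples)])
        out["tukey"] = pairwise_tukeyhsd(values, labels).summary().as_text()
    return out


def rm_anova(data: pd.DataFrame, subject: str, within: str, value: str) -> dict:
    """Repeated-measures ANOVA (one within factor) on long-format data."""
    counts = data.groupby(subject)[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("repeated-measures ANOVA needs a balanced design")
    res = AnovaRM(data, depvar=value, subject=subject, within=[within]).fit()
    row = res.anova_table.iloc[0]
    f = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    return {
        "test": "rm_anova",
        "statistic": f,
        "df": (df1, df2),
        "p": float(row["Pr > F"]),
        "effect_size": f * df1 / (f * df1 + df2),  # partial eta^2 from F
        "n": data[subject].nunique(),
    }
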