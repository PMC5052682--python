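"""Statistical layer: rank tests, Cuzick's trend test, contingency tests,
per-signature association tables, Kaplan-Meier / logrank (plain and trend)
and the Cox proportional-hazards contract.

Cuzick's nonparametric test for trend across ordered groups — an adjunct to
Kruskal-Wallis — is implemented from its rank-sum formulation with mid-ranks
and a tie-corrected variance.  The logrank machinery computes the per-group
observed-minus-expected vector and its covariance directly from the risk
tables, which yields both the standard (G-1)-df chi-square test and the
1-df trend test with ordered group scores; Kaplan-Meier estimation and Cox
regression are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Signatures excluded from the per-signature tables for having too few
#: carriers in the source cohort; only applied when actually present.
DEFAULT_EXCLUDED_SIGNATURES: tuple[str, ...] = ("6", "17", "20", "26", "30")


@dataclass
class AssociationResult:
    """One test result: statistic, p-value and group summaries."""

    test: str
    statistic: float
    p: float
    z: float | None = None
    group_ns: dict = field(default_factory=dict)
    group_summaries: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------- rank tests

def mann_whitney_u(x, y) -> AssociationResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return AssociationResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_ns={"x": len(x), "y": len(y)},
        group_summaries={
            "mean_x": float(np.mean(x)), "mean_y": float(np.mean(y)),
            "median_x": float(np.median(x)), "median_y": float(np.median(y)),
        },
    )


def kruskal_wallis(groups: list) -> AssociationResult:
    """Kruskal-Wallis H with tie correction across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return AssociationResult(
            "kruskal_wallis", 0.0, 1.0,
            group_ns={i: len(g) for i, g in enumerate(groups)},
            note="degenerate: all observations equal",
        )
    h, p = sps.kruskal(*groups)
    return AssociationResult(
        test="kruskal_wallis",
        statistic=float(h),
        p=float(p),
        group_ns={i: len(g) for i, g in enumerate(groups)},
        group_summaries={i: float(np.mean(g)) for i, g in enumerate(groups)},
    )


def cuzick_trend(
    values,
    groups,
    scores: dict | None = None,
    alternative: str = "two-sided",
) -> AssociationResult:
    """Cuzick's nonparametric test for trend across ordered groups.

    With pooled mid-ranks R over N observations, group scores l_i and group
    rank-sums R_i the statistic is T = sum_i l_i R_i with

        E(T)   = (N + 1)/2 * sum_i n_i l_i
        Var(T) = (N + 1)/12 * (N sum_i n_i l_i^2 - (sum_i n_i l_i)^2)

    The variance carries the usual tie correction 1 - sum(t^3 - t)/(N^3 - N);
    z = (T - E)/sqrt(Var) is referred to the standard normal.  Group scores
    default to consecutive integers 1..G in the sorted order of the group
    labels; the z-statistic is invariant to affine rescaling of the scores.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("fewer than 2 occupied ordered groups")
    if scores is None:
        scores = {lev: i + 1 for i, lev in enumerate(levels)}
    score_per_obs = np.array([scores[g] for g in groups], dtype=float)

    n = len(values)
    ranks = sps.rankdata(values)  # mid-ranks
    t_stat = float(np.sum(score_per_obs * ranks))
    sum_nl = float(np.sum(score_per_obs))
    sum_nl2 = float(np.sum(score_per_obs**2))
    expect = (n + 1) / 2.0 * sum_nl
    var = (n + 1) / 12.0 * (n * sum_nl2 - sum_nl**2)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    var *= tie_corr
    ns = {lev: int(np.sum(groups == lev)) for lev in levels}
    summaries = {lev: float(values[groups == lev].mean()) for lev in levels}
    if var <= 0:
        return AssociationResult(
            "cuzick_trend", t_stat, 1.0, z=0.0, group_ns=ns,
            group_summaries=summaries, note="degenerate: zero variance (all ties)",
        )
    z = (t_stat - expect) / np.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return AssociationResult(
        "cuzick_trend", t_stat, float(min(p, 1.0)), z=float(z),
        group_ns=ns, group_summaries=summaries,
    )


# --------------------------------------------------------- contingency tests

def contingency_test(table) -> AssociationResult:
    """Pearson chi-square with automatic fall-back to Fisher's exact test.

    For a 2x2 table with any expected cell below 5, Fisher's exact p is
    reported as primary (the chi-square value is kept in the summaries); the
    rule applied is recorded in ``note``.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("need a 2-D non-negative integer table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, chi2_p, _, expected = sps.chi2_contingency(tab, correction=False)
    low_counts = bool((expected < 5).any())
    summaries = {"chi2": float(chi2), "chi2_p": float(chi2_p)}
    if tab.shape == (2, 2):
        odds, fisher_p = sps.fisher_exact(tab)
        summaries["fisher_p"] = float(fisher_p)
        summaries["odds_ratio"] = float(odds)
        if low_counts:
            return AssociationResult(
                "fisher_exact", float(odds), float(fisher_p),
                group_summaries=summaries,
                note="expected cell < 5: Fisher exact reported as primary",
            )
    elif low_counts:
        logger.warning("low expected counts in a non-2x2 table; chi-square kept")
    return AssociationResult(
        "chi2", float(chi2), float(chi2_p), group_summaries=summaries,
        note="low expected counts" if low_counts else "",
    )


# ------------------------------------------- per-signature association tables

def _prepare_counts(
    counts: pd.DataFrame, mode: str
) -> pd.DataFrame:
    if mode not in ("absolute", "proportional"):
        raise ValueError(f"mode must be absolute|proportional, got {mode!r}")
    if mode == "absolute":
        return counts.astype(float)
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"proportional mode requires positive totals; zero for {list(zero.index)[:10]}"
        )
    return counts.div(totals, axis=0)


def per_signature_group_association(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    mode: str = "absolute",
    exclude_signatures: tuple[str, ...] = DEFAULT_EXCLUDED_SIGNATURES,
    group_order: list | None = None,
) -> pd.DataFrame:
    """Mann-Whitney per signature between two sample groups.

    Mirrors the two-group association table: one row per signature with the
    number of carriers, the MWU p and the per-group mean counts (absolute
    counts or per-sample proportions).  Excluded signatures are reported
    "N.D." with no test run.
    """
    labels = group_labels.reindex(counts.index)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    groups = group_order if group_order is not None else sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    data = _prepare_counts(counts, mode)
    rows = []
    for sig in counts.columns:
        carriers = int((counts[sig] > 0).sum())
        a = data.loc[labels == groups[0], sig].values
        b = data.loc[labels == groups[1], sig].values
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group for signature {sig}")
        means = {f"mean_{groups[0]}": float(np.mean(a)),
                 f"mean_{groups[1]}": float(np.mean(b))}
        if str(sig) in exclude_signatures:
            rows.append({"signature": sig, "n_carriers": carriers,
                         "test": "N.D.", "p": np.nan, **means,
                         "note": "excluded (too few carriers)"})
            continue
        res = mann_whitney_u(a, b)
        rows.append({"signature": sig, "n_carriers": carriers,
                     "test": res.test, "p": res.p, **means, "note": ""})
    return pd.DataFrame(rows).set_index("signature")


def infiltrate_trend_per_signature(
    counts: pd.DataFrame,
    infiltrate: pd.Series,
    mode: str = "absolute",
    exclude_signatures: tuple[str, ...] = DEFAULT_EXCLUDED_SIGNATURES,
) -> pd.DataFrame:
    """Cuzick trend per signature across ordered infiltrate groups.

    One row per signature with carriers, trend p and per-level mean counts.
    """
    inf = infiltrate.reindex(counts.index)
    if inf.isna().any():
        raise ValueError("infiltrate labels missing for some samples")
    data = _prepare_counts(counts, mode)
    levels = sorted(inf.unique())
    rows = []
    for sig in counts.columns:
        carriers = int((counts[sig] > 0).sum())
        means = {
            f"mean_level_{lev}": float(data.loc[inf == lev, sig].mean())
            for lev in levels
        }
        if str(sig) in exclude_signatures:
            rows.append({"signature": sig, "n_carriers": carriers,
                         "test": "N.D.", "p": np.nan, "z": np.nan, **means,
                         "note": "excluded (too few carriers)"})
            continue
        res = cuzick_trend(data[sig].values, inf.values)
        rows.append({"signature": sig, "n_carriers": carriers,
                     "test": res.test, "p": res.p, "z": res.z, **means,
                     "note": res.note})
    return pd.DataFrame(rows).set_index("signature")


# ----------------------------------------------------------- survival layer

def _logrank_oe(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray, levels: list
):
    """Observed-minus-expected event vector and its covariance per group."""
    g_index = np.array([levels.index(g) for g in groups])
    n_groups = len(levels)
    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n_at_risk = np.array(
            [np.sum(at_risk & (g_index == g)) for g in range(n_groups)], dtype=float
        )
        n_total = n_at_risk.sum()
        deaths = event[(time == t)].astype(bool)
        d_total = float(np.sum(deaths))
        d_group = np.array(
            [np.sum(deaths & (g_index[time == t] == g)) for g in range(n_groups)],
            dtype=float,
        )
        observed += d_group
        expected += d_total * n_at_risk / n_total
        if n_total > 1:
            factor = d_total * (n_total - d_total) / (n_total - 1)
            outer = np.outer(n_at_risk, n_at_risk) / n_total**2
            cov += factor * (np.diag(n_at_risk / n_total) - outer)
    return observed, expected, cov


def km_logrank(
    survival: pd.DataFrame,
    trend: bool = False,
    group_order: list | None = None,
    scores: list | None = None,
) -> tuple[AssociationResult, dict[str, pd.DataFrame]]:
    """Kaplan-Meier curves per group plus a logrank test across groups.

    ``survival`` needs columns time, event, group.  With ``trend`` the 1-df
    logrank test for trend with ordered integer group scores is used instead
    of the (G-1)-df test; ``group_order`` fixes the ordering (default: sorted
    labels).  Returns the test result and per-group KM tables
    (time, at_risk, events, survival).
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=int)
    groups = np.asarray(survival["group"])
    if (time < 0).any():
        raise ValueError("negative survival times")
    if event.sum() == 0:
        raise ValueError("no events observed")
    levels = group_order if group_order is not None else sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    km_tables = {}
    for lev in levels:
        mask = groups == lev
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(lev))
        tab = kmf.event_table.copy()
        tab["survival"] = kmf.survival_function_.iloc[:, 0].values
        km_tables[lev] = (
            tab.reset_index()
            .rename(columns={"event_at": "time", "observed": "events"})
            [["time", "at_risk", "events", "survival"]]
        )

    observed, expected, cov = _logrank_oe(time, event, groups, list(levels))
    diff = observed - expected
    ns = {lev: int(np.sum(groups == lev)) for lev in levels}
    if trend:
        c = np.asarray(
            scores if scores is not None else np.arange(1, len(levels) + 1),
            dtype=float,
        )
        var = float(c @ cov @ c)
        if var <= 0:
            result = AssociationResult(
                "logrank_trend", 0.0, 1.0, z=0.0, group_ns=ns,
                note="degenerate: zero trend variance",
            )
        else:
            z = float(c @ diff) / np.sqrt(var)
            result = AssociationResult(
                "logrank_trend", float(z**2), float(sps.chi2.sf(z**2, 1)),
                z=float(z), group_ns=ns,
            )
    else:
        sub = np.ix_(range(len(levels) - 1), range(len(levels) - 1))
        try:
            chi2 = float(diff[:-1] @ np.linalg.solve(cov[sub], diff[:-1]))
        except np.linalg.LinAlgError:
            chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
        result = AssociationResult(
            "logrank", chi2, float(sps.chi2.sf(chi2, len(levels) - 1)),
            group_ns=ns,
        )
    result.group_summaries = {
        str(lev): {"observed": float(o), "expected": float(e)}
        for lev, o, e in zip(levels, observed, expected)
    }
    return result, km_tables


def cox_ph(
    covariates: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    Returns one row per covariate: coef, HR, 95% CI bounds and Wald p.
    Constant covariates are rejected by name; non-convergence propagates as
    an error with lifelines' diagnostic.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if len(covariates) != len(survival):
        raise ValueError("covariates and survival tables differ in length")
    if np.asarray(survival["event"]).sum() == 0:
        raise ValueError("no events observed")
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    df = covariates.reset_index(drop=True).copy()
    df["time"] = np.asarray(survival["time"], dtype=float)
    df["event"] = np.asarray(survival["event"], dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    out = cph.summary[
        ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "exp(coef)": "HR",
            "exp(coef) lower 95%": "HR_lower95",
            "exp(coef) upper 95%": "HR_upper95",
        }
    )
    out.index.name = "covariate"
    return out
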