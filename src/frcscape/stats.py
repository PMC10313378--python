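"""Group-comparison and survival statistics.

Two-sample comparisons use the unpaired Mann-Whitney U test (exact
enumeration for small samples, normal approximation with tie correction
otherwise); three or more groups use one-way ANOVA with Tukey's HSD.
Survival is summarized with the Kaplan-Meier product-limit estimator and
compared across groups with the log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .exceptions import DegenerateInputError, ValidationError

#: largest per-group size for exact Mann-Whitney enumeration
EXACT_MW_LIMIT = 8


@dataclass
class SurvivalFit:
    """Per-group KM curves plus the across-group log-rank test."""

    groups: dict[str, dict]  # name -> {times, survival, n, n_events, median}
    statistic: float
    df: int
    p_value: float


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival step function.

    Returns a frame with columns (time, survival, n_at_risk); censored
    times reduce the risk set without creating steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DegenerateInputError("empty survival input")
    if (times < 0).any():
        raise ValidationError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ev = kmf.event_table
    out = pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "n_at_risk": ev["at_risk"].reindex(sf.index).to_numpy(dtype=float),
        }
    )
    out.attrs["median"] = float(kmf.median_survival_time_)
    return out


def km_median(times, events) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    return float(kmf.median_survival_time_)


def logrank_test(groups: dict[str, tuple]) -> tuple[float, int, float]:
    """k-group log-rank (Mantel-Cox) test.

    groups maps name -> (times, events).  Returns (chi-square statistic,
    df = k - 1, p value).
    """
    if len(groups) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    rows = []
    for name, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValidationError(f"group {name!r} has zero subjects")
        rows.append(pd.DataFrame({"time": t, "event": e, "group": name}))
    df = pd.concat(rows, ignore_index=True)
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def survival_fit(clinical: pd.DataFrame, group_labels: pd.Series) -> SurvivalFit:
    """KM curves per group (e.g. per TFE) plus the log-rank comparison."""
    df = clinical.copy()
    df["group"] = df["sample_id"].map(group_labels)
    df = df.dropna(subset=["group"])
    groups = {}
    gdata = {}
    for name, sub in df.groupby("group"):
        t = sub["os_time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=int)
        curve = km_estimate(t, e)
        groups[name] = {
            "times": curve["time"].tolist(),
            "survival": curve["survival"].tolist(),
            "n": int(len(sub)),
            "n_events": int(e.sum()),
            "median": curve.attrs["median"],
        }
        gdata[name] = (t, e)
    stat, dof, p = logrank_test(gdata)
    return SurvivalFit(groups, stat, dof, p)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney via full enumeration of group splits."""
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2  # U for sample a
    mu = n * m / 2
    total = comb(n + m, n)
    idx_all = range(n + m)
    count = 0
    obs_dev = abs(u_obs - mu)
    for pick in combinations(idx_all, n):
        u = ranks[list(pick)].sum() - n * (n + 1) / 2
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return float(u_obs), count / total


def mann_whitney(a, b) -> tuple[float, float]:
    """Unpaired two-sided Mann-Whitney U test.

    Exact enumeration when both samples have <= 8 observations, otherwise
    the normal approximation with midrank tie correction.  Returns
    (U statistic of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if a.size <= EXACT_MW_LIMIT and b.size <= EXACT_MW_LIMIT:
        return _mann_whitney_exact(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def anova_tukey(groups: dict[str, np.ndarray], pairwise: bool = True) -> dict:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    groups maps name -> sample.  Returns F, p and (when pairwise) the
    Tukey-adjusted pairwise p values keyed by (name_a, name_b).
    """
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if len(samples) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
    f_stat, p = sps.f_oneway(*samples)
    out = {"F": float(f_stat), "p": float(p)}
    if pairwise:
        tk = sps.tukey_hsd(*samples)
        out["tukey_p"] = {
            (names[i], names[j]): float(tk.pvalue[i, j])
            for i, j in combinations(range(len(names)), 2)
        }
    return out
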