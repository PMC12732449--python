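"""Group-level statistics: summaries, normality-gated comparisons, correlation.

The comparison procedure reproduces a conventional two-track design: each
group's values are screened with a battery of normality tests (Shapiro–Wilk,
Kolmogorov–Smirnov on standardized values, Lilliefors, Anderson–Darling) and
a per-group majority vote; if every group passes, a one-way ANOVA with
Tukey's HSD post hoc is run, otherwise Kruskal–Wallis with Dunn's post hoc
test (tie-corrected z statistics, Bonferroni-adjusted by default). Summaries
are mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupTable",
    "TestReport",
    "summarize",
    "compare_groups",
    "correlate_metrics",
    "dunn_test",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupTable:
    """Long-format values of one metric across stacks and groups."""

    metric: str
    data: pd.DataFrame  # columns: stack_id, group, subgroup, value

    def __post_init__(self):
        req = {"stack_id", "group", "value"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"GroupTable missing columns: {sorted(missing)}")
        if "subgroup" not in self.data.columns:
            self.data = self.data.assign(subgroup="")
        if not np.isfinite(self.data["value"]).all():
            raise ValueError(f"metric {self.metric!r} has non-finite values")

    def groups(self) -> dict[str, np.ndarray]:
        return {g: sub["value"].to_numpy(dtype=float)
                for g, sub in self.data.groupby("group", sort=True)}


@dataclass
class TestReport:
    """Result of the gated omnibus + post hoc comparison of one metric."""

    metric: str
    summary: pd.DataFrame                 # group, mean, sd, n
    normality: pd.DataFrame               # group, test, p, normal
    all_normal: bool
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame                # group_a, group_b, p_adj, significant
    alpha: float = ALPHA_DEFAULT


def summarize(table: GroupTable) -> pd.DataFrame:
    """Per-group mean, sample SD (n−1), and n; SD is NaN (flagged) at n=1."""
    rows = []
    for g, v in table.groups().items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        rows.append({
            "group": g,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            "n": int(v.size),
        })
    return pd.DataFrame(rows)


def _normality_battery(values: np.ndarray, alpha: float) -> list[dict]:
    """P-values of the applicable normality tests for one sample."""
    out = []
    v = np.asarray(values, float)
    if v.std(ddof=1) == 0:
        # constant sample: normality ill-posed; treat as non-normal
        return [{"test": "degenerate", "p": 0.0, "normal": False}]
    if v.size >= 3:
        p = float(stats.shapiro(v).pvalue)
        out.append({"test": "shapiro", "p": p, "normal": p >= alpha})
    z = (v - v.mean()) / v.std(ddof=1)
    p = float(stats.kstest(z, "norm").pvalue)
    out.append({"test": "ks", "p": p, "normal": p >= alpha})
    if v.size >= 4:
        p = float(lilliefors(v, dist="norm")[1])
        out.append({"test": "lilliefors", "p": p, "normal": p >= alpha})
    ad = stats.anderson(v, dist="norm")
    # Anderson–Darling: compare the statistic to the 5% critical value
    idx = int(np.argmin(np.abs(np.asarray(ad.significance_level) - 100 * alpha)))
    out.append({
        "test": "anderson",
        "p": float("nan"),
        "normal": bool(ad.statistic < ad.critical_values[idx]),
    })
    return out


def dunn_test(groups: dict[str, np.ndarray],
              adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc rank comparison after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with tie
    correction T = Σ(t³ − t)/(12(N − 1)); two-sided p, adjusted by
    Bonferroni (default) or Holm.
    """
    names = sorted(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = {g: len(groups[g]) for g in names}
    N = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var0 = N * (N + 1) / 12.0 - T
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[i])
            adj[i] = min(running, 1.0)
        df["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def compare_groups(table: GroupTable, alpha: float = ALPHA_DEFAULT,
                   dunn_adjust: str = "bonferroni",
                   force: str | None = None) -> TestReport:
    """Normality-gated omnibus comparison with post hoc pairwise tests.

    All groups normal (majority vote over the battery, at ``alpha``) →
    one-way ANOVA + Tukey HSD; otherwise Kruskal–Wallis + Dunn. The report
    records which path was taken, every normality verdict, and all C(k,2)
    pairwise adjusted p-values. Decisions are invariant to group order and
    to adding a constant to every value. ``force`` overrides the gate with
    ``"parametric"`` or ``"nonparametric"``.
    """
    groups = table.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    small = [g for g, v in groups.items() if len(v) < 3]
    if small:
        raise ValueError(f"groups too small for testing (n < 3): {small}")
    norm_rows = []
    verdicts = {}
    for g, v in groups.items():
        battery = _normality_battery(v, alpha)
        for b in battery:
            norm_rows.append({"group": g, **b})
        votes = [b["normal"] for b in battery]
        verdicts[g] = sum(votes) > len(votes) / 2
    all_normal = all(verdicts.values())
    if force == "parametric":
        all_normal = True
    elif force == "nonparametric":
        all_normal = False
    elif force is not None:
        raise ValueError(f"unknown force mode {force!r}")
    names = sorted(groups)
    samples = [groups[g] for g in names]
    rows = []
    if all_normal:
        stat, p = stats.f_oneway(*samples)
        omnibus = ("one-way ANOVA", float(stat), float(p))
        res = stats.tukey_hsd(*samples)
        for i, j in combinations(range(len(names)), 2):
            padj = float(res.pvalue[i, j])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "p_adj": padj, "significant": padj < alpha})
        pairwise = pd.DataFrame(rows)
    else:
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0  # all values identical: no evidence either way
        else:
            stat, p = stats.kruskal(*samples)
        omnibus = ("Kruskal-Wallis", float(stat), float(p))
        df = dunn_test(groups, adjust=dunn_adjust)
        df["significant"] = df["p_adj"] < alpha
        pairwise = df[["group_a", "group_b", "p_adj", "significant"]]
    return TestReport(
        metric=table.metric,
        summary=summarize(table),
        normality=pd.DataFrame(norm_rows),
        all_normal=all_normal,
        omnibus_name=omnibus[0],
        omnibus_statistic=omnibus[1],
        omnibus_p=omnibus[2],
        pairwise=pairwise,
        alpha=alpha,
    )


def correlate_metrics(x, y) -> float:
    """Pearson correlation of paired (typically per-group mean) values.

    Requires ≥3 pairs; degenerate variance yields NaN (flagged by warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    if x.std() == 0 or y.std() == 0:
        import warnings

        warnings.warn("correlation undefined: zero variance")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
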