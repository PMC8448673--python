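"""Group statistics with a normality gate, omnibus designs and posthoc tests.

Two-group comparisons apply a Shapiro-Wilk gate per group: both normal ->
Student's t-test, otherwise Mann-Whitney.  Omnibus designs cover one-way
ANOVA (Tukey or Bonferroni posthoc), two-way ANOVA, and Kruskal-Wallis
(Dunn posthoc).  Summaries report mean +/- SEM (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PosthocResult",
    "GroupComparison",
    "compare_two_groups",
    "omnibus_with_posthoc",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class PosthocResult:
    group_a: str
    group_b: str
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    design: str
    groups: list[GroupSummary]
    posthoc: list[PosthocResult] | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.design == "two_group" and self.posthoc is not None:
            raise ValueError("posthoc applies only to omnibus designs")

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "design": self.design,
            "groups": [vars(g) for g in self.groups],
        }
        if self.posthoc is not None:
            d["posthoc"] = [vars(p) for p in self.posthoc]
        d.update(self.details)
        return d


def _summary(label: str, x: np.ndarray) -> GroupSummary:
    x = np.asarray(x, dtype=float)
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return GroupSummary(label, int(x.size), float(x.mean()), sem)


def compare_two_groups(
    a,
    b,
    alpha_normality: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-group comparison behind a Shapiro-Wilk normality gate.

    Both groups passing at ``alpha_normality`` routes to a two-sided
    Student's t-test; either failing routes to Mann-Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    p_norm_a = float(sps.shapiro(a).pvalue)
    p_norm_b = float(sps.shapiro(b).pvalue)
    normal = p_norm_a >= alpha_normality and p_norm_b >= alpha_normality
    if normal:
        res = sps.ttest_ind(a, b)
        name = "student_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        design="two_group",
        groups=[_summary(labels[0], a), _summary(labels[1], b)],
        details={"shapiro_p": {labels[0]: p_norm_a, labels[1]: p_norm_b}},
    )


def dunn_posthoc(samples: dict, alpha: float = 0.05) -> list[PosthocResult]:
    """Dunn's rank-based pairwise test with tie correction, Bonferroni adjusted."""
    labels = list(samples)
    pooled = np.concatenate([np.asarray(samples[k], dtype=float) for k in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_rank = {}
    sizes = {}
    i = 0
    for k in labels:
        n_k = len(samples[k])
        mean_rank[k] = ranks[i : i + n_k].mean()
        sizes[k] = n_k
        i += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m)
        out.append(PosthocResult(a, b, float(z), float(p_adj), bool(p_adj < alpha)))
    return out


def _bonferroni_pairwise(samples: dict, alpha: float) -> list[PosthocResult]:
    m = len(samples) * (len(samples) - 1) // 2
    out = []
    for a, b in combinations(samples, 2):
        res = sps.ttest_ind(samples[a], samples[b])
        p_adj = min(1.0, float(res.pvalue) * m)
        out.append(
            PosthocResult(a, b, float(res.statistic), p_adj, bool(p_adj < alpha))
        )
    return out


def _tukey_pairwise(samples: dict, alpha: float) -> list[PosthocResult]:
    labels = list(samples)
    res = sps.tukey_hsd(*[np.asarray(samples[k], dtype=float) for k in labels])
    out = []
    for i, j in combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        out.append(
            PosthocResult(
                labels[i], labels[j], float(res.statistic[i, j]), p, bool(p < alpha)
            )
        )
    return out


def omnibus_with_posthoc(
    values,
    factors: dict,
    design: str,
    posthoc: str = "bonferroni",
    alpha: float = 0.05,
) -> GroupComparison:
    """Omnibus test per design with pairwise posthoc at the stated correction.

    Parameters
    ----------
    values : array-like
        Observations.
    factors : dict
        Factor name -> label array.  One factor for ``one_way`` / ``kruskal``,
        two for ``two_way``.
    design : {'one_way', 'two_way', 'kruskal'}
    posthoc : {'bonferroni', 'tukey', 'dunn'}

    For ``two_way`` the omnibus is a type-II ANOVA with interaction; the
    posthoc compares levels of the first factor within each level of the
    second (Bonferroni across all comparisons), matching per-pressure
    group comparisons.  Empty cells raise an error.
    """
    values = np.asarray(values, dtype=float)
    if design not in ("one_way", "two_way", "kruskal"):
        raise ValueError(f"unknown design {design!r}")
    if posthoc not in ("bonferroni", "tukey", "dunn"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    names = list(factors)

    if design in ("one_way", "kruskal"):
        f = np.asarray(factors[names[0]])
        levels = list(pd.unique(f))
        if len(levels) < 2:
            raise ValueError("need >= 2 levels")
        samples = {str(lv): values[f == lv] for lv in levels}
        if design == "one_way":
            res = sps.f_oneway(*samples.values())
            name = "one_way_anova"
        else:
            res = sps.kruskal(*samples.values())
            name = "kruskal_wallis"
        ph = {
            "bonferroni": _bonferroni_pairwise,
            "tukey": _tukey_pairwise,
            "dunn": dunn_posthoc,
        }[posthoc](samples, alpha)
        return GroupComparison(
            test_name=name,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            design=design,
            groups=[_summary(k, v) for k, v in samples.items()],
            posthoc=ph,
        )

    # two-way ANOVA
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    f1 = np.asarray(factors[names[0]])
    f2 = np.asarray(factors[names[1]])
    for fac, nm in ((f1, names[0]), (f2, names[1])):
        if len(pd.unique(fac)) < 2:
            raise ValueError(f"factor {nm!r} needs >= 2 levels")
    df = pd.DataFrame({"value": values, "f1": f1.astype(str), "f2": f2.astype(str)})
    cell_counts = df.groupby(["f1", "f2"]).size().unstack(fill_value=0)
    if (cell_counts.to_numpy() == 0).any():
        raise ValueError("two-way design has empty cells")
    model = smf.ols("value ~ C(f1) * C(f2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_f1 = float(table.loc["C(f1)", "PR(>F)"])
    stat_f1 = float(table.loc["C(f1)", "F"])
    # posthoc: first-factor comparisons within each second-factor level
    pairs = []
    for lv2 in pd.unique(df["f2"]):
        sub = df[df["f2"] == lv2]
        for a, b in combinations(pd.unique(sub["f1"]), 2):
            pairs.append(
                (
                    f"{a}@{lv2}",
                    f"{b}@{lv2}",
                    sub.loc[sub["f1"] == a, "value"].to_numpy(),
                    sub.loc[sub["f1"] == b, "value"].to_numpy(),
                )
            )
    m = len(pairs)
    ph = []
    for la, lb, xa, xb in pairs:
        res = sps.ttest_ind(xa, xb)
        p_adj = min(1.0, float(res.pvalue) * m)
        ph.append(PosthocResult(la, lb, float(res.statistic), p_adj, bool(p_adj < alpha)))
    groups = [
        _summary(f"{a}@{b}", g["value"].to_numpy())
        for (a, b), g in df.groupby(["f1", "f2"])
    ]
    anova_p = {
        str(idx): float(row["PR(>F)"])
        for idx, row in table.iterrows()
        if np.isfinite(row["PR(>F)"])
    }
    return GroupComparison(
        test_name="two_way_anova",
        statistic=stat_f1,
        p_value=p_f1,
        design="two_way",
        groups=groups,
        posthoc=ph,
        details={"anova_table_p": anova_p, "factor_names": names},
    )
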