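"""Group statistics for genotype comparisons.

The measurement tables compare each mutant genotype against the wild-type
reference: D'Agostino-Pearson omnibus normality, Kruskal-Wallis with
Dunn's many-to-one post hoc (non-normal metrics), ordinary one-way ANOVA
with Dunnett's comparisons (normal metrics), Pearson chi-square on
phenotype-category count tables, and the conventional significance-star
mapping (ns p > 0.05, * p <= 0.05, ** p <= 0.01, *** p <= 0.001,
**** p <= 0.0001).  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "StatResult",
    "normality",
    "kw_dunn",
    "anova_dunnett",
    "phenotype_chisq",
    "star_map",
    "summary_table",
    "summary_markdown",
]


@dataclass
class GroupData:
    """One genotype's measurements for one metric."""

    label: str
    values: np.ndarray
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in group {self.label!r}")


@dataclass
class StatResult:
    """Omnibus test plus per-group comparisons against the reference."""

    test: str
    statistic: float
    pvalue: float
    #: group label -> (comparison statistic, adjusted p, stars)
    comparisons: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def star_map(p: float) -> str:
    """Significance stars; each boundary is closed (p = 0.05 earns '*')."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def normality(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """D'Agostino-Pearson omnibus K² test; normal? = (p > alpha)."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"insufficient n for omnibus test: {x.size} < 8")
    k2, p = stats.normaltest(x)
    return float(k2), float(p), bool(p > alpha)


def _split_reference(groups: list[GroupData]) -> tuple[GroupData, list[GroupData]]:
    refs = [g for g in groups if g.is_reference]
    if len(refs) != 1:
        raise ValueError(f"need exactly one reference group, got {len(refs)}")
    return refs[0], [g for g in groups if not g.is_reference]


def kw_dunn(groups: list[GroupData], pairwise: bool = False) -> StatResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post hoc vs reference.

    Dunn z uses mean ranks from the pooled ranking with the tie-corrected
    variance; adjusted p is Bonferroni over the many-to-one comparisons
    (or over all pairs with ``pairwise``), matching the usual many-to-one
    post-hoc reading.  All-identical data yields H = 0, p = 1 (flagged).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ref, others = _split_reference(groups)
    samples = [g.values for g in groups]
    pooled = np.concatenate(samples)
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    flags = []
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
        flags.append("all values identical")
    else:
        h, p = stats.kruskal(*samples)
    # Dunn: mean ranks of the pooled ranking
    ranks = stats.rankdata(pooled)
    N = pooled.size
    bounds = np.cumsum([0] + [g.values.size for g in groups])
    mean_rank = {
        g.label: ranks[bounds[i]:bounds[i + 1]].mean() for i, g in enumerate(groups)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12 - tie_term
    m = len(others) if not pairwise else len(groups) * (len(groups) - 1) // 2
    comparisons = {}
    for g in others:
        se = np.sqrt(var_unit * (1 / g.values.size + 1 / ref.values.size))
        z = 0.0 if se == 0 else (mean_rank[g.label] - mean_rank[ref.label]) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        comparisons[g.label] = (float(z), float(p_adj), star_map(p_adj))
    return StatResult(
        test="Kruskal-Wallis + Dunn",
        statistic=float(h),
        pvalue=float(p),
        comparisons=comparisons,
        n={g.label: g.values.size for g in groups},
        flags=flags,
    )


def anova_dunnett(groups: list[GroupData], rng: int = 0) -> StatResult:
    """Ordinary one-way ANOVA with Dunnett's many-to-one comparisons.

    Dunnett's adjusted p comes from the multivariate-t distribution of the
    comparison statistics (seeded quasi-Monte-Carlo evaluation).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.values.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    ref, others = _split_reference(groups)
    if all(np.ptp(g.values) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*[g.values for g in groups])
    res = stats.dunnett(
        *[g.values for g in others], control=ref.values, rng=rng
    )
    comparisons = {
        g.label: (float(res.statistic[i]), float(res.pvalue[i]),
                  star_map(float(res.pvalue[i])))
        for i, g in enumerate(others)
    }
    return StatResult(
        test="one-way ANOVA + Dunnett",
        statistic=float(f),
        pvalue=float(p),
        comparisons=comparisons,
        n={g.label: g.values.size for g in groups},
    )


def phenotype_chisq(counts, reference: str | None = None) -> StatResult | dict[str, StatResult]:
    """Pearson chi-square (no continuity correction) on a count table.

    ``counts`` is a genotype × category table (DataFrame or 2-D array of
    non-negative integers).  Without ``reference`` the test runs on the
    table as given; with a reference row label, each other genotype is
    tested in its own 2 × k table against the reference, matching the
    per-mutant many-to-one comparisons.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    arr = df.to_numpy()
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if reference is not None:
        if reference not in df.index:
            raise ValueError(f"reference row {reference!r} not in table")
        out = {}
        for row in df.index:
            if row == reference:
                continue
            out[str(row)] = phenotype_chisq(df.loc[[reference, row]])
        return out
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal in count table")
    if (arr == arr[0]).all():
        return StatResult(test="chi-square", statistic=0.0, pvalue=1.0,
                          n={"total": int(arr.sum())})
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return StatResult(
        test="chi-square", statistic=float(chi2), pvalue=float(p),
        n={"total": int(arr.sum())},
    )


def summary_table(results: dict[str, StatResult]) -> pd.DataFrame:
    """Measurement × genotype grid of sample sizes and adjusted p-values.

    Rows are measurements, columns genotypes; each cell shows "n=..;
    p=.. (stars)" for that genotype's comparison against the reference
    (reference cells show only n).
    """
    genotypes: list[str] = []
    for res in results.values():
        for g in res.n:
            if g not in genotypes:
                genotypes.append(g)
    rows = {}
    for metric, res in results.items():
        row = {}
        for g in genotypes:
            if g not in res.n:
                row[g] = ""
            elif g in res.comparisons:
                _, p_adj, stars = res.comparisons[g]
                row[g] = f"n={res.n[g]}; p={p_adj:.4g} ({stars})"
            else:
                row[g] = f"n={res.n[g]}"
        rows[metric] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=genotypes)


def summary_markdown(results: dict[str, StatResult]) -> str:
    return summary_table(results).to_markdown()
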