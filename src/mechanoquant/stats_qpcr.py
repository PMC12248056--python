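"""Normality-gated group comparisons and ΔΔCT qPCR fold changes.

Group comparison follows the common immunofluorescence-quantification
protocol: every group is first tested for normality (Shapiro-Wilk,
alpha = 0.05). If all groups pass, a one-way ANOVA with Tukey's HSD post hoc
is used; otherwise the nonparametric Kruskal-Wallis test with Dunn's post
hoc (Bonferroni family correction by default). qPCR relative expression uses
the ΔΔCT method with duplicate wells averaged on the CT scale and a
reference (housekeeping) gene such as β-actin.

Dunn's rank-based pairwise test is implemented here (rank-sum z statistics
with tie correction); no dependency in the scientific Python stack ships it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_groups",
    "dunn_test",
    "ddct_fold_change",
]


@dataclass
class GroupComparison:
    """Result of a normality-gated multi-group comparison."""

    group_names: list[str]
    normality_p: dict[str, float]
    chosen_test: str  # "parametric" | "nonparametric"
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: pd.DataFrame  # corrected p-values, symmetric, NaN diagonal
    alpha: float = 0.05
    warnings_: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.omnibus_p < self.alpha)

    def summary(self) -> str:
        lines = [
            f"test: {self.chosen_test}",
            f"omnibus stat={self.omnibus_stat:.4g} p={self.omnibus_p:.4g} "
            f"({'significant' if self.significant else 'n.s.'} at alpha={self.alpha})",
            "pairwise corrected p-values:",
            self.pairwise_p.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        lines += [f"warning: {w}" for w in self.warnings_]
        return "\n".join(lines)


def dunn_test(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank comparison following Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) ),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tied-value
    multiplicities t. Two-sided p-values are corrected across the
    k(k-1)/2 comparisons by ``adjust`` ('bonferroni', 'holm', or 'none').
    """
    if adjust not in ("bonferroni", "holm", "none"):
        raise ValueError("adjust must be 'bonferroni', 'holm', or 'none'")
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([len(d) for d in data])
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(names)), 2))
    raw_p = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw_p.append(2.0 * stats.norm.sf(abs(z)))
    raw_p = np.asarray(raw_p)

    m = len(pairs)
    if adjust == "bonferroni":
        adj = np.minimum(raw_p * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(raw_p)
        adj = np.empty_like(raw_p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw_p[idx] * (m - rank))
            adj[idx] = min(running, 1.0)
    else:
        adj = raw_p

    table = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        table.iloc[i, j] = table.iloc[j, i] = p
    return table


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    dunn_adjust: str = "bonferroni",
) -> GroupComparison:
    """Shapiro-Wilk-gated multi-group comparison.

    All groups normal at ``alpha`` -> one-way ANOVA + Tukey HSD pairwise;
    any group non-normal (or zero-variance, which forces the nonparametric
    branch with a warning) -> Kruskal-Wallis + Dunn pairwise with
    multiplicity correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")
    names = list(data)
    warn: list[str] = []

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in data.items():
        if np.ptp(v) == 0:
            normality_p[g] = 0.0
            all_normal = False
            warn.append(f"group {g!r} has zero variance; nonparametric branch forced")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(v).pvalue)
        normality_p[g] = p
        if p < alpha:
            all_normal = False

    if all_normal:
        chosen = "parametric"
        stat, p = stats.f_oneway(*data.values())
        # identical groups: rounding can give F = -eps and p = nan
        if not np.isfinite(p):
            stat = max(float(stat), 0.0)
            dfn = len(data) - 1
            dfd = sum(len(v) for v in data.values()) - len(data)
            p = float(stats.f.sf(stat, dfn, dfd))
        res = stats.tukey_hsd(*data.values())
        table = pd.DataFrame(np.asarray(res.pvalue), index=names, columns=names)
        np.fill_diagonal(table.values, np.nan)
    else:
        chosen = "nonparametric"
        stat, p = stats.kruskal(*data.values())
        table = dunn_test(data, adjust=dunn_adjust)

    return GroupComparison(
        group_names=names,
        normality_p=normality_p,
        chosen_test=chosen,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise_p=table,
        alpha=alpha,
        warnings_=warn,
    )


def ddct_fold_change(
    records: pd.DataFrame,
    control_group: str,
    target_gene: str | None = None,
    reference_gene: str = "ActB",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCT method.

    ``records`` columns: ``sample``, ``group``, ``gene``, ``ct``; duplicate
    wells of the same sample/gene are averaged on the CT scale. Per sample,
    ΔCT = CT_target − CT_reference; ΔΔCT = ΔCT − mean(ΔCT of the control
    group); fold change = 2^(−ΔΔCT). Samples missing the reference (or
    target) CT are returned excluded with a reason rather than dropped.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    genes = [g for g in records["gene"].unique() if g != reference_gene]
    if target_gene is None:
        if len(genes) != 1:
            raise ValueError(f"ambiguous target gene among {genes}; pass target_gene")
        target_gene = genes[0]

    ct = (
        records.groupby(["sample", "group", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    for col in (target_gene, reference_gene):
        if col not in ct.columns:
            ct[col] = np.nan

    ct["dct"] = ct[target_gene] - ct[reference_gene]
    ct["excluded"] = ct[target_gene].isna() | ct[reference_gene].isna()
    ct["reason"] = np.where(
        ct[reference_gene].isna(),
        "missing reference CT",
        np.where(ct[target_gene].isna(), "missing target CT", ""),
    )

    control = ct.loc[(ct["group"] == control_group) & ~ct["excluded"], "dct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no usable samples")
    ct["ddct"] = ct["dct"] - control.mean()
    ct["fold_change"] = np.where(ct["excluded"], np.nan, 2.0 ** (-ct["ddct"]))
    cols = ["sample", "group", target_gene, reference_gene, "dct", "ddct", "fold_change", "excluded", "reason"]
    out = ct[cols].rename(columns={target_gene: "ct_target", reference_gene: "ct_reference"})
    return out
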