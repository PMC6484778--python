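"""Population-level statistics for control vs deprived comparisons.

Group summaries are median and interquartile range (quartiles by linear
interpolation); medians are compared by the Wilcoxon rank-sum test (exact
for small samples without ties, normal approximation with tie correction
otherwise), distributions by the two-sample Kolmogorov-Smirnov test,
correlations by Spearman's rank-order coefficient, correlation differences
between independent groups by Fisher's Z-transformation, and proportions by
Fisher's exact test.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_RANKSUM_MAX_N = 30


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n1: int
    median1: float
    iqr1: float
    n2: int
    median2: float
    iqr2: float
    test: str
    statistic: float
    p: float


@dataclass(frozen=True)
class CorrelationEntry:
    var_x: str
    var_y: str
    group: str
    rho: float
    n: int
    p: float
    flagged: bool = False


def summarize_group(values: Sequence[float]) -> tuple[int, float, float]:
    """(n, median, IQR) over the finite values; errors if none remain."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarize")
    q1, q3 = np.percentile(v, [25, 75])
    return int(v.size), float(np.median(v)), float(q3 - q1)


def compare_groups(a: Sequence[float], b: Sequence[float],
                   kind: str = "ranksum", variable: str = "") -> GroupComparison:
    """Two-sided two-sample test between groups ``a`` and ``b``.

    ``kind='ranksum'``: Wilcoxon rank-sum (Mann-Whitney U); exact null
    distribution when the combined sample is small (<= 30) and tie-free,
    otherwise the tie-corrected normal approximation.
    ``kind='ks'``: two-sample Kolmogorov-Smirnov.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, m1, i1 = summarize_group(x)
    n2, m2, i2 = summarize_group(y)
    if kind == "ranksum":
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size + y.size <= EXACT_RANKSUM_MAX_N and not ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test = f"ranksum ({method})"
    elif kind == "ks":
        res = sps.ks_2samp(x, y, alternative="two-sided")
        test = "ks"
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return GroupComparison(variable=variable, n1=n1, median1=m1, iqr1=i1,
                           n2=n2, median2=m2, iqr2=i2, test=test,
                           statistic=float(res.statistic), p=float(res.pvalue))


def spearman_correlation(x: Sequence[float], y: Sequence[float]
                         ) -> tuple[float, int, float, bool]:
    """(rho, n, p, flagged) on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        return float("nan"), n, float("nan"), True
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), n, float("nan"), True  # constant variable
    rho, p = sps.spearmanr(x, y)
    return float(rho), n, float(p), False


def spearman_matrix(table: pd.DataFrame, variables: Sequence[str],
                    group_col: str = "condition",
                    rank_group: str = "control") -> list[CorrelationEntry]:
    """Spearman rho/p for every variable pair within each group.

    Pairs are ordered by their p value in ``rank_group`` (most significant
    first), matching how correlation matrices are presented with variables
    ranked by correlation in the control group.
    """
    groups = list(dict.fromkeys(table[group_col]))
    entries: dict[tuple[str, str], dict[str, CorrelationEntry]] = {}
    for gi, g in enumerate(groups):
        sub = table[table[group_col] == g]
        for i, vx in enumerate(variables):
            for vy in variables[i + 1:]:
                rho, n, p, flagged = spearman_correlation(sub[vx], sub[vy])
                entries.setdefault((vx, vy), {})[g] = CorrelationEntry(
                    var_x=vx, var_y=vy, group=str(g), rho=rho, n=n, p=p,
                    flagged=flagged)

    def sort_key(pair):
        e = entries[pair].get(rank_group)
        if e is None or not np.isfinite(e.p):
            return math.inf
        return e.p

    out: list[CorrelationEntry] = []
    for pair in sorted(entries, key=sort_key):
        for g in groups:
            if g in entries[pair]:
                out.append(entries[pair][g])
    return out


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int
                     ) -> tuple[float, float]:
    """Compare two independent Spearman correlations via Fisher's Z.

    Z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p value.
    """
    for rho in (rho1, rho2):
        if not abs(rho) < 1:
            raise ValueError("|rho| must be < 1 (Fisher transform diverges)")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 in each group")
    z = (math.atanh(rho1) - math.atanh(rho2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n in each group")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(p)


def comparison_report(table: pd.DataFrame,
                      ranksum_vars: Sequence[str],
                      ks_vars: Sequence[str],
                      corr_vars: Sequence[str],
                      corr_target: Optional[str] = None,
                      group_col: str = "condition",
                      groups: tuple[str, str] = ("control", "deprived"),
                      ) -> dict:
    """Full group-comparison report on a feature table.

    Runs rank-sum comparisons on ``ranksum_vars``, KS comparisons on
    ``ks_vars``, per-group Spearman correlations of each of ``corr_vars``
    against ``corr_target`` plus Fisher-Z differences between groups.
    Returns a JSON-serializable dict; with fewer than two groups present,
    comparisons are skipped (no error).
    """
    present = [g for g in groups if (table[group_col] == g).any()]
    report: dict = {"groups": present, "comparisons": [], "ks": [],
                    "correlations": [], "fisher_z": []}
    if len(present) == 2:
        ga = table[table[group_col] == present[0]]
        gb = table[table[group_col] == present[1]]
        for var in ranksum_vars:
            a = ga[var].to_numpy(dtype=float)
            b = gb[var].to_numpy(dtype=float)
            if np.isfinite(a).any() and np.isfinite(b).any():
                report["comparisons"].append(
                    asdict(compare_groups(a, b, "ranksum", variable=var)))
        for var in ks_vars:
            a = ga[var].to_numpy(dtype=float)
            b = gb[var].to_numpy(dtype=float)
            if np.isfinite(a).any() and np.isfinite(b).any():
                report["ks"].append(
                    asdict(compare_groups(a, b, "ks", variable=var)))
    if corr_target is not None:
        per_group: dict[str, dict[str, CorrelationEntry]] = {}
        for g in present:
            sub = table[table[group_col] == g]
            for var in corr_vars:
                rho, n, p, flagged = spearman_correlation(
                    sub[var], sub[corr_target])
                e = CorrelationEntry(var_x=var, var_y=corr_target,
                                     group=str(g), rho=rho, n=n, p=p,
                                     flagged=flagged)
                per_group.setdefault(var, {})[g] = e
                report["correlations"].append(asdict(e))
        if len(present) == 2:
            for var in corr_vars:
                e1 = per_group[var].get(present[0])
                e2 = per_group[var].get(present[1])
                if e1 and e2 and not (e1.flagged or e2.flagged) \
                        and abs(e1.rho) < 1 and abs(e2.rho) < 1 \
                        and min(e1.n, e2.n) >= 4:
                    z, p = fisher_z_compare(e1.rho, e1.n, e2.rho, e2.n)
                    report["fisher_z"].append(
                        {"variable": var, "target": corr_target,
                         "z": z, "p": p})
    return report
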