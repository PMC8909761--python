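"""Group-comparison statistics for the per-cell endpoints.

Two groups are compared by Mann–Whitney U (exact null distribution when the
smaller group has n ≤ 8 and there are no ties, normal approximation with tie
correction otherwise) or Student's t on request.  Three or more groups use
Kruskal–Wallis with tie correction followed by Dunn's pairwise z tests;
multiplicity is controlled family-wise (Bonferroni over the Dunn family, the
convention of the usual "Dunn's multiple comparison test") or by
Benjamini–Hochberg FDR / Holm, selectable because the procedure name in
common methods sections is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonEntry:
    endpoint: str
    test: str
    statistic: float
    p_value: float
    adjusted_p: float
    groups: dict = field(default_factory=dict)  # label -> summary dict


def group_summary(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": float(np.mean(x)),
        "sd": sd,
        "sem": sd / np.sqrt(n) if n > 1 else 0.0,
        "median": float(np.median(x)),
    }


def mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of the U null.

    Valid without ties; used when min(n) is small.  Returns (U of sample a,
    two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    a,
    b,
    endpoint: str = "endpoint",
    labels: tuple[str, str] = ("a", "b"),
    test: str = "mannwhitney",  # or "ttest"
    exact_max_n: int = 8,
) -> ComparisonEntry:
    """Two-group comparison (Mann–Whitney U default, Student's t optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
        warnings.warn("identical constant groups; p set to 1", stacklevel=2)
        return ComparisonEntry(
            endpoint, test, np.nan, 1.0, 1.0,
            {labels[0]: group_summary(a), labels[1]: group_summary(b)},
        )
    if test == "ttest":
        stat, p = sps.ttest_ind(a, b)
    elif test == "mannwhitney":
        ties = np.unique(np.concatenate([a, b])).size < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= exact_max_n and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(min(p, 1.0))
    return ComparisonEntry(
        endpoint,
        test,
        float(stat),
        p,
        p,  # single comparison: no adjustment
        {labels[0]: group_summary(a), labels[1]: group_summary(b)},
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and its chi-square p-value."""
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def dunn_pairwise(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> list[dict]:
    """Dunn's rank-based pairwise z tests after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt(S²·(1/n_i + 1/n_j)) with
    S² = (N(N+1)/12)·tie-correction on the pooled ranks; unadjusted
    two-sided p-values are returned per pair.
    """
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    s2 = (n_tot * (n_tot + 1) / 12.0) - tie_term / (12.0 * (n_tot - 1))
    mean_ranks = []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0:i0 + len(g)].mean())
        i0 += len(g)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(s2 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            out.append(
                {"pair": (labels[i], labels[j]), "z": float(z), "p": float(min(p, 1.0))}
            )
    return out


def adjust_pvalues(pvals: list[float], method: str = "bh") -> list[float]:
    """Multiple-comparison adjustment: 'bh' (FDR), 'holm', or 'bonferroni'."""
    mapping = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment {method!r}")
    if not pvals:
        return []
    return list(multipletests(pvals, method=mapping[method])[1])


def compare_multi_groups(
    groups: list,
    labels: list[str] | None = None,
    endpoint: str = "endpoint",
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal–Wallis across ≥ 3 groups with Dunn's pairwise follow-up.

    Returns the omnibus H and p plus the per-pair Dunn z tests with adjusted
    p-values (Bonferroni family-wise by default — the classical Dunn's
    multiple comparison convention — or 'bh' / 'holm').
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use compare_two_groups for two")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    h, p_omni = kruskal_wallis(groups)
    pairs = dunn_pairwise(groups, labels)
    adj = adjust_pvalues([pr["p"] for pr in pairs], method=adjust)
    for pr, ap in zip(pairs, adj):
        pr["adjusted_p"] = float(max(ap, pr["p"]))
    return {
        "endpoint": endpoint,
        "test": "kruskal-wallis+dunn",
        "H": h,
        "p_value": p_omni,
        "pairwise": pairs,
        "adjust": adjust,
        "groups": {lab: group_summary(g) for lab, g in zip(labels, groups)},
    }
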