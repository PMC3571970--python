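"""Statistical layer: rank tests, category representation, multiplicity.

Links per-gene stability statistics (e.g. mean promoter-window SIDD) to
functional category labels via two-sample rank-sum tests, compares
category membership between a gene subset and its universe with exact
hypergeometric tests (Benjamini-Hochberg adjusted across categories),
and compares per-gene category-count (multiplicity) distributions
between gene sets.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CategoryTestResult",
    "class_rank_test",
    "category_representation",
    "multiplicity_comparison",
    "results_to_frame",
]


@dataclass(frozen=True)
class CategoryTestResult:
    category: str
    n_in: int
    n_out: int
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # {"lower", "higher", "none"}


def _direction(in_vals, out_vals) -> str:
    mi, mo = np.median(in_vals), np.median(out_vals)
    if mi < mo:
        return "lower"
    if mi > mo:
        return "higher"
    return "none"


def class_rank_test(values: dict, category_map: dict, category: str,
                    alternative: str = "two-sided") -> CategoryTestResult:
    """Rank-sum test of in-category vs out-of-category per-gene values.

    ``values`` maps gene id -> value; ``category_map`` maps gene id ->
    set of labels.  Exact null distribution for group sizes <= 25 (no
    ties), normal approximation with continuity correction otherwise.
    Requires >= 3 genes on each side.
    """
    in_vals, out_vals = [], []
    for gid, v in values.items():
        if np.isnan(v):
            continue
        (in_vals if category in category_map.get(gid, ()) else out_vals).append(v)
    if not in_vals:
        raise ValueError(f"empty category {category!r}")
    if len(in_vals) < 3 or len(out_vals) < 3:
        raise ValueError("need >= 3 genes in and out of the category")
    in_vals = np.asarray(in_vals)
    out_vals = np.asarray(out_vals)
    if np.ptp(np.concatenate((in_vals, out_vals))) == 0:
        return CategoryTestResult(category, len(in_vals), len(out_vals),
                                  np.nan, 1.0, 1.0, "none")
    exact = len(in_vals) <= 25 and len(out_vals) <= 25
    has_ties = len(np.unique(np.concatenate((in_vals, out_vals)))) < (
        len(in_vals) + len(out_vals))
    method = "exact" if exact and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(in_vals, out_vals, alternative=alternative,
                             method=method)
    return CategoryTestResult(
        category, len(in_vals), len(out_vals), float(res.statistic),
        float(res.pvalue), float(res.pvalue), _direction(in_vals, out_vals),
    )


def rank_tests_all_categories(values: dict, category_map: dict,
                              alternative: str = "two-sided",
                              min_size: int = 3):
    """class_rank_test across every category, with BH adjustment."""
    cats = sorted({c for labels in category_map.values() for c in labels})
    results = []
    for cat in cats:
        try:
            results.append(class_rank_test(values, category_map, cat, alternative))
        except ValueError:
            continue
    if not results:
        return []
    adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
    return [
        CategoryTestResult(r.category, r.n_in, r.n_out, r.statistic,
                           r.p_raw, float(a), r.direction)
        for r, a in zip(results, adj)
    ]


def _hypergeom_two_sided(k: int, M: int, n: int, N: int) -> float:
    """Exact two-sided p: sum of outcomes no more probable than observed."""
    rv = stats.hypergeom(M, n, N)
    support = np.arange(max(0, n + N - M), min(n, N) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(k)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def category_representation(gene_universe_categories: dict, subset_ids):
    """Per-category over/under-representation of a subset vs its universe.

    Exact hypergeometric two-sided test per category with BH adjustment
    across categories.  ``subset_ids`` must be a subset of the universe.
    """
    universe = list(gene_universe_categories)
    subset = set(subset_ids)
    if not subset <= set(universe):
        raise ValueError("subset_ids must be contained in the universe")
    M, N = len(universe), len(subset)
    cats = sorted({c for labels in gene_universe_categories.values() for c in labels})
    results = []
    for cat in cats:
        members = {g for g, labels in gene_universe_categories.items() if cat in labels}
        n = len(members)
        k = len(members & subset)
        p = _hypergeom_two_sided(k, M, n, N)
        expected = n * N / M
        direction = "higher" if k > expected else ("lower" if k < expected else "none")
        results.append(
            CategoryTestResult(cat, k, n - k, float(k), p, p, direction)
        )
    if results:
        adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        results = [
            CategoryTestResult(r.category, r.n_in, r.n_out, r.statistic,
                               r.p_raw, float(a), r.direction)
            for r, a in zip(results, adj)
        ]
    return results


def multiplicity_comparison(categories_a: dict, categories_b: dict,
                            exclude_label: str = None) -> dict:
    """Compare per-gene category-count distributions between two gene sets.

    Rank-sum test (normal approximation, tie-corrected) on the number of
    labels per gene; ``exclude_label`` removes genes carrying that label
    before testing (mirrors dropping a dominant blanket annotation).
    """
    def counts(cat_map):
        return np.array(
            [len(labels) for g, labels in cat_map.items()
             if exclude_label is None or exclude_label not in labels]
        )

    ca, cb = counts(categories_a), counts(categories_b)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("both gene sets must be non-empty after exclusion")
    if np.ptp(np.concatenate((ca, cb))) == 0:
        p = 1.0
        stat = np.nan
    else:
        res = stats.mannwhitneyu(ca, cb, alternative="two-sided",
                                 method="asymptotic")
        p, stat = float(res.pvalue), float(res.statistic)
    top = int(max(ca.max(), cb.max()))
    return {
        "rank_sum_p": p,
        "statistic": stat,
        "n_a": len(ca),
        "n_b": len(cb),
        "histogram_a": np.bincount(ca, minlength=top + 1),
        "histogram_b": np.bincount(cb, minlength=top + 1),
    }


def results_to_frame(results):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "category": r.category, "n_in": r.n_in, "n_out": r.n_out,
                "statistic": r.statistic, "p_raw": r.p_raw,
                "p_BH": r.p_adjusted, "direction": r.direction,
            }
            for r in results
        ]
    )
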