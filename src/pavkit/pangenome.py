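"""Pan-genome gene classification from presence frequencies.

Genes are partitioned by the fraction of individuals carrying them:
core (100%), softcore (>99% and <100%), shell (1%-99%, both ends
inclusive) and cloud (<1%).  Softcore + shell + cloud form the
dispensable genome.  Frequencies are compared as exact rationals
(integer cross-multiplication), so boundary genes never misclassify
through floating-point rounding; percentages are only rounded (half-up,
two decimals) for display.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import PopulationMap

__all__ = [
    "CATEGORIES",
    "round_half_up",
    "percent",
    "presence_frequency",
    "classify_genes",
    "category_summary",
    "per_individual_gene_count",
    "mann_whitney_u",
]

CATEGORIES = ("core", "softcore", "shell", "cloud")


def round_half_up(value: Fraction | float, ndigits: int = 2) -> float:
    """Round with ties going away from zero toward +inf (half-up).

    Exact for Fraction inputs; used for all displayed percentages.
    """
    frac = Fraction(value) * 10**ndigits
    q, r = divmod(frac.numerator, frac.denominator)
    if 2 * r >= frac.denominator:
        q += 1
    return q / 10**ndigits


def percent(n_present: int, n_total: int, ndigits: int = 2) -> float:
    """Presence count as a display percentage, e.g. 120/121 -> 99.17."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(Fraction(100 * n_present, n_total), ndigits)


def presence_frequency(
    matrix: pd.DataFrame, individuals: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene presence counts and frequency over a cohort.

    Returns a frame indexed by gene with integer ``n_present``/``n_total``
    (the exact rational numerator/denominator), a float ``frequency`` and
    the display ``percent``.
    """
    if individuals is not None:
        if len(individuals) == 0:
            raise ValueError("individual subset is empty")
        matrix = matrix[list(individuals)]
    n_total = matrix.shape[1]
    if n_total == 0:
        raise ValueError("presence matrix has no individuals")
    n_present = matrix.to_numpy(dtype=bool).sum(axis=1)
    return pd.DataFrame(
        {
            "n_present": n_present,
            "n_total": n_total,
            "frequency": n_present / n_total,
            "percent": [percent(int(k), n_total) for k in n_present],
        },
        index=matrix.index,
    )


def classify_genes(freq: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene a core/softcore/shell/cloud category.

    Boundaries are exact: core iff n_present == n_total; softcore iff
    frequency lies strictly between 0.99 and 1; cloud iff frequency < 0.01
    (including genes present in nobody, which are flagged); shell otherwise.
    """
    categories = []
    flags = []
    for gene_id, row in zip(freq.index, freq[["n_present", "n_total"]].to_numpy()):
        k, n = int(row[0]), int(row[1])
        if k == n:
            cat = "core"
        elif 100 * k > 99 * n:
            cat = "softcore"
        elif 100 * k < n:
            cat = "cloud"
        else:
            cat = "shell"
        categories.append(cat)
        flags.append(k == 0)
    return pd.DataFrame(
        {"category": pd.Categorical(categories, categories=CATEGORIES),
         "flagged_zero_presence": flags},
        index=freq.index,
    )


def category_summary(assignment: pd.DataFrame | Mapping[str, str]) -> pd.DataFrame:
    """Count and percentage per category, plus the dispensable total.

    Accepts the frame from :func:`classify_genes` or any gene->category
    mapping.  Percentages are half-up two-decimal shares of all genes.
    """
    if isinstance(assignment, pd.DataFrame):
        series = assignment["category"]
    else:
        series = pd.Series(dict(assignment))
    total = len(series)
    counts = {cat: int((series == cat).sum()) for cat in CATEGORIES}
    if sum(counts.values()) != total:
        raise ValueError("categories do not partition the genes")
    rows = [
        {"category": cat, "count": counts[cat], "percent": percent(counts[cat], total)}
        for cat in CATEGORIES
    ]
    dispensable = total - counts["core"]
    rows.append(
        {"category": "dispensable", "count": dispensable,
         "percent": percent(dispensable, total)}
    )
    rows.append({"category": "total", "count": total, "percent": 100.0})
    return pd.DataFrame(rows)


def per_individual_gene_count(
    matrix: pd.DataFrame,
    popmap: PopulationMap | None = None,
    class_filter: str | None = None,
) -> pd.Series:
    """Number of genes called present in each individual (column sums)."""
    counts = matrix.to_numpy(dtype=bool).sum(axis=0)
    series = pd.Series(counts, index=matrix.columns, name="gene_count")
    if class_filter is not None:
        if popmap is None:
            raise ValueError("class_filter requires a population map")
        members = popmap.members_of_class(class_filter)  # raises on unknown class
        series = series[[i for i in series.index if i in set(members)]]
    return series


def mann_whitney_u(counts_a: Sequence[float], counts_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two groups of per-individual counts.

    Uses the exact null distribution when the problem is small
    (n_a * n_b <= 400) and tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), min(float(res.pvalue), 1.0)
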