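"""Presence-frequency selection scan between two populations.

Each gene's presence counts in a reference population (e.g. the wild
Bezoar progenitor) and a derived population (e.g. native or improved
domestic goats) form a 2x2 table tested with a two-sided Fisher's exact
test.  Genes with raw P below the significance threshold (0.005 by
default, no multiple-testing correction for the flag) are labeled
*favorable* when their frequency is higher in the derived population
and *unfavorable* when lower — the directions of gene gain and gene
loss under domestication or improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PopulationMap
from .pangenome import round_half_up

__all__ = [
    "ContingencyTable",
    "ScanConfig",
    "fisher_exact_two_sided",
    "scan",
    "direction_summary",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Presence/absence counts: a,b = present/absent in A; c,d in B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_a(self) -> int:
        return self.a + self.b

    @property
    def n_b(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.005
    reference_population: str = "reference"
    derived_population: str = "derived"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact P under the probability-mass convention.

    The P-value sums hypergeometric probabilities of every table with
    the same margins whose point probability does not exceed that of the
    observed table.
    """
    if table.a == table.b == table.c == table.d == 0:
        raise ValueError("all-zero contingency table")
    _, p = scipy.stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return min(float(p), 1.0)


def scan(matrix: pd.DataFrame, popmap: PopulationMap, config: ScanConfig) -> pd.DataFrame:
    """Per-gene Fisher scan between the configured populations.

    Returns one row per gene sorted by (P, gene_id) with columns
    gene_id, n_present_ref, n_ref, n_present_der, n_der, freq_ref,
    freq_der, p, q_bh, significant, direction.  The significance flag
    uses raw P < alpha; BH q-values are reported for transparency only.
    """
    ref_members = popmap.members(config.reference_population)
    der_members = popmap.members(config.derived_population)
    missing = [i for i in ref_members + der_members if i not in matrix.columns]
    if missing:
        raise KeyError(f"individuals absent from the presence matrix: {missing}")

    ref = matrix[ref_members].to_numpy(dtype=bool)
    der = matrix[der_members].to_numpy(dtype=bool)
    n_ref, n_der = ref.shape[1], der.shape[1]
    k_ref = ref.sum(axis=1)
    k_der = der.sum(axis=1)

    pvals = np.empty(len(matrix.index))
    memo: dict[tuple[int, int], float] = {}  # many genes share a table
    for i, (a, c) in enumerate(zip(k_ref, k_der)):
        key = (int(a), int(c))
        if key not in memo:
            memo[key] = fisher_exact_two_sided(
                ContingencyTable(key[0], n_ref - key[0], key[1], n_der - key[1])
            )
        pvals[i] = memo[key]
    q_bh = multipletests(pvals, method="fdr_bh")[1]

    significant = pvals < config.alpha
    direction = np.where(
        ~significant,
        "none",
        np.where(
            k_der * n_ref > k_ref * n_der,   # freq_der > freq_ref, exact
            "favorable",
            np.where(k_der * n_ref < k_ref * n_der, "unfavorable", "none"),
        ),
    )
    records = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "n_present_ref": k_ref,
            "n_ref": n_ref,
            "n_present_der": k_der,
            "n_der": n_der,
            "freq_ref": k_ref / n_ref,
            "freq_der": k_der / n_der,
            "p": pvals,
            "q_bh": q_bh,
            "significant": significant,
            "direction": direction,
        }
    )
    return records.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)


def direction_summary(records: pd.DataFrame) -> dict:
    """Counts and percentage shares of favorable/unfavorable genes.

    Percentages are half-up two-decimal shares of all significant genes.
    """
    favorable = int((records["direction"] == "favorable").sum())
    unfavorable = int((records["direction"] == "unfavorable").sum())
    significant = int(records["significant"].sum())
    if favorable + unfavorable != significant:
        raise ValueError(
            "favorable + unfavorable must equal the significant total "
            "(equal-frequency significant genes should be impossible)"
        )
    if significant:
        pct_fav = round_half_up(Fraction(100 * favorable, significant))
        pct_unf = round_half_up(Fraction(100 * unfavorable, significant))
    else:
        pct_fav = pct_unf = 0.0
    return {
        "n_significant": significant,
        "n_favorable": favorable,
        "n_unfavorable": unfavorable,
        "pct_favorable": pct_fav,
        "pct_unfavorable": pct_unf,
    }
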