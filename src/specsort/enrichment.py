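"""Exclusive/shared partitioning and Fisher's-exact reassignment.

A protein detected in only one sorted population is *exclusive* to it.
Proteins detected in both populations may still be population-specific —
cross-contamination of the sorts (damaged, unlabeled hair cells falling
into the non-sensory gate) puts counts on the wrong side — so each shared
protein's count split is tested against the overall count margins with a
two-sided Fisher's exact test and reassigned when p < alpha.

The 2x2 table for a protein with counts (a, b) against population margins
(T_H, T_N) is [a, b; T_H - a, T_N - b]: the protein's spectra versus all
other retained spectra in each population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .spectral_counting import CountProfile

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "VennSummary",
    "classify_exclusive",
    "fisher_exact_two_sided",
    "reassign_shared",
    "classify_proteins",
    "venn_shared_count",
    "filter_printed_pvalues",
    "format_pvalue",
    "results_to_frame",
]

#: Relative slack when deciding which tables are "as or less likely" than
#: the observed one; guards against floating-point ties in the pmf.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 spectral-count table: protein vs rest, HC vs NSC columns."""

    a: int  # protein count in HC
    b: int  # protein count in NSC
    c: int  # remaining HC margin
    d: int  # remaining NSC margin

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def margin_HC(self) -> int:
        return self.a + self.c

    @property
    def margin_NSC(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    accession: str
    category: Literal[
        "HC_ONLY", "NSC_ONLY", "HC_ENRICHED", "NSC_ENRICHED", "SHARED_UNRESOLVED"
    ]
    p_value: float
    direction: Literal["HC", "NSC", "none"]
    table: ContingencyTable | None


@dataclass(frozen=True)
class VennSummary:
    n_HC_only: int
    n_NSC_only: int
    n_shared: int

    @property
    def n_total(self) -> int:
        return self.n_HC_only + self.n_NSC_only + self.n_shared


def classify_exclusive(
    profiles: Sequence[CountProfile],
) -> tuple[VennSummary, dict[str, str]]:
    """Partition proteins into HC-only / NSC-only / shared by zero counts."""
    categories: dict[str, str] = {}
    for p in profiles:
        a, b = p.count_HC, p.count_NSC
        if a == 0 and b == 0:
            raise ValueError(
                f"protein {p.accession!r} has zero counts in both populations; "
                "it cannot have passed the upstream filter"
            )
        if b == 0:
            categories[p.accession] = "HC_ONLY"
        elif a == 0:
            categories[p.accession] = "NSC_ONLY"
        else:
            categories[p.accession] = "SHARED"
    summary = VennSummary(
        n_HC_only=sum(1 for c in categories.values() if c == "HC_ONLY"),
        n_NSC_only=sum(1 for c in categories.values() if c == "NSC_ONLY"),
        n_shared=sum(1 for c in categories.values() if c == "SHARED"),
    )
    return summary, categories


def fisher_exact_two_sided(
    table: ContingencyTable,
    method: Literal["min_likelihood", "double_tail"] = "min_likelihood",
) -> float:
    """Exact two-sided p-value for a 2x2 table with fixed margins.

    Under the null the HC cell count follows a hypergeometric law over all
    tables with the observed margins.  ``min_likelihood`` (the default,
    and the convention of most statistical software) sums the point
    probabilities of every table no more probable than the observed one;
    ``double_tail`` doubles the smaller one-sided tail (capped at 1).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    M = a + b + c + d  # all spectra
    K = a + c          # HC column margin
    n = a + b          # protein row margin
    if M == 0:
        return 1.0
    rv = hypergeom(M, K, n)
    support = np.arange(max(0, n - (M - K)), min(n, K) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    if method == "min_likelihood":
        p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    elif method == "double_tail":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    # the full support sums to 1 up to rounding; snap rather than report 1-1e-12
    if p >= 1.0 - 1e-9:
        return 1.0
    return max(p, 0.0)


def reassign_shared(
    profiles: Sequence[CountProfile],
    margins: tuple[int, int] | None = None,
    alpha: float = 0.05,
    method: Literal["min_likelihood", "double_tail"] = "min_likelihood",
) -> list[EnrichmentResult]:
    """Test each shared protein's count split against the margins.

    ``margins`` defaults to the total retained spectral counts per
    population over the whole profile set.  A shared protein with
    p < alpha is reassigned toward the population where its count share
    exceeds the margin share; otherwise it stays SHARED_UNRESOLVED.
    Exclusive proteins are passed through with their exclusive category
    and no test.
    """
    if margins is None:
        margins = (sum(p.count_HC for p in profiles),
                   sum(p.count_NSC for p in profiles))
    T_H, T_N = margins
    results: list[EnrichmentResult] = []
    for p in profiles:
        a, b = p.count_HC, p.count_NSC
        if a > T_H or b > T_N:
            raise ValueError(
                f"margins ({T_H}, {T_N}) smaller than counts of {p.accession!r}"
            )
        if a == 0 or b == 0:
            _, cats = classify_exclusive([p])
            results.append(
                EnrichmentResult(p.accession, cats[p.accession], 1.0, "none", None)
            )
            continue
        table = ContingencyTable(a, b, T_H - a, T_N - b)
        pval = fisher_exact_two_sided(table, method)
        if pval < alpha:
            share_hc = a / T_H
            share_nsc = b / T_N
            if share_hc > share_nsc:
                cat, direction = "HC_ENRICHED", "HC"
            elif share_nsc > share_hc:
                cat, direction = "NSC_ENRICHED", "NSC"
            else:  # only possible with degenerate margins
                cat, direction = "SHARED_UNRESOLVED", "none"
        else:
            cat, direction = "SHARED_UNRESOLVED", "none"
        results.append(EnrichmentResult(p.accession, cat, pval, direction, table))
    return results


def classify_proteins(
    profiles: Sequence[CountProfile],
    margins: tuple[int, int] | None = None,
    alpha: float = 0.05,
    method: Literal["min_likelihood", "double_tail"] = "min_likelihood",
) -> tuple[VennSummary, list[EnrichmentResult]]:
    """Full classification: exclusive partition plus shared reassignment."""
    summary, _ = classify_exclusive(profiles)
    return summary, reassign_shared(profiles, margins, alpha, method)


def venn_shared_count(n_total: int, n_HC_only: int, n_NSC_only: int) -> int:
    """Number of shared proteins implied by the totals."""
    shared = n_total - n_HC_only - n_NSC_only
    if shared < 0:
        raise ValueError(
            f"exclusive counts {n_HC_only}+{n_NSC_only} exceed total {n_total}"
        )
    return shared


def filter_printed_pvalues(pvalues: Iterable[float], alpha: float = 0.05) -> np.ndarray:
    """Significance mask for p-values printed at reduced precision.

    Published tables round p to ~2 significant digits, so a value printed
    exactly at alpha (e.g. "0.05") represents an underlying p < alpha;
    the comparison is therefore <=.  Use strict < on full-precision
    values (see :func:`reassign_shared`).
    """
    return np.asarray(list(pvalues), dtype=float) <= alpha


def format_pvalue(p: float) -> str:
    """Table-style p formatting: 2 significant digits, underflow as 0."""
    if p < 1e-300:
        return "0"
    return f"{p:.2g}"


def results_to_frame(results: Sequence[EnrichmentResult],
                     bh_column: bool = True) -> pd.DataFrame:
    """Tabulate results; optionally append Benjamini-Hochberg q-values.

    The q-value column is informational only — classification uses the
    raw alpha cutoff.
    """
    frame = pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "category": [r.category for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "p_printed": [format_pvalue(r.p_value) for r in results],
        }
    )
    if bh_column and len(frame):
        from statsmodels.stats.multitest import multipletests

        frame["q_value_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame
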