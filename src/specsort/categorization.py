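"""Category profiling of a protein list by localization or function.

Two weightings are reported for each category vocabulary: the fraction of
*proteins* falling in a category ("before quantification") and the
fraction of *spectral counts* ("after quantification").  Comparing the
two shows which compartments or functions are dominated by a few highly
abundant proteins.  Annotations are a user-supplied table — categories
depend on the annotation snapshot used, so no live ontology lookup is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .spectral_counting import CountProfile

__all__ = ["AnnotationMap", "CategoryProfile", "profile_categories", "compare_profiles"]

NOT_ANNOTATED = "not annotated"


@dataclass
class AnnotationMap:
    """Accession -> (localization, function), with ordered vocabularies.

    Unmapped accessions resolve to ``"not annotated"``, which is appended
    to each vocabulary when absent.  A protein annotated with several
    categories keeps the first listed one.
    """

    localization: Mapping[str, str]
    function: Mapping[str, str]
    localization_vocabulary: list[str]
    function_vocabulary: list[str]

    def __post_init__(self) -> None:
        for vocab_name in ("localization_vocabulary", "function_vocabulary"):
            vocab = getattr(self, vocab_name)
            if not vocab:
                raise ValueError(f"{vocab_name} is empty")
            if NOT_ANNOTATED not in vocab:
                vocab.append(NOT_ANNOTATED)
        for axis in ("localization", "function"):
            vocab = set(getattr(self, f"{axis}_vocabulary"))
            bad = set(getattr(self, axis).values()) - vocab
            if bad:
                raise ValueError(f"{axis} categories outside vocabulary: {sorted(bad)}")

    def category(self, accession: str, axis: Literal["localization", "function"]) -> str:
        return getattr(self, axis).get(accession, NOT_ANNOTATED)


@dataclass
class CategoryProfile:
    """Per-category proportions under both weightings."""

    axis: str
    categories: list[str]
    proportion_before: pd.Series  # protein-count weighted
    proportion_after: pd.Series   # spectral-count weighted
    n_proteins: int
    n_counts: int


def profile_categories(
    proteins: Sequence[CountProfile],
    annot: AnnotationMap,
    axis: Literal["localization", "function"] = "localization",
    population: Literal["HC", "NSC", "both"] = "both",
) -> CategoryProfile:
    """Category proportions of a protein list, protein- and count-weighted.

    ``population`` selects which spectral counts weight the "after"
    proportions; the protein list itself is taken as given (subset it
    upstream for population-specific panels).
    """
    if not proteins:
        raise ValueError("protein list is empty")
    vocab = list(getattr(annot, f"{axis}_vocabulary"))
    n_prot = pd.Series(0, index=vocab, dtype=float)
    n_cnt = pd.Series(0, index=vocab, dtype=float)
    for p in proteins:
        cat = annot.category(p.accession, axis)
        count = {
            "HC": p.count_HC,
            "NSC": p.count_NSC,
            "both": p.count_HC + p.count_NSC,
        }[population]
        n_prot[cat] += 1
        n_cnt[cat] += count
    total_counts = n_cnt.sum()
    return CategoryProfile(
        axis=axis,
        categories=vocab,
        proportion_before=n_prot / n_prot.sum(),
        proportion_after=n_cnt / total_counts if total_counts else n_prot / n_prot.sum(),
        n_proteins=int(n_prot.sum()),
        n_counts=int(total_counts),
    )


def compare_profiles(profile_HC: CategoryProfile,
                     profile_NSC: CategoryProfile) -> pd.DataFrame:
    """Signed per-category differences in percentage points (HC - NSC)."""
    if list(profile_HC.categories) != list(profile_NSC.categories):
        raise ValueError("category vocabularies differ between profiles")
    return pd.DataFrame(
        {
            "category": profile_HC.categories,
            "diff_before_pp": (
                100 * (profile_HC.proportion_before - profile_NSC.proportion_before)
            ).to_numpy(),
            "diff_after_pp": (
                100 * (profile_HC.proportion_after - profile_NSC.proportion_after)
            ).to_numpy(),
        }
    )
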