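"""Concatenated target-decoy FDR estimation and cascade filtering.

Spectra are searched against a composite database of target protein
sequences plus their reversals (accessions prefixed ``REV_``).  Incorrect
matches land on targets and decoys in roughly equal proportion, so with T
target and D decoy hits above a score threshold the expected fraction of
incorrect matches among *all* accepted hits is estimated as 2D/(T+D).

Filtering cascades PSM -> peptide -> protein: each unique peptide is
represented by its best-scoring PSM, each protein group by its best
peptide, and a minimum number of distinct peptides per protein is enforced
before the protein-level threshold is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

DECOY_PREFIX = "REV_"

__all__ = [
    "DECOY_PREFIX",
    "PSM",
    "FilterPolicy",
    "FilteredSet",
    "UnsatisfiableFDR",
    "build_decoy_database",
    "estimate_fdr",
    "threshold_for_fdr",
    "apply_filter_policy",
]


@dataclass(frozen=True)
class PSM:
    """One scored peptide-spectrum match.

    ``group`` is the sorted cell population the run came from (``HC`` for
    the dye-high presumptive hair cells, ``NSC`` for the dye-low
    non-sensory cells); ``fraction`` the gel fraction of the run.
    """

    spectrum_id: str
    experiment_id: int
    group: str
    fraction: int
    peptide: str
    mods: tuple[tuple[int, str], ...]
    charge: int
    experimental_mz: float
    score: float
    proteins: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"PSM {self.spectrum_id!r} maps to no protein")
        if self.group not in ("HC", "NSC"):
            raise ValueError(f"group must be 'HC' or 'NSC', got {self.group!r}")

    @property
    def is_decoy(self) -> bool:
        """True iff every mapped accession is a decoy."""
        return all(p.startswith(DECOY_PREFIX) for p in self.proteins)

    @property
    def peptide_key(self) -> tuple[str, tuple[tuple[int, str], ...]]:
        """Peptide identity: sequence plus modification set, charge-agnostic."""
        return (self.peptide, tuple(sorted(self.mods)))


@dataclass(frozen=True)
class FilterPolicy:
    """FDR maxima per level plus the distinct-peptides-per-protein floor."""

    psm_fdr_max: float = 0.05
    peptide_fdr_max: float = 0.01
    protein_fdr_max: float = 0.03
    min_peptides_per_protein: int = 2

    def __post_init__(self) -> None:
        for name in ("psm_fdr_max", "peptide_fdr_max", "protein_fdr_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")


@dataclass
class PeptideEvidence:
    """Best-scoring evidence for one unique peptide (sequence + mods)."""

    key: tuple[str, tuple[tuple[int, str], ...]]
    best_psm: PSM
    n_psms: int
    proteins: tuple[str, ...]

    @property
    def score(self) -> float:
        return self.best_psm.score

    @property
    def is_decoy(self) -> bool:
        return all(p.startswith(DECOY_PREFIX) for p in self.proteins)


@dataclass
class ProteinGroup:
    """Single-accession protein group with its distinct retained peptides."""

    accession: str
    peptide_keys: tuple[tuple[str, tuple[tuple[int, str], ...]], ...]
    score: float

    @property
    def is_decoy(self) -> bool:
        return self.accession.startswith(DECOY_PREFIX)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_keys)


@dataclass
class FilteredSet:
    """Outcome of the PSM -> peptide -> protein filtering cascade."""

    psms: list[PSM]
    peptides: dict
    proteins: dict
    achieved_psm_fdr: float
    achieved_peptide_fdr: float
    achieved_protein_fdr: float
    thresholds: dict
    diagnostics: list = field(default_factory=list)

    @property
    def n_psms(self) -> int:
        return len(self.psms)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)


class UnsatisfiableFDR(Exception):
    """No score threshold achieves the requested FDR."""


def build_decoy_database(targets: Mapping[str, str]) -> dict[str, str]:
    """Append one reversed-sequence decoy per target record.

    Returns an ordered mapping of 2N records: every target followed by its
    reversal under the accession prefix ``REV_``.  Accessions already
    carrying the prefix are rejected, as are duplicates (mapping input
    makes duplicates impossible; sequences may repeat, e.g. palindromes).
    """
    if not targets:
        raise ValueError("target database is empty")
    out: dict[str, str] = {}
    for acc, seq in targets.items():
        if acc.startswith(DECOY_PREFIX):
            raise ValueError(f"target accession {acc!r} already carries {DECOY_PREFIX!r}")
        out[acc] = seq
    for acc, seq in targets.items():
        out[DECOY_PREFIX + acc] = seq[::-1]
    return out


def estimate_fdr(
    hits: Sequence[tuple[float, bool]],
    threshold: float,
    estimator: Literal["concatenated", "decoy_ratio"] = "concatenated",
) -> float:
    """Estimated FDR among hits with score >= threshold, capped at 1.

    ``concatenated`` is 2D/(T+D) (both halves of the incorrect matches are
    removed from the report, but both were counted while estimating);
    ``decoy_ratio`` is the simple D/T alternative.
    """
    if not hits:
        raise ValueError("empty hit list")
    t = d = 0
    for score, is_decoy in hits:
        if score >= threshold:
            if is_decoy:
                d += 1
            else:
                t += 1
    if t + d == 0:
        return 0.0
    if estimator == "concatenated":
        return min(1.0, 2.0 * d / (t + d))
    if estimator == "decoy_ratio":
        if t == 0:
            return 1.0 if d else 0.0
        return min(1.0, d / t)
    raise ValueError(f"unknown estimator {estimator!r}")


def threshold_for_fdr(
    hits: Sequence[tuple[float, bool]],
    fdr_max: float,
    estimator: Literal["concatenated", "decoy_ratio"] = "concatenated",
) -> float:
    """Lowest score threshold whose estimated FDR is <= fdr_max.

    Candidate thresholds are the distinct hit scores (comparison is >=, so
    ties at the threshold are retained).  Picking the lowest qualifying
    threshold maximises retained hits; because the qualifying set only
    shrinks as fdr_max decreases, retention is monotone in fdr_max.

    Raises :class:`UnsatisfiableFDR` when even the strictest threshold
    fails the bound.
    """
    if not hits:
        raise ValueError("empty hit list")
    import numpy as np

    scores = np.array([s for s, _ in hits], dtype=float)
    decoys = np.array([d for _, d in hits], dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, decoys = scores[order], decoys[order]
    cum_d = np.cumsum(decoys)
    cum_n = np.arange(1, len(scores) + 1)
    # prefix boundaries: last index of each distinct score (ties included)
    last = np.nonzero(np.diff(scores, append=np.nan) != 0)[0]
    d, n = cum_d[last], cum_n[last]
    if estimator == "concatenated":
        est = np.minimum(1.0, 2.0 * d / n)
    elif estimator == "decoy_ratio":
        t = n - d
        est = np.where(t == 0, np.where(d > 0, 1.0, 0.0),
                       np.minimum(1.0, d / np.maximum(t, 1)))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    ok = np.nonzero(est <= fdr_max)[0]
    if ok.size == 0:
        raise UnsatisfiableFDR(
            f"no score threshold achieves FDR <= {fdr_max} "
            f"(best at strictest threshold: {est[0]:.4f})"
        )
    return float(scores[last[ok[-1]]])


def _empty_set(policy: FilterPolicy, reason: str) -> FilteredSet:
    return FilteredSet(
        psms=[],
        peptides={},
        proteins={},
        achieved_psm_fdr=0.0,
        achieved_peptide_fdr=0.0,
        achieved_protein_fdr=0.0,
        thresholds={},
        diagnostics=[f"policy unsatisfiable: {reason}"],
    )


def apply_filter_policy(
    psms: Sequence[PSM],
    policy: FilterPolicy,
    estimator: Literal["concatenated", "decoy_ratio"] = "concatenated",
) -> FilteredSet:
    """Cascade PSM, peptide and protein FDR filtering.

    Decoy entries drive the thresholds and achieved-FDR estimates, then
    are removed from the returned report.  An unsatisfiable policy yields
    an empty :class:`FilteredSet` with diagnostics rather than raising.
    """
    if not psms:
        return _empty_set(policy, "no input PSMs")

    ordered = sorted(psms, key=lambda p: (-p.score, p.spectrum_id))

    # --- PSM level -------------------------------------------------------
    psm_hits = [(p.score, p.is_decoy) for p in ordered]
    try:
        psm_thr = threshold_for_fdr(psm_hits, policy.psm_fdr_max, estimator)
    except UnsatisfiableFDR as exc:
        return _empty_set(policy, f"PSM level: {exc}")
    achieved_psm = estimate_fdr(psm_hits, psm_thr, estimator)
    retained_psms = [p for p in ordered if p.score >= psm_thr]

    # --- peptide level ---------------------------------------------------
    peptides: dict = {}
    for p in retained_psms:
        key = p.peptide_key
        ev = peptides.get(key)
        if ev is None:
            peptides[key] = PeptideEvidence(key, p, 1, tuple(sorted(set(p.proteins))))
        else:
            ev.n_psms += 1
            ev.proteins = tuple(sorted(set(ev.proteins) | set(p.proteins)))
            if p.score > ev.best_psm.score:
                ev.best_psm = p
    pep_hits = [(ev.score, ev.is_decoy) for ev in peptides.values()]
    try:
        pep_thr = threshold_for_fdr(pep_hits, policy.peptide_fdr_max, estimator)
    except UnsatisfiableFDR as exc:
        return _empty_set(policy, f"peptide level: {exc}")
    achieved_pep = estimate_fdr(pep_hits, pep_thr, estimator)
    retained_peptides = {k: ev for k, ev in peptides.items() if ev.score >= pep_thr}

    # --- protein level ---------------------------------------------------
    by_protein: dict[str, list] = {}
    for ev in retained_peptides.values():
        for acc in ev.proteins:
            by_protein.setdefault(acc, []).append(ev)
    groups = {
        acc: ProteinGroup(
            accession=acc,
            peptide_keys=tuple(sorted(ev.key for ev in evs)),
            score=max(ev.score for ev in evs),
        )
        for acc, evs in by_protein.items()
        if len({ev.key for ev in evs}) >= policy.min_peptides_per_protein
    }
    if not groups:
        return _empty_set(policy, "no protein reaches min_peptides_per_protein")
    prot_hits = [(g.score, g.is_decoy) for g in groups.values()]
    try:
        prot_thr = threshold_for_fdr(prot_hits, policy.protein_fdr_max, estimator)
    except UnsatisfiableFDR as exc:
        return _empty_set(policy, f"protein level: {exc}")
    achieved_prot = estimate_fdr(prot_hits, prot_thr, estimator)
    retained_proteins = {
        acc: g for acc, g in groups.items() if g.score >= prot_thr and not g.is_decoy
    }

    # --- final report: decoys out, evidence restricted to retained ------
    retained_pep_keys = {
        k for k, ev in retained_peptides.items()
        if any(acc in retained_proteins for acc in ev.proteins)
    }
    final_peptides = {
        k: ev for k, ev in retained_peptides.items()
        if k in retained_pep_keys and not ev.is_decoy
    }
    final_psms = [
        p for p in retained_psms
        if p.peptide_key in final_peptides
        and any(acc in retained_proteins for acc in p.proteins)
    ]
    logger.info(
        "filter cascade: %d/%d PSMs, %d peptides, %d proteins "
        "(achieved FDR psm=%.4f pep=%.4f prot=%.4f)",
        len(final_psms), len(psms), len(final_peptides), len(retained_proteins),
        achieved_psm, achieved_pep, achieved_prot,
    )
    return FilteredSet(
        psms=final_psms,
        peptides=final_peptides,
        proteins=retained_proteins,
        achieved_psm_fdr=achieved_psm,
        achieved_peptide_fdr=achieved_pep,
        achieved_protein_fdr=achieved_prot,
        thresholds={"psm": psm_thr, "peptide": pep_thr, "protein": prot_thr},
    )
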