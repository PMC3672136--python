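"""Ground-truth-labelled synthetic protein databases and PSM tables.

Emulates the study design the pipeline is built for: two FACS-sorted cell
populations (HC and NSC) measured in 3 independent runs each, every run
split over 8 gel fractions, searched against a concatenated target-decoy
database.  Designated proteins are population-specific (present in one
population's abundance profile only) or enriched (up-weighted by a fold
factor); the NSC sort is contaminated by a fraction ``epsilon`` of
spectra drawn from the HC abundance profile, mimicking damaged unlabeled
hair cells falling into the dye-low gate.

Abundances are a single symmetric Dirichlet draw over proteins, shared by
both populations, with class-specific multiplicative bumps — balanced
proteins therefore have identical expected count rates in both
populations.  Search scores are two Gaussians (correct vs incorrect
match), a stand-in for a database-search score that is adequate for
FDR-calibration work.  Peptides are sampled from an in-silico tryptic
digest (cleave after K/R, not before P, up to 2 missed cleavages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masscalc import Peptide, monoisotopic_mass, precursor_mz
from .target_decoy import DECOY_PREFIX, PSM, build_decoy_database

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDatabase",
    "tryptic_peptides",
    "generate_database",
    "generate_psms",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Peptide length window retained from the digest; shorter tryptic
#: fragments are rarely identified, longer ones rarely fragment cleanly.
MIN_PEPTIDE_LEN = 6
MAX_PEPTIDE_LEN = 40


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated design: 3 runs per population at a depth
    of 5,000 PSMs each, 8 gel fractions, 20 designated proteins per
    specific/enriched class at 8-fold enrichment, 5% contamination of the
    NSC sort, and a 10% incorrect-match rate.
    """

    n_proteins: int = 300
    n_HC_specific: int = 20
    n_NSC_specific: int = 20
    n_HC_enriched: int = 20
    n_NSC_enriched: int = 20
    enrichment_fold: float = 8.0
    psms_per_run: int = 5000
    n_runs_per_group: int = 3
    n_fractions: int = 8
    contamination_epsilon: float = 0.05
    decoy_hit_rate: float = 0.10
    correct_score: tuple[float, float] = (3.5, 0.8)
    incorrect_score: tuple[float, float] = (1.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        designated = (self.n_HC_specific + self.n_NSC_specific
                      + self.n_HC_enriched + self.n_NSC_enriched)
        if designated > self.n_proteins:
            raise ValueError("designated protein classes exceed n_proteins")
        if not (0.0 <= self.contamination_epsilon < 1.0):
            raise ValueError("contamination_epsilon must be in [0, 1)")
        if self.enrichment_fold <= 1.0:
            raise ValueError("enrichment_fold must exceed 1")
        if not (0.0 <= self.decoy_hit_rate <= 1.0):
            raise ValueError("decoy_hit_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """True protein classes and per-PSM correctness labels."""

    protein_class: dict[str, str]
    psm_correct: dict[str, bool] = field(default_factory=dict)


def tryptic_peptides(
    sequence: str,
    missed_cleavages: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P."""
    sites = [0]
    for i, r in enumerate(sequence[:-1]):
        if r in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    sites.append(len(sequence))
    peptides: list[str] = []
    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(sites))):
            pep = sequence[sites[i]:sites[j]]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


@dataclass
class SyntheticDatabase:
    """Target + decoy records with ground-truth classes and cached digest."""

    targets: dict[str, str]
    composite: dict[str, str]
    protein_class: dict[str, str]
    peptides: dict[str, list[str]] = field(default_factory=dict, repr=False)
    peptide_mz2: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def accessions(self) -> list[str]:
        return list(self.targets)

    def digest(self, accession: str) -> list[str]:
        if accession not in self.peptides:
            peps = tryptic_peptides(self.composite[accession])
            self.peptides[accession] = peps
            self.peptide_mz2[accession] = np.array(
                [precursor_mz(monoisotopic_mass(Peptide(p)), 2) for p in peps]
            )
        return self.peptides[accession]


_CLASS_ORDER = ("HC_SPECIFIC", "NSC_SPECIFIC", "HC_ENRICHED", "NSC_ENRICHED")


def generate_database(config: SyntheticConfig) -> SyntheticDatabase:
    """Random protein records (length 100-600) with designated classes.

    Deterministic under ``config.seed``; the first proteins in accession
    order carry the designated classes, the remainder are balanced.
    """
    rng = np.random.default_rng(config.seed)
    targets: dict[str, str] = {}
    classes: dict[str, str] = {}
    sizes = [config.n_HC_specific, config.n_NSC_specific,
             config.n_HC_enriched, config.n_NSC_enriched]
    labels: list[str] = []
    for label, k in zip(_CLASS_ORDER, sizes):
        labels += [label] * k
    labels += ["BALANCED"] * (config.n_proteins - len(labels))
    width = max(4, len(str(config.n_proteins)))
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:0{width}d}"
        length = int(rng.integers(100, 601))
        targets[acc] = "".join(rng.choice(_RESIDUES, size=length))
        classes[acc] = labels[i]
    composite = build_decoy_database(targets) if targets else {}
    return SyntheticDatabase(targets=targets, composite=composite,
                             protein_class=classes)


def _abundance_profiles(config: SyntheticConfig,
                        db: SyntheticDatabase,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """HC and NSC sampling profiles over target proteins (rows sum to 1).

    Balanced (shared) proteins draw their relative abundances from a
    symmetric Dirichlet; designated proteins get the deterministic mean
    weight 1/n before their class bump.  Keeping the designated classes'
    total mass deterministic makes a symmetric design yield *exactly*
    equal sampling rates for balanced proteins in both populations —
    otherwise the random class-mass imbalance would shift every balanced
    protein's share between groups.
    """
    n = len(db.targets)
    cls = np.array([db.protein_class[a] for a in db.accessions])
    base = np.full(n, 1.0 / n)
    bal = cls == "BALANCED"
    if bal.any():
        base[bal] = rng.dirichlet(np.ones(bal.sum())) * (bal.sum() / n)
    w_hc = base.copy()
    w_nsc = base.copy()
    w_hc[cls == "NSC_SPECIFIC"] = 0.0
    w_nsc[cls == "HC_SPECIFIC"] = 0.0
    w_hc[cls == "HC_ENRICHED"] *= config.enrichment_fold
    w_nsc[cls == "NSC_ENRICHED"] *= config.enrichment_fold
    # proteins whose digest yields no sampleable peptide are resampled away
    has_pep = np.array([len(db.digest(a)) > 0 for a in db.accessions])
    w_hc[~has_pep] = 0.0
    w_nsc[~has_pep] = 0.0
    return w_hc / w_hc.sum(), w_nsc / w_nsc.sum()


def _length_fractions(db: SyntheticDatabase, n_fractions: int) -> dict[str, int]:
    """Gel fraction per protein: octile (generally n-tile) of sequence length."""
    accs = db.accessions
    lengths = np.array([len(db.targets[a]) for a in accs])
    order = np.argsort(np.argsort(lengths, kind="stable"), kind="stable")
    frac = 1 + (order * n_fractions) // len(accs)
    return dict(zip(accs, frac.astype(int)))


def generate_psms(
    config: SyntheticConfig,
    db: SyntheticDatabase,
) -> tuple[list[PSM], GroundTruth]:
    """Simulate all runs of the design into one labelled PSM table.

    Each run draws ``psms_per_run`` spectra.  Correct matches sample a
    protein from the run's population profile (NSC runs from the
    epsilon-contaminated mixture), then a uniform tryptic peptide of that
    protein; incorrect matches are injected at ``decoy_hit_rate`` and land
    on a reversed (decoy) or random target sequence with equal
    probability, scored from the incorrect distribution.  One RNG stream
    per run, seeded ``seed + run_index``, keeps runs independently
    reproducible.
    """
    accs = db.accessions
    if not accs:
        return [], GroundTruth(protein_class=dict(db.protein_class))
    profile_rng = np.random.default_rng(config.seed)
    w_hc, w_nsc = _abundance_profiles(config, db, profile_rng)
    eps = config.contamination_epsilon
    w_nsc_run = (1.0 - eps) * w_nsc + eps * w_hc
    fractions = _length_fractions(db, config.n_fractions)
    decoy_accs = [DECOY_PREFIX + a for a in accs
                  if len(db.digest(DECOY_PREFIX + a)) > 0]
    target_ok = [a for a in accs if len(db.digest(a)) > 0]

    truth = GroundTruth(protein_class=dict(db.protein_class))
    psms: list[PSM] = []
    run_index = 0
    for group, w in (("HC", w_hc), ("NSC", w_nsc_run)):
        for exp_id in range(1, config.n_runs_per_group + 1):
            rng = np.random.default_rng(config.seed + run_index)
            n = config.psms_per_run
            incorrect = rng.random(n) < config.decoy_hit_rate
            prot_idx = rng.choice(len(accs), size=n, p=w)
            on_decoy = rng.random(n) < 0.5
            wrong_idx = rng.integers(0, len(target_ok), size=n)
            decoy_idx = rng.integers(0, max(len(decoy_accs), 1), size=n)
            charges = rng.choice([2, 3], size=n, p=[0.7, 0.3])
            ppm_noise = rng.normal(0.0, 1.0, size=n)  # ~1 ppm instrument error
            scores = np.where(
                incorrect,
                rng.normal(*config.incorrect_score, size=n),
                rng.normal(*config.correct_score, size=n),
            )
            rand_frac = rng.integers(1, config.n_fractions + 1, size=n)
            pep_u = rng.random(n)
            for i in range(n):
                if incorrect[i] and decoy_accs and on_decoy[i]:
                    acc = decoy_accs[decoy_idx[i]]
                elif incorrect[i]:
                    acc = target_ok[wrong_idx[i]]
                else:
                    acc = accs[prot_idx[i]]
                peps = db.digest(acc)
                j = int(pep_u[i] * len(peps))
                pep = peps[j]
                z = int(charges[i])
                mz2 = db.peptide_mz2[acc][j]
                neutral = (mz2 - 1.00727646688) * 2
                theo = (neutral + z * 1.00727646688) / z
                sid = f"run{run_index}_scan{i + 1}"
                psms.append(
                    PSM(
                        spectrum_id=sid,
                        experiment_id=exp_id,
                        group=group,
                        fraction=int(rand_frac[i]) if incorrect[i]
                        else fractions.get(acc.removeprefix(DECOY_PREFIX),
                                           int(rand_frac[i])),
                        peptide=pep,
                        mods=(),
                        charge=z,
                        experimental_mz=theo * (1.0 + ppm_noise[i] * 1e-6),
                        score=float(scores[i]),
                        proteins=(acc,),
                    )
                )
                truth.psm_correct[sid] = not bool(incorrect[i])
            run_index += 1
    return psms, truth
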