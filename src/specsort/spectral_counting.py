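"""Spectral counting: per-protein, per-population PSM tallies.

Every retained PSM contributes one count to every protein it maps to
(shared peptides multi-count, an acknowledged upward bias), split by
population group and experiment, alongside the number of independent
experiments a protein was observed in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .target_decoy import PSM, FilteredSet

logger = logging.getLogger(__name__)

__all__ = ["CountProfile", "count_spectra", "profiles_to_frame"]


@dataclass
class CountProfile:
    """Summed spectral counts for one protein, split by population."""

    accession: str
    description: str = ""
    per_experiment: dict = field(default_factory=dict)  # (experiment_id, group) -> count
    count_missing: bool = False

    @property
    def count_HC(self) -> int:
        return sum(c for (_, g), c in self.per_experiment.items() if g == "HC")

    @property
    def count_NSC(self) -> int:
        return sum(c for (_, g), c in self.per_experiment.items() if g == "NSC")

    @property
    def experiments_observed_HC(self) -> int:
        return sum(1 for (_, g), c in self.per_experiment.items() if g == "HC" and c >= 1)

    @property
    def experiments_observed_NSC(self) -> int:
        return sum(1 for (_, g), c in self.per_experiment.items() if g == "NSC" and c >= 1)

    @property
    def experiments_observed_total(self) -> int:
        return self.experiments_observed_HC + self.experiments_observed_NSC


def count_spectra(filtered: FilteredSet | list[PSM],
                  retained_proteins: set[str] | None = None) -> list[CountProfile]:
    """Aggregate retained PSMs into :class:`CountProfile` records.

    Accepts either the output of the filter cascade (protein set taken
    from it) or a bare PSM list with an explicit retained-protein set
    (``None`` retains every mapped protein).  PSMs whose proteins were all
    dropped upstream are ignored with a warning.
    """
    if isinstance(filtered, FilteredSet):
        psms = filtered.psms
        retained = set(filtered.proteins)
    else:
        psms = list(filtered)
        retained = retained_proteins
    profiles: dict[str, CountProfile] = {}
    n_orphans = 0
    for psm in psms:
        accs = [a for a in psm.proteins if retained is None or a in retained]
        if not accs:
            n_orphans += 1
            continue
        for acc in accs:
            prof = profiles.setdefault(acc, CountProfile(acc))
            key = (psm.experiment_id, psm.group)
            prof.per_experiment[key] = prof.per_experiment.get(key, 0) + 1
    if n_orphans:
        logger.warning("%d PSMs referenced no retained protein and were ignored",
                       n_orphans)
    return sorted(profiles.values(), key=lambda p: p.accession)


def profiles_to_frame(profiles: list[CountProfile]) -> pd.DataFrame:
    """Tabulate profiles in the report column layout."""
    return pd.DataFrame(
        {
            "accession": [p.accession for p in profiles],
            "description": [p.description for p in profiles],
            "experiments_observed_HC": [p.experiments_observed_HC for p in profiles],
            "experiments_observed_NSC": [p.experiments_observed_NSC for p in profiles],
            "sum_count_HC": [p.count_HC for p in profiles],
            "sum_count_NSC": [p.count_NSC for p in profiles],
        }
    )
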