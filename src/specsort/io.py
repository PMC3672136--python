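"""File formats: FASTA databases, PSM tables, annotations, fixtures.

The PSM table is a UTF-8, tab-separated file with header columns
``spectrum_id, experiment_id, group, fraction, peptide, mods, charge,
exp_mz, score, proteins``; ``proteins`` is a semicolon-separated
accession list and ``mods`` a semicolon-separated list of
``position:name`` pairs (empty when unmodified).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .categorization import NOT_ANNOTATED, AnnotationMap
from .masscalc import Modification, ModificationRegistry
from .spectral_counting import CountProfile
from .target_decoy import PSM

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_annotations",
    "read_modifications",
    "load_fixture",
    "fixture_profiles",
    "FIXTURE_NAMES",
]

PSM_COLUMNS = [
    "spectrum_id", "experiment_id", "group", "fraction", "peptide",
    "mods", "charge", "exp_mz", "score", "proteins",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered accession -> sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records.items()),
        str(path),
        "fasta",
    )


def _format_mods(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def _parse_mods(text: str) -> tuple[tuple[int, str], ...]:
    if not text or text != text:  # empty or NaN
        return ()
    out = []
    for item in str(text).split(";"):
        pos, name = item.split(":", 1)
        out.append((int(pos), name))
    return tuple(out)


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    psms = list(psms)
    frame = pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "experiment_id": [p.experiment_id for p in psms],
            "group": [p.group for p in psms],
            "fraction": [p.fraction for p in psms],
            "peptide": [p.peptide for p in psms],
            "mods": [_format_mods(p.mods) for p in psms],
            "charge": [p.charge for p in psms],
            "exp_mz": [round(p.experimental_mz, 4) for p in psms],
            "score": [p.score for p in psms],
            "proteins": [";".join(p.proteins) for p in psms],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> list[PSM]:
    frame = pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False,
                        na_values=[""])
    missing = set(PSM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"PSM table {path} lacks columns: {sorted(missing)}")
    out: list[PSM] = []
    for row in frame.itertuples(index=False):
        out.append(
            PSM(
                spectrum_id=str(row.spectrum_id),
                experiment_id=int(row.experiment_id),
                group=str(row.group),
                fraction=int(row.fraction),
                peptide=str(row.peptide),
                mods=_parse_mods(row.mods if isinstance(row.mods, str) else ""),
                charge=int(row.charge),
                experimental_mz=float(row.exp_mz),
                score=float(row.score),
                proteins=tuple(str(row.proteins).split(";")),
            )
        )
    return out


def read_annotations(
    path: str | Path,
    localization_vocabulary: list[str] | None = None,
    function_vocabulary: list[str] | None = None,
) -> AnnotationMap:
    """Read an accession -> (localization, function) table.

    Expected TSV columns: ``accession``, ``localization``, ``function``.
    Vocabularies default to first-appearance order with "not annotated"
    appended.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna(NOT_ANNOTATED)
    for col in ("accession", "localization", "function"):
        if col not in frame.columns:
            raise ValueError(f"annotation table {path} lacks column {col!r}")
    loc = dict(zip(frame["accession"], frame["localization"]))
    fun = dict(zip(frame["accession"], frame["function"]))
    return AnnotationMap(
        localization=loc,
        function=fun,
        localization_vocabulary=(
            localization_vocabulary
            or list(dict.fromkeys(frame["localization"]))
        ),
        function_vocabulary=(
            function_vocabulary or list(dict.fromkeys(frame["function"]))
        ),
    )


def read_modifications(path: str | Path) -> ModificationRegistry:
    """Load a modification registry from a JSON config.

    Format: list of objects with keys ``name``, ``residues`` (string of
    single-letter codes), ``delta_mass`` and ``mode``.
    """
    with open(path) as fh:
        spec = json.load(fh)
    return ModificationRegistry(
        Modification(
            name=entry["name"],
            target_residues=frozenset(entry["residues"]),
            delta_mass=float(entry["delta_mass"]),
            mode=entry["mode"],
        )
        for entry in spec
    )


FIXTURE_NAMES = {
    "hc_only": "table1_hc_only.tsv",
    "nsc_only": "table2_nsc_only.tsv",
    "hc_enriched": "table3_hc_enriched.tsv",
    "nsc_enriched": "table4_nsc_enriched.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table (keys of :data:`FIXTURE_NAMES`)."""
    fname = FIXTURE_NAMES[name]
    with resources.files("specsort.fixtures").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def fixture_profiles() -> tuple[list[CountProfile], dict[str, pd.DataFrame]]:
    """Packaged reference tables as count profiles plus the raw frames.

    Exclusive-table rows become single-population profiles; enriched-table
    rows carry counts in both populations.  One exclusive row prints no
    spectral count (a gap in the published table); it is flagged
    ``count_missing`` and imputed to 1 so it participates in membership
    classification but must be excluded from any sum check.  The printed
    experiments-observed totals are kept on the frames; the profiles place
    each population's counts in a single pseudo-experiment.
    """
    frames = {k: load_fixture(k) for k in FIXTURE_NAMES}
    profiles: list[CountProfile] = []

    def add(acc, desc, hc, nsc, missing=False):
        prof = CountProfile(accession=acc, description=desc, count_missing=missing)
        if hc:
            prof.per_experiment[(1, "HC")] = int(hc)
        if nsc:
            prof.per_experiment[(1, "NSC")] = int(nsc)
        profiles.append(prof)

    for row in frames["hc_only"].itertuples(index=False):
        count = row.sum_count_HC
        missing = pd.isna(count)
        add(row.accession, row.description, 1 if missing else int(count), 0, missing)
    for row in frames["nsc_only"].itertuples(index=False):
        count = row.sum_count_NSC
        missing = pd.isna(count)
        add(row.accession, row.description, 0, 1 if missing else int(count), missing)
    for key in ("hc_enriched", "nsc_enriched"):
        for row in frames[key].itertuples(index=False):
            add(row.accession, row.description,
                int(row.sum_count_HC), int(row.sum_count_NSC))
    return profiles, frames
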