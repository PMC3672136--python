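"""End-to-end orchestration: decoy -> filter -> count -> classify -> categorize.

A run is driven by a single JSON config; every stage writes plain TSV/JSON
outputs plus one log line with its input/output counts, so a run is fully
reconstructable.  All randomness (simulate mode) flows from one declared
seed; re-running with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as sio
from .categorization import profile_categories
from .enrichment import (
    classify_exclusive,
    filter_printed_pvalues,
    format_pvalue,
    reassign_shared,
    venn_shared_count,
)
from .spectral_counting import count_spectra, profiles_to_frame
from .synthetic_data import SyntheticConfig, generate_database, generate_psms
from .target_decoy import FilterPolicy, apply_filter_policy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageFailure", "run_pipeline", "make_report"]

_CLASS_FILES = {
    "HC_ONLY": "class_hc_only.tsv",
    "NSC_ONLY": "class_nsc_only.tsv",
    "HC_ENRICHED": "class_hc_enriched.tsv",
    "NSC_ENRICHED": "class_nsc_enriched.tsv",
}


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``data`` (filter a PSM table), ``simulate`` (generate the
    inputs first) or ``fixture`` (classify the packaged reference tables,
    whose shared rows carry pre-computed printed p-values).
    """

    outdir: str
    mode: str = "data"
    psms: str | None = None
    database: str | None = None
    annotations: str | None = None
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    alpha: float = 0.05
    margins: tuple[int, int] | None = None
    n_total: int | None = None
    seed: int = 0
    simulate: SyntheticConfig | None = None

    @classmethod
    def from_json(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("policy"), dict):
            raw["policy"] = FilterPolicy(**raw["policy"])
        if isinstance(raw.get("simulate"), dict):
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = SyntheticConfig(**sim)
        if raw.get("margins") is not None:
            raw["margins"] = tuple(raw["margins"])
        return cls(**raw)


def _log(lines: list[str], msg: str) -> None:
    logger.info(msg)
    lines.append(msg)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages, write the report bundle, return a summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict[str, Any] = {"mode": config.mode}

    if config.mode == "fixture":
        profiles, frames = sio.fixture_profiles()
        results = _classify_fixture(profiles, frames, config.alpha)
        summary.update(_emit_classification(profiles, results, config, out, log_lines))
        filtered = None
    else:
        psms = _obtain_psms(config, out, log_lines)
        try:
            filtered = apply_filter_policy(psms, config.policy)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageFailure("filter", str(exc)) from exc
        _log(log_lines,
             f"filter: {len(psms)} PSMs in -> {filtered.n_psms} PSMs, "
             f"{filtered.n_peptides} peptides, {filtered.n_proteins} proteins "
             f"(thresholds {filtered.thresholds}, achieved FDR "
             f"psm={filtered.achieved_psm_fdr:.4f} "
             f"pep={filtered.achieved_peptide_fdr:.4f} "
             f"prot={filtered.achieved_protein_fdr:.4f})")
        for note in filtered.diagnostics:
            _log(log_lines, f"filter: WARNING {note}")
        sio.write_psm_table(filtered.psms, out / "filtered_psms.tsv")
        _write_json(
            {
                "n_input_psms": len(psms),
                "n_psms": filtered.n_psms,
                "n_peptides": filtered.n_peptides,
                "n_proteins": filtered.n_proteins,
                "achieved_fdr": {
                    "psm": filtered.achieved_psm_fdr,
                    "peptide": filtered.achieved_peptide_fdr,
                    "protein": filtered.achieved_protein_fdr,
                },
                "thresholds": filtered.thresholds,
                "diagnostics": filtered.diagnostics,
            },
            out / "filter_summary.json",
        )
        summary["filter"] = {
            "n_input_psms": len(psms),
            "n_psms": filtered.n_psms,
            "n_peptides": filtered.n_peptides,
            "n_proteins": filtered.n_proteins,
        }
        profiles = count_spectra(filtered)
        _log(log_lines, f"count: {len(profiles)} protein profiles")
        if profiles:
            results = reassign_shared(profiles, config.margins, config.alpha)
        else:
            results = []
        summary.update(_emit_classification(profiles, results, config, out, log_lines))

    # ---- categorization (optional) -------------------------------------
    if config.annotations and profiles:
        annot = sio.read_annotations(config.annotations)
        for axis in ("localization", "function"):
            rows = []
            for pop in ("HC", "NSC"):
                prof = profile_categories(profiles, annot, axis, population=pop)
                for cat in prof.categories:
                    rows.append(
                        {
                            "axis": axis,
                            "population": pop,
                            "category": cat,
                            "proportion_before": prof.proportion_before[cat],
                            "proportion_after": prof.proportion_after[cat],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / f"profile_{axis}.tsv", sep="\t",
                                      index=False)
        _log(log_lines, "categorize: wrote profile_localization.tsv, "
                        "profile_function.tsv")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    report = make_report(summary, profiles, results)
    (out / "report.md").write_text(report)
    summary["report_path"] = str(out / "report.md")
    return summary


def _obtain_psms(config: RunConfig, out: Path, log_lines: list[str]):
    if config.mode == "simulate":
        sim = config.simulate or SyntheticConfig(seed=config.seed)
        db = generate_database(sim)
        psms, truth = generate_psms(sim, db)
        sio.write_fasta(db.composite, out / "composite.fasta")
        sio.write_psm_table(psms, out / "psms.tsv")
        pd.DataFrame(
            {
                "accession": list(truth.protein_class),
                "true_class": list(truth.protein_class.values()),
            }
        ).to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "spectrum_id": list(truth.psm_correct),
                "correct": [int(v) for v in truth.psm_correct.values()],
            }
        ).to_csv(out / "truth_psms.tsv", sep="\t", index=False)
        _log(log_lines,
             f"simulate: {len(db.targets)} targets, {len(psms)} PSMs "
             f"(seed {sim.seed})")
        return psms
    if config.mode == "data":
        if not config.psms:
            raise StageFailure("input", "data mode requires a PSM table path")
        psms = sio.read_psm_table(config.psms)
        _log(log_lines, f"input: read {len(psms)} PSMs from {config.psms}")
        return psms
    raise StageFailure("input", f"unknown mode {config.mode!r}")


def _classify_fixture(profiles, frames, alpha):
    """Fixture classification uses the tables' own printed p-values."""
    from .enrichment import EnrichmentResult

    results = []
    printed: dict[str, float] = {}
    direction: dict[str, str] = {}
    for key, d in (("hc_enriched", "HC"), ("nsc_enriched", "NSC")):
        for row in frames[key].itertuples(index=False):
            printed[row.accession] = float(row.p_value)
            direction[row.accession] = d
    _, cats = classify_exclusive(profiles)
    for p in profiles:
        cat = cats[p.accession]
        if cat == "SHARED":
            pv = printed.get(p.accession, 1.0)
            if filter_printed_pvalues([pv], alpha)[0]:
                d = direction[p.accession]
                results.append(
                    EnrichmentResult(p.accession, f"{d}_ENRICHED", pv, d, None)
                )
            else:
                results.append(
                    EnrichmentResult(p.accession, "SHARED_UNRESOLVED", pv, "none", None)
                )
        else:
            results.append(EnrichmentResult(p.accession, cat, 1.0, "none", None))
    return results


def _emit_classification(profiles, results, config, out: Path,
                         log_lines: list[str]) -> dict[str, Any]:
    by_acc = {p.accession: p for p in profiles}
    counts_frame = profiles_to_frame(list(profiles))
    counts_frame.to_csv(out / "counts.tsv", sep="\t", index=False)

    for category, fname in _CLASS_FILES.items():
        rows = []
        for r in results:
            if r.category != category:
                continue
            p = by_acc[r.accession]
            rows.append(
                {
                    "accession": r.accession,
                    "description": p.description,
                    "sum_count_HC": p.count_HC,
                    "sum_count_NSC": p.count_NSC,
                    "p_value": format_pvalue(r.p_value)
                    if "ENRICHED" in category else "",
                }
            )
        frame = pd.DataFrame(rows, columns=["accession", "description",
                                            "sum_count_HC", "sum_count_NSC",
                                            "p_value"])
        frame.sort_values("sum_count_HC" if category.startswith("HC")
                          else "sum_count_NSC",
                          ascending=False, kind="stable").to_csv(
            out / fname, sep="\t", index=False)

    n_hc_only = sum(1 for r in results if r.category == "HC_ONLY")
    n_nsc_only = sum(1 for r in results if r.category == "NSC_ONLY")
    n_total = config.n_total if config.n_total is not None else len(profiles)
    venn = {
        "HC_only": n_hc_only,
        "NSC_only": n_nsc_only,
        "shared": venn_shared_count(n_total, n_hc_only, n_nsc_only),
        "n_total": n_total,
    }
    _write_json(venn, out / "venn.json")
    _log(log_lines,
         f"classify: alpha={config.alpha}, venn={venn}, "
         f"HC_enriched={sum(1 for r in results if r.category == 'HC_ENRICHED')}, "
         f"NSC_enriched={sum(1 for r in results if r.category == 'NSC_ENRICHED')}")
    return {
        "venn": venn,
        "n_HC_enriched": sum(1 for r in results if r.category == "HC_ENRICHED"),
        "n_NSC_enriched": sum(1 for r in results if r.category == "NSC_ENRICHED"),
    }


def make_report(summary: dict[str, Any], profiles, results, top_n: int = 10) -> str:
    """Human-readable markdown summary of a finished run."""
    lines = ["# specsort run report", ""]
    filt = summary.get("filter")
    if filt:
        lines += [
            "## Filtering",
            "",
            "| stage | records |",
            "|---|---|",
            f"| input PSMs | {filt['n_input_psms']} |",
            f"| retained PSMs | {filt['n_psms']} |",
            f"| retained peptides | {filt['n_peptides']} |",
            f"| retained proteins | {filt['n_proteins']} |",
            "",
        ]
    else:
        lines += ["## Filtering", "", "absent (fixture mode)", ""]
    venn = summary.get("venn")
    if venn:
        lines += [
            "## Population overlap",
            "",
            f"- HC only: {venn['HC_only']}",
            f"- NSC only: {venn['NSC_only']}",
            f"- shared: {venn['shared']} (of {venn['n_total']} total)",
            "",
        ]
    by_acc = {p.accession: p for p in profiles}
    for direction, label in (("HC", "hair-cell"), ("NSC", "non-sensory")):
        enriched = [r for r in results if r.category == f"{direction}_ENRICHED"]
        key = (lambda r: by_acc[r.accession].count_HC) if direction == "HC" \
            else (lambda r: by_acc[r.accession].count_NSC)
        enriched.sort(key=key, reverse=True)
        lines.append(f"## Top {label}-enriched proteins (by spectral count)")
        lines.append("")
        if not enriched:
            lines.append("none")
        for r in enriched[:top_n]:
            p = by_acc[r.accession]
            lines.append(
                f"- {r.accession} {p.description or ''} "
                f"(HC {p.count_HC} / NSC {p.count_NSC}, p={format_pvalue(r.p_value)})"
            )
        lines.append("")
    return "\n".join(lines)
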