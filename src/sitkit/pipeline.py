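"""Orchestration of the full decontamination run: mask -> all-vs-all ->
detect -> purge, with a manifest recording inputs, parameters and seed."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .align import all_vs_all
from .config import ToolConfig
from .decontam import DecontamResult, purge, run_decontam
from .io import (
    ContigRecord,
    DataError,
    ExpressionRecord,
    ProteinRecord,
    write_fasta,
    write_hits_table,
    write_report_tsv,
)
from .masking import dust_mask

__all__ = ["run_pipeline", "decontaminate"]


def decontaminate(
    projects: Mapping[str, Sequence[ContigRecord]],
    counts: Sequence[ExpressionRecord] | None,
    cfg: ToolConfig = ToolConfig(),
) -> DecontamResult:
    """In-memory mask -> all-vs-all -> decision pipeline."""
    masked = {
        label: [dust_mask(c, cfg.mask) for c in contigs]
        for label, contigs in projects.items()
    }
    hits = all_vs_all(masked, cfg.align)
    return run_decontam(masked, hits, counts, cfg.decontam)


def run_pipeline(
    projects: Mapping[str, Sequence[ContigRecord]],
    counts: Sequence[ExpressionRecord] | None,
    out_dir: str | Path,
    cfg: ToolConfig = ToolConfig(),
    proteins: Mapping[str, Sequence[ProteinRecord]] | None = None,
    input_paths: Sequence[str] = (),
) -> DecontamResult:
    """Run the full pipeline and write stage artifacts under ``out_dir``.

    Writes masked FASTAs, the best-hit table, decision/threshold/summary
    reports, retained and purged FASTAs, and a manifest; reruns with
    identical inputs and config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.config_hash(), "seed": cfg.seed}
    stages = []

    masked = {
        label: [dust_mask(c, cfg.mask) for c in contigs]
        for label, contigs in sorted(projects.items())
    }
    for label, contigs in masked.items():
        write_fasta(contigs, out / f"{label}.masked.fasta")
    stages.append("mask")

    hits = all_vs_all(masked, cfg.align)
    write_hits_table(hits, out / "hits.tsv")
    stages.append("all_vs_all")

    try:
        result = run_decontam(masked, hits, counts, cfg.decontam)
    except DataError as exc:
        raise DataError(f"stage detect: {exc}") from exc
    write_report_tsv(
        out / "decisions.tsv",
        ["project", "contig_id", "status", "reason", "evidence"],
        result.decision_rows(),
        meta,
    )
    write_report_tsv(
        out / "pair_thresholds.tsv",
        ["pair", "n_hits", "contaminated", "threshold_bin",
         "fallback_used", "n_flagged_hits"],
        [
            (r["pair"], r["n_hits"], r["contaminated"], r["threshold_bin"],
             r["fallback_used"], r["n_flagged_hits"])
            for r in result.pair_stats
        ],
        meta,
    )
    write_report_tsv(
        out / "summary.tsv",
        ["project", "n_contigs", "n_flagged", "n_discarded",
         "n_retained_by_exception"],
        [
            (r["project"], r["n_contigs"], r["n_flagged"], r["n_discarded"],
             r["n_retained_by_exception"])
            for r in result.project_summary
        ],
        meta,
    )
    stages.append("detect")

    for label, contigs in masked.items():
        prots = list((proteins or {}).get(label, []))
        pr = purge(contigs, prots, result.decisions)
        write_fasta(pr.retained_nt, out / f"{label}.retained.fasta")
        write_fasta(pr.purged_nt, out / f"{label}.purged.fasta")
        if prots:
            write_fasta(pr.retained_aa, out / f"{label}.retained.pep.fasta")
            write_fasta(pr.purged_aa, out / f"{label}.purged.pep.fasta")
    stages.append("purge")

    manifest = {
        "tool": "sitkit",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "inputs": list(input_paths),
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
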