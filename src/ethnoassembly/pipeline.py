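"""End-to-end orchestration: reconcile -> matrix -> indices -> Jaccard -> overlay.

Runs the four analysis stages over file inputs, writes every artifact as
UTF-8 comma-delimited CSV (species rendered "Genus epithet" without
authorities in matrix exports), and emits exactly one JSON run manifest
recording input hashes, the config echo, per-stage row counts and all
collected warnings.  Outputs are a pure function of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .crosscultural import DEFAULT_DOMAINS, jaccard_matrix
from .indices import index_table
from .phylo_overlay import align_matrix_to_tree, clade_use_summary, read_tree
from .taxonomy import (apply_revision_rules, build_comparison,
                       read_checklists_csv, read_decisions_csv, upset_counts)
from .usedata import UseMatrix, build_matrix, read_mapping_csv, read_reports_csv

__all__ = ["PipelineError", "run_pipeline", "export_heatmap_tables"]

log = logging.getLogger("ethnoassembly")


class PipelineError(RuntimeError):
    """A fatal, stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(path, stage: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise PipelineError(stage, f"missing input file: {p}")
    return p


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full pipeline described by ``config`` into ``out_dir``.

    Config keys: ``checklists`` (CSV path), ``decisions`` (CSV path,
    optional), ``reports`` (CSV path), ``mapping`` (CSV path, optional),
    ``tree`` (Newick path, optional), ``count_unit`` (triple|source),
    ``domains`` (list, for the Jaccard stage).  Non-fatal issues (review
    queue, rejected reports) are collected into the manifest; fatal ones
    raise :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": {k: str(v) for k, v in config.items()},
        "input_hashes": {},
        "stage_counts": {},
        "warnings": [],
    }
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # -- stage 1: taxonomic reconciliation ---------------------------
        checklist_path = _require(config["checklists"], "reconcile")
        manifest["input_hashes"]["checklists"] = _sha256(checklist_path)
        checklists = read_checklists_csv(checklist_path)
        decisions = []
        if config.get("decisions"):
            dec_path = _require(config["decisions"], "reconcile")
            manifest["input_hashes"]["decisions"] = _sha256(dec_path)
            decisions = read_decisions_csv(dec_path)
        table = build_comparison(checklists)
        revised = apply_revision_rules(table, decisions)
        table.presence.to_csv(out / "comparison_table.csv",
                              index_label="name")
        revised.to_frame().to_csv(out / "revised_checklist.csv", index=False)
        sets = {
            s: {b for b in table.presence.index
                if table.presence.loc[b, s] != "absent"}
            for s in table.sources
        }
        sets["Revised"] = set(revised.accepted_binomials)
        upset = upset_counts(sets)
        upset.to_frame().to_csv(out / "upset_summary.csv", index=False)
        manifest["stage_counts"]["reconcile"] = {
            "names": len(table.names),
            "accepted": len(revised.accepted),
            "needs_review": len(revised.needs_review),
        }
        log.info("reconcile: %d names -> %d accepted (%d need review)",
                 len(table.names), len(revised.accepted),
                 len(revised.needs_review))

        # -- stage 2: use matrix -----------------------------------------
        reports_path = _require(config["reports"], "matrix")
        manifest["input_hashes"]["reports"] = _sha256(reports_path)
        mapping = {}
        if config.get("mapping"):
            map_path = _require(config["mapping"], "matrix")
            manifest["input_hashes"]["mapping"] = _sha256(map_path)
            mapping = read_mapping_csv(map_path)
        reports = read_reports_csv(reports_path, mapping)
        if not reports:
            raise PipelineError("matrix", "use-report file is empty; "
                                "stages 2-4 cannot run")
        matrix = build_matrix(
            reports,
            revised_checklist=revised.accepted_binomials or None,
            count_unit=config.get("count_unit", "triple"),
        )
        matrix.to_csv(out / "use_matrix.csv", out / "use_matrix.meta.json")
        if matrix.rejected is not None:
            matrix.rejected.to_csv(out / "rejected_reports.csv", index=False)
        manifest["stage_counts"]["matrix"] = {
            "reports": len(reports),
            "cells": len(matrix.counts),
            "species": len(matrix.species_order),
            "cultures": matrix.N,
            "rejected": 0 if matrix.rejected is None else len(matrix.rejected),
        }
        log.info("matrix: %d reports -> %d cells, %d species, N=%d cultures",
                 len(reports), len(matrix.counts),
                 len(matrix.species_order), matrix.N)

        # -- stage 3: indices --------------------------------------------
        if matrix.counts.empty:
            raise PipelineError("indices", "use matrix is empty")
        indices = index_table(matrix)
        indices.to_long().round(2).to_csv(out / "indices.csv", index=False)
        manifest["stage_counts"]["indices"] = {
            "uses": len(indices.per_use), "species": len(indices.per_species)}

        # -- stage 4: cross-cultural similarity --------------------------
        domains = tuple(config.get("domains", DEFAULT_DOMAINS))
        if matrix.N < 2:
            raise PipelineError("jaccard",
                                "need >= 2 cultures for pairwise comparison")
        ji = jaccard_matrix(matrix, domains)
        ji.values.round(2).to_csv(out / "jaccard_square.csv",
                                  index_label="culture")
        ji.to_long().round(2).to_csv(out / "jaccard_long.csv", index=False)
        manifest["stage_counts"]["jaccard"] = {
            "cultures": len(ji.cultures),
            "isolated": len(ji.isolated_cultures()),
        }

        # -- stage 5 (optional): phylogeny overlay ------------------------
        overlay = None
        if config.get("tree"):
            tree_path = _require(config["tree"], "overlay")
            manifest["input_hashes"]["tree"] = _sha256(tree_path)
            tree = read_tree(tree_path.read_text(encoding="utf-8"))
            report, reordered = align_matrix_to_tree(tree, matrix)
            overlay = (report, reordered)
            clades = clade_use_summary(tree, matrix)
            clades.to_csv(out / "clade_summary.csv", index=False)
            manifest["stage_counts"]["overlay"] = {
                "tips": len(report.tip_order),
                "matched": sum(v is not None for v in report.matched.values()),
                "unplaced": len(report.unplaced),
            }

        export_heatmap_tables(matrix, indices, ji, overlay, out)
        caught = [str(w.message) for w in wrec]

    manifest["warnings"] = caught
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def export_heatmap_tables(matrix: UseMatrix, indices, ji, overlay,
                          out_dir) -> None:
    """Write heatmap-ready wide CSVs.

    ``use_heatmap.csv`` holds species rows (tree-tip order when an overlay
    is available, else matrix order) by use-category columns, with one
    appended ``FL`` row per column as a bottom band.
    """
    out = Path(out_dir)
    wide = overlay[1] if overlay is not None else matrix.to_wide()
    wide = wide.copy()
    wide.columns = [f"{d}:{s}" if s else d for d, s in wide.columns]
    fl_by_use = dict(zip(indices.per_use["use"], indices.per_use["FL"]))
    fl_row = pd.DataFrame(
        [{c: round(fl_by_use.get(c, 0.0), 2) for c in wide.columns}],
        index=["FL"])
    pd.concat([wide, fl_row]).to_csv(out / "use_heatmap.csv",
                                     index_label="species")
    ji.values.round(2).to_csv(out / "jaccard_heatmap.csv",
                              index_label="culture")
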