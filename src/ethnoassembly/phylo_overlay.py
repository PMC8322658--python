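"""Overlay the use matrix on an externally inferred phylogeny.

The tree (e.g. a maximum-likelihood GBSSI gene tree) is consumed as Newick;
inference itself is out of scope.  The matrix rows are reordered to tree
tip order so that use heatmaps can be drawn against the phylogeny, and each
internal node gets a descriptive "use density" summary (what fraction of
the clade's tips carry any recorded use, and how many use domains occur in
the clade) — a description, not an inference.

Tip labels are matched to species binomials case-insensitively and
underscore/space-insensitively, on the binomial only; unmatched tips and
unplaced species are reported, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .usedata import UseMatrix

__all__ = ["OverlayReport", "read_tree", "align_matrix_to_tree",
           "clade_use_summary"]


def _norm_label(label: str) -> str:
    return " ".join(label.replace("_", " ").split()).lower()


def read_tree(newick_text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy Tree.

    Raises ValueError on syntax errors (with the parser's position message)
    and on duplicate tip labels.  Internal node labels, when numeric, are
    bootstrap support values in [0, 100].
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.is_internal() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                continue
            if not 0 <= support <= 100:
                raise ValueError(f"support value out of [0, 100]: {support}")
    return tree


@dataclass
class OverlayReport:
    """Tip-order mapping between a tree and a use matrix.

    ``tip_order`` lists tree tips top-to-bottom; ``matched`` maps each tip
    label to the matrix species it resolved to (or None); ``unplaced``
    lists matrix species absent from the tree (appended after the
    tree-ordered block in the reordered matrix).
    """

    tip_order: list[str]
    matched: dict[str, str | None]
    unplaced: list[str]

    @property
    def row_order(self) -> list[str]:
        ordered = [self.matched[t] for t in self.tip_order
                   if self.matched[t] is not None]
        return ordered + self.unplaced


def align_matrix_to_tree(
    tree: dendropy.Tree, matrix: UseMatrix
) -> tuple[OverlayReport, pd.DataFrame]:
    """Match tree tips to matrix species and reorder the wide matrix.

    Returns the overlay report and the species x category wide table with
    rows in tree-tip order, unplaced species appended and flagged.  Raises
    when no tip matches any matrix species.
    """
    by_norm = {_norm_label(s): s for s in matrix.species_order}
    tip_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    matched = {tip: by_norm.get(_norm_label(tip)) for tip in tip_order}
    placed = {s for s in matched.values() if s is not None}
    if not placed:
        raise ValueError("no tree tip matches any matrix species")
    unplaced = [s for s in matrix.species_order if s not in placed]
    report = OverlayReport(tip_order=tip_order, matched=matched,
                           unplaced=unplaced)
    wide = matrix.to_wide()
    reordered = wide.reindex(
        [s for s in report.row_order if s in wide.index])
    return report, reordered


def clade_use_summary(
    tree: dendropy.Tree,
    matrix: UseMatrix,
    domains: tuple[str, ...] = ("food", "medicinal", "ritual", "cosmetic"),
) -> pd.DataFrame:
    """Per-internal-node use-density summary over the clade's tips.

    Columns: node_id, n_tips, n_used_tips, fraction_used, n_domains.  The
    "hot clade" score is fraction_used — the share of the clade's tips with
    at least one recorded use in the selected domains.
    """
    df = matrix.counts
    df = df[df["domain"].isin(domains)]
    used_species = set(df["species"])
    domains_by_species = df.groupby("species")["domain"].agg(set).to_dict()

    rows = []
    node_id = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        matched = [_norm_label(t) for t in tips]
        species = [s for s in matrix.species_order
                   if _norm_label(s) in set(matched)]
        used = [s for s in species if s in used_species]
        clade_domains = set().union(
            *(domains_by_species.get(s, set()) for s in used)) if used else set()
        rows.append({
            "node_id": node_id,
            "n_tips": len(tips),
            "n_used_tips": len(used),
            "fraction_used": len(used) / len(tips) if tips else 0.0,
            "n_domains": len(clade_domains),
            "domains": "+".join(sorted(clade_domains)),
        })
        node_id += 1
    return pd.DataFrame(rows, columns=[
        "node_id", "n_tips", "n_used_tips", "fraction_used",
        "n_domains", "domains"])
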