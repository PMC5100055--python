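"""Tree-based contamination screening of housekeeping-gene phylogenies.

A transcriptome is at risk of contamination when its housekeeping-gene
contig branches, with high bootstrap support, away from the framework
sequences of the expected taxonomic group and inside a clade of a
single foreign group.  Walking outward from the query tip, the first
well-supported ancestor clade that discriminates decides: if it
contains any expected-group leaf the query is clean; if its other
leaves all belong to one foreign group the query is flagged — unless
that group is an exception group (by default prokaryotes, whose
presence in non-axenic cultures is routine and was found not to explain
transporter hits).  Clades without support, below the threshold, or
mixing several foreign groups do not discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .io import DataError

__all__ = ["ScreenConfig", "screen_query"]


@dataclass(frozen=True)
class ScreenConfig:
    group_map: Mapping[str, str]
    expected_group: str
    support_threshold: float = 70.0  # strict greater-than
    exception_groups: frozenset[str] = frozenset({"prokaryote"})


def screen_query(
    tree: dendropy.Tree, query_leaf: str, cfg: ScreenConfig
) -> str:
    """Screen one query tip; returns 'flagged', 'clean' or 'exception'."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if len(leaves) < 3:
        raise DataError("screening requires a tree with >= 3 leaves")
    if query_leaf not in leaves:
        raise DataError(f"query leaf {query_leaf!r} not found in tree")
    missing = sorted(
        label for label in leaves
        if label != query_leaf and label not in cfg.group_map
    )
    if missing:
        raise DataError(f"leaves without a group mapping: {missing}")

    node = leaves[query_leaf].parent_node
    while node is not None:
        support = getattr(node, "support", None)
        if support is not None and support > cfg.support_threshold:
            members = [
                lf.taxon.label
                for lf in node.leaf_iter()
                if lf.taxon.label != query_leaf
            ]
            if members:
                groups = {cfg.group_map[label] for label in members}
                if cfg.expected_group in groups:
                    return "clean"
                if len(groups) == 1:
                    (group,) = groups
                    if group in cfg.exception_groups:
                        return "exception"
                    return "flagged"
                # mixed foreign groups: not discriminating, keep walking
        node = node.parent_node
    return "clean"
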