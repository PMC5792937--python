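"""Patristic distances and node ages from phylogenetic trees.

Patristic distance between two tips is the sum of branch lengths along
the unique path connecting them; on an ultrametric chronogram it equals
twice the age of the pair's most recent common ancestor.  Crown age of
a clade is the age (depth above the present) of the MRCA of its sampled
members; stem age is the age of that node's parent, i.e. the point at
which the clade's lineage split from its sister.  For a clade sampled
by a single tip the crown is undefined and the stem is the age of the
tip's attachment node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths; wraps a dendropy Tree.

    ``ultrametric`` is auto-detected: all root-to-tip depths equal
    within a relative tolerance of 1e-6 of the depth (absorbs chronogram
    rounding).
    """

    tree: dendropy.Tree
    ultrametric: bool

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def depth(self) -> float:
        return max(self._tip_depths().values())

    def _tip_depths(self) -> dict[str, float]:
        return {lf.taxon.label: lf.distance_from_root()
                for lf in self.tree.leaf_node_iter()}


def _wrap(tree: dendropy.Tree) -> PhyloTree:
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(l is None for l in labels):
        raise DataError("tree has unlabelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise DataError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            raise DataError("tree has edges without branch lengths")
        if edge.length < 0:
            raise DataError("negative branch length")
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    dmax = max(depths)
    ultra = dmax > 0 and (dmax - min(depths)) <= ULTRAMETRIC_RTOL * dmax
    return PhyloTree(tree, ultra)


def read_tree(source: str | Path, schema: str | None = None) -> PhyloTree:
    """Parse a Newick or NEXUS tree from a string or file path.

    ``schema`` is "newick" or "nexus"; when omitted it is inferred
    (NEXUS files start with "#NEXUS").
    """
    if isinstance(source, Path) or (isinstance(source, str) and
                                    "\n" not in source and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(data=text, schema=schema)
    except Exception as exc:
        raise DataError(f"cannot parse {schema} tree: {exc}") from exc
    tree.is_rooted = True
    return _wrap(tree)


def patristic_matrix(tree: PhyloTree, taxa: Sequence[str] | None = None
                     ) -> pd.DataFrame:
    """Pairwise patristic distances: branch lengths summed along the
    unique path connecting each pair of tips.

    Returns a symmetric labelled DataFrame with zero diagonal,
    optionally restricted to ``taxa``.
    """
    pdm = tree.tree.phylogenetic_distance_matrix()
    all_labels = tree.tip_labels
    if taxa is None:
        labels = sorted(all_labels)
    else:
        missing = sorted(set(taxa) - set(all_labels))
        if missing:
            raise DataError(f"taxa not in tree: {missing}")
        labels = list(taxa)
    taxon_of = {t.label: t for t in tree.tree.taxon_namespace
                if t.label in set(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxon_of[labels[i]], taxon_of[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class NodeAges:
    """Crown and stem ages (time above the present) for a tip set."""

    tips: tuple[str, ...]
    crown: float | None
    stem: float | None
    note: str = ""


def crown_stem_ages(tree: PhyloTree, tips: Iterable[str]) -> NodeAges:
    """Crown/stem ages of the clade spanned by ``tips`` on a chronogram.

    Requires an ultrametric tree.  For a single tip the crown is absent
    and the stem is the age of the tip's attachment node; when the MRCA
    is the root, the stem is absent (noted).
    """
    tips = tuple(tips)
    if not tips:
        raise DataError("empty tip set")
    if not tree.ultrametric:
        raise DataError("crown/stem ages require an ultrametric chronogram")
    labels = set(tree.tip_labels)
    missing = sorted(set(tips) - labels)
    if missing:
        raise DataError(f"taxa not in tree: {missing}")
    depth = tree.depth

    def age(node: dendropy.Node) -> float:
        return depth - node.distance_from_root()

    if len(tips) == 1:
        leaf = next(lf for lf in tree.tree.leaf_node_iter()
                    if lf.taxon.label == tips[0])
        parent = leaf.parent_node
        if parent is None:
            return NodeAges(tips, None, None, note="tip is the root")
        return NodeAges(tips, None, age(parent))

    mrca = tree.tree.mrca(taxon_labels=list(tips))
    crown = age(mrca)
    if mrca.parent_node is None:
        return NodeAges(tips, crown, None, note="MRCA is the root; stem undefined")
    return NodeAges(tips, crown, age(mrca.parent_node))


def ages_table(tree: PhyloTree, clades: dict[str, Sequence[str]]) -> pd.DataFrame:
    """Crown/stem ages for a set of named clades (one row per clade)."""
    rows = []
    for name, tips in clades.items():
        res = crown_stem_ages(tree, tips)
        rows.append({"clade": name, "n_tips": len(res.tips),
                     "stem_age": res.stem, "crown_age": res.crown,
                     "note": res.note})
    return pd.DataFrame(rows)
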