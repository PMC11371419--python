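"""Time-calibrated trees, stable branch identities, node ages and pruning.

A branch is identified by the set of tip labels descending from its child
node (a :data:`BranchID`).  Unlike node labels, this identity survives the
per-gene pruning that comparative screens perform: the branch of a pruned
gene tree corresponds to the species-tree branch whose clade tip set,
intersected with the retained taxa, matches it.

Node age for a species pair is computed as the average of the two
tip-to-MRCA path lengths; on an ultrametric chronogram this equals the
depth of the MRCA below the present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

#: A branch is named by the tip labels below it.
BranchID = frozenset

__all__ = [
    "BranchID",
    "PairAge",
    "TimeTree",
    "branch_key",
    "parse_branch_key",
    "read_tree",
    "filter_alignable_genes",
    "read_group_map",
    "write_group_map",
]


def branch_key(bid: Iterable[str]) -> str:
    """Serialize a BranchID as its sorted tip labels joined with ``|``."""
    return "|".join(sorted(bid))


def parse_branch_key(key: str) -> BranchID:
    return frozenset(key.split("|"))


@dataclass(frozen=True)
class PairAge:
    """Divergence-time estimate for a species pair, in millions of years."""

    species_a: str
    species_b: str
    age: float


class TimeTree:
    """Rooted tree with branch lengths and unique tip labels.

    Thin wrapper around a :class:`dendropy.Tree` that adds stable branch
    identities and the pairwise node-age computation.  Branch lengths are
    in millions of years for chronograms and substitutions/site for gene
    trees; the class does not distinguish the two.
    """

    def __init__(self, tree: dendropy.Tree, allow_missing_lengths: bool = False):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        n_missing = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                n_missing += 1
                if not allow_missing_lengths:
                    raise ValueError("tree has branches without lengths")
                node.edge.length = 0.0
            elif node.edge.length < 0:
                raise ValueError("negative branch length")
        if n_missing:
            warnings.warn(f"{n_missing} missing branch lengths treated as 0")
        self._index()

    def _index(self) -> None:
        self._tips = frozenset(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )
        self._depth = {}
        self._clade = {}
        self._leaf_node = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else self._depth[parent] + (node.edge.length or 0.0)
            self._depth[node] = d
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._clade[node] = frozenset([node.taxon.label])
                self._leaf_node[node.taxon.label] = node
            else:
                tips: set[str] = set()
                for child in node.child_nodes():
                    tips |= self._clade[child]
                self._clade[node] = frozenset(tips)
        n_zero_terminal = sum(
            1
            for leaf in self._tree.leaf_node_iter()
            if (leaf.edge.length or 0.0) == 0.0 and leaf.parent_node is not None
        )
        if n_zero_terminal:
            warnings.warn(
                f"{n_zero_terminal} zero-length terminal branches (age ties possible)"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, allow_missing_lengths: bool = False) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip labels: {e}") from e
        return cls(tree, allow_missing_lengths=allow_missing_lengths)

    @classmethod
    def read(cls, path: str | Path, allow_missing_lengths: bool = False) -> "TimeTree":
        return cls.from_newick(
            Path(path).read_text(), allow_missing_lengths=allow_missing_lengths
        )

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    # -- basic queries ----------------------------------------------------

    @property
    def tips(self) -> frozenset:
        return self._tips

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def branch_ids(self, include_root: bool = False) -> list[BranchID]:
        """BranchIDs for every branch (child-node clade tip sets), preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None and not include_root:
                continue
            out.append(self._clade[node])
        return out

    def terminal_branch_ids(self) -> list[BranchID]:
        return [frozenset([t]) for t in sorted(self._tips)]

    def branch_length_of(self, bid: BranchID) -> float:
        node = self._node_for(bid)
        return node.edge.length or 0.0

    def _node_for(self, bid: BranchID):
        bid = frozenset(bid)
        for node, clade in self._clade.items():
            if clade == bid:
                return node
        raise KeyError(f"no branch with clade {sorted(bid)}")

    def depth_of_tip(self, tip: str) -> float:
        return self._depth[self._leaf_node[tip]]

    # -- node age ---------------------------------------------------------

    def mrca(self, a: str, b: str):
        if a not in self._tips or b not in self._tips:
            missing = [t for t in (a, b) if t not in self._tips]
            raise KeyError(f"unknown tip(s): {missing}")
        anc_a = []
        node = self._leaf_node[a]
        while node is not None:
            anc_a.append(node)
            node = node.parent_node
        anc_a_set = set(id(n) for n in anc_a)
        node = self._leaf_node[b]
        while node is not None:
            if id(node) in anc_a_set:
                return node
            node = node.parent_node
        raise RuntimeError("disconnected tree")

    def node_age(self, a: str, b: str) -> PairAge:
        """Mean of the two tip-to-MRCA path lengths for a species pair."""
        if a == b:
            raise ValueError("node_age requires two distinct tips")
        m = self.mrca(a, b)
        da = self.depth_of_tip(a) - self._depth[m]
        db = self.depth_of_tip(b) - self._depth[m]
        return PairAge(a, b, (da + db) / 2.0)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = [self.depth_of_tip(t) for t in self._tips]
        return max(depths) - min(depths) <= tol

    # -- pruning ----------------------------------------------------------

    def prune_to_taxa(self, keep: Iterable[str]) -> "TimeTree":
        """Restrict to ``keep``, collapsing degree-2 nodes by summing lengths.

        BranchIDs of surviving branches equal the original clade tip sets
        intersected with ``keep``; pairwise path lengths among kept tips are
        preserved exactly.
        """
        keep = set(keep)
        if not keep <= self._tips:
            raise KeyError(f"unknown tips: {sorted(keep - self._tips)}")
        if len(keep) < 2:
            raise ValueError("prune_to_taxa needs at least 2 tips")
        clone = dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        drop = [
            leaf.taxon
            for leaf in clone.leaf_node_iter()
            if leaf.taxon.label not in keep
        ]
        clone.prune_taxa(drop, suppress_unifurcations=True)
        # dendropy can leave a unifurcating root; merge it away so the root
        # edge carries no length.
        root = clone.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            clone.seed_node = child
            child.parent_node = None
            child.edge.length = None
            root = child
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return TimeTree(clone, allow_missing_lengths=True)


def read_tree(path: str | Path, allow_missing_lengths: bool = False) -> TimeTree:
    """Read a newick file into a :class:`TimeTree`."""
    return TimeTree.read(path, allow_missing_lengths=allow_missing_lengths)


def filter_alignable_genes(
    gene_taxa: Mapping[str, Iterable[str]],
    min_taxa: int = 20,
    clade_requirements: Mapping[str, Iterable[str]] | None = None,
) -> set:
    """Alignment-retention filter used ahead of genome-wide screens.

    A gene is retained when its alignment covers at least ``min_taxa``
    species and, for every configured biogeographic clade, contains at
    least one member species of that clade (any ecomorph).
    """
    if min_taxa < 2:
        raise ValueError("min_taxa must be >= 2")
    reqs = {
        clade: set(members) for clade, members in (clade_requirements or {}).items()
    }
    kept = set()
    for gene, taxa in gene_taxa.items():
        taxa = set(taxa)
        if len(taxa) < min_taxa:
            continue
        if all(taxa & members for members in reqs.values()):
            kept.add(gene)
    return kept


def read_group_map(path: str | Path) -> dict:
    """Read a 2-column TSV (species, group) into a dict."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        species, group = line.rstrip("\n").split("\t")[:2]
        out[species] = group
    return out


def write_group_map(mapping: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{sp}\t{grp}" for sp, grp in sorted(mapping.items())]
    Path(path).write_text("\n".join(lines) + "\n")
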