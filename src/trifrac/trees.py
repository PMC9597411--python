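"""Rooted species tree with branch lengths in expected-loss units.

Branch lengths are the product alpha*t of the base loss rate and time, so a
length of 0.5 means each triplicated pillar expects half a loss event (per
unit channel rate) along that branch.  The *root branch* is the stem edge
between the triplication event and the first speciation; gene losses on it
are shared by all descendant genomes.  Because the loss process is not
time-reversible, every edge of the rooted tree, including the stem, is a
separate parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TreeNode", "read_tree"]


@dataclass
class TreeNode:
    index: int
    length: float
    name: str | None = None
    children: list[int] = field(default_factory=list)
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SpeciesTree:
    """Post-order node array; the root is the last node, its ``length`` is the
    stem (root branch) leading back to the polyploidy event."""

    nodes: list[TreeNode]

    @property
    def root(self) -> TreeNode:
        return self.nodes[-1]

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_branches(self) -> int:
        """All edges of the rooted tree plus the stem."""
        return len(self.nodes)

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.nodes], dtype=float)

    def with_branch_lengths(self, u: np.ndarray) -> "SpeciesTree":
        if len(u) != len(self.nodes):
            raise ValueError("branch length vector has wrong size")
        if np.any(np.asarray(u) < 0):
            raise ValueError("branch lengths must be >= 0")
        nodes = [
            TreeNode(n.index, float(u[i]), n.name, list(n.children), n.parent)
            for i, n in enumerate(self.nodes)
        ]
        return SpeciesTree(nodes)

    def validate_leaves(self, genome_names: list[str]) -> None:
        if sorted(self.leaf_names) != sorted(genome_names):
            raise ValueError(
                f"tree leaves {sorted(self.leaf_names)} do not match genomes "
                f"{sorted(genome_names)}"
            )

    # ---------------------------------------------------------------- newick
    @classmethod
    def from_newick(
        cls,
        text: str,
        allow_missing_lengths: bool = False,
        resolve_root: bool = False,
    ) -> "SpeciesTree":
        dt = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
        seed = dt.seed_node
        if len(seed.child_nodes()) > 2:
            if not resolve_root:
                raise ValueError(
                    "root is not bifurcating; pass resolve_root=True to resolve arbitrarily"
                )
            dt.resolve_polytomies()
        nodes: list[TreeNode] = []
        index_of: dict = {}

        def visit(dnode) -> int:
            child_idx = [visit(c) for c in dnode.child_nodes()]
            length = dnode.edge.length
            if length is None:
                if dnode is seed:
                    length = 0.0  # stem omitted in newick -> zero-length root branch
                elif allow_missing_lengths:
                    length = 0.1
                else:
                    raise ValueError(
                        f"missing branch length above {dnode.taxon or 'internal node'}"
                    )
            if length < 0:
                raise ValueError("negative branch length")
            idx = len(nodes)
            name = dnode.taxon.label if dnode.taxon is not None else None
            nodes.append(TreeNode(idx, float(length), name, child_idx))
            for c in child_idx:
                nodes[c].parent = idx
            index_of[dnode] = idx
            return idx

        visit(seed)
        tree = cls(nodes)
        names = tree.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        return tree

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(self.nodes[c]) for c in n.children)
            return f"({inner}):{n.length:.10g}"

        return fmt(self.root) + ";"


def read_tree(path, allow_missing_lengths: bool = False, resolve_root: bool = False) -> SpeciesTree:
    """Read a rooted newick tree with branch lengths (alpha*t units)."""
    with open(path) as fh:
        return SpeciesTree.from_newick(
            fh.read(), allow_missing_lengths=allow_missing_lengths, resolve_root=resolve_root
        )
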