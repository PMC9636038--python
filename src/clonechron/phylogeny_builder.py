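"""Clone-tree construction from CCF clusters via the pigeonhole principle.

Two rules order clusters into a phylogeny. A cluster can only descend from
one whose CCF is at least as large in every sample (ancestry), and sibling
clusters nested inside the same parent cannot have CCFs summing to more
than the parent's in any sample (pigeonhole) — cells carrying the sibling
mutations are disjoint subpopulations of the parent clone. A sum that
exceeds the parent forces one sibling to nest inside the other. Both rules
are applied with an absolute CCF tolerance (default 0.05, roughly two
binomial standard errors of a cluster center at 80x coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .dirichlet_clustering import MutationCluster

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.05


class TreeConstraintError(ValueError):
    """No tree satisfies the pigeonhole constraints; names the offenders."""


@dataclass
class CloneTree:
    """Rooted clone tree; branch lengths are cluster mutation counts."""

    clusters: dict[str, MutationCluster]
    parent: dict[str, str | None]
    root: str
    tolerance: float = DEFAULT_TOLERANCE

    def children(self, node: str) -> list[str]:
        return sorted(k for k, p in self.parent.items() if p == node)

    def leaves(self) -> list[str]:
        return [k for k in self.clusters if not self.children(k)]

    def validate(self) -> None:
        """Re-assert acyclicity, single root, and the pigeonhole invariant."""
        roots = [k for k, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise TreeConstraintError(f"expected single root {self.root}, found {roots}")
        seen = set()
        for k in self.clusters:
            path = set()
            node = k
            while node is not None:
                if node in path:
                    raise TreeConstraintError(f"cycle through {node}")
                path.add(node)
                node = self.parent[node]
            seen |= path
        samples = list(self.clusters[self.root].ccf_center)
        for node in self.clusters:
            kids = self.children(node)
            for s in samples:
                total = sum(self.clusters[c].ccf_center[s] for c in kids)
                if total > self.clusters[node].ccf_center[s] + self.tolerance + 1e-12:
                    raise TreeConstraintError(
                        f"children of {node} sum to CCF {total:.3f} > parent "
                        f"{self.clusters[node].ccf_center[s]:.3f} in sample {s}"
                    )


@dataclass
class TreeStats:
    n_terminal_branches: int
    truncal_burden: int
    branch_burdens: dict[str, int] = field(default_factory=dict)


def _feasible_ancestor(anc: MutationCluster, desc: MutationCluster, tol: float) -> bool:
    return all(anc.ccf_center[s] >= desc.ccf_center[s] - tol for s in anc.ccf_center)


def build_tree(clusters: list[MutationCluster], tolerance: float = DEFAULT_TOLERANCE) -> CloneTree:
    """Order clusters into a clone tree by the pigeonhole principle.

    The root is the unique cluster that is a feasible ancestor of every
    other. Remaining clusters are attached in decreasing CCF order; each
    picks the feasible parent with the smallest CCF (the most recent
    ancestor), and sibling-sum violations are resolved by nesting the
    smaller sibling inside the larger where ancestry permits. Unresolvable
    configurations raise :class:`TreeConstraintError` naming the offending
    cluster pair and sample.
    """
    if not clusters:
        raise ValueError("no clusters to build a tree from")
    by_id = {c.cluster_id: c for c in clusters}
    if len(by_id) != len(clusters):
        raise ValueError("duplicate cluster ids")

    roots = [c for c in clusters if all(_feasible_ancestor(c, o, tolerance) for o in clusters)]
    if not roots:
        raise TreeConstraintError("no cluster is a feasible ancestor of all others (no valid root)")
    root = max(roots, key=lambda c: (c.mean_center(), c.n_mutations, c.cluster_id))

    def sort_key(c: MutationCluster):
        return (-c.mean_center(), -c.n_mutations, c.cluster_id)

    parent: dict[str, str | None] = {root.cluster_id: None}
    placed = [root]

    def resolve_siblings(p: MutationCluster) -> None:
        samples = list(p.ccf_center)
        while True:
            kids = [by_id[k] for k, pp in parent.items() if pp == p.cluster_id]
            bad_sample = None
            for s in samples:
                if sum(c.ccf_center[s] for c in kids) > p.ccf_center[s] + tolerance:
                    bad_sample = s
                    break
            if bad_sample is None:
                return
            kids_sorted = sorted(kids, key=sort_key)
            moved = False
            # nest the smallest sibling under the largest feasible one
            for small in reversed(kids_sorted):
                for big in kids_sorted:
                    if big is small:
                        continue
                    if _feasible_ancestor(big, small, tolerance):
                        parent[small.cluster_id] = big.cluster_id
                        resolve_siblings(big)
                        moved = True
                        break
                if moved:
                    break
            if not moved:
                a, b = kids_sorted[0], kids_sorted[-1]
                raise TreeConstraintError(
                    f"siblings {a.cluster_id} and {b.cluster_id} under {p.cluster_id} "
                    f"violate the pigeonhole constraint in sample {bad_sample} and "
                    "neither can nest inside the other"
                )

    for c in sorted((c for c in clusters if c is not root), key=sort_key):
        feasible = [p for p in placed if _feasible_ancestor(p, c, tolerance)]
        if not feasible:
            nearest = min(placed, key=lambda p: max(
                c.ccf_center[s] - p.ccf_center[s] for s in c.ccf_center))
            s_bad = max(c.ccf_center, key=lambda s: c.ccf_center[s] - nearest.ccf_center[s])
            raise TreeConstraintError(
                f"cluster {c.cluster_id} has no feasible parent (closest {nearest.cluster_id} "
                f"is smaller in sample {s_bad})"
            )
        # the most recent feasible ancestor; ties to the larger then lexically
        # earlier cluster for determinism
        chosen = min(feasible, key=lambda p: (p.mean_center(), -p.n_mutations, p.cluster_id))
        parent[c.cluster_id] = chosen.cluster_id
        placed.append(c)
        resolve_siblings(chosen)

    tree = CloneTree(by_id, parent, root.cluster_id, tolerance)
    tree.validate()
    return tree


def tree_stats(tree: CloneTree) -> TreeStats:
    """Terminal-branch count and per-branch mutation burdens.

    A root with no children counts as a single terminal branch.
    """
    leaves = tree.leaves()
    return TreeStats(
        n_terminal_branches=len(leaves),
        truncal_burden=tree.clusters[tree.root].n_mutations,
        branch_burdens={k: c.n_mutations for k, c in tree.clusters.items()},
    )
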