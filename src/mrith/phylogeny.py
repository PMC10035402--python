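"""Per-patient clonal trees from biopsy-presence patterns.

Each distinct presence bitmask of a patient's mutations is a candidate tree
edge whose length is its mutation count.  A compatible (laminar) set of
masks — any two nested or disjoint — defines a perfect phylogeny: the Hasse
diagram of bitmask containment, rooted at the full-biopsy trunk.  Real data
contain conflicting patterns; these are resolved greedily by mutation count
before construction, and dropped patterns are reported, never silently
discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class PresencePattern:
    """A biopsy-presence bitmask with the number of mutations showing it."""

    mask: int
    mutation_count: int

    def __post_init__(self) -> None:
        if self.mask <= 0:
            raise ValueError("pattern bitmask must be nonempty")
        if self.mutation_count < 0:
            raise ValueError("mutation_count must be >= 0")


@dataclass
class TreeNode:
    mask: int
    length: int                      # mutations on the edge above this node
    children: "list[TreeNode]" = field(default_factory=list)


@dataclass
class ClonalTree:
    """Rooted per-patient tree; edge lengths are mutation counts."""

    root: TreeNode
    biopsy_order: tuple[str, ...]

    def total_length(self) -> int:
        def walk(node: TreeNode) -> int:
            return node.length + sum(walk(c) for c in node.children)
        return walk(self.root)

    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if not node.children:
                names.append(self._mask_name(node.mask))
            for c in node.children:
                walk(c)

        walk(self.root)
        return names

    def _mask_name(self, mask: int) -> str:
        bits = [b for i, b in enumerate(self.biopsy_order) if mask >> i & 1]
        if len(bits) != 1:
            raise ValueError(f"leaf mask {mask:b} is not a single biopsy")
        return bits[0]

    def to_newick(self) -> str:
        """Newick string; leaf names are biopsy ids, the trunk is the root edge."""
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate leaf names: {sorted(names)}")

        def render(node: TreeNode) -> str:
            if not node.children:
                return f"{self._mask_name(node.mask)}:{node.length}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.length}"

        return render(self.root) + ";"


def build_presence_patterns(merged: Iterable) -> list[PresencePattern]:
    """Group a patient's classified variants by presence bitmask.

    NONE-labeled (zero-presence) variants are excluded; pattern counts sum
    to the number of included variants.
    """
    counter: Counter[int] = Counter()
    for m in merged:
        mask = m.presence_mask() if hasattr(m, "presence_mask") else int(m)
        if mask == 0:
            continue
        counter[mask] += 1
    return [
        PresencePattern(mask=mask, mutation_count=count)
        for mask, count in sorted(counter.items())
    ]


def compatible(a: int, b: int) -> bool:
    """Two bitmasks are compatible when nested or disjoint."""
    inter = a & b
    return inter == 0 or inter == a or inter == b


def resolve_conflicts(patterns: Sequence[PresencePattern]
                      ) -> tuple[list[PresencePattern], list[PresencePattern]]:
    """Greedily select a pairwise-compatible subset of presence patterns.

    Patterns are visited in order of descending mutation count, ties broken
    by smaller bitmask integer value; each is accepted iff compatible with
    everything accepted so far.  Returns (kept, dropped).
    """
    kept: list[PresencePattern] = []
    dropped: list[PresencePattern] = []
    for p in sorted(patterns, key=lambda p: (-p.mutation_count, p.mask)):
        if all(compatible(p.mask, q.mask) for q in kept):
            kept.append(p)
        else:
            dropped.append(p)
    return kept, dropped


def max_compatible_subset(patterns: Sequence[PresencePattern]
                          ) -> tuple[list[PresencePattern], int]:
    """Exhaustive maximum-weight compatible subset (for small inputs).

    Brute force over all subsets; intended as an independent check of the
    greedy resolver at <= ~12 patterns.
    """
    n = len(patterns)
    if n > 20:
        raise ValueError("exhaustive search limited to 20 patterns")
    best_subset: list[PresencePattern] = []
    best_weight = -1
    for sub in range(1 << n):
        chosen = [patterns[i] for i in range(n) if sub >> i & 1]
        ok = all(
            compatible(chosen[i].mask, chosen[j].mask)
            for i in range(len(chosen)) for j in range(i + 1, len(chosen))
        )
        if not ok:
            continue
        w = sum(p.mutation_count for p in chosen)
        if w > best_weight:
            best_weight, best_subset = w, chosen
    return best_subset, best_weight


def build_tree(patterns: Sequence[PresencePattern],
               biopsy_order: Sequence[str]) -> ClonalTree:
    """Assemble the containment tree of a compatible pattern set.

    The root is the full-biopsy mask (trunk), inserted with length 0 when no
    clonal pattern exists.  Every biopsy appears as a leaf; biopsies without
    a private pattern get a zero-length leaf edge.  Raises ``ValueError`` on
    incompatible input.
    """
    order = tuple(biopsy_order)
    if not order:
        raise ValueError("biopsy_order must be nonempty")
    for i, p in enumerate(patterns):
        for q in patterns[i + 1:]:
            if not compatible(p.mask, q.mask):
                raise ValueError(
                    f"incompatible patterns {p.mask:b} and {q.mask:b}; "
                    "run resolve_conflicts first"
                )
    full_mask = (1 << len(order)) - 1
    counts = {p.mask: p.mutation_count for p in patterns}
    if any(mask > full_mask for mask in counts):
        raise ValueError("pattern mask references a biopsy outside biopsy_order")
    counts.setdefault(full_mask, 0)

    nodes = {mask: TreeNode(mask=mask, length=length) for mask, length in counts.items()}
    # parent of each mask = its minimal strict superset among the masks
    masks_desc = sorted(nodes, key=lambda m: (bin(m).count("1"), m))
    for mask in masks_desc:
        if mask == full_mask:
            continue
        supersets = [m for m in nodes if m != mask and (mask & m) == mask]
        parent = min(supersets, key=lambda m: (bin(m).count("1"), m))
        nodes[parent].children.append(nodes[mask])

    # every biopsy must end at a leaf edge
    for i, _ in enumerate(order):
        bit = 1 << i
        containing = [m for m in nodes if m & bit]
        host = min(containing, key=lambda m: (bin(m).count("1"), m))
        if host != bit:
            leaf = TreeNode(mask=bit, length=0)
            nodes[host].children.append(leaf)
        elif nodes[bit].children:
            raise AssertionError("singleton node unexpectedly internal")
    # the degenerate single-biopsy patient: root == singleton needs a leaf below
    root = nodes[full_mask]
    if len(order) == 1 and not root.children:
        root.children.append(TreeNode(mask=full_mask, length=0))

    # deterministic child order: by smallest member biopsy index
    def sort_children(node: TreeNode) -> None:
        node.children.sort(key=lambda c: (c.mask & -c.mask, c.mask))
        for c in node.children:
            sort_children(c)

    sort_children(root)
    return ClonalTree(root=root, biopsy_order=order)


def patient_tree(merged: Iterable, biopsy_order: Sequence[str]
                 ) -> tuple[ClonalTree, list[PresencePattern]]:
    """Patterns -> conflict resolution -> tree, returning dropped patterns too."""
    patterns = build_presence_patterns(merged)
    kept, dropped = resolve_conflicts(patterns)
    return build_tree(kept, biopsy_order), dropped
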