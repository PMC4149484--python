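"""Rooted genealogies and perfect-phylogeny reconstruction from binary sites.

A :class:`Genealogy` is a rooted tree whose edges carry an integer
substitution count (plus the site identifiers placed on the edge) and whose
nodes may carry ages: true ages in years for simulated scenarios, or
:class:`~ystar.clock.AgeEstimate` objects after dating. Multifurcations are
represented natively, because polytomies (star-like expansions) are the
object of study and must not be resolved arbitrarily.

Reconstruction is the rooted perfect-phylogeny construction for binary
characters with a known ancestral state (0 = reference): a set of sites is
compatible iff every pair of derived-carrier sets is nested or disjoint
(the rooted three-gamete condition). Sites that violate it are flagged as
homoplasic and reported for curation rather than placed on the tree.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "Genealogy",
    "check_compatibility",
    "build_tree",
    "branch_counts",
]

# State characters carrying definite information after curation-mark folding:
# "x" = curated back to ancestral, "@" = curated to derived.
_CARRIER = frozenset("1@")
_ANCESTRAL = frozenset("0x")
_MISSING = frozenset("?-")


class Node:
    """A node of a rooted genealogy.

    Attributes
    ----------
    name:
        Unique label (tips carry sample names; internal nodes are generated).
    age:
        True age in years (simulation scenarios); ``None`` when unknown.
    edge_sites:
        Site identifiers placed on the edge above this node.
    edge_count:
        Substitution count of the edge above this node. Normally
        ``len(edge_sites)``; branch collapsing may migrate counts without
        migrating site IDs, so the two are kept separately.
    age_estimate:
        Inferred age (set by :func:`ystar.clock.date_tree`).
    star_window:
        Upper bound (years) on the splitting window if this node became a
        multifurcation through branch collapsing.
    """

    __slots__ = (
        "name",
        "age",
        "parent",
        "children",
        "edge_sites",
        "edge_count",
        "age_estimate",
        "star_window",
    )

    def __init__(self, name: Optional[str] = None, age: Optional[float] = None):
        self.name = name
        self.age = age
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.edge_sites: list = []
        self.edge_count: int = 0
        self.age_estimate = None
        self.star_window: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self):  # pragma: no cover - debug aid
        return f"<Node {self.name!r} age={self.age} n={self.edge_count}>"


class Genealogy:
    """A rooted tree with per-edge substitution counts and optional ages."""

    def __init__(self, root: Node, conflicts: Optional[list] = None):
        self.root = root
        #: homoplasic sites that could not be placed: list of (site, clashing site)
        self.conflicts: list = conflicts or []

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        nodes = [n for n in self.preorder() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    # -- structure queries -------------------------------------------------

    def clades(self) -> dict[str, frozenset]:
        """Map internal node name -> frozenset of descendant tip names."""
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        return {n.name: below[id(n)] for n in self.preorder() if not n.is_leaf}

    def node_to_tip_counts(self, node: Node) -> dict[str, int]:
        """Substitution count from ``node`` down to each descendant tip.

        The count excludes the edge above ``node`` itself.
        """

        out: dict[str, int] = {}

        def rec(n: Node, acc: int):
            if n.is_leaf:
                out[n.name] = acc
            for c in n.children:
                rec(c, acc + c.edge_count)

        rec(node, 0)
        return out

    def branch_counts(self, tip_name: str) -> int:
        """Root-to-tip substitution count (excludes the root's own stem)."""
        return self.node_to_tip_counts(self.root)[tip_name]

    def total_placed(self) -> int:
        return sum(n.edge_count for n in self.preorder())

    def sort(self) -> "Genealogy":
        """Order children by their smallest descendant tip name (stable output)."""
        smallest: dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                smallest[id(node)] = node.name
            else:
                node.children.sort(key=lambda c: smallest[id(c)])
                smallest[id(node)] = smallest[id(node.children[0])]
        return self

    def copy(self) -> "Genealogy":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.age)
            m.edge_sites = list(n.edge_sites)
            m.edge_count = n.edge_count
            m.age_estimate = n.age_estimate
            m.star_window = n.star_window
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Genealogy(rec(self.root), conflicts=list(self.conflicts))

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: str = "count", annotate_ages: bool = False) -> str:
        """Serialize to Newick.

        lengths="count" writes integer substitution counts as branch lengths;
        lengths="years" writes ``parent.age - node.age`` (scenario trees).
        With ``annotate_ages`` each dated node carries a comment
        ``[&age=...,lo=...,hi=...]``.
        """

        buf = _io.StringIO()

        def brlen(n: Node) -> str:
            if n.parent is None:
                return ""
            if lengths == "count":
                return f":{n.edge_count}"
            if lengths == "years":
                if n.age is None or n.parent.age is None:
                    raise ValueError("node ages unset; cannot write year lengths")
                return f":{n.parent.age - n.age:.6g}"
            raise ValueError(f"unknown lengths mode {lengths!r}")

        def comment(n: Node) -> str:
            if not annotate_ages or n.age_estimate is None:
                return ""
            e = n.age_estimate
            return f"[&age={e.point:.1f},lo={e.ci_low:.1f},hi={e.ci_high:.1f}]"

        def rec(n: Node):
            if n.children:
                buf.write("(")
                for i, c in enumerate(n.children):
                    if i:
                        buf.write(",")
                    rec(c)
                buf.write(")")
            if n.name:
                buf.write(n.name)
            buf.write(comment(n))
            buf.write(brlen(n))

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    @classmethod
    def from_newick(cls, text: str, lengths: str = "count") -> "Genealogy":
        """Parse Newick (via dendropy). See :meth:`to_newick` for modes."""
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )

        def rec(dn) -> Node:
            label = None
            if dn.taxon is not None:
                label = dn.taxon.label
            elif dn.label:
                label = dn.label
            node = Node(label)
            length = dn.edge.length
            if length is not None:
                if lengths == "count":
                    node.edge_count = int(round(length))
                else:
                    node.edge_count = 0
            for dc in dn.child_nodes():
                node.add_child(rec(dc))
            return node

        root = rec(dtree.seed_node)
        g = cls(root)
        if lengths == "years":
            # reconstruct ages bottom-up: tips at 0, parent = child age + edge years
            yrs = {}
            for dn, n in zip(dtree.preorder_node_iter(), g.preorder()):
                yrs[id(n)] = dn.edge.length or 0.0
            for node in g.postorder():
                if node.is_leaf:
                    node.age = 0.0
                else:
                    node.age = max(c.age + yrs[id(c)] for c in node.children)
        return g


# ---------------------------------------------------------------------------
# perfect-phylogeny reconstruction


def _carrier_sets(matrix, missing_as_ancestral: bool = False):
    """Yield (site_id, frozenset of carrier sample names) per site.

    Raises on non-binary cells unless ``missing_as_ancestral`` treats
    '?'/'-' as the ancestral state (used for the provisional tree built
    before imputation).
    """
    states = matrix.states
    samples = list(matrix.samples)
    positions = list(matrix.sites["pos"])
    for j, site in enumerate(positions):
        carriers = []
        for i, s in enumerate(samples):
            ch = states[i, j]
            if ch in _CARRIER:
                carriers.append(s)
            elif ch in _ANCESTRAL:
                pass
            elif ch in _MISSING:
                if not missing_as_ancestral:
                    raise ValueError(
                        f"non-binary state {ch!r} at site {site}, sample {s}; "
                        "impute first or pass missing_as_ancestral=True"
                    )
            else:
                raise ValueError(f"unknown state {ch!r}")
        yield site, frozenset(carriers)


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def check_compatibility(matrix, missing_as_ancestral: bool = False) -> list:
    """All site pairs violating the rooted three-gamete condition.

    An empty result means a perfect phylogeny exists for the matrix.
    """
    per_set: dict[frozenset, list] = {}
    for site, cs in _carrier_sets(matrix, missing_as_ancestral):
        per_set.setdefault(cs, []).append(site)
    sets = sorted(per_set, key=lambda s: (-len(s), sorted(s)))
    bad = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if not _compatible(sets[i], sets[j]):
                bad.append((per_set[sets[i]][0], per_set[sets[j]][0]))
    return bad


def build_tree(matrix, missing_as_ancestral: bool = False) -> Genealogy:
    """Reconstruct the rooted perfect phylogeny of a binary call matrix.

    Clades are exactly the derived-carrier sets, nested by inclusion; every
    site lands on the unique edge whose clade equals its carrier set.
    Conflicting sites are resolved greedily: carrier sets are admitted in
    order of decreasing support (number of sites sharing the set), then
    decreasing size, then lexicographic site ID; a set incompatible with an
    already-admitted one is flagged as homoplasic, reported in
    ``Genealogy.conflicts`` and left off the tree. Minority patterns —
    typically the product of a stray miscall — thus lose to well-supported
    clades, mirroring curation for phylogenetic consistency.
    """
    samples = list(matrix.samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a tree")

    per_set: dict[frozenset, list] = {}
    for site, cs in _carrier_sets(matrix, missing_as_ancestral):
        if cs:  # monomorphic-ancestral sites carry no signal
            per_set.setdefault(cs, []).append(site)
    for sites in per_set.values():
        sites.sort()

    # admit best-supported carrier sets first: a pattern recurring across
    # many sites outranks a sparsely supported (possibly corrupt) one
    order = sorted(
        per_set,
        key=lambda s: (-len(per_set[s]), -len(s), sorted(per_set[s])[0]),
    )

    accepted: list[frozenset] = []
    conflicts: list = []
    for cs in order:
        clash = next((a for a in accepted if not _compatible(cs, a)), None)
        if clash is None:
            accepted.append(cs)
        else:
            conflicts.extend((site, per_set[clash][0]) for site in per_set[cs])

    all_samples = frozenset(samples)
    root = Node("root")
    node_of: dict[frozenset, Node] = {all_samples: root}

    # decreasing size: supersets exist before their subsets
    internal_counter = 0
    tip_nodes: dict[str, Node] = {}
    for cs in sorted(accepted, key=lambda s: (-len(s), sorted(s))):
        if cs == all_samples:
            # derived in every sample: the mutation sits on the root's stem
            root.edge_sites.extend(per_set[cs])
            root.edge_count += len(per_set[cs])
            continue
        # parent: smallest already-created strict superset
        parent = root
        best = all_samples
        for other, node in node_of.items():
            if cs < other and len(other) < len(best):
                parent, best = node, other
        if len(cs) == 1:
            (sample,) = cs
            node = Node(sample)
        else:
            internal_counter += 1
            node = Node(f"n{internal_counter:03d}")
        node.edge_sites = list(per_set[cs])
        node.edge_count = len(node.edge_sites)
        parent.add_child(node)
        node_of[cs] = node
        if len(cs) == 1:
            tip_nodes[next(iter(cs))] = node

    # samples without a private carrier set attach below their smallest clade
    for sample in samples:
        if sample in tip_nodes:
            continue
        parent = root
        best = all_samples
        for cs, node in node_of.items():
            if sample in cs and len(cs) < len(best) and len(cs) > 1:
                parent, best = node, cs
        tip_nodes[sample] = parent.add_child(Node(sample))

    g = Genealogy(root, conflicts=conflicts)
    g.sort()
    return g


def branch_counts(tree: Genealogy, tip: str) -> int:
    """Root-to-tip substitution count for one tip (root stem excluded)."""
    return tree.branch_counts(tip)
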