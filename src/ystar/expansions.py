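"""Star-like expansion detection, Greek-letter naming, descent fractions.

A star-like expansion is a node from which many lineages radiate within a
window too short to accumulate shared substitutions — the signature of
rapid growth of one paternal line. Operationally: internal branches whose
substitution count cannot exclude a duration above the window (upper
one-sided 95% Poisson bound on the branch time, i.e. the rule-of-three
bound 3/(mu*L) for a zero-count branch) are contracted into explicit
multifurcations, and any node left with at least ``min_lineages`` children
is reported as an expansion.

Resolving a 1,000-year window requires enough sequence: with less than
about 1 Mbp analyzed the zero-count bound itself exceeds the window, so
detection warns when ``clock.L`` is that small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

from scipy import stats

from .clock import AgeEstimate, ClockModel, node_age
from .tree import Genealogy

__all__ = [
    "StarExpansion",
    "GREEK",
    "branch_time_upper_bound",
    "collapse_short_branches",
    "detect_stars",
    "assign_names",
    "descent_fraction",
]

GREEK = "αβγδεζηθικλμ" \
        "νξοπρστυφχψω"


@dataclass(frozen=True)
class StarExpansion:
    """A detected multifurcation."""

    node: str
    lineage_count: int
    window_years: float
    n_tips: int
    age: Optional[AgeEstimate] = None
    name: Optional[str] = None
    clade_frequency: Optional[float] = None


def branch_time_upper_bound(
    count: int, clock: ClockModel, conf: float = 0.95
) -> float:
    """Upper one-sided Poisson bound (years) on a branch's duration.

    For count 0 this is the rule-of-three bound ~3/(mu*L).
    """
    return float(stats.chi2.ppf(conf, 2 * (count + 1)) / 2.0) / clock.rate


def collapse_short_branches(
    tree: Genealogy, clock: ClockModel, max_window_years: float = 1_000.0
) -> Genealogy:
    """Contract internal branches whose duration bound is below the window.

    Children of a contracted node re-attach to its parent, producing
    explicit multifurcations. To preserve every root-to-tip path count
    exactly, a contracted edge's count is added to each re-attached child
    edge; its site IDs are recorded once in ``Genealogy.collapsed`` rather
    than duplicated. The resulting parent records the largest duration
    bound among its contracted edges in ``Node.star_window``. Idempotent.
    """
    if max_window_years <= 0:
        raise ValueError("max_window_years must be positive")
    out = tree.copy()
    out.collapsed = []  # (node name, count, sites) of contracted edges
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.is_leaf or node.parent is None:
                continue
            bound = branch_time_upper_bound(node.edge_count, clock)
            if bound >= max_window_years:
                continue
            parent = node.parent
            out.collapsed.append((node.name, node.edge_count, list(node.edge_sites)))
            prev = parent.star_window or 0.0
            parent.star_window = max(prev, node.star_window or 0.0, bound)
            pos = parent.children.index(node)
            for child in node.children:
                child.edge_count += node.edge_count
                child.parent = parent
            parent.children[pos:pos + 1] = node.children
            changed = True
    out.sort()
    return out


def detect_stars(
    tree: Genealogy,
    clock: ClockModel,
    min_lineages: int = 5,
    max_window_years: float = 1_000.0,
    conf: float = 0.95,
    date: bool = True,
) -> list[StarExpansion]:
    """Report every internal node with at least ``min_lineages`` children.

    The tree must already be collapsed (see :func:`collapse_short_branches`).
    ``window_years`` is the recorded collapse bound, or the zero-count
    bound for a natively multifurcating node (no site separates any subset
    of its children, so the splits fit within the rule-of-three window).
    """
    if clock.L <= 1_000_000:
        warnings.warn(
            "analyzed length <= 1 Mbp cannot confine an expansion window to "
            "1,000 years; star calls will be unreliable",
            stacklevel=2,
        )
    zero_bound = branch_time_upper_bound(0, clock, conf)
    clades = tree.clades()
    stars = []
    for node in tree.internal_nodes():
        k = len(node.children)
        if k < min_lineages:
            continue
        window = max(node.star_window or 0.0, zero_bound)
        age = node_age(tree, node, clock, conf=conf) if date else None
        stars.append(
            StarExpansion(
                node=node.name,
                lineage_count=k,
                window_years=window,
                n_tips=len(clades[node.name]),
                age=age,
            )
        )
    return stars


def assign_names(
    stars: list[StarExpansion], haplogroup_letter: str = "O"
) -> list[StarExpansion]:
    """Attach Greek-letter names (Oalpha, Obeta, ...) in a stable order.

    Published names follow clade identity, which synthetic data lacks, so
    names are assigned by decreasing descendant-tip count, then by
    decreasing point age, then by node name — documented and stable. Names
    attach to the expansion node itself, never to a defining SNP; a
    downstream lineage of Oalpha is labeled "Oalpha1...".
    """
    if len(stars) > len(GREEK):
        raise ValueError(f"more than {len(GREEK)} expansions; alphabet exhausted")

    def key(s: StarExpansion):
        age = s.age.point if s.age is not None else 0.0
        return (-s.n_tips, -age, s.node)

    return [
        replace(s, name=f"{haplogroup_letter}{GREEK[i]}")
        for i, s in enumerate(sorted(stars, key=key))
    ]


def descent_fraction(clade_frequencies) -> float:
    """Combined population share of disjoint clades, in percent."""
    freqs = list(clade_frequencies)
    for f in freqs:
        if not (0 <= f <= 100):
            raise ValueError(f"frequency {f} outside [0, 100]")
    total = float(sum(freqs))
    if total > 100:
        raise ValueError(f"clades overlap: combined share {total} > 100%")
    return total
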