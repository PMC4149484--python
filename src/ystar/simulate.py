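"""Synthetic genealogies, infinite-sites mutations, and pooled-capture reads.

The generator produces exactly the statistical structure the downstream
analysis assumes: a rooted genealogy with known node ages (tips at 0 years),
Poisson substitutions at a strict per-year clock (rate ``mu`` per bp over
``L`` bp), distinct site positions (infinite-sites), Poisson per-cell
sequencing depth and a small symmetric per-read miscall rate. Every stage
is reproducible from a single seed.

Scenarios are scripted (explicit node ages) so simulations carry exact
ground truth; :func:`binary_scenario` provides a randomized binary
background with splits spread through time, and :func:`star_scenario` /
:func:`multi_star_scenario` plant true multifurcations of a chosen degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrices import AlleleCountMatrix, CallMatrix
from .tree import Genealogy, Node

__all__ = [
    "SeqParams",
    "Scenario",
    "MutationSet",
    "star_scenario",
    "binary_scenario",
    "multi_star_scenario",
    "demo_scenario",
    "simulate_mutations",
    "simulate_reads",
    "perfect_calls",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SeqParams:
    """Sequence-evolution and sequencing parameters.

    L: analyzed length in bp. mu: substitutions per bp per year.
    depth_mean: mean per-cell coverage. error_rate: per-read per-site
    miscall probability (symmetric biallelic).
    """

    L: int = 3_900_000
    mu: float = 1e-9
    depth_mean: float = 6.0
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")

    def with_seed(self, seed: int) -> "SeqParams":
        return replace(self, seed=seed)


@dataclass
class Scenario:
    """A rooted genealogy with known node ages (years; tips at 0)."""

    genealogy: Genealogy
    name: str = "scenario"
    haplogroups: dict = field(default_factory=dict)

    def __post_init__(self):
        g = self.genealogy
        tips = g.tips()
        if len(tips) < 2:
            raise ValueError("a scenario needs at least 2 tips")
        for node in g.preorder():
            if node.age is None:
                raise ValueError(f"node {node.name!r} has no age")
            if node.parent is not None and node.parent.age < node.age:
                raise ValueError(
                    f"parent {node.parent.name!r} younger than child {node.name!r}"
                )

    @property
    def tip_names(self) -> list[str]:
        return self.genealogy.tip_names

    @property
    def root_age(self) -> float:
        return self.genealogy.root.age


@dataclass
class MutationSet:
    """Result of :func:`simulate_mutations`.

    positions: distinct site positions in [0, L), in placement order.
    branch_names: per site, the name of the node below the mutated edge.
    carrier: boolean (n_tips, n_sites) matrix of derived-allele carriers.
    branch_count: true per-edge substitution counts.
    """

    tip_names: list[str]
    positions: np.ndarray
    branch_names: list[str]
    carrier: np.ndarray
    branch_count: dict[str, int]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# scenario builders


def star_scenario(
    n_lineages: int, star_age_years: float, root_age_years: float
) -> Scenario:
    """One multifurcation of the given degree nested in a small binary tree.

    The star node (k tip lineages attached at ``star_age_years``) hangs off
    a binary backbone below a root at ``root_age_years``; with
    ``n_lineages=2`` it degenerates to an ordinary binary node.
    """
    if n_lineages < 2:
        raise ValueError("n_lineages must be >= 2")
    if not (0 < star_age_years < root_age_years):
        raise ValueError("need 0 < star_age < root_age")
    root = Node("root", age=float(root_age_years))
    root.add_child(Node("OUT1", age=0.0))
    mid = root.add_child(Node("mid", age=(root_age_years + star_age_years) / 2.0))
    mid.add_child(Node("OUT2", age=0.0))
    star = mid.add_child(Node("star", age=float(star_age_years)))
    for i in range(n_lineages):
        star.add_child(Node(f"S{i + 1:02d}", age=0.0))
    return Scenario(Genealogy(root), name=f"star{n_lineages}")


def binary_scenario(
    n_tips: int,
    root_age_years: float = 54_100.0,
    seed: int = 0,
    min_age_years: float = 1_000.0,
) -> Scenario:
    """Random binary clock genealogy with splits spread through time.

    Coalescence ages are the root age plus n-2 draws uniform on
    (min_age, root_age); lineages merge pairwise at random. This emulates a
    drift-dominated history in which divergences are binary and scattered
    across the whole depth of the tree, with no burst of near-simultaneous
    splits.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (0 < min_age_years < root_age_years):
        raise ValueError("need 0 < min_age < root_age")
    rng = np.random.default_rng([seed, 101])
    ages = np.sort(rng.uniform(min_age_years, root_age_years, size=n_tips - 2))
    ages = np.append(ages, root_age_years)
    lineages: list[Node] = [Node(f"T{i + 1:02d}", age=0.0) for i in range(n_tips)]
    counter = 0
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        counter += 1
        name = "root" if len(lineages) == 2 else f"b{counter:03d}"
        parent = Node(name, age=float(age))
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    return Scenario(Genealogy(lineages[0]), name=f"binary{n_tips}")


def multi_star_scenario(
    star_specs=((10, 5_400.0), (10, 6_500.0), (10, 6_800.0)),
    n_background: int = 19,
    root_age_years: float = 54_100.0,
    seed: int = 0,
    min_split_age_years: float = 9_000.0,
) -> Scenario:
    """Binary background with one planted star clade per (k, age) spec.

    Background splits are kept older than ``min_split_age_years`` so each
    star attaches below a strictly older parent. The defaults reproduce the
    study conditions: three k=10 expansions at 5.4/6.5/6.8 kyr under a
    54.1-kyr root, 49 tips in total.
    """
    specs = list(star_specs)
    if any(age >= min_split_age_years for _, age in specs):
        raise ValueError("star ages must be younger than min_split_age_years")
    n_slots = n_background + len(specs)
    base = binary_scenario(
        n_slots, root_age_years, seed=seed, min_age_years=min_split_age_years
    )
    g = base.genealogy
    rng = np.random.default_rng([seed, 202])
    tipnames = g.tip_names
    chosen = rng.choice(len(tipnames), size=len(specs), replace=False)
    for s, slot in enumerate(sorted(chosen)):
        k, age = specs[s]
        node = g.find(tipnames[slot])
        node.name = f"star{s + 1}"
        node.age = float(age)
        for i in range(k):
            node.add_child(Node(f"S{s + 1}_{i + 1:02d}", age=0.0))
    return Scenario(g, name="multistar")


def demo_scenario(seed: int = 0) -> Scenario:
    """The default demonstration genealogy: 49 tips, three k=10 stars."""
    return multi_star_scenario(seed=seed)


# ---------------------------------------------------------------------------
# mutation and read simulation


def simulate_mutations(
    scenario: Scenario, params: SeqParams, rng: np.random.Generator | None = None
) -> MutationSet:
    """Drop Poisson(mu*L*dt) mutations on every branch at distinct positions.

    Infinite-sites contract: colliding positions are redrawn, so each site
    maps to exactly one branch and no site back-mutates. Deterministic
    under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    g = scenario.genealogy
    lam_per_year = params.mu * params.L

    branch_nodes = [n for n in g.preorder() if n.parent is not None]
    ks = []
    for node in branch_nodes:
        dt = node.parent.age - node.age
        ks.append(int(rng.poisson(lam_per_year * dt)) if dt > 0 else 0)
    total = int(np.sum(ks))
    if total > params.L:
        raise ValueError(
            f"{total} mutations exceed {params.L} available positions; "
            "infinite-sites model degenerate"
        )

    taken: set[int] = set()
    positions: list[int] = []
    while len(positions) < total:
        draw = rng.integers(0, params.L, size=total - len(positions))
        for p in draw.tolist():
            if p not in taken:
                taken.add(p)
                positions.append(p)
    positions_arr = np.array(positions, dtype=np.int64)

    branch_names: list[str] = []
    branch_count: dict[str, int] = {}
    site_branch_idx = np.empty(total, dtype=np.int64)
    cursor = 0
    for b, (node, k) in enumerate(zip(branch_nodes, ks)):
        branch_count[node.name] = k
        branch_names.extend([node.name] * k)
        site_branch_idx[cursor:cursor + k] = b
        cursor += k

    # carriers: tips below the mutated branch
    tips = g.tips()
    tip_idx = {t.name: i for i, t in enumerate(tips)}
    below = np.zeros((len(branch_nodes), len(tips)), dtype=bool)
    for b, node in enumerate(branch_nodes):
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                below[b, tip_idx[n.name]] = True
            stack.extend(n.children)
    carrier = below[site_branch_idx].T  # (n_tips, n_sites)

    return MutationSet(
        tip_names=[t.name for t in tips],
        positions=positions_arr,
        branch_names=branch_names,
        carrier=carrier,
        branch_count=branch_count,
    )


def _site_table(mut: MutationSet, rng: np.random.Generator) -> pd.DataFrame:
    ref_idx = rng.integers(0, 4, size=mut.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=mut.n_sites)) % 4
    return pd.DataFrame(
        {
            "pos": mut.positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def simulate_reads(
    mut: MutationSet, params: SeqParams, rng: np.random.Generator | None = None
) -> AlleleCountMatrix:
    """Poisson per-cell depth; each read miscalls with ``error_rate``."""
    if rng is None:
        rng = np.random.default_rng([params.seed, 2])
    shape = mut.carrier.shape
    depth = rng.poisson(params.depth_mean, size=shape)
    p_alt = np.where(mut.carrier, 1.0 - params.error_rate, params.error_rate)
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    sites = _site_table(mut, rng)
    meta = {
        "kind": "allele_counts",
        "L": params.L,
        "mu": params.mu,
        "depth_mean": params.depth_mean,
        "error_rate": params.error_rate,
        "seed": params.seed,
    }
    return AlleleCountMatrix(list(mut.tip_names), sites, ref, alt, meta=meta)


def perfect_calls(
    mut: MutationSet, rng: np.random.Generator | None = None
) -> CallMatrix:
    """Error-free, full-coverage call matrix straight from the truth."""
    if rng is None:
        rng = np.random.default_rng(0)
    states = np.where(mut.carrier, "1", "0").astype("<U1")
    return CallMatrix(
        list(mut.tip_names),
        _site_table(mut, rng),
        states,
        meta={"kind": "calls", "source": "perfect"},
    )
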