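"""Genotype-state calling, quality filters, imputation and pseudo-sequences.

States per cell: ``1`` (derived) when the alternative allele has at least
``min_alt_reads`` reads and at least ``alt_fraction`` of the coverage;
``0`` (ancestral) when the reference allele holds at least ``alt_fraction``
of a positive coverage; ``-`` for no coverage; ``?`` otherwise. Both
fraction comparisons are inclusive. Private (singleton) derived calls are
additionally demoted to ``?`` unless backed by ``private_min_alt`` reads.

Sites enter the phylogenetic analysis only when enough samples carry an
unambiguous 0/1: strictly more than ``min_informative`` out of
``total_samples``, scaled proportionally for other cohort sizes.

Curation marks ``x`` (called 1, should be 0) and ``@`` (called ?, should
be 1) are accepted on input and folded to 0/1 for analysis; they are never
produced automatically, since they encode manual review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .matrices import AlleleCountMatrix, CallMatrix
from .tree import Genealogy

__all__ = [
    "SiteFilterPolicy",
    "call_state",
    "call_matrix",
    "apply_private_filter",
    "filter_sites",
    "normalize_curation",
    "impute_missing",
    "quality_tier",
    "pseudo_sequences",
    "write_pseudo_fasta",
]


@dataclass(frozen=True)
class SiteFilterPolicy:
    """Thresholds for calling and site selection."""

    min_informative: int = 100
    total_samples: int = 110
    min_alt_reads: int = 2
    alt_fraction: float = 0.75
    private_min_alt: int = 4

    def __post_init__(self):
        if not (0 < self.min_informative <= self.total_samples):
            raise ValueError("need 0 < min_informative <= total_samples")
        if self.min_alt_reads <= 0 or self.private_min_alt <= 0:
            raise ValueError("read-count thresholds must be positive")
        if not (0 < self.alt_fraction <= 1):
            raise ValueError("alt_fraction must be in (0, 1]")


def _call_array(
    ref: np.ndarray, alt: np.ndarray, policy: SiteFilterPolicy
) -> np.ndarray:
    total = ref + alt
    out = np.full(ref.shape, "?", dtype="<U1")
    out[total == 0] = "-"
    frac = policy.alt_fraction
    one = (alt >= policy.min_alt_reads) & (alt >= frac * total) & (total > 0)
    zero = (ref >= frac * total) & (total > 0) & ~one
    out[one] = "1"
    out[zero] = "0"
    return out


def call_state(ref_count: int, alt_count: int, policy: SiteFilterPolicy | None = None) -> str:
    """Call one cell; total function on non-negative count pairs."""
    if policy is None:
        policy = SiteFilterPolicy()
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    return _call_array(
        np.array([[ref_count]]), np.array([[alt_count]]), policy
    )[0, 0]


def call_matrix(
    counts: AlleleCountMatrix, policy: SiteFilterPolicy | None = None
) -> CallMatrix:
    """Call every cell of an allele-count matrix."""
    if policy is None:
        policy = SiteFilterPolicy()
    states = _call_array(counts.ref, counts.alt, policy)
    meta = dict(counts.meta)
    meta["kind"] = "calls"
    return CallMatrix(list(counts.samples), counts.sites.copy(), states, meta=meta)


def apply_private_filter(
    matrix: CallMatrix,
    counts: AlleleCountMatrix,
    policy: SiteFilterPolicy | None = None,
) -> CallMatrix:
    """Demote singleton derived calls lacking ``private_min_alt`` coverage.

    A site whose derived state occurs in exactly one sample keeps that call
    only if the sample's alternative reads reach the private threshold;
    otherwise the cell becomes ``?``.
    """
    if policy is None:
        policy = SiteFilterPolicy()
    if matrix.states.shape != counts.alt.shape or list(matrix.samples) != list(
        counts.samples
    ):
        raise ValueError("call matrix and count matrix are not congruent")
    out = matrix.copy()
    ones = out.states == "1"
    singleton_sites = np.flatnonzero(ones.sum(axis=0) == 1)
    for j in singleton_sites:
        i = int(np.argmax(ones[:, j]))
        if counts.alt[i, j] < policy.private_min_alt:
            out.states[i, j] = "?"
    return out


def filter_sites(
    matrix: CallMatrix,
    policy: SiteFilterPolicy | None = None,
    drop_monomorphic: bool = True,
) -> CallMatrix:
    """Keep sites with enough unambiguous calls; drop monomorphic ones.

    A site passes when its number of definite cells (0/1, including folded
    curation marks) strictly exceeds ``min_informative * n / total_samples``
    for a cohort of n samples — the exact published behavior at n = 110.
    """
    if policy is None:
        policy = SiteFilterPolicy()
    definite = np.isin(matrix.states, list("01x@"))
    threshold = policy.min_informative * matrix.n_samples / policy.total_samples
    keep = definite.sum(axis=0) > threshold
    if drop_monomorphic:
        derived = np.isin(matrix.states, list("1@"))
        ancestral = np.isin(matrix.states, list("0x"))
        keep &= derived.any(axis=0) & ancestral.any(axis=0)
    return matrix.subset_sites(keep)


def normalize_curation(matrix: CallMatrix) -> CallMatrix:
    """Fold curation marks for analysis: ``x`` -> 0, ``@`` -> 1."""
    out = matrix.copy()
    out.states[out.states == "x"] = "0"
    out.states[out.states == "@"] = "1"
    return out


_BIG = np.int64(1) << 20  # parsimony cost for a forbidden tip state


def impute_missing(
    matrix: CallMatrix, tree: Genealogy, seed: int = 0
) -> CallMatrix:
    """Fill ``?``/``-`` cells by minimum-parsimony reconstruction on the tree.

    Per site, every missing tip receives the state it takes in the
    maximum-parsimony assignments of the observed cells (computed by a
    vectorized two-pass small-parsimony recursion over all sites at once).
    When both states are attainable at minimum cost — a genuine tie — the
    allele is drawn uniformly with the given seed, reproducibly.
    """
    out = normalize_curation(matrix)
    tip_row = {s: i for i, s in enumerate(out.samples)}
    tips = tree.tips()
    for t in tips:
        if t.name not in tip_row:
            raise KeyError(f"tree tip {t.name!r} absent from matrix")
    missing_any = np.isin(out.states, list("?-"))
    if not missing_any.any():
        return out

    n_sites = out.n_sites
    # bottom-up: c0/c1 = min substitutions in the subtree given this node's state
    cost0: dict[int, np.ndarray] = {}
    cost1: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            row = out.states[tip_row[node.name]]
            c0 = np.where(row == "1", _BIG, 0)
            c1 = np.where(row == "0", _BIG, 0)
        else:
            c0 = np.zeros(n_sites, dtype=np.int64)
            c1 = np.zeros(n_sites, dtype=np.int64)
            for ch in node.children:
                c0 = c0 + np.minimum(cost0[id(ch)], cost1[id(ch)] + 1)
                c1 = c1 + np.minimum(cost1[id(ch)], cost0[id(ch)] + 1)
        cost0[id(node)], cost1[id(node)] = c0, c1

    # top-down: which states are attainable in some minimum-cost assignment
    allow0: dict[int, np.ndarray] = {}
    allow1: dict[int, np.ndarray] = {}
    r0, r1 = cost0[id(tree.root)], cost1[id(tree.root)]
    allow0[id(tree.root)] = r0 <= r1
    allow1[id(tree.root)] = r1 <= r0
    for node in tree.preorder():
        if node is tree.root:
            continue
        pa0, pa1 = allow0[id(node.parent)], allow1[id(node.parent)]
        c0, c1 = cost0[id(node)], cost1[id(node)]
        allow0[id(node)] = (pa0 & (c0 <= c1 + 1)) | (pa1 & (c0 + 1 <= c1))
        allow1[id(node)] = (pa0 & (c1 + 1 <= c0)) | (pa1 & (c1 <= c0 + 1))

    rng = np.random.default_rng([seed, 3])
    coin = rng.random(out.states.shape) < 0.5
    for t in tips:
        i = tip_row[t.name]
        miss = missing_any[i]
        if not miss.any():
            continue
        a0, a1 = allow0[id(t)], allow1[id(t)]
        fill = np.where(a0 & ~a1, "0", np.where(a1 & ~a0, "1", ""))
        tie = a0 & a1
        fill = np.where(tie, np.where(coin[i], "1", "0"), fill)
        out.states[i] = np.where(miss, fill, out.states[i])
    return out


def quality_tier(mean_depth: float) -> str:
    """Coverage tier: good above 6x, moderate within 1-6x, low below."""
    if mean_depth > 6:
        return "good"
    if mean_depth >= 1:
        return "moderate"
    return "low"


def pseudo_sequences(matrix: CallMatrix) -> dict[str, str]:
    """Concatenate each sample's alleles at the retained sites.

    Requires a complete (imputed) matrix; the characters are the actual
    ref/alt bases of each site, so the result is a plain alignment.
    """
    m = normalize_curation(matrix)
    if np.isin(m.states, list("?-")).any():
        raise ValueError("matrix has missing cells; impute before exporting")
    refs = m.sites["ref"].to_numpy(dtype="<U1")
    alts = m.sites["alt"].to_numpy(dtype="<U1")
    out = {}
    for i, s in enumerate(m.samples):
        alleles = np.where(m.states[i] == "1", alts, refs)
        out[s] = "".join(alleles)
    return out


def write_pseudo_fasta(matrix: CallMatrix, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in pseudo_sequences(matrix).items()
    ]
    SeqIO.write(records, str(path), "fasta")
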