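"""Capture-bait design: tiling-fragment uniqueness, merging, length filter.

The designer tiles a target sequence into ``window``-bp fragments every
``step`` bp, counts how often each fragment occurs in the whole genome at
Hamming distance at most ``max_mismatches`` (both strands; N matches
nothing), keeps only fragments occurring exactly once (their own origin),
merges the kept fragment ranges (overlapping or abutting), and drops
merged ranges shorter than ``min_merged_length``.

Matching uses an exact seeded Hamming search: the fragment is split into
``max_mismatches + 1`` disjoint seeds, so any qualifying occurrence leaves
at least one seed intact (pigeonhole) and can be found by exact k-mer
lookup plus verification. No external aligner is involved and the search
is exhaustive — every qualifying occurrence is found. Intended for
desk-scale genomes: indexing is O(genome), each fragment costs its seed
lookups plus one O(window) verification per candidate.

A plain brute-force scan (:func:`unique_regions_bruteforce`) is provided
as an independent reference for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BaitDesignParams",
    "IntervalSet",
    "tile_fragments",
    "GenomeIndex",
    "count_matches",
    "unique_regions",
    "unique_regions_bruteforce",
    "merge_intervals",
    "revcomp",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class BaitDesignParams:
    window: int = 70
    step: int = 10
    max_mismatches: int = 2
    min_merged_length: int = 240
    both_strands: bool = True

    def __post_init__(self):
        if not (0 < self.step <= self.window):
            raise ValueError("need 0 < step <= window")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_merged_length < self.window:
            raise ValueError("min_merged_length must be >= window")


@dataclass
class IntervalSet:
    """Sorted, non-overlapping half-open 0-based intervals on one target."""

    target: str
    intervals: list[tuple[int, int]]

    def __post_init__(self):
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval ({s}, {e})")
        ends = [e for _, e in self.intervals]
        starts = [s for s, _ in self.intervals]
        if sorted(starts) != starts or any(
            s < e0 for e0, s in zip(ends, starts[1:])
        ):
            raise ValueError("intervals must be sorted and non-overlapping")

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def to_bed(self, path) -> None:
        """0-based half-open BED."""
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{self.target}\t{s}\t{e}\n")

    def to_tsv_1based(self, path) -> None:
        """Companion 1-based inclusive table (supplementary convention)."""
        with open(path, "w") as fh:
            fh.write("target\tstart\tend\tlength\n")
            for s, e in self.intervals:
                fh.write(f"{self.target}\t{s + 1}\t{e}\t{e - s}\n")


def tile_fragments(target: str, params: BaitDesignParams) -> list[tuple[int, str]]:
    """(offset, fragment) pairs at offsets 0, step, 2*step, ...

    The count is floor((len - window)/step) + 1; a length-``window`` target
    yields exactly one fragment.
    """
    seq = target.upper()
    w = params.window
    if len(seq) < w:
        raise ValueError(f"target ({len(seq)} bp) shorter than window ({w} bp)")
    return [(o, seq[o:o + w]) for o in range(0, len(seq) - w + 1, params.step)]


def _hamming_within(a: str, b: str, limit: int) -> bool:
    """True if Hamming(a, b) <= limit, with N matching nothing."""
    budget = limit
    for x, y in zip(a, b):
        if x != y or x == "N":
            budget -= 1
            if budget < 0:
                return False
    return True


class GenomeIndex:
    """Exact k-mer index over a genome for seeded Hamming search."""

    def __init__(self, genome: dict[str, str], seed_len: int):
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.seed_len = seed_len
        self.seqs = {name: seq.upper() for name, seq in genome.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.seqs.items():
            for p in range(len(seq) - seed_len + 1):
                kmer = seq[p:p + seed_len]
                if "N" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((name, p))

    def _candidates(self, fragment: str):
        w = len(fragment)
        s = self.seed_len
        seen = set()
        n_seeds = max(1, w // s)
        for i in range(n_seeds):
            off = i * s
            seed = fragment[off:off + s]
            if "N" in seed:
                continue
            for name, p in self.kmers.get(seed, ()):
                start = p - off
                if start < 0 or start + w > len(self.seqs[name]):
                    continue
                if (name, start) not in seen:
                    seen.add((name, start))
                    yield name, start

    def occurrences(
        self,
        fragment: str,
        max_mismatches: int,
        both_strands: bool = True,
        at_most: int | None = None,
    ) -> int:
        """Number of genome positions matching within ``max_mismatches``.

        Counts plus- and (optionally) minus-strand placements; a position
        matched on both strands (palindromic fragment) counts twice. With
        ``at_most`` the scan stops early once that many hits are found.
        """
        frag = fragment.upper()
        count = 0
        queries = [frag]
        if both_strands:
            queries.append(revcomp(frag))
        for q in queries:
            for name, start in self._candidates(q):
                text = self.seqs[name][start:start + len(q)]
                if _hamming_within(q, text, max_mismatches):
                    count += 1
                    if at_most is not None and count >= at_most:
                        return count
        return count


def count_matches(
    fragment: str,
    genome: dict[str, str],
    max_mismatches: int = 2,
    both_strands: bool = True,
    index: GenomeIndex | None = None,
) -> int:
    """Occurrences of ``fragment`` in ``genome`` within the mismatch budget."""
    if index is None:
        seed_len = max(1, len(fragment) // (max_mismatches + 1))
        index = GenomeIndex(genome, seed_len)
    return index.occurrences(fragment, max_mismatches, both_strands)


def merge_intervals(
    intervals: list[tuple[int, int]], min_length: int = 0
) -> list[tuple[int, int]]:
    """Union of half-open intervals; merges overlap and adjacency."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_length]


def unique_regions(
    target: str,
    genome: dict[str, str],
    params: BaitDesignParams | None = None,
) -> IntervalSet:
    """Merged ranges of genome-unique tiling fragments of one target.

    ``target`` names a sequence of ``genome``. A fragment is unique when
    its only qualifying occurrence is its own origin (count exactly 1);
    near-matches elsewhere — including reverse-complement copies — disqualify
    it. Merged ranges shorter than ``min_merged_length`` are dropped.
    """
    if params is None:
        params = BaitDesignParams()
    if target not in genome:
        raise KeyError(f"target {target!r} not in genome")
    seed_len = max(1, params.window // (params.max_mismatches + 1))
    index = GenomeIndex(genome, seed_len)
    kept = []
    for offset, frag in tile_fragments(genome[target], params):
        if "N" in frag:
            continue  # an N can never match its own origin: not designable
        hits = index.occurrences(
            frag, params.max_mismatches, params.both_strands, at_most=2
        )
        if hits == 1:
            kept.append((offset, offset + params.window))
    return IntervalSet(target, merge_intervals(kept, params.min_merged_length))


def unique_regions_bruteforce(
    target: str,
    genome: dict[str, str],
    params: BaitDesignParams | None = None,
) -> IntervalSet:
    """Reference implementation: full Hamming scan of every placement.

    Vectorized over genome positions with numpy; O(genome x window) per
    fragment, practical only for small genomes. Used to validate
    :func:`unique_regions` exhaustively.
    """
    if params is None:
        params = BaitDesignParams()
    arrs = {
        name: np.frombuffer(seq.upper().encode(), dtype="S1")
        for name, seq in genome.items()
    }
    n_byte = np.bytes_(b"N")
    w = params.window
    windows = {}
    for name, arr in arrs.items():
        if len(arr) < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, w)
        windows[name] = (win, (win == n_byte))

    def occurrences(frag: str) -> int:
        total = 0
        queries = [frag]
        if params.both_strands:
            queries.append(revcomp(frag))
        for q in queries:
            qa = np.frombuffer(q.encode(), dtype="S1")
            q_is_n = qa == n_byte
            for win, win_is_n in windows.values():
                mm = (win != qa) | win_is_n | q_is_n
                total += int((mm.sum(axis=1) <= params.max_mismatches).sum())
        return total

    kept = []
    for offset, frag in tile_fragments(genome[target], params):
        if "N" in frag:
            continue
        if occurrences(frag) == 1:
            kept.append((offset, offset + w))
    return IntervalSet(target, merge_intervals(kept, params.min_merged_length))
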