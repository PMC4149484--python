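"""Bait designer: tiling, seeded Hamming matching, interval logic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ystar import baits as b
from ystar.experiments import bait_oracle_agreement, _random_genome_with_duplication

_MM = str.maketrans("ACGT", "CATG")  # base-wise never-equal mapping


def _rand(rng, n):
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


class TestTiling:
    def test_offsets_every_step(self):
        frags = b.tile_fragments("A" * 100, b.BaitDesignParams())
        assert [o for o, _ in frags] == [0, 10, 20, 30]

    def test_exact_window_single_fragment(self):
        frags = b.tile_fragments("A" * 70, b.BaitDesignParams())
        assert len(frags) == 1 and frags[0][0] == 0

    def test_first_two_fragments_match_1based_convention(self):
        rng = np.random.default_rng(0)
        seq = _rand(rng, 200)
        frags = b.tile_fragments(seq, b.BaitDesignParams())
        # 1-based chrY:1-70 and chrY:11-80
        assert frags[0][1] == seq[0:70]
        assert frags[1][1] == seq[10:80]

    def test_short_target_rejected(self):
        with pytest.raises(ValueError):
            b.tile_fragments("ACGT", b.BaitDesignParams())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            b.BaitDesignParams(step=0)
        with pytest.raises(ValueError):
            b.BaitDesignParams(min_merged_length=10)


class TestCountMatches:
    def test_unique_fragment_counts_once(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": _rand(rng, 2_000)}
        frag = genome["chr1"][300:370]
        assert b.count_matches(frag, genome) == 1

    def test_near_copy_found_within_mismatch_budget(self):
        rng = np.random.default_rng(2)
        base = _rand(rng, 1_000)
        frag = base[100:170]
        mutated = list(frag)
        mutated[10] = mutated[10].translate(_MM)
        mutated[50] = mutated[50].translate(_MM)
        genome = {"chr1": base + _rand(rng, 100) + "".join(mutated)}
        assert b.count_matches(frag, genome, max_mismatches=2) == 2
        assert b.count_matches(frag, genome, max_mismatches=1) == 1

    def test_reverse_complement_copy_counted(self):
        rng = np.random.default_rng(3)
        base = _rand(rng, 1_000)
        frag = base[200:270]
        genome = {"chr1": base + _rand(rng, 50) + b.revcomp(frag)}
        assert b.count_matches(frag, genome) == 2
        assert b.count_matches(frag, genome, both_strands=False) == 1

    def test_n_matches_nothing(self):
        genome = {"chr1": "A" * 200}
        frag = "A" * 67 + "NNN"
        assert b.count_matches(frag, genome, max_mismatches=2) == 0


class TestUniqueRegions:
    def test_repeat_free_target_single_interval(self):
        rng = np.random.default_rng(4)
        genome = {"t": _rand(rng, 3_000)}
        out = b.unique_regions("t", genome)
        assert out.intervals == [(0, 3_000)]

    def test_internal_duplication_splits_range(self):
        rng = np.random.default_rng(5)
        genome = {"t": _rand(rng, 2_000)}
        seq = genome["t"]
        genome["d"] = _rand(rng, 300) + seq[700:1200] + _rand(rng, 300)
        fast = b.unique_regions("t", genome)
        slow = b.unique_regions_bruteforce("t", genome)
        assert fast.intervals == slow.intervals
        assert len(fast.intervals) == 2  # gap at the duplicated block

    def test_230bp_island_dropped_by_length_filter(self):
        # flanking repeats + 110 bp unique core leave a 230-bp unique range
        rng = np.random.default_rng(6)
        r1, r2 = _rand(rng, 300), _rand(rng, 300)
        unique = _rand(rng, 110)
        target = r1 + unique + r2
        decoy = (
            _rand(rng, 100) + r1 + unique.translate(_MM) * 2
            + _rand(rng, 100) + unique.translate(_MM) + r2 + _rand(rng, 100)
        )
        genome = {"t": target, "d": decoy}
        island = b.unique_regions("t", genome, b.BaitDesignParams(min_merged_length=70))
        assert island.intervals == [(240, 470)]
        assert island.total_bp == 230
        dropped = b.unique_regions("t", genome)  # default 240 bp minimum
        assert dropped.intervals == []

    def test_matches_bruteforce_on_random_genomes(self):
        out = bait_oracle_agreement(n_reps=10, seed=7)
        assert out["agreement"] == 1.0

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(8)
        genome = _random_genome_with_duplication(rng)
        bps = []
        for mm in (0, 1, 2):
            p = b.BaitDesignParams(max_mismatches=mm, min_merged_length=70)
            bps.append(b.unique_regions("chrT", genome, p).total_bp)
        assert bps[0] >= bps[1] >= bps[2]

    def test_min_length_monotonicity(self):
        rng = np.random.default_rng(9)
        genome = _random_genome_with_duplication(rng)
        a = b.unique_regions("chrT", genome, b.BaitDesignParams(min_merged_length=70))
        c = b.unique_regions("chrT", genome, b.BaitDesignParams(min_merged_length=300))
        assert a.total_bp >= c.total_bp

    def test_missing_target_rejected(self):
        with pytest.raises(KeyError):
            b.unique_regions("nope", {"t": "A" * 100})


class TestIntervals:
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 80)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=20,
        )
    )
    def test_merge_produces_disjoint_sorted_cover(self, intervals):
        merged = b.merge_intervals(intervals)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2  # disjoint and non-adjacent after merging
        covered = set()
        for s, e in intervals:
            covered.update(range(s, e))
        merged_cover = set()
        for s, e in merged:
            merged_cover.update(range(s, e))
        assert merged_cover == covered

    def test_adjacent_intervals_merge(self):
        assert b.merge_intervals([(0, 70), (70, 140)]) == [(0, 140)]

    def test_bed_output_deterministic(self, tmp_path):
        iv = b.IntervalSet("chrT", [(0, 240), (400, 700)])
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        iv.to_bed(p1)
        iv.to_bed(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text() == "chrT\t0\t240\nchrT\t400\t700\n"

    def test_tsv_uses_1based_inclusive(self, tmp_path):
        iv = b.IntervalSet("chrT", [(0, 240)])
        p = tmp_path / "a.tsv"
        iv.to_tsv_1based(p)
        assert "chrT\t1\t240\t240" in p.read_text()

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            b.IntervalSet("t", [(10, 10)])
        with pytest.raises(ValueError):
            b.IntervalSet("t", [(0, 50), (40, 90)])
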