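"""Consensus intersection, split-segment merging and marker counting."""

import numpy as np
import pandas as pd
import pytest

from cnvburden.harmonize import (
    MarkerIndex,
    count_markers,
    intersect_caller_calls,
    merge_adjacent,
)

from conftest import make_call


def calls_df(rows):
    return pd.DataFrame(rows)


class TestCountMarkers:
    def test_inclusive_boundaries(self):
        mm = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c"],
                "chromosome": "1",
                "position_bp": [10, 20, 30],
                "is_cnv_probe": False,
            }
        )
        assert count_markers(mm, "1", 10, 30) == 3
        assert count_markers(mm, "1", 11, 19) == 0
        with pytest.raises(ValueError):
            count_markers(mm, "7", 1, 100)

    def test_matches_linear_scan_oracle(self, small_map):
        idx = MarkerIndex.from_frame(small_map)
        rng = np.random.default_rng(3)
        chroms = list(idx.positions)
        pos_by_chrom = {c: small_map.loc[small_map.chromosome == c, "position_bp"].to_numpy() for c in chroms}
        for _ in range(1000):
            c = chroms[rng.integers(len(chroms))]
            a, b = sorted(rng.integers(1, 50_000_000, size=2).tolist())
            expected = int(((pos_by_chrom[c] >= a) & (pos_by_chrom[c] <= b)).sum())
            assert idx.count(c, a, b) == expected


class TestIntersect:
    def test_overlapping_region_boundaries(self, dense_map):
        a = calls_df([make_call("s1", 1, 100_000, 1_000_000, 1, "A")])
        b = calls_df([make_call("s1", 1, 500_000, 1_500_000, 1, "B")])
        out = intersect_caller_calls(a, b, dense_map)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start_bp, row.end_bp) == (500_000, 1_000_000)
        assert row.dosage_class == "deletion"
        assert row.length_bp == 500_001

    def test_class_mismatch_gives_no_consensus(self, dense_map):
        a = calls_df([make_call("s1", 1, 100_000, 1_000_000, 1, "A")])
        b = calls_df([make_call("s1", 1, 100_000, 1_000_000, 3, "B")])
        assert intersect_caller_calls(a, b, dense_map).empty

    def test_symmetry_and_anti_extension(self, small_map):
        rng = np.random.default_rng(9)
        rows_a, rows_b = [], []
        for s in range(10):
            for _ in range(5):
                c = str(rng.integers(1, 9))
                start = int(rng.integers(1, 45_000_000))
                rows_a.append(make_call(f"s{s}", c, start, start + int(rng.integers(2e5, 2e6)), rng.choice([1, 3]), "A"))
                start = int(rng.integers(1, 45_000_000))
                rows_b.append(make_call(f"s{s}", c, start, start + int(rng.integers(2e5, 2e6)), rng.choice([1, 3]), "B"))
        a, b = calls_df(rows_a), calls_df(rows_b)
        ab = intersect_caller_calls(a, b, small_map)
        ba = intersect_caller_calls(b, a, small_map)
        key = ["sample_id", "chromosome", "start_bp", "end_bp", "dosage_class", "n_markers"]
        pd.testing.assert_frame_equal(ab[key], ba[key])
        # swapped provenance
        assert list(ab["copy_number_a"]) == list(ba["copy_number_b"])
        # every consensus segment contained in both source calls
        assert (ab["start_bp"] >= ab[["caller_a_start", "caller_b_start"]].max(axis=1)).all()
        assert (ab["end_bp"] <= ab[["caller_a_end", "caller_b_end"]].min(axis=1)).all()

    def test_matches_marker_set_oracle(self, small_map):
        """Unambiguous pairings equal pure set-algebra on marker sets."""
        idx = MarkerIndex.from_frame(small_map)
        rng = np.random.default_rng(17)
        n_checked = 0
        for _ in range(1000):
            # disjoint loci => unambiguous matching
            n_loci = int(rng.integers(1, 5))
            rows_a, rows_b, expected = [], [], []
            for k in range(n_loci):
                base = 1 + k * 12_000_000
                cn = int(rng.choice([0, 1, 3, 4]))
                sa = base + int(rng.integers(0, 2_000_000))
                ea = sa + int(rng.integers(100_000, 4_000_000))
                sb = base + int(rng.integers(0, 2_000_000))
                eb = sb + int(rng.integers(100_000, 4_000_000))
                rows_a.append(make_call("s", 1, sa, ea, cn, "A"))
                rows_b.append(make_call("s", 1, sb, eb, cn, "B"))
                lo, hi = max(sa, sb), min(ea, eb)
                if hi >= lo:
                    pos = idx.positions["1"]
                    in_a = set(pos[(pos >= sa) & (pos <= ea)])
                    in_b = set(pos[(pos >= sb) & (pos <= eb)])
                    expected.append((lo, hi, len(in_a & in_b)))
            out = intersect_caller_calls(calls_df(rows_a), calls_df(rows_b), small_map)
            got = sorted(zip(out.start_bp, out.end_bp, out.n_markers))
            assert got == sorted(expected)
            n_checked += len(expected)
        assert n_checked > 1000

    def test_each_call_used_at_most_once(self, dense_map):
        # one call of A overlapping two calls of B: only one consensus record
        a = calls_df([make_call("s1", 1, 100_000, 5_000_000, 1, "A")])
        b = calls_df(
            [
                make_call("s1", 1, 200_000, 900_000, 1, "B"),
                make_call("s1", 1, 1_000_000, 4_500_000, 1, "B"),
            ]
        )
        out = intersect_caller_calls(a, b, dense_map)
        assert len(out) == 1
        # greedy: larger overlap wins
        assert (out.iloc[0].start_bp, out.iloc[0].end_bp) == (1_000_000, 4_500_000)

    def test_off_map_chromosome_skipped_with_warning(self, dense_map, caplog):
        a = calls_df([make_call("s1", "99", 100_000, 1_000_000, 1, "A")])
        b = calls_df([make_call("s1", "99", 100_000, 1_000_000, 1, "B")])
        with caplog.at_level("WARNING"):
            out = intersect_caller_calls(a, b, dense_map)
        assert out.empty
        assert "off the marker map" in caplog.text


def consensus_row(sample, chrom, start, end, dclass="deletion", cn=1):
    return {
        "sample_id": sample,
        "chromosome": str(chrom),
        "start_bp": int(start),
        "end_bp": int(end),
        "dosage_class": dclass,
        "copy_number_a": cn,
        "copy_number_b": cn,
        "n_markers": 1,
        "length_bp": int(end) - int(start) + 1,
        "caller_a_start": int(start),
        "caller_a_end": int(end),
        "caller_b_start": int(start),
        "caller_b_end": int(end),
    }


class TestMergeAdjacent:
    def test_merges_when_gap_under_half_span(self, dense_map):
        df = pd.DataFrame(
            [consensus_row("s", 1, 1, 300_000), consensus_row("s", 1, 400_001, 700_000)]
        )
        out = merge_adjacent(df, dense_map)
        assert len(out) == 1
        assert (out.iloc[0].start_bp, out.iloc[0].end_bp) == (1, 700_000)

    def test_short_members_not_merged(self, dense_map):
        df = pd.DataFrame(
            [consensus_row("s", 1, 1, 150_000), consensus_row("s", 1, 200_001, 350_000)]
        )
        out = merge_adjacent(df, dense_map)
        assert len(out) == 2

    def test_class_mismatch_not_merged(self, dense_map):
        df = pd.DataFrame(
            [
                consensus_row("s", 1, 1, 300_000, "deletion"),
                consensus_row("s", 1, 400_001, 700_000, "duplication", cn=3),
            ]
        )
        assert len(merge_adjacent(df, dense_map)) == 2

    def test_idempotent(self, dense_map):
        rng = np.random.default_rng(23)
        rows = []
        pos = 1
        for _ in range(8):
            length = int(rng.integers(100_000, 600_000))
            rows.append(consensus_row("s", 1, pos, pos + length))
            pos += length + int(rng.integers(10_000, 500_000))
        df = pd.DataFrame(rows)
        once = merge_adjacent(df, dense_map)
        twice = merge_adjacent(once, dense_map)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_exhaustive_order_oracle(self, dense_map):
        """All merge orders reach the same fixpoint, equal to the output."""

        def mergeable(a, b):
            gap = b[0] - a[1] - 1
            span = b[1] - a[0] + 1
            return (
                gap >= 0
                and (a[1] - a[0] + 1) > 200_000
                and (b[1] - b[0] + 1) > 200_000
                and gap < 0.5 * span
            )

        def fixpoints(state):
            state = tuple(state)
            candidates = [
                i for i in range(len(state) - 1) if mergeable(state[i], state[i + 1])
            ]
            if not candidates:
                return {state}
            out = set()
            for i in candidates:
                nxt = state[:i] + ((state[i][0], state[i + 1][1]),) + state[i + 2 :]
                out |= fixpoints(nxt)
            return out

        rng = np.random.default_rng(41)
        for _ in range(1000):
            n = int(rng.integers(3, 7))
            segs = []
            pos = 1
            for _ in range(n):
                length = int(rng.integers(50_000, 700_000))
                segs.append((pos, pos + length))
                pos += length + int(rng.integers(1, 400_000))
            all_fp = fixpoints(segs)
            assert len(all_fp) == 1, f"order-dependent fixpoint for {segs}"
            df = pd.DataFrame([consensus_row("s", 1, a, b) for a, b in segs])
            out = merge_adjacent(df, dense_map)
            got = list(zip(out.start_bp, out.end_bp))
            assert got == list(next(iter(all_fp)))
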