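"""Dual-caller consensus CNV harmonization.

Two CNV callers observe the same samples and report marker-delimited
segments with boundary disagreement, missed calls and occasional
artificially split segments. Only variants called by both algorithms are
analysed; where boundaries differ, the start and end of the overlapping
region are taken as the consensus boundaries. Adjacent same-state segments
that look artificially split are re-joined by a deterministic merge rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = [
    "sample_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "dosage_class",
    "copy_number_a",
    "copy_number_b",
    "n_markers",
    "length_bp",
    "caller_a_start",
    "caller_a_end",
    "caller_b_start",
    "caller_b_end",
]


def dosage_class(copy_number: int) -> str:
    """Classify a copy number as deletion (<2) or duplication (>2)."""
    if copy_number == 2:
        raise ValueError("copy number 2 is not a CNV")
    return "deletion" if copy_number < 2 else "duplication"


@dataclass(frozen=True)
class MarkerIndex:
    """Per-chromosome sorted marker positions for O(log n) range counts."""

    positions: dict[str, np.ndarray]

    @classmethod
    def from_frame(cls, marker_map: pd.DataFrame) -> "MarkerIndex":
        pos: dict[str, np.ndarray] = {}
        for chrom, grp in marker_map.groupby("chromosome", sort=False):
            p = np.asarray(grp["position_bp"], dtype=np.int64)
            if not np.all(np.diff(p) > 0):
                p = np.sort(p)
            pos[str(chrom)] = p
        if not pos:
            raise ValueError("empty marker map")
        return cls(positions=pos)

    def count(self, chromosome: str, start_bp: int, end_bp: int) -> int:
        """Number of markers p with start_bp <= p <= end_bp."""
        p = self.positions.get(str(chromosome))
        if p is None:
            raise ValueError(f"chromosome {chromosome!r} not on marker map")
        lo = int(np.searchsorted(p, start_bp, side="left"))
        hi = int(np.searchsorted(p, end_bp, side="right"))
        return hi - lo

    def span(self, chromosome: str, start_bp: int, end_bp: int) -> tuple[int, int] | None:
        """Positions of the first and last marker inside [start, end], or None."""
        p = self.positions.get(str(chromosome))
        if p is None:
            raise ValueError(f"chromosome {chromosome!r} not on marker map")
        lo = int(np.searchsorted(p, start_bp, side="left"))
        hi = int(np.searchsorted(p, end_bp, side="right"))
        if hi <= lo:
            return None
        return int(p[lo]), int(p[hi - 1])


def count_markers(
    marker_map: pd.DataFrame | MarkerIndex, chromosome: str, start_bp: int, end_bp: int
) -> int:
    """Count markers of the map lying within [start_bp, end_bp] inclusive."""
    idx = marker_map if isinstance(marker_map, MarkerIndex) else MarkerIndex.from_frame(marker_map)
    return idx.count(chromosome, start_bp, end_bp)


def _prep_calls(calls: pd.DataFrame, which: str) -> pd.DataFrame:
    df = calls.copy()
    required = {"sample_id", "chromosome", "start_bp", "end_bp", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"caller {which} calls missing columns: {sorted(missing)}")
    if (df["copy_number"] == 2).any():
        raise ValueError("copy number 2 present in caller calls")
    df["dosage_class"] = np.where(df["copy_number"] < 2, "deletion", "duplication")
    df["chromosome"] = df["chromosome"].astype(str)
    return df.sort_values(["sample_id", "chromosome", "start_bp", "end_bp"]).reset_index(drop=True)


def intersect_caller_calls(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, marker_map: pd.DataFrame | MarkerIndex
) -> pd.DataFrame:
    """Consensus of two callers: one record per matched pair of calls.

    A match requires the same sample, chromosome and dosage class and a
    positive coordinate overlap; consensus boundaries are the intersection
    [max(starts), min(ends)]. Each input call participates in at most one
    consensus record; one-to-many overlaps are resolved greedily by largest
    overlap length, ties by leftmost start. Marker counts are recomputed
    from the map. Calls on chromosomes absent from the map are skipped with
    a warning.

    Returns a consensus table sorted by (sample, chromosome, start).
    """
    idx = marker_map if isinstance(marker_map, MarkerIndex) else MarkerIndex.from_frame(marker_map)
    a = _prep_calls(calls_a, "A")
    b = _prep_calls(calls_b, "B")

    off_map = sorted(
        (set(a["chromosome"]) | set(b["chromosome"])) - set(idx.positions)
    )
    if off_map:
        logger.warning("skipping calls on chromosomes off the marker map: %s", off_map)
        a = a[~a["chromosome"].isin(off_map)]
        b = b[~b["chromosome"].isin(off_map)]

    rows: list[dict] = []
    b_groups = {k: g for k, g in b.groupby(["sample_id", "chromosome", "dosage_class"], sort=False)}
    for key, ga in a.groupby(["sample_id", "chromosome", "dosage_class"], sort=False):
        gb = b_groups.get(key)
        if gb is None:
            continue
        sample, chrom, dclass = key
        # all positively overlapping pairs, then greedy one-to-one matching
        pairs = []
        for ia, ra in enumerate(ga.itertuples(index=False)):
            for ib, rb in enumerate(gb.itertuples(index=False)):
                lo = max(ra.start_bp, rb.start_bp)
                hi = min(ra.end_bp, rb.end_bp)
                if hi >= lo:
                    pairs.append((hi - lo + 1, lo, hi, ia, ib))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ov, lo, hi, ia, ib in pairs:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            ra = ga.iloc[ia]
            rb = gb.iloc[ib]
            rows.append(
                {
                    "sample_id": sample,
                    "chromosome": chrom,
                    "start_bp": lo,
                    "end_bp": hi,
                    "dosage_class": dclass,
                    "copy_number_a": int(ra["copy_number"]),
                    "copy_number_b": int(rb["copy_number"]),
                    "n_markers": idx.count(chrom, lo, hi),
                    "length_bp": hi - lo + 1,
                    "caller_a_start": int(ra["start_bp"]),
                    "caller_a_end": int(ra["end_bp"]),
                    "caller_b_start": int(rb["start_bp"]),
                    "caller_b_end": int(rb["end_bp"]),
                }
            )
    out = pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)
    return out.sort_values(["sample_id", "chromosome", "start_bp", "end_bp"]).reset_index(drop=True)


def merge_adjacent(
    consensus: pd.DataFrame,
    marker_map: pd.DataFrame | MarkerIndex,
    min_member_length_bp: int = 200_000,
    max_gap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Re-join artificially split segments.

    Two adjacent segments of the same sample, chromosome and dosage class
    are merged into one spanning segment when each member is strictly
    longer than ``min_member_length_bp`` and the gap between them is
    strictly less than ``max_gap_fraction`` times the merged span. The rule
    is applied left-to-right and iterated to a fixpoint; because merging
    only enlarges segments, the fixpoint does not depend on merge order.
    Marker counts are recomputed over merged spans.
    """
    idx = marker_map if isinstance(marker_map, MarkerIndex) else MarkerIndex.from_frame(marker_map)
    if consensus.empty:
        return consensus.copy()
    out_groups = []
    sort_cols = ["sample_id", "chromosome", "start_bp", "end_bp"]
    df = consensus.sort_values(sort_cols).reset_index(drop=True)
    for key, grp in df.groupby(["sample_id", "chromosome", "dosage_class"], sort=False):
        segs = grp.to_dict("records")
        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(segs) - 1:
                cur, nxt = segs[i], segs[i + 1]
                len_cur = cur["end_bp"] - cur["start_bp"] + 1
                len_nxt = nxt["end_bp"] - nxt["start_bp"] + 1
                gap = nxt["start_bp"] - cur["end_bp"] - 1
                span = nxt["end_bp"] - cur["start_bp"] + 1
                if (
                    gap >= 0
                    and len_cur > min_member_length_bp
                    and len_nxt > min_member_length_bp
                    and gap < max_gap_fraction * span
                ):
                    merged = dict(cur)
                    merged["end_bp"] = nxt["end_bp"]
                    merged["length_bp"] = span
                    merged["n_markers"] = idx.count(
                        merged["chromosome"], merged["start_bp"], merged["end_bp"]
                    )
                    for col, fn in (
                        ("caller_a_start", min),
                        ("caller_b_start", min),
                        ("caller_a_end", max),
                        ("caller_b_end", max),
                    ):
                        if col in merged:
                            merged[col] = fn(cur[col], nxt[col])
                    segs[i : i + 2] = [merged]
                    changed = True
                else:
                    i += 1
        out_groups.extend(segs)
    out = pd.DataFrame(out_groups, columns=df.columns)
    return out.sort_values(sort_cols).reset_index(drop=True)
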