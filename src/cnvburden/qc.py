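"""Sample-level QC, CNV-level QC and the per-cohort rarity filter.

Sample exclusions: high Log-R-Ratio standard deviation (array noise),
an excess of long CNV calls (unreliable samples), and the lower-call-rate
member of each duplicate-genotyped pair. CNV exclusions: too few markers,
too short, or common — any marker along the CNV lying in a CNV region in
more than ``max_frequency`` of the sample's cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import FilterConfig
from .harmonize import MarkerIndex

logger = logging.getLogger(__name__)

WHOLE_SAMPLE_COHORT = "__all__"


def filter_samples(
    qc_records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply sample-level QC.

    Excludes samples with LRR SD strictly greater than ``lrr_sd_max``,
    samples with ``max_cnvs_gt_100kb`` or more CNVs longer than 100 kb,
    and, within each duplicate-genotyped pair, the member with the lower
    SNP call rate.

    Returns (kept sample ids in input order, exclusion log with one row
    per (sample, reason)).
    """
    config = config or FilterConfig()
    df = qc_records
    if df["sample_id"].duplicated().any():
        raise ValueError("multiple QC records for one sample")
    known = set(df["sample_id"])
    exclusions: list[dict] = []
    excluded: set[str] = set()

    for row in df.itertuples(index=False):
        if row.lrr_sd > config.lrr_sd_max:
            exclusions.append(
                {"sample_id": row.sample_id, "reason": "lrr_sd", "value": row.lrr_sd}
            )
            excluded.add(row.sample_id)
        if row.n_cnv_gt_100kb >= config.max_cnvs_gt_100kb:
            exclusions.append(
                {
                    "sample_id": row.sample_id,
                    "reason": "excess_long_cnvs",
                    "value": row.n_cnv_gt_100kb,
                }
            )
            excluded.add(row.sample_id)

    # duplicate pairs: drop the lower-call-rate member
    call_rate = dict(zip(df["sample_id"], df["snp_call_rate"]))
    partner = {
        r.sample_id: r.duplicate_partner
        for r in df.itertuples(index=False)
        if isinstance(r.duplicate_partner, str) and r.duplicate_partner
    }
    seen_pairs: set[tuple[str, str]] = set()
    for s, p in partner.items():
        if p not in known:
            raise ValueError(f"duplicate_partner {p!r} of {s!r} is not a known sample")
        key = tuple(sorted((s, p)))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        # ties broken by sample id so the outcome is deterministic
        loser = min(key, key=lambda x: (call_rate[x], x))
        exclusions.append(
            {"sample_id": loser, "reason": "duplicate_lower_call_rate", "value": call_rate[loser]}
        )
        excluded.add(loser)

    kept = [s for s in df["sample_id"] if s not in excluded]
    log = pd.DataFrame(exclusions, columns=["sample_id", "reason", "value"])
    logger.info("sample QC: kept %d of %d samples", len(kept), len(df))
    return kept, log


def filter_cnvs_basic(
    consensus: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Keep consensus CNVs spanning >= min_markers markers and >= min_length_bp."""
    config = config or FilterConfig()
    keep = (consensus["n_markers"] >= config.min_markers) & (
        consensus["length_bp"] >= config.min_length_bp
    )
    out = consensus[keep].reset_index(drop=True)
    logger.info("CNV QC: kept %d of %d consensus CNVs", len(out), len(consensus))
    return out


def marker_cnv_frequency(
    consensus: pd.DataFrame,
    marker_map: pd.DataFrame,
    cohort_assignment: pd.Series | dict,
) -> pd.DataFrame:
    """Per-marker, per-cohort CNV carrier frequency.

    For each marker m and cohort c the frequency is the number of distinct
    samples in c with at least one consensus CNV covering m, divided by
    the cohort size. A sample with two CNVs over the same marker counts
    once. Returns a wide table: marker_id, chromosome, position_bp, then
    one frequency column per cohort.
    """
    cohort_of = dict(cohort_assignment) if not isinstance(cohort_assignment, dict) else cohort_assignment
    cohorts = sorted(set(cohort_of.values()))
    sizes = {c: 0 for c in cohorts}
    for c in cohort_of.values():
        sizes[c] += 1
    if any(n == 0 for n in sizes.values()):
        raise ValueError("empty cohort in assignment")

    mm = marker_map.sort_values(["chromosome", "position_bp"], kind="stable")
    chrom_pos: dict[str, np.ndarray] = {}
    chrom_offset: dict[str, int] = {}
    off = 0
    for chrom, grp in mm.groupby("chromosome", sort=False):
        chrom_pos[str(chrom)] = np.asarray(grp["position_bp"], dtype=np.int64)
        chrom_offset[str(chrom)] = off
        off += len(grp)
    n_markers = off

    counts = np.zeros((n_markers, len(cohorts)), dtype=np.int64)
    cohort_col = {c: j for j, c in enumerate(cohorts)}
    # per sample: union of covered marker index ranges, then +1 per cohort
    for (sample, _), grp in consensus.groupby(["sample_id", "chromosome"], sort=False):
        if sample not in cohort_of:
            raise ValueError(f"sample {sample!r} has no cohort assignment")
        chrom = str(grp["chromosome"].iloc[0])
        pos = chrom_pos.get(chrom)
        if pos is None:
            continue
        covered = np.zeros(len(pos), dtype=bool)
        for row in grp.itertuples(index=False):
            lo = np.searchsorted(pos, row.start_bp, side="left")
            hi = np.searchsorted(pos, row.end_bp, side="right")
            covered[lo:hi] = True
        j = cohort_col[cohort_of[sample]]
        base = chrom_offset[chrom]
        counts[base : base + len(pos), j] += covered

    out = mm[["marker_id", "chromosome", "position_bp"]].reset_index(drop=True)
    for c in cohorts:
        out[c] = counts[:, cohort_col[c]] / sizes[c]
    return out


def filter_rare(
    consensus: pd.DataFrame,
    frequency_table: pd.DataFrame,
    cohort_assignment: pd.Series | dict,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Drop CNVs overlapping any marker commoner than ``max_frequency``.

    A CNV is removed when at least one marker along its length has a CNV
    carrier frequency strictly greater than ``max_frequency`` in the
    sample's cohort (or in the whole sample when ``frequency_scope`` is
    ``whole_sample``, in which case the frequency table must carry the
    whole-sample column). Single pass: frequencies are not recomputed
    after removals.
    """
    config = config or FilterConfig()
    cohort_of = dict(cohort_assignment) if not isinstance(cohort_assignment, dict) else cohort_assignment

    ft = frequency_table.sort_values(["chromosome", "position_bp"], kind="stable")
    chrom_pos: dict[str, np.ndarray] = {}
    chrom_freq: dict[str, pd.DataFrame] = {}
    for chrom, grp in ft.groupby("chromosome", sort=False):
        chrom_pos[str(chrom)] = np.asarray(grp["position_bp"], dtype=np.int64)
        chrom_freq[str(chrom)] = grp.reset_index(drop=True)

    keep_mask = []
    for row in consensus.itertuples(index=False):
        chrom = str(row.chromosome)
        pos = chrom_pos.get(chrom)
        if pos is None:
            raise ValueError(f"frequency table lacks chromosome {chrom!r}")
        if config.frequency_scope == "whole_sample":
            col = WHOLE_SAMPLE_COHORT
        else:
            col = cohort_of[row.sample_id]
        freqs = np.asarray(chrom_freq[chrom][col], dtype=float)
        lo = np.searchsorted(pos, row.start_bp, side="left")
        hi = np.searchsorted(pos, row.end_bp, side="right")
        keep_mask.append(not bool((freqs[lo:hi] > config.max_frequency).any()))
    out = consensus[np.asarray(keep_mask, dtype=bool)].reset_index(drop=True)
    logger.info("rarity filter: kept %d of %d CNVs", len(out), len(consensus))
    return out


def whole_sample_assignment(cohort_assignment: pd.Series | dict) -> dict:
    """Collapse all samples into one pseudo-cohort for whole-sample scope."""
    cohort_of = dict(cohort_assignment) if not isinstance(cohort_assignment, dict) else cohort_assignment
    return {s: WHOLE_SAMPLE_COHORT for s in cohort_of}


def duplicate_concordance(
    consensus: pd.DataFrame, qc_records: pd.DataFrame, min_length_bp: int = 0
) -> float:
    """Diagnostic: fraction of CNVs shared by both members of duplicate pairs.

    For each duplicate-genotyped pair, a CNV of one member is counted as
    concordant when the other member has an overlapping CNV of the same
    dosage class. Optionally restrict to CNVs of at least ``min_length_bp``.
    Returns NaN when the duplicate pairs carry no CNVs.
    """
    pairs = {
        tuple(sorted((r.sample_id, r.duplicate_partner)))
        for r in qc_records.itertuples(index=False)
        if isinstance(r.duplicate_partner, str) and r.duplicate_partner
    }
    cnvs = consensus[consensus["length_bp"] >= min_length_bp]
    by_sample = {k: g for k, g in cnvs.groupby("sample_id", sort=False)}
    total = 0
    shared = 0
    for s1, s2 in sorted(pairs):
        for a, b in ((s1, s2), (s2, s1)):
            ga = by_sample.get(a)
            gb = by_sample.get(b)
            if ga is None:
                continue
            for row in ga.itertuples(index=False):
                total += 1
                if gb is None:
                    continue
                hit = (
                    (gb["chromosome"] == row.chromosome)
                    & (gb["dosage_class"] == row.dosage_class)
                    & (gb["start_bp"] <= row.end_bp)
                    & (gb["end_bp"] >= row.start_bp)
                )
                if bool(hit.any()):
                    shared += 1
    return shared / total if total else float("nan")
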