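"""Synthetic study generator.

Generates everything the pipeline consumes — marker maps, true rare-CNV
sets with known per-sample burden, two noisy caller call tables, gene
annotations, candidate-region panels, per-sample QC metrics, and cognitive
test scores with configurable CNV effect sizes — so every downstream stage
is testable against known ground truth without any external data.

Every output is a pure function of (config, seed): each stage draws from
an independent, deterministically derived substream of the configured
seed.

The caller noise model emulates two HMM-based CNV callers as noisy
observers of a common truth: reported boundaries are true boundaries
plus jitter snapped to marker positions (callers report marker-delimited
segments), whole calls are missed with a per-caller probability, and a
true segment is occasionally emitted as two adjacent fragments separated
by a one-marker gap (the artefact the downstream merge rule repairs).
LRR/BAF intensity signals themselves are not simulated.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import DEFAULT_COHORT_AGES, SimulationConfig

_STREAM_SAMPLES = 0
_STREAM_CNVS = 1
_STREAM_QC = 2
_STREAM_PHENOTYPES = 3
_STREAM_CALLER = 4
_STREAM_GENES = 5
_STREAM_REGIONS = 6

TRUTH_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp", "copy_number"]


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, extra)))


def gen_marker_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    seed: int,
    chromosome_length_bp: int = 50_000_000,
) -> pd.DataFrame:
    """Random marker map: uniform marker positions per chromosome.

    Per chromosome, ``markers_per_chromosome`` distinct positions are drawn
    uniformly without replacement from 1..chromosome_length_bp and sorted.
    Roughly 4% of markers are flagged as non-polymorphic CNV probes.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("chromosome and marker counts must be >= 1")
    if markers_per_chromosome > chromosome_length_bp:
        raise ValueError("more markers than base pairs")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(rng.choice(chromosome_length_bp, size=markers_per_chromosome, replace=False)) + 1
        is_cnv = rng.random(markers_per_chromosome) < 0.04
        for k, (p, q) in enumerate(zip(pos, is_cnv)):
            rows.append(
                {
                    "marker_id": f"chr{c}_m{k:05d}",
                    "chromosome": str(c),
                    "position_bp": int(p),
                    "is_cnv_probe": bool(q),
                }
            )
    return pd.DataFrame(rows)


def _cohort_age(cohort: str) -> tuple[float, float]:
    return DEFAULT_COHORT_AGES.get(cohort, (70.0, 5.0))


def gen_truth(
    config: SimulationConfig, marker_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the study sample: cohorts, true rare CNVs and QC metrics.

    Returns (samples, truth, qc):

    - samples: sample_id, cohort, age, sex;
    - truth: true CNV segments (Poisson count per sample at ``cnv_rate``,
      log-uniform lengths, deletions with probability ``deletion_fraction``,
      plus optional common loci carried by >1% of samples);
    - qc: per-sample LRR SD, SNP call rate, long-CNV count and duplicate
      partner, with configured fractions of QC-failing samples.
    """
    config.validate()
    chroms = [str(c) for c in pd.unique(marker_map["chromosome"])]
    chrom_len = {
        c: int(marker_map.loc[marker_map["chromosome"] == c, "position_bp"].max()) for c in chroms
    }

    rng_s = _rng(config.seed, _STREAM_SAMPLES)
    sample_rows = []
    for cohort in config.n_samples_per_cohort:
        n = config.n_samples_per_cohort[cohort]
        mean_age, sd_age = _cohort_age(cohort)
        ages = rng_s.normal(mean_age, sd_age, size=n)
        sexes = rng_s.choice(["female", "male"], size=n)
        for i in range(n):
            sample_rows.append(
                {
                    "sample_id": f"{cohort}_{i:05d}",
                    "cohort": cohort,
                    "age": round(float(ages[i]), 2),
                    "sex": str(sexes[i]),
                }
            )
    samples = pd.DataFrame(sample_rows)

    rng_c = _rng(config.seed, _STREAM_CNVS)
    truth_rows = []
    log_lo, log_hi = np.log(config.length_min_bp), np.log(config.length_max_bp)
    for sid in samples["sample_id"]:
        for _ in range(rng_c.poisson(config.cnv_rate)):
            chrom = chroms[rng_c.integers(len(chroms))]
            length = int(np.exp(rng_c.uniform(log_lo, log_hi)))
            length = min(length, chrom_len[chrom] - 1)
            start = int(rng_c.integers(1, chrom_len[chrom] - length + 1))
            if rng_c.random() < config.deletion_fraction:
                cn = int(rng_c.choice([0, 1], p=[0.2, 0.8]))
            else:
                cn = int(rng_c.choice([3, 4], p=[0.85, 0.15]))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "chromosome": chrom,
                    "start_bp": start,
                    "end_bp": start + length - 1,
                    "copy_number": cn,
                }
            )
    # optional common loci to exercise the rarity filter
    for j in range(config.n_common_loci):
        chrom = chroms[rng_c.integers(len(chroms))]
        length = int(rng_c.uniform(600_000, 1_200_000))
        start = int(rng_c.integers(1, max(2, chrom_len[chrom] - length)))
        cn = 1 if rng_c.random() < 0.5 else 3
        carriers = rng_c.random(len(samples)) < config.common_carrier_fraction
        for sid in samples["sample_id"][carriers]:
            truth_rows.append(
                {
                    "sample_id": sid,
                    "chromosome": chrom,
                    "start_bp": start,
                    "end_bp": start + length - 1,
                    "copy_number": cn,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    rng_q = _rng(config.seed, _STREAM_QC)
    n = len(samples)
    lrr = np.abs(rng_q.normal(0.12, 0.04, size=n)).clip(0.01, 0.29)
    bad = rng_q.random(n) < config.bad_lrr_fraction
    lrr[bad] = rng_q.uniform(0.31, 0.50, size=int(bad.sum()))
    call_rate = rng_q.uniform(0.95, 0.999, size=n)
    n_long = rng_q.poisson(6, size=n)
    noisy = rng_q.random(n) < config.noisy_cnv_fraction
    n_long[noisy] = rng_q.integers(30, 60, size=int(noisy.sum()))
    partner = [""] * n
    if config.n_duplicate_pairs > 0:
        if 2 * config.n_duplicate_pairs > n:
            raise ValueError("more duplicate pairs than samples")
        chosen = rng_q.choice(n, size=2 * config.n_duplicate_pairs, replace=False)
        ids = samples["sample_id"].to_numpy()
        for a, b in zip(chosen[::2], chosen[1::2]):
            partner[a] = ids[b]
            partner[b] = ids[a]
    qc = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "cohort": samples["cohort"],
            "lrr_sd": np.round(lrr, 4),
            "snp_call_rate": np.round(call_rate, 4),
            "n_cnv_gt_100kb": n_long,
            "duplicate_partner": partner,
        }
    )
    return samples, truth, qc


def snap_to_markers(truth: pd.DataFrame, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Truth segments restricted to marker-delimited boundaries.

    Each segment becomes [first marker >= start, last marker <= end];
    segments containing no marker are dropped. This is the reference for
    round-trip comparisons against harmonized caller output.
    """
    from .harmonize import MarkerIndex

    idx = MarkerIndex.from_frame(marker_map)
    rows = []
    for row in truth.itertuples(index=False):
        span = idx.span(str(row.chromosome), int(row.start_bp), int(row.end_bp))
        if span is None:
            continue
        rows.append(
            {
                "sample_id": row.sample_id,
                "chromosome": str(row.chromosome),
                "start_bp": span[0],
                "end_bp": span[1],
                "copy_number": int(row.copy_number),
                "n_markers": idx.count(str(row.chromosome), span[0], span[1]),
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS + ["n_markers"])


def emit_caller_calls(
    truth: pd.DataFrame,
    marker_map: pd.DataFrame,
    config: SimulationConfig,
    caller_id: str,
) -> pd.DataFrame:
    """One caller's noisy observation of the truth set.

    Per true segment: missed entirely with probability ``caller_miss_rate``;
    otherwise boundaries are jittered by +/- ``caller_boundary_jitter_bp``
    and snapped to the first/last marker inside the jittered span; with
    probability ``split_probability`` the call is emitted as two fragments
    separated by a one-marker gap (split point 40-60% along the markers).
    Marker counts are recomputed from the map. Each caller draws from its
    own deterministic substream of the seed.
    """
    from .harmonize import MarkerIndex

    if marker_map.empty:
        raise ValueError("empty marker map")
    idx = MarkerIndex.from_frame(marker_map)
    rng = _rng(config.seed, _STREAM_CALLER, extra=zlib.crc32(caller_id.encode()))
    j = config.caller_boundary_jitter_bp
    rows = []
    for row in truth.itertuples(index=False):
        if rng.random() < config.caller_miss_rate:
            continue
        chrom = str(row.chromosome)
        pos = idx.positions.get(chrom)
        if pos is None:
            raise ValueError(f"truth CNV on chromosome {chrom!r} absent from marker map")
        s = int(row.start_bp) + (int(rng.integers(-j, j + 1)) if j else 0)
        e = int(row.end_bp) + (int(rng.integers(-j, j + 1)) if j else 0)
        if e < s:
            s, e = e, s
        lo = int(np.searchsorted(pos, s, side="left"))
        hi = int(np.searchsorted(pos, e, side="right"))
        if hi - lo < 1:
            continue  # jittered span covers no marker: effectively missed
        fragments = [(lo, hi - 1)]
        if hi - lo >= 4 and rng.random() < config.split_probability:
            cut = lo + int(np.floor(rng.uniform(0.4, 0.6) * (hi - lo)))
            cut = min(max(cut, lo + 1), hi - 3)
            fragments = [(lo, cut - 1), (cut + 1, hi - 1)]
        for flo, fhi in fragments:
            rows.append(
                {
                    "sample_id": row.sample_id,
                    "caller_id": caller_id,
                    "chromosome": chrom,
                    "start_bp": int(pos[flo]),
                    "end_bp": int(pos[fhi]),
                    "copy_number": int(row.copy_number),
                    "n_markers": fhi - flo + 1,
                }
            )
    cols = ["sample_id", "caller_id", "chromosome", "start_bp", "end_bp", "copy_number", "n_markers"]
    return pd.DataFrame(rows, columns=cols)


def gen_genes(
    marker_map: pd.DataFrame, genes_per_chromosome: int = 40, seed: int = 0
) -> pd.DataFrame:
    """Random gene annotation (1-based inclusive coordinates).

    Gene lengths are log-uniform between 5 kb and 200 kb, starts uniform
    along each chromosome's marker-covered span.
    """
    rng = _rng(seed, _STREAM_GENES)
    rows = []
    for chrom, grp in marker_map.groupby("chromosome", sort=False):
        length_span = int(grp["position_bp"].max())
        for k in range(genes_per_chromosome):
            glen = int(np.exp(rng.uniform(np.log(5_000), np.log(200_000))))
            start = int(rng.integers(1, max(2, length_span - glen)))
            rows.append(
                {
                    "gene_id": f"GENE{chrom}_{k:03d}",
                    "chromosome": str(chrom),
                    "start_bp": start,
                    "end_bp": start + glen - 1,
                }
            )
    return pd.DataFrame(rows)


def gen_candidate_regions(
    marker_map: pd.DataFrame, n_regions: int = 20, seed: int = 0
) -> pd.DataFrame:
    """A panel of candidate CNV regions (neurodevelopmental-disorder style).

    Regions are 300 kb - 1.5 Mb, placed on chromosomes round-robin, with
    an alternating source-disorder label.
    """
    rng = _rng(seed, _STREAM_REGIONS)
    chroms = [str(c) for c in pd.unique(marker_map["chromosome"])]
    chrom_len = {
        c: int(marker_map.loc[marker_map["chromosome"] == c, "position_bp"].max()) for c in chroms
    }
    rows = []
    for k in range(n_regions):
        chrom = chroms[k % len(chroms)]
        length = int(rng.uniform(300_000, 1_500_000))
        start = int(rng.integers(1, max(2, chrom_len[chrom] - length)))
        rows.append(
            {
                "region_id": f"region_{k + 1:02d}",
                "chromosome": chrom,
                "start_bp": start,
                "end_bp": start + length - 1,
                "source_disorder": "schizophrenia" if k % 2 == 0 else "autism",
            }
        )
    return pd.DataFrame(rows)


def plant_region_carriers(
    region: pd.Series | dict,
    sample_ids: list[str],
    copy_number: int = 1,
) -> pd.DataFrame:
    """Truth rows giving each listed sample a CNV covering the region."""
    rows = [
        {
            "sample_id": sid,
            "chromosome": str(region["chromosome"]),
            "start_bp": int(region["start_bp"]),
            "end_bp": int(region["end_bp"]),
            "copy_number": copy_number,
        }
        for sid in sample_ids
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def gen_phenotypes(
    samples: pd.DataFrame,
    burden_truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Raw cognitive test scores with known CNV-burden effects.

    Each sample gets ``n_subtests`` fluid-type subtest scores and one
    vocabulary score. Scores are driven by a shared latent factor (subtest
    loading ``factor_loading``, so PC1 of the battery captures about half
    the variance at the default 0.7), plus an age slope, a sex offset, a
    cohort offset, and noise. The configured standardized burden effects
    enter the latent factors directly, with the latent residual variance
    shrunk so each latent keeps unit variance — a planted effect of beta
    is therefore recoverable as a standardized regression coefficient of
    ~beta on the single-score (vocabulary) phenotype; the PCA-derived
    fluid phenotype recovers it attenuated by the PC1-latent correlation.

    ``burden_truth`` is a per-sample burden table (columns count_all,
    length_all, genes_all; compute_burden output works directly).
    """
    required = {"sample_id", "cohort", "age", "sex"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    unknown = set(burden_truth["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"burden rows for unknown samples: {sorted(unknown)[:5]}")

    df = samples.merge(
        burden_truth[["sample_id", "count_all", "length_all", "genes_all"]],
        on="sample_id",
        how="left",
    ).fillna({"count_all": 0, "length_all": 0, "genes_all": 0})
    n = len(df)

    def z(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    signal = (
        config.effect_beta_count * z(df["count_all"])
        + config.effect_beta_length * z(df["length_all"])
        + config.effect_beta_genes * z(df["genes_all"])
    )
    v = float(signal.var())
    if v >= 1.0:
        raise ValueError("combined burden effects exceed unit latent variance")

    rng = _rng(config.seed, _STREAM_PHENOTYPES)
    latent_f = signal + np.sqrt(1.0 - v) * rng.normal(size=n)
    latent_c = signal + np.sqrt(1.0 - v) * rng.normal(size=n)

    cohort_names = sorted(df["cohort"].unique())
    offset = {c: 0.15 * (i - (len(cohort_names) - 1) / 2) for i, c in enumerate(cohort_names)}
    mean_age = df.groupby("cohort")["age"].transform("mean").to_numpy()
    age_c = df["age"].to_numpy() - mean_age
    sex_male = (df["sex"] == "male").astype(float).to_numpy()
    coh = df["cohort"].map(offset).to_numpy()

    loading = config.factor_loading
    out = df[["sample_id", "cohort", "age", "sex"]].copy()
    for jx in range(1, config.n_subtests + 1):
        noise = rng.normal(size=n)
        score = (
            loading * latent_f
            - 0.03 * age_c
            + 0.10 * sex_male
            + coh
            + np.sqrt(1.0 - loading**2) * noise
        )
        out[f"subtest_{jx}"] = np.round(score, 6)
    vocab = latent_c - 0.01 * age_c + 0.10 * sex_male + coh
    out["vocabulary"] = np.round(vocab, 6)
    return out
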