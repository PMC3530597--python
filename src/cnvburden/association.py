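"""Burden regressions and candidate-region carrier tests.

Burden regressions fit a residualized intelligence phenotype on one CNV
load variable with cohort as a covariate; the effect size is the
standardized beta (coefficient after scaling predictor and outcome to unit
SD) and its empirical p-value comes from permutations of the phenotype
vector across individuals. Candidate regions are tested by two-sample
t-tests of carriers (>= 1 rare CNV overlapping the region) against
non-carriers (pooled variance by default; Welch available),
family-wise corrected by the max-statistic permutation method: at every
permutation the maximum test statistic over all testable regions is
retained, and each region's empirical p is the proportion of permutations
whose maximum exceeds that region's observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

_PERM_CHUNK = 512  # fixed so the permutation stream is reproducible


@dataclass
class RegressionResult:
    """One burden-regression fit."""

    standardized_beta: float
    p_value: float
    n: int
    std_error: float = float("nan")
    empirical_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    defined: bool = True
    predictor: str = ""
    dosage_class: str = ""
    phenotype: str = ""


@dataclass(frozen=True)
class RegionDef:
    """A candidate CNV region (e.g. 16p13.11, SHANK3)."""

    region_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    source_disorder: str = ""

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start must be <= end")


@dataclass
class RegionTestResult:
    """Carrier vs non-carrier test of one candidate region."""

    region_id: str
    n_carriers: int
    tested: bool
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    empirical_p: float | None = None


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def _cohort_design(cohorts: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus cohort indicator columns (first level as reference)."""
    if cohorts is None:
        return np.ones((n, 1))
    cohorts = np.asarray(cohorts)
    levels = pd.unique(cohorts)
    cols = [np.ones(n)]
    for lev in levels[1:]:
        cols.append((cohorts == lev).astype(float))
    return np.column_stack(cols)


def burden_regression(
    phenotype: np.ndarray,
    burden_variable: np.ndarray,
    cohorts: np.ndarray | None = None,
    predictor: str = "",
    dosage_class: str = "",
    phenotype_name: str = "",
) -> RegressionResult:
    """OLS of phenotype on one burden variable plus cohort indicators.

    Both outcome and predictor are scaled to unit SD so the reported
    coefficient is a standardized beta; the two-sided p-value comes from
    the coefficient's t distribution. A zero-variance burden variable
    (nobody carries a CNV) yields a flagged, undefined result.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(burden_variable, dtype=float)
    if y.shape != x.shape:
        raise ValueError("phenotype and burden vectors must align")
    n = len(y)
    meta = dict(predictor=predictor, dosage_class=dosage_class, phenotype=phenotype_name)
    if x.std(ddof=1) == 0:
        return RegressionResult(
            standardized_beta=float("nan"), p_value=float("nan"), n=n, defined=False, **meta
        )
    X = np.column_stack([_zscore(x), _cohort_design(cohorts, n)])
    fit = sm.OLS(_zscore(y), X).fit()
    return RegressionResult(
        standardized_beta=float(fit.params[0]),
        p_value=float(fit.pvalues[0]),
        n=n,
        std_error=float(fit.bse[0]),
        **meta,
    )


def _fwl_residual(x_z: np.ndarray, cohorts: np.ndarray | None) -> np.ndarray:
    """Residual of the standardized predictor on the cohort design."""
    C = _cohort_design(cohorts, len(x_z))
    coef, *_ = np.linalg.lstsq(C, x_z, rcond=None)
    return x_z - C @ coef


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permutation_p_regression(
    phenotype: np.ndarray,
    burden_variable: np.ndarray,
    cohorts: np.ndarray | None = None,
    n_permutations: int = 100_000,
    seed=0,
    within_cohort: bool = False,
    smoothed: bool = False,
) -> float:
    """Permutation empirical p for a burden regression.

    The phenotype vector is permuted uniformly across individuals (the
    burden variable and cohort covariates stay with the individuals) and
    the model refit each permutation; the empirical p is the proportion
    of permutations with |beta_perm| >= |beta_obs|. With ``smoothed`` the
    add-one rule (k+1)/(B+1) is used instead, which cannot return 0.
    By Frisch-Waugh-Lovell the refit reduces to a dot product with the
    cohort-residualized predictor, which is what makes 100,000 refits
    cheap.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = _zscore(np.asarray(phenotype, dtype=float))
    x = _zscore(np.asarray(burden_variable, dtype=float))
    n = len(y)
    x_res = _fwl_residual(x, cohorts)
    denom = x_res @ x_res
    beta_obs = abs(x_res @ y / denom)
    rng = _as_rng(seed)
    cohort_idx = None
    if within_cohort and cohorts is not None:
        cohorts = np.asarray(cohorts)
        cohort_idx = [np.flatnonzero(cohorts == lev) for lev in pd.unique(cohorts)]
    exceed = 0
    done = 0
    while done < n_permutations:
        m = min(_PERM_CHUNK, n_permutations - done)
        Y = np.tile(y, (m, 1))
        if cohort_idx is None:
            Y = rng.permuted(Y, axis=1)
        else:
            for idx in cohort_idx:
                Y[:, idx] = rng.permuted(Y[:, idx], axis=1)
        betas = Y @ x_res / denom
        exceed += int((np.abs(betas) >= beta_obs).sum())
        done += m
    if smoothed:
        return (exceed + 1) / (n_permutations + 1)
    return exceed / n_permutations


def region_carrier_mask(
    region: RegionDef, rare_cnvs: pd.DataFrame, sample_ids: np.ndarray
) -> np.ndarray:
    """Boolean mask over sample_ids: >= 1 rare CNV overlapping the region.

    Any positive coordinate overlap counts, for either dosage class.
    """
    hits = rare_cnvs[
        (rare_cnvs["chromosome"].astype(str) == str(region.chromosome))
        & (rare_cnvs["start_bp"] <= region.end_bp)
        & (rare_cnvs["end_bp"] >= region.start_bp)
    ]
    carriers = set(hits["sample_id"])
    return np.asarray([s in carriers for s in sample_ids], dtype=bool)


def _ttest_from_mask(
    y: np.ndarray, mask: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    """Two-sample two-sided t statistic and p for mask vs rest."""
    res = scipy.stats.ttest_ind(y[mask], y[~mask], equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def carrier_ttest(
    region: RegionDef,
    rare_cnvs: pd.DataFrame,
    phenotype: pd.DataFrame,
    value_col: str = "gf_residual",
    min_carriers: int = 3,
    equal_var: bool = True,
) -> RegionTestResult:
    """t-test of carrier vs non-carrier phenotype means for one region.

    A region is testable only when more than two individuals carry a rare
    CNV overlapping it (``min_carriers`` = 3); otherwise tested is False
    and no statistic is computed. The default pools variances: carrier
    groups this small leave a Welch statistic with ~2 effective degrees
    of freedom and an essentially powerless permutation null, whereas the
    pooled statistic borrows the (large) non-carrier group's variance;
    ``equal_var=False`` gives the Welch variant. Degenerate variance (all
    phenotype values equal) yields NaN statistics, flagged not-computable.
    """
    sample_ids = phenotype["sample_id"].to_numpy()
    y = phenotype[value_col].to_numpy(dtype=float)
    mask = region_carrier_mask(region, rare_cnvs, sample_ids)
    k = int(mask.sum())
    if k < min_carriers or k > len(y) - 2:
        return RegionTestResult(region_id=region.region_id, n_carriers=k, tested=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = _ttest_from_mask(y, mask, equal_var)
    return RegionTestResult(
        region_id=region.region_id, n_carriers=k, tested=True, t_statistic=t, p_value=p
    )


def _t_matrix(
    Y: np.ndarray,
    carrier_cols: np.ndarray,
    total_sum: float,
    total_ss: float,
    equal_var: bool,
) -> np.ndarray:
    """Two-sample t for each permuted row of Y against its complement.

    Y is (chunk, n); carrier_cols indexes the carrier slots. The
    complement's mean and variance are recovered from the permutation-
    invariant total sum and sum of squares.
    """
    n = Y.shape[1]
    cv = Y[:, carrier_cols]
    k = cv.shape[1]
    m = n - k
    s1 = cv.sum(axis=1)
    ss1 = (cv * cv).sum(axis=1)
    mean1 = s1 / k
    mean2 = (total_sum - s1) / m
    css1 = ss1 - k * mean1**2
    css2 = total_ss - ss1 - m * mean2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = (css1 + css2) / (n - 2)
            return (mean1 - mean2) / np.sqrt(sp2 * (1.0 / k + 1.0 / m))
        var1 = css1 / (k - 1)
        var2 = css2 / (m - 1)
        return (mean1 - mean2) / np.sqrt(var1 / k + var2 / m)


def maxT_correction(
    regions: list[RegionDef],
    rare_cnvs: pd.DataFrame,
    phenotype: pd.DataFrame,
    value_col: str = "gf_residual",
    n_permutations: int = 100_000,
    seed=0,
    signed: bool = False,
    min_carriers: int = 3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Max-statistic permutation correction over a candidate-region panel.

    Carrier sets (hence testability) are fixed from the observed data. At
    each permutation the phenotype vector is shuffled across individuals,
    every testable region's t statistic recomputed, and the maximum
    retained; a region's empirical p is the proportion of permutations
    where that maximum strictly exceeds its observed statistic. By default
    statistics are compared in absolute value; ``signed`` compares raw t.

    Returns a table with one row per region (region_id, n_carriers,
    t_statistic, p_value, empirical_p, tested). Untestable regions carry
    NaN statistics. An empty result with a warning is returned when no
    region is testable.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sample_ids = phenotype["sample_id"].to_numpy()
    y = phenotype[value_col].to_numpy(dtype=float)
    n = len(y)

    observed = [
        carrier_ttest(r, rare_cnvs, phenotype, value_col, min_carriers, equal_var)
        for r in regions
    ]
    testable = [
        (i, region_carrier_mask(regions[i], rare_cnvs, sample_ids))
        for i, res in enumerate(observed)
        if res.tested and np.isfinite(res.t_statistic)
    ]
    rows = [
        {
            "region_id": res.region_id,
            "n_carriers": res.n_carriers,
            "tested": res.tested,
            "t_statistic": res.t_statistic,
            "p_value": res.p_value,
            "empirical_p": np.nan,
        }
        for res in observed
    ]
    out = pd.DataFrame(rows)
    if not testable:
        import warnings

        warnings.warn("no testable regions (all have fewer than 3 carriers)")
        return out

    carrier_cols = [np.flatnonzero(mask) for _, mask in testable]
    stat = (lambda t: t) if signed else np.abs
    t_obs = np.array([stat(observed[i].t_statistic) for i, _ in testable])
    total_sum = float(y.sum())
    total_ss = float((y * y).sum())

    rng = _as_rng(seed)
    exceed = np.zeros(len(testable), dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(_PERM_CHUNK, n_permutations - done)
        Y = rng.permuted(np.tile(y, (m, 1)), axis=1)
        ts = np.column_stack(
            [_t_matrix(Y, cols, total_sum, total_ss, equal_var) for cols in carrier_cols]
        )
        max_t = np.nanmax(stat(ts), axis=1)
        exceed += (max_t[:, None] > t_obs[None, :]).sum(axis=0)
        done += m
    for j, (i, _) in enumerate(testable):
        out.loc[i, "empirical_p"] = exceed[j] / n_permutations
    return out


PREDICTORS = ("count", "length", "genes")
CLASS_SHORT = {"all": "all", "deletion": "del", "duplication": "dup"}


def regression_grid(
    burden_records: pd.DataFrame,
    derived_phenotypes: pd.DataFrame,
    n_permutations: int = 1_000,
    seed: int = 0,
    within_cohort: bool = False,
) -> pd.DataFrame:
    """All burden regressions: phenotype x predictor x dosage class.

    Fits 18 models (g_f and g_c; count/length/genes; all/deletions/
    duplications), each with cohort as covariate and a permutation
    empirical p from an independent substream of the base seed. Returns a
    tidy table, one row per model.
    """
    merged = burden_records.merge(
        derived_phenotypes[["sample_id", "gf_residual", "gc_residual"]],
        on="sample_id",
        how="inner",
    )
    cohorts = merged["cohort"].to_numpy()
    rows = []
    model_index = 0
    for pheno_name, col in (("g_f", "gf_residual"), ("g_c", "gc_residual")):
        y = merged[col].to_numpy(dtype=float)
        for predictor in PREDICTORS:
            for cls, short in CLASS_SHORT.items():
                x = merged[f"{predictor}_{short}"].to_numpy(dtype=float)
                res = burden_regression(
                    y, x, cohorts, predictor=predictor, dosage_class=cls, phenotype_name=pheno_name
                )
                if res.defined:
                    sub_seed = np.random.SeedSequence(entropy=seed, spawn_key=(model_index,))
                    res.empirical_p = permutation_p_regression(
                        y,
                        x,
                        cohorts,
                        n_permutations=n_permutations,
                        seed=np.random.default_rng(sub_seed),
                        within_cohort=within_cohort,
                    )
                    res.n_permutations = n_permutations
                    res.seed = seed
                rows.append(
                    {
                        "phenotype": pheno_name,
                        "predictor": predictor,
                        "dosage_class": cls,
                        "standardized_beta": res.standardized_beta,
                        "p_value": res.p_value,
                        "empirical_p": res.empirical_p if res.defined else np.nan,
                        "n": res.n,
                        "defined": res.defined,
                    }
                )
                model_index += 1
    return pd.DataFrame(rows)
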