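"""Derivation of fluid and crystallized cognitive phenotypes.

Fluid-type general intelligence (g_f) is the first unrotated principal
component of a battery of fluid-type subtest scores, extracted per cohort
from the subtest correlation matrix. Crystallized intelligence (g_c) is a
single vocabulary-type test score. Both are corrected for age (and sex,
unless derived separately by sex) by ordinary least squares, and the
standardized residuals (mean 0, SD 1 within the derivation group) are the
phenotypes used in all association analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    """First-principal-component extraction over a subtest battery.

    loadings: component loadings (correlation of each subtest with PC1);
    scores: per-sample PC1 scores (standardized subtests projected on the
    leading eigenvector); eigenvalues: all eigenvalues of the correlation
    matrix, nonincreasing; variance_explained: lambda_1 / p; single_component:
    whether only the first eigenvalue exceeds one.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: float
    single_component: bool


def derive_gf_pca(score_matrix: np.ndarray | pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix of subtest scores; returns PC1.

    Requires >= 2 subtests and >= 3 complete cases (rows with any missing
    value are excluded before the eigen-decomposition; their scores are
    NaN). The component sign is fixed so that the majority of loadings are
    positive (higher scores = better ability).
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D score matrix with at least 2 subtests")
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if Xc.shape[0] < 3:
        raise ValueError("need at least 3 complete cases")
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant subtest column (zero variance)")
    Z = (Xc - Xc.mean(axis=0)) / sd
    corr = np.corrcoef(Xc, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    v1 = eigvecs[:, 0]
    if np.sum(v1 > 0) < np.sum(v1 < 0):
        v1 = -v1
    loadings = v1 * np.sqrt(max(eigvals[0], 0.0))
    scores = np.full(X.shape[0], np.nan)
    scores[complete] = Z @ v1
    return PcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigvals,
        variance_explained=float(eigvals[0] / eigvals.sum()),
        single_component=bool(eigvals[0] > 1.0 and (eigvals[1:] <= 1.0).all()),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance residuals cannot be standardized")
    return (x - x.mean()) / sd


def residualize(
    values: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray | None = None,
    stratify_by_sex: bool = False,
) -> np.ndarray:
    """OLS-residualize a phenotype on age (and sex), then standardize.

    When ``stratify_by_sex`` the model (intercept + age) is fitted and the
    residuals standardized within each sex separately, then re-assembled in
    the original order; otherwise one model with intercept, age and a sex
    indicator (when ``sex`` is given) is used. Residuals are standardized
    to mean 0, SD 1 within each derivation group.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.isnan(y).any() or np.isnan(age).any():
        raise ValueError("missing values among phenotype or covariates")
    if stratify_by_sex:
        if sex is None:
            raise ValueError("stratify_by_sex requires sex")
        sex = np.asarray(sex)
        out = np.empty_like(y)
        for s in np.unique(sex):
            m = sex == s
            out[m] = residualize(y[m], age[m], sex=None, stratify_by_sex=False)
        return out
    cols = [np.ones_like(y), age]
    if sex is not None:
        sex = np.asarray(sex)
        codes = (sex == np.unique(sex)[-1]).astype(float)
        cols.append(codes)
    X = np.column_stack(cols)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations to residualize")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    # covariates explaining (numerically) all variance leave nothing to analyse
    if resid.std(ddof=0) <= 1e-8 * max(y.std(ddof=0), 1e-30):
        raise ValueError("zero-variance residuals cannot be standardized")
    return _standardize(resid)


def derive_phenotypes(
    phenotype_table: pd.DataFrame,
    sex_stratified_cohorts: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive g_f and g_c standardized residuals per cohort.

    ``phenotype_table`` needs columns sample_id, cohort, age, sex, one or
    more ``subtest_*`` columns (the fluid battery) and ``vocabulary`` (the
    crystallized test). g_f is PC1 of the subtests; g_c the vocabulary
    score; both are age-corrected (and sex-corrected, except in cohorts
    listed in ``sex_stratified_cohorts``, where derivation is within sex).

    Returns (derived table with gf_residual / gc_residual, per-cohort PCA
    report with eigenvalues, loadings and variance explained).
    """
    subtest_cols = sorted(c for c in phenotype_table.columns if c.startswith("subtest_"))
    if not subtest_cols:
        raise ValueError("no subtest_* columns in phenotype table")
    if "vocabulary" not in phenotype_table.columns:
        raise ValueError("no vocabulary column in phenotype table")

    out_rows = []
    report_rows = []
    for cohort, grp in phenotype_table.groupby("cohort", sort=False):
        # complete-case within battery: drop rows missing any subtest,
        # the vocabulary score or a covariate
        needed = subtest_cols + ["vocabulary", "age"]
        grp = grp[grp[needed].notna().all(axis=1)].reset_index(drop=True)
        stratified = cohort in sex_stratified_cohorts
        pca = derive_gf_pca(grp[subtest_cols].to_numpy(dtype=float))
        gf = residualize(
            pca.scores,
            grp["age"].to_numpy(),
            sex=grp["sex"].to_numpy(),
            stratify_by_sex=stratified,
        )
        gc = residualize(
            grp["vocabulary"].to_numpy(dtype=float),
            grp["age"].to_numpy(),
            sex=grp["sex"].to_numpy(),
            stratify_by_sex=stratified,
        )
        out = grp[["sample_id", "cohort"]].copy()
        out["gf_residual"] = gf
        out["gc_residual"] = gc
        out_rows.append(out)
        report_rows.append(
            {
                "cohort": cohort,
                "n_subtests": len(subtest_cols),
                "variance_explained": pca.variance_explained,
                "single_component": pca.single_component,
                "eigenvalues": ";".join(f"{v:.4f}" for v in pca.eigenvalues),
                "loadings": ";".join(f"{v:.4f}" for v in pca.loadings),
                "sex_stratified": stratified,
            }
        )
    derived = pd.concat(out_rows, ignore_index=True)
    report = pd.DataFrame(report_rows)
    return derived, report
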