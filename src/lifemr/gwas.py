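"""Per-SNP association scans producing GWAS-style summary statistics.

Each SNP is tested by ordinary least squares of the trait on its allele count
plus any covariates. Binary traits are analysed on the linear (risk-difference)
scale so that summary-data MR estimates and the individual-level structural
mean model estimates share units. Computation uses Frisch-Waugh
residualization: trait and genotypes are residualized on the covariates (plus
intercept) once, then each SNP reduces to a simple regression. The estimates,
classical standard errors, and t-test p-values are identical to a per-SNP
joint OLS fit with n - C - 2 residual degrees of freedom.

Monomorphic SNPs cannot be tested; they are emitted with a ``monomorphic``
flag and must be excluded from instrument candidacy downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = ["assoc_scan", "SUMMARY_COLUMNS"]

#: canonical column order of the summary-statistics TSV dialect
SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "n"]


def _trait_vector(cohort: Cohort, trait: str) -> np.ndarray:
    if trait in ("x1", "x2", "y"):
        return np.asarray(getattr(cohort, trait), dtype=float)
    if trait in ("x1_tier", "x2_tier"):
        return cohort.tier_codes(trait[:2])
    raise KeyError(f"unknown trait selector: {trait!r}")


def assoc_scan(
    cohort: Cohort,
    trait: str,
    covariates: bool | list[str] = True,
) -> pd.DataFrame:
    """Scan every SNP for association with a trait.

    Parameters
    ----------
    cohort : Cohort
        Individual-level data (complete cases).
    trait : str
        One of ``x1``, ``x2``, ``y``, ``x1_tier``, ``x2_tier``. Tier traits
        are coded ordinally 1-3.
    covariates : bool or list of str
        ``True`` adjusts for all cohort covariates, ``False`` for none, or a
        list of covariate names selects a subset.

    Returns
    -------
    DataFrame in the summary-statistics dialect with one row per SNP and an
    extra boolean ``monomorphic`` column; monomorphic SNPs carry NaN
    beta/se/pval.
    """
    yv = _trait_vector(cohort, trait)
    n = yv.shape[0]
    if covariates is True:
        cov = cohort.covariates
    elif covariates is False:
        cov = np.empty((n, 0))
    else:
        idx = [cohort.covariate_names.index(c) for c in covariates]
        cov = cohort.covariates[:, idx]
    C = cov.shape[1]
    if n <= C + 2:
        raise ValueError("need n > C + 2 observations for the per-SNP fit")

    design = np.column_stack([np.ones(n), cov])
    # residualize trait and genotypes on [1, covariates] (Frisch-Waugh)
    coef_y, *_ = np.linalg.lstsq(design, yv, rcond=None)
    ry = yv - design @ coef_y
    g = cohort.genotypes.astype(float)
    coef_g, *_ = np.linalg.lstsq(design, g, rcond=None)
    rg = g - design @ coef_g

    gss = np.einsum("ij,ij->j", rg, rg)
    mono = np.ptp(cohort.genotypes, axis=0) == 0
    dof = n - C - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (rg.T @ ry) / gss
        rss = ry @ ry - beta**2 * gss
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / gss)
        tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), dof)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan
    return pd.DataFrame(
        {
            "snp": cohort.snp_ids,
            "effect_allele": cohort.effect_alleles,
            "other_allele": cohort.other_alleles,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
            "monomorphic": mono,
        }
    )
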