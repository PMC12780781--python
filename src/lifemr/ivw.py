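"""Inverse-variance-weighted MR from summary statistics.

The univariable IVW estimator regresses SNP-outcome associations on
SNP-exposure associations through the origin, weighting each SNP by the
inverse variance of its SNP-outcome estimate. The multivariable variant
(IVW-MVMR) is the analogous weighted least-squares fit on a matrix of
exposure-association columns and targets controlled period effects of
liability to each exposure. Between-SNP heterogeneity is summarized by
Cochran's Q, and standard errors carry a multiplicative random-effects
scale max(1, sqrt(Q / df)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smm import Z975

__all__ = ["IvwEstimate", "harmonize", "ivw_univariable", "ivw_mvmr"]


@dataclass
class IvwEstimate:
    """IVW regression result with heterogeneity diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    heterogeneity_Q: float
    df: int
    re_scale: float
    method: str  # ivw-univariable | ivw-mvmr
    n_snps: int = 0

    def __post_init__(self) -> None:
        for name in ("beta", "se", "ci_low", "ci_high"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if self.heterogeneity_Q < 0:
            raise ValueError("Q must be non-negative")
        if self.re_scale < 1:
            raise ValueError("random-effects scale has a floor of 1")


def harmonize(
    exposure_stats: pd.DataFrame | list[pd.DataFrame],
    outcome_stats: pd.DataFrame,
) -> pd.DataFrame:
    """Align one or more exposure scans with an outcome scan on SNP/alleles.

    Inner-joins on ``snp``; where a trait's effect/other alleles are swapped
    relative to the first exposure's orientation its beta sign is flipped;
    SNPs whose allele pairs do not match are dropped (count retrievable from
    the ``n_dropped`` attribute of the returned frame's ``attrs``).

    Returns a frame with columns ``snp``, ``bx_1`` .. ``bx_K``, ``se_x_1``
    .. , ``by``, ``se_y``.
    """
    if isinstance(exposure_stats, pd.DataFrame):
        exposure_stats = [exposure_stats]
    ref = exposure_stats[0]
    out = ref[["snp", "effect_allele", "other_allele"]].copy()
    out["bx_1"] = ref["beta"].to_numpy()
    out["se_x_1"] = ref["se"].to_numpy()
    dropped = 0
    for k, stats in enumerate(exposure_stats[1:], start=2):
        out, d = _merge_oriented(out, stats, f"bx_{k}", f"se_x_{k}")
        dropped += d
    out, d = _merge_oriented(out, outcome_stats, "by", "se_y")
    dropped += d
    if len(out) == 0:
        raise ValueError("no SNPs shared between exposure and outcome statistics")
    out = out.reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def _merge_oriented(
    base: pd.DataFrame, stats: pd.DataFrame, beta_col: str, se_col: str
) -> tuple[pd.DataFrame, int]:
    m = base.merge(
        stats[["snp", "effect_allele", "other_allele", "beta", "se"]],
        on="snp",
        suffixes=("", "_new"),
    )
    same = (m["effect_allele"] == m["effect_allele_new"]) & (
        m["other_allele"] == m["other_allele_new"]
    )
    swapped = (m["effect_allele"] == m["other_allele_new"]) & (
        m["other_allele"] == m["effect_allele_new"]
    )
    sign = np.where(same, 1.0, np.where(swapped, -1.0, np.nan))
    m[beta_col] = sign * m["beta"].to_numpy()
    m[se_col] = m["se"].to_numpy()
    keep = same | swapped
    n_dropped = int((~keep).sum())
    m = m[keep].drop(columns=["effect_allele_new", "other_allele_new", "beta", "se"])
    return m, n_dropped


def ivw_univariable(
    bx: np.ndarray, by: np.ndarray, se_y: np.ndarray
) -> IvwEstimate:
    """Zero-intercept weighted regression of by on bx with weights 1/se_y^2."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    j = bx.shape[0]
    if j < 2:
        raise ValueError("IVW requires at least 2 SNPs")
    if np.allclose(bx, 0):
        raise ValueError("no instrument relevance: all SNP-exposure betas are zero")
    w = 1.0 / se_y**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = j - 1
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    se = float(np.sqrt(1.0 / np.sum(w * bx**2))) * scale
    return IvwEstimate(
        beta=np.array([beta]),
        se=np.array([se]),
        ci_low=np.array([beta - Z975 * se]),
        ci_high=np.array([beta + Z975 * se]),
        heterogeneity_Q=q,
        df=df,
        re_scale=scale,
        method="ivw-univariable",
        n_snps=j,
    )


def ivw_mvmr(
    bx_matrix: np.ndarray, by: np.ndarray, se_y: np.ndarray
) -> IvwEstimate:
    """Multivariable IVW: WLS of by on the exposure-beta columns, no intercept."""
    bx = np.atleast_2d(np.asarray(bx_matrix, float).T).T
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    j, k = bx.shape
    if j <= k:
        raise ValueError("need more SNPs than exposures")
    if np.linalg.matrix_rank(bx) < k:
        raise ValueError("exposure betas collinear")
    w = 1.0 / se_y**2
    xtw = bx.T * w
    beta = np.linalg.solve(xtw @ bx, xtw @ by)
    resid = by - bx @ beta
    q = float(np.sum(w * resid**2))
    df = j - k
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    se = np.sqrt(np.diag(np.linalg.inv(xtw @ bx))) * scale
    return IvwEstimate(
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        heterogeneity_Q=q,
        df=df,
        re_scale=scale,
        method="ivw-mvmr",
        n_snps=j,
    )
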