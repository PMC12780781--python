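"""G-estimation of additive structural mean models on the risk-difference scale.

The additive SMM assumes the effect of shifting the exposure vector X by one
unit is a constant risk difference psi, and identifies psi through the moment
condition that the (centred) instrument is uncorrelated with the treatment-free
residual:

    E[(Z - E[Z]) (Y - X' psi)] = 0.

With a single instrument and exposure this solves in closed form to the Wald
ratio cov(Z, Y)/cov(Z, X). With K exposures and M = K instruments (one
polygenic score per exposure period) it is the solution of a K x K linear
system in sample cross-covariances; with M > K instruments the system is
over-identified and solved by two-stage projection, numerically identical to
two-stage least squares.

The same numeric estimate is interpreted as a point, period, or lifetime
effect depending only on what one assumes about when the instruments act on
the exposure; the :class:`EstimandRegime` records that interpretation as
metadata, never as a different formula.

Inference is by the estimating-equation sandwich (default) or a nonparametric
case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EstimandRegime",
    "SmmEstimate",
    "REGIME_REGISTRY",
    "smm_univariable",
    "smm_multivariable",
    "sandwich_se",
    "bootstrap_se",
]

Z975 = 1.959964  # normal 97.5% quantile for 95% CIs

#: fixed registry of estimand interpretations and the instrument assumptions
#: under which each holds; the label is metadata attached to an estimate, and
#: switching label never changes the numbers.
REGIME_REGISTRY: dict[str, str] = {
    "point": (
        "The instruments affect the exposure only at the single time point "
        "considered; the estimate is the effect of a one-unit increase in the "
        "exposure at that point."
    ),
    "period": (
        "The instruments exert a constant effect on the exposure throughout "
        "the stated period and none outside it; the estimate is the effect of "
        "a sustained one-unit increase over that period."
    ),
    "lifetime": (
        "The instruments influence the exposure uniformly from conception to "
        "outcome measurement; the estimate is the effect of a one-unit "
        "increase sustained over the whole lifecourse."
    ),
    "controlled-period": (
        "The instruments have distinct effects on the exposure in each "
        "modelled period; the estimate for one period is the effect of a "
        "one-unit increase in that period holding exposure in the other "
        "modelled periods fixed."
    ),
}


@dataclass(frozen=True)
class EstimandRegime:
    """Which lifecourse causal parameter an estimate is read as, and why."""

    label: str
    assumption_text: str = ""

    def __post_init__(self) -> None:
        if self.label not in REGIME_REGISTRY:
            raise ValueError(f"unknown estimand regime {self.label!r}")
        object.__setattr__(self, "assumption_text", REGIME_REGISTRY[self.label])


@dataclass
class SmmEstimate:
    """G-estimation result on the risk-difference scale."""

    psi: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    method: str  # smm-univariable | smm-multivariable
    se_method: str  # sandwich | bootstrap
    estimand_regime: EstimandRegime
    n_used: int
    first_stage_F: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        for name in ("psi", "se", "ci_low", "ci_high", "first_stage_F"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.se < 0):
            raise ValueError("standard errors must be non-negative")
        if np.any(self.ci_low > self.psi) or np.any(self.ci_high < self.psi):
            raise ValueError("confidence interval must bracket the estimate")


# relative tolerance factor for the instrument-relevance denominator
_RELEVANCE_RTOL = 1e-12
_COND_CEILING = 1e10


def _residualize(arrays: list[np.ndarray], covariates: np.ndarray) -> list[np.ndarray]:
    n = arrays[0].shape[0]
    design = np.column_stack([np.ones(n), covariates])
    out = []
    for a in arrays:
        a2 = a if a.ndim == 2 else a[:, None]
        coef, *_ = np.linalg.lstsq(design, a2, rcond=None)
        r = a2 - design @ coef
        out.append(r if a.ndim == 2 else r[:, 0])
    return out


def first_stage_f(z: np.ndarray, x: np.ndarray) -> float:
    """F-statistic of the regression of x on z (with intercept)."""
    z = np.atleast_2d(np.asarray(z, float).T).T
    n, m = z.shape
    design = np.column_stack([np.ones(n), z])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    fitted = design @ coef
    rss = np.sum((x - fitted) ** 2)
    tss = np.sum((x - x.mean()) ** 2)
    ess = tss - rss
    if rss <= 1e-12 * max(tss, 1.0):
        return np.inf
    return (ess / m) / (rss / (n - m - 1))


def smm_univariable(
    z: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    se_method: str = "sandwich",
    regime: str = "period",
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> SmmEstimate:
    """Single-instrument g-estimate: psi = sum (z-zbar) y / sum (z-zbar) x.

    Identical to the Wald ratio cov(z,y)/cov(z,x). ``y`` is typically binary
    but any real outcome is accepted. Raises if the instrument carries no
    information about the exposure (denominator below tolerance).
    """
    z = np.asarray(z, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (z.shape == x.shape == y.shape):
        raise ValueError("z, x, y must have equal length")
    if covariates is not None and covariates.size:
        z, x, y = _residualize([z, x, y], covariates)
    n = z.shape[0]
    zc = z - z.mean()
    denom = zc @ x
    tol = _RELEVANCE_RTOL * n * max(z.std(), 1e-300) * max(x.std(), 1e-300)
    if abs(denom) <= tol:
        raise ValueError("no instrument relevance: cov(z, x) is numerically zero")
    psi = float(zc @ y / denom)
    est = SmmEstimate(
        psi=np.array([psi]),
        se=np.zeros(1),
        ci_low=np.array([psi]),
        ci_high=np.array([psi]),
        method="smm-univariable",
        se_method=se_method,
        estimand_regime=EstimandRegime(regime),
        n_used=n,
        first_stage_F=np.array([first_stage_f(z, x)]),
    )
    return _attach_se(est, z[:, None], x[:, None], y, n_boot=n_boot, seed=seed)


def smm_multivariable(
    z_matrix: np.ndarray,
    x_matrix: np.ndarray,
    y: np.ndarray,
    se_method: str = "sandwich",
    regime: str = "controlled-period",
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> SmmEstimate:
    """Multi-exposure g-estimate solving E[(Z - E Z)(Y - X' psi)] = 0.

    Just-identified (M = K instruments): psi = S_ZX^{-1} s_ZY in sample
    cross-covariances. Over-identified (M > K): each exposure is projected on
    all instruments first and the just-identified system is solved with the
    fitted values (two-stage least squares). Conditional instrument-strength
    F-statistics are reported per exposure: the F of the regression of that
    exposure on the instruments after partialling out the other exposures'
    instrument-predicted components.
    """
    z = np.asarray(z_matrix, float)
    x = np.asarray(x_matrix, float)
    y = np.asarray(y, float)
    if z.ndim == 1:
        z = z[:, None]
    if x.ndim == 1:
        x = x[:, None]
    n, m = z.shape
    k = x.shape[1]
    if x.shape[0] != n or y.shape[0] != n:
        raise ValueError("z_matrix, x_matrix, y must have equal row counts")
    if m < k:
        raise ValueError("need at least as many instruments as exposures")
    if covariates is not None and covariates.size:
        z, x, y = _residualize([z, x, y], covariates)

    zc = z - z.mean(axis=0)
    if m == k:
        z_eff = z
    else:
        # project exposures on all instruments; fitted values are the
        # effective just-identified instruments (2SLS weighting)
        design = np.column_stack([np.ones(n), z])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        z_eff = design @ coef
    zec = z_eff - z_eff.mean(axis=0)
    s_zx = zec.T @ x / n
    if np.linalg.cond(s_zx) > _COND_CEILING:
        raise ValueError("instruments do not separate exposures (S_ZX ill-conditioned)")
    s_zy = zec.T @ y / n
    psi = np.linalg.solve(s_zx, s_zy)

    cond_f = np.array([_conditional_f(zc, x, j) for j in range(k)])
    est = SmmEstimate(
        psi=psi,
        se=np.zeros(k),
        ci_low=psi.copy(),
        ci_high=psi.copy(),
        method="smm-multivariable",
        se_method=se_method,
        estimand_regime=EstimandRegime(regime),
        n_used=n,
        first_stage_F=cond_f,
    )
    return _attach_se(est, z_eff, x, y, n_boot=n_boot, seed=seed)


def _conditional_f(zc: np.ndarray, x: np.ndarray, j: int) -> float:
    """Instrument strength for exposure j conditional on the other exposures.

    Residualizes x_j on the instrument-predicted components of the other
    exposures, then computes the F of the residual on the instruments,
    rescaled by the Sanderson-Windmeijer degrees-of-freedom convention
    (m - k + 1 numerator terms).
    """
    n, m = zc.shape
    k = x.shape[1]
    xj = x[:, j]
    others = np.delete(x, j, axis=1)
    if others.shape[1]:
        fitted_others, *_ = np.linalg.lstsq(zc, others, rcond=None)
        pred = zc @ fitted_others
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), pred]), xj, rcond=None
        )
        resid = xj - np.column_stack([np.ones(n), pred]) @ coef
    else:
        resid = xj - xj.mean()
    coef_z, *_ = np.linalg.lstsq(zc, resid, rcond=None)
    fitted = zc @ coef_z
    rss = np.sum((resid - fitted) ** 2)
    ess = np.sum(fitted**2)
    df_num = max(m - k + 1, 1)
    df_den = n - m - 1
    if rss == 0:
        return np.inf
    return (ess / df_num) / (rss / df_den)


def sandwich_se(
    z_matrix: np.ndarray,
    x_matrix: np.ndarray,
    y: np.ndarray,
    psi_hat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimating-equation sandwich SEs and 95% normal CIs for a g-estimate.

    With e_i = y_i - X_i' psi and g_i = (Z_i - Zbar)(e_i - ebar):
    A = mean over i of (Z_i - Zbar) X_i', B = mean of g_i g_i',
    Var(psi_hat) = A^{-1} B A^{-T} / n.

    The residuals entering B are centred because the moment condition is a
    covariance (the instrument mean is estimated); omitting the centring
    inflates B by (mean residual)^2 Var(Z) and over-covers.

    For over-identified fits pass the effective (projected) instruments so
    that A is square. Returns (se, ci_low, ci_high).
    """
    z = np.atleast_2d(np.asarray(z_matrix, float).T).T
    x = np.atleast_2d(np.asarray(x_matrix, float).T).T
    y = np.asarray(y, float)
    psi_hat = np.atleast_1d(np.asarray(psi_hat, float))
    n = z.shape[0]
    zc = z - z.mean(axis=0)
    a = zc.T @ x / n
    if a.shape[0] != a.shape[1]:
        raise ValueError("A must be square; pass effective instruments (M = K)")
    resid = y - x @ psi_hat
    resid = resid - resid.mean()
    g = zc * resid[:, None]
    b = g.T @ g / n
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise ValueError("singular bread matrix in sandwich variance") from exc
    cov = a_inv @ b @ a_inv.T / n
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return se, psi_hat - Z975 * se, psi_hat + Z975 * se


def bootstrap_se(
    estimator,
    data: tuple[np.ndarray, ...],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Case-resampling bootstrap SE and percentile 95% CI.

    ``estimator`` maps resampled ``data`` arrays (first axis = individuals)
    to a parameter vector. Replicates that raise (e.g. resampled-constant
    instruments) are dropped; more than 10% failures aborts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = data[0].shape[0]
    reps = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps.append(np.atleast_1d(estimator(*(d[idx] for d in data))))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > 0.1 * n_boot:
                raise ValueError(
                    f"bootstrap unstable: >{0.1:.0%} of replicates failed"
                )
    reps = np.asarray(reps)
    se = reps.std(axis=0, ddof=1)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    return se, lo, hi


def _attach_se(
    est: SmmEstimate,
    z_eff: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    seed: int,
) -> SmmEstimate:
    if est.se_method == "sandwich":
        se, lo, hi = sandwich_se(z_eff, x, y, est.psi)
    elif est.se_method == "bootstrap":

        def point(zb, xb, yb):
            zbc = zb - zb.mean(axis=0)
            return np.linalg.solve(zbc.T @ xb, zbc.T @ yb)

        se, lo, hi = bootstrap_se(point, (z_eff, x, y), n_boot=n_boot, seed=seed)
        lo = np.minimum(lo, est.psi)
        hi = np.maximum(hi, est.psi)
    else:
        raise ValueError("se_method must be 'sandwich' or 'bootstrap'")
    return replace(est, se=se, ci_low=lo, ci_high=hi)
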