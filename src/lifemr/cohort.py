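"""Synthetic one-sample cohorts with period-specific genetic effects.

The generating model has two exposure periods. Independent biallelic SNPs
(Hardy-Weinberg, no LD) carry per-allele effects ``alpha1`` on the early
exposure X1 and direct effects ``alpha2`` on the late exposure X2; the early
exposure tracks into the late one with coefficient ``theta``. A single latent
standard-normal confounder U loads on both exposures and on the outcome. The
binary outcome is drawn from a linear-probability (risk-difference) model, so
the causal period effects ``psi1`` and ``psi2`` are risk differences per unit
of exposure. Both exposures are additionally recoded into an ordinal 3-tier
variable (thinner / average / plumper) by empirical proportions, mimicking
recall-questionnaire adiposity measures.

All randomness is driven by the seed stored in :class:`SimulationTruth`;
identical truth objects yield bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationTruth",
    "Cohort",
    "TIER_LABELS",
    "generate_genotypes",
    "generate_cohort",
    "categorize_three_tier",
    "filter_complete_cases",
    "default_truth",
]

TIER_LABELS = ("thinner", "average", "plumper")

#: floor for clamping linear-model risks into (0, 1)
RISK_EPS = 1e-6
#: default ceiling on the clamped fraction before warning/erroring
CLAMP_CEILING = 0.01


class ClampError(RuntimeError):
    """Raised in strict mode when too many linear risks fall outside (0, 1)."""


@dataclass(frozen=True)
class SimulationTruth:
    """Complete data-generating parameters for one synthetic cohort.

    Attributes
    ----------
    n_individuals : int
        Cohort size.
    maf : ndarray, shape (J,)
        Effect-allele frequencies, each in (0, 1).
    alpha1, alpha2 : ndarray, shape (J,)
        Per-allele effects on the early exposure X1 and direct per-allele
        effects on the late exposure X2. Disjoint supports give fully
        period-specific variants; overlapping supports give shared variants.
    theta : float
        Tracking coefficient of X1 into X2.
    conf_load_x1, conf_load_x2, conf_load_y : float
        Loadings of the latent standard-normal confounder U.
    sigma1, sigma2 : float
        Residual SDs of the exposures.
    baseline_risk : float
        Outcome risk at zero exposure and zero confounder.
    psi1, psi2 : float
        True controlled period effects on the risk-difference scale.
    tier_proportions : ndarray, shape (3,)
        Target proportions for the thinner/average/plumper recoding.
    seed : int
        Seed for all random draws.
    """

    n_individuals: int
    maf: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    theta: float
    conf_load_x1: float
    conf_load_x2: float
    conf_load_y: float
    sigma1: float
    sigma2: float
    baseline_risk: float
    psi1: float
    psi2: float
    tier_proportions: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.5, 0.2])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "maf", np.asarray(self.maf, dtype=float))
        object.__setattr__(self, "alpha1", np.asarray(self.alpha1, dtype=float))
        object.__setattr__(self, "alpha2", np.asarray(self.alpha2, dtype=float))
        object.__setattr__(
            self, "tier_proportions", np.asarray(self.tier_proportions, dtype=float)
        )
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if np.any(self.maf <= 0) or np.any(self.maf >= 1):
            raise ValueError("maf entries must lie in the open interval (0, 1)")
        if not (self.alpha1.shape == self.alpha2.shape == self.maf.shape):
            raise ValueError("maf, alpha1, alpha2 must share one length J")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("exposure noise SDs must be positive")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must lie in (0, 1)")
        if self.tier_proportions.shape != (3,):
            raise ValueError("tier_proportions must have length 3")
        if abs(self.tier_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("tier_proportions must sum to 1 within 1e-12")
        if np.any(self.tier_proportions <= 0):
            raise ValueError("tier_proportions must be positive")

    @property
    def n_snps(self) -> int:
        return self.maf.shape[0]

    @property
    def total_effect_early(self) -> float:
        """True total (univariable) early-period effect, psi1 + theta * psi2.

        With instruments acting only on X1, the early exposure reaches the
        outcome both directly and through tracking into X2; the univariable
        estimand is this sum, not psi1.
        """
        return self.psi1 + self.theta * self.psi2

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{j + 1}" for j in range(self.n_snps)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("maf", "alpha1", "alpha2", "tier_proportions"):
            d[k] = [float(v) for v in d[k]]
        d["total_effect_early"] = float(self.total_effect_early)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        d.pop("total_effect_early", None)
        return cls(**d)


@dataclass
class Cohort:
    """Individual-level data: genotypes, exposures, 3-tier recodings, outcome.

    ``confounder`` and ``truth`` are present only on simulated cohorts and are
    stripped by :meth:`observed` to mimic what an analyst would actually see.
    """

    genotypes: np.ndarray  # n x J allele counts in {0, 1, 2}
    snp_ids: list[str]
    x1: np.ndarray
    x2: np.ndarray
    x1_tier: pd.Categorical
    x2_tier: pd.Categorical
    y: np.ndarray
    covariates: np.ndarray  # n x C, possibly C == 0
    covariate_names: list[str] = field(default_factory=list)
    confounder: np.ndarray | None = None
    truth: SimulationTruth | None = None
    clamp_fraction: float = 0.0
    effect_alleles: list[str] | None = None
    other_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        for name in ("x1", "x2", "y"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match genotypes")
        if self.effect_alleles is None:
            self.effect_alleles = ["A"] * len(self.snp_ids)
        if self.other_alleles is None:
            self.other_alleles = ["G"] * len(self.snp_ids)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def tier_codes(self, which: str) -> np.ndarray:
        """Ordinal 1-3 coding of a tier variable ('x1' or 'x2')."""
        cat = self.x1_tier if which == "x1" else self.x2_tier
        return np.asarray(cat.codes, dtype=float) + 1.0

    def observed(self) -> "Cohort":
        """View without the latent confounder or generating truth."""
        return dataclasses.replace(self, confounder=None, truth=None)

    def genotype_frame(self) -> pd.DataFrame:
        cols = [
            f"{sid}_{ea}" for sid, ea in zip(self.snp_ids, self.effect_alleles)
        ]
        return pd.DataFrame(self.genotypes, columns=cols)


def generate_genotypes(maf: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw an n x J allele-count matrix, column j ~ Binomial(2, maf_j).

    SNPs are mutually independent (no LD) and in Hardy-Weinberg proportions.
    Allows boundary frequencies 0 and 1 (monomorphic columns) for testing.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf < 0) or np.any(maf > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, maf, size=(n, maf.shape[0])).astype(np.int8)


def categorize_three_tier(values: np.ndarray, proportions) -> pd.Categorical:
    """Recode a continuous vector into ordinal thinner/average/plumper tiers.

    The lowest ``floor(n*p1)`` ranked values become "thinner", the next
    ``floor(n*p2)`` "average", and the remainder "plumper". Ties are broken by
    stable original order, so the recoding is deterministic even for constant
    input.
    """
    values = np.asarray(values, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (3,) or abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be a 3-vector summing to 1")
    if np.isnan(values).any():
        raise ValueError("values must not contain missing entries")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to form 3 tiers")
    n1 = int(np.floor(n * proportions[0]))
    n2 = int(np.floor(n * proportions[1]))
    order = np.argsort(values, kind="stable")
    codes = np.empty(n, dtype=np.int8)
    codes[order[:n1]] = 0
    codes[order[n1 : n1 + n2]] = 1
    codes[order[n1 + n2 :]] = 2
    return pd.Categorical.from_codes(codes, categories=list(TIER_LABELS), ordered=True)


def generate_cohort(
    truth: SimulationTruth,
    strict: bool = False,
    clamp_ceiling: float = CLAMP_CEILING,
) -> Cohort:
    """Simulate a complete cohort from the generating model.

    The model is linear throughout, with no exposure-period interactions and
    no time-varying confounding:

    ``X1 = G a1 + c1 U + e1``,
    ``X2 = theta X1 + G a2 + c2 U + e2``,
    ``P(Y=1) = clamp(b0 + psi1 X1 + psi2 X2 + cY U)``.

    Risks outside ``(RISK_EPS, 1 - RISK_EPS)`` are clamped; the clamped
    fraction is stored on the cohort because clamping breaks the linear-risk
    identification. If it exceeds ``clamp_ceiling`` a warning is issued, or
    :class:`ClampError` raised when ``strict``.
    """
    rng = np.random.default_rng(truth.seed)
    n, J = truth.n_individuals, truth.n_snps
    g = rng.binomial(2, truth.maf, size=(n, J)).astype(np.int8)
    u = rng.standard_normal(n)
    x1 = g @ truth.alpha1 + truth.conf_load_x1 * u + truth.sigma1 * rng.standard_normal(n)
    x2 = (
        truth.theta * x1
        + g @ truth.alpha2
        + truth.conf_load_x2 * u
        + truth.sigma2 * rng.standard_normal(n)
    )
    risk = truth.baseline_risk + truth.psi1 * x1 + truth.psi2 * x2 + truth.conf_load_y * u
    clamped = (risk < RISK_EPS) | (risk > 1 - RISK_EPS)
    clamp_fraction = float(clamped.mean())
    risk = np.clip(risk, RISK_EPS, 1 - RISK_EPS)
    if clamp_fraction > clamp_ceiling:
        msg = (
            f"{clamp_fraction:.2%} of linear risks clamped into (0,1); "
            "risk-difference identification degrades"
        )
        if strict:
            raise ClampError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    y = (rng.random(n) < risk).astype(np.int8)
    return Cohort(
        genotypes=g,
        snp_ids=truth.snp_ids,
        x1=x1,
        x2=x2,
        x1_tier=categorize_three_tier(x1, truth.tier_proportions),
        x2_tier=categorize_three_tier(x2, truth.tier_proportions),
        y=y.astype(float),
        covariates=np.empty((n, 0)),
        covariate_names=[],
        confounder=u,
        truth=truth,
        clamp_fraction=clamp_fraction,
    )


def filter_complete_cases(cohort: Cohort) -> Cohort:
    """Drop individuals missing either exposure measure or the outcome.

    Mirrors the design rule that only participants with both an early and a
    late adiposity measure enter analysis. Returns a new cohort; raises if no
    rows survive.
    """
    keep = ~(np.isnan(cohort.x1) | np.isnan(cohort.x2) | np.isnan(cohort.y))
    if not keep.any():
        raise ValueError("no complete cases remain after filtering")
    if keep.all():
        return cohort
    return dataclasses.replace(
        cohort,
        genotypes=cohort.genotypes[keep],
        x1=cohort.x1[keep],
        x2=cohort.x2[keep],
        x1_tier=cohort.x1_tier[keep],
        x2_tier=cohort.x2_tier[keep],
        y=cohort.y[keep],
        covariates=cohort.covariates[keep],
        confounder=None if cohort.confounder is None else cohort.confounder[keep],
    )


def default_truth(
    n_individuals: int = 20_000,
    n_early: int = 40,
    n_late: int = 40,
    n_shared: int = 0,
    psi1: float = -0.02,
    psi2: float = 0.10,
    theta: float = 0.6,
    seed: int = 0,
) -> SimulationTruth:
    """A realistic two-period adiposity-like generating model.

    ``n_early`` SNPs act only on the early exposure, ``n_late`` only
    (directly) on the late one, and ``n_shared`` on both. Allele frequencies
    are drawn uniformly on (0.05, 0.5) and per-allele effects on (0.06, 0.12)
    standard deviations, sized so that genome-wide discovery at the default
    cohort size has power comparable to a biobank-scale scan of common
    adiposity variants; signs are random because effect-allele orientation is
    arbitrary, which keeps genetic score means near zero. The baseline risk
    of 0.45 (an outcome as common as lifetime CVD) keeps the linear risk
    model interior to (0, 1) so essentially nothing is clamped. The
    default period effects are a small protective early effect and a strong
    adverse late effect with substantial tracking, the constellation under
    which the univariable/controlled contrast is most informative.
    """
    rng = np.random.default_rng(seed)
    J = n_early + n_late + n_shared

    def effects(size: int) -> np.ndarray:
        # signed per-allele effects: effect-allele orientation is arbitrary
        return rng.uniform(0.06, 0.12, size) * rng.choice([-1.0, 1.0], size)

    maf = rng.uniform(0.05, 0.5, J)
    alpha1 = np.zeros(J)
    alpha2 = np.zeros(J)
    alpha1[:n_early] = effects(n_early)
    alpha2[n_early : n_early + n_late] = effects(n_late)
    if n_shared:
        alpha1[n_early + n_late :] = effects(n_shared)
        alpha2[n_early + n_late :] = effects(n_shared)
    return SimulationTruth(
        n_individuals=n_individuals,
        maf=maf,
        alpha1=alpha1,
        alpha2=alpha2,
        theta=theta,
        conf_load_x1=0.3,
        conf_load_x2=0.3,
        conf_load_y=0.05,
        sigma1=1.0,
        sigma2=1.0,
        baseline_risk=0.45,
        psi1=psi1,
        psi2=psi2,
        tier_proportions=np.array([0.3, 0.5, 0.2]),
        seed=seed,
    )
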