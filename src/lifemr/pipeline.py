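"""End-to-end lifecourse MR comparison on a simulated one-sample cohort.

``run_analysis`` wires the stages together: simulate a cohort, run discovery
association scans for both exposure periods, select instruments at each
stringency tier, build polygenic scores, and estimate period and controlled
period effects with g-estimated structural mean models and with IVW from the
scan summary statistics. Because the generating truth is known, every result
row carries the true value its estimator targets, including the mediation
identity for univariable early-period analyses (the estimand is
psi1 + theta * psi2 when the instruments act only on the early exposure, plus
a contamination term when they also load on the late one).

``mediation_scenario`` replicates the qualitative attenuation pattern: a
positive univariable early-period effect that disappears (or reverses) once
the late-period exposure is controlled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, SimulationTruth, filter_complete_cases, generate_cohort
from .gwas import assoc_scan
from .ivw import harmonize, ivw_mvmr, ivw_univariable
from .prs import TIERS, InstrumentSet, compute_prs, select_instruments
from .smm import smm_multivariable, smm_univariable

__all__ = [
    "AnalysisConfig",
    "run_analysis",
    "mediation_scenario",
    "implied_univariable_target",
    "RESULT_COLUMNS",
]

logger = logging.getLogger("lifemr")

FRAMEWORKS = ("smm-uni", "smm-multi", "ivw-uni", "ivw-mvmr")

RESULT_COLUMNS = [
    "exposure",
    "estimator",
    "tier",
    "estimand_regime",
    "psi",
    "se",
    "ci_low",
    "ci_high",
    "n",
    "first_stage_F",
    "n_snps",
    "true_target",
]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full comparison run."""

    truth: SimulationTruth
    tiers: tuple[str, ...] = TIERS
    frameworks: tuple[str, ...] = FRAMEWORKS
    sample_design: str = "one-sample"  # or "split-sample"
    se_method: str = "sandwich"
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tiers or not self.frameworks:
            raise ValueError("need at least one tier and one framework")
        bad = set(self.frameworks) - set(FRAMEWORKS)
        if bad:
            raise ValueError(f"unknown frameworks: {sorted(bad)}")
        bad = set(self.tiers) - set(TIERS)
        if bad:
            raise ValueError(f"unknown tiers: {sorted(bad)}")
        if self.sample_design not in ("one-sample", "split-sample"):
            raise ValueError("sample_design must be 'one-sample' or 'split-sample'")
        if self.sample_design == "split-sample" and self.truth.n_individuals % 2:
            raise ValueError("split-sample design requires an even cohort size")


def implied_univariable_target(
    truth: SimulationTruth, instruments: InstrumentSet, period: str
) -> float:
    """Population value of the univariable Wald/SMM estimand for a given score.

    For score Z = G w and the linear generating model, cov(Z, X1) = w'D a1 and
    cov(Z, X2) = w'D (theta a1 + a2) with D = diag(2 f (1 - f)). The
    early-period estimand cov(Z,Y)/cov(Z,X1) therefore equals
    psi1 + psi2 (theta + w'D a2 / w'D a1): with purely early-acting
    instruments it reduces to the tracking identity psi1 + theta psi2.
    """
    w = np.zeros(truth.n_snps)
    col = {s: j for j, s in enumerate(truth.snp_ids)}
    for s, wt in zip(instruments.snp_ids, instruments.weights):
        w[col[s]] = wt
    d = 2 * truth.maf * (1 - truth.maf)
    cov_zx1 = w @ (d * truth.alpha1)
    cov_zx2 = truth.theta * cov_zx1 + w @ (d * truth.alpha2)
    cov_zy = truth.psi1 * cov_zx1 + truth.psi2 * cov_zx2
    denom = cov_zx1 if period == "early" else cov_zx2
    if denom == 0:
        return np.nan
    return float(cov_zy / denom)


def _select_tier_sets(
    stats_x1: pd.DataFrame, stats_x2: pd.DataFrame, tiers
) -> tuple[dict, list[str]]:
    """Instrument sets per (tier, period); failed tiers reported, not fatal."""
    sets: dict[tuple[str, str], InstrumentSet] = {}
    failures: list[str] = []
    for tier in tiers:
        for period, (tgt, oth) in {
            "early": (stats_x1, stats_x2),
            "late": (stats_x2, stats_x1),
        }.items():
            try:
                sets[(tier, period)] = select_instruments(
                    tgt, oth, tier, target_period=period
                )
            except ValueError as exc:
                failures.append(f"{tier}/{period}: {exc}")
    return sets, failures


def run_analysis(config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full simulate-scan-select-score-estimate comparison.

    Returns a results table (one row per exposure period x tier x framework)
    and a run report with the seed, clamp fraction, per-tier SNP counts,
    per-stage timings, and any tiers whose selection came up empty.
    """
    t0 = time.perf_counter()
    truth = config.truth
    cohort = filter_complete_cases(generate_cohort(truth))
    timings = {"simulate": time.perf_counter() - t0}

    if config.sample_design == "split-sample":
        half = cohort.n // 2
        disc = _subset(cohort, np.arange(half))
        est_cohort = _subset(cohort, np.arange(half, cohort.n))
    else:
        disc = est_cohort = cohort

    t1 = time.perf_counter()
    stats_x1 = assoc_scan(disc, "x1")
    stats_x2 = assoc_scan(disc, "x2")
    stats_y = assoc_scan(est_cohort, "y")
    timings["scan"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    sets, failures = _select_tier_sets(stats_x1, stats_x2, config.tiers)
    timings["select"] = time.perf_counter() - t2

    rows: list[dict] = []
    t3 = time.perf_counter()
    for tier in config.tiers:
        early = sets.get((tier, "early"))
        late = sets.get((tier, "late"))
        scores = {
            p: compute_prs(est_cohort, s)
            for p, s in (("early", early), ("late", late))
            if s is not None
        }
        if "smm-uni" in config.frameworks:
            for period, inst in (("early", early), ("late", late)):
                if inst is None:
                    continue
                x = est_cohort.x1 if period == "early" else est_cohort.x2
                est = smm_univariable(
                    scores[period],
                    x,
                    est_cohort.y,
                    se_method=config.se_method,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                rows.append(
                    _row(period, "smm-uni", tier, est, 0, inst.n_snps,
                         implied_univariable_target(truth, inst, period))
                )
        if "smm-multi" in config.frameworks and early is not None and late is not None:
            est = smm_multivariable(
                np.column_stack([scores["early"], scores["late"]]),
                np.column_stack([est_cohort.x1, est_cohort.x2]),
                est_cohort.y,
                se_method=config.se_method,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            for k, (period, target) in enumerate(
                (("early", truth.psi1), ("late", truth.psi2))
            ):
                n_snps = early.n_snps if period == "early" else late.n_snps
                rows.append(_row(period, "smm-multi", tier, est, k, n_snps, target))
        if "ivw-uni" in config.frameworks:
            for period, inst, tgt_stats in (
                ("early", early, stats_x1),
                ("late", late, stats_x2),
            ):
                if inst is None or inst.n_snps < 2:
                    continue
                sub = tgt_stats[tgt_stats["snp"].isin(inst.snp_ids)]
                h = harmonize(sub, stats_y)
                iv = ivw_univariable(h["bx_1"], h["by"], h["se_y"])
                rows.append(
                    _ivw_row(period, "ivw-uni", tier, iv, 0,
                             implied_univariable_target(truth, inst, period),
                             est_cohort.n)
                )
        if "ivw-mvmr" in config.frameworks and early is not None and late is not None:
            union = sorted(set(early.snp_ids) | set(late.snp_ids))
            if len(union) > 2:
                h = harmonize(
                    [
                        stats_x1[stats_x1["snp"].isin(union)],
                        stats_x2[stats_x2["snp"].isin(union)],
                    ],
                    stats_y,
                )
                iv = ivw_mvmr(
                    h[["bx_1", "bx_2"]].to_numpy(), h["by"], h["se_y"]
                )
                for k, (period, target) in enumerate(
                    (("early", truth.psi1), ("late", truth.psi2))
                ):
                    rows.append(
                        _ivw_row(period, "ivw-mvmr", tier, iv, k, target,
                                 est_cohort.n)
                    )
    timings["estimate"] = time.perf_counter() - t3

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    report = {
        "version": __version__,
        "seed": truth.seed,
        "sample_design": config.sample_design,
        "n_discovery": disc.n,
        "n_estimation": est_cohort.n,
        "clamp_fraction": cohort.clamp_fraction,
        "snp_counts": {
            f"{tier}/{period}": s.n_snps for (tier, period), s in sets.items()
        },
        "empty_tiers": failures,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    for line in failures:
        logger.warning("empty instrument selection: %s", line)
    return results, report


def _row(period, estimator, tier, est, k, n_snps, target) -> dict:
    return {
        "exposure": period,
        "estimator": estimator,
        "tier": tier,
        "estimand_regime": est.estimand_regime.label,
        "psi": float(est.psi[k]),
        "se": float(est.se[k]),
        "ci_low": float(est.ci_low[k]),
        "ci_high": float(est.ci_high[k]),
        "n": est.n_used,
        "first_stage_F": float(est.first_stage_F[k]),
        "n_snps": n_snps,
        "true_target": target,
    }


def _ivw_row(period, estimator, tier, iv, k, target, n) -> dict:
    regime = "controlled-period" if estimator == "ivw-mvmr" else "period"
    return {
        "exposure": period,
        "estimator": estimator,
        "tier": tier,
        "estimand_regime": regime,
        "psi": float(iv.beta[k]),
        "se": float(iv.se[k]),
        "ci_low": float(iv.ci_low[k]),
        "ci_high": float(iv.ci_high[k]),
        "n": n,
        "first_stage_F": np.nan,
        "n_snps": iv.n_snps,
        "true_target": target,
    }


def _subset(cohort: Cohort, idx: np.ndarray) -> Cohort:
    return replace(
        cohort,
        genotypes=cohort.genotypes[idx],
        x1=cohort.x1[idx],
        x2=cohort.x2[idx],
        x1_tier=cohort.x1_tier[idx],
        x2_tier=cohort.x2_tier[idx],
        y=cohort.y[idx],
        covariates=cohort.covariates[idx],
        confounder=None if cohort.confounder is None else cohort.confounder[idx],
    )


def _oracle_scores(cohort: Cohort, truth: SimulationTruth) -> tuple[np.ndarray, np.ndarray]:
    """Period-specific scores weighted by the true per-allele effects."""
    g = cohort.genotypes.astype(float)
    early = np.where(truth.alpha1 != 0, truth.alpha1, 0.0)
    late = np.where(truth.alpha2 != 0, truth.alpha2, 0.0)
    return g @ early, g @ late


def mediation_scenario(
    truth: SimulationTruth,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Monte-Carlo demonstration of the mediation/attenuation pattern.

    Requires a generating model with psi1 <= 0 < psi2 and positive tracking
    (theta > 0), with disjoint period-specific SNP supports. Across
    replicates it estimates the univariable early-period effect (whose target
    is psi1 + theta * psi2) and the controlled period effects, using
    true-support polygenic scores, and reports Monte-Carlo means, 95% CIs of
    the mean, and the qualitative sign pattern.
    """
    if not (truth.psi1 <= 0 < truth.psi2 and truth.theta > 0):
        raise ValueError("scenario expects psi1 <= 0 < psi2 and theta > 0")
    rng = np.random.default_rng(seed)
    uni_early = np.empty(n_replicates)
    ctrl = np.empty((n_replicates, 2))
    for r in range(n_replicates):
        t = replace(truth, seed=int(rng.integers(0, 2**31 - 1)))
        cohort = generate_cohort(t)
        z1, z2 = _oracle_scores(cohort, t)
        uni_early[r] = smm_univariable(z1, cohort.x1, cohort.y).psi[0]
        ctrl[r] = smm_multivariable(
            np.column_stack([z1, z2]),
            np.column_stack([cohort.x1, cohort.x2]),
            cohort.y,
        ).psi
    def mc_ci(a: np.ndarray) -> tuple[float, float]:
        m, s = a.mean(), a.std(ddof=1) / np.sqrt(len(a))
        return float(m - 1.959964 * s), float(m + 1.959964 * s)

    ctrl_early_ci = mc_ci(ctrl[:, 0])
    return {
        "n_replicates": n_replicates,
        "univariable_early_mean": float(uni_early.mean()),
        "univariable_early_mc_ci": mc_ci(uni_early),
        "univariable_early_target": truth.total_effect_early,
        "controlled_early_mean": float(ctrl[:, 0].mean()),
        "controlled_early_mc_ci": ctrl_early_ci,
        "controlled_late_mean": float(ctrl[:, 1].mean()),
        "controlled_late_mc_ci": mc_ci(ctrl[:, 1]),
        "pattern": {
            "univariable_early_positive": bool(uni_early.mean() > 0),
            "controlled_early_ci_covers_truth": bool(
                ctrl_early_ci[0] <= truth.psi1 <= ctrl_early_ci[1]
            ),
            "controlled_late_positive": bool(ctrl[:, 1].mean() > 0),
        },
    }
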