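"""Instrument selection under tiered stringency and polygenic-score computation.

Instruments for each exposure period are chosen from discovery summary
statistics at four stringency tiers. All tiers require genome-wide
significance (p <= 5e-8) with the target period; successive tiers
additionally exclude SNPs associated with the *other* period at increasingly
lenient thresholds, so the sets are nested:

==============  ==========================================================
tier            rule
==============  ==========================================================
low             p_target <= 5e-8
low-medium      ... and p_other > 5e-8
medium-high     ... and p_other > Bonferroni-corrected 0.05
high            ... and p_other > 0.05
==============  ==========================================================

The Bonferroni denominator pools the counts of period-specific variants for
both periods (those passing the ``high`` rule), i.e. 0.05 / (n_early_specific
+ n_late_specific).

Exclusion thresholds are inclusive ("associated at p <= t" is excluded), so
retention requires p strictly greater than the threshold. Scores are weighted
sums of effect-allele counts, with weights taken from the discovery betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "TIERS",
    "InstrumentSet",
    "bonferroni_threshold",
    "select_instruments",
    "compute_prs",
]

TIERS = ("low", "low-medium", "medium-high", "high")
GW_THRESHOLD = 5e-8


@dataclass(frozen=True)
class InstrumentSet:
    """A selected SNP set with per-allele weights for one exposure period."""

    snp_ids: list[str]
    weights: np.ndarray
    tier: str
    target_period: str  # "early" or "late"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.snp_ids) != self.weights.shape[0]:
            raise ValueError("snp_ids and weights must have equal length")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "weight": self.weights,
                "tier": self.tier,
                "target_period": self.target_period,
            }
        )


def bonferroni_threshold(count_early_specific: int, count_late_specific: int) -> float:
    """Bonferroni-corrected 0.05 threshold over the pooled period-specific SNPs."""
    if count_early_specific < 0 or count_late_specific < 0:
        raise ValueError("counts must be non-negative")
    total = count_early_specific + count_late_specific
    if total == 0:
        raise ValueError("at least one period-specific SNP is required")
    return 0.05 / total


def _count_specific(stats_a: pd.DataFrame, stats_b: pd.DataFrame, gw: float) -> int:
    """SNPs genome-wide significant for trait a but not nominally (0.05) for b."""
    merged = stats_a.merge(stats_b, on="snp", suffixes=("_a", "_b"))
    keep = (merged["pval_a"] <= gw) & (merged["pval_b"] > 0.05)
    return int(keep.sum())


def select_instruments(
    stats_target: pd.DataFrame,
    stats_other: pd.DataFrame,
    tier: str,
    target_period: str = "early",
    gw_threshold: float = GW_THRESHOLD,
    bonferroni: float | None = None,
) -> InstrumentSet:
    """Select instruments for one period at a given stringency tier.

    ``stats_target`` and ``stats_other`` are summary-statistics frames for the
    target and other exposure period, indexed by shared SNP ids. Weights are
    the target-trait discovery betas oriented to the effect allele. SNPs
    flagged monomorphic in either scan are never candidates.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    t = stats_target
    if "monomorphic" in t.columns:
        t = t[~t["monomorphic"]]
    o = stats_other
    if "monomorphic" in o.columns:
        o = o[~o["monomorphic"]]
    candidates = t[t["pval"] <= gw_threshold]
    if tier != "low":
        other_p = o.set_index("snp")["pval"]
        missing = [s for s in candidates["snp"] if s not in other_p.index]
        if missing:
            raise ValueError(
                f"no other-period p-value for candidate SNP(s): {missing[:5]}"
            )
        p_other = other_p.loc[candidates["snp"]].to_numpy()
        if tier == "low-medium":
            cutoff = gw_threshold
        elif tier == "medium-high":
            if bonferroni is None:
                bonferroni = bonferroni_threshold(
                    _count_specific(t, o, gw_threshold),
                    _count_specific(o, t, gw_threshold),
                )
            cutoff = bonferroni
        else:  # high
            cutoff = 0.05
        candidates = candidates[p_other > cutoff]
    if len(candidates) == 0:
        raise ValueError(
            f"no instruments survive tier {tier!r} for period {target_period!r}"
        )
    return InstrumentSet(
        snp_ids=list(candidates["snp"]),
        weights=candidates["beta"].to_numpy(dtype=float),
        tier=tier,
        target_period=target_period,
    )


def compute_prs(
    genotypes: Cohort | pd.DataFrame | np.ndarray,
    instruments: InstrumentSet,
    snp_ids: list[str] | None = None,
) -> np.ndarray:
    """Per-individual polygenic score: weighted sum of effect-allele counts.

    ``genotypes`` may be a :class:`Cohort`, a DataFrame with SNP-id columns,
    or a raw allele-count matrix accompanied by ``snp_ids``. Allele
    orientation is assumed already harmonized (the summary-statistics dialect
    carries the effect allele for this purpose).
    """
    if isinstance(genotypes, Cohort):
        mat, ids = genotypes.genotypes, genotypes.snp_ids
    elif isinstance(genotypes, pd.DataFrame):
        mat, ids = genotypes.to_numpy(), list(genotypes.columns)
    else:
        if snp_ids is None:
            raise ValueError("snp_ids required with a raw genotype matrix")
        mat, ids = np.asarray(genotypes), list(snp_ids)
    col = {s: j for j, s in enumerate(ids)}
    missing = [s for s in instruments.snp_ids if s not in col]
    if missing:
        raise KeyError(f"instrument SNP(s) absent from genotypes: {missing[:5]}")
    idx = [col[s] for s in instruments.snp_ids]
    return mat[:, idx].astype(float) @ instruments.weights
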