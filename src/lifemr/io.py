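"""Plain-text readers and writers for the package's data interchange formats.

* cohort tables: tab-separated, PLINK-.raw-style genotype columns named
  ``<snp>_<effect-allele>`` holding effect-allele counts, alongside phenotype
  and covariate columns; missing values encoded as ``NA``;
* generating truth: YAML sidecar mirroring ``SimulationTruth`` field names;
* summary statistics: the TSV dialect ``snp, effect_allele, other_allele,
  beta, se, pval, n``;
* instrument sets and estimate tables: TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import TIER_LABELS, Cohort, SimulationTruth
from .gwas import SUMMARY_COLUMNS
from .prs import InstrumentSet

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
    "write_summary_stats",
    "read_summary_stats",
    "write_instruments",
    "read_instruments",
]

_PHENO_COLS = ["x1", "x2", "x1_tier", "x2_tier", "y"]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a PLINK-.raw-like TSV (genotypes = allele counts)."""
    df = pd.DataFrame({"IID": np.arange(1, cohort.n + 1)})
    gf = cohort.genotype_frame()
    df = pd.concat([df, gf], axis=1)
    df["x1"] = cohort.x1
    df["x2"] = cohort.x2
    df["x1_tier"] = cohort.x1_tier.astype(str)
    df["x2_tier"] = cohort.x2_tier.astype(str)
    df["y"] = cohort.y
    for i, name in enumerate(cohort.covariate_names):
        df[name] = cohort.covariates[:, i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path, truth: SimulationTruth | None = None) -> Cohort:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    geno_cols = [
        c for c in df.columns if c not in _PHENO_COLS and c != "IID" and "_" in c
    ]
    snp_ids = [c.rsplit("_", 1)[0] for c in geno_cols]
    effect_alleles = [c.rsplit("_", 1)[1] for c in geno_cols]
    cov_names = [
        c
        for c in df.columns
        if c not in geno_cols and c not in _PHENO_COLS and c != "IID"
    ]

    def tiers(col: str) -> pd.Categorical:
        return pd.Categorical(df[col], categories=list(TIER_LABELS), ordered=True)

    return Cohort(
        genotypes=df[geno_cols].to_numpy(dtype=np.int8),
        snp_ids=snp_ids,
        x1=df["x1"].to_numpy(float),
        x2=df["x2"].to_numpy(float),
        x1_tier=tiers("x1_tier"),
        x2_tier=tiers("x2_tier"),
        y=df["y"].to_numpy(float),
        covariates=df[cov_names].to_numpy(float) if cov_names else np.empty((len(df), 0)),
        covariate_names=cov_names,
        truth=truth,
        effect_alleles=effect_alleles,
    )


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(yaml.safe_load(fh))


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: {missing}")
    return df


def write_instruments(instruments: InstrumentSet, path: str | Path) -> None:
    instruments.to_frame().to_csv(path, sep="\t", index=False)


def read_instruments(path: str | Path) -> InstrumentSet:
    df = pd.read_csv(path, sep="\t")
    tier = df["tier"].iloc[0]
    period = df["target_period"].iloc[0]
    return InstrumentSet(
        snp_ids=list(df["snp"]),
        weights=df["weight"].to_numpy(float),
        tier=tier,
        target_period=period,
    )
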