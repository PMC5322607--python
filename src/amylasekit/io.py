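"""Flat-file interchange formats used between pipeline stages.

Cohort tables and SNP summary statistics travel as tab-separated text with a
header row; droplet wells as comma-separated text. Empty cells mean missing.
Every stage can therefore be run standalone on real exports with matching
columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimulationConfig

SNP_STATS_COLUMNS = [
    "snp_id", "chr", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "maf", "n",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_wells(wells: pd.DataFrame, path: str | Path) -> None:
    wells.to_csv(path, index=False)


def read_wells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snp_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write a GWAS-summary-statistics-style table (1-based positions)."""
    cols = [c for c in SNP_STATS_COLUMNS if c in stats.columns]
    extra = [c for c in stats.columns if c not in cols]
    stats[cols + extra].to_csv(path, sep="\t", index=False, na_rep="")


def read_snp_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cn_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML key-value file.

    Unknown keys are rejected so typos cannot silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimulationConfig(**raw)
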