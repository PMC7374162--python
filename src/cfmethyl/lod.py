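"""Analytical limit-of-detection analysis over a spike-in dilution series.

Baseline (0% spike) replicates define, for every panel region, a cutoff at
``mean + sd_multiplier * SD`` of the baseline AMF (default three standard
deviations, sample SD).  Every other sample is summarized by the number of
regions whose AMF strictly exceeds its cutoff; a spike-in level is called
separable when all of its replicates exceed the largest count among the
held-out baseline replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amf import QCConfig, build_amf_matrix

__all__ = ["LoDConfig", "LoDReport", "region_cutoffs", "count_exceedances", "run_lod"]


@dataclass
class LoDConfig:
    n_baseline_training: int = 4
    sd_multiplier: float = 3.0
    sd_mode: str = "sample_sd"   # n-1 denominator; "population_sd" uses n

    def __post_init__(self) -> None:
        if self.n_baseline_training < 2:
            raise ValueError("n_baseline_training must be >= 2")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.sd_mode not in ("sample_sd", "population_sd"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")


def region_cutoffs(baseline_amf: pd.DataFrame, cfg: LoDConfig | None = None) -> pd.DataFrame:
    """Per-region thresholds mean + k*SD from the baseline training columns.

    ``baseline_amf`` must contain exactly ``cfg.n_baseline_training`` columns;
    regions with any MISSING baseline value are excluded with a warning.
    Returns a frame indexed by region_id with columns mean, sd, threshold.
    """
    cfg = cfg or LoDConfig()
    if baseline_amf.shape[1] != cfg.n_baseline_training:
        raise ValueError(
            f"expected exactly {cfg.n_baseline_training} baseline training columns, "
            f"got {baseline_amf.shape[1]}")
    complete = baseline_amf.dropna(axis=0)
    n_dropped = len(baseline_amf) - len(complete)
    if n_dropped:
        warnings.warn(f"{n_dropped} regions excluded from LoD cutoffs (missing baseline values)")
    vals = complete.to_numpy(dtype=float)
    ddof = 1 if cfg.sd_mode == "sample_sd" else 0
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    return pd.DataFrame({"mean": mean, "sd": sd,
                         "threshold": mean + cfg.sd_multiplier * sd},
                        index=complete.index)


def count_exceedances(sample_amf: pd.Series, cutoffs: pd.DataFrame) -> int:
    """Number of regions whose AMF strictly exceeds the region cutoff.

    Strict ">" so zero-variance baselines never self-exceed; MISSING regions
    contribute 0.
    """
    common = cutoffs.index.intersection(sample_amf.index)
    vals = sample_amf.loc[common].to_numpy(dtype=float)
    thr = cutoffs.loc[common, "threshold"].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    return int((vals[ok] > thr[ok]).sum())


@dataclass
class LoDReport:
    cutoffs: pd.DataFrame
    counts: pd.DataFrame          # sample_id, spike_ratio, n_regions_above_cutoff
    summary: pd.DataFrame         # per-ratio min/median/max counts
    baseline_training_ids: list[str]
    heldout_baseline_max: int
    separable: dict[float, bool]  # ratio -> all replicates above held-out baseline max
    log: list[str] = field(default_factory=list)


def run_lod(counts: pd.DataFrame, meta: pd.DataFrame, panel: pd.DataFrame,
            cfg: LoDConfig | None = None) -> LoDReport:
    """Full LoD analysis from spike-in counts.

    Builds the AMF matrix, takes the first ``n_baseline_training`` 0%-spike
    replicates (sample-sheet order) as cutoff-training baselines, counts
    exceedances for every remaining sample, and reports per-ratio summaries
    plus a separability verdict: min count at the ratio strictly above the
    max count among held-out baselines.
    """
    cfg = cfg or LoDConfig()
    if "spike_ratio" not in meta.columns:
        raise ValueError("sample sheet lacks a spike_ratio column")
    matrix = build_amf_matrix(counts, panel, QCConfig(min_unique_molecules=0),
                              sample_order=meta["sample_id"].tolist())
    baseline_ids = meta.loc[meta["spike_ratio"] == 0, "sample_id"].tolist()
    if len(baseline_ids) < cfg.n_baseline_training:
        raise ValueError(
            f"need at least {cfg.n_baseline_training} baseline replicates, "
            f"got {len(baseline_ids)}")
    train_ids = baseline_ids[: cfg.n_baseline_training]
    log = [f"baseline training replicates (sample-sheet order): {train_ids}"]
    cutoffs = region_cutoffs(matrix[train_ids], cfg)

    rest = meta[~meta["sample_id"].isin(train_ids)]
    rows = [{"sample_id": sid,
             "spike_ratio": ratio,
             "n_regions_above_cutoff": count_exceedances(matrix[sid], cutoffs)}
            for sid, ratio in zip(rest["sample_id"], rest["spike_ratio"])]
    cdf = pd.DataFrame(rows)

    heldout = cdf.loc[cdf["spike_ratio"] == 0, "n_regions_above_cutoff"]
    heldout_max = int(heldout.max()) if len(heldout) else 0
    summary = (cdf.groupby("spike_ratio")["n_regions_above_cutoff"]
               .agg(["min", "median", "max", "count"]).reset_index())
    separable = {
        float(r): bool(g.min() > heldout_max)
        for r, g in cdf[cdf["spike_ratio"] > 0].groupby("spike_ratio")["n_regions_above_cutoff"]
    }
    return LoDReport(cutoffs, cdf, summary, train_ids, heldout_max, separable, log)
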