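"""Differentially methylated region (DMR) selection from tissue references.

Per tissue type, each panel region's AMF is compared between tumor and normal
tissue with a two-sided t-test (Welch by default); p-values are
Benjamini-Hochberg adjusted, by default within each tissue type's family of
tests.  A region is selected if its adjusted q <= alpha in at least one
tissue type.  Each selected region gets a direction (hyper/hypo) from the
sign of the tumor-minus-normal mean difference in its most significant
tissue type.  An optional concordance filter keeps only regions whose
direction in tissue agrees with the cancer-vs-healthy difference in
*training-set* plasma; passing any test-set sample to that filter is a hard
error (leakage guard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DMRConfig", "DMRSet", "bh_adjust", "select_dmrs", "concordance_filter"]


@dataclass
class DMRConfig:
    alpha: float = 0.05
    test: str = "welch_t"                 # or "pooled_t"
    family_scope: str = "per_tissue_type"  # or "global"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("welch_t", "pooled_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.family_scope not in ("per_tissue_type", "global"):
            raise ValueError(f"unknown family_scope {self.family_scope!r}")


@dataclass
class DMRSet:
    """Selected regions with per-(region, tissue type) statistics.

    ``table`` columns: region_id, tissue_type, mean_diff (tumor - normal),
    p, q, degenerate.  ``direction`` maps each selected region to
    "hyper"/"hypo"; ``log`` records filtering decisions.
    """

    selected_region_ids: list[str]
    table: pd.DataFrame
    direction: dict[str, str]
    degenerate_region_ids: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["selected"] = out["region_id"].isin(set(self.selected_region_ids))
        out["direction"] = out["region_id"].map(self.direction).fillna("")
        return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _ttest(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    res = stats.ttest_ind(x, y, equal_var=(kind == "pooled_t"))
    return float(res.pvalue)


def select_dmrs(tissue_amf: pd.DataFrame, meta: pd.DataFrame,
                cfg: DMRConfig | None = None) -> DMRSet:
    """Select cancer-informative regions from the tissue reference cohort.

    For each tissue type (cancer_type of tumor samples), the tumor samples of
    that type are compared to all normal tissue samples, region by region, on
    non-missing AMF values.  Regions with an undefined statistic (fewer than
    two observations in either group, or zero variance in both) are flagged
    degenerate and never selected.
    """
    cfg = cfg or DMRConfig()
    tumor_meta = meta[meta["group"] == "tissue_tumor"]
    normal_meta = meta[meta["group"] == "tissue_normal"]
    log: list[str] = []
    rows = []
    degenerate: set[str] = set()
    region_ids = tissue_amf.index.tolist()
    normal_vals = tissue_amf[normal_meta["sample_id"].tolist()].to_numpy()

    for ttype in sorted(tumor_meta["cancer_type"].unique()):
        tumor_ids = tumor_meta.loc[tumor_meta["cancer_type"] == ttype, "sample_id"].tolist()
        if len(tumor_ids) == 0 or len(normal_meta) == 0:
            warnings.warn(f"tissue type {ttype!r} skipped: missing tumor or normal samples")
            log.append(f"skipped tissue type {ttype}: no tumor or no normal samples")
            continue
        tumor_vals = tissue_amf[tumor_ids].to_numpy()
        for r, region in enumerate(region_ids):
            x = tumor_vals[r][~np.isnan(tumor_vals[r])]
            y = normal_vals[r][~np.isnan(normal_vals[r])]
            if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
                degenerate.add(region)
                rows.append((region, ttype, np.nan, np.nan, True))
                continue
            diff = float(np.mean(x) - np.mean(y))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = _ttest(x, y, cfg.test)
            if np.isnan(p):
                degenerate.add(region)
                rows.append((region, ttype, diff, np.nan, True))
                continue
            rows.append((region, ttype, diff, p, False))

    table = pd.DataFrame(rows, columns=["region_id", "tissue_type", "mean_diff", "p", "degenerate"])
    if table.empty:
        return DMRSet([], table.assign(q=np.nan), {}, sorted(degenerate), log)

    table["q"] = np.nan
    ok = ~table["degenerate"]
    if cfg.family_scope == "per_tissue_type":
        for ttype, idx in table[ok].groupby("tissue_type").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    else:
        idx = table.index[ok]
        table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())

    hits = table[ok & (table["q"] <= cfg.alpha)]
    selected = []
    direction = {}
    for region, sub in hits.groupby("region_id", sort=False):
        best = sub.loc[sub["q"].idxmin()]
        selected.append(region)
        direction[region] = "hyper" if best["mean_diff"] > 0 else "hypo"
    # preserve panel order
    sel_set = set(selected)
    selected = [r for r in region_ids if r in sel_set]
    return DMRSet(selected, table, direction, sorted(degenerate), log)


def concordance_filter(dmrs: DMRSet, plasma_train_amf: pd.DataFrame,
                       train_meta: pd.DataFrame) -> DMRSet:
    """Restrict a DMRSet to regions concordant between tissue and plasma.

    A region is kept when the sign of (mean cancer-plasma AMF - mean
    healthy-plasma AMF) over the training set matches its tissue direction.
    Any sample in ``train_meta`` not labeled split == 'train' raises — the
    filter must never see test data.
    """
    if (train_meta["split"] != "train").any():
        bad = train_meta.loc[train_meta["split"] != "train", "sample_id"].tolist()
        raise ValueError(f"concordance_filter received non-training samples: {bad[:5]}")
    cancer_ids = train_meta.loc[train_meta["group"].isin(["pre_dx", "post_dx"]), "sample_id"]
    healthy_ids = train_meta.loc[train_meta["group"] == "healthy", "sample_id"]
    cancer_ids = [s for s in cancer_ids if s in plasma_train_amf.columns]
    healthy_ids = [s for s in healthy_ids if s in plasma_train_amf.columns]

    kept, log = [], list(dmrs.log)
    for region in dmrs.selected_region_ids:
        diff = (np.nanmean(plasma_train_amf.loc[region, cancer_ids].to_numpy(dtype=float))
                - np.nanmean(plasma_train_amf.loc[region, healthy_ids].to_numpy(dtype=float)))
        plasma_dir = "hyper" if diff > 0 else "hypo"
        if plasma_dir == dmrs.direction[region]:
            kept.append(region)
        else:
            log.append(f"dropped {region}: tissue {dmrs.direction[region]} but plasma {plasma_dir}")
    direction = {r: dmrs.direction[r] for r in kept}
    return DMRSet(kept, dmrs.table, direction, dmrs.degenerate_region_ids, log)
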