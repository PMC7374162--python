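"""Average methylation fraction (AMF) matrix construction and sample QC.

For one region in one sample the AMF is the total number of methylated
(cytosine) observations across the region's covered CpG sites divided by the
total depth at those sites:

    AMF = sum_i N_C,i / sum_i (N_C,i + N_T,i)

Regions with no molecules in a sample are MISSING — an explicit sentinel
(NaN), distinct from 0, because downstream modeling drops regions with any
missing value and 0-imputation would silently change the model.

Sample-level QC removes samples with fewer than 200,000 unique mapped
molecules, together with their matched partner, to keep the case/control set
balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCConfig", "compute_amf", "build_amf_matrix", "qc_filter_samples", "MISSING"]

MISSING = float("nan")


@dataclass
class QCConfig:
    """Sample/region quality-control thresholds.

    min_unique_molecules: samples below this are excluded (with their matched
    partner).  min_region_depth: minimum total depth for a region to yield an
    AMF instead of MISSING; the default 1 means any molecule yields an AMF,
    with a stricter value available as a robustness variant.
    """

    min_unique_molecules: int = 200_000
    min_region_depth: int = 1

    def __post_init__(self) -> None:
        if self.min_unique_molecules < 0:
            raise ValueError("min_unique_molecules must be >= 0")
        if self.min_region_depth < 0:
            raise ValueError("min_region_depth must be >= 0")


def compute_amf(site_counts, min_region_depth: int = 1) -> float:
    """AMF of one region from its per-site (N_C, N_T) counts.

    Returns MISSING (NaN) when the region's total depth is below
    ``max(1, min_region_depth)``.  Site order is irrelevant: the statistic is
    the depth-weighted mean of per-site methylation fractions.
    """
    arr = np.asarray(list(site_counts), dtype=float)
    if arr.size == 0:
        return MISSING
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("site_counts must be a sequence of (N_C, N_T) pairs")
    if (arr < 0).any():
        raise ValueError("negative counts in site_counts")
    total = arr.sum()
    if total < max(1, min_region_depth):
        return MISSING
    return float(arr[:, 0].sum() / total)


def build_amf_matrix(counts: pd.DataFrame, panel: pd.DataFrame,
                     qc: QCConfig | None = None,
                     sample_order: list[str] | None = None) -> pd.DataFrame:
    """Region x sample AMF matrix from the long-format count table.

    Rows follow panel order; columns follow ``sample_order`` (normally the
    sample sheet) or, by default, first appearance in the count table.
    Regions absent from a sample, or below ``qc.min_region_depth``, are
    MISSING.  Region ids in the counts that are not in the panel are an
    error.
    """
    qc = qc or QCConfig()
    panel_regions = panel["region_id"].tolist()
    unknown = set(counts["region_id"].unique()) - set(panel_regions)
    if unknown:
        raise KeyError(f"count table contains region ids not in panel: {sorted(unknown)[:5]}")

    g = counts.groupby(["region_id", "sample_id"], sort=False)[["n_meth", "n_unmeth"]].sum()
    depth = g["n_meth"] + g["n_unmeth"]
    amf = g["n_meth"].astype(float) / depth
    amf[depth < max(1, qc.min_region_depth)] = np.nan

    matrix = amf.unstack("sample_id")
    if sample_order is None:
        sample_order = list(dict.fromkeys(counts["sample_id"]))
    matrix = matrix.reindex(index=panel_regions, columns=sample_order)
    matrix.index.name = "region_id"
    matrix.columns.name = None
    return matrix


def qc_filter_samples(matrix: pd.DataFrame, meta: pd.DataFrame,
                      qc: QCConfig | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop low-molecule samples and their matched partners.

    Returns the filtered matrix, filtered sample sheet, and an exclusion log
    with one row per removed sample (reason ``low_molecules`` or
    ``partner_removed``).  The cascade never chains beyond the pair.
    Idempotent: re-running on the output removes nothing.
    """
    qc = qc or QCConfig()
    meta = meta.reset_index(drop=True)
    low = meta.loc[meta["unique_molecules"] < qc.min_unique_molecules, "sample_id"]
    removed: dict[str, str] = {sid: "low_molecules" for sid in low}
    partner_of = meta.set_index("sample_id")["matched_partner"]
    for sid in list(removed):
        partner = partner_of.get(sid)
        if pd.notna(partner) and partner in partner_of.index and partner not in removed:
            removed[partner] = "partner_removed"

    log = pd.DataFrame({"sample_id": list(removed), "reason": list(removed.values())})
    keep = ~meta["sample_id"].isin(removed)
    meta_out = meta.loc[keep].reset_index(drop=True)
    matrix_out = matrix.loc[:, [c for c in matrix.columns if c not in removed]]
    return matrix_out, meta_out, log
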