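"""Plain-text readers and writers for the pipeline's on-disk artifacts.

Formats
-------
* Region panel: BED6+1 — ``chrom  start  end  region_id  n_cpgs  strand
  cpg_offsets`` with 0-based half-open coordinates and comma-separated CpG
  offsets relative to ``start``.  Simulation truth columns (DMR flags, true
  baseline/tumor AMF profiles) are written to a separate sidecar TSV so the
  analysis stages never see them.
* Count table: long-format TSV ``sample_id  region_id  cpg_index  n_meth
  n_unmeth``.
* Sample sheet: one row per sample, ISO-8601 dates.
* AMF matrix: TSV, first column ``region_id``, one column per sample, missing
  values encoded as ``NA``.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["chrom", "start", "end", "region_id", "n_cpgs", "strand", "cpg_offsets"]
TRUTH_COLUMNS = ["region_id", "is_dmr_hyper", "is_dmr_hypo", "baseline_amf", "tumor_amf"]
COUNT_COLUMNS = ["sample_id", "region_id", "cpg_index", "n_meth", "n_unmeth"]


def write_panel(panel: pd.DataFrame, path: str | pathlib.Path) -> None:
    """Write the BED6+1 panel (public columns only)."""
    out = panel.copy()
    if not isinstance(out["cpg_offsets"].iloc[0], str):
        out["cpg_offsets"] = out["cpg_offsets"].map(lambda v: ",".join(str(int(x)) for x in v))
    out[PANEL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_panel(path: str | pathlib.Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", header=None, names=PANEL_COLUMNS)
    panel["cpg_offsets"] = panel["cpg_offsets"].map(
        lambda s: np.array([int(x) for x in str(s).split(",")], dtype=int)
    )
    return panel


def write_panel_truth(panel: pd.DataFrame, path: str | pathlib.Path) -> None:
    """Simulation truth sidecar (kept out of the BED seen by the pipeline)."""
    panel[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_panel_truth(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path: str | pathlib.Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "region_id": str, "cpg_index": int, "n_meth": int, "n_unmeth": int},
    )


def write_sample_sheet(meta: pd.DataFrame, path: str | pathlib.Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | pathlib.Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "matched_partner" in meta.columns:
        meta["matched_partner"] = meta["matched_partner"].astype("string")
    return meta


def write_amf_matrix(matrix: pd.DataFrame, path: str | pathlib.Path) -> None:
    """AMF matrix TSV; MISSING cells are written as ``NA``."""
    matrix.to_csv(path, sep="\t", index_label="region_id", na_rep="NA")


def read_amf_matrix(path: str | pathlib.Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="region_id", na_values=["NA"])
    return matrix.astype(float)
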