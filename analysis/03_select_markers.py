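"""Select cancer-informative regions from the tissue references.

Per tissue type: Welch t-test tumor vs normal per region, BH-adjusted within
the tissue type, selected at q <= 0.05 in any type.  Compares the selection
against the simulation truth labels (which the selection itself never sees).
"""

import subprocess
import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from _workspace import RESULTS, ROOT, SCRATCH  # noqa: E402

import cfmethyl as cf  # noqa: E402
from cfmethyl import io  # noqa: E402


def main() -> None:
    if not (SCRATCH / "tissue_amf.tsv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis/02_build_amf_matrices.py")],
                       check=True)
    tissue_amf = io.read_amf_matrix(SCRATCH / "tissue_amf.tsv")
    tissue_meta = io.read_sample_sheet(SCRATCH / "tissue_samples_qc.tsv")
    dmrs = cf.select_dmrs(tissue_amf, tissue_meta, cf.DMRConfig())
    dmrs.to_frame().to_csv(SCRATCH / "markers_full.tsv", sep="\t", index=False)

    truth = io.read_panel_truth(SCRATCH / "sim_truth.tsv")
    true_set = set(truth.loc[truth["is_dmr_hyper"] | truth["is_dmr_hypo"], "region_id"])
    sel = set(dmrs.selected_region_ids)
    recall = len(sel & true_set) / len(true_set)
    fsr = len(sel - true_set) / (len(truth) - len(true_set))

    best = (dmrs.table[dmrs.table["region_id"].isin(sel)]
            .sort_values("q").groupby("region_id", sort=False).first().reset_index())
    best["direction"] = best["region_id"].map(dmrs.direction)
    best["is_true_dmr"] = best["region_id"].isin(true_set)
    best.sort_values("q").to_csv(RESULTS / "selected_markers.tsv", sep="\t", index=False)

    print(f"selected {len(sel)} of {len(truth)} regions "
          f"(recall of true DMRs {recall:.3f}, false-selection rate {fsr:.4f})")
    print(f"degenerate regions flagged: {len(dmrs.degenerate_region_ids)}")
    print(f"per-region summary -> {RESULTS / 'selected_markers.tsv'}")


if __name__ == "__main__":
    main()
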