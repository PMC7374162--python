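"""Simulate the study cohort: panel, plasma cases/controls, tissue references.

Default conditions: a 595-region panel with 60 tumor-shifted regions,
100 pre-diagnosis + 100 post-diagnosis plasma samples with 1:1 matched
healthy controls (ctDNA fractions U(0.01, 0.05) pre, U(0.05, 0.15) post),
and a 160 tumor / 40 normal tissue reference set.
"""

import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from _workspace import RESULTS, SCRATCH, SEED  # noqa: E402

import cfmethyl as cf  # noqa: E402
from cfmethyl import io  # noqa: E402


def main() -> None:
    params = cf.SimParams(seed=SEED)
    panel = cf.gen_panel(params)
    plasma_counts, plasma_meta = cf.gen_plasma_cohort(panel, params)
    tissue_counts, tissue_meta = cf.gen_tissue_cohort(panel, params)

    io.write_panel(panel, SCRATCH / "panel.bed")
    io.write_panel_truth(panel, SCRATCH / "sim_truth.tsv")
    io.write_counts(plasma_counts, SCRATCH / "plasma_counts.tsv")
    io.write_sample_sheet(plasma_meta, SCRATCH / "plasma_samples.tsv")
    io.write_counts(tissue_counts, SCRATCH / "tissue_counts.tsv")
    io.write_sample_sheet(tissue_meta, SCRATCH / "tissue_samples.tsv")

    summary = (plasma_meta.groupby(["group", "split"])
               .agg(n=("sample_id", "size"),
                    median_age=("age", "median"),
                    median_ctdna_fraction=("true_ctdna_fraction", "median"))
               .reset_index())
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)
    print(f"panel: {len(panel)} regions, {panel['n_cpgs'].sum()} CpGs, "
          f"{int((panel['is_dmr_hyper'] | panel['is_dmr_hypo']).sum())} true DMRs")
    print(summary.to_string(index=False))
    print(f"artifacts -> {SCRATCH}")


if __name__ == "__main__":
    main()
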