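"""Build the AMF matrices and apply sample QC.

AMF per (region, sample) = methylated observations / total CpG depth;
samples under 200,000 unique molecules are excluded with their matched
partner.
"""

import subprocess
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from _workspace import RESULTS, ROOT, SCRATCH  # noqa: E402

import cfmethyl as cf  # noqa: E402
from cfmethyl import io  # noqa: E402


def main() -> None:
    if not (SCRATCH / "plasma_counts.tsv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis/01_simulate_cohort.py")],
                       check=True)
    panel = io.read_panel(SCRATCH / "panel.bed")
    qc = cf.QCConfig()
    for tag in ("plasma", "tissue"):
        counts = io.read_counts(SCRATCH / f"{tag}_counts.tsv")
        meta = io.read_sample_sheet(SCRATCH / f"{tag}_samples.tsv")
        tag_qc = qc if tag == "plasma" else cf.QCConfig(min_unique_molecules=0)
        matrix = cf.build_amf_matrix(counts, panel, tag_qc,
                                     sample_order=meta["sample_id"].tolist())
        matrix, meta, log = cf.qc_filter_samples(matrix, meta, tag_qc)
        io.write_amf_matrix(matrix, SCRATCH / f"{tag}_amf.tsv")
        io.write_sample_sheet(meta, SCRATCH / f"{tag}_samples_qc.tsv")
        frac_missing = float(matrix.isna().to_numpy().mean())
        print(f"{tag}: {matrix.shape[0]} regions x {matrix.shape[1]} samples, "
              f"{len(log)} QC exclusions, missing fraction {frac_missing:.2%}")
        if len(log):
            print(log.to_string(index=False))
    with open(RESULTS / "amf_qc_summary.txt", "w") as fh:
        for tag in ("plasma", "tissue"):
            m = io.read_amf_matrix(SCRATCH / f"{tag}_amf.tsv")
            fh.write(f"{tag}\t{m.shape[0]} regions\t{m.shape[1]} samples\t"
                     f"missing {float(m.isna().to_numpy().mean()):.4%}\n")


if __name__ == "__main__":
    main()
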