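"""Train and freeze the split-ensemble classifier on the training half.

200 random 50/50 splits of the training set; each builds one L1-penalized
logistic component (penalty chosen by internal CV on the building half);
training scores are validation-half averages; the decision cutoff is frozen
at the training specificity closest to 95%.
"""

import subprocess
import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from _workspace import RESULTS, ROOT, SCRATCH, SEED  # noqa: E402

import cfmethyl as cf  # noqa: E402
from cfmethyl import io  # noqa: E402


def main() -> None:
    if not (SCRATCH / "markers_full.tsv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis/03_select_markers.py")],
                       check=True)
    plasma_amf = io.read_amf_matrix(SCRATCH / "plasma_amf.tsv")
    meta = io.read_sample_sheet(SCRATCH / "plasma_samples_qc.tsv")
    markers = pd.read_csv(SCRATCH / "markers_full.tsv", sep="\t")
    selected = markers.loc[markers["selected"], "region_id"].unique().tolist()
    marker_amf = plasma_amf.loc[[r for r in plasma_amf.index if r in set(selected)]]

    train_meta = meta[meta["split"] == "train"].reset_index(drop=True)
    cfg = cf.EnsembleConfig(n_iter=200, seed=SEED)
    model, train_scores = cf.fit_ensemble(
        marker_amf[train_meta["sample_id"].tolist()], train_meta, cfg)
    model.save(SCRATCH / "model.json")
    train_scores.to_csv(SCRATCH / "train_scores.tsv", sep="\t", index=False)

    trm = train_scores.merge(train_meta, on="sample_id")
    healthy = trm[trm["group"] == "healthy"]
    spec = (healthy["call"] == "healthy").mean()
    sens = (trm.loc[trm["group"] != "healthy", "call"] == "cancer").mean()
    nz = sum(1 for c in model.components for _ in [1] if (c.coef != 0).any())
    print(f"frozen model: {len(model.components)} components over "
          f"{len(model.region_ids)} regions, cutoff {model.cutoff:.4f} "
          f"(checksum {cf.model_checksum(model)[:12]})")
    print(f"training specificity {spec:.3f} (n={len(healthy)}), "
          f"training sensitivity {sens:.3f}; {nz} components use >=1 region")
    with open(RESULTS / "model_summary.txt", "w") as fh:
        fh.write(f"components\t{len(model.components)}\n"
                 f"modeled_regions\t{len(model.region_ids)}\n"
                 f"cutoff\t{model.cutoff:.6f}\n"
                 f"train_specificity\t{spec:.4f}\n"
                 f"train_sensitivity\t{sens:.4f}\n"
                 f"model_checksum\t{cf.model_checksum(model)}\n")


if __name__ == "__main__":
    main()
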