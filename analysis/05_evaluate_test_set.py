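"""Score the held-out test set with the frozen model and report accuracy.

Every test sample is scored by all components; calls compare the mean score
to the frozen cutoff.  Reports the subgroup accuracy table with exact
binomial CIs, held-out ROC/AUC, and a covariate screen of the scores.
"""

import subprocess
import sys

import pandas as pd

sys.path.insert(0, str(__import__("pathlib").Path(__file__).resolve().parents[1] / "src"))
from _workspace import RESULTS, ROOT, SCRATCH  # noqa: E402

import cfmethyl as cf  # noqa: E402
from cfmethyl import io  # noqa: E402


def main() -> None:
    if not (SCRATCH / "model.json").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis/04_train_classifier.py")],
                       check=True)
    model = cf.EnsembleModel.load(SCRATCH / "model.json")
    plasma_amf = io.read_amf_matrix(SCRATCH / "plasma_amf.tsv")
    meta = io.read_sample_sheet(SCRATCH / "plasma_samples_qc.tsv")
    test_meta = meta[meta["split"] == "test"].reset_index(drop=True)

    sub = plasma_amf.loc[model.region_ids, test_meta["sample_id"]]
    incomplete = set(sub.columns[sub.isna().any()])
    partner = test_meta.set_index("sample_id")["matched_partner"]
    for sid in list(incomplete):
        p = partner.get(sid)
        if pd.notna(p) and p in partner.index:
            incomplete.add(p)
    if incomplete:
        print(f"excluded {len(incomplete)} test samples incomplete on modeled "
              f"regions (with partners): {sorted(incomplete)}")
        test_meta = test_meta[~test_meta["sample_id"].isin(incomplete)]

    test_scores = cf.apply_ensemble(model, plasma_amf[test_meta["sample_id"].tolist()])
    test_scores.to_csv(SCRATCH / "test_scores.tsv", sep="\t", index=False)
    train_scores = pd.read_csv(SCRATCH / "train_scores.tsv", sep="\t")

    report = cf.subgroup_report(pd.concat([train_scores, test_scores]), meta)
    report.to_csv(RESULTS / "accuracy_table.tsv", sep="\t", index=False)

    m = test_scores.merge(test_meta, on="sample_id")
    healthy = m["group"] == "healthy"
    for grp in ("post_dx", "pre_dx"):
        sel = (m["group"] == grp) | healthy
        _, auc = cf.roc_auc(m.loc[sel, "final_score"],
                            (m.loc[sel, "group"] == grp).astype(int))
        print(f"held-out AUC {grp} vs healthy: {auc:.4f}")
    screens = cf.covariate_screen(test_scores, test_meta)
    flagged = [s for s in screens if s.p < 0.05]
    print(f"covariate screen: {len(screens)} tests, {len(flagged)} with p < 0.05")
    pd.DataFrame([{"group": s.group, "covariate": s.covariate,
                   "kruskal_H": s.kruskal_H, "p": s.p,
                   "n_posthoc_significant": sum(r[4] < 0.05 for r in s.posthoc)}
                  for s in screens]).to_csv(RESULTS / "covariate_screen.tsv",
                                            sep="\t", index=False)
    print(f"accuracy table -> {RESULTS / 'accuracy_table.tsv'}")


if __name__ == "__main__":
    main()
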