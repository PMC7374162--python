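"""Canned end-to-end experiments over the synthetic cohort.

These drive the full analysis path — simulate, AMF + QC, marker selection,
ensemble training, frozen-cutoff test scoring — and return the quantities the
study design cares about: held-out AUCs, sensitivity/specificity at the
frozen cutoff, marker recovery against simulation truth, permutation-null
AUC, and limit-of-detection separability.  They are used by the analysis
scripts, the test suite and the acceptance script alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .amf import QCConfig, build_amf_matrix, qc_filter_samples
from .dmr import DMRConfig, DMRSet, select_dmrs
from .ensemble import EnsembleConfig, EnsembleModel, apply_ensemble, fit_ensemble
from .evaluation import confusion_metrics, roc_auc
from .lod import LoDConfig, LoDReport, run_lod
from .simulate import SimParams, gen_panel, gen_plasma_cohort, gen_spikein_series, gen_tissue_cohort

__all__ = ["CohortData", "prepare_cohort", "RecoveryResult", "recovery_experiment",
           "permutation_null_auc", "lod_experiment", "dmr_recovery"]


@dataclass
class CohortData:
    """Simulated cohort with its AMF matrices and selected markers."""

    panel: pd.DataFrame
    plasma_meta: pd.DataFrame
    plasma_amf: pd.DataFrame
    tissue_meta: pd.DataFrame
    tissue_amf: pd.DataFrame
    dmrs: DMRSet
    marker_amf: pd.DataFrame
    train_meta: pd.DataFrame
    test_meta: pd.DataFrame


def prepare_cohort(seed: int, params: SimParams | None = None,
                   dmr_cfg: DMRConfig | None = None) -> CohortData:
    """Simulate plasma + tissue cohorts, build AMF matrices, select markers."""
    params = (params or SimParams()).replace(seed=seed)
    panel = gen_panel(params)
    plasma_counts, plasma_meta = gen_plasma_cohort(panel, params)
    tissue_counts, tissue_meta = gen_tissue_cohort(panel, params)
    qc = QCConfig()
    plasma_amf = build_amf_matrix(plasma_counts, panel, qc,
                                  sample_order=plasma_meta["sample_id"].tolist())
    plasma_amf, plasma_meta, _ = qc_filter_samples(plasma_amf, plasma_meta, qc)
    tissue_amf = build_amf_matrix(tissue_counts, panel, QCConfig(min_unique_molecules=0),
                                  sample_order=tissue_meta["sample_id"].tolist())
    dmrs = select_dmrs(tissue_amf, tissue_meta, dmr_cfg or DMRConfig())
    marker_amf = plasma_amf.loc[dmrs.selected_region_ids]
    train_meta = plasma_meta[plasma_meta["split"] == "train"].reset_index(drop=True)
    test_meta = plasma_meta[plasma_meta["split"] == "test"].reset_index(drop=True)
    return CohortData(panel, plasma_meta, plasma_amf, tissue_meta, tissue_amf,
                      dmrs, marker_amf, train_meta, test_meta)


def _complete_test_meta(marker_amf: pd.DataFrame, model: EnsembleModel,
                        test_meta: pd.DataFrame) -> pd.DataFrame:
    """Test samples scoreable by the frozen model (all modeled regions present)."""
    sub = marker_amf.loc[model.region_ids, test_meta["sample_id"]]
    bad = set(sub.columns[sub.isna().any()])
    partner = test_meta.set_index("sample_id")["matched_partner"]
    for sid in list(bad):
        p = partner.get(sid)
        if pd.notna(p) and p in partner.index:
            bad.add(p)
    return test_meta[~test_meta["sample_id"].isin(bad)].reset_index(drop=True)


@dataclass
class RecoveryResult:
    model: EnsembleModel
    train_scores: pd.DataFrame
    test_scores: pd.DataFrame
    test_meta: pd.DataFrame
    auc_post: float
    auc_pre: float
    auc_all: float
    train_specificity: float
    n_healthy_train: int
    test_sensitivity_post: float
    test_sensitivity_pre: float
    test_specificity: float


def recovery_experiment(seed: int, params: SimParams | None = None,
                        n_iter: int = 200,
                        base_learner: str = "logistic_regression",
                        cohort: CohortData | None = None) -> RecoveryResult:
    """Train the ensemble on the synthetic training set, score the test set.

    Reports held-out AUCs (post-dx vs healthy, pre-dx vs healthy, all cancer
    vs healthy), training specificity at the frozen cutoff, and test-set
    sensitivity/specificity at that cutoff.
    """
    data = cohort or prepare_cohort(seed, params)
    cfg = EnsembleConfig(n_iter=n_iter, seed=seed, base_learner=base_learner)
    model, train_scores = fit_ensemble(
        data.marker_amf[data.train_meta["sample_id"]], data.train_meta, cfg)
    test_meta = _complete_test_meta(data.marker_amf, model, data.test_meta)
    test_scores = apply_ensemble(model, data.marker_amf[test_meta["sample_id"]])

    m = test_scores.merge(test_meta, on="sample_id")
    healthy = m["group"] == "healthy"

    def auc_vs_healthy(mask):
        sub = m[mask | healthy]
        return roc_auc(sub["final_score"].to_numpy(),
                       (sub["group"] != "healthy").astype(int).to_numpy())[1]

    trm = train_scores.merge(data.train_meta, on="sample_id")
    htr = trm[trm["group"] == "healthy"]
    sens_cell, spec_cell = confusion_metrics(m["call"] == "cancer", ~healthy)
    post = m[(m["group"] == "post_dx")]
    pre = m[(m["group"] == "pre_dx")]
    return RecoveryResult(
        model=model, train_scores=train_scores, test_scores=test_scores,
        test_meta=test_meta,
        auc_post=auc_vs_healthy(m["group"] == "post_dx"),
        auc_pre=auc_vs_healthy(m["group"] == "pre_dx"),
        auc_all=auc_vs_healthy(~healthy),
        train_specificity=float((htr["call"] == "healthy").mean()),
        n_healthy_train=len(htr),
        test_sensitivity_post=float((post["call"] == "cancer").mean()),
        test_sensitivity_pre=float((pre["call"] == "cancer").mean()),
        test_specificity=float(spec_cell.point),
    )


def permutation_null_auc(seed: int, params: SimParams | None = None,
                         n_iter: int = 200,
                         cohort: CohortData | None = None) -> float:
    """Held-out AUC under a global label permutation (permutation null).

    The cancer/healthy label vector of the whole plasma cohort is permuted
    once; the pipeline then trains on the permuted training labels and the
    held-out AUC is computed against the permuted test labels.  Under the
    null the score carries no information about the permuted labels, so the
    AUC should sit near 0.5.
    """
    data = cohort or prepare_cohort(seed, params)
    rng = substream(seed, "label-permutation")
    all_ids = pd.concat([data.train_meta, data.test_meta])["sample_id"]
    y_all = pd.concat([data.train_meta, data.test_meta])["group"] \
        .isin(["pre_dx", "post_dx"]).to_numpy().astype(int)
    y_perm = pd.Series(rng.permutation(y_all), index=all_ids.to_numpy())

    cfg = EnsembleConfig(n_iter=n_iter, seed=seed)
    y_train = y_perm.loc[data.train_meta["sample_id"]].to_numpy()
    model, _ = fit_ensemble(data.marker_amf[data.train_meta["sample_id"]],
                            data.train_meta, cfg, y=y_train)
    test_meta = _complete_test_meta(data.marker_amf, model, data.test_meta)
    test_scores = apply_ensemble(model, data.marker_amf[test_meta["sample_id"]])
    y_test = y_perm.loc[test_scores["sample_id"]].to_numpy()
    return roc_auc(test_scores["final_score"].to_numpy(), y_test)[1]


def lod_experiment(seed: int, params: SimParams | None = None,
                   ratios=None, replicates: int = 6,
                   cfg: LoDConfig | None = None) -> LoDReport:
    """Generate a spike-in dilution series and run the LoD analysis."""
    params = (params or SimParams()).replace(seed=seed)
    panel = gen_panel(params)
    counts, meta = gen_spikein_series(panel, params, ratios, replicates)
    return run_lod(counts, meta, panel, cfg)


def dmr_recovery(cohort: CohortData) -> dict:
    """Marker-selection accuracy against simulation truth labels."""
    panel = cohort.panel
    truth = set(panel.loc[panel["is_dmr_hyper"] | panel["is_dmr_hypo"], "region_id"])
    sel = set(cohort.dmrs.selected_region_ids)
    n_null = len(panel) - len(truth)
    return {
        "recall": len(sel & truth) / len(truth) if truth else float("nan"),
        "false_selection_rate": len(sel - truth) / n_null if n_null else float("nan"),
        "n_selected": len(sel),
        "n_true": len(truth),
    }
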