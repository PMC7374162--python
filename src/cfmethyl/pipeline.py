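"""End-to-end orchestration: simulate -> AMF -> markers -> train -> predict
-> evaluate -> LoD, with plain-text artifacts and a provenance manifest.

One master seed fans out to named substreams per stage; re-running with an
identical config reproduces byte-identical artifacts.  The manifest records
the config hash, seed, per-stage timings and SHA-256 checksums of every
artifact, including the frozen model's checksum both at training completion
and after test-set scoring (the train/test firewall is auditable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io
from ._rng import substream_seed
from .amf import QCConfig, build_amf_matrix, qc_filter_samples
from .dmr import DMRConfig, concordance_filter, select_dmrs
from .ensemble import EnsembleConfig, apply_ensemble, fit_ensemble, model_checksum
from .evaluation import confusion_metrics, roc_auc, subgroup_report
from .lod import LoDConfig, run_lod
from .simulate import (DEFAULT_SPIKEIN_RATIOS, SimParams, gen_panel,
                       gen_plasma_cohort, gen_spikein_series, gen_tissue_cohort)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ["simulate", "amf", "select_markers", "train", "predict", "evaluate", "lod"]


@dataclass
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    qc: QCConfig = field(default_factory=QCConfig)
    dmr: DMRConfig = field(default_factory=DMRConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    lod: LoDConfig = field(default_factory=LoDConfig)
    spikein_ratios: list[float] = field(default_factory=lambda: list(DEFAULT_SPIKEIN_RATIOS))
    spikein_replicates: int = 6
    concordance: bool = False
    seed: int = 0
    outdir: str = "run_out"

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for name, sub_cls in (("sim", SimParams), ("qc", QCConfig), ("dmr", DMRConfig),
                              ("ensemble", EnsembleConfig), ("lod", LoDConfig)):
            if name in raw:
                kw[name] = sub_cls(**raw.pop(name))
        kw.update(raw)
        return cls(**kw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(dataclasses.asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | pathlib.Path | None = None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = pathlib.Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": [], "artifacts": {}}
    artifacts: dict[str, pathlib.Path] = {}

    def record(stage: str, t0: float, files: dict[str, pathlib.Path]) -> None:
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 3)})
        for k, p in files.items():
            artifacts[k] = p
            manifest["artifacts"][k] = {"path": str(p), "sha256": _sha256(p)}

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    sim = config.sim.replace(seed=substream_seed(config.seed, "sim"))
    panel = gen_panel(sim)
    plasma_counts, plasma_meta = gen_plasma_cohort(panel, sim)
    tissue_counts, tissue_meta = gen_tissue_cohort(panel, sim)
    spike_counts, spike_meta = gen_spikein_series(panel, sim, config.spikein_ratios,
                                                  config.spikein_replicates)
    files = {}
    io.write_panel(panel, out / "panel.bed"); files["panel"] = out / "panel.bed"
    io.write_panel_truth(panel, out / "sim_truth.tsv"); files["sim_truth"] = out / "sim_truth.tsv"
    for tag, (cnt, meta) in {"plasma": (plasma_counts, plasma_meta),
                             "tissue": (tissue_counts, tissue_meta),
                             "spikein": (spike_counts, spike_meta)}.items():
        io.write_counts(cnt, out / f"{tag}_counts.tsv")
        io.write_sample_sheet(meta, out / f"{tag}_samples.tsv")
        files[f"{tag}_counts"] = out / f"{tag}_counts.tsv"
        files[f"{tag}_samples"] = out / f"{tag}_samples.tsv"
    record("simulate", t0, files)

    # --- AMF + QC -----------------------------------------------------------
    t0 = time.time()
    plasma_amf = build_amf_matrix(plasma_counts, panel, config.qc,
                                  sample_order=plasma_meta["sample_id"].tolist())
    plasma_amf, plasma_meta, qc_log = qc_filter_samples(plasma_amf, plasma_meta, config.qc)
    tissue_amf = build_amf_matrix(tissue_counts, panel, config.qc,
                                  sample_order=tissue_meta["sample_id"].tolist())
    io.write_amf_matrix(plasma_amf, out / "plasma_amf.tsv")
    io.write_amf_matrix(tissue_amf, out / "tissue_amf.tsv")
    qc_log.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    record("amf", t0, {"plasma_amf": out / "plasma_amf.tsv",
                       "tissue_amf": out / "tissue_amf.tsv",
                       "qc_exclusions": out / "qc_exclusions.tsv"})

    # --- marker selection ---------------------------------------------------
    t0 = time.time()
    dmrs = select_dmrs(tissue_amf, tissue_meta, config.dmr)
    train_meta = plasma_meta[plasma_meta["split"] == "train"].reset_index(drop=True)
    test_meta = plasma_meta[plasma_meta["split"] == "test"].reset_index(drop=True)
    if config.concordance:
        dmrs = concordance_filter(dmrs, plasma_amf[train_meta["sample_id"]], train_meta)
    dmrs.to_frame().to_csv(out / "markers.tsv", sep="\t", index=False)
    record("select_markers", t0, {"markers": out / "markers.tsv"})
    if not dmrs.selected_region_ids:
        raise RuntimeError("stage select_markers produced no regions "
                           f"(see {out / 'markers.tsv'})")

    # --- train --------------------------------------------------------------
    t0 = time.time()
    ecfg = dataclasses.replace(config.ensemble, seed=substream_seed(config.seed, "ensemble"))
    marker_amf = plasma_amf.loc[dmrs.selected_region_ids]
    model, train_scores = fit_ensemble(marker_amf[train_meta["sample_id"]], train_meta, ecfg)
    model.save(out / "model.json")
    train_scores.to_csv(out / "train_scores.tsv", sep="\t", index=False)
    manifest["model_checksum_after_training"] = model_checksum(model)
    record("train", t0, {"model": out / "model.json",
                         "train_scores": out / "train_scores.tsv"})

    # --- predict ------------------------------------------------------------
    # A test sample missing any modeled region cannot be scored by the frozen
    # model (no imputation); it is excluded together with its matched partner,
    # mirroring the molecule-count QC, and logged.
    t0 = time.time()
    test_m = marker_amf.loc[model.region_ids, test_meta["sample_id"]]
    incomplete = set(test_m.columns[test_m.isna().any()])
    partner = test_meta.set_index("sample_id")["matched_partner"]
    for sid in list(incomplete):
        p = partner.get(sid)
        if pd.notna(p) and p in partner.index:
            incomplete.add(p)
    if incomplete:
        pd.DataFrame({"sample_id": sorted(incomplete),
                      "reason": "incomplete_modeled_regions_or_partner"}).to_csv(
            out / "test_exclusions.tsv", sep="\t", index=False)
        test_meta = test_meta[~test_meta["sample_id"].isin(incomplete)].reset_index(drop=True)
    test_scores = apply_ensemble(model, marker_amf[test_meta["sample_id"]])
    test_scores.to_csv(out / "test_scores.tsv", sep="\t", index=False)
    manifest["model_checksum_after_test_scoring"] = model_checksum(model)
    record("predict", t0, {"test_scores": out / "test_scores.tsv"})

    # --- evaluate -----------------------------------------------------------
    t0 = time.time()
    all_scores = pd.concat([train_scores, test_scores], ignore_index=True)
    report = subgroup_report(all_scores, plasma_meta)
    report.to_csv(out / "accuracy_table.tsv", sep="\t", index=False)
    truth = test_meta["group"].isin(["pre_dx", "post_dx"]).to_numpy().astype(int)
    roc_points, auc = roc_auc(test_scores["final_score"].to_numpy(), truth)
    roc_points.to_csv(out / "roc_test.tsv", sep="\t", index=False)
    manifest["test_auc"] = auc
    record("evaluate", t0, {"accuracy_table": out / "accuracy_table.tsv",
                            "roc_test": out / "roc_test.tsv"})

    # --- LoD ----------------------------------------------------------------
    t0 = time.time()
    lod_report = run_lod(spike_counts, spike_meta, panel, config.lod)
    lod_report.counts.to_csv(out / "lod_counts.tsv", sep="\t", index=False)
    lod_report.cutoffs.to_csv(out / "lod_cutoffs.tsv", sep="\t", index_label="region_id")
    record("lod", t0, {"lod_counts": out / "lod_counts.tsv",
                       "lod_cutoffs": out / "lod_cutoffs.tsv"})

    manifest["n_stages"] = len(manifest["stages"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
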