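# cfmethyl

Cell-free DNA methylation cancer classification, end to end: from per-CpG
bisulfite C/T molecule counts over a targeted region panel to a frozen
ensemble classifier with full diagnostic-accuracy and limit-of-detection
reporting.

The package is aimed at computational biologists working on liquid-biopsy
methylation assays: it implements the complete analysis a targeted-panel
screening study needs — average-methylation-fraction (AMF) matrices with
sample QC, differentially methylated region (DMR) selection from tissue
references, a split-ensemble penalized logistic-regression classifier that is
trained and *frozen* before any test-set contact, exact-binomial accuracy
tables, and an analytical limit-of-detection analysis over a spike-in
dilution series — together with a synthetic cohort generator that makes every
stage testable without patient data.

## The model

For each panel region the assay yields per-CpG methylated/unmethylated
molecule counts; the region's **average methylation fraction** is

    AMF = Σᵢ N_C,i / Σᵢ (N_C,i + N_T,i)

over its covered CpG sites. A plasma sample with circulating-tumor-DNA
fraction *f* mixes the healthy background *b* and tumor profile *t* of each
region: E[AMF] = (1 − f)·b + f·t.

The classifier is an **average of L1-penalized logistic models**: the
training set is repeatedly (default 1000×) split 50/50 into model-building
and model-validation halves; each building half fits one component

    P = 1 / (1 + exp(−(Σᵢ Mᵢ Xᵢ + B)))

with the penalty strength chosen by internal cross-validation on the
building half only. A training sample's score is the mean of its
validation-half probabilities; the decision cutoff is set where training
specificity is closest to 95%, and the whole ensemble is then frozen
(checksummed) before the held-out test set is scored by all components.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
cohort at its default conditions (595 regions with 60 true DMRs; 100 pre- +
100 post-diagnosis plasma samples with 200 matched healthy controls, split
50/50 into training and test; 160 tumor / 40 normal tissue references).
Large intermediates go to `scratch/`, summary tables to `results/`.

```bash
python analysis/01_simulate_cohort.py
python analysis/03_select_markers.py     # (re)builds AMF matrices if needed
python analysis/04_train_classifier.py
python analysis/05_evaluate_test_set.py
python analysis/07_limit_of_detection.py
```

prints, in turn:

```
panel: 595 regions, 11920 CpGs, 60 true DMRs
selected 69 of 595 regions (recall of true DMRs 1.000, false-selection rate 0.0168)
frozen model: 200 components over 69 regions, cutoff 0.2912 (checksum 107b3743d729)
training specificity 0.950 (n=100), training sensitivity 0.970
held-out AUC post_dx vs healthy: 1.0000
held-out AUC pre_dx vs healthy: 0.9688
limit of detection (all replicates above baseline): 0.1% spike fraction
```

Reading: marker selection recovers all 60 planted DMRs from tissue at a 1.7%
false-selection rate; the frozen cutoff lands training specificity exactly on
the 95% target; held-out separation is essentially perfect for
post-diagnosis samples (tumor fraction 5–15%) and strong for pre-diagnosis
samples (1–5%); and in the spike-in series every 0.1% replicate exceeds the
baseline-derived per-region thresholds (43–54 regions above cutoff vs. a
held-out-baseline maximum of 30). `analysis/06_permutation_null.py` confirms
the machinery finds nothing under permuted labels (held-out AUC 0.42–0.52
across five seeds).

The same stages are available as a CLI (`cfmethyl simulate|amf|
select-markers|train|predict|evaluate|lod|run`) and as library functions
(`cfmethyl.fit_ensemble`, `cfmethyl.apply_ensemble`, ...); see
`docs/methods.md` for the statistical details and design decisions.

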