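"""Synthetic cfDNA methylation cohort generator.

Emulates the data a targeted bisulfite panel produces over a liquid-biopsy
screening study: a panel of ~595 genomic regions, per-sample per-CpG
methylated/unmethylated molecule counts, matched case/control plasma cohorts
with pre- and post-diagnosis cancer samples, tumor/normal tissue reference
sets, and a cell-line spike-in dilution series for limit-of-detection work.

The central model is a two-component mixture: a plasma sample with circulating
tumor DNA fraction ``f`` has per-region methylation probability

    p_r = (1 - f) * b_r + f * t_r

where ``b_r`` is the healthy-plasma (leukocyte background) methylation level of
region ``r`` and ``t_r`` the tumor profile.  Healthy samples have ``f = 0``;
pre-diagnosis samples draw ``f`` from a distribution stochastically smaller
than post-diagnosis samples.  Counts are binomial draws at a negative-binomial
per-region molecule depth, with region dropout.

Simulation truth (which regions are real DMRs, each sample's true ``f``) is
carried on the panel/sample-sheet objects but written to sidecar files so the
analysis stages never see it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "SimParams",
    "gen_panel",
    "gen_plasma_cohort",
    "gen_tissue_cohort",
    "gen_spikein_series",
    "DEFAULT_SPIKEIN_RATIOS",
]

CANCER_TYPES = ["stomach", "esophagus", "colorectum", "lung", "liver"]
YEARS_BINS = ["0-1", "1-2", "2-3", "3-4"]
DEFAULT_SPIKEIN_RATIOS = [0.0, 0.001, 0.005, 0.01, 0.05, 0.10]

META_COLUMNS = [
    "sample_id", "group", "cancer_type", "stage", "years_to_dx_bin", "age",
    "sex", "collection_date", "collection_site", "smoking", "unique_molecules",
    "total_dna_ng", "split", "matched_partner", "true_ctdna_fraction",
]


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the package is built around:
    a 595-region panel with 60 true tumor-shifted regions, post-diagnosis
    ctDNA fractions ~ U(0.05, 0.15), pre-diagnosis ~ U(0.01, 0.05), matched
    1:1 healthy controls, and a deeply sequenced spike-in series.
    """

    n_regions: int = 595
    cpgs_per_region: tuple[int, int] = (10, 30)
    n_dmr_hyper: int = 40
    n_dmr_hypo: int = 20
    # Beta(a, b) for per-region healthy-plasma baseline AMF by region class.
    hyper_baseline_beta: tuple[float, float] = (1.5, 48.5)   # mean 0.03
    hypo_baseline_beta: tuple[float, float] = (17.0, 3.0)    # mean 0.85
    background_baseline_beta: tuple[float, float] = (2.0, 8.0)  # mean 0.20
    tumor_level_hyper: float = 0.75
    tumor_level_hypo: float = 0.05
    # Uniform ranges for the ctDNA fraction f by group.
    ctdna_fraction_post: tuple[float, float] = (0.05, 0.15)
    ctdna_fraction_pre: tuple[float, float] = (0.01, 0.05)
    # Per-region molecule depth ~ NegativeBinomial(mean, size=dispersion).
    depth_mean: float = 200.0
    depth_dispersion: float = 5.0
    # Per-(sample, region) probability of zero molecules.  The assay targets
    # regions at high depth precisely to avoid dropout; a per-cell rate of
    # ~2.5e-5 reproduces the observed rarity of incomplete regions (a handful
    # out of ~500 across hundreds of samples).
    dropout_rate: float = 2.5e-5
    n_healthy: int = 200
    n_pre: int = 100
    n_post: int = 100
    n_tissue_tumor: int = 160
    n_tissue_normal: int = 40
    tissue_purity: tuple[float, float] = (0.7, 1.0)
    # Beta concentration of per-sample biological noise around region profiles.
    sample_concentration: float = 200.0
    # Spike-in series: pooled plasma and a deeply sequenced dilution run.
    pool_concentration: float = 2000.0
    cellline_concentration: float = 30.0
    spikein_depth_mean: float = 50000.0
    spikein_depth_dispersion: float = 50.0
    unique_molecules_log_mean: float = 13.3   # median ~ 6e5 molecules
    unique_molecules_log_sd: float = 0.4
    total_dna_ng_median: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "n_tissue_tumor": self.n_tissue_tumor,
            "n_tissue_normal": self.n_tissue_normal,
        }
        for name, v in counts.items():
            if int(v) != v or v < (1 if name == "n_regions" else 0):
                raise ValueError(f"invalid {name}: {v!r}")
        for name in ("n_dmr_hyper", "n_dmr_hypo", "n_healthy", "n_pre", "n_post"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"invalid {name}: {v!r} (must be a non-negative count)")
        if self.n_dmr_hyper + self.n_dmr_hypo > self.n_regions:
            raise ValueError("invalid n_dmr_hyper/n_dmr_hypo: more DMRs than regions")
        lo, hi = self.cpgs_per_region
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid cpgs_per_region: {self.cpgs_per_region!r}")
        for name in ("tumor_level_hyper", "tumor_level_hypo", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid {name}: {v!r} (must be in [0, 1])")
        for name in ("ctdna_fraction_post", "ctdna_fraction_pre", "tissue_purity"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid {name}: must satisfy 0 <= lo <= hi <= 1")
        for name in ("depth_mean", "depth_dispersion", "sample_concentration",
                     "pool_concentration", "cellline_concentration",
                     "spikein_depth_mean", "spikein_depth_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid {name}: must be positive")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Panel


def gen_panel(params: SimParams) -> pd.DataFrame:
    """Generate the targeted region panel with simulation truth columns.

    Regions are non-overlapping, sorted, 0-based half-open; CpG offsets lie
    strictly inside each region.  Truth columns: ``is_dmr_hyper``,
    ``is_dmr_hypo``, per-region healthy baseline AMF ``baseline_amf`` and
    tumor profile ``tumor_amf``.
    """
    params.validate()
    rng = substream(params.seed, "panel")
    R = params.n_regions
    lo, hi = params.cpgs_per_region
    n_cpgs = rng.integers(lo, hi + 1, size=R)

    lengths = 20 * n_cpgs + 100
    gaps = rng.integers(500, 2000, size=R)
    starts = np.cumsum(gaps + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths

    offsets = []
    for m, L in zip(n_cpgs, lengths):
        offs = np.sort(rng.choice(np.arange(1, L - 1), size=m, replace=False))
        offsets.append(offs)

    dmr_idx = rng.choice(R, size=params.n_dmr_hyper + params.n_dmr_hypo, replace=False)
    hyper_idx = dmr_idx[: params.n_dmr_hyper]
    hypo_idx = dmr_idx[params.n_dmr_hyper:]
    is_hyper = np.zeros(R, dtype=bool)
    is_hypo = np.zeros(R, dtype=bool)
    is_hyper[hyper_idx] = True
    is_hypo[hypo_idx] = True

    baseline = rng.beta(*params.background_baseline_beta, size=R)
    baseline[is_hyper] = rng.beta(*params.hyper_baseline_beta, size=params.n_dmr_hyper)
    baseline[is_hypo] = rng.beta(*params.hypo_baseline_beta, size=params.n_dmr_hypo)
    baseline = np.clip(baseline, 1e-4, 1 - 1e-4)

    tumor = baseline.copy()           # background regions: no tumor shift
    tumor[is_hyper] = params.tumor_level_hyper
    tumor[is_hypo] = params.tumor_level_hypo

    return pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": ends,
        "region_id": [f"region_{i:04d}" for i in range(R)],
        "n_cpgs": n_cpgs,
        "strand": "+",
        "cpg_offsets": offsets,
        "is_dmr_hyper": is_hyper,
        "is_dmr_hypo": is_hypo,
        "baseline_amf": baseline,
        "tumor_amf": tumor,
    })


# ---------------------------------------------------------------------------
# Count sampling machinery


def _nb_depth(rng, mean: float, dispersion: float, shape) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape)


def _sample_counts(rng, panel: pd.DataFrame, probs: np.ndarray, depth: np.ndarray,
                   sample_ids: list[str]) -> pd.DataFrame:
    """Draw per-CpG binomial counts for an S x R probability/depth grid.

    Every molecule covers all CpGs of its region (amplicon reads span the
    region), so each CpG of region r in sample s has total depth
    ``depth[s, r]``.  Zero-depth (dropout or absent) regions emit no rows.
    """
    n_cpgs = panel["n_cpgs"].to_numpy()
    R = len(panel)
    reg_rep = np.repeat(np.arange(R), n_cpgs)                 # region index per CpG slot
    cpg_idx = np.concatenate([np.arange(m) for m in n_cpgs])  # within-region CpG index
    K = reg_rep.size

    P = np.clip(probs[:, reg_rep], 0.0, 1.0)
    D = depth[:, reg_rep]
    n_meth = rng.binomial(D, P)

    S = len(sample_ids)
    flat_mask = (D > 0).ravel()
    region_ids = panel["region_id"].to_numpy()
    df = pd.DataFrame({
        "sample_id": np.repeat(np.asarray(sample_ids, dtype=object), K)[flat_mask],
        "region_id": np.tile(region_ids[reg_rep], S)[flat_mask],
        "cpg_index": np.tile(cpg_idx, S)[flat_mask],
        "n_meth": n_meth.ravel()[flat_mask],
        "n_unmeth": (D - n_meth).ravel()[flat_mask],
    })
    return df


def _beta_around(rng, mean: np.ndarray, concentration: float, size=None) -> np.ndarray:
    """Beta draws with the given mean and concentration (a+b)."""
    m = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(m * concentration, (1 - m) * concentration, size=size)


def _random_dates(rng, n: int, start="2007-01-01", end="2014-12-31") -> pd.Series:
    t0 = pd.Timestamp(start)
    span = (pd.Timestamp(end) - t0).days
    return pd.Series(t0 + pd.to_timedelta(rng.integers(0, span + 1, size=n), unit="D")).dt.date


# ---------------------------------------------------------------------------
# Plasma cohort


def gen_plasma_cohort(panel: pd.DataFrame, params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the matched plasma cohort: counts plus a sample sheet.

    Every cancer sample (pre- or post-diagnosis) gets exactly one healthy
    partner matched on sex, 10-year age group, collection date and
    unique-molecule count; pairs share their train/test split so the matching
    never leaks across the firewall.
    """
    params.validate()
    if params.n_healthy + params.n_pre + params.n_post == 0:
        raise ValueError("invalid cohort sizes: all of n_healthy, n_pre, n_post are zero")
    n_cancer = params.n_pre + params.n_post
    if params.n_healthy < n_cancer:
        raise ValueError("invalid n_healthy: fewer healthy samples than cancer samples to match")
    rng = substream(params.seed, "plasma")

    pre_ids = [f"P{i:04d}" for i in range(params.n_pre)]
    post_ids = [f"D{i:04d}" for i in range(params.n_post)]
    healthy_ids = [f"H{i:04d}" for i in range(params.n_healthy)]
    cancer_ids = pre_ids + post_ids

    # --- cancer sample attributes
    ages_c = rng.integers(35, 86, size=n_cancer)
    sex_c = rng.choice(["F", "M"], size=n_cancer)
    dates_c = _random_dates(rng, n_cancer)
    um_c = np.exp(rng.normal(params.unique_molecules_log_mean,
                             params.unique_molecules_log_sd, size=n_cancer)).astype(int)
    groups_c = ["pre_dx"] * params.n_pre + ["post_dx"] * params.n_post
    ctype_c = rng.choice(CANCER_TYPES, size=n_cancer)
    stage_c = rng.choice(["I", "II", "III", "IV"], size=n_cancer, p=[0.3, 0.3, 0.25, 0.15])
    stage_c = np.where(rng.random(n_cancer) < 0.1, "unknown", stage_c)
    years_c = np.array(list(rng.choice(YEARS_BINS, size=params.n_pre)) + ["n/a"] * params.n_post)
    f_pre = rng.uniform(*params.ctdna_fraction_pre, size=params.n_pre)
    f_post = rng.uniform(*params.ctdna_fraction_post, size=params.n_post)
    f_cancer = np.concatenate([f_pre, f_post])

    # --- matched healthy partners mirror the cancer attributes
    n_extra = params.n_healthy - n_cancer
    decade = (ages_c // 10) * 10
    ages_h = np.minimum(decade + rng.integers(0, 10, size=n_cancer), 85)
    dates_h = pd.Series(pd.to_datetime(dates_c) +
                        pd.to_timedelta(rng.integers(-30, 31, size=n_cancer), unit="D")).dt.date
    um_h = (um_c * np.exp(rng.normal(0, 0.1, size=n_cancer))).astype(int)
    ages_x = rng.integers(35, 86, size=n_extra)
    sex_x = rng.choice(["F", "M"], size=n_extra)
    dates_x = _random_dates(rng, n_extra)
    um_x = np.exp(rng.normal(params.unique_molecules_log_mean,
                             params.unique_molecules_log_sd, size=n_extra)).astype(int)

    # --- split assignment: pairs move together, stratified by cancer group
    split_cancer = np.empty(n_cancer, dtype=object)
    for gmask in (np.arange(n_cancer) < params.n_pre, np.arange(n_cancer) >= params.n_pre):
        idx = np.flatnonzero(gmask)
        perm = rng.permutation(idx)
        half = (len(idx) + 1) // 2
        split_cancer[perm[:half]] = "train"
        split_cancer[perm[half:]] = "test"
    split_extra = np.array(["train"] * ((n_extra + 1) // 2) + ["test"] * (n_extra // 2), dtype=object)
    if n_extra:
        split_extra = split_extra[rng.permutation(n_extra)]

    n_total = params.n_healthy + n_cancer
    meta = pd.DataFrame({
        "sample_id": healthy_ids + cancer_ids,
        "group": ["healthy"] * params.n_healthy + groups_c,
        "cancer_type": ["none"] * params.n_healthy + list(ctype_c),
        "stage": ["unknown"] * params.n_healthy + list(stage_c),
        "years_to_dx_bin": ["n/a"] * params.n_healthy + list(years_c),
        "age": np.concatenate([ages_h, ages_x, ages_c]),
        "sex": np.concatenate([sex_c, sex_x, sex_c]),
        "collection_date": pd.concat([pd.Series(dates_h), pd.Series(dates_x),
                                      pd.Series(dates_c)], ignore_index=True),
        "collection_site": rng.choice(["site_A", "site_B", "site_C"], size=n_total),
        "smoking": rng.choice(["never", "former", "current"], size=n_total, p=[0.6, 0.2, 0.2]),
        "unique_molecules": np.concatenate([um_h, um_x, um_c]),
        "total_dna_ng": np.round(params.total_dna_ng_median *
                                 np.exp(rng.normal(0, 0.35, size=n_total)), 2),
        "split": np.concatenate([split_cancer, split_extra, split_cancer]),
        "matched_partner": (cancer_ids + [pd.NA] * n_extra + healthy_ids[:n_cancer]),
        "true_ctdna_fraction": np.concatenate([np.zeros(params.n_healthy), f_cancer]),
    })
    meta["matched_partner"] = meta["matched_partner"].astype("string")

    counts = _mixture_counts(rng, panel, params, meta,
                             depth_mean=params.depth_mean,
                             depth_dispersion=params.depth_dispersion,
                             dropout=params.dropout_rate)
    return counts, meta


def _mixture_counts(rng, panel, params, meta, depth_mean, depth_dispersion, dropout):
    """Draw counts for all samples in ``meta`` under the (1-f)b + f*t mixture."""
    S = len(meta)
    b = panel["baseline_amf"].to_numpy()
    t = panel["tumor_amf"].to_numpy()
    R = len(panel)
    f = meta["true_ctdna_fraction"].to_numpy()[:, None]
    b_s = _beta_around(rng, np.broadcast_to(b, (S, R)), params.sample_concentration)
    t_s = _beta_around(rng, np.broadcast_to(t, (S, R)), params.sample_concentration)
    probs = (1 - f) * b_s + f * t_s
    depth = _nb_depth(rng, depth_mean, depth_dispersion, (S, R))
    if dropout > 0:
        depth[rng.random((S, R)) < dropout] = 0
    return _sample_counts(rng, panel, probs, depth, list(meta["sample_id"]))


# ---------------------------------------------------------------------------
# Tissue reference cohort


def gen_tissue_cohort(panel: pd.DataFrame, params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor/normal tissue reference set used for marker selection.

    Tumor tissue mixes the tumor profile at a purity drawn from
    ``params.tissue_purity`` (near 1); normal tissue is pure baseline.
    """
    params.validate()
    if params.n_tissue_tumor + params.n_tissue_normal == 0:
        raise ValueError("invalid cohort sizes: both n_tissue_tumor and n_tissue_normal are zero")
    rng = substream(params.seed, "tissue")
    nT, nN = params.n_tissue_tumor, params.n_tissue_normal
    purity = rng.uniform(*params.tissue_purity, size=nT)
    ctype = [CANCER_TYPES[i % len(CANCER_TYPES)] for i in range(nT)]
    n_total = nT + nN
    meta = pd.DataFrame({
        "sample_id": [f"TT{i:04d}" for i in range(nT)] + [f"TN{i:04d}" for i in range(nN)],
        "group": ["tissue_tumor"] * nT + ["tissue_normal"] * nN,
        "cancer_type": ctype + ["none"] * nN,
        "stage": list(rng.choice(["I", "II", "III", "IV"], size=nT)) + ["unknown"] * nN,
        "years_to_dx_bin": "n/a",
        "age": rng.integers(35, 86, size=n_total),
        "sex": rng.choice(["F", "M"], size=n_total),
        "collection_date": _random_dates(rng, n_total),
        "collection_site": "biobank",
        "smoking": rng.choice(["never", "former", "current"], size=n_total),
        "unique_molecules": np.exp(rng.normal(params.unique_molecules_log_mean + 0.7, 0.3,
                                              size=n_total)).astype(int),
        "total_dna_ng": np.round(np.exp(rng.normal(np.log(200), 0.3, size=n_total)), 2),
        "split": "unassigned",
        "matched_partner": pd.NA,
        "true_ctdna_fraction": np.concatenate([purity, np.zeros(nN)]),
    })
    meta["matched_partner"] = meta["matched_partner"].astype("string")
    counts = _mixture_counts(rng, panel, params, meta,
                             depth_mean=params.depth_mean,
                             depth_dispersion=params.depth_dispersion,
                             dropout=params.dropout_rate)
    return counts, meta


# ---------------------------------------------------------------------------
# Spike-in dilution series


def gen_spikein_series(panel: pd.DataFrame, params: SimParams,
                       ratios: list[float] | None = None,
                       replicates: int = 6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-line DNA spiked into pooled healthy plasma at given molar ratios.

    One pooled-plasma baseline profile and one cell-line profile are drawn
    once and shared by all replicates, so technical replicates differ only by
    counting noise — the construction a physical dilution series implies.
    The cell line carries the tumor profile at DMRs and drifts moderately
    from plasma at background regions.  No region dropout: the dilution run
    is sequenced deep (``spikein_depth_mean``).
    """
    params.validate()
    if ratios is None:
        ratios = DEFAULT_SPIKEIN_RATIOS
    if len(ratios) == 0:
        raise ValueError("invalid ratios: empty list")
    if any(not 0.0 <= r <= 1.0 for r in ratios):
        raise ValueError("invalid ratios: all must be in [0, 1]")
    if replicates < 1:
        raise ValueError("invalid replicates: must be >= 1")
    rng = substream(params.seed, "spikein")

    b = panel["baseline_amf"].to_numpy()
    t = panel["tumor_amf"].to_numpy()
    is_dmr = (panel["is_dmr_hyper"] | panel["is_dmr_hypo"]).to_numpy()
    pool_b = _beta_around(rng, b, params.pool_concentration)
    cell_t = np.where(is_dmr, t, _beta_around(rng, b, params.cellline_concentration))

    ratios = sorted(float(r) for r in ratios)
    rows, probs = [], []
    for r in ratios:
        for j in range(replicates):
            rows.append({"sample_id": f"SPK_{r:.4f}_r{j + 1}", "ratio": r, "replicate": j + 1})
            probs.append((1 - r) * pool_b + r * cell_t)
    probs = np.asarray(probs)
    S = len(rows)
    meta = pd.DataFrame({
        "sample_id": [r["sample_id"] for r in rows],
        "group": "healthy",
        "cancer_type": "none",
        "stage": "unknown",
        "years_to_dx_bin": "n/a",
        "age": 0,
        "sex": "F",
        "collection_date": "2014-01-01",
        "collection_site": "spikein_pool",
        "smoking": "never",
        "unique_molecules": int(params.spikein_depth_mean * params.n_regions),
        "total_dna_ng": params.total_dna_ng_median,
        "split": "unassigned",
        "matched_partner": pd.NA,
        "true_ctdna_fraction": [r["ratio"] for r in rows],
        "spike_ratio": [r["ratio"] for r in rows],
        "replicate": [r["replicate"] for r in rows],
    })
    meta["matched_partner"] = meta["matched_partner"].astype("string")
    depth = _nb_depth(rng, params.spikein_depth_mean, params.spikein_depth_dispersion,
                      (S, len(panel)))
    counts = _sample_counts(rng, panel, probs, depth, list(meta["sample_id"]))
    return counts, meta
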