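"""Synthetic cohort generator: structure, determinism, mixture model."""

import numpy as np
import pandas as pd
import pytest

import cfmethyl as cf


class TestParams:
    @pytest.mark.parametrize("kw, field", [
        ({"n_regions": 0}, "n_regions"),
        ({"n_dmr_hyper": 30, "n_dmr_hypo": 20, "n_regions": 40}, "n_dmr"),
        ({"dropout_rate": 1.5}, "dropout_rate"),
        ({"ctdna_fraction_pre": (0.5, 0.1)}, "ctdna_fraction_pre"),
        ({"depth_mean": -1}, "depth_mean"),
    ])
    def test_validation_names_offending_field(self, kw, field):
        with pytest.raises(ValueError, match=field):
            cf.SimParams(**kw)


class TestPanel:
    def test_structure_and_truth_flags(self, small_panel, small_params):
        p = small_params
        assert len(small_panel) == p.n_regions
        lo, hi = p.cpgs_per_region
        total = small_panel["n_cpgs"].sum()
        assert lo * p.n_regions <= total <= hi * p.n_regions
        assert small_panel["is_dmr_hyper"].sum() == p.n_dmr_hyper
        assert small_panel["is_dmr_hypo"].sum() == p.n_dmr_hypo
        assert not (small_panel["is_dmr_hyper"] & small_panel["is_dmr_hypo"]).any()
        # sorted, non-overlapping, half-open; CpGs strictly inside
        assert (small_panel["start"] < small_panel["end"]).all()
        assert (small_panel["start"].to_numpy()[1:] >= small_panel["end"].to_numpy()[:-1]).all()
        for _, row in small_panel.iterrows():
            offs = row["cpg_offsets"]
            assert len(offs) == row["n_cpgs"]
            assert offs.min() >= 1 and offs.max() < row["end"] - row["start"] - 1

    def test_single_region(self):
        p = cf.SimParams(n_regions=1, n_dmr_hyper=1, n_dmr_hypo=0)
        panel = cf.gen_panel(p)
        assert len(panel) == 1 and panel["is_dmr_hyper"].iloc[0]

    def test_seed_determinism(self, small_params):
        a = cf.gen_panel(small_params)
        b = cf.gen_panel(small_params)
        pd.testing.assert_frame_equal(a.drop(columns="cpg_offsets"),
                                      b.drop(columns="cpg_offsets"))
        assert all((x == y).all() for x, y in zip(a["cpg_offsets"], b["cpg_offsets"]))


class TestPlasmaCohort:
    def test_determinism_and_seed_sensitivity(self, small_panel, small_params):
        c1, m1 = cf.gen_plasma_cohort(small_panel, small_params)
        c2, m2 = cf.gen_plasma_cohort(small_panel, small_params)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)
        c3, _ = cf.gen_plasma_cohort(small_panel, small_params.replace(seed=999))
        assert not c1.equals(c3)

    def test_metadata_contract(self, small_plasma, small_params):
        _, meta = small_plasma
        p = small_params
        assert (meta["group"].value_counts()[["healthy", "pre_dx", "post_dx"]].tolist()
                == [p.n_healthy, p.n_pre, p.n_post])
        # matched partner symmetric; partners share the train/test split
        by_id = meta.set_index("sample_id")
        cancers = meta[meta["group"] != "healthy"]
        for _, row in cancers.iterrows():
            partner = row["matched_partner"]
            assert by_id.loc[partner, "matched_partner"] == row["sample_id"]
            assert by_id.loc[partner, "split"] == row["split"]
            assert by_id.loc[partner, "sex"] == row["sex"]
            assert by_id.loc[partner, "age"] // 10 == row["age"] // 10
        # years-to-diagnosis bins only for pre-diagnosis samples
        assert (meta.loc[meta["group"] != "pre_dx", "years_to_dx_bin"] == "n/a").all()
        assert (meta.loc[meta["group"] == "pre_dx", "years_to_dx_bin"] != "n/a").all()
        assert (meta.loc[meta["group"] == "healthy", "true_ctdna_fraction"] == 0).all()

    def test_all_zero_cohort_rejected(self, small_panel, small_params):
        with pytest.raises(ValueError):
            cf.gen_plasma_cohort(small_panel,
                                 small_params.replace(n_healthy=0, n_pre=0, n_post=0))

    def test_pure_tumor_high_depth_converges_to_tumor_level(self, small_params):
        """f=1 and deep counting pins hyper-DMR AMF near the tumor level."""
        p = small_params.replace(
            n_healthy=4, n_pre=0, n_post=4, depth_mean=5000.0, dropout_rate=0.0,
            ctdna_fraction_post=(1.0, 1.0), sample_concentration=1e5)
        panel = cf.gen_panel(p)
        counts, meta = cf.gen_plasma_cohort(panel, p)
        m = cf.build_amf_matrix(counts, panel, cf.QCConfig(min_unique_molecules=0),
                                sample_order=meta["sample_id"].tolist())
        hyper = panel.loc[panel["is_dmr_hyper"], "region_id"]
        post_ids = meta.loc[meta["group"] == "post_dx", "sample_id"]
        vals = m.loc[hyper, post_ids].to_numpy()
        assert abs(vals.mean() - p.tumor_level_hyper) < 0.02

    def test_mixture_consistency_monte_carlo(self, small_params):
        """E[AMF] matches (1-f) E[b] + f t at a fixed f, within 3 SE."""
        f = 0.5
        p = small_params.replace(
            n_healthy=40, n_pre=0, n_post=40, depth_mean=2000.0, dropout_rate=0.0,
            ctdna_fraction_post=(f, f), seed=77)
        panel = cf.gen_panel(p)
        counts, meta = cf.gen_plasma_cohort(panel, p)
        m = cf.build_amf_matrix(counts, panel, cf.QCConfig(min_unique_molecules=0),
                                sample_order=meta["sample_id"].tolist())
        post_ids = meta.loc[meta["group"] == "post_dx", "sample_id"]
        for region in panel.loc[panel["is_dmr_hyper"], "region_id"].iloc[:4]:
            row = panel.set_index("region_id").loc[region]
            expect = (1 - f) * row["baseline_amf"] + f * row["tumor_amf"]
            vals = m.loc[region, post_ids].to_numpy(dtype=float)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expect) < 3 * se + 1e-3

    def test_hyper_dmr_amf_monotone_in_ctdna_fraction(self, small_params):
        means = []
        for f in (0.0, 0.02, 0.05, 0.1, 0.3):
            p = small_params.replace(
                n_healthy=12, n_pre=0, n_post=12, depth_mean=1000.0, dropout_rate=0.0,
                ctdna_fraction_post=(f, f), seed=42)
            panel = cf.gen_panel(p)
            counts, meta = cf.gen_plasma_cohort(panel, p)
            m = cf.build_amf_matrix(counts, panel, cf.QCConfig(min_unique_molecules=0),
                                    sample_order=meta["sample_id"].tolist())
            hyper = panel.loc[panel["is_dmr_hyper"], "region_id"]
            post_ids = meta.loc[meta["group"] == "post_dx", "sample_id"]
            means.append(m.loc[hyper, post_ids].to_numpy().mean())
        assert all(b > a - 1e-3 for a, b in zip(means, means[1:]))


class TestTissueCohort:
    def test_group_counts_and_determinism(self, small_panel, small_params, small_tissue):
        counts, meta = small_tissue
        assert (meta["group"] == "tissue_tumor").sum() == small_params.n_tissue_tumor
        assert (meta["group"] == "tissue_normal").sum() == small_params.n_tissue_normal
        c2, m2 = cf.gen_tissue_cohort(small_panel, small_params)
        pd.testing.assert_frame_equal(counts, c2)
        pd.testing.assert_frame_equal(meta, m2)

    def test_purity_one_centers_on_tumor_level(self, small_params):
        p = small_params.replace(tissue_purity=(1.0, 1.0), depth_mean=3000.0,
                                 dropout_rate=0.0, sample_concentration=1e5)
        panel = cf.gen_panel(p)
        counts, meta = cf.gen_tissue_cohort(panel, p)
        m = cf.build_amf_matrix(counts, panel, cf.QCConfig(min_unique_molecules=0),
                                sample_order=meta["sample_id"].tolist())
        hyper = panel.loc[panel["is_dmr_hyper"], "region_id"]
        tumor_ids = meta.loc[meta["group"] == "tissue_tumor", "sample_id"]
        assert abs(m.loc[hyper, tumor_ids].to_numpy().mean() - p.tumor_level_hyper) < 0.02


class TestSpikeinSeries:
    def test_sample_count_and_determinism(self, small_panel, small_params):
        ratios = [0.0, 0.001, 0.005, 0.01, 0.05, 0.10]
        c1, m1 = cf.gen_spikein_series(small_panel, small_params, ratios, 6)
        assert len(m1) == 36
        assert sorted(m1["spike_ratio"].unique()) == ratios
        c2, m2 = cf.gen_spikein_series(small_panel, small_params, ratios, 6)
        pd.testing.assert_frame_equal(c1, c2)

    def test_empty_ratios_rejected(self, small_panel, small_params):
        with pytest.raises(ValueError):
            cf.gen_spikein_series(small_panel, small_params, [], 6)

    def test_zero_ratio_matches_pooled_baseline(self, small_panel, small_params):
        """0% spike replicates fluctuate around the shared pool profile."""
        counts, meta = cf.gen_spikein_series(small_panel, small_params, [0.0], 6)
        m = cf.build_amf_matrix(counts, small_panel, cf.QCConfig(min_unique_molecules=0),
                                sample_order=meta["sample_id"].tolist())
        spread = m.std(axis=1)
        # technical replicates: only counting noise at depth ~50k per region
        assert spread.median() < 0.005
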