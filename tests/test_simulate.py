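"""Synthetic-data generators: shapes, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sickstate.simulate import (
    FosSimConfig,
    GeneSpec,
    SpatialSimConfig,
    UsvSimConfig,
    default_planted_map,
    generate_fos,
    generate_spatial,
    generate_usv,
)


class TestFos:
    def test_default_dimensions_and_positivity(self):
        table, truth = generate_fos()
        regions = [c for c in table.columns if c.startswith("region_")]
        assert table.shape[0] == 48 and len(regions) == 641
        assert (table[regions].to_numpy() > 0).all()
        assert set(table["condition"]) == set(FosSimConfig().conditions)

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = FosSimConfig(n_animals=12, n_regions=20, planted_map={}, seed=9)
        a, _ = generate_fos(cfg)
        b, _ = generate_fos(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_effect_recovered_empirically(self):
        # +2 sd on one region for one condition; estimate the standardized
        # group-mean shift on the log scale at large n
        cfg = FosSimConfig(
            n_animals=6000, n_regions=5, planted_map={"LPS": {2: 2.0}}, seed=3
        )
        table, _ = generate_fos(cfg)
        logx = np.log(table["region_0002"].to_numpy())
        lps = table["condition"] == "LPS"
        others = ~lps
        pooled_sd = np.std(logx[others], ddof=1)
        shift = (logx[lps].mean() - logx[others].mean()) / pooled_sd
        assert shift == pytest.approx(2.0, abs=0.1)

    def test_nonplanted_region_identical_across_conditions(self):
        cfg = FosSimConfig(
            n_animals=10_000, n_regions=4, planted_map={"DSS": {0: 1.5}}, seed=7
        )
        table, _ = generate_fos(cfg)
        a = table.loc[table["condition"] == "Saline", "region_0003"]
        b = table.loc[table["condition"] == "STAg", "region_0003"]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_ground_truth_consistent_with_matrix(self):
        pm = default_planted_map(n_regions=60, regions_per_condition=6, effect=2.0)
        cfg = FosSimConfig(n_animals=3000, n_regions=60, planted_map=pm, seed=5)
        table, truth = generate_fos(cfg)
        logx = np.log(table[truth.region_names].to_numpy())
        for cond, effects in truth.planted_map.items():
            rows = (table["condition"] == cond).to_numpy()
            for region, eff in effects.items():
                delta = logx[rows, region].mean() - logx[~rows, region].mean()
                assert np.sign(delta) == np.sign(eff)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_animals=0),
            dict(conditions=("only",)),
            dict(n_animals=3),  # fewer animals than conditions
            dict(planted_map={"LPS": {999: 1.0}}, n_regions=10),
            dict(planted_map={"LPS": {0: np.inf}}),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_fos(FosSimConfig(**bad))

    def test_confusable_pairs_share_half_their_regions(self):
        pm = default_planted_map(n_regions=100, regions_per_condition=10)
        shared = set(pm["STAg"]) & set(pm["DSS"])
        assert len(shared) == 5
        assert len(set(pm["LPS"]) & set(pm["pIC"])) == 5
        assert not set(pm["PLA2"]) & set(pm["LPS"])


class TestUsv:
    def test_shape_and_labels(self):
        cfg = UsvSimConfig(n_calls_per_condition=50, seed=1)
        t = generate_usv(cfg)
        feature_cols = [c for c in t.columns if c not in ("onset_s", "duration_ms", "condition")]
        assert len(feature_cols) == 35
        assert len(t) == 50 * 6
        assert (t["duration_ms"] > 0).all()
        for _, grp in t.groupby("condition"):
            assert (np.diff(grp["onset_s"]) >= 0).all()

    def test_fixed_seed_byte_identical(self):
        cfg = UsvSimConfig(n_calls_per_condition=30, seed=4)
        a, b = generate_usv(cfg), generate_usv(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_short_call_fraction_matches_normal_cdf(self):
        cfg = UsvSimConfig(
            n_calls_per_condition=1000,
            conditions=("Saline",),
            duration_mean_ms=10.0,
            duration_sd_ms=3.0,
            seed=11,
        )
        t = generate_usv(cfg)
        frac = float((t["duration_ms"] < 5.0).mean())
        expected = stats.norm.cdf((5 - 10) / 3)
        # binomial Monte-Carlo tolerance at n=1000
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 1000))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_usv(UsvSimConfig(n_calls_per_condition=0))
        with pytest.raises(ValueError):
            generate_usv(UsvSimConfig(n_features=3))


class TestSpatial:
    def test_outputs_and_de_table_shape(self):
        cfg = SpatialSimConfig(n_cells=300, seed=2)
        maps, de, truth = generate_spatial(cfg)
        assert set(maps) == {"treated", "control"}
        assert maps["treated"].n_cells == 300
        assert len(de) == len(cfg.genes) * cfg.n_cell_types
        assert de["padj"].between(0, 1).all()
        assert truth == {"focal_gene": "focal", "broad_gene": "broad", "null_gene": "null"}

    def test_planted_patterns_reflected_in_de(self):
        cfg = SpatialSimConfig(n_cells=1000, seed=8)
        _, de, _ = generate_spatial(cfg)
        broad = de[de["gene"] == "broad_gene"]
        null = de[de["gene"] == "null_gene"]
        # broad gene is upregulated everywhere at the planted magnitude
        assert (broad["log2fc"] > 2.0).all() and (broad["padj"] < 0.01).all()
        assert null["log2fc"].abs().max() < 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_spatial(SpatialSimConfig(arena_size=0.0))
        with pytest.raises(ValueError):
            generate_spatial(SpatialSimConfig(n_cells=5))
        with pytest.raises(ValueError):
            generate_spatial(SpatialSimConfig(genes=(GeneSpec("g", "weird"),)))

    def test_fixed_seed_reproducible(self):
        cfg = SpatialSimConfig(n_cells=100, seed=6)
        m1, de1, _ = generate_spatial(cfg)
        m2, de2, _ = generate_spatial(cfg)
        np.testing.assert_array_equal(m1["treated"].coords, m2["treated"].coords)
        pd.testing.assert_frame_equal(de1, de2)
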