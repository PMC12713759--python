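"""Moran's I, delta Moran's I, and specificity counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from oracles import morans_i_bruteforce
from sickstate.simulate import SpatialSimConfig, generate_spatial
from sickstate.spatial import (
    LAX_THRESHOLDS,
    SpatialCellMap,
    delta_morans_i,
    knn_weights,
    morans_i,
    row_standardize,
    specificity_count,
)

# 2x2 grid, rook adjacency, binary weights
CHECKER_W = sparse.csr_matrix(
    np.array(
        [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], dtype=float
    )
)
CHECKER_X = np.array([1.0, -1.0, -1.0, 1.0])


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        assert morans_i(CHECKER_X, CHECKER_W) == pytest.approx(-1.0, abs=1e-12)
        assert morans_i(CHECKER_X, CHECKER_W) == pytest.approx(
            morans_i_bruteforce(CHECKER_X, CHECKER_W), abs=1e-12
        )

    def test_row_standardization_keeps_checkerboard_sign(self):
        assert morans_i(CHECKER_X, row_standardize(CHECKER_W)) < 0

    def test_matches_bruteforce_on_random_maps(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 15))
            coords = rng.uniform(0, 10, (n, 2))
            W = knn_weights(coords, k=min(3, n - 2))
            x = rng.standard_normal(n)
            assert morans_i(x, W) == pytest.approx(morans_i_bruteforce(x, W), abs=1e-10)

    def test_permutation_expectation(self, rng):
        n = 40
        coords = rng.uniform(0, 10, (n, 2))
        W = knn_weights(coords, k=4)
        x = rng.standard_normal(n)
        vals = [morans_i(rng.permutation(x), W) for _ in range(1000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-1 / (n - 1))) <= 3 * se

    def test_smooth_gradient_positive(self):
        g = np.arange(6)
        coords = np.array([[i, j] for i in g for j in g], float)
        x = coords[:, 0] + coords[:, 1]
        assert morans_i(x, knn_weights(coords, k=4)) > 0.5

    def test_degenerate_inputs_rejected(self, rng):
        coords = rng.uniform(0, 1, (10, 2))
        W = knn_weights(coords, k=3)
        with pytest.raises(ValueError, match="zero variance|constant"):
            morans_i(np.ones(10), W)
        with pytest.raises(ValueError):
            morans_i(rng.standard_normal(3), sparse.eye(3))
        with pytest.raises(ValueError, match="empty"):
            morans_i(rng.standard_normal(10), sparse.csr_matrix((10, 10)))


@pytest.fixture(scope="module")
def spatial_maps():
    cfg = SpatialSimConfig(n_cells=1200, seed=42)
    maps, de, truth = generate_spatial(cfg)
    return maps, de, truth


class TestDeltaMoransI:
    def test_identical_maps_give_zero(self, spatial_maps):
        maps, _, _ = spatial_maps
        m = maps["treated"]
        assert delta_morans_i(m, m, "focal_gene") == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, spatial_maps):
        maps, _, _ = spatial_maps
        d = delta_morans_i(maps["treated"], maps["control"], "focal_gene")
        flipped = delta_morans_i(maps["control"], maps["treated"], "focal_gene")
        assert d == pytest.approx(-flipped, abs=1e-12)

    def test_focal_positive_broad_and_null_near_zero(self, spatial_maps):
        maps, _, _ = spatial_maps
        d_focal = delta_morans_i(maps["treated"], maps["control"], "focal_gene")
        d_broad = delta_morans_i(maps["treated"], maps["control"], "broad_gene")
        d_null = delta_morans_i(maps["treated"], maps["control"], "null_gene")
        assert d_focal > 0.05
        assert abs(d_broad) < 0.05 and abs(d_null) < 0.05
        assert d_focal > d_broad and d_focal > d_null

    def test_pooled_mode_agrees_in_sign(self, spatial_maps):
        maps, _, _ = spatial_maps
        d = delta_morans_i(maps["treated"], maps["control"], "focal_gene", per_animal=False)
        assert d > 0

    def test_missing_gene_rejected(self, spatial_maps):
        maps, _, _ = spatial_maps
        with pytest.raises(KeyError, match="absent"):
            delta_morans_i(maps["treated"], maps["control"], "no_such_gene")


class TestSpecificityCount:
    TABLE = pd.DataFrame(
        {
            "gene": ["g1"] * 10 + ["g2"] * 4,
            "cell_type": [f"t{i}" for i in range(10)] + [f"t{i}" for i in range(4)],
            "log2fc": [2.5, 2.5, 2.5] + [0.5] * 7 + [2.0, 1.0, 3.0, 0.0],
            "padj": [0.005] * 3 + [0.5] * 7 + [0.005, 0.02, 0.005, 0.9],
        }
    )

    def test_direct_count(self):
        counts = specificity_count(self.TABLE)
        assert counts["g1"] == 3

    def test_boundary_log2fc_strict_vs_lax(self):
        # log2FC exactly 2 is excluded under the strict preset ...
        strict = specificity_count(self.TABLE)
        assert strict["g2"] == 1  # only the 3.0 entry
        # ... while log2FC exactly 1 counts under the lax preset
        lax = specificity_count(self.TABLE, **LAX_THRESHOLDS)
        assert lax["g2"] == 3  # 2.0, 1.0 and 3.0 entries

    def test_empty_table_counts_zero(self):
        counts = specificity_count(pd.DataFrame(), genes=["a", "b"])
        assert (counts == 0).all()

    def test_monotone_in_thresholds(self, rng):
        table = pd.DataFrame(
            {
                "gene": rng.choice(["a", "b", "c"], 60),
                "cell_type": rng.choice([f"t{i}" for i in range(8)], 60),
                "log2fc": rng.normal(1.5, 1.5, 60),
                "padj": rng.uniform(0, 1, 60),
            }
        ).drop_duplicates(["gene", "cell_type"])
        tight = specificity_count(table, genes=list("abc"))
        loose = specificity_count(table, genes=list("abc"), **LAX_THRESHOLDS)
        assert (loose >= tight).all()

    def test_malformed_tables_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            specificity_count(pd.DataFrame({"gene": ["g"], "padj": [0.1]}))
        bad = self.TABLE.copy()
        bad.loc[0, "padj"] = 1.5
        with pytest.raises(ValueError, match="adjusted p"):
            specificity_count(bad)


class TestCellMap:
    def test_shape_validation(self, rng):
        with pytest.raises(ValueError):
            SpatialCellMap(
                coords=rng.uniform(0, 1, (5, 3)),
                expression=pd.DataFrame({"g": np.ones(5)}),
                condition="c",
            )
        with pytest.raises(ValueError):
            SpatialCellMap(
                coords=rng.uniform(0, 1, (5, 2)),
                expression=pd.DataFrame({"g": np.ones(4)}),
                condition="c",
            )

    def test_to_frame_roundtrip_columns(self, spatial_maps):
        maps, _, _ = spatial_maps
        df = maps["treated"].to_frame()
        assert {"x", "y", "condition", "animal", "cell_type", "focal_gene"} <= set(df.columns)
        assert len(df) == maps["treated"].n_cells
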