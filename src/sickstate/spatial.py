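"""Moran's I spatial autocorrelation, the differential (delta) Moran's I,
and cell-type specificity counting of upregulated genes.

Moran's I over a spatial weight graph W,

    I = (n / W_sum) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

is positive when a gene's expression is spatially clustered and has
expectation -1/(n-1) under spatial randomness. The delta statistic
I(treated) - I(control) separates focal (region-specific) upregulation,
which raises spatial autocorrelation in treated tissue, from broad
upregulation, which does not. The weight graph is k-nearest-neighbor on
cell coordinates (default k = 6), symmetrized and row-standardized; the
delta is computed per animal and averaged, with a pooled mode available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpatialCellMap:
    """Per-cell coordinates, expression and labels for one condition."""

    coords: np.ndarray  # (n, 2)
    expression: pd.DataFrame  # n x genes
    condition: str
    cell_types: np.ndarray | None = None
    animals: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.expression) != self.coords.shape[0]:
            raise ValueError("expression rows must match coords")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y"])
        df["condition"] = self.condition
        if self.animals is not None:
            df["animal"] = self.animals
        if self.cell_types is not None:
            df["cell_type"] = self.cell_types
        return pd.concat([df, self.expression.reset_index(drop=True)], axis=1)


def knn_weights(coords: np.ndarray, k: int = 6) -> sparse.csr_matrix:
    """Symmetrized, row-standardized k-nearest-neighbor weights (no self)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells to build a kNN graph")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    A = nn.kneighbors_graph(coords, mode="connectivity")
    A = A.tolil()
    A.setdiag(0)
    A = A.tocsr()
    A = ((A + A.T) > 0).astype(float)  # symmetrize by union
    return row_standardize(A)


def row_standardize(W: sparse.spmatrix) -> sparse.csr_matrix:
    W = sparse.csr_matrix(W, dtype=float)
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    return sparse.diags(inv) @ W


def morans_i(values, weights: sparse.spmatrix) -> float:
    """Global Moran's I of ``values`` over the weight graph."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("morans_i requires at least 4 observations")
    W = sparse.csr_matrix(weights, dtype=float)
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match values")
    w_sum = W.sum()
    if w_sum == 0:
        raise ValueError("empty weight graph")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined (zero variance)")
    return float((n / w_sum) * (z @ (W @ z)) / denom)


def _map_morans_i(cell_map: SpatialCellMap, gene: str, k: int, log1p: bool,
                  per_animal: bool) -> float:
    if gene not in cell_map.expression.columns:
        raise KeyError(f"gene {gene!r} absent from the {cell_map.condition} map")
    x = cell_map.expression[gene].to_numpy(float)
    if log1p:
        x = np.log1p(x)
    if per_animal and cell_map.animals is not None:
        vals = []
        for a in np.unique(cell_map.animals):
            mask = cell_map.animals == a
            if mask.sum() <= k + 1:
                continue
            W = knn_weights(cell_map.coords[mask], k=k)
            vals.append(morans_i(x[mask], W))
        if not vals:
            raise ValueError("no animal section large enough for the kNN graph")
        return float(np.mean(vals))
    W = knn_weights(cell_map.coords, k=k)
    return morans_i(x, W)


def delta_morans_i(
    treated: SpatialCellMap,
    control: SpatialCellMap,
    gene: str,
    *,
    k: int = 6,
    log1p: bool = True,
    per_animal: bool = True,
) -> float:
    """Delta Moran's I = I(treated) - I(control) for one gene.

    With ``per_animal=True`` (default) I is computed per animal section and
    averaged within each condition before differencing.
    """
    it = _map_morans_i(treated, gene, k, log1p, per_animal)
    ic = _map_morans_i(control, gene, k, log1p, per_animal)
    return it - ic


# preset thresholds for upregulation calls
STRICT_THRESHOLDS = {"padj_max": 0.01, "lfc_min": 2.0, "lfc_strict": True}
LAX_THRESHOLDS = {"padj_max": 0.05, "lfc_min": 1.0, "lfc_strict": False}


def specificity_count(
    de_table: pd.DataFrame,
    *,
    padj_max: float = 0.01,
    lfc_min: float = 2.0,
    lfc_strict: bool = True,
    genes=None,
) -> pd.Series:
    """Per-gene count of cell types in which the gene is upregulated.

    Default thresholds are the stringent preset (adjusted p < 0.01 and
    log2FC > 2, strict); the lax preset (adjusted p < 0.05 and log2FC >= 1)
    is available as ``**LAX_THRESHOLDS``. Genes absent from the table (or
    an empty table) count 0.
    """
    required = {"gene", "cell_type", "log2fc", "padj"}
    if not de_table.empty:
        missing = required - set(de_table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        bad = de_table[(de_table["padj"] < 0) | (de_table["padj"] > 1)]
        if not bad.empty:
            raise ValueError("adjusted p-values must lie in [0, 1]")
    if de_table.empty:
        hits = pd.Series(dtype=int)
    else:
        up = de_table["padj"] < padj_max
        if lfc_strict:
            up &= de_table["log2fc"] > lfc_min
        else:
            up &= de_table["log2fc"] >= lfc_min
        hits = de_table[up].groupby("gene")["cell_type"].nunique()
    if genes is not None:
        hits = hits.reindex(list(genes), fill_value=0)
    return hits.astype(int).rename("n_cell_types_upregulated")
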