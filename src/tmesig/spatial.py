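"""Spatial organization analyses.

Pairwise cell-cell interaction scores with a label-permutation null
(radius method: neighbors within 30 µm capped at the 10 nearest), cellular
neighborhoods from 10-nearest-neighbor composition vectors clustered by
k-means into ten groups, OLS differential enrichment of cell types across
neighborhoods by binary outcome, and per-patient neighborhood frequencies
compared by Welch t-tests.

All neighbor relations are computed within a region (a tissue core / ROI);
coordinates are assumed to be in physical µm already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .synthetic import SpatialCellTable

__all__ = [
    "InteractionMatrix",
    "NeighborhoodModel",
    "neighbor_query",
    "interaction_scores",
    "neighborhood_features",
    "cluster_neighborhoods",
    "neighborhood_enrichment",
    "neighborhood_frequency_by_outcome",
]


@dataclass
class InteractionMatrix:
    score: pd.DataFrame        # type x type observed interaction scores
    zscore: pd.DataFrame       # vs the permutation null
    pvalue: pd.DataFrame       # two-sided permutation p
    radius_um: float
    k: int
    n_permutations: int


@dataclass
class NeighborhoodModel:
    features: pd.DataFrame     # per-cell composition vectors (simplex rows)
    assignments: pd.Series     # per-cell cluster id (0..n_clusters-1)
    centroids: pd.DataFrame    # cluster x cell-type centroid compositions
    annotations: Dict[int, str]
    n_clusters: int
    seed: int
    flagged_cells: pd.Series   # cells with fewer than k available neighbors


def _regions(table: SpatialCellTable):
    for rid, idx in table.data.groupby("region_id", sort=True).indices.items():
        yield rid, np.asarray(idx)


def neighbor_query(table: SpatialCellTable,
                   mode: Literal["radius", "knn"] = "radius",
                   radius_um: float = 30.0, k: int = 10
                   ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Per-cell neighbor index lists (indices into the table's row order).

    ``radius`` mode returns all cells within ``radius_um`` capped at the k
    nearest (both constraints honored); ``knn`` returns the k nearest.  Self
    is always excluded; Euclidean metric; neighbors never cross regions.
    Returns (lists, flagged) where ``flagged`` marks cells whose list has
    fewer than k entries (including singleton regions, which get empty
    lists).
    """
    n = len(table)
    xy_all = table.data[["x_um", "y_um"]].to_numpy(dtype=float)
    out: List[Optional[np.ndarray]] = [None] * n
    flagged = np.zeros(n, dtype=bool)
    for rid, idx in _regions(table):
        if idx.size < 2:
            for i in idx:
                out[i] = np.empty(0, dtype=np.int64)
                flagged[i] = True
            continue
        xy = xy_all[idx]
        tree = cKDTree(xy)
        kk = min(k + 1, idx.size)
        dist, nbr = tree.query(xy, k=kk)
        for row in range(idx.size):
            d, nb = dist[row], nbr[row]
            keep = nb != row
            d, nb = d[keep], nb[keep]
            if mode == "radius":
                within = d <= radius_um
                d, nb = d[within], nb[within]
            nb = nb[:k]
            out[idx[row]] = idx[nb].astype(np.int64)
            if nb.size < k:
                flagged[idx[row]] = True
    return out, flagged  # type: ignore[return-value]


def _neighbor_padded(table: SpatialCellTable, mode, radius_um, k):
    """Neighbor lists as a padded (n, k) int array with -1 fill."""
    lists, flagged = neighbor_query(table, mode, radius_um, k)
    n = len(lists)
    padded = np.full((n, k), -1, dtype=np.int64)
    for i, nb in enumerate(lists):
        padded[i, :nb.size] = nb
    return padded, flagged


def interaction_scores(table: SpatialCellTable, radius_um: float = 30.0,
                       k: int = 10, n_permutations: int = 1000,
                       seed: int = 0) -> InteractionMatrix:
    """Pairwise interaction analysis against a label-permutation null.

    score(A->B) = mean over type-A cells of the proportion of their
    neighbors (radius method) that are type B.  The null shuffles labels
    within each region, preserving geometry; z-scores and two-sided
    permutation p-values are reported per ordered pair.  Types absent from
    the table yield NA rows/columns.
    """
    padded, _ = _neighbor_padded(table, "radius", radius_um, k)
    n = len(table)
    n_nb = (padded >= 0).sum(axis=1)
    if (n_nb > 0).mean() < 0.5:
        warnings.warn("fewer than half of cells have any neighbors at this "
                      "radius", stacklevel=2)
    types = sorted(table.data["cell_type"].unique())
    T = len(types)
    tcode = table.data["cell_type"].map({t: i for i, t in enumerate(types)})
    labels = tcode.to_numpy(dtype=np.int64)

    region_codes = table.data["region_id"].to_numpy()
    rng = np.random.default_rng(seed)

    safe = np.where(padded >= 0, padded, 0)
    valid = padded >= 0
    has_nb = n_nb > 0

    def scores_for(lab: np.ndarray) -> np.ndarray:
        # per-cell neighbor-type proportions
        nb_lab = lab[safe]
        sc = np.full((T, T), np.nan)
        rows = np.repeat(np.arange(n), valid.sum(axis=1))
        counts = np.zeros((n, T), dtype=np.float64)
        flat = nb_lab[valid] + T * rows
        np.add.at(counts.reshape(-1), flat, 1.0)
        prop = counts[has_nb] / n_nb[has_nb][:, None]
        lab_h = lab[has_nb]
        for a in range(T):
            m = lab_h == a
            if m.any():
                sc[a] = prop[m].mean(axis=0)
        return sc

    obs = scores_for(labels)

    null = np.empty((n_permutations, T, T))
    # permute labels within region
    region_groups = [np.asarray(ix) for _, ix in
                     table.data.groupby("region_id", sort=True).indices.items()]
    for p in range(n_permutations):
        lab = labels.copy()
        for ix in region_groups:
            lab[ix] = lab[rng.permutation(ix)]
        null[p] = scores_for(lab)

    mu = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    dev_null = np.abs(null - mu[None, :, :])
    dev_obs = np.abs(obs - mu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        exceed = np.nansum(dev_null >= dev_obs[None, :, :] - 1e-15, axis=0)
    pval = (1.0 + exceed) / (n_permutations + 1.0)
    pval = np.where(np.isnan(obs), np.nan, pval)

    mk = lambda a: pd.DataFrame(a, index=types, columns=types)
    return InteractionMatrix(mk(obs), mk(z), mk(pval), radius_um, k,
                             n_permutations)


def neighborhood_features(table: SpatialCellTable, k: int = 10,
                          types: Optional[Sequence[str]] = None
                          ) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-cell composition of the k nearest neighbors' cell types.

    Rows sum to 1.  Regions with fewer than k+1 cells use all available
    neighbors and are flagged; an empty table is an error.
    """
    if len(table) == 0:
        raise ValueError("empty spatial table")
    padded, flagged = _neighbor_padded(table, "knn", np.inf, k)
    if types is None:
        types = sorted(table.data["cell_type"].unique())
    tmap = {t: i for i, t in enumerate(types)}
    labels = table.data["cell_type"].map(tmap).to_numpy()
    n, T = len(table), len(types)
    valid = padded >= 0
    n_nb = valid.sum(axis=1)
    if np.any(n_nb == 0):
        raise ValueError("cells with no neighbors; regions need >= 2 cells")
    counts = np.zeros((n, T))
    rows = np.repeat(np.arange(n), n_nb)
    flat = labels[padded[valid]] + T * rows
    np.add.at(counts.reshape(-1), flat, 1.0)
    comp = counts / n_nb[:, None]
    feats = pd.DataFrame(comp, index=table.data["cell_id"].to_numpy(),
                         columns=list(types))
    return feats, pd.Series(flagged, index=feats.index, name="flagged")


def cluster_neighborhoods(features: pd.DataFrame, n_clusters: int = 10,
                          seed: int = 0, n_init: int = 10,
                          flagged: Optional[pd.Series] = None
                          ) -> NeighborhoodModel:
    """K-means clustering of composition vectors into spatial neighborhoods.

    Deterministic under a fixed seed.  If the data hold fewer distinct
    vectors than clusters, the cluster count is reduced with a warning.
    Clusters are annotated post hoc by their dominant centroid cell types.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < n_clusters:
        raise ValueError("fewer cells than clusters")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < n_clusters:
        warnings.warn(f"only {n_distinct} distinct composition vectors; "
                      f"reducing clusters from {n_clusters}", stacklevel=2)
        n_clusters = n_distinct
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    assign = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=features.columns)
    annotations = {}
    for c in range(n_clusters):
        top = centroids.iloc[c].sort_values(ascending=False)
        annotations[c] = "/".join(top.index[:2])
    if flagged is None:
        flagged = pd.Series(False, index=features.index)
    return NeighborhoodModel(features, pd.Series(assign, index=features.index,
                                                 name="neighborhood"),
                             centroids, annotations, n_clusters, seed, flagged)


def _cells_with_assignment(model: NeighborhoodModel, table: SpatialCellTable
                           ) -> pd.DataFrame:
    df = table.data.set_index("cell_id")
    return df.assign(neighborhood=model.assignments.reindex(df.index))


def neighborhood_enrichment(model: NeighborhoodModel, table: SpatialCellTable,
                            outcome: pd.Series) -> pd.DataFrame:
    """OLS differential enrichment of cell types across neighborhoods.

    For each (neighborhood, cell type): per-patient composition of that type
    within the neighborhood's cells is regressed on the binary outcome; the
    coefficient is reported on a log2 fold-change scale with its t-test p,
    BH-adjusted across all performed tests.  Neighborhood/type combinations
    absent in a group are NA and excluded from the BH family.
    """
    df = _cells_with_assignment(model, table)
    patients = df["patient_id"].unique()
    out = outcome.reindex(patients)
    if out.isna().any():
        raise ValueError("outcome missing for some patients")
    for v in (0, 1):
        if (out == v).sum() < 2:
            raise ValueError("need at least 2 patients per outcome group")
    types = list(model.features.columns)
    eps = 1e-3
    rows = []
    for nb in sorted(df["neighborhood"].dropna().unique()):
        sub = df[df["neighborhood"] == nb]
        comp = (sub.groupby("patient_id")["cell_type"]
                .value_counts(normalize=True).unstack(fill_value=0.0)
                .reindex(columns=types, fill_value=0.0))
        y_out = out.reindex(comp.index).to_numpy(dtype=float)
        groups_present = len(np.unique(y_out)) == 2
        for ct in types:
            if not groups_present or len(comp) < 4:
                rows.append((nb, ct, np.nan, np.nan))
                continue
            y = np.log2(comp[ct].to_numpy() + eps)
            Xd = sm.add_constant(y_out)
            res = sm.OLS(y, Xd).fit()
            rows.append((nb, ct, float(res.params[1]), float(res.pvalues[1])))
    tbl = pd.DataFrame(rows, columns=["neighborhood", "cell_type",
                                      "log2_fc", "p"])
    mask = tbl["p"].notna()
    adj = np.full(len(tbl), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(tbl.loc[mask, "p"],
                                             method="fdr_bh")[1]
    tbl["p_adj"] = adj
    return tbl


def neighborhood_frequency_by_outcome(model: NeighborhoodModel,
                                      table: SpatialCellTable,
                                      outcome: pd.Series) -> pd.DataFrame:
    """Per-patient neighborhood frequencies with Welch t-tests by outcome.

    A patient's frequency vector is the fraction of their cells assigned to
    each neighborhood (sums to 1).  Groups with fewer than 2 patients yield
    NA p-values.
    """
    df = _cells_with_assignment(model, table)
    freq = (df.groupby("patient_id")["neighborhood"]
            .value_counts(normalize=True).unstack(fill_value=0.0)
            .reindex(columns=range(model.n_clusters), fill_value=0.0))
    out = outcome.reindex(freq.index)
    rows = []
    for nb in freq.columns:
        a = freq.loc[out == 1, nb].to_numpy()
        b = freq.loc[out == 0, nb].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append((nb, a.mean() if a.size else np.nan,
                         b.mean() if b.size else np.nan, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(t):  # identical constant groups
            t, p = 0.0, 1.0
        rows.append((nb, float(a.mean()), float(b.mean()), float(t), float(p)))
    return pd.DataFrame(rows, columns=["neighborhood", "mean_freq_group1",
                                       "mean_freq_group0", "t", "p"])
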