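"""Cross-sample analyses: region similarity and two-group comparison.

The group comparison follows the multiple-t-tests design used for the
control vs disease-model cohorts: one two-sample Student t test (equal
variance, two-sided) per region on per-starter-neuron densities, with the
family-wise Holm-Sidak step-down adjustment over exactly the regions passed
in, significance at adjusted p < alpha, and means +/- SEM reported per
group.

The similarity analysis correlates per-sample density vectors between
regions (Pearson by default, Spearman behind a flag) and clusters regions
hierarchically on distance ``1 - r`` with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

RESULT_COLUMNS = [
    "region",
    "mean_con",
    "sem_con",
    "mean_ad",
    "sem_ad",
    "t_stat",
    "df",
    "p_raw",
    "p_adj",
    "significant",
    "n_con",
    "n_ad",
]


@dataclass
class SimilarityMatrix:
    """Pairwise region correlations with a hierarchical clustering."""

    regions: list
    matrix: pd.DataFrame  # symmetric, unit diagonal
    linkage: np.ndarray  # scipy linkage matrix on 1 - r
    cluster_labels: dict  # region -> cluster id at the stated cut
    cut_distance: float


def similarity_matrix(
    density_table: pd.DataFrame,
    method: str = "pearson",
    linkage_method: str = "average",
    cut_distance: float = 0.5,
) -> SimilarityMatrix:
    """Correlate region density columns across samples and cluster regions.

    ``density_table`` has one row per sample and one column per region.
    Requires >= 3 samples, >= 2 regions, no missing values, and nonzero
    variance in every column (a constant column has undefined correlation).
    Clustering is deterministic given column order; scipy's linkage breaks
    ties by input order.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if density_table.shape[0] < 3:
        raise ValueError("similarity matrix requires >= 3 samples")
    if density_table.shape[1] < 2:
        raise ValueError("similarity matrix requires >= 2 regions")
    if density_table.isna().any().any():
        bad = density_table.columns[density_table.isna().any()].tolist()
        rows = density_table.index[density_table.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in regions {bad} (samples {rows})")
    variances = density_table.var(axis=0, ddof=0)
    zero_var = variances[variances == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance region column(s): {zero_var}; correlation undefined")
    corr = density_table.corr(method=method)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method=linkage_method)
    flat = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    clusters = {region: int(c) for region, c in zip(density_table.columns, flat)}
    return SimilarityMatrix(
        regions=list(density_table.columns),
        matrix=corr,
        linkage=link,
        cluster_labels=clusters,
        cut_distance=cut_distance,
    )


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p values, returned in input order.

    With raw p values sorted ascending, the rank-i (1-based) adjusted value
    is ``1 - (1 - p_(i))^(m - i + 1)``; a running maximum enforces
    monotonicity and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _ttest_equal_var(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Pooled-variance two-sample t test; degenerate zero-spread -> t=0, p=1."""
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    df = len(a) + len(b) - 2
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, df
        return float(np.inf) if a.mean() > b.mean() else float(-np.inf), 0.0, df
    return t, p, df


def group_compare(
    con: pd.DataFrame,
    ad: pd.DataFrame,
    regions: list | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Region-wise two-group comparison with Holm-Sidak correction.

    ``con`` and ``ad`` hold one row per sample and one density column per
    region. The multiple-testing family is exactly the listed regions
    (default: all shared columns, in ``con``'s order). Returns one row per
    region with group means, SEMs, t, df, raw and adjusted p, and the
    significance flag at ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if regions is None:
        regions = [r for r in con.columns if r in set(ad.columns)]
    for name, table in (("CON", con), ("AD", ad)):
        if table.shape[0] < 2:
            raise ValueError(f"{name} group needs >= 2 samples for a t test")
        missing = [r for r in regions if r not in table.columns]
        if missing:
            raise ValueError(f"regions {missing} missing from {name} tables")
    rows = []
    for region in regions:
        a = con[region].to_numpy(dtype=float)
        b = ad[region].to_numpy(dtype=float)
        if equal_var:
            t, p, df = _ttest_equal_var(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        rows.append(
            {
                "region": region,
                "mean_con": float(a.mean()),
                "sem_con": float(stats.sem(a)),
                "mean_ad": float(b.mean()),
                "sem_ad": float(stats.sem(b)),
                "t_stat": t,
                "df": df,
                "p_raw": p,
                "n_con": len(a),
                "n_ad": len(b),
            }
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = holm_sidak_adjust(result["p_raw"].to_numpy())
    result["significant"] = result["p_adj"] < alpha
    return result[RESULT_COLUMNS]


def densities_wide(quant_tables: dict[str, pd.DataFrame], key: str = "region_label") -> pd.DataFrame:
    """Stack per-sample region-quantification tables into samples x regions.

    ``quant_tables`` maps sample id -> a table from
    :func:`synaptomap.quantify.quantify_sample`; the wide result holds the
    density column, indexed by sample, one column per region.
    """
    frames = {}
    for sample, table in quant_tables.items():
        frames[sample] = table.set_index(key)["syp_density_per_mm3_per_neuron"]
    wide = pd.DataFrame(frames).T
    wide.index.name = "sample"
    return wide
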