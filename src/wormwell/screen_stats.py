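"""Screen-level statistics: hit calling, normalization, clustering, qPCR.

Hit calling compares each RNAi clone's replicate intensities (by default the
background-adjusted 90th-percentile statistic) against the pooled
vector-control replicates of the same strain with an unequal-variance
(Welch) two-tailed t-test, corrected for multiple hypothesis testing across
all genes tested in that strain.  Plain Bonferroni is the default stringent
cutoff; the Bonferroni step-down (Holm) correction is also provided and is
uniformly at least as powerful at the same family-wise error rate.

Gene x strain matrices are log2 transformed and quantile normalized before
k-means clustering; the number of clusters is chosen by least squares (the
within-cluster total sum of squares as a function of k): the first strict
local minimum, or the elbow (largest second difference) when the curve is
monotone.  Columns (mutant backgrounds) are ordered by complete-linkage
hierarchical clustering and cluster separation is visualized with the first
two principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

TABLE_COLUMNS = ["gene", "strain", "replicate", "value"]


@dataclass(frozen=True)
class ScreenTable:
    """Long-form (gene, strain, replicate, value) measurements.

    ``control_label`` names the gene entry that marks vector-control wells;
    all control replicates of a strain are pooled into that strain's single
    control sample.
    """

    table: pd.DataFrame
    control_label: str = "control"

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"screen table missing columns: {missing}")
        if not np.isfinite(df["value"].to_numpy(float)).all():
            raise ValueError("screen table contains non-finite values")
        for strain, sub in df.groupby("strain"):
            if not (sub["gene"] == self.control_label).any():
                raise ValueError(f"strain {strain!r} has no {self.control_label!r} wells")

    @property
    def strains(self) -> list:
        return sorted(self.table["strain"].unique())


@dataclass(frozen=True)
class ClusterResult:
    """k-means model-selection output for a genes x strains matrix."""

    matrix: pd.DataFrame  # normalized genes x strains
    wss_by_k: dict[int, float]
    k_selected: int
    assignments: np.ndarray  # in [1, k_selected], aligned with matrix rows
    column_order: list
    pc_coordinates: np.ndarray  # first two principal components per gene
    no_local_minimum: bool


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-tailed p).

    Degenerate spread is handled by convention: two constant groups with
    equal means give p = 1; with different means, p = 0 (t = +/-inf).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t_test requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def multiple_test_correct(
    p, method: str = "bonferroni", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni or Holm (step-down) adjusted p-values and rejection flags."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"method must be bonferroni or holm, got {method!r}")
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    return p_adj, reject


def call_hits(
    table: ScreenTable,
    alpha: float = 0.05,
    method: str = "bonferroni",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch tests against the pooled strain control, corrected per strain.

    Returns one row per gene x strain with columns gene, strain, n_treat,
    n_ctrl, fold_change (ratio of arithmetic means; of log-scale means when
    ``log_scale``), t, df, p_raw, p_bonferroni, p_holm and ``significant``
    at the stated alpha under the chosen correction.  Genes with fewer than
    2 replicates are skipped.
    """
    rows = []
    for strain, sub in table.table.groupby("strain"):
        ctrl = sub.loc[sub["gene"] == table.control_label, "value"].to_numpy(float)
        if ctrl.size < 2:
            raise ValueError(f"strain {strain!r}: control has fewer than 2 replicates")
        if log_scale:
            ctrl = np.log2(ctrl)
        strain_rows = []
        for gene, g in sub[sub["gene"] != table.control_label].groupby("gene"):
            treat = g["value"].to_numpy(float)
            if treat.size < 2:
                continue  # logged by caller; cannot test a single replicate
            if log_scale:
                treat = np.log2(treat)
            t, df, p = welch_t_test(treat, ctrl)
            fold = float(treat.mean() / ctrl.mean()) if ctrl.mean() != 0 else float("nan")
            strain_rows.append(
                {"gene": gene, "strain": strain, "n_treat": treat.size, "n_ctrl": ctrl.size,
                 "fold_change": fold, "t": t, "df": df, "p_raw": p}
            )
        if not strain_rows:
            continue
        sf = pd.DataFrame(strain_rows)
        sf["p_bonferroni"], rej_b = multiple_test_correct(sf["p_raw"], "bonferroni", alpha)
        sf["p_holm"], rej_h = multiple_test_correct(sf["p_raw"], "holm", alpha)
        sf["significant"] = rej_b if method == "bonferroni" else rej_h
        rows.append(sf)
    return pd.concat(rows, ignore_index=True)


def anova_bonferroni(groups, comparisons=None, alpha: float = 0.05):
    """One-way ANOVA with Bonferroni-corrected pairwise (pooled-t) comparisons.

    ``comparisons`` is a list of (i, j) group-index pairs; default all pairs.
    Returns ``(F, p_anova, DataFrame[i, j, t, p_raw, p_adj, significant])``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("anova requires >=2 groups with >=2 values each")
    pooled = np.concatenate(groups)
    if pooled.var(ddof=0) == 0:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = (float(x) for x in sps.f_oneway(*groups))
    if comparisons is None:
        comparisons = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    rows = []
    for i, j in comparisons:
        a, b = groups[i], groups[j]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (
                float(np.sign(a.mean() - b.mean()) * np.inf), 0.0)
        else:
            t, p = (float(x) for x in sps.ttest_ind(a, b, equal_var=True))
        rows.append({"i": i, "j": j, "t": t, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"], df["significant"] = multiple_test_correct(df["p_raw"], "bonferroni", alpha)
    return F, p_anova, df


def log2_quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 transform then classic quantile normalization across columns.

    Each column's rank-r value is replaced by the mean of the r-th order
    statistics across columns; tied values within a column receive the mean
    of their ranks' reference values.  Requires strictly positive input.
    """
    df = pd.DataFrame(matrix).astype(float)
    bad = df.le(0)
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"non-positive value at ({r!r}, {c!r}): {df.loc[r, c]}")
    X = np.log2(df.to_numpy())
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = np.empty(X.shape[0])
        col[order[:, j]] = ref
        # ties share the mean of the reference values their ranks received
        col = pd.Series(col).groupby(X[:, j]).transform("mean").to_numpy()
        out[:, j] = col
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def kmeans_select_k(
    matrix,
    k_range=range(1, 16),
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """k-means over a range of k, selecting k by least squares.

    For each k the best of ``n_restarts`` k-means++ runs (by within-cluster
    total sum of squares, wss) is kept.  The selected k is the first strict
    local minimum of wss as a function of k; when the curve is monotone the
    elbow (largest second difference) is used instead and the result is
    flagged ``no_local_minimum``.  Fully reproducible for a fixed seed.
    """
    df = pd.DataFrame(matrix).astype(float)
    X = df.to_numpy()
    ks = sorted(k_range)
    if ks[-1] > X.shape[0]:
        raise ValueError(f"k_range max {ks[-1]} exceeds row count {X.shape[0]}")
    wss_by_k: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for i, k in enumerate(ks):
        km = KMeans(
            n_clusters=k, n_init=n_restarts, init="k-means++",
            tol=1e-8, random_state=(seed + 7919 * i) % (2**31 - 1),
        ).fit(X)
        wss_by_k[k] = float(km.inertia_)
        models[k] = km

    wss = np.array([wss_by_k[k] for k in ks])
    k_selected = None
    for i in range(1, len(ks) - 1):
        if wss[i] < wss[i - 1] and wss[i] < wss[i + 1]:
            k_selected = ks[i]
            break
    no_local_minimum = k_selected is None
    if no_local_minimum:
        if len(ks) >= 3:
            second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
            k_selected = ks[1 + int(np.argmax(second_diff))]
        else:
            k_selected = ks[int(np.argmin(wss))]

    assignments = models[k_selected].labels_ + 1
    column_order, _ = (
        hierarchical_cluster_columns(df) if df.shape[1] >= 2 else (list(df.columns), None)
    )
    pcs = pca_clusters(df, assignments)[0] if df.shape[0] >= 2 else np.zeros((df.shape[0], 2))
    return ClusterResult(
        matrix=df, wss_by_k=wss_by_k, k_selected=k_selected,
        assignments=assignments, column_order=column_order,
        pc_coordinates=pcs, no_local_minimum=no_local_minimum,
    )


def hierarchical_cluster_columns(matrix) -> tuple[list, np.ndarray]:
    """Complete-linkage hierarchical clustering of column profiles.

    Euclidean distances between columns; returns the dendrogram leaf order
    (as column labels) and the linkage matrix.  Ties resolve to the lower
    original index by scipy's deterministic merge order.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns to cluster")
    Z = linkage(pdist(df.to_numpy().T, metric="euclidean"), method="complete")
    order = leaves_list(Z)
    return [df.columns[i] for i in order], Z


def scale_rows_for_heatmap(matrix) -> pd.DataFrame:
    """Z-score each column (mean 0, sd 1) for heatmap display.

    Raises on zero-variance columns; heatmaps of scaled data show direction
    of effect per background, not absolute magnitude.
    """
    df = pd.DataFrame(matrix).astype(float)
    sd = df.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(df.columns[sd == 0])
        raise ValueError(f"zero-variance columns cannot be scaled: {bad}")
    return (df - df.mean(axis=0)) / sd


def pca_clusters(matrix, assignments=None) -> tuple[np.ndarray, float]:
    """Project centered rows onto the first two principal axes.

    Returns the 2-D coordinates and, when cluster assignments are given,
    the minimum pairwise distance between cluster centroids in PC space
    (0.0 without assignments or with a single cluster).
    """
    df = pd.DataFrame(matrix).astype(float)
    X = df.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if np.allclose(X, X.mean(axis=0)):
        raise ValueError("zero total variance: PCA undefined")
    n_comp = min(2, X.shape[1])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    if n_comp == 1:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    separation = 0.0
    if assignments is not None:
        labels = np.asarray(assignments)
        cents = np.array([coords[labels == c].mean(axis=0) for c in np.unique(labels)])
        if len(cents) >= 2:
            separation = float(pdist(cents).min())
    return coords, separation


def ddct_fold_change(
    ct_target_treated: float,
    ct_target_ctrl: float,
    ct_ref_treated: float,
    ct_ref_ctrl: float,
    eff_target: float = 2.0,
    eff_ref: float = 2.0,
) -> float:
    """Efficiency-corrected relative expression by the delta-delta-Ct method.

    fold = eff_target**(Ct_target_ctrl - Ct_target_treated)
         / eff_ref**(Ct_ref_ctrl - Ct_ref_treated)

    Amplification efficiencies are per-cycle factors, experimentally
    determined, in (1, 2.2] (2.0 = perfect doubling).
    """
    for name, eff in (("eff_target", eff_target), ("eff_ref", eff_ref)):
        if not (1.0 < eff <= 2.2):
            raise ValueError(f"{name} must be in (1, 2.2], got {eff}")
    return float(
        eff_target ** (ct_target_ctrl - ct_target_treated)
        / eff_ref ** (ct_ref_ctrl - ct_ref_treated)
    )
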