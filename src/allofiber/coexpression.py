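"""Weighted co-expression networks, modules, eigengenes and hub genes.

Per species, an unsigned weighted network is built from per-sample
expression: adjacency a_ij = |Pearson cor|^beta with beta picked by the
scale-free topology criterion, turned into a topological overlap matrix
(TOM), and clustered (average linkage on 1 - TOM). Modules come from a
static tree cut — the cut height, among the dendrogram's merge heights,
that maximizes the number of modules meeting the size floor (then the
number of assigned genes) — followed by merging of modules whose
eigengenes correlate above a threshold. This static cut is a
reproducible simplification of dynamic tree cutting.

A module's eigengene is the first principal component of its
standardized expression (unit variance, oriented to correlate
positively with the module's mean expression); kME is each gene's
correlation with an eigengene, modules are associated with the stage
whose indicator best correlates with their eigengene, and hubs are the
top-kME members of each module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

__all__ = [
    "NetworkParams",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_cor",
    "kme",
    "select_hubs",
    "hub_report",
    "export_top_edges",
]


@dataclass
class NetworkParams:
    """Network construction settings.

    beta_candidates
        Candidate soft-threshold powers (default 1..20).
    scale_free_r2_target
        R^2 at which a power is accepted as scale-free (default 0.8).
    min_module_size
        Size floor for a cluster to count as a module (default 30).
    merge_cor_min
        Modules whose eigengenes correlate above this are merged
        (default 0.75).
    top_edges
        Number of highest-weight edges exported per network (default
        100; the conventional range is 50-100).
    n_hubs
        Hub genes per module, ranked by kME (default 3).
    """

    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    min_module_size: int = 30
    merge_cor_min: float = 0.75
    top_edges: int = 100
    n_hubs: int = 3


def _safe_gene_cor(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation; constant genes get zero correlation."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of connectivity-bin frequency on k."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    freq, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (freq > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0
    lx, ly = np.log10(centers[keep]), np.log10(freq[keep])
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    expr: pd.DataFrame, params: NetworkParams = NetworkParams()
) -> int:
    """Pick the soft-threshold power by approximate scale-free topology.

    For each candidate beta, connectivity k_i = sum_j |cor(x_i, x_j)|^beta
    is computed and the fit of log10(frequency) vs log10(k) over 10
    connectivity bins scored by R^2. Returns the smallest candidate
    whose R^2 reaches the target, else the candidate with maximal R^2.
    Requires at least 8 samples for stable correlations.
    """
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples to estimate correlations")
    cor = np.abs(_safe_gene_cor(expr))
    best_beta, best_r2 = params.beta_candidates[0], -1.0
    for beta in params.beta_candidates:
        a = cor**beta
        k = a.sum(axis=1) - 1.0
        r2 = scale_free_r2(k)
        if r2 >= params.scale_free_r2_target:
            return int(beta)
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    return int(best_beta)


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |Pearson cor|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _safe_gene_cor(expr)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal; the diagonal is set
    to 1. Entries lie in [0, 1] for adjacencies in [0, 1].
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum over all u; u = i and u = j contribute 0 (diag zeroed)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def _cut_labels(z: np.ndarray, heights: np.ndarray, min_size: int) -> np.ndarray:
    """Static cut: pick the height giving the best (n modules, n assigned)."""
    best = None
    best_labels = None
    for h in heights:
        labels = fcluster(z, t=h, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        big = sizes[sizes >= min_size]
        score = (len(big), int(big.sum()), -h)
        if best is None or score > best:
            best = score
            keep = set(big.index)
            best_labels = np.where(np.isin(labels, list(keep)), labels, 0)
    return best_labels if best_labels is not None else np.zeros(z.shape[0] + 1, int)


def detect_modules(
    tom_matrix: pd.DataFrame,
    expr: pd.DataFrame,
    params: NetworkParams = NetworkParams(),
) -> pd.Series:
    """Detect co-expression modules from a TOM.

    Average-linkage hierarchical clustering on 1 - TOM, a static cut at
    the merge height maximizing (number of modules of size >=
    ``min_module_size``, genes assigned), then iterative merging of the
    module pair whose eigengenes (computed from ``expr``) correlate most,
    while that correlation exceeds ``merge_cor_min``. Returns a label
    per gene; unassigned genes are labeled ``"grey"`` and modules
    ``"M1"``, ``"M2"``, ... in decreasing size order.
    """
    genes = tom_matrix.index
    d = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = np.unique(z[:, 2])
    raw = _cut_labels(z, heights, params.min_module_size)
    labels = pd.Series(raw, index=genes)

    if (labels == 0).all():
        warnings.warn("no module met the size floor; all genes unassigned",
                      stacklevel=2)
        return pd.Series("grey", index=genes)

    # merge highly correlated modules via their eigengenes
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig = {m: module_eigengene(expr, labels.index[labels == m]) for m in mods}
        best_pair, best_cor = None, params.merge_cor_min
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1 :]:
                c = float(np.corrcoef(eig[m1], eig[m2])[0, 1])
                if c > best_cor:
                    best_pair, best_cor = (m1, m2), c
        if best_pair is None:
            break
        m1, m2 = best_pair
        labels[labels == m2] = m1

    sizes = labels[labels != 0].value_counts()
    rename = {m: f"M{i + 1}" for i, m in enumerate(sizes.index)}
    out = labels.map(lambda v: rename.get(v, "grey"))
    out.name = "module"
    return out


def module_eigengene(expr: pd.DataFrame, genes: pd.Index | list) -> pd.Series:
    """First principal component of a module's standardized expression.

    Returned over samples with unit variance, sign-oriented so that its
    correlation with the module's mean expression is positive. A
    single-gene module yields that gene's standardized profile.
    """
    x = expr.loc[list(genes)].to_numpy(dtype=float)
    if x.shape[0] == 0:
        raise ValueError("module is empty")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    if x.shape[0] == 1:
        e = xs[0]
    else:
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
    if e.std() > 0:
        e = e / e.std()
    mean_profile = xs.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return pd.Series(e, index=expr.columns, name="eigengene")


def module_trait_cor(
    eigengenes: pd.DataFrame, stages: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate module eigengenes with per-stage indicators.

    ``eigengenes`` is samples x modules; ``stages`` gives each sample's
    stage (DPA). Returns (r, p) frames of shape modules x stages, with p
    from the t distribution on n - 2 degrees of freedom.
    """
    n = len(stages)
    if n < 3:
        raise ValueError("need >= 3 samples for a correlation p-value")
    stage_values = sorted(set(stages))
    r = pd.DataFrame(index=eigengenes.columns, columns=stage_values, dtype=float)
    for s in stage_values:
        ind = (stages == s).astype(float).to_numpy()
        for m in eigengenes.columns:
            r.loc[m, s] = float(np.corrcoef(eigengenes[m].to_numpy(), ind)[0, 1])
    rv = r.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    p = pd.DataFrame(
        2 * t_dist.sf(np.abs(tstat), df=n - 2), index=r.index, columns=r.columns
    )
    return r, p


def kme(expr: pd.DataFrame, eigengene: pd.Series) -> pd.Series:
    """Module membership: correlation of each gene with an eigengene."""
    x = expr.to_numpy(dtype=float)
    e = eigengene.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): kME set to 0", stacklevel=2
        )
    xc = x - x.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ec) / denom
    r[constant] = 0.0
    return pd.Series(r, index=expr.index, name="kme")


def select_hubs(kme_values: pd.Series, n_hubs: int = 3) -> list[str]:
    """Top genes of a module by kME; ties broken by gene id (ascending)."""
    order = sorted(kme_values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:n_hubs]]


def hub_report(
    expr: pd.DataFrame,
    labels: pd.Series,
    stages: pd.Series,
    params: NetworkParams = NetworkParams(),
) -> pd.DataFrame:
    """kME-ranked hubs per module plus each module's best stage.

    A module's stage association is the stage with maximal |r| between
    its eigengene and the stage indicator.
    """
    modules = sorted(set(labels) - {"grey"})
    eig = pd.DataFrame(
        {m: module_eigengene(expr, labels.index[labels == m]) for m in modules}
    )
    if not modules:
        return pd.DataFrame(
            columns=["module", "stage_dpa", "rank", "gene_id", "kme"]
        )
    r, _ = module_trait_cor(eig, stages)
    rows = []
    for m in modules:
        members = labels.index[labels == m]
        km = kme(expr.loc[members], eig[m])
        stage = r.loc[m].abs().astype(float).idxmax()
        for rank, g in enumerate(select_hubs(km, params.n_hubs), start=1):
            rows.append(
                {
                    "module": m,
                    "stage_dpa": stage,
                    "rank": rank,
                    "gene_id": g,
                    "kme": float(km[g]),
                }
            )
    return pd.DataFrame(rows)


def export_top_edges(weights: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """Top-n edges by weight from a symmetric weight matrix.

    Upper triangle only (no duplicate symmetric pairs), sorted by weight
    descending with a deterministic (source, target) tie-break.
    """
    genes = list(weights.index)
    w = weights.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    frame = pd.DataFrame(
        {
            "source": [genes[i] for i in iu],
            "target": [genes[j] for j in ju],
            "weight": w[iu, ju],
        }
    )
    frame = frame.sort_values(
        ["weight", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame.head(n)
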