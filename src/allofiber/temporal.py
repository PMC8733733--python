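"""Temporal soft clustering and cross-species postponement detection.

Stage-course profiles (group-mean FPKM of one species' reference
cultivar over the seven sampled stages) are log-transformed, z-scored
per gene, and soft-clustered with fuzzy c-means. Each cluster's *peak
stage* is the stage at which its center is maximal; a gene inherits the
peak stage of the cluster it belongs to, provided its maximal membership
reaches a gate (default 0.5). Peak stages are restricted to the key
fiber stages {10, 20, 25} DPA for cross-species comparisons — genes in
clusters peaking at 0-5 DPA carry no peak stage there.

Linked orthologs between the two species are then classified: a pair is
*consistent* when both species peak at the same key stage, *postponed*
when the G. barbadense ortholog peaks later than its G. hirsutum
counterpart (the shift classes 10->20, 10->25 and 20->25 DPA), and
*advanced* in the mirror case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FuzzyParams",
    "FuzzyClustering",
    "standardize",
    "fuzzy_cmeans",
    "assign_peak_stage",
    "compare_predominance",
    "detect_postponement",
    "postponement_counts",
    "POSTPONEMENT_CLASSES",
]

#: Comparison stages for predominance/postponement, in DPA.
KEY_STAGES = (10, 20, 25)

POSTPONEMENT_CLASSES = (
    "consistent",
    "postponed_10_20",
    "postponed_10_25",
    "postponed_20_25",
    "advanced",
    "other",
    "unassigned",
)


@dataclass
class FuzzyParams:
    """Fuzzy c-means settings.

    n_clusters
        Number of soft clusters c (default 9: several clusters per key
        stage of the 7-stage course).
    fuzzifier
        Softness exponent m > 1 (default 1.25, the usual choice for
        standardized expression profiles; m -> 1 approaches k-means).
    membership_min
        A gene is assigned to its argmax cluster only if that membership
        reaches this gate (default 0.5).
    """

    n_clusters: int = 9
    fuzzifier: float = 1.25
    membership_min: float = 0.5
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.fuzzifier > 1:
            raise ValueError("fuzzifier must exceed 1")
        if not 0 < self.membership_min <= 1:
            raise ValueError("membership_min must be in (0, 1]")


@dataclass
class FuzzyClustering:
    """Converged fuzzy c-means state."""

    centers: pd.DataFrame  # clusters x stages
    memberships: pd.DataFrame  # genes x clusters
    objective: float
    n_iter: int
    converged: bool
    objective_path: list[float] | None = None


def standardize(stage_expr: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Z-score log2(FPKM+1) per gene across stages.

    ``stage_expr`` is genes x stages (FPKM). Genes whose raw profile is
    constant have no defined z-score and are excluded; the count of
    excluded genes is returned alongside the standardized profiles.
    """
    logx = np.log2(stage_expr.astype(float) + 1.0)
    # constancy judged on the raw profile range (a summary statistic like
    # std can return ~1e-16 for exactly constant input)
    keep = (stage_expr.max(axis=1) - stage_expr.min(axis=1)) > 0
    z = logx[keep]
    sd = z.std(axis=1, ddof=0)
    z = z.sub(z.mean(axis=1), axis=0).div(sd, axis=0)
    return z, int((~keep).sum())


def fuzzy_cmeans(profiles: pd.DataFrame, params: FuzzyParams) -> FuzzyClustering:
    """Fuzzy c-means by alternating minimization.

    Memberships are initialized at random (seeded) and iterated with the
    standard update pair — centers as membership^m-weighted means,
    memberships from inverse-distance ratios with exponent 2/(m-1) — to
    Euclidean distances, until the objective J = sum u^m d^2 changes by
    less than ``tol`` or ``max_iter`` is reached. A point coinciding
    with a center receives full membership in that cluster. Deterministic
    given the seed.
    """
    x = profiles.to_numpy(dtype=float)
    n, _ = x.shape
    c, m = params.n_clusters, params.fuzzifier
    if n < c:
        raise ValueError(f"need at least {c} profiles, got {n}")
    if len(np.unique(x, axis=0)) < c:
        raise ValueError("need at least n_clusters distinct profiles")
    rng = np.random.default_rng(params.seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    obj_prev = np.inf
    obj = np.inf
    converged = False
    path: list[float] = []
    for it in range(1, params.max_iter + 1):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float((um * d2).sum())
        path.append(obj)
        zero = d2 <= 1e-300
        d2s = np.where(zero, 1.0, d2)
        inv = d2s ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        if abs(obj_prev - obj) < params.tol:
            converged = True
            break
        obj_prev = obj

    return FuzzyClustering(
        centers=pd.DataFrame(centers, columns=profiles.columns),
        memberships=pd.DataFrame(u, index=profiles.index),
        objective=obj,
        n_iter=it,
        converged=converged,
        objective_path=path,
    )


def assign_peak_stage(
    clustering: FuzzyClustering,
    params: FuzzyParams,
    allowed_stages: tuple[int, ...] = KEY_STAGES,
) -> pd.DataFrame:
    """Assign each gene a cluster and a predominant (peak) stage.

    A gene joins its argmax-membership cluster when that membership
    reaches ``params.membership_min``, else cluster is -1. The cluster's
    peak stage is the stage of its center's maximum; peaks outside
    ``allowed_stages`` yield a missing peak stage (the gene stays
    clustered but takes no part in stage comparisons).
    """
    u = clustering.memberships.to_numpy()
    best = u.argmax(axis=1)
    best_u = u[np.arange(len(u)), best]
    assigned = best_u >= params.membership_min
    stages = np.asarray(clustering.centers.columns, dtype=int)
    cluster_peak = stages[clustering.centers.to_numpy().argmax(axis=1)]
    peak = cluster_peak[best].astype(float)
    peak[~assigned] = np.nan
    peak[~np.isin(cluster_peak[best], allowed_stages)] = np.nan
    return pd.DataFrame(
        {
            "gene_id": clustering.memberships.index.to_numpy(),
            "cluster": np.where(assigned, best, -1),
            "membership": best_u,
            "peak_stage_dpa": peak,
        }
    )


def _peak_lookup(assign: pd.DataFrame) -> pd.Series:
    return assign.set_index("gene_id")["peak_stage_dpa"]


def compare_predominance(
    assign_gh: pd.DataFrame,
    assign_gb: pd.DataFrame,
    orthologs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-stage predominance comparison of linked orthologs.

    ``orthologs`` maps ``gh_gene`` to ``gb_gene``. For each key stage s,
    tallies orthologs peaking at s in both species (consistent), at s in
    G. hirsutum only, and at s in G. barbadense only ("only" meaning the
    other species peaks elsewhere or is unassigned). Returns a tidy
    frame with gene-set columns alongside counts.
    """
    gh = _peak_lookup(assign_gh)
    gb = _peak_lookup(assign_gb)
    links = orthologs[["gh_gene", "gb_gene"]].copy()
    links["stage_gh"] = gh.reindex(links["gh_gene"]).to_numpy()
    links["stage_gb"] = gb.reindex(links["gb_gene"]).to_numpy()
    rows = []
    for s in KEY_STAGES:
        at_gh = links["stage_gh"] == s
        at_gb = links["stage_gb"] == s
        rows.append(
            {
                "stage_dpa": s,
                "n_consistent": int((at_gh & at_gb).sum()),
                "n_gh_only": int((at_gh & ~at_gb).sum()),
                "n_gb_only": int((~at_gh & at_gb).sum()),
            }
        )
    return pd.DataFrame(rows)


def detect_postponement(
    assign_gh: pd.DataFrame,
    assign_gb: pd.DataFrame,
    orthologs: pd.DataFrame,
) -> pd.DataFrame:
    """Classify each linked ortholog pair's cross-species timing.

    Classes: ``consistent`` (same key peak stage in both species),
    ``postponed_10_20`` / ``postponed_10_25`` / ``postponed_20_25``
    (G. barbadense peaks later), ``advanced`` (G. barbadense peaks
    earlier), ``unassigned`` (either species lacks a key peak stage) and
    ``other`` (a later-stage combination outside the named shifts; empty
    when peaks are restricted to {10, 20, 25}). Every pair receives
    exactly one class.
    """
    gh = _peak_lookup(assign_gh)
    gb = _peak_lookup(assign_gb)
    out = orthologs[["gh_gene", "gb_gene"]].copy()
    sg = gh.reindex(out["gh_gene"]).to_numpy()
    sb = gb.reindex(out["gb_gene"]).to_numpy()
    out["stage_gh"] = sg
    out["stage_gb"] = sb

    cls = np.full(len(out), "other", dtype=object)
    cls[np.isnan(sg) | np.isnan(sb)] = "unassigned"
    both = ~(np.isnan(sg) | np.isnan(sb))
    cls[both & (sg == sb)] = "consistent"
    cls[both & (sb < sg)] = "advanced"
    for x, y in ((10, 20), (10, 25), (20, 25)):
        cls[both & (sg == x) & (sb == y)] = f"postponed_{x}_{y}"
    out["class"] = cls
    return out


def postponement_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts of postponement calls, in canonical class order."""
    counts = calls["class"].value_counts()
    return pd.DataFrame(
        {
            "class": POSTPONEMENT_CLASSES,
            "n": [int(counts.get(k, 0)) for k in POSTPONEMENT_CLASSES],
        }
    )
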