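"""Soft clustering, peak-stage assignment and postponement classes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allofiber.temporal import (
    FuzzyParams,
    assign_peak_stage,
    compare_predominance,
    detect_postponement,
    fuzzy_cmeans,
    postponement_counts,
    standardize,
)

STAGES = [0, 1, 3, 5, 10, 20, 25]


def test_standardize_zero_mean_unit_sd():
    expr = pd.DataFrame([[0, 0, 0, 0, 10, 20, 10]], columns=STAGES, index=["g"])
    z, n_excluded = standardize(expr)
    assert n_excluded == 0
    assert z.loc["g"].mean() == pytest.approx(0.0, abs=1e-9)
    assert z.loc["g"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_standardize_excludes_constant_profiles():
    expr = pd.DataFrame(
        [[5, 5, 5, 5, 5, 5, 5], [0, 1, 2, 3, 4, 5, 6]],
        columns=STAGES, index=["flat", "ramp"],
    )
    z, n_excluded = standardize(expr)
    assert n_excluded == 1
    assert list(z.index) == ["ramp"]


def test_standardize_affine_invariance():
    raw = np.array([[1.0, 2.0, 4.0, 8.0, 16.0, 8.0, 4.0]])
    expr = pd.DataFrame(raw, columns=STAGES)
    # affine transform on the log2(FPKM+1) scale leaves the z-score unchanged
    log_aff = 3.0 * np.log2(raw + 1) + 2.0
    expr_aff = pd.DataFrame(2.0**log_aff - 1, columns=STAGES)
    z1, _ = standardize(expr)
    z2, _ = standardize(expr_aff)
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


def _blobs(n_per=30, centers=(-5.0, 5.0), sd=0.3, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [rng.normal(c, sd, size=(n_per, dim)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pd.DataFrame(x), labels


def test_two_blobs_strong_membership():
    x, labels = _blobs()
    clust = fuzzy_cmeans(x, FuzzyParams(n_clusters=2, fuzzifier=2.0, seed=3))
    u = clust.memberships.to_numpy()
    home = u.max(axis=1)
    assert (home > 0.95).all()
    hard = u.argmax(axis=1)
    # clusters separate the blobs (up to label swap)
    assert len(set(zip(labels, hard))) == 2


def test_equidistant_point_splits_membership():
    pts = pd.DataFrame(
        [[-5.0, 0.0]] * 20 + [[5.0, 0.0]] * 20 + [[0.0, 0.0]]
    )
    clust = fuzzy_cmeans(pts, FuzzyParams(n_clusters=2, fuzzifier=2.0, seed=1))
    np.testing.assert_allclose(
        clust.memberships.iloc[-1].to_numpy(), [0.5, 0.5], atol=1e-6
    )


def test_membership_rows_sum_to_one_and_objective_monotone():
    x, _ = _blobs(n_per=40, centers=(-5, 0, 5), sd=1.0, seed=5)
    clust = fuzzy_cmeans(x, FuzzyParams(n_clusters=3, fuzzifier=1.5, seed=2))
    u = clust.memberships.to_numpy()
    np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
    path = np.array(clust.objective_path)
    assert (np.diff(path) <= 1e-8 * np.maximum(path[:-1], 1.0)).all()


def test_near_hard_limit_matches_kmeans_partition():
    x, labels = _blobs()
    clust = fuzzy_cmeans(x, FuzzyParams(n_clusters=2, fuzzifier=1.05, seed=4))
    u = clust.memberships.to_numpy()
    assert (u.max(axis=1) > 0.999).all()
    hard = u.argmax(axis=1)
    assert len(set(zip(labels, hard))) == 2


def test_too_many_clusters_error():
    x = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError, match="at least"):
        fuzzy_cmeans(x, FuzzyParams(n_clusters=5))


def _clustering_with(centers, memberships, genes):
    from allofiber.temporal import FuzzyClustering

    return FuzzyClustering(
        centers=pd.DataFrame(centers, columns=STAGES),
        memberships=pd.DataFrame(memberships, index=genes),
        objective=0.0,
        n_iter=1,
        converged=True,
    )


def test_peak_stage_assignment_and_gate():
    centers = [
        [-1, -1, -1, -1, 2, 0, 0],  # peaks at 10 DPA
        [-1, -1, 2, -1, 0, 0, 0],  # peaks at 3 DPA: outside key stages
    ]
    clust = _clustering_with(
        centers, [[0.9, 0.1], [0.1, 0.9]], ["g1", "g2"]
    )
    out = assign_peak_stage(clust, FuzzyParams(n_clusters=2)).set_index("gene_id")
    assert out.loc["g1", "peak_stage_dpa"] == 10
    assert out.loc["g2", "cluster"] == 1  # assigned, but no key-stage peak
    assert np.isnan(out.loc["g2", "peak_stage_dpa"])


def test_low_membership_unassigned():
    clust = _clustering_with(
        [[0, 0, 0, 0, 2, 0, 0], [0, 0, 0, 0, 0, 2, 0], [0, 0, 0, 0, 0, 0, 2]],
        [[0.4, 0.3, 0.3], [0.1, 0.8, 0.1]],
        ["ga", "gb"],
    )
    out = assign_peak_stage(clust, FuzzyParams(n_clusters=3)).set_index("gene_id")
    assert out.loc["ga", "cluster"] == -1  # max membership 0.4 < 0.5
    assert np.isnan(out.loc["ga", "peak_stage_dpa"])
    assert out.loc["gb", "peak_stage_dpa"] == 20


def _assign(mapping):
    return pd.DataFrame(
        {
            "gene_id": list(mapping),
            "cluster": 0,
            "membership": 0.9,
            "peak_stage_dpa": [
                np.nan if v is None else float(v) for v in mapping.values()
            ],
        }
    )


ORTHOLOGS = pd.DataFrame(
    {
        "gh_gene": ["h1", "h2", "h3", "h4", "h5"],
        "gb_gene": ["b1", "b2", "b3", "b4", "b5"],
    }
)


def test_postponement_classes():
    gh = _assign({"h1": 10, "h2": 20, "h3": 20, "h4": 10, "h5": None})
    gb = _assign({"b1": 20, "b2": 20, "b3": 10, "b4": 25, "b5": 10})
    calls = detect_postponement(gh, gb, ORTHOLOGS).set_index("gh_gene")
    assert calls.loc["h1", "class"] == "postponed_10_20"
    assert calls.loc["h2", "class"] == "consistent"
    assert calls.loc["h3", "class"] == "advanced"
    assert calls.loc["h4", "class"] == "postponed_10_25"
    assert calls.loc["h5", "class"] == "unassigned"


def test_every_pair_gets_exactly_one_class():
    rng = np.random.default_rng(7)
    stages = [10, 20, 25, None]
    gh = _assign({f"h{i}": stages[rng.integers(4)] for i in range(60)})
    gb = _assign({f"b{i}": stages[rng.integers(4)] for i in range(60)})
    orthologs = pd.DataFrame(
        {"gh_gene": [f"h{i}" for i in range(60)],
         "gb_gene": [f"b{i}" for i in range(60)]}
    )
    calls = detect_postponement(gh, gb, orthologs)
    assert len(calls) == 60
    counts = postponement_counts(calls)
    assert counts["n"].sum() == 60


def test_predominance_sets_disjoint():
    gh = _assign({"h1": 10, "h2": 10, "h3": 20})
    gb = _assign({"b1": 10, "b2": 25, "b3": None})
    orthologs = ORTHOLOGS.iloc[:3]
    table = compare_predominance(gh, gb, orthologs).set_index("stage_dpa")
    assert table.loc[10, "n_consistent"] == 1
    assert table.loc[10, "n_gh_only"] == 1
    # consistent and one-species-only are disjoint by construction
    assert table.loc[10, "n_consistent"] + table.loc[10, "n_gh_only"] == 2


def test_planted_peaks_recovered(default_sim, default_temporal):
    """Genes land in clusters peaking at their planted stage (>= 90%)."""
    dataset, truth = default_sim
    out = default_temporal
    t = truth.genes[truth.genes.species == "Gh"].set_index("gene_id")
    assign = out["assignments_gh"].set_index("gene_id")
    key = t[t.peak_stage.isin([10, 20, 25])]
    joined = assign.loc[assign.index.intersection(key.index)]
    planted = key.loc[joined.index, "peak_stage"].astype(float)
    hit = (joined["peak_stage_dpa"] == planted).mean()
    assert hit >= 0.9
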