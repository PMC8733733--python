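"""Homoeolog (subgenome) expression-bias calling and classification.

Per (cultivar, stage) group, each expressed homoeolog pair is tested for
unequal expression of its At and Dt copies:

* an exact two-sided test on the summed replicate read counts of the two
  homoeologs against the remainder of their libraries (a 2x2 table
  ``[[sum_A, sum_D], [lib_A - sum_A, lib_D - sum_D]]``) — the exact-test
  construction requires integer counts even though fold change is judged
  on FPKM;
* Benjamini-Hochberg adjustment across the expressed pairs of the group;
* a 2-fold gate on group-mean FPKM: the call is At-biased (Dt-biased)
  only when FPKM_A > FPKM_D (resp. <), |log2 FPKM ratio| >= log2(2) and
  the adjusted p is below 0.05. A pair with one homoeolog at zero FPKM
  and the other at or above the expression floor passes the fold-change
  gate with a +/-inf log-ratio sentinel.

Group-level direction (Table-1 style "bias toward") is an exact
two-sided binomial test of the At-biased count against half of all
biased pairs. Strict cross-cultivar consensus per species and the
8-way interspecific classification (Table-2 style) build on the calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from allofiber.io import CountsTable, HomoeologPairMap, SampleSheet
from allofiber.quantify import compute_fpkm, filter_expressed_pairs, group_mean

__all__ = [
    "BiasParams",
    "fisher_exact_2x2",
    "bh_adjust",
    "call_pair_bias",
    "call_bias",
    "binomial_direction_test",
    "summarize_bias",
    "species_consensus",
    "consensus_counts",
    "classify_interspecific",
    "count_interspecific",
    "INTERSPECIFIC_CATEGORIES",
]

#: The 8 strict interspecific categories, in Table-2 row order:
#: (pattern in G. hirsutum, pattern in G. barbadense).
INTERSPECIFIC_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("A_all", "none_all"),
    ("A_all", "D_all"),
    ("A_all", "A_all"),
    ("D_all", "none_all"),
    ("D_all", "A_all"),
    ("D_all", "D_all"),
    ("none_all", "A_all"),
    ("none_all", "D_all"),
)

_SAME_DIRECTION = {("A_all", "A_all"), ("D_all", "D_all")}


@dataclass
class BiasParams:
    """Thresholds of the bias caller.

    fold_change_min
        Minimum FPKM fold change between homoeologs (default 2.0).
    fdr_alpha
        BH-adjusted significance level (default 0.05).
    min_fpkm
        Expression floor: a pair is testable when max(FPKM_A, FPKM_D)
        reaches this value, and a zero-FPKM side passes the fold-change
        gate only if the other side reaches it (default 1.0).
    """

    fold_change_min: float = 2.0
    fdr_alpha: float = 0.05
    min_fpkm: float = 1.0

    def __post_init__(self) -> None:
        if not self.fold_change_min > 1:
            raise ValueError("fold_change_min must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


# Relative slack when comparing hypergeometric point probabilities to the
# observed table's probability; ties are only defined up to float rounding.
_TIE_SLACK = math.log1p(1e-12)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support fixed by the
    table's margins, every point probability not exceeding that of the
    observed table (within 1e-12 relative slack). Computed from
    log-gamma so tables with library-scale margins are exact-test cheap.
    """
    vals = (a, b, c, d)
    for v in vals:
        if v < 0:
            raise ValueError("table entries must be non-negative")
        if v != int(v):
            raise ValueError("table entries must be integers")
    a, b, c, d = (int(v) for v in vals)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValueError("at least one margin must be positive")
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(n - r1 - c1 + x + 1)
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
    )
    l_obs = logpmf[a - lo]
    p = float(np.exp(logpmf[logpmf <= l_obs + _TIE_SLACK]).sum())
    return min(p, 1.0)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_pair_bias(
    table: pd.DataFrame,
    lib_a: int,
    lib_d: int,
    params: BiasParams = BiasParams(),
) -> pd.DataFrame:
    """Call bias for the expressed pairs of one (cultivar, stage) group.

    ``table`` needs columns ``pair_id``, ``count_a``, ``count_d`` (summed
    replicate read counts per homoeolog), ``fpkm_a`` and ``fpkm_d``
    (group-mean FPKM). ``lib_a``/``lib_d`` are the summed library sizes
    of the replicates contributing to each homoeolog's counts. BH
    adjustment is applied across the rows of ``table`` (the family is
    the group's expressed pairs).

    Returns the table with ``log2fc``, ``p_raw``, ``q`` and ``call``
    columns appended; ``call`` is one of ``A_biased``, ``D_biased``,
    ``unbiased``.
    """
    out = table.copy()
    ca = out["count_a"].to_numpy()
    cd = out["count_d"].to_numpy()
    p_raw = np.array(
        [
            fisher_exact_2x2(int(a), int(d), int(lib_a - a), int(lib_d - d))
            for a, d in zip(ca, cd)
        ]
    )
    q = bh_adjust(p_raw)

    fa = out["fpkm_a"].to_numpy(dtype=float)
    fd = out["fpkm_d"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log2fc = np.where(
            (fa > 0) & (fd > 0),
            np.log2(np.where(fd > 0, fa, 1.0) / np.where(fd > 0, fd, 1.0)),
            np.where(fa > 0, np.inf, -np.inf),
        )
    lfc_min = np.log2(params.fold_change_min)
    pass_a = np.where(
        np.isinf(log2fc) & (log2fc > 0), fa >= params.min_fpkm, log2fc >= lfc_min
    )
    pass_d = np.where(
        np.isinf(log2fc) & (log2fc < 0), fd >= params.min_fpkm, log2fc <= -lfc_min
    )
    sig = q < params.fdr_alpha
    call = np.where(
        sig & (fa > fd) & pass_a,
        "A_biased",
        np.where(sig & (fd > fa) & pass_d, "D_biased", "unbiased"),
    )
    out["log2fc"] = log2fc
    out["p_raw"] = p_raw
    out["q"] = q
    out["call"] = call
    return out


def call_bias(
    counts: CountsTable,
    sheet: SampleSheet,
    pairs: HomoeologPairMap,
    params: BiasParams = BiasParams(),
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Run the bias caller over every (cultivar, stage) group.

    Returns one row per (pair, cultivar, stage) with the pair's counts,
    group-mean FPKM, test results and call; pairs failing the expression
    filter get ``call = not_expressed`` with no test performed. When the
    pair map carries a ``species`` column, each group is tested only
    against the pairs of its own species.
    """
    fpkm = compute_fpkm(counts, lengths)
    gmean = group_mean(fpkm, sheet)
    species_of = sheet.species_of()
    has_species = "species" in pairs.frame.columns

    lib = counts.library_sizes()
    frames = []
    for (cultivar, stage), samples in sheet.groups().items():
        pmap = pairs.subset(species_of[cultivar]) if has_species else pairs
        expressed, _ = filter_expressed_pairs(
            gmean[[(cultivar, stage)]], pmap, params.min_fpkm
        )
        mask = expressed[(cultivar, stage)]
        f = pmap.frame[pmap.frame["pair_id"].isin(mask.index)]
        group_counts = counts.counts[samples].sum(axis=1)
        g_fpkm = gmean[(cultivar, stage)]
        base = pd.DataFrame(
            {
                "pair_id": f["pair_id"].to_numpy(),
                "cultivar": cultivar,
                "stage_dpa": stage,
                "count_a": group_counts.loc[f["a_gene"]].to_numpy(),
                "count_d": group_counts.loc[f["d_gene"]].to_numpy(),
                "fpkm_a": g_fpkm.loc[f["a_gene"]].to_numpy(),
                "fpkm_d": g_fpkm.loc[f["d_gene"]].to_numpy(),
            }
        )
        is_expr = mask.loc[base["pair_id"]].to_numpy()
        lib_sum = int(lib[samples].sum())
        tested = call_pair_bias(base[is_expr], lib_sum, lib_sum, params)
        rest = base[~is_expr].copy()
        rest["log2fc"] = np.nan
        rest["p_raw"] = np.nan
        rest["q"] = np.nan
        rest["call"] = "not_expressed"
        frames.append(pd.concat([tested, rest], ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def binomial_direction_test(n_a: int, n_d: int) -> tuple[float, str]:
    """Exact two-sided binomial test of the At/Dt split of biased pairs.

    Tests ``n_a`` successes in ``n_a + n_d`` trials against 0.5 (the
    two-sided p sums outcome probabilities not exceeding that of the
    observed count). Returns (p, direction) where direction names the
    subgenome with the larger count when p < 0.05, else ``"none"``.
    """
    if n_a < 0 or n_d < 0:
        raise ValueError("counts must be non-negative")
    if n_a + n_d == 0:
        raise ValueError("at least one biased pair is required")
    p = float(binomtest(int(n_a), int(n_a) + int(n_d), 0.5).pvalue)
    if p < 0.05 and n_a != n_d:
        direction = "At" if n_a > n_d else "Dt"
    else:
        direction = "none"
    return p, direction


def summarize_bias(calls: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: one row per (cultivar, stage).

    Columns: total expressed pairs, total biased, At-biased ("At > Dt"),
    Dt-biased ("At < Dt"), percent biased of expressed, the binomial
    direction p and the direction verdict. The percentage is stored at
    full precision; round on output.
    """
    rows = []
    for (cultivar, stage), g in calls.groupby(["cultivar", "stage_dpa"], sort=False):
        expressed = int((g["call"] != "not_expressed").sum())
        n_a = int((g["call"] == "A_biased").sum())
        n_d = int((g["call"] == "D_biased").sum())
        total = n_a + n_d
        if total > 0:
            p, direction = binomial_direction_test(n_a, n_d)
        else:
            p, direction = np.nan, "none"
        rows.append(
            {
                "cultivar": cultivar,
                "stage_dpa": stage,
                "total_expressed": expressed,
                "total_biased": total,
                "n_a_biased": n_a,
                "n_d_biased": n_d,
                "pct_biased": 100.0 * total / expressed if expressed else 0.0,
                "direction_p": p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def species_consensus(
    calls: pd.DataFrame,
    cultivars: Sequence[str],
    stage: int,
    species: str,
) -> pd.DataFrame:
    """Strict cross-cultivar consensus pattern per pair at one stage.

    ``A_all`` (``D_all``) means At-biased (Dt-biased) in *every* listed
    cultivar; ``none_all`` means unbiased in every cultivar; anything
    else is ``mixed``. Pairs not expressed (or missing) in any cultivar
    are excluded from the consensus.
    """
    sub = calls[
        (calls["stage_dpa"] == stage) & calls["cultivar"].isin(list(cultivars))
    ]
    wide = sub.pivot(index="pair_id", columns="cultivar", values="call")
    wide = wide.reindex(columns=list(cultivars))
    complete = wide.notna().all(axis=1) & (wide != "not_expressed").all(axis=1)
    wide = wide[complete]
    arr = wide.to_numpy()
    pattern = np.full(len(wide), "mixed", dtype=object)
    pattern[(arr == "A_biased").all(axis=1)] = "A_all"
    pattern[(arr == "D_biased").all(axis=1)] = "D_all"
    pattern[(arr == "unbiased").all(axis=1)] = "none_all"
    return pd.DataFrame(
        {
            "pair_id": wide.index.to_numpy(),
            "species": species,
            "stage_dpa": stage,
            "pattern": pattern,
        }
    )


def consensus_counts(patterns: pd.DataFrame) -> dict[str, int]:
    """Shared-set sizes per direction (Venn-style counts) for one species/stage."""
    c = patterns["pattern"].value_counts()
    return {
        "n_a_all": int(c.get("A_all", 0)),
        "n_d_all": int(c.get("D_all", 0)),
        "n_none_all": int(c.get("none_all", 0)),
        "n_mixed": int(c.get("mixed", 0)),
    }


def classify_interspecific(
    gh_patterns: pd.DataFrame,
    gb_patterns: pd.DataFrame,
    links: pd.DataFrame,
) -> pd.DataFrame:
    """Classify linked pairs into the 8 strict interspecific categories.

    ``links`` maps ``gh_pair`` to ``gb_pair``. Both inputs must contain
    only strict patterns (``A_all``/``D_all``/``none_all``); a ``mixed``
    pattern is rejected — the caller filters those out first. Pairs where
    both species are ``none_all`` receive no category.
    """
    for name, f in (("gh", gh_patterns), ("gb", gb_patterns)):
        if (f["pattern"] == "mixed").any():
            raise ValueError(f"{name} patterns contain 'mixed'; filter them first")
    gh = gh_patterns.set_index("pair_id")["pattern"]
    gb = gb_patterns.set_index("pair_id")["pattern"]
    merged = links[
        links["gh_pair"].isin(gh.index) & links["gb_pair"].isin(gb.index)
    ].copy()
    merged["gh_pattern"] = gh.loc[merged["gh_pair"]].to_numpy()
    merged["gb_pattern"] = gb.loc[merged["gb_pair"]].to_numpy()
    keep = ~((merged["gh_pattern"] == "none_all") & (merged["gb_pattern"] == "none_all"))
    merged = merged[keep]
    merged["category"] = merged["gh_pattern"] + "|" + merged["gb_pattern"]
    merged["differing"] = merged["gh_pattern"] != merged["gb_pattern"]
    return merged.reset_index(drop=True)


def count_interspecific(categories: pd.DataFrame) -> dict[str, int]:
    """Total strict-pattern pairs and the subset with differing patterns.

    ``total_extreme`` sums all 8 categories; ``n_differing`` excludes the
    two same-direction categories (A|A and D|D).
    """
    total = len(categories)
    same = sum(
        ((categories["gh_pattern"] == a) & (categories["gb_pattern"] == b)).sum()
        for a, b in _SAME_DIRECTION
    )
    return {"total_extreme": int(total), "n_differing": int(total - same)}
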