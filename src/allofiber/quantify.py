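"""FPKM quantification, replicate aggregation and expression filtering.

FPKM(g, s) = count(g, s) * 1e9 / (length(g) * librarySize(s)), with the
library size taken as the column sum of assigned counts — self-contained
and deterministic, rather than an external "total mapped reads" figure.

Replicate concordance is assessed with Pearson correlation on
log2(FPKM + 1), the conventional scale for expression QC; pairs are
flagged against a configurable threshold (default 0.84).

A homoeolog pair counts as *expressed* in a (cultivar, stage) group when
the larger of its two group-mean FPKM values reaches ``min_fpkm``
(default 1.0): a silenced homoeolog must not mask a strongly expressed
partner, since one-sided silencing is itself an extreme form of bias.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from allofiber.io import CountsTable, HomoeologPairMap, SampleSheet

__all__ = [
    "compute_fpkm",
    "group_mean",
    "replicate_correlation",
    "filter_expressed_pairs",
]


def compute_fpkm(
    counts: CountsTable, lengths: pd.Series | None = None
) -> pd.DataFrame:
    """Convert a counts table to FPKM.

    ``lengths`` defaults to the lengths carried by the counts table.
    Zero counts map to zero FPKM; a zero library size or a missing /
    non-positive gene length is an error.
    """
    if lengths is None:
        lengths = counts.lengths
    if lengths is None:
        raise ValueError("no gene lengths available: pass `lengths`")
    lengths = lengths.reindex(counts.genes)
    missing = lengths.index[lengths.isna()]
    if len(missing) > 0:
        raise ValueError(f"missing length for gene {missing[0]!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    lib = counts.library_sizes()
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"zero library size for sample {bad!r}")
    fpkm = counts.counts.astype(float) * 1e9
    fpkm = fpkm.div(lengths.astype(float), axis=0).div(lib.astype(float), axis=1)
    return fpkm


def group_mean(expr: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Average expression over replicates of each (cultivar, stage) group.

    Returns a matrix with a (cultivar, stage_dpa) MultiIndex on columns.
    """
    groups = sheet.groups()
    cols = {}
    for (cultivar, stage), samples in groups.items():
        present = [s for s in samples if s in expr.columns]
        if not present:
            raise ValueError(f"group ({cultivar}, {stage}) has no samples in matrix")
        cols[(cultivar, stage)] = expr[present].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cultivar", "stage_dpa"])
    return out


def replicate_correlation(
    expr: pd.DataFrame, sheet: SampleSheet, threshold: float = 0.84
) -> pd.DataFrame:
    """Pearson correlation of log2(FPKM+1) for within-group replicate pairs.

    Returns one row per replicate pair with columns ``cultivar``,
    ``stage_dpa``, ``sample_1``, ``sample_2``, ``pearson_r``,
    ``computable`` and ``passed``. A constant replicate vector makes r
    undefined; such pairs are reported with ``computable = false`` rather
    than as failures.
    """
    logx = np.log2(expr + 1.0)
    rows = []
    for (cultivar, stage), samples in sheet.groups().items():
        for s1, s2 in combinations(samples, 2):
            x, y = logx[s1].to_numpy(), logx[s2].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, ok = np.nan, False
            else:
                r, ok = float(np.corrcoef(x, y)[0, 1]), True
            rows.append(
                {
                    "cultivar": cultivar,
                    "stage_dpa": stage,
                    "sample_1": s1,
                    "sample_2": s2,
                    "pearson_r": r,
                    "computable": ok,
                    "passed": bool(ok and r >= threshold),
                }
            )
    return pd.DataFrame(rows)


def filter_expressed_pairs(
    group_expr: pd.DataFrame,
    pairs: HomoeologPairMap,
    min_fpkm: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Determine which homoeolog pairs are expressed in each group.

    A pair is expressed in a group iff max(FPKM_A, FPKM_D) >= min_fpkm on
    group-mean FPKM. Returns a boolean pair-by-group frame plus the list
    of pair ids skipped because a member gene is absent from the matrix
    (also reported via a warning).
    """
    f = pairs.frame
    present = f["a_gene"].isin(group_expr.index) & f["d_gene"].isin(group_expr.index)
    skipped = list(f.loc[~present, "pair_id"])
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} pair(s) with genes absent from the matrix",
            stacklevel=2,
        )
    f = f[present]
    a = group_expr.loc[f["a_gene"]].to_numpy()
    d = group_expr.loc[f["d_gene"]].to_numpy()
    expressed = np.maximum(a, d) >= min_fpkm
    out = pd.DataFrame(
        expressed, index=pd.Index(f["pair_id"], name="pair_id"),
        columns=group_expr.columns,
    )
    return out, skipped
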