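"""Bias caller: exact tests, BH, calls, consensus and classification."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from allofiber.bias import (
    BiasParams,
    INTERSPECIFIC_CATEGORIES,
    bh_adjust,
    binomial_direction_test,
    call_pair_bias,
    classify_interspecific,
    count_interspecific,
    fisher_exact_2x2,
    species_consensus,
    summarize_bias,
)


def enumeration_fisher(a, b, c, d):
    """Independent oracle: exact integer hypergeometric enumeration."""
    n, r, col = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    nums = [comb(r, x) * comb(n - r, col - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(v for v in nums if v <= obs) / comb(n, col)


@pytest.mark.parametrize(
    "table, expected",
    [
        ((5, 5, 95, 95), 1.0),  # perfectly symmetric table
        ((8, 2, 2, 8), 0.023014137565221155),
        ((0, 10, 10, 0), 2 * comb(10, 10) * comb(10, 0) / comb(20, 10)),
    ],
)
def test_fisher_worked_examples(table, expected):
    assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-9)


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError, match="non-negative"):
        fisher_exact_2x2(1, -1, 2, 3)


def test_fisher_matches_scipy_on_random_and_large_tables():
    """Dual route: the log-gamma summation against scipy's fisher_exact."""
    rng = np.random.default_rng(0)
    tables = [tuple(rng.integers(0, 80, size=4)) for _ in range(60)]
    tables += [
        (1650, 410, 60_000_000 - 1650, 60_000_000 - 410),
        (5000, 5100, 19_995_000, 19_994_900),
    ]
    for t in tables:
        if sum(t) == 0:
            continue
        ours = fisher_exact_2x2(*t)
        ref = scipy_fisher([[t[0], t[1]], [t[2], t[3]]]).pvalue
        # log-gamma round-off grows with the margins; ~1e-7 relative at
        # library-scale tables, far below any decision threshold
        rel = 1e-8 if sum(t) < 10_000 else 1e-5
        assert ours == pytest.approx(ref, rel=rel, abs=1e-300)


def step_up_bh(pvals):
    """Oracle: literal Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def test_bh_single_p_is_identity():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_worked_vector():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_properties_and_oracle(pvals):
    q = bh_adjust(pvals)
    np.testing.assert_allclose(q, step_up_bh(np.asarray(pvals)), atol=1e-12)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    assert (q <= 1 + 1e-12).all()
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def _pair_table(count_a, count_d, fpkm_a, fpkm_d):
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(len(count_a))],
            "count_a": count_a,
            "count_d": count_d,
            "fpkm_a": fpkm_a,
            "fpkm_d": fpkm_d,
        }
    )


def test_identical_counts_are_unbiased():
    table = _pair_table([500], [500], [10.0], [10.0])
    out = call_pair_bias(table, 1_000_000, 1_000_000)
    assert out.loc[0, "p_raw"] == pytest.approx(1.0)
    assert out.loc[0, "call"] == "unbiased"


def test_fold_change_gate_blocks_significant_small_ratio():
    # hugely significant count difference but FPKM ratio only 1.8
    table = _pair_table([90_000], [50_000], [18.0], [10.0])
    out = call_pair_bias(table, 10_000_000, 10_000_000)
    assert out.loc[0, "q"] < 1e-10
    assert out.loc[0, "call"] == "unbiased"


def test_one_sided_zero_passes_gate_with_sentinel():
    table = _pair_table([800, 10], [0, 12], [5.0, 1.0], [0.0, 1.1])
    out = call_pair_bias(table, 1_000_000, 1_000_000)
    assert np.isposinf(out.loc[0, "log2fc"])
    assert out.loc[0, "call"] == "A_biased"


def test_silenced_side_below_floor_does_not_pass():
    table = _pair_table([40], [0], [0.5], [0.0])
    out = call_pair_bias(table, 1_000_000, 1_000_000, BiasParams(min_fpkm=1.0))
    assert out.loc[0, "call"] == "unbiased"


def binomial_two_sided_oracle(k, n):
    """Sum of binomial(n, 0.5) point masses not exceeding P(k)."""
    from math import lgamma, log

    logpmf = np.array(
        [
            lgamma(n + 1) - lgamma(i + 1) - lgamma(n - i + 1) + n * log(0.5)
            for i in range(n + 1)
        ]
    )
    sel = logpmf <= logpmf[k] + 1e-12
    return float(np.exp(logpmf[sel]).sum())


@pytest.mark.parametrize(
    "n_a, n_d, expected_dir",
    [(10, 10, "none"), (1733, 1924, "Dt"), (0, 20, "Dt"), (25, 5, "At")],
)
def test_binomial_direction_against_enumeration(n_a, n_d, expected_dir):
    p, direction = binomial_direction_test(n_a, n_d)
    assert p == pytest.approx(binomial_two_sided_oracle(n_a, n_a + n_d), rel=1e-9)
    assert direction == expected_dir


def test_binomial_direction_closed_forms():
    p, _ = binomial_direction_test(0, 20)
    assert p == pytest.approx(2 * 0.5**20)
    assert binomial_direction_test(10, 10)[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        binomial_direction_test(0, 0)


def make_calls(cultivar, stage, n_a, n_d, n_unbiased, n_not_expressed=0):
    calls = (
        ["A_biased"] * n_a + ["D_biased"] * n_d + ["unbiased"] * n_unbiased
        + ["not_expressed"] * n_not_expressed
    )
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(len(calls))],
            "cultivar": cultivar,
            "stage_dpa": stage,
            "call": calls,
        }
    )


def test_summary_counts_and_percentage():
    calls = make_calls("J220", 10, 1733, 1924, 14595 - 3657, 100)
    row = summarize_bias(calls).iloc[0]
    assert row.total_expressed == 14595
    assert row.total_biased == 3657
    assert round(row.pct_biased, 2) == 25.06
    assert row.direction == "Dt"


def test_summary_no_biased_pairs():
    row = summarize_bias(make_calls("TM-1", 10, 0, 0, 50)).iloc[0]
    assert row.pct_biased == 0.0
    assert row.direction == "none"


def _calls_for_consensus(per_cultivar):
    frames = []
    for cultivar, calls in per_cultivar.items():
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": [f"p{i}" for i in range(len(calls))],
                    "cultivar": cultivar,
                    "stage_dpa": 10,
                    "call": calls,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_consensus_strictness():
    cultivars = ["c1", "c2", "c3", "c4"]
    calls = _calls_for_consensus(
        {
            "c1": ["A_biased", "A_biased", "unbiased", "A_biased"],
            "c2": ["A_biased", "A_biased", "unbiased", "not_expressed"],
            "c3": ["A_biased", "unbiased", "unbiased", "A_biased"],
            "c4": ["A_biased", "A_biased", "unbiased", "A_biased"],
        }
    )
    patterns = species_consensus(calls, cultivars, 10, "Gh")
    by_pair = patterns.set_index("pair_id")["pattern"]
    assert by_pair["p0"] == "A_all"  # biased in all four cultivars
    assert by_pair["p1"] == "mixed"  # 3 of 4 is not consensus
    assert by_pair["p2"] == "none_all"
    assert "p3" not in by_pair.index  # not expressed somewhere: excluded


def _patterns(species, mapping):
    return pd.DataFrame(
        {
            "pair_id": list(mapping),
            "species": species,
            "stage_dpa": 10,
            "pattern": list(mapping.values()),
        }
    )


def test_classification_categories_and_exclusions():
    gh = _patterns("Gh", {"p1": "A_all", "p2": "A_all", "p3": "none_all",
                          "p4": "none_all"})
    gb = _patterns("Gb", {"p1": "none_all", "p2": "D_all", "p3": "none_all",
                          "p4": "D_all"})
    links = pd.DataFrame({"gh_pair": ["p1", "p2", "p3", "p4"],
                          "gb_pair": ["p1", "p2", "p3", "p4"]})
    cats = classify_interspecific(gh, gb, links)
    assert set(cats["gh_pair"]) == {"p1", "p2", "p4"}  # (none, none) dropped
    row = cats.set_index("gh_pair")
    assert row.loc["p1", "category"] == "A_all|none_all"
    assert row.loc["p2", "category"] == "A_all|D_all" and row.loc["p2", "differing"]
    counts = count_interspecific(cats)
    assert counts == {"total_extreme": 3, "n_differing": 3}
    assert all(
        "|".join(c) in {"|".join(x) for x in INTERSPECIFIC_CATEGORIES}
        for c in zip(cats["gh_pattern"], cats["gb_pattern"])
    )


def test_classification_rejects_mixed():
    gh = _patterns("Gh", {"p1": "mixed"})
    gb = _patterns("Gb", {"p1": "A_all"})
    links = pd.DataFrame({"gh_pair": ["p1"], "gb_pair": ["p1"]})
    with pytest.raises(ValueError, match="mixed"):
        classify_interspecific(gh, gb, links)


def test_more_discoveries_on_raw_than_adjusted():
    """BH never yields more discoveries at q < a than raw p < a."""
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(0, 1, 200), rng.uniform(0, 1e-3, 20)])
    q = bh_adjust(p)
    assert (q < 0.05).sum() <= (p < 0.05).sum()
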