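"""Synthetic allotetraploid fiber RNA-seq with planted ground truth.

Emulates the study design downstream code expects: two species
(4 G. hirsutum and 3 G. barbadense cultivars), the reference cultivar of
each species sampled at 0/1/3/5/10/20/25 DPA and the rest at 10 and 20
DPA, three replicates, and a homoeolog pair map linking At/Dt copies
within species and ortholog pairs across species.

Per gene, the expected FPKM at a stage is a shared per-pair baseline
(log-normal), modulated by a discrete Gaussian bump over the ordered
stage axis centered at the pair's planted peak stage (width one stage,
floored at 5% of baseline). Planted effects:

* *bias*: a fraction of pairs get a +/- bias_log2fc/2 shift on the
  At/Dt copies (direction split 50:50);
* *postponement*: a fraction of pairs peak one shift later in
  G. barbadense than in G. hirsutum (shift classes 10->20 and 20->25);
* *modules*: blocks of G. hirsutum homoeolog pairs share a latent
  stage contrast (a centered indicator of the module's key stage, so
  different modules' factors are close to uncorrelated) with
  uniform[0.6, 1] loadings and log-scale residual noise; both
  homoeologs of a module pair carry the same loading and residual so
  module structure does not masquerade as subgenome bias. Each module
  has a seed pair with loading 1 and no residual — its At gene is the
  module's generating hub.

Observed counts are negative binomial around FPKM-implied means
(count = FPKM x length x library / 1e9) with a fixed dispersion.
Everything is deterministic given the seed, and the emitted tables
round-trip through :mod:`allofiber.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from allofiber.io import (
    CountsTable,
    DEFAULT_STAGES,
    HomoeologPairMap,
    SampleSheet,
    write_table,
)

__all__ = [
    "SimConfig",
    "SimDataset",
    "SimTruth",
    "simulate_dataset",
    "write_dataset",
    "evaluate_bias_recovery",
    "evaluate_postponement_recovery",
    "evaluate_module_recovery",
]


@dataclass
class SimConfig:
    """Simulation settings (defaults are the emulated study conditions)."""

    n_pairs: int = 3000
    gh_cultivars: tuple[str, ...] = ("TM-1", "J220", "4005", "XLZ42")
    gb_cultivars: tuple[str, ...] = ("Hai7124", "R4-4", "3-79")
    stages_full: tuple[int, ...] = DEFAULT_STAGES
    stages_partial: tuple[int, ...] = (10, 20)
    n_reps: int = 3
    library_size: float = 2e7
    nb_dispersion: float = 0.05
    frac_biased: float = 0.1
    bias_log2fc: float = 2.0
    frac_postponed: float = 0.1
    peak_shifts: tuple[tuple[int, int], ...] = ((10, 20), (20, 25))
    n_modules: int = 3
    module_size: int = 60
    module_noise_sd: float = 0.5
    base_fpkm_meanlog: float = math.log(10.0)
    base_fpkm_sdlog: float = 1.0
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 1

    def __post_init__(self) -> None:
        for frac in (self.frac_biased, self.frac_postponed):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_pairs < 1 or self.n_reps < 1:
            raise ValueError("counts must be positive")
        if self.module_size % 2 != 0:
            raise ValueError("module_size must be even (a module is whole pairs)")
        if self.n_modules * self.module_size // 2 > self.n_pairs:
            raise ValueError("module genes exceed the number of genes")


@dataclass
class SimDataset:
    counts: CountsTable
    sheet: SampleSheet
    pairs: HomoeologPairMap
    lengths: pd.Series


@dataclass
class SimTruth:
    """Planted truth: one row per pair per species and one per gene.

    ``expected_counts`` holds the analytic expected read count per gene
    and stage (identical across cultivars and replicates of a species;
    module pairs include the log-normal mean factor exp(sd^2/2) of their
    per-sample residual). It is derivable from the config, so it is not
    written to disk.
    """

    pairs: pd.DataFrame
    genes: pd.DataFrame
    expected_counts: pd.DataFrame | None = None


_TEMPORAL_FLOOR = 0.05


def _bump(stage_idx: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    """Discrete Gaussian bump over stage index, width 1, floored at 5%."""
    g = np.exp(-0.5 * (stage_idx[None, :] - peak_idx[:, None]) ** 2)
    return np.maximum(_TEMPORAL_FLOOR, g)


def simulate_dataset(config: SimConfig = SimConfig()) -> tuple[SimDataset, SimTruth]:
    """Generate a dataset and its planted truth. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    stages = np.asarray(config.stages_full)
    stage_idx = {s: i for i, s in enumerate(stages)}
    npairs = config.n_pairs

    # --- pair-level plan (shared across species unless postponed) ---------
    pairs_per_module = config.module_size // 2
    n_module_pairs = config.n_modules * pairs_per_module
    module_of_pair = np.full(npairs, -1)
    for m in range(config.n_modules):
        module_of_pair[m * pairs_per_module : (m + 1) * pairs_per_module] = m
    # module stages cycle through the key fiber stages
    key = (10, 20, 25)
    module_stage = np.array([key[m % 3] for m in range(config.n_modules)])

    free = np.arange(n_module_pairs, npairs)
    postponed = np.zeros(npairs, dtype=bool)
    if len(free) > 0:
        postponed[free] = rng.random(len(free)) < config.frac_postponed
    shift_class = np.full(npairs, -1)
    idx_post = np.flatnonzero(postponed)
    if len(idx_post) > 0 and config.peak_shifts:
        shift_class[idx_post] = np.arange(len(idx_post)) % len(config.peak_shifts)

    peak_gh = np.empty(npairs, dtype=int)
    peak_gb = np.empty(npairs, dtype=int)
    random_peaks = rng.choice(stages, size=npairs)
    for i in range(npairs):
        if module_of_pair[i] >= 0:
            peak_gh[i] = peak_gb[i] = module_stage[module_of_pair[i]]
        elif postponed[i]:
            x, y = config.peak_shifts[shift_class[i]]
            peak_gh[i], peak_gb[i] = x, y
        else:
            peak_gh[i] = peak_gb[i] = random_peaks[i]

    biased = rng.random(npairs) < config.frac_biased
    direction = np.where(rng.random(npairs) < 0.5, "A", "D")
    direction = np.where(biased, direction, "none")

    loadings = rng.uniform(0.6, 1.0, size=n_module_pairs)
    # each module's seed pair defines the factor realization: loading 1,
    # no residual; its At gene is the module's generating hub
    seed_pairs = np.zeros(n_module_pairs, dtype=bool)
    for m in range(config.n_modules):
        seed_pair = m * pairs_per_module
        loadings[seed_pair] = 1.0
        seed_pairs[seed_pair] = True

    species_spec = (
        ("Gh", "GH", config.gh_cultivars),
        ("Gb", "GB", config.gb_cultivars),
    )

    counts_blocks: list[pd.DataFrame] = []
    expected_blocks: list[pd.DataFrame] = []
    sheet_rows: list[dict] = []
    pair_rows: list[dict] = []
    gene_rows: list[dict] = []
    lengths_all: list[pd.Series] = []

    shift_names = {
        i: f"postponed_{x}_{y}" for i, (x, y) in enumerate(config.peak_shifts)
    }

    for sp_code, prefix, cultivars in species_spec:
        peak = peak_gh if sp_code == "Gh" else peak_gb
        peak_idx = np.array([stage_idx[s] for s in peak])
        base = rng.lognormal(config.base_fpkm_meanlog, config.base_fpkm_sdlog,
                             size=npairs)
        lengths = rng.integers(config.gene_length_range[0],
                               config.gene_length_range[1] + 1,
                               size=2 * npairs)

        # expected FPKM per gene x stage (genes ordered A-block then D-block)
        profile = _bump(np.arange(len(stages), dtype=float), peak_idx.astype(float))
        log_fpkm_a = np.log(base)[:, None] + np.log(profile)
        log_fpkm_d = log_fpkm_a.copy()
        if sp_code == "Gh" and n_module_pairs > 0:
            # centered one-hot stage contrast per module; amplitude matches
            # the temporal profile's dynamic range (ln of the 5% floor)
            amp = -math.log(_TEMPORAL_FLOOR)
            onehot = np.zeros((n_module_pairs, len(stages)))
            for i in range(n_module_pairs):
                onehot[i, stage_idx[module_stage[module_of_pair[i]]]] = 1.0
            f_m = amp * (onehot - 1.0 / len(stages))
            module_log = np.log(base[:n_module_pairs])[:, None] + loadings[:, None] * f_m
            log_fpkm_a[:n_module_pairs] = module_log
            log_fpkm_d[:n_module_pairs] = module_log
        shift = np.log(2.0) * config.bias_log2fc / 2.0
        sgn = np.where(direction == "A", 1.0, np.where(direction == "D", -1.0, 0.0))
        log_fpkm_a += (sgn * shift)[:, None]
        log_fpkm_d += (-sgn * shift)[:, None]
        fpkm = np.exp(np.vstack([log_fpkm_a, log_fpkm_d]))  # 2*npairs x stages

        gene_a = [f"{prefix}_P{i:05d}_A" for i in range(npairs)]
        gene_d = [f"{prefix}_P{i:05d}_D" for i in range(npairs)]
        genes = gene_a + gene_d
        lengths_all.append(pd.Series(lengths, index=pd.Index(genes), name="length"))

        mean_per_count = (
            fpkm * lengths[:, None].astype(float) * config.library_size / 1e9
        )
        expected = mean_per_count.copy()
        if sp_code == "Gh" and n_module_pairs > 0:
            lognormal_mean = math.exp(config.module_noise_sd**2 / 2.0)
            factor = np.where(seed_pairs, 1.0, lognormal_mean)
            expected[:n_module_pairs] *= factor[:, None]
            expected[npairs : npairs + n_module_pairs] *= factor[:, None]

        cols = {}
        for cultivar in cultivars:
            cv_stages = (
                config.stages_full if cultivar == cultivars[0]
                else config.stages_partial
            )
            for s in cv_stages:
                base_mu = mean_per_count[:, stage_idx[s]]
                for rep in range(1, config.n_reps + 1):
                    sid = f"{cultivar}_{s}dpa_r{rep}"
                    mu = base_mu
                    if sp_code == "Gh" and n_module_pairs > 0:
                        # per-sample residual expression noise of module
                        # pairs; shared by the two homoeologs so the
                        # At/Dt ratio stays unbiased (seed pair: none)
                        eps = rng.normal(
                            0.0, config.module_noise_sd, size=n_module_pairs
                        )
                        eps[seed_pairs] = 0.0
                        factor = np.exp(eps)
                        mu = base_mu.copy()
                        mu[:n_module_pairs] *= factor
                        mu[npairs : npairs + n_module_pairs] *= factor
                    nb_n = 1.0 / config.nb_dispersion
                    p = nb_n / (nb_n + mu)
                    cols[sid] = rng.negative_binomial(nb_n, p)
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "species": sp_code,
                            "cultivar": cultivar,
                            "stage_dpa": s,
                            "replicate": rep,
                        }
                    )
        counts_blocks.append(
            pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        )
        expected_blocks.append(
            pd.DataFrame(expected, index=pd.Index(genes, name="gene_id"),
                         columns=list(stages))
        )

        other_prefix = "Gb" if sp_code == "Gh" else "Gh"
        for i in range(npairs):
            pid = f"{sp_code}P{i:05d}"
            postponed_class = (
                shift_names[shift_class[i]] if postponed[i] else "consistent"
            )
            pair_rows.append(
                {
                    "pair_id": pid,
                    "a_gene": gene_a[i],
                    "d_gene": gene_d[i],
                    "species": sp_code,
                    "ortholog_pair_id": f"{other_prefix}P{i:05d}",
                    "bias_direction": direction[i],
                    "bias_log2fc": config.bias_log2fc if biased[i] else 0.0,
                    "peak_stage": int(peak[i]),
                    "postponed_class": postponed_class,
                }
            )
            module = (
                f"M{module_of_pair[i] + 1}"
                if sp_code == "Gh" and module_of_pair[i] >= 0
                else "none"
            )
            is_hub_pair = (
                module != "none" and i % pairs_per_module == 0
            )
            for role, g in (("A", gene_a[i]), ("D", gene_d[i])):
                gene_rows.append(
                    {
                        "gene_id": g,
                        "species": sp_code,
                        "pair_id": pid,
                        "subgenome": role,
                        "peak_stage": int(peak[i]),
                        "postponed_class": postponed_class,
                        "module": module,
                        "loading": float(loadings[i]) if module != "none" else 0.0,
                        "is_hub": bool(is_hub_pair and role == "A"),
                    }
                )

    # assemble one counts table: zero counts for cross-species blocks
    all_samples = [r["sample_id"] for r in sheet_rows]
    full = pd.concat(counts_blocks).reindex(columns=all_samples).fillna(0)
    counts = CountsTable(
        counts=full.astype(np.int64), lengths=pd.concat(lengths_all)
    )
    sheet = SampleSheet(
        frame=pd.DataFrame(sheet_rows),
        stage_set=tuple(sorted(set(config.stages_full) | set(config.stages_partial))),
    )
    pair_frame = pd.DataFrame(pair_rows)
    pairs = HomoeologPairMap(
        frame=pair_frame[
            ["pair_id", "a_gene", "d_gene", "species", "ortholog_pair_id"]
        ]
    )
    truth = SimTruth(
        pairs=pair_frame,
        genes=pd.DataFrame(gene_rows),
        expected_counts=pd.concat(expected_blocks),
    )
    return SimDataset(counts=counts, sheet=sheet, pairs=pairs,
                      lengths=counts.lengths), truth


def write_dataset(
    dataset: SimDataset,
    truth: SimTruth,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write a simulated dataset directory in the pipeline's TSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(dataset.counts, outdir / "counts.tsv")
    write_table(dataset.sheet.frame, outdir / "samples.tsv")
    write_table(dataset.pairs.frame, outdir / "pairs.tsv")
    lengths = dataset.lengths.rename_axis("gene_id").reset_index()
    write_table(lengths, outdir / "lengths.tsv")
    write_table(truth.pairs, outdir / "truth_pairs.tsv")
    write_table(truth.genes, outdir / "truth_genes.tsv")
    if config is not None:
        import yaml

        (outdir / "config.yaml").write_text(
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(config).items()
                },
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def evaluate_bias_recovery(
    calls: pd.DataFrame,
    truth_pairs: pd.DataFrame,
    min_mean_fpkm: float | None = None,
) -> dict[str, float]:
    """Score bias calls against planted truth.

    Sensitivity is the fraction of planted-biased pairs *that were
    tested* (passed the expression filter; optionally further restricted
    to mean FPKM >= ``min_mean_fpkm``) called biased in the planted
    direction; the empirical FDR is the fraction of biased calls whose
    pair is planted null. Returns NaN for ratios with an empty
    denominator.
    """
    t = truth_pairs.set_index("pair_id")["bias_direction"]
    c = calls[calls["pair_id"].isin(t.index)].copy()
    c["planted"] = t.loc[c["pair_id"]].to_numpy()
    tested = c[c["call"] != "not_expressed"].copy()
    if min_mean_fpkm is not None:
        tested = tested[
            (tested["fpkm_a"] + tested["fpkm_d"]) / 2.0 >= min_mean_fpkm
        ]
    called = tested[tested["call"].isin(["A_biased", "D_biased"])]
    planted_pos = tested["planted"].isin(["A", "D"])
    match = (
        (tested["call"] == "A_biased") & (tested["planted"] == "A")
    ) | ((tested["call"] == "D_biased") & (tested["planted"] == "D"))

    n_planted = int(planted_pos.sum())
    n_called = len(called)
    n_false = int((called["planted"] == "none").sum())
    planted_called = called[called["planted"].isin(["A", "D"])]
    correct_dir = (
        (planted_called["call"] == "A_biased") & (planted_called["planted"] == "A")
    ) | ((planted_called["call"] == "D_biased") & (planted_called["planted"] == "D"))
    return {
        "sensitivity": float(match.sum()) / n_planted if n_planted else float("nan"),
        "empirical_fdr": n_false / n_called if n_called else float("nan"),
        "direction_accuracy": (
            float(correct_dir.sum()) / len(planted_called)
            if len(planted_called)
            else float("nan")
        ),
        "n_planted_tested": float(n_planted),
        "n_called": float(n_called),
    }


def evaluate_postponement_recovery(
    calls: pd.DataFrame, truth_genes: pd.DataFrame
) -> dict[str, float]:
    """Score postponement calls against planted per-gene truth.

    ``calls`` come from :func:`allofiber.temporal.detect_postponement`
    (keyed by ``gh_gene``); truth supplies each G. hirsutum gene's
    planted class. Reports per-shift-class sensitivity, the fraction of
    planted-postponed genes wrongly called advanced, and the empirical
    FDR of postponed calls.
    """
    t = truth_genes[truth_genes["species"] == "Gh"].set_index("gene_id")[
        "postponed_class"
    ]
    c = calls[calls["gh_gene"].isin(t.index)].copy()
    c["planted"] = t.loc[c["gh_gene"]].to_numpy()
    out: dict[str, float] = {}
    planted_post = c[c["planted"].str.startswith("postponed")]
    for cls in sorted(set(t) - {"consistent"}):
        sub = c[c["planted"] == cls]
        out[f"sensitivity_{cls.removeprefix('postponed_')}"] = (
            float((sub["class"] == cls).sum()) / len(sub) if len(sub) else float("nan")
        )
    called_post = c[c["class"].str.startswith("postponed")]
    out["empirical_fdr"] = (
        float((called_post["planted"] == "consistent").sum()) / len(called_post)
        if len(called_post)
        else float("nan")
    )
    out["frac_advanced_among_planted"] = (
        float((planted_post["class"] == "advanced").sum()) / len(planted_post)
        if len(planted_post)
        else float("nan")
    )
    return out


def evaluate_module_recovery(
    labels: pd.Series, truth_labels: pd.Series
) -> float:
    """Adjusted Rand index between detected and planted module labels.

    Evaluated over the genes present in both labelings; the unassigned
    category counts as its own label.
    """
    common = labels.index.intersection(truth_labels.index)
    return float(
        adjusted_rand_score(
            truth_labels.loc[common].astype(str), labels.loc[common].astype(str)
        )
    )
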