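"""Reading and writing the pipeline's tabular formats.

Everything on disk is tab-separated UTF-8 text. Counts arrive either as
featureCounts output (``Geneid/Chr/Start/End/Strand/Length`` plus sample
columns, optionally preceded by a ``#`` comment line) or as a plain
gene-by-sample table. Sample metadata, homoeolog pair maps and every
pipeline output use plain TSV with a fixed column order. Leading ``#``
comment lines are tolerated by all readers so that the pipeline's own
provenance-stamped outputs round-trip.

Gene identifiers are opaque strings: the subgenome of a gene is taken
only from the pair map, never parsed out of the identifier text.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_CODES",
    "DEFAULT_STAGES",
    "CountsTable",
    "SampleSheet",
    "HomoeologPairMap",
    "FormatError",
    "read_counts",
    "read_sample_sheet",
    "read_pair_map",
    "write_table",
]

#: Recognised species codes: Gh = G. hirsutum, Gb = G. barbadense.
SPECIES_CODES = ("Gh", "Gb")

#: Fiber developmental stages sampled, in days post-anthesis.
DEFAULT_STAGES = (0, 1, 3, 5, 10, 20, 25)

_FEATURECOUNTS_META = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


@dataclass
class CountsTable:
    """Gene-level read counts with optional transcript lengths.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, indexed by gene id, one column per
        sample.
    lengths : pandas.Series or None
        Transcript length in bp per gene, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in counts table: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample library size: the column sum of assigned counts."""
        return self.counts.sum(axis=0)


@dataclass
class SampleSheet:
    """Sample metadata: species, cultivar, stage (DPA) and replicate."""

    frame: pd.DataFrame
    stage_set: tuple[int, ...] = DEFAULT_STAGES

    REQUIRED = ("sample_id", "species", "cultivar", "stage_dpa", "replicate")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        f = f.copy()
        f["sample_id"] = f["sample_id"].astype(str)
        f["stage_dpa"] = pd.to_numeric(f["stage_dpa"], errors="raise").astype(int)
        f["replicate"] = pd.to_numeric(f["replicate"], errors="raise").astype(int)
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        bad_sp = sorted(set(f["species"]) - set(SPECIES_CODES))
        if bad_sp:
            raise FormatError(f"unknown species code(s): {bad_sp}")
        bad_stage = sorted(set(f["stage_dpa"]) - set(self.stage_set))
        if bad_stage:
            raise FormatError(
                f"stage(s) {bad_stage} not in declared stage set {self.stage_set}"
            )
        if (f["replicate"] < 1).any():
            raise FormatError("replicate must be a positive integer")
        mixed = f.groupby("cultivar")["species"].nunique()
        mixed = mixed[mixed > 1]
        if not mixed.empty:
            raise FormatError(
                f"cultivar(s) mapped to more than one species: {list(mixed.index)}"
            )
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def species_of(self) -> dict[str, str]:
        return dict(
            self.frame.drop_duplicates("cultivar").set_index("cultivar")["species"]
        )

    def cultivars(self, species: str | None = None) -> list[str]:
        f = self.frame
        if species is not None:
            f = f[f["species"] == species]
        return list(dict.fromkeys(f["cultivar"]))

    def groups(self) -> dict[tuple[str, int], list[str]]:
        """Map (cultivar, stage_dpa) to the sample ids of its replicates."""
        out: dict[tuple[str, int], list[str]] = {}
        for row in self.frame.itertuples(index=False):
            out.setdefault((row.cultivar, row.stage_dpa), []).append(row.sample_id)
        return out

    def stages(self, cultivar: str) -> list[int]:
        f = self.frame[self.frame["cultivar"] == cultivar]
        return sorted(set(f["stage_dpa"]))


@dataclass
class HomoeologPairMap:
    """At/Dt homoeolog pairs, optionally linked across species.

    ``frame`` has columns ``pair_id``, ``a_gene``, ``d_gene`` and
    optionally ``species`` and ``ortholog_pair_id`` (the partner pair in
    the other species, enabling TM-1 <-> Hai7124 ortholog comparisons).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("pair_id", "a_gene", "d_gene"):
            if col not in f.columns:
                raise FormatError(f"pair map missing column {col!r}")
        if f["pair_id"].duplicated().any():
            dup = f.loc[f["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise FormatError(f"duplicate pair_id: {dup!r}")
        same = f["a_gene"] == f["d_gene"]
        if same.any():
            raise FormatError(
                f"a_gene == d_gene for pair {f.loc[same, 'pair_id'].iloc[0]!r}"
            )
        all_genes = pd.concat([f["a_gene"], f["d_gene"]])
        if all_genes.duplicated().any():
            dup = all_genes[all_genes.duplicated()].iloc[0]
            raise FormatError(f"gene {dup!r} appears in more than one pair")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, species: str) -> "HomoeologPairMap":
        if "species" not in self.frame.columns:
            raise KeyError("pair map has no species column")
        return HomoeologPairMap(self.frame[self.frame["species"] == species])

    def cross_species_links(self) -> pd.DataFrame:
        """Pair-level links between the two species.

        Returns a frame with columns ``gh_pair`` and ``gb_pair``; requires
        ``species`` and ``ortholog_pair_id`` columns.
        """
        f = self.frame
        if "ortholog_pair_id" not in f.columns or "species" not in f.columns:
            raise KeyError("pair map has no cross-species link columns")
        gh = f[(f["species"] == "Gh") & f["ortholog_pair_id"].notna()]
        known_gb = set(f.loc[f["species"] == "Gb", "pair_id"])
        links = gh[gh["ortholog_pair_id"].isin(known_gb)]
        return pd.DataFrame(
            {
                "gh_pair": links["pair_id"].to_numpy(),
                "gb_pair": links["ortholog_pair_id"].to_numpy(),
            }
        )

    def ortholog_gene_links(self) -> pd.DataFrame:
        """Gene-level ortholog links (A with A, D with D) across species."""
        pairs = self.cross_species_links()
        f = self.frame.set_index("pair_id")
        gh = f.loc[pairs["gh_pair"]]
        gb = f.loc[pairs["gb_pair"]]
        out = pd.DataFrame(
            {
                "gh_gene": np.concatenate(
                    [gh["a_gene"].to_numpy(), gh["d_gene"].to_numpy()]
                ),
                "gb_gene": np.concatenate(
                    [gb["a_gene"].to_numpy(), gb["d_gene"].to_numpy()]
                ),
                "subgenome": ["A"] * len(gh) + ["D"] * len(gb),
            }
        )
        return out.reset_index(drop=True)


def _read_tsv_lines(path: str | Path) -> tuple[list[str], list[str]]:
    """Return (comment lines, data lines) of a TSV file."""
    text = Path(path).read_text(encoding="utf-8")
    comments, data = [], []
    for line in text.splitlines():
        if not data and line.startswith("#"):
            comments.append(line)
        else:
            data.append(line)
    while data and data[-1] == "":
        data.pop()
    return comments, data


def read_counts(path: str | Path, dialect: str = "plain") -> CountsTable:
    """Read a gene-level counts table.

    Parameters
    ----------
    path : path
        TSV file to read.
    dialect : {"plain", "featurecounts"}
        ``featurecounts`` expects the tool's native header (optional
        leading ``#`` comment line, then
        ``Geneid/Chr/Start/End/Strand/Length`` plus one column per
        sample); ``Length`` is captured as transcript length. ``plain``
        expects a gene-id column followed by sample columns.

    Raises
    ------
    FormatError
        On a missing/incorrect header, a non-integer count cell (reported
        with row and column), or a duplicated gene id.
    """
    if dialect not in ("plain", "featurecounts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    _, data = _read_tsv_lines(path)
    if not data:
        raise FormatError(f"{path}: empty file (dialect {dialect!r})")
    header = data[0].split("\t")
    if dialect == "featurecounts":
        if header[: len(_FEATURECOUNTS_META)] != _FEATURECOUNTS_META:
            raise FormatError(
                f"{path}: missing featureCounts header "
                f"{'/'.join(_FEATURECOUNTS_META)} (dialect 'featurecounts')"
            )
        sample_cols = header[len(_FEATURECOUNTS_META) :]
        first_count_col = len(_FEATURECOUNTS_META)
    else:
        if len(header) < 2:
            raise FormatError(
                f"{path}: plain counts header needs a gene-id column plus "
                "at least one sample column (dialect 'plain')"
            )
        sample_cols = header[1:]
        first_count_col = 1

    genes: list[str] = []
    lengths: list[int] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(data[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        if dialect == "featurecounts":
            lengths.append(int(fields[5]))
        row = []
        for j, cell in enumerate(fields[first_count_col:]):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} in column "
                    f"{sample_cols[j]!r}"
                ) from None
            row.append(value)
        rows.append(row)

    counts = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                          columns=sample_cols, dtype=np.int64)
    length_series = (
        pd.Series(lengths, index=counts.index, name="length")
        if dialect == "featurecounts"
        else None
    )
    return CountsTable(counts=counts, lengths=length_series)


def read_sample_sheet(
    path: str | Path, stage_set: Sequence[int] = DEFAULT_STAGES
) -> SampleSheet:
    """Read and validate a sample sheet TSV."""
    _, data = _read_tsv_lines(path)
    frame = pd.read_csv(_io.StringIO("\n".join(data)), sep="\t", dtype=str)
    return SampleSheet(frame=frame, stage_set=tuple(stage_set))


def read_pair_map(path: str | Path) -> HomoeologPairMap:
    """Read and validate a homoeolog pair map TSV."""
    _, data = _read_tsv_lines(path)
    frame = pd.read_csv(_io.StringIO("\n".join(data)), sep="\t", dtype=str)
    return HomoeologPairMap(frame=frame)


def read_lengths(path: str | Path) -> pd.Series:
    """Read a 2-column gene-length TSV (gene_id, length in bp)."""
    _, data = _read_tsv_lines(path)
    frame = pd.read_csv(_io.StringIO("\n".join(data)), sep="\t")
    frame = frame.set_index(frame.columns[0])
    s = frame.iloc[:, 0].astype(int)
    s.index.name = "gene_id"
    s.name = "length"
    return s


def _format_value(v: object) -> str:
    if isinstance(v, (float, np.floating)):
        v = float(v)
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        if v != 0 and abs(v) < 1e-4:
            return f"{v:.11e}"
        return f"{v:.12g}"
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    return str(v)


def write_table(
    obj: pd.DataFrame | CountsTable,
    path: str | Path,
    header_comments: Iterable[str] = (),
    index: bool = False,
) -> None:
    """Write a tabular result as TSV.

    Floats are rendered with 12 significant digits ('.' decimal,
    scientific notation below 1e-4) so that a write/read round trip
    reproduces values to 12 significant digits. The file is
    newline-terminated. ``header_comments`` are emitted first as
    ``#``-prefixed lines.
    """
    if isinstance(obj, CountsTable):
        frame = obj.counts.reset_index()
    elif isinstance(obj, pd.DataFrame):
        frame = obj.reset_index() if index else obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    lines = [f"# {c}" if not c.startswith("#") else c for c in header_comments]
    lines.append("\t".join(str(c) for c in frame.columns))
    for row in frame.itertuples(index=False):
        lines.append("\t".join(_format_value(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
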