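"""Readers and writers for the plain-text formats the pipeline consumes,
plus the shared domain types.

Input dialects
--------------
* HTSeq-count per-sample files: two-column TSV ``gene_id<TAB>count`` with
  trailing ``__``-prefixed summary rows (``__no_feature``, ``__ambiguous``,
  ...). Summary rows are dropped on read; their totals are kept for
  book-keeping so nothing is silently lost.
* Merged count matrix TSV: header row of sample ids, one row per gene.
* Gene length table TSV: ``gene_id<TAB>length_bp`` (union-exon length).
* Sample design TSV: ``sample_id<TAB>stage`` with stage in {NP, MT, LT}.
* Human DE table TSV: columns ``gene``, ``log2fc``, ``significant`` —
  a ripe-vs-unripe cervix differential-expression gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three reproductive stages: non-pregnant (estrus), mid-pregnancy,
#: late pregnancy/term.
STAGES = ("NP", "MT", "LT")


class FormatError(ValueError):
    """An input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample to one reproductive stage.

    Parameters
    ----------
    stages
        Mapping sample_id -> stage; insertion order defines sample order.
    """

    stages: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s: st for s, st in self.stages.items() if st not in STAGES}
        if bad:
            raise FormatError(f"unknown stage(s): {bad}; expected one of {STAGES}")
        object.__setattr__(self, "stages", dict(self.stages))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.stages)

    def samples_for(self, stage: str) -> list[str]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        return [s for s, st in self.stages.items() if st == stage]

    def require_replicates(self, minimum: int = 2) -> None:
        """Raise if any present stage has fewer than ``minimum`` samples."""
        for stage in STAGES:
            n = len(self.samples_for(stage))
            if 0 < n < minimum:
                raise ValueError(
                    f"stage {stage} has {n} sample(s); at least {minimum} required"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "stage"],
                         dtype=str, comment="#")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in design {path}")
        return cls(dict(zip(df["sample_id"], df["stage"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids,
                      "stage": [self.stages[s] for s in self.sample_ids]}
                     ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with the sample->stage design.

    ``counts`` is a DataFrame indexed by gene_id with one column per sample;
    ``summary`` holds the per-sample totals of the dropped ``__*`` rows.
    """

    counts: pd.DataFrame
    design: SampleDesign
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if any(g.startswith("__") for g in self.counts.index):
            raise FormatError("summary rows (__*) must not be retained as genes")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        self.counts.index.name = "gene_id"
        missing = set(self.counts.columns) - set(self.design.sample_ids)
        if missing:
            raise FormatError(f"samples missing from design: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def to_htseq_files(self, directory: str | Path) -> dict[str, Path]:
        """Write one HTSeq-dialect file per sample (``<sample>.counts.tsv``).

        Summary rows are appended (zeros if none were recorded), so the
        files round-trip through :func:`read_htseq_counts`.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample in self.sample_ids:
            path = directory / f"{sample}.counts.tsv"
            with open(path, "w") as fh:
                for gene, count in self.counts[sample].items():
                    fh.write(f"{gene}\t{int(count)}\n")
                for row in HTSEQ_SUMMARY_ROWS:
                    total = 0
                    if not self.summary.empty and row in self.summary.index \
                            and sample in self.summary.columns:
                        total = int(self.summary.loc[row, sample])
                    fh.write(f"{row}\t{total}\n")
            paths[sample] = path
        return paths


@dataclass(frozen=True)
class GeneLengthTable:
    """Union-exon gene lengths in base pairs, as required by the TPM definition."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for g, l in self.lengths.items():
            if int(l) < 1:
                raise FormatError(f"gene {g!r} has non-positive length {l}")
        object.__setattr__(self, "lengths", {g: int(l) for g, l in self.lengths.items()})

    def __getitem__(self, gene_id: str) -> int:
        return self.lengths[gene_id]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": list(self.lengths), "length_bp": list(self.lengths.values())}
                     ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class HumanDETable:
    """Human cervix ripe-vs-unripe differential-expression gene list.

    ``table`` columns: gene_symbol (uppercased, unique), log2fc, significant.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_symbol", "log2fc", "significant"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"human DE table needs columns {sorted(required)}")
        if self.table["gene_symbol"].duplicated().any():
            dup = self.table.loc[self.table["gene_symbol"].duplicated(), "gene_symbol"].iloc[0]
            raise FormatError(f"duplicate gene symbol {dup!r} after uppercasing")

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_up(self) -> int:
        sig = self.significant
        return int((sig["log2fc"] > 0).sum())

    @property
    def n_down(self) -> int:
        sig = self.significant
        return int((sig["log2fc"] < 0).sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"gene_symbol": "gene"})
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: HTSeq-count summary rows dropped from count files.
HTSEQ_SUMMARY_ROWS = (
    "__no_feature",
    "__ambiguous",
    "__too_low_aQual",
    "__not_aligned",
    "__alignment_not_unique",
)


def _read_one_htseq(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Read one two-column HTSeq file; return (gene counts, summary totals)."""
    genes: dict[str, int] = {}
    summary: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene, raw = parts
            try:
                count = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {raw!r}") from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            target = summary if gene.startswith("__") else genes
            if gene in target:
                raise FormatError(f"{path}:{lineno}: duplicate entry {gene!r}")
            target[gene] = count
    return pd.Series(genes, dtype="int64"), pd.Series(summary, dtype="int64")


def read_htseq_counts(paths: Mapping[str, str | Path], design: SampleDesign) -> CountMatrix:
    """Assemble a :class:`CountMatrix` from per-sample HTSeq-count files.

    Parameters
    ----------
    paths
        Mapping sample_id -> file path; every sample in ``design`` must be
        present and all files must share the same gene universe.
    design
        Sample-to-stage assignment; its order fixes the column order.

    Raises
    ------
    FormatError
        On malformed lines, mismatched gene universes (the offending sample
        is named) or samples missing from either side.
    """
    missing = set(design.sample_ids) - set(paths)
    if missing:
        raise FormatError(f"no count file for sample(s): {sorted(missing)}")
    columns: dict[str, pd.Series] = {}
    summaries: dict[str, pd.Series] = {}
    universe: frozenset[str] | None = None
    first_sample = None
    for sample in design.sample_ids:
        counts, summary = _read_one_htseq(paths[sample])
        if universe is None:
            universe, first_sample = frozenset(counts.index), sample
        elif frozenset(counts.index) != universe:
            diff = universe.symmetric_difference(counts.index)
            raise FormatError(
                f"sample {sample!r} gene universe differs from {first_sample!r} "
                f"(e.g. {sorted(diff)[:3]})")
        columns[sample] = counts
        summaries[sample] = summary
        logger.info("sample %s: %d genes, %d reads in __* summary rows",
                    sample, len(counts), int(summary.sum()))
    counts = pd.DataFrame(columns).sort_index()
    summary = pd.DataFrame(summaries).fillna(0).astype("int64")
    return CountMatrix(counts=counts, design=design, summary=summary)


def read_count_matrix(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Read a merged genes x samples count matrix TSV (header = sample ids).

    ``__*`` rows, if present, are split off into the summary block exactly as
    for per-sample files.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    is_summary = df.index.str.startswith("__")
    summary = df.loc[is_summary]
    df = df.loc[~is_summary].sort_index()
    if not np.issubdtype(df.to_numpy().dtype, np.integer):
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: non-integer counts in matrix")
        df = df.round().astype("int64")
    missing = set(design.sample_ids) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: design samples absent from matrix: {sorted(missing)}")
    return CountMatrix(counts=df[design.sample_ids], design=design,
                       summary=summary.astype("int64"))


def read_length_table(path: str | Path) -> GeneLengthTable:
    """Read a two-column ``gene_id<TAB>length_bp`` TSV.

    A header row is auto-detected when the second field of the first line is
    non-numeric. Duplicate gene ids and non-positive lengths are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df.columns = ["gene_id", "length_bp"]
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no length rows")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    try:
        lengths = {g: int(float(l)) for g, l in zip(df["gene_id"], df["length_bp"])}
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric length: {exc}") from None
    return GeneLengthTable(lengths)


def read_human_de_table(path: str | Path) -> HumanDETable:
    """Read a human DE table TSV with columns ``gene``, ``log2fc``, ``significant``.

    Symbols are uppercased; duplicates after uppercasing are an error. The
    numbers of significant up- and down-regulated genes are logged.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("gene", "log2fc", "significant"):
        if needed not in cols:
            raise FormatError(f"{path}: missing column {needed!r}")
    out = pd.DataFrame({
        "gene_symbol": df[cols["gene"]].astype(str).str.upper(),
        "log2fc": df[cols["log2fc"]].astype(float),
        "significant": df[cols["significant"]].astype(bool),
    })
    if out.empty:
        logger.warning("%s: empty human DE table", path)
    table = HumanDETable(out)
    logger.info("%s: %d significant genes (%d up, %d down)",
                path, len(table.significant), table.n_up, table.n_down)
    return table
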