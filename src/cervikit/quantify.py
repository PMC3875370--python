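"""Count-to-abundance conversion and the square-root variance-stabilizing
transform.

Abundance is expressed as transcripts per million (TPM): per sample, counts
are divided by gene length to give length-normalized rates, which are then
rescaled to sum to 10^6. TPM is preferred over RPKM because its unit is
consistent across samples of different transcript composition; RPKM is
provided so the 3 TPM ~ 1 RPKM correspondence can be inspected on any
dataset. Statistical testing downstream operates on sqrt(TPM), which maps
0 to 0 (unlike the log) and stabilizes the variance of count-derived
abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cervikit.core_io import CountMatrix, GeneLengthTable, SampleDesign, STAGES

logger = logging.getLogger(__name__)


@dataclass
class TPMMatrix:
    """Per-sample TPM values, genes x samples, with the design carried along."""

    tpm: pd.DataFrame
    design: SampleDesign

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def to_tsv(self, path) -> None:
        out = self.tpm.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class StageProfile:
    """Per-stage mean TPM per gene; per-replicate values retained.

    ``means`` has one column per stage present in the design; ``replicates``
    is the underlying per-sample TPM frame.
    """

    means: pd.DataFrame
    replicates: pd.DataFrame
    design: SampleDesign

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    def stage(self, stage: str) -> pd.Series:
        if stage not in self.means.columns:
            raise ValueError(f"stage {stage!r} not present in profile")
        return self.means[stage]

    def to_tsv(self, path) -> None:
        out = self.means.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _length_vector(counts: CountMatrix, lengths: GeneLengthTable) -> np.ndarray:
    missing = [g for g in counts.gene_ids if g not in lengths.lengths]
    if missing:
        raise ValueError(
            f"{len(missing)} gene(s) without a length, e.g. {missing[:3]}")
    return np.array([lengths[g] for g in counts.gene_ids], dtype=float)


def compute_tpm(counts: CountMatrix, lengths: GeneLengthTable) -> TPMMatrix:
    """Convert read counts to TPM, per sample independently.

    tpm_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6. Columns with no reads at
    all stay all-zero (with a warning) rather than dividing by zero.
    """
    lens = _length_vector(counts, lengths)
    rates = counts.counts.to_numpy(dtype=float) / lens[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero count column(s): %s",
                       [s for s, z in zip(counts.sample_ids, zero) if z])
        totals = np.where(zero, 1.0, totals)
    tpm = rates / totals * 1e6
    frame = pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)
    return TPMMatrix(tpm=frame, design=counts.design)


def compute_rpkm(counts: CountMatrix, lengths: GeneLengthTable) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    rpkm_i = c_i / (l_i/1e3 * N/1e6) with N the retained column sum (mapped
    reads after dropping the ``__*`` summary rows). Unlike TPM this is not
    invariant in unit across samples; it exists for cross-checks.
    """
    lens = _length_vector(counts, lengths)
    arr = counts.counts.to_numpy(dtype=float)
    n = arr.sum(axis=0)
    n = np.where(n == 0, 1.0, n)
    rpkm = arr / (lens[:, None] / 1e3 * n / 1e6)
    return pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids)


def sqrt_transform(values):
    """Elementwise square root: 0 -> 0, strictly monotone on non-negatives."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("sqrt_transform requires non-negative input")
    out = np.sqrt(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def stage_means(tpm: TPMMatrix, design: SampleDesign | None = None,
                stages: tuple[str, ...] = STAGES) -> StageProfile:
    """Arithmetic mean of per-sample TPM within each requested stage.

    A requested stage with no samples in the design is an error.
    """
    design = design or tpm.design
    cols = {}
    for stage in stages:
        samples = design.samples_for(stage)
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples in the design")
        cols[stage] = tpm.tpm[samples].mean(axis=1)
    return StageProfile(means=pd.DataFrame(cols), replicates=tpm.tpm, design=design)
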