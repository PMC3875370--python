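"""Differential-expression testing on square-root-transformed TPM.

Testing here is hypothesis-driven, not a genome-wide discovery screen: a
one-way fixed-effects ANOVA across the three reproductive stages and
two-tailed pairwise t-tests, all on sqrt(TPM), with **no** multiple-testing
correction — p-values are reported raw, and callers testing many genes must
interpret them accordingly.

The pairwise test defaults to the classical pooled-variance Student's t
(df = n1 + n2 - 2); Welch's unequal-variance test is available behind the
``welch`` flag. Genes with zero variance everywhere return F = 0 / t = 0
and p = 1 rather than failing, so pipelines over thousands of genes never
abort on a degenerate gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from cervikit.core_io import SampleDesign, STAGES
from cervikit.quantify import TPMMatrix, sqrt_transform


def anova_three_stage(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA on already-transformed replicate vectors.

    Returns ``(F, p)`` with p the upper tail of F(k-1, N-k). Every group
    needs at least two replicates. Inputs with zero between- and
    within-group variance return ``(0.0, 1.0)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 replicates")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    grand = flat.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = len(flat) - len(arrays)
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def pairwise_t(values_a: Sequence[float], values_b: Sequence[float],
               welch: bool = False) -> tuple[float, float]:
    """Two-tailed t-test; pooled-variance Student's t by default.

    Returns ``(t, p)``. Zero pooled variance with equal means gives
    ``(0.0, 1.0)``; with unequal means it gives an infinite t and p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fold_change(mean_late: float, mean_early: float) -> float:
    """Ratio late/early of stage-mean abundances; NaN when early is zero."""
    if mean_early < 0 or mean_late < 0:
        raise ValueError("stage means must be non-negative")
    if mean_early == 0:
        return float("nan")
    return mean_late / mean_early


@dataclass
class DiffTestResult:
    """Per-gene ANOVA + pairwise results as a flat table.

    Columns: ``F``, ``p_anova``, and per stage pair ``t_<A>_<B>``,
    ``p_<A>_<B>``, ``fc_<A>_<B>`` (fold change later/earlier on the raw TPM
    scale).
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def test_gene_set(tpm: TPMMatrix, design: SampleDesign | None = None,
                  genes: Sequence[str] | None = None,
                  welch: bool = False) -> DiffTestResult:
    """ANOVA across stages plus all pairwise t-tests for each gene.

    TPM values are sqrt-transformed first; fold changes are computed on the
    untransformed stage means. p-values are raw (no correction).
    """
    design = design or tpm.design
    design.require_replicates(2)
    genes = list(genes) if genes is not None else tpm.gene_ids
    stage_samples = {st: design.samples_for(st) for st in STAGES
                     if design.samples_for(st)}
    if len(stage_samples) < 2:
        raise ValueError("need at least two stages with samples")
    pairs = [p for p in combinations(STAGES, 2)
             if p[0] in stage_samples and p[1] in stage_samples]

    sub = tpm.tpm.loc[genes]
    sq = sqrt_transform(sub)
    rows = []
    for gene in genes:
        vecs = {st: sq.loc[gene, samples].to_numpy()
                for st, samples in stage_samples.items()}
        row: dict[str, float] = {}
        if len(vecs) >= 2 and all(len(v) >= 2 for v in vecs.values()):
            row["F"], row["p_anova"] = anova_three_stage(*vecs.values())
        for early, late in pairs:
            t, p = pairwise_t(vecs[early], vecs[late], welch=welch)
            row[f"t_{early}_{late}"] = t
            row[f"p_{early}_{late}"] = p
            m_early = sub.loc[gene, stage_samples[early]].mean()
            m_late = sub.loc[gene, stage_samples[late]].mean()
            row[f"fc_{early}_{late}"] = fold_change(m_late, m_early)
        rows.append(row)
    return DiffTestResult(pd.DataFrame(rows, index=pd.Index(genes, name="gene_id")))
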