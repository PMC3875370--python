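"""Cross-species fold-change concordance against a human cervix DE table.

The human ripe-vs-unripe significant gene list is joined to the guinea-pig
mid-to-late pregnancy (MT -> LT) results by uppercased gene symbol. Fold
changes are compared on the log2 scale — fold changes are scale-free, so no
cross-platform normalization is attempted beyond that. A joined gene is

* ``concordant``  — same fold-change direction as in human AND a significant
  guinea-pig MT-vs-LT pairwise t-test (sqrt scale, uncorrected);
* ``discordant``  — opposite direction AND significant in guinea pig;
* ``unresolved``  — otherwise (not significant, or a zero/undefined guinea
  pig fold change).

Only *detected* genes — expressed at or above the 3-TPM threshold in MT or
LT per the calls module — are classified at all.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from cervikit.core_io import HumanDETable

logger = logging.getLogger(__name__)

CLASSES = ("concordant", "discordant", "unresolved")


def join_by_symbol(human: HumanDETable, gp_results: pd.DataFrame,
                   gp_calls: pd.DataFrame) -> pd.DataFrame:
    """Join the human significant set to guinea-pig MT->LT results by symbol.

    Parameters
    ----------
    human
        The human DE table; only its significant rows enter the join.
    gp_results
        Per-gene test results (from ``stats.test_gene_set``) indexed by gene
        id, with columns ``p_MT_LT`` and ``fc_MT_LT``.
    gp_calls
        MT->LT transition calls (from ``calls.classify_transition``); a gene
        is *detected* unless its call is ``silent`` (i.e. it is expressed in
        MT or LT).

    Returns an unclassified concordance table indexed by symbol with columns
    ``human_log2fc``, ``gp_log2fc``, ``gp_p``, ``gp_detected``. Guinea-pig
    fold changes of zero or from a zero early mean give NaN log2fc.
    """
    for col in ("p_MT_LT", "fc_MT_LT"):
        if col not in gp_results.columns:
            raise ValueError(f"gp_results lacks column {col!r}")
    sig = human.significant.set_index("gene_symbol")
    gp_index = pd.Index([g.upper() for g in gp_results.index])
    upper_results = gp_results.set_axis(gp_index)
    detected = gp_calls["call"] != "silent"
    detected = detected.set_axis([g.upper() for g in detected.index])

    common = sig.index.intersection(upper_results.index)
    absent = sig.index.difference(upper_results.index)
    if len(common) == 0:
        logger.warning("no human symbols found in the guinea-pig universe")
    logger.info("human significant genes: %d; in gp universe: %d; absent: %d",
                len(sig), len(common), len(absent))

    fc = upper_results.loc[common, "fc_MT_LT"].astype(float).to_numpy()
    gp_log2fc = np.full(len(fc), np.nan)
    pos = np.isfinite(fc) & (fc > 0)
    gp_log2fc[pos] = np.log2(fc[pos])
    table = pd.DataFrame(
        {
            "human_log2fc": sig.loc[common, "log2fc"].astype(float),
            "gp_log2fc": gp_log2fc,
            "gp_p": upper_results.loc[common, "p_MT_LT"].astype(float),
            "gp_detected": detected.reindex(common, fill_value=False).astype(bool),
        },
        index=common,
    )
    table.index.name = "gene_symbol"
    table.attrs["n_input"] = len(sig)
    table.attrs["n_detected"] = int(table["gp_detected"].sum())
    return table


def fold_change_correlation(table: pd.DataFrame, method: str = "pearson") -> float:
    """Correlation of (human, guinea pig) log2 fold changes over detected genes.

    Pearson by default; Spearman available via ``method``. Genes with an
    undefined guinea-pig log2fc are dropped. Requires at least 3 usable
    genes.
    """
    sub = table[table["gp_detected"]].dropna(subset=["gp_log2fc", "human_log2fc"])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 detected genes, have {len(sub)}")
    if method == "pearson":
        r = sps.pearsonr(sub["human_log2fc"], sub["gp_log2fc"]).statistic
    elif method == "spearman":
        r = sps.spearmanr(sub["human_log2fc"], sub["gp_log2fc"]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def classify_concordance(table: pd.DataFrame, alpha: float = 0.05
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign concordant/discordant/unresolved to each detected gene.

    Returns the classified table (new ``class`` column; undetected genes get
    NA) and a summary dict with ``n_input``, ``n_detected``,
    ``n_concordant``, ``n_discordant``, ``n_unresolved``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = table.copy()
    h = out["human_log2fc"].to_numpy(dtype=float)
    g = out["gp_log2fc"].to_numpy(dtype=float)
    p = out["gp_p"].to_numpy(dtype=float)
    det = out["gp_detected"].to_numpy(dtype=bool)

    usable = det & np.isfinite(g) & (np.sign(g) != 0) & (np.sign(h) != 0)
    significant = usable & (p < alpha)
    same = significant & (np.sign(h) == np.sign(g))
    opposite = significant & (np.sign(h) != np.sign(g))

    cls = np.full(len(out), None, dtype=object)
    cls[det] = "unresolved"
    cls[same] = "concordant"
    cls[opposite] = "discordant"
    out["class"] = pd.Categorical(cls, categories=CLASSES)

    summary = {
        "n_input": int(out.attrs.get("n_input", len(out))),
        "n_detected": int(det.sum()),
        "n_concordant": int(same.sum()),
        "n_discordant": int(opposite.sum()),
        "n_unresolved": int((cls == "unresolved").sum()),
    }
    return out, summary
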