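"""The operational on/off calculus for stage transitions.

A gene is *expressed* at a stage when its mean abundance is at or above the
operational threshold of 3 TPM (which corresponds to roughly 1 RPKM).
Between an earlier and a later reproductive stage a gene is then

* ``induced``        — below the threshold early, at/above it late (turned ON);
* ``repressed``      — at/above early, below late (turned OFF);
* ``modulated_up``   — expressed in both, fold change > 1;
* ``modulated_down`` — expressed in both, fold change < 1;
* ``modulated_flat`` — expressed in both, fold change == 1 within tolerance;
* ``silent``         — below the threshold in both.

Fold changes are only meaningful for modulated genes (both abundances are
real expression levels); for induced/repressed/silent genes they are left
undefined (NaN).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from cervikit.quantify import StageProfile

#: Operational expressed/off threshold in TPM.
DEFAULT_THRESHOLD = 3.0

#: Relative tolerance under which a modulated fold change counts as flat.
_FLAT_RTOL = 1e-9

CALL_CATEGORIES = (
    "induced", "repressed", "modulated_up", "modulated_down",
    "modulated_flat", "silent",
)

#: Valid ordered stage pairs along the reproductive cycle.
TRANSITIONS = (("NP", "MT"), ("MT", "LT"))


def classify_transition(profile: StageProfile, early: str, late: str,
                        threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Classify every gene for the ``early -> late`` stage transition.

    Returns a DataFrame indexed by gene_id with columns ``transition``,
    ``call``, ``early_tpm``, ``late_tpm``, ``fold_change`` (NaN except for
    modulated calls, where it is late/early).
    """
    if early == late:
        raise ValueError("early and late stage must differ")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    e = profile.stage(early).to_numpy(dtype=float)
    l = profile.stage(late).to_numpy(dtype=float)

    on_e, on_l = e >= threshold, l >= threshold
    call = np.empty(len(e), dtype=object)
    call[~on_e & on_l] = "induced"
    call[on_e & ~on_l] = "repressed"
    call[~on_e & ~on_l] = "silent"
    both = on_e & on_l
    fc = np.full(len(e), np.nan)
    fc[both] = l[both] / e[both]
    flat = both & np.isclose(fc, 1.0, rtol=_FLAT_RTOL, atol=0.0)
    call[both & (fc > 1) & ~flat] = "modulated_up"
    call[both & (fc < 1) & ~flat] = "modulated_down"
    call[flat] = "modulated_flat"

    return pd.DataFrame(
        {
            "transition": f"{early}->{late}",
            "call": pd.Categorical(call, categories=CALL_CATEGORIES),
            "early_tpm": e,
            "late_tpm": l,
            "fold_change": fc,
        },
        index=pd.Index(profile.gene_ids, name="gene_id"),
    )


def rank_state_change(calls: pd.DataFrame, which: str) -> pd.DataFrame:
    """Ranked list of induced or repressed genes for one transition.

    Induced genes are ordered by descending late-stage TPM, repressed genes
    by descending early-stage TPM — in each case the stage in which the gene
    is actually expressed. Ties break lexicographically by gene_id.
    """
    if which not in ("induced", "repressed"):
        raise ValueError("which must be 'induced' or 'repressed'")
    sort_col = "late_tpm" if which == "induced" else "early_tpm"
    sub = calls[calls["call"] == which].copy()
    sub = sub.rename_axis("gene_id").sort_values(
        [sort_col, "gene_id"], ascending=[False, True])
    return sub


def find_expression_gap(ranked_tpm: Iterable[float], max_rank: int = 50) -> int:
    """Index of the largest abundance discontinuity in a ranked list.

    Given TPM values sorted in descending order, returns the index ``i``
    maximizing ``ranked_tpm[i] / ranked_tpm[i+1]`` over ``i < max_rank``;
    the "head" of the list is the first ``i + 1`` genes. Ratios (log-scale
    gaps) are used because ranked expression spans decades; the first
    occurrence wins ties.
    """
    vals = np.asarray(list(ranked_tpm), dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two values to locate a gap")
    if (vals <= 0).any():
        raise ValueError("all values must be positive")
    if np.any(np.diff(vals) > 0):
        raise ValueError("values must be sorted in descending order")
    upto = min(max_rank, len(vals) - 1)
    ratios = vals[:upto] / vals[1:upto + 1]
    return int(np.argmax(ratios))


def call_summary(calls: pd.DataFrame) -> pd.Series:
    """Counts per call category; the four coarse classes plus flat sum to
    the gene universe."""
    return calls["call"].value_counts().reindex(CALL_CATEGORIES, fill_value=0)
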