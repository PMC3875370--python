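"""Synthetic RNA-seq data with planted ground truth.

The generator emulates the study design the pipeline targets: cervical
tissue at three reproductive stages with 3 (NP) / 3 (MT) / 4 (LT)
biological replicates, negative-binomial read counts, and a matched
human-style DE table with a controllable concordance structure. Real
sequencing depth in such studies is ~45 million reads per sample; the
default here is scaled to one million so desk-scale tests stay fast while
keeping counting noise realistically small relative to the planted effects.

Genes are planted in classes defined on the MT -> LT transition (NP is set
equal to MT): ``induced``, ``repressed``, ``modulated_up``,
``modulated_down``, ``null`` (expressed, unchanged) and ``silent``. Planted
stage means are kept at least 4x away from the 3-TPM threshold, and a small
set of highly expressed filler genes absorbs the remaining transcriptome so
that planted per-stage TPMs sum to exactly 10^6 — realized TPM then matches
the planted abundance in expectation.

Counts are negative binomial with variance mu + phi * mu^2 (per-gene
dispersion phi, default 0.1, the conventional bulk RNA-seq noise scale);
phi = 0 falls back to Poisson. All randomness flows from one seed through
a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from cervikit.core_io import (
    CountMatrix,
    GeneLengthTable,
    HumanDETable,
    SampleDesign,
    STAGES,
)

THRESHOLD = 3.0

#: Default planted class mix (fractions of the gene universe).
DEFAULT_CLASS_FRACTIONS = {
    "induced": 0.05,
    "repressed": 0.05,
    "modulated_up": 0.05,
    "modulated_down": 0.05,
    "null": 0.70,
    "silent": 0.10,
}

#: Default replicate structure: triplicates for NP and MT, four for LT.
DEFAULT_REPLICATES = {"NP": 3, "MT": 3, "LT": 4}

_N_FILLER = 20


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` is indexed by gene_id with columns ``class_MT_LT``,
    ``class_NP_MT``, ``tpm_NP``, ``tpm_MT``, ``tpm_LT``, ``dispersion`` and
    ``concordance_role`` (one of concordant/discordant/none).
    """

    table: pd.DataFrame
    seed: int

    def genes_in_class(self, cls: str, transition: str = "MT_LT") -> list[str]:
        col = f"class_{transition}"
        return list(self.table.index[self.table[col] == cls])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _classify_true(early: np.ndarray, late: np.ndarray) -> np.ndarray:
    """Apply the 3-TPM calculus to noise-free planted means."""
    call = np.empty(len(early), dtype=object)
    on_e, on_l = early >= THRESHOLD, late >= THRESHOLD
    call[~on_e & on_l] = "induced"
    call[on_e & ~on_l] = "repressed"
    call[~on_e & ~on_l] = "silent"
    both = on_e & on_l
    call[both & (late > early)] = "modulated_up"
    call[both & (late < early)] = "modulated_down"
    call[both & (late == early)] = "null"
    return call


def generate_counts(
    n_genes: int = 2000,
    class_fractions: Mapping[str, float] | None = None,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    depth_reads: int = 1_000_000,
    replicates: Mapping[str, int] | None = None,
    seed: int = 0,
    n_concordant: int = 9,
    n_discordant: int = 27,
) -> tuple[CountMatrix, GeneLengthTable, SampleDesign, SyntheticTruth]:
    """Simulate a staged count matrix with planted transition classes.

    Parameters
    ----------
    n_genes
        Size of the gene universe (filler genes come on top).
    class_fractions
        Fractions per planted MT->LT class; must sum to 1.
    effect_log2fc
        Planted |log2 fold change| for modulated genes (>= 2 keeps effects
        unambiguous at the default noise level).
    dispersion
        Negative-binomial dispersion phi (variance mu + phi mu^2); 0 gives
        Poisson counts.
    depth_reads
        Target library size per sample; realized sizes get ~5% lognormal
        jitter.
    replicates
        Samples per stage; defaults to NP:3, MT:3, LT:4.
    n_concordant, n_discordant
        Genes marked with a concordance role for the cross-species stage:
        concordant roles are drawn from modulated-up genes, discordant roles
        from modulated-down genes (mirroring a mostly-up human gene list).
    """
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {sum(fractions.values())}")
    unknown = set(fractions) - set(DEFAULT_CLASS_FRACTIONS)
    if unknown:
        raise ValueError(f"unknown class(es): {sorted(unknown)}")
    replicates = dict(replicates or DEFAULT_REPLICATES)
    rng = np.random.default_rng(seed)

    # planted class assignment
    classes = []
    for cls, frac in fractions.items():
        classes.extend([cls] * int(round(frac * n_genes)))
    while len(classes) < n_genes:
        classes.append("null")
    classes = np.array(classes[:n_genes], dtype=object)
    rng.shuffle(classes)

    lo_off, hi_off = 0.05, THRESHOLD / 4      # "off" means, 4x below threshold
    lo_on, hi_on = THRESHOLD * 4, 300.0       # expressed means, 4x above
    eff = 2.0 ** effect_log2fc

    mt = np.empty(n_genes)
    lt = np.empty(n_genes)
    off = lambda n: rng.uniform(lo_off, hi_off, n)
    on = lambda n: rng.uniform(lo_on, hi_on, n)
    for cls in DEFAULT_CLASS_FRACTIONS:
        idx = np.flatnonzero(classes == cls)
        n = len(idx)
        if cls == "silent":
            mt[idx], lt[idx] = off(n), off(n)
        elif cls == "induced":
            mt[idx], lt[idx] = off(n), on(n)
        elif cls == "repressed":
            mt[idx], lt[idx] = on(n), off(n)
        elif cls == "modulated_up":
            mt[idx] = rng.uniform(lo_on, hi_on / eff, n)
            lt[idx] = mt[idx] * eff
        elif cls == "modulated_down":
            lt[idx] = rng.uniform(lo_on, hi_on / eff, n)
            mt[idx] = lt[idx] * eff
        else:  # null
            mt[idx] = on(n)
            lt[idx] = mt[idx]
    np_means = mt.copy()  # NP profile identical to MT by construction

    # filler genes absorb the rest of the transcriptome so per-stage planted
    # TPMs sum to exactly 1e6 (TPM is compositional)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    filler_ids = [f"FILLER{i:02d}" for i in range(_N_FILLER)]
    means = pd.DataFrame(
        {"NP": np_means, "MT": mt, "LT": lt}, index=gene_ids)
    filler = pd.DataFrame(
        {st: np.full(_N_FILLER, (1e6 - means[st].sum()) / _N_FILLER)
         for st in STAGES},
        index=filler_ids)
    if (filler.to_numpy() <= 0).any():
        raise ValueError("planted means exceed 1e6 TPM; reduce n_genes or means")
    means = pd.concat([means, filler])

    # concordance roles
    role = pd.Series("none", index=means.index, dtype=object)
    up_genes = [g for g, c in zip(gene_ids, classes) if c == "modulated_up"]
    down_genes = [g for g, c in zip(gene_ids, classes) if c == "modulated_down"]
    if n_concordant > len(up_genes) or n_discordant > len(down_genes):
        raise ValueError("not enough modulated genes to host the planted roles")
    role[rng.choice(up_genes, size=n_concordant, replace=False)] = "concordant"
    role[rng.choice(down_genes, size=n_discordant, replace=False)] = "discordant"

    # design and lengths
    design = SampleDesign({
        f"{st}{i + 1}": st for st in STAGES for i in range(replicates.get(st, 0))
    })
    lengths = np.exp(rng.uniform(np.log(300), np.log(30_000), len(means))).round()
    length_table = GeneLengthTable(dict(zip(means.index, lengths.astype(int))))

    # expected counts: reads proportional to tpm * length, scaled to depth
    counts = {}
    for sample, stage in design.stages.items():
        tpm = means[stage].to_numpy()
        weights = tpm * lengths
        lib = depth_reads * rng.lognormal(0.0, 0.05)
        mu = lib * weights / weights.sum()
        if dispersion > 0:
            size = 1.0 / dispersion
            counts[sample] = rng.negative_binomial(size, size / (size + mu))
        else:
            counts[sample] = rng.poisson(mu)
    count_frame = pd.DataFrame(counts, index=means.index).sort_index()

    truth_table = pd.DataFrame({
        "class_MT_LT": _classify_true(means["MT"].to_numpy(), means["LT"].to_numpy()),
        "class_NP_MT": _classify_true(means["NP"].to_numpy(), means["MT"].to_numpy()),
        "tpm_NP": means["NP"],
        "tpm_MT": means["MT"],
        "tpm_LT": means["LT"],
        "dispersion": dispersion,
        "concordance_role": role,
    }, index=means.index).sort_index()

    matrix = CountMatrix(counts=count_frame, design=design)
    return matrix, length_table, design, SyntheticTruth(truth_table, seed=seed)


def generate_human_table(
    truth: SyntheticTruth,
    n_significant: int = 89,
    n_up: int = 81,
    n_undetected: int = 13,
    seed: int = 0,
) -> HumanDETable:
    """Build a human-style DE table matched to the planted truth.

    The significant list contains every gene with a planted concordance
    role — its human log2fc sign agrees with the planted guinea-pig MT->LT
    direction for ``concordant`` genes and disagrees for ``discordant``
    ones — padded with ``n_undetected`` silent genes (absent/undetected in
    the simulated tissue) and with expressed-but-unchanged ``null`` genes.
    Signs of the padding genes are chosen to hit ``n_up`` positive log2fc
    among the significant set.
    """
    if n_up > n_significant:
        raise ValueError("n_up cannot exceed n_significant")
    rng = np.random.default_rng(seed)
    t = truth.table
    conc = list(t.index[t["concordance_role"] == "concordant"])
    disc = list(t.index[t["concordance_role"] == "discordant"])

    rows: list[tuple[str, float]] = []
    for g in conc:
        sign = 1.0 if t.loc[g, "class_MT_LT"] == "modulated_up" else -1.0
        rows.append((g, sign))
    for g in disc:
        sign = -1.0 if t.loc[g, "class_MT_LT"] == "modulated_down" else 1.0
        rows.append((g, -sign))  # opposite of the guinea-pig direction
    # note: discordant = human sign opposite to planted gp sign

    n_pad = n_significant - len(rows)
    if n_pad < 0:
        raise ValueError("more planted roles than n_significant")
    silent = [g for g in truth.genes_in_class("silent") if t.loc[g, "concordance_role"] == "none"]
    null = [g for g in truth.genes_in_class("null") if t.loc[g, "concordance_role"] == "none"]
    if n_undetected > len(silent) or n_pad - n_undetected > len(null):
        raise ValueError("not enough silent/null genes to pad the human table")
    pad = list(rng.choice(silent, size=n_undetected, replace=False))
    pad += list(rng.choice(null, size=n_pad - n_undetected, replace=False))

    up_so_far = sum(1 for _, s in rows if s > 0)
    need_up = n_up - up_so_far
    if not 0 <= need_up <= len(pad):
        raise ValueError(
            f"cannot reach {n_up} up-regulated genes: roles fix {up_so_far} up "
            f"and only {len(pad)} padding genes remain")
    pad_signs = np.array([1.0] * need_up + [-1.0] * (len(pad) - need_up))
    rng.shuffle(pad_signs)
    rows.extend(zip(pad, pad_signs))

    symbols = [g.upper() for g, _ in rows]
    signs = np.array([s for _, s in rows])
    magnitudes = rng.uniform(0.5, 3.0, len(rows))
    table = pd.DataFrame({
        "gene_symbol": symbols,
        "log2fc": signs * magnitudes,
        "significant": True,
    })
    return HumanDETable(table)


# ---------------------------------------------------------------------------
# Phylogenetic fixture
# ---------------------------------------------------------------------------

#: The two alternative assumptions for the mouse lemur, whose peripartum
#: progesterone profile is uncertain: state 1 = no systemic withdrawal
#: (FPW), state 0 = withdrawal.
FIXTURE_SCENARIOS = {
    "lemur=1": {"MouseLemur": 1},
    "lemur=0": {"MouseLemur": 0},
}


def fixture_phylo() -> tuple[str, pd.DataFrame, dict[str, dict[str, int]]]:
    """The Euarchontoglires progesterone-withdrawal fixture.

    Returns the newick text (16 tips including the Laurasiatheria
    outgroup), the character table (taxon, state with the mouse lemur left
    ``?``), and the two lemur scenarios. Byte-stable: read from files
    shipped with the package.
    """
    data = importlib.resources.files("cervikit") / "data"
    newick = (data / "fpw_tree.nwk").read_text()
    chars = pd.read_csv(str(data / "fpw_characters.tsv"), sep="\t",
                        header=None, names=["taxon", "state"], dtype=str)
    return newick, chars, {k: dict(v) for k, v in FIXTURE_SCENARIOS.items()}


def fixture_characterized_tree(root_constraint: int | None = 0):
    """Convenience: the fixture as a ready-to-run CharacterizedTree."""
    from cervikit.phylo import CharacterizedTree, parse_newick

    newick, chars, _ = fixture_phylo()
    tree = parse_newick(newick)
    states = dict(zip(chars["taxon"], chars["state"]))
    return CharacterizedTree(tree, states, root_constraint=root_constraint)
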