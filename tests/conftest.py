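import numpy as np
import pandas as pd
import pytest

from cervikit import calls, quantify, stats, synth
from cervikit.core_io import CountMatrix, GeneLengthTable, SampleDesign


#: Library depth for the recovery experiments: an 11x scale-down from the
#: ~45M-read study regime. At this depth a sub-threshold gene still draws
#: enough reads that one stray read cannot push its stage mean past 3 TPM,
#: which is the regime the planted-recovery claims describe.
RECOVERY_DEPTH = 4_000_000


@pytest.fixture(scope="session")
def sim():
    """A seeded synthetic dataset with planted classes and roles."""
    cm, lengths, design, truth = synth.generate_counts(
        n_genes=800, depth_reads=RECOVERY_DEPTH, seed=11)
    return cm, lengths, design, truth


@pytest.fixture(scope="session")
def sim_strong():
    """Strong-effect dataset: |log2fc| = 3 puts modulated effects above 5
    within-group SDs on the sqrt scale at dispersion 0.1, the regime where
    per-gene concordance-role recovery is expected to be exact."""
    cm, lengths, design, truth = synth.generate_counts(
        n_genes=800, effect_log2fc=3.0, depth_reads=RECOVERY_DEPTH, seed=11)
    tpm = quantify.compute_tpm(cm, lengths)
    profile = quantify.stage_means(tpm)
    mt_lt = calls.classify_transition(profile, "MT", "LT")
    results = stats.test_gene_set(tpm, design)
    human = synth.generate_human_table(truth, seed=11)
    return dict(truth=truth, design=design, tpm=tpm, mt_lt=mt_lt,
                results=results, human=human)


@pytest.fixture(scope="session")
def sim_pipeline(sim):
    """TPM, stage profile and MT->LT calls/tests derived from ``sim``."""
    cm, lengths, design, truth = sim
    tpm = quantify.compute_tpm(cm, lengths)
    profile = quantify.stage_means(tpm)
    mt_lt = calls.classify_transition(profile, "MT", "LT")
    results = stats.test_gene_set(tpm, design)
    return dict(tpm=tpm, profile=profile, mt_lt=mt_lt, results=results)


@pytest.fixture()
def tiny_counts():
    """Three genes, two samples per stage pair, trivially checkable."""
    design = SampleDesign({"NP1": "NP", "NP2": "NP", "MT1": "MT", "MT2": "MT"})
    counts = pd.DataFrame(
        {"NP1": [100, 100, 0], "NP2": [120, 80, 0],
         "MT1": [10, 200, 40], "MT2": [12, 180, 36]},
        index=["g1", "g2", "g3"],
    )
    lengths = GeneLengthTable({"g1": 1000, "g2": 2000, "g3": 500})
    return CountMatrix(counts=counts, design=design), lengths, design
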