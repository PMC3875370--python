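# cervikit

Tools for two intertwined questions about the biology of birth:

1. **How did functional progesterone withdrawal (FPW) evolve?** Most
   placental mammals show a pre-partum drop in serum progesterone
   (*systemic withdrawal*); humans, other catarrhines and guinea pigs give
   birth with progesterone still high (*functional* withdrawal). `cervikit`
   reconstructs this binary character on the Euarchontoglires phylogeny by
   parsimony — Fitch/Hartigan change counts, exact enumeration of all
   most-parsimonious reconstructions (MPRs), and independent-origin
   counting — with the mouse lemur's uncertain state exposed as an explicit
   scenario.
2. **What does the cervix transcriptome do across the reproductive
   cycle?** A bulk RNA-seq pipeline for staged samples (non-pregnant NP,
   mid-pregnancy MT, late pregnancy/term LT): TPM quantification
   (`tpm_i = (c_i/l_i)/Σ_j(c_j/l_j) × 10⁶`), an operational on/off calculus
   at 3 TPM separating gene *induction*/*repression* from *expression
   modulation*, square-root-scale ANOVA and pairwise t-tests (raw
   p-values, hypothesis-driven by design), and fold-change concordance
   against a human ripe-vs-unripe cervix DE gene list.

A negative-binomial simulator with planted gene classes and concordance
roles provides ground truth for every stage, so the whole pipeline is
testable without any external data. See `docs/methods.md` for the models
and their assumptions.

## Worked example

The phylogenetic question, from the shipped fixture (16 taxa, root fixed
to systemic withdrawal):

```sh
$ cervikit phylo --scenario both --out out/phylo
scenario lemur=1:
  minimum changes: 3  (over 1 MPRs)
  origins of state 1: 2
  Euarchonta ancestor: 1
  Primates ancestor: 1
  Glires ancestor: 0
  Euarchontoglires ancestor: 0
scenario lemur=0:
  minimum changes: 4  (over 3 MPRs)
  origins of state 1: 2-4
  Euarchonta ancestor: 0/1 (ambiguous)
  Primates ancestor: 0/1 (ambiguous)
  Glires ancestor: 0
  Euarchontoglires ancestor: 0
```

Reading: if the mouse lemur lacks systemic withdrawal (`lemur=1`), three
state changes suffice and every MPR makes FPW ancestral for Euarchonta
(tree shrews + primates), with the marmoset a reversal; if the lemur has
withdrawal (`lemur=0`), four changes are needed and the primate stem is
ambiguous. Either way the Glires ancestor retains withdrawal and FPW
arises at minimum **twice** — once in Euarchonta, once in the guinea-pig
lineage, which is deeply nested among withdrawal taxa.

The transcriptome pipeline on synthetic data with planted truth:

```python
from cervikit import synth, quantify, calls, stats, crossmap

cm, lengths, design, truth = synth.generate_counts(
    n_genes=800, effect_log2fc=3.0, depth_reads=4_000_000, seed=1)
human = synth.generate_human_table(truth, seed=1)

tpm = quantify.compute_tpm(cm, lengths)            # columns sum to 1e6
profile = quantify.stage_means(tpm)
mt_lt = calls.classify_transition(profile, "MT", "LT")   # 3-TPM calculus
print(calls.call_summary(mt_lt).to_dict())
# {'induced': 40, 'repressed': 40, 'modulated_up': 355,
#  'modulated_down': 305, 'modulated_flat': 0, 'silent': 80}

results = stats.test_gene_set(tpm, design)         # sqrt-scale ANOVA + t
joined = crossmap.join_by_symbol(human, results.table, mt_lt)
table, summary = crossmap.classify_concordance(joined, alpha=0.05)
print(summary)
# {'n_input': 89, 'n_detected': 76, 'n_concordant': 10,
#  'n_discordant': 27, 'n_unresolved': 39}
```

Of the 89 "human-significant" genes, 76 are detected in the simulated
tissue; all 9 planted concordant and all 27 planted discordant roles are
recovered (the extra concordant gene is a chance significance among the
padding genes — p-values are deliberately uncorrected). The same calculus
reproduces single-gene anchors such as a 122 → 9 TPM collapse being a
0.07-fold change.

One-shot end-to-end run (simulate → quantify → classify → test → phylo →
concordance, with a manifest):

```sh
cervikit reproduce --out out/run --seed 1
```

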