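# leakygene

Tools for deciding whether a gene is **actively expressed**, **leakily
expressed**, or **not expressed** in a cell type, by combining evidence from
bulk RNA-seq compendia, genomic-neighbourhood co-expression, single-cell
RNA-seq, proteomics, and chromatin accessibility.

## The scientific problem

A transcript showing up in an RNA-seq sample does not mean the gene is doing
anything there. Many genes register low but non-zero TPM values in cell types
where they have no known function, no active chromatin, and no detectable
protein. One proposed explanation is *leaky* (spillover) transcription: a
gene caught in the transcriptional wake of a highly expressed neighbour
produces a trickle of presumably non-functional transcript. Distinguishing
this from genuine low-level activity matters whenever expression catalogues
are used to assign genes to cell types.

`leakygene` operationalises that distinction:

- **Mixture model.** Across a compendium, a gene's detected log2-TPM values
  often form two modes. A two-component Gaussian mixture, fitted by an
  expectation–maximisation routine written in this package, separates a low
  ("leaky") from a high ("active") component; per-dataset posteriors
  P(active)/P(leaky) classify each observation. Bimodality itself is
  assessed by a BIC comparison against a single Gaussian.
- **zTPM standardisation.** Each dataset's detected genes are z-scored on the
  log2 scale, making levels comparable across datasets regardless of global
  scale; a fixed threshold (−2.38, inclusive) flags values in the
  lowest-expression tail. A simple 1-TPM rule is also provided.
- **Detection vs depth.** A logistic regression of detection (TPM > 0) on
  aligned read count tests whether "detected" is mostly a function of how
  hard you looked.
- **Transcriptional ripple.** The target's zTPM is correlated across datasets
  with the zTPMs of its genomic neighbours (Pearson, Holm-corrected); a
  leaky gene should track the activity of an adjacent highly expressed gene.
- **Single cell, proteome, chromatin.** Per-cluster detection rates in
  scRNA-seq, presence/absence calls plus marker-panel enrichment in
  proteomic data (hypergeometric test, Benjamini–Hochberg), and
  promoter-accessibility calls from DNase-seq meta-profiles complete the
  evidence dossier.

A seeded simulator generates bulk compendia, single-cell counts, proteome
tables, and DNase tracks with known ground truth, so every analysis can be
validated end to end.

## Worked example

Fit the mixture to 10,000 synthetic log2-TPM values drawn from
0.4·N(−2, 1.2) + 0.6·N(4, 2) and classify a few TPM values:

```python
import numpy as np
from leakygene.classify import fit_gmm, classify_gene_gmm

rng = np.random.default_rng(42)
n = 10_000
is_active = rng.random(n) < 0.6
values = np.where(is_active, rng.normal(4.0, 2.0, n), rng.normal(-2.0, 1.2, n))

fit = fit_gmm(values)
print(fit.w_low, fit.mu_low, fit.sigma_low)   # 0.3899 -1.9943 1.1729
print(fit.mu_high, fit.sigma_high)            # 3.9925  2.0173

for tpm in (0.25, 1.0, 8.0):
    p_active, p_leaky, call = classify_gene_gmm(tpm, fit)
    print(tpm, round(p_active, 4), call)
# 0.25 0.0109 leaky
# 1.0  0.3527 leaky
# 8.0  0.9999 active
```

The recovered parameters sit within a few hundredths of the generating truth
(0.4, −2, 1.2, 4, 2), and posterior classification agrees with the true
component labels for 96.75% of the 10,000 draws.

The zTPM hand example: a dataset whose detected genes have log2-TPM values
{0, 2, 4} (TPM 1, 4, 16) standardises to zTPMs {−1, 0, 1}.

The same analyses are available from the command line:

```bash
leakygene simulate --kind bulk --config bulk.yaml --seed 5 --out sim
leakygene classify --gene target --tpm-matrix sim.tpm.tsv \
    --metadata sim.metadata.tsv --out calls.tsv
leakygene summarize --calls calls.tsv --metadata sim.metadata.tsv --out summary.tsv
leakygene evidence --config evidence.yaml --out dossier.json
```

## Testing

```bash
python -m pytest -q tests/
```

The suite covers I/O round trips, the EM fitter against labelled synthetic
mixtures, threshold boundary semantics, depth-model coefficient recovery,
planted ripple correlations, single-cell normalisation worked examples,
exact hypergeometric enumeration oracles, DNase profile algebra, and
bit-identical determinism of the full evidence run.

## Reproduction

`scripts/acceptance.py` reruns the package's main computations on synthetic
data and records the headline quantities:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the same seed reproduces the output
bit for bit. With seed 1 the script recovers, among other quantities, mixture
means −1.98/3.97 (truth −2/4), a planted neighbour correlation r = 0.637 at
n = 126 (target 0.67), logistic depth coefficients −1.08 and 3.94e-8
(truth −0.97, 3.96e-8), a 0.83% single-cell leaky detection rate at a planted
1% rate, and a DNase promoter fold of 9.9 at a simulated signal-to-noise
ratio of 10.

See `docs/methods.md` for the statistical methods, parameter defaults, and
known limitations.
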