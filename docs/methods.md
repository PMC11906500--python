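# Methods

This note documents the statistical methods, numerical choices, and default
parameters used throughout `leakygene`, and states what the bundled
simulators do and do not emulate.

## Expression calls on bulk RNA-seq

### Detection and thresholds

A gene is *detected* in a dataset iff its TPM is strictly greater than zero;
no pseudocount is added anywhere in the package. Two simple per-dataset
calls are layered on top:

- **1-TPM rule** (`classify_gene_1tpm`): `ge_1` when TPM ≥ 1 (inclusive),
  `lt_1_detected` when 0 < TPM < 1, `not_detected` at exactly 0.
- **zTPM rule** (`classify_gene_ztpm`): `above` when zTPM ≥ −2.38
  (inclusive), `below` otherwise. The −2.38 cut marks the extreme
  low-expression tail of the standardised distribution.

### zTPM standardisation

For each dataset, zTPM is the z-score of log2-TPM computed over that
dataset's detected genes, using the sample standard deviation (ddof = 1). At
least three detected genes are required, and a dataset whose detected genes
all share one value is rejected as degenerate. Because a global rescale of a
dataset's TPMs shifts every log2 value by the same constant, zTPMs are
exactly invariant to per-dataset scale — this is what makes them comparable
across heterogeneous compendia.

### Two-component mixture and EM

Across a compendium, a gene's detected log2-TPM values are modelled as a
two-component Gaussian mixture (leaky low component, active high
component). The expectation–maximisation fitter is written in this package:

- Initialisation: split the sorted values at the median; each half seeds one
  component's mean, standard deviation, and weight. This is deterministic.
- Convergence: absolute change in mean log-likelihood below 1e-8, capped at
  500 iterations; a standard-deviation floor of 1e-3 prevents component
  collapse.
- Components are reported with `mu_low < mu_high`.

Bimodality is assessed by comparing the two-component fit against a single
Gaussian: the distribution is called *bimodal* when BIC(1) − BIC(2) ≥ 10
(strong evidence on the conventional BIC scale), and *undetermined* when
fewer than 500 values are available (the default `min_n`), since the BIC
comparison is unreliable on small samples.

Given a fit, `classify_gene_gmm` returns P(active), P(leaky) and an
argmax call (with an optional decision margin around 0.5).

**Caveat — posterior non-monotonicity.** When `sigma_high > sigma_low`
(the usual case), the active component has fatter tails on *both* sides, so
the posterior log-odds of "active" is an upward-opening parabola in
log2-TPM: at absurdly low values (far below the leaky mean) P(active) rises
again. The posterior is monotone increasing only over the data-supported
range, roughly `[mu_low, mu_high + 4·sigma_high]`. Calls outside that range
should not be trusted; in practice TPM values that low are never observed.

### Detection versus sequencing depth

`fit_detection_depth_model` fits logit P(detected) = a + b·reads by
maximum likelihood (statsmodels GLM, binomial family, IRLS, coefficient
tolerance 1e-10). Reads enter untransformed, so `b` has units of
per-aligned-read. Single-class outcomes and complete separation are
detected and rejected explicitly, since the MLE does not exist there. The
simulator's default coefficients (−0.97, 3.96e-8) put the 50% detection
point near 24.5 million aligned reads.

## Transcriptional ripple (genomic neighbourhood)

`neighbor_correlations` computes the Pearson correlation between the
target's and each neighbour's zTPM across datasets, using pairwise-complete
observations (both genes detected). P-values come from the two-sided
t-distribution transform of r; family-wise error is controlled by a
hand-written Holm step-down (verified against the
(0.01, 0.02, 0.04) → (0.03, 0.04, 0.04) worked example and bounded above by
Bonferroni). Pairs with fewer than three complete observations are flagged
`insufficient` rather than raised. `regress_target_on_neighbor` adds an
ordinary least-squares slope and R²; with standardised inputs R² equals the
squared Pearson correlation.

Neighbourhood context is summarised by `classify_neighborhood`: a gene is
HE (highly expressed) when ≥ 90% of its calls are ≥ 1 TPM, NE when it is
detected in ≤ 10% of datasets, and LE between.

## Single-cell statistics

- **QC:** cells with *strictly fewer* detected features than the threshold
  are removed; a cell exactly at the threshold is retained.
- **Normalisation:** LogNormalize — each cell's counts are scaled to a
  fixed total (default 10,000) and transformed by the natural `log1p`.
  Worked example: count 5 in a 1,000-count cell → ln(1 + 50) = ln 51 =
  3.9318.
- **Variable genes:** a variance-stabilising-style ranking. The
  mean–variance trend is estimated by a quadratic polynomial fit in
  log10–log10 space (a deliberate, simpler substitute for a loess smoother;
  adequate for the smooth trends produced here), counts are standardised by
  the trend-predicted standard deviation with values clipped at
  sqrt(n_cells), and genes are ranked by standardised variance.
- **Cluster statistics:** per (gene, cluster), the percentage of cells with
  count > 0 and the mean normalised expression *including zeros*. Marker
  selection keeps clusters where every marker exceeds 30% detection and
  0.25 mean normalised expression (defaults).

## Proteome detection

A protein is *detected* in a sample iff its value is present, greater than
zero, and not equal to the imputation sentinel 0.001 (matched with absolute
tolerance 1e-12; the sentinel is configurable). A protein is detected in a
dataset iff it is detected in at least one sample — a deliberately liberal
rule, so dataset-level non-detection is strong evidence of absence.
Signature flags test samples against endothelial, immune, and mural marker
panels; proteins exclusive to a sample group are tested for panel
over-representation with the exact hypergeometric upper tail
P[X ≥ k] (`scipy.stats.hypergeom.sf(k−1, N, K, n)`), with
Benjamini–Hochberg q-values across panels.

## Chromatin accessibility

DNase tracks are averaged into a meta-profile: each track is binned
(default 20 bp) with coverage-weighted means (uncovered bases count as
zero), and the profile is the unweighted mean over tracks, so identical
tracks reproduce the single-track profile exactly. A promoter is called
*open* when its mean profile value is at least 3-fold (default) above the
background level, estimated as the 10%-trimmed mean of bins outside the
promoter. The fold is scale-free, so calls are invariant to global signal
rescaling; an all-zero background yields a `closed` call with
`fold_defined = False` rather than a division error.

## Simulators

All simulators draw from counter-based Philox streams keyed by
`(seed, stream identifiers)`, so adding datasets or tracks to a
configuration does not perturb previously generated ones, and every output
is bit-reproducible from the seed.

- **Bulk compendium:** genes are assigned active / leaky / not-expressed
  labels (defaults 60/15/25%); log2-TPM is drawn from N(4, 2) for active
  and N(−2, 1.2) for leaky genes; per-dataset detection dropout follows the
  logistic depth model; an optional *ripple pair* couples a target gene to
  a neighbour so their zTPMs correlate at a requested r (coupling
  `y = mu_low + sigma_low·(r·u + sqrt(1−r²)·ε)` with `u` the neighbour's
  standardised activity).
- **Single cell:** Poisson–log-normal counts per cell-type program, with a
  designated gene leaking a single count into a configurable fraction of
  non-expressing cells.
- **Proteome:** log-normal intensities for present proteins, with absences
  rendered as missing or as the 0.001 sentinel at random, and optional
  marker-panel contamination of specific samples.
- **DNase:** exponential background noise, multiplied by a signal-to-noise
  factor inside designated open windows.

The simulators emulate the *statistical structure* the analyses rely on
(bimodality, depth-dependent dropout, correlated neighbours, sparse counts,
missingness, enrichment). They do not emulate read-level artefacts, gene
length or GC bias, batch effects, doublets or ambient RNA in single-cell
data, or peptide-level identification noise in proteomics.

## Limitations

- The mixture model assumes Gaussian components on the log2 scale; heavy
  skew or more than two modes will be mis-summarised, and the BIC
  bimodality call needs several hundred observations to be meaningful.
- The ripple correlation is associational: a significant r does not by
  itself distinguish spillover transcription from co-regulation.
- The depth model uses untransformed read counts and a single slope; real
  detection curves may saturate differently across platforms.
- The variable-gene trend uses a quadratic fit rather than a local
  smoother and can be leverage-sensitive when a gene's mean is isolated.
- Proteome detection treats one peptide-level observation in one sample as
  dataset-level detection; with many samples this is permissive by design.
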