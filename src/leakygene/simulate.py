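"""Synthetic data with the statistical structure the analysis assumes.

Four generators mirror the four kinds of evidence the pipeline consumes:

* a bulk RNA-seq compendium whose log2-TPM values are a two-component
  Gaussian mixture (low/leaky + high/active), with read-depth-dependent
  dropout of leaky transcripts and optional "ripple" pairs in which a leaky
  gene tracks a highly expressed neighbour across datasets;
* a sparse cell-type-structured UMI count matrix in which a designated
  leaky gene sporadically appears in a non-expressing cell type;
* presence/absence proteome tables with depth-limited sampling and optional
  marker-panel contamination of individual samples;
* DNase signal tracks with exponential background and open windows scaled
  by a signal-to-noise ratio.

Every generator is a pure function of its parameters and a single integer
seed.  Per-dataset substreams are derived by counter-based (Philox) key
splitting, so adding a dataset never perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from leakygene.io import Compendium, ExpressionDataset, SignalTrack
from leakygene.sc import ScDataset

import scipy.sparse as sp

__all__ = [
    "BulkSimParams",
    "TruthLabels",
    "simulate_bulk_compendium",
    "simulate_sc_dataset",
    "simulate_proteome",
    "simulate_dnase_tracks",
]


def _substream(seed: int, *stream_ids: int) -> np.random.Generator:
    """Counter-based substream: one Philox key per (seed, stream path)."""
    h = 0xB5AD4ECEDA1CE2A9
    for sid in stream_ids:
        h = (h * 6364136223846793005 + int(sid) + 1442695040888963407) % 2**64
    key = np.array([int(seed) % 2**64, h], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


@dataclass
class BulkSimParams:
    """Generative settings for a synthetic bulk compendium.

    The defaults reproduce the shape of a bimodal endothelial log2-TPM
    distribution: a leaky component at N(-2, 1.2), an active component at
    N(4, 2), with 15% leaky / 25% not-expressed / 60% active genes.  Leaky
    transcripts are observed (TPM > 0) with probability
    ``logistic(dropout_intercept + dropout_beta * aligned_reads)``; the
    default coefficients make detection climb from ~27% at negligible depth
    to near-certainty at 1e8 aligned reads.
    """

    n_datasets: int = 200
    n_genes: int = 1000
    frac_active: float = 0.60
    frac_leaky: float = 0.15
    frac_ne: float = 0.25
    mu_low: float = -2.0
    sigma_low: float = 1.2
    mu_high: float = 4.0
    sigma_high: float = 2.0
    depth_range: tuple[float, float] = (1e6, 1e8)
    dropout_intercept: float = -0.97
    dropout_beta: float = 3.96e-8
    ripple_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    subtype_labels: list[str] = field(default_factory=lambda: ["HUVEC"])
    species: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_active + self.frac_leaky + self.frac_ne
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for frac in (self.frac_active, self.frac_leaky, self.frac_ne):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("class fractions must lie in [0, 1]")
        if self.mu_low >= self.mu_high:
            raise ValueError("mu_low must be below mu_high")
        for _, _, r in self.ripple_pairs:
            if not abs(r) < 1.0:
                raise ValueError(f"|target_r| must be < 1, got {r}")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (min, max)")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside simulated data.

    ``gene_labels`` maps every simulated gene to exactly one of
    ``active``/``leaky``/``not_expressed``; ``detected`` records whether the
    gene was observed (> 0) per (gene, dataset).  ``extra`` carries
    generator-specific truth such as the identity of a designated leaky
    gene in single-cell data.
    """

    gene_labels: dict[str, str] = field(default_factory=dict)
    detected: dict[tuple[str, str], bool] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def simulate_bulk_compendium(params: BulkSimParams) -> tuple[Compendium, TruthLabels]:
    """Draw a synthetic bulk compendium and its ground-truth labels.

    Per dataset: aligned reads uniform over ``depth_range``; active genes'
    log2-TPM ~ N(mu_high, sigma_high); leaky genes ~ N(mu_low, sigma_low)
    but observed only with the depth-dependent dropout probability; absent
    genes are always 0 TPM.  Each ripple pair's leaky gene is rebuilt in a
    second pass as an affine function of the neighbour's within-dataset
    z-score (standardised across datasets) plus Gaussian noise, with the
    coefficients solved so the across-dataset correlation of z-scores has
    the requested expectation.
    """
    seed = params.seed
    rng_labels = _substream(seed, 0)

    base_genes = [f"g{i:05d}" for i in range(params.n_genes)]
    labels_arr = rng_labels.choice(
        ["active", "leaky", "not_expressed"],
        size=params.n_genes,
        p=[params.frac_active, params.frac_leaky, params.frac_ne],
    )
    gene_labels = dict(zip(base_genes, labels_arr))

    ripple_leaky = [pair[0] for pair in params.ripple_pairs]
    ripple_he = [pair[1] for pair in params.ripple_pairs]
    for g in ripple_leaky:
        gene_labels[g] = "leaky"
    for g in ripple_he:
        gene_labels.setdefault(g, "active")

    all_genes = base_genes + [
        g for g in ripple_leaky + ripple_he if g not in base_genes
    ]

    active = [g for g in base_genes if gene_labels[g] == "active"]
    leaky = [g for g in base_genes if gene_labels[g] == "leaky"]

    datasets: list[ExpressionDataset] = []
    truth = TruthLabels(gene_labels=gene_labels)
    neighbor_z: dict[str, np.ndarray] = {g: np.empty(params.n_datasets) for g in ripple_he}
    detect_p = np.empty(params.n_datasets)

    for d in range(params.n_datasets):
        rng = _substream(seed, 1, d)
        reads = int(rng.uniform(*params.depth_range))
        p_det = float(expit(params.dropout_intercept + params.dropout_beta * reads))
        detect_p[d] = p_det

        tpm: dict[str, float] = {g: 0.0 for g in all_genes}
        log2_active = rng.normal(params.mu_high, params.sigma_high, size=len(active))
        for g, v in zip(active, log2_active):
            tpm[g] = float(2.0**v)

        log2_leaky = rng.normal(params.mu_low, params.sigma_low, size=len(leaky))
        observed = rng.random(len(leaky)) < p_det
        for g, v, obs in zip(leaky, log2_leaky, observed):
            tpm[g] = float(2.0**v) if obs else 0.0

        log2_he = rng.normal(params.mu_high, params.sigma_high, size=len(ripple_he))
        for g, v in zip(ripple_he, log2_he):
            tpm[g] = float(2.0**v)

        # within-dataset z-scores of the HE neighbours over detected genes
        detected_vals = np.log2([v for v in tpm.values() if v > 0])
        mean, sd = detected_vals.mean(), detected_vals.std(ddof=1)
        for g, v in zip(ripple_he, log2_he):
            neighbor_z[g][d] = (v - mean) / sd

        subtype = params.subtype_labels[d % len(params.subtype_labels)]
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{d:04d}",
                species=params.species,
                subtype=subtype,
                condition="control",
                aligned_reads=reads,
                tpm=tpm,
            )
        )

    # second pass: couple each ripple pair's leaky gene to its neighbour
    for pair_idx, (leaky_gene, he_gene, target_r) in enumerate(params.ripple_pairs):
        rng = _substream(seed, 2, pair_idx)
        z = neighbor_z[he_gene]
        u = (z - z.mean()) / z.std()
        eps = rng.standard_normal(params.n_datasets)
        y = params.mu_low + params.sigma_low * (
            target_r * u + np.sqrt(1.0 - target_r**2) * eps
        )
        observed = rng.random(params.n_datasets) < detect_p
        for d, ds in enumerate(datasets):
            ds.tpm[leaky_gene] = float(2.0 ** y[d]) if observed[d] else 0.0

    for ds in datasets:
        for g in all_genes:
            truth.detected[(g, ds.dataset_id)] = ds.tpm[g] > 0

    compendium = Compendium(datasets=datasets, gene_universe=set(all_genes))
    return compendium, truth


def simulate_sc_dataset(
    n_cells_per_type: Mapping[str, int],
    programs: Mapping[str, Mapping[str, float]],
    leaky_rate: float,
    seed: int = 0,
    leaky_gene: str | None = None,
    dispersion_sigma: float = 0.5,
) -> tuple[ScDataset, TruthLabels]:
    """Draw a sparse cell-type-structured UMI matrix with a planted leaky gene.

    Counts are Poisson-lognormal around each cell type's expression
    program: every cell gets a lognormal size factor (sigma
    ``dispersion_sigma`` on the log scale, mean 1) multiplying its
    program's means.  The designated leaky gene (default: the first gene
    expressed in one program but absent from another) additionally appears
    with count 1 in a fraction ``leaky_rate`` of the cells of each
    non-expressing type, mimicking rare spurious detection.
    """
    if not programs:
        raise ValueError("programs must not be empty")
    for ct, prog in programs.items():
        for g, m in prog.items():
            if m < 0:
                raise ValueError(f"negative program mean for {g!r} in {ct!r}")
    if not 0.0 <= leaky_rate <= 1.0:
        raise ValueError("leaky_rate must be a probability")
    unknown = set(n_cells_per_type) - set(programs)
    if unknown:
        raise ValueError(f"cell types without a program: {sorted(unknown)}")

    genes = sorted({g for prog in programs.values() for g in prog})
    gene_index = {g: i for i, g in enumerate(genes)}

    if leaky_gene is None:
        for g in genes:
            expressed_in = [ct for ct, p in programs.items() if p.get(g, 0.0) > 0]
            absent_in = [ct for ct in n_cells_per_type if programs[ct].get(g, 0.0) == 0]
            if expressed_in and absent_in:
                leaky_gene = g
                break
    nonexpressing_types = (
        [ct for ct in n_cells_per_type if programs[ct].get(leaky_gene, 0.0) == 0]
        if leaky_gene is not None
        else []
    )

    columns: list[np.ndarray] = []
    cell_ids: list[str] = []
    cluster_labels: list[str] = []
    leaky_cells: list[str] = []
    sigma2 = dispersion_sigma**2

    for ct_idx, (cell_type, n_cells) in enumerate(sorted(n_cells_per_type.items())):
        rng = _substream(seed, 3, ct_idx)
        means = np.array([programs[cell_type].get(g, 0.0) for g in genes])
        is_nonexpressing = cell_type in nonexpressing_types
        for c in range(n_cells):
            cell_id = f"{cell_type}_{c:05d}"
            # lognormal size factor with mean 1
            factor = np.exp(rng.normal(-sigma2 / 2.0, dispersion_sigma))
            counts = rng.poisson(means * factor)
            if is_nonexpressing and leaky_rate > 0 and rng.random() < leaky_rate:
                counts[gene_index[leaky_gene]] = 1
                leaky_cells.append(cell_id)
            columns.append(counts)
            cell_ids.append(cell_id)
            cluster_labels.append(cell_type)

    matrix = sp.csr_matrix(np.column_stack(columns).astype(np.int64))
    ds = ScDataset(
        counts=matrix, gene_ids=genes, cell_ids=cell_ids, cluster_labels=cluster_labels
    )
    truth = TruthLabels(
        extra={
            "leaky_gene": leaky_gene,
            "nonexpressing_types": nonexpressing_types,
            "leaky_cells": leaky_cells,
        }
    )
    return ds, truth


def simulate_proteome(
    n_samples: int,
    depth_per_sample: int,
    truth_present: set[str],
    marker_panels: Mapping[str, Sequence[str]] | None = None,
    contaminate: Sequence[tuple[int, str]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a wide protein x sample intensity table with planted contamination.

    Each sample reports log-normal intensities for a random depth-limited
    subset of ``truth_present``.  Samples named in ``contaminate`` (by index
    and panel name) additionally report every marker of that panel.  Absent
    proteins are emitted either as missing (NaN) or as the imputation
    sentinel 0.001, at random, so both not-detected conventions are
    exercised downstream.
    """
    marker_panels = dict(marker_panels or {})
    pool = sorted(truth_present)
    if depth_per_sample > len(pool):
        raise ValueError(
            f"depth {depth_per_sample} exceeds the {len(pool)}-protein pool"
        )
    for sample_idx, panel in contaminate:
        if panel not in marker_panels:
            raise ValueError(f"unknown marker panel {panel!r}")
        if not 0 <= sample_idx < n_samples:
            raise ValueError(f"sample index {sample_idx} out of range")

    contaminated_markers: dict[int, set[str]] = {}
    for sample_idx, panel in contaminate:
        contaminated_markers.setdefault(sample_idx, set()).update(marker_panels[panel])

    universe = sorted(
        set(pool) | {m for ms in contaminated_markers.values() for m in ms}
    )
    rng = _substream(seed, 4)
    table = pd.DataFrame(index=universe, columns=[f"s{i:03d}" for i in range(n_samples)],
                         dtype=float)
    for i, sample in enumerate(table.columns):
        present = set(rng.choice(pool, size=depth_per_sample, replace=False))
        present |= contaminated_markers.get(i, set())
        intensities = {p: float(np.exp(rng.normal(18.0, 2.0))) for p in present}
        col = np.full(len(universe), np.nan)
        for j, protein in enumerate(universe):
            if protein in intensities:
                col[j] = intensities[protein]
            elif rng.random() < 0.5:
                col[j] = 0.001  # imputation sentinel for a not-detected protein
        table[sample] = col
    return table


def simulate_dnase_tracks(
    n_tracks: int,
    region: tuple[str, int, int],
    open_windows: Sequence[tuple[int, int]],
    snr: float,
    seed: int = 0,
    bin_size: int = 20,
) -> list[SignalTrack]:
    """Draw DNase-like signal tracks: Exp(1) background, open windows scaled by snr."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    if snr <= 0:
        raise ValueError("snr must be positive")
    windows = sorted(open_windows)
    prev_end: int | None = None
    for w_start, w_end in windows:
        if w_end <= w_start:
            raise ValueError(f"open window ({w_start}, {w_end}) is empty or inverted")
        if w_start < start or w_end > end:
            raise ValueError(f"open window ({w_start}, {w_end}) outside region")
        if prev_end is not None and w_start < prev_end:
            raise ValueError("open windows must not overlap")
        prev_end = w_end

    edges = np.arange(start, end, bin_size)
    tracks = []
    for t in range(n_tracks):
        rng = _substream(seed, 5, t)
        values = rng.exponential(1.0, size=len(edges))
        for w_start, w_end in windows:
            in_window = (edges < w_end) & (edges + bin_size > w_start)
            values[in_window] *= snr
        intervals = [
            (int(e), int(min(e + bin_size, end)), float(v))
            for e, v in zip(edges, values)
        ]
        tracks.append(SignalTrack(chrom=chrom, intervals=intervals))
    return tracks
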