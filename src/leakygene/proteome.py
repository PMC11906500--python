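"""Presence/absence scoring of mass-spectrometry proteome tables.

A protein is "detected" in a sample only when its reported value is
present, positive, and not the 0.001 imputation sentinel some pipelines
emit for missing quantifications.  Dataset-level detection requires at
least one detecting sample.  Cell-identity flags are raised from fixed
marker panels (endothelial, immune, mesenchymal), and over-representation
of a gene set among a protein list is tested with a one-sided
hypergeometric test followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteomeDataset",
    "SignatureFlags",
    "EnrichmentResult",
    "DEFAULT_PANELS",
    "call_detection",
    "dataset_detection",
    "signature_flags",
    "exclusive_proteins",
    "hypergeometric_enrichment",
]

#: sentinel intensity emitted by imputation for a not-detected protein
IMPUTED_SENTINEL = 0.001
_SENTINEL_TOL = 1e-12

#: marker panels used to flag the cellular signature of a sample:
#: core endothelial (EC), immune (IC) and mesenchymal (MC) markers
DEFAULT_PANELS: dict[str, list[str]] = {
    "EC": ["KDR", "CDH5", "FLT1", "NOS3", "VWF", "PLXND1", "TIE1", "TEK", "PLVAP"],
    "IC": ["PTPRC", "CD3E", "CD247", "CD8A", "ITGAM"],
    "MC": ["ELN", "PDGFRA", "PDGFRB", "CD248"],
}


@dataclass
class ProteomeDataset:
    """One proteome study: per-sample protein -> intensity maps plus metadata."""

    dataset_id: str
    samples: dict[str, dict[str, float | None]]
    species: str = "human"
    cell_type: str = ""

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        dataset_id: str,
        species: str = "human",
        cell_type: str = "",
    ) -> "ProteomeDataset":
        """Build from a wide protein x sample DataFrame (NaN = missing)."""
        samples = {
            str(col): {
                str(protein): (None if pd.isna(v) else float(v))
                for protein, v in table[col].items()
            }
            for col in table.columns
        }
        return cls(
            dataset_id=dataset_id, samples=samples, species=species, cell_type=cell_type
        )


@dataclass
class SignatureFlags:
    """Per-sample cell-identity flags with the markers that raised each flag."""

    ec: bool
    ic: bool
    mc: bool
    hits: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap of query with the set
    K: int  # set size within the universe
    n: int  # query size
    N: int  # universe size
    p_hyper: float
    q_bh: float = math.nan

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap cannot exceed set or query size")
        if not 0.0 <= self.p_hyper <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


def call_detection(value: float | None, sentinel: float = IMPUTED_SENTINEL) -> bool:
    """True iff a reported value counts as detection.

    Missing values, zeroes, and the imputation sentinel (matched to within
    1e-12) are all "not detected"; anything else positive is detected.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if value < 0:
        raise ValueError(f"negative intensity {value}")
    if value == 0:
        return False
    if abs(value - sentinel) <= _SENTINEL_TOL:
        return False
    return True


def dataset_detection(
    ds: ProteomeDataset, proteins: list[str] | None = None
) -> tuple[dict[str, bool], pd.DataFrame, int]:
    """Dataset-level and per-sample detection calls.

    Returns ``(dataset_calls, sample_matrix, n_total_detected)``: a protein
    is called detected at the dataset level when at least one sample detects
    it; ``sample_matrix`` is a boolean proteins x samples frame;
    ``n_total_detected`` counts proteins detected in >= 1 sample anywhere in
    the dataset (the dataset's reported depth).
    """
    all_proteins = sorted({p for sample in ds.samples.values() for p in sample})
    queried = all_proteins if proteins is None else proteins
    sample_ids = list(ds.samples)
    matrix = pd.DataFrame(False, index=queried, columns=sample_ids)
    for sample_id, values in ds.samples.items():
        for protein in queried:
            matrix.loc[protein, sample_id] = call_detection(values.get(protein))
    dataset_calls = {p: bool(matrix.loc[p].any()) for p in queried}
    n_total = sum(
        any(call_detection(ds.samples[s].get(p)) for s in sample_ids)
        for p in all_proteins
    )
    return dataset_calls, matrix, n_total


def signature_flags(
    sample_detections: dict[str, bool] | set[str],
    panels: dict[str, list[str]] | None = None,
) -> SignatureFlags:
    """Raise EC/IC/MC flags for one sample from its detected proteins.

    A flag is true when at least one marker of that panel is detected.
    ``sample_detections`` may be a protein -> bool map or a set of detected
    proteins.
    """
    panels = panels or DEFAULT_PANELS
    if not all(panels.get(name) for name in ("EC", "IC", "MC")):
        raise ValueError("panels must provide non-empty EC, IC and MC lists")
    if isinstance(sample_detections, dict):
        detected = {p for p, d in sample_detections.items() if d}
    else:
        detected = set(sample_detections)
    hits = {name: sorted(detected & set(markers)) for name, markers in panels.items()}
    return SignatureFlags(
        ec=bool(hits["EC"]), ic=bool(hits["IC"]), mc=bool(hits["MC"]), hits=hits
    )


def exclusive_proteins(
    samples_of_interest: dict[str, set[str]],
    other_samples: dict[str, set[str]],
) -> set[str]:
    """Proteins detected in >= 1 sample of interest and in no other sample.

    Both arguments map sample id -> set of detected proteins; the two
    groups must be disjoint.
    """
    overlap = set(samples_of_interest) & set(other_samples)
    if overlap:
        raise ValueError(f"sample groups overlap: {sorted(overlap)}")
    if not samples_of_interest or not other_samples:
        raise ValueError("both sample groups must be non-empty")
    interest_union = set().union(*samples_of_interest.values())
    other_union = set().union(*other_samples.values())
    return interest_union - other_union


def hypergeometric_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation of each gene set in the query.

    p = P[X >= k] for X ~ Hypergeometric(N, K, n), where N is the universe
    size, K the set size after intersecting with the universe, n the query
    size and k the observed overlap.  Sets empty after intersection are
    skipped.  Benjamini-Hochberg q-values are computed across all tested
    sets; ``alpha`` is the significance level callers should compare q
    against.
    """
    offenders = query - universe
    if offenders:
        raise ValueError(f"query genes outside the universe: {sorted(offenders)[:10]}")
    N = len(universe)
    n = len(query)
    results = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        # survival function at k-1 gives P[X >= k]; computed in log-gamma space
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(set_name=name, k=k, K=K, n=n, N=N, p_hyper=min(p, 1.0))
        )
    if results:
        _, q_values, _, _ = multipletests(
            [r.p_hyper for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, q in zip(results, q_values):
            r.q_bh = float(q)
    return sorted(results, key=lambda r: r.p_hyper)
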