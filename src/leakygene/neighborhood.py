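"""Transcriptional ripple analysis: does a lowly expressed gene track its
highly expressed genomic neighbours across datasets?

Leaky transcription predicts that a gene's residual expression is spillover
from adjacent active genes, so its level should correlate with theirs
across many independent datasets.  Correlations are computed on zTPM values
(z-scores of log2-TPM within each dataset) so that a shared global shift in
a dataset's expression scale cannot manufacture correlation.  Each
target-neighbour pair uses its own pairwise-complete subset of datasets
(both genes detected, dataset not unimodal), which is why different
neighbours can legitimately report different n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from leakygene.classify import GeneCall, assess_modality, compute_ztpm, log2_detected
from leakygene.io import Compendium

__all__ = [
    "NeighborhoodReport",
    "neighbor_correlations",
    "holm_adjust",
    "regress_target_on_neighbor",
    "classify_neighborhood",
]


@dataclass
class NeighborhoodReport:
    """Correlation, regression and HE/LE/NE classification around one target gene."""

    target: str
    correlations: pd.DataFrame
    regression: dict | None = None
    neighborhood_calls: dict[str, str] = field(default_factory=dict)


def _dataset_ztpms(
    compendium: Compendium, exclude_unimodal: bool
) -> dict[str, dict[str, float]]:
    """zTPM maps per eligible dataset (skips unimodal ones when requested)."""
    out = {}
    for ds in compendium.datasets:
        values = log2_detected(ds)
        if values.size < 3:
            continue
        if exclude_unimodal and assess_modality(values) == "unimodal":
            continue
        out[ds.dataset_id] = compute_ztpm(ds)
    return out


def neighbor_correlations(
    compendium: Compendium,
    target: str,
    neighbors: list[str],
    use_ztpm: bool = True,
    exclude_unimodal: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of the target with each neighbour across datasets.

    For each neighbour, only datasets where both genes are detected
    (TPM > 0) enter (pairwise-complete); two-sided p-values come from the
    t distribution with n - 2 degrees of freedom, and Holm's step-down
    adjustment is applied across the neighbour family.  Neighbours with
    fewer than 3 co-detected datasets are reported with NaN and flagged
    ``insufficient`` rather than raising.
    """
    missing = [g for g in [target, *neighbors] if g not in compendium.gene_universe]
    if missing:
        raise ValueError(f"genes not in the compendium: {missing}")

    if use_ztpm:
        per_dataset = _dataset_ztpms(compendium, exclude_unimodal)
    else:
        per_dataset = {
            ds.dataset_id: {g: np.log2(v) for g, v in ds.tpm.items() if v > 0}
            for ds in compendium.datasets
        }

    rows = []
    for neighbor in neighbors:
        xs, ys = [], []
        for values in per_dataset.values():
            if target in values and neighbor in values:
                xs.append(values[target])
                ys.append(values[neighbor])
        n = len(xs)
        if n < 3:
            rows.append(
                {
                    "neighbor": neighbor,
                    "n": n,
                    "r": np.nan,
                    "p_raw": np.nan,
                    "insufficient": True,
                }
            )
            continue
        r, p = stats.pearsonr(xs, ys)
        rows.append(
            {"neighbor": neighbor, "n": n, "r": float(r), "p_raw": float(p),
             "insufficient": False}
        )

    frame = pd.DataFrame(rows)
    testable = ~frame["insufficient"]
    frame["p_holm"] = np.nan
    if testable.any():
        frame.loc[testable, "p_holm"] = holm_adjust(
            frame.loc[testable, "p_raw"].to_numpy()
        )
    return frame


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm's step-down adjustment, returned in the input order.

    p_(i) (ascending) is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


def regress_target_on_neighbor(
    compendium: Compendium,
    target: str,
    neighbor: str,
    exclude_unimodal: bool = True,
) -> dict:
    """OLS of the target's zTPM on a neighbour's zTPM over co-detected datasets.

    Returns slope, intercept, R^2 (= 1 - SS_res/SS_tot, which for simple
    regression equals the squared Pearson r) and the two-sided slope
    p-value.
    """
    per_dataset = _dataset_ztpms(compendium, exclude_unimodal)
    xs, ys = [], []
    for values in per_dataset.values():
        if target in values and neighbor in values:
            xs.append(values[neighbor])
            ys.append(values[target])
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 co-detected datasets, got {len(xs)} for "
            f"{target!r} ~ {neighbor!r}"
        )
    x = np.array(xs)
    y = np.array(ys)
    if np.allclose(x, x[0]):
        raise ValueError(f"neighbour {neighbor!r} has zero variance")
    result = stats.linregress(x, y)
    ss_res = float(((y - (result.intercept + result.slope * x)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "target": target,
        "neighbor": neighbor,
        "n": len(xs),
        "slope": float(result.slope),
        "intercept": float(result.intercept),
        "r_squared": 1.0 - ss_res / ss_tot,
        "p": float(result.pvalue),
    }


def classify_neighborhood(
    calls_by_gene: dict[str, list[GeneCall]],
    he_min_frac: float = 0.9,
    ne_max_det_frac: float = 0.1,
) -> dict[str, str]:
    """HE/LE/NE classification of each gene in a neighbourhood.

    HE: at or above 1 TPM in >= ``he_min_frac`` of datasets.  NE: detected
    in <= ``ne_max_det_frac`` of datasets.  Everything between is LE — the
    profile of a leaky gene, present at trace levels in some datasets but
    rarely at functional levels.
    """
    out = {}
    for gene, calls in calls_by_gene.items():
        if not calls:
            raise ValueError(f"no calls for gene {gene!r}")
        n = len(calls)
        frac_ge1 = sum(c.call_1tpm == "ge_1" for c in calls) / n
        frac_detected = sum(c.tpm > 0 for c in calls) / n
        if frac_ge1 >= he_min_frac:
            out[gene] = "HE"
        elif frac_detected <= ne_max_det_frac:
            out[gene] = "NE"
        else:
            out[gene] = "LE"
    return out


def build_report(
    compendium: Compendium,
    target: str,
    neighbors: list[str],
    calls_by_gene: dict[str, list[GeneCall]] | None = None,
    regression_neighbor: str | None = None,
    exclude_unimodal: bool = True,
) -> NeighborhoodReport:
    """Assemble the full neighbourhood report for one target gene."""
    correlations = neighbor_correlations(
        compendium, target, neighbors, exclude_unimodal=exclude_unimodal
    )
    regression = None
    if regression_neighbor is not None:
        regression = regress_target_on_neighbor(
            compendium, target, regression_neighbor, exclude_unimodal=exclude_unimodal
        )
    neighborhood_calls = (
        classify_neighborhood(calls_by_gene) if calls_by_gene else {}
    )
    return NeighborhoodReport(
        target=target,
        correlations=correlations,
        regression=regression,
        neighborhood_calls=neighborhood_calls,
    )
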