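"""Compendium-level summaries: stacked-bar counts, detection-vs-depth model,
and per-condition TPM ranges.

A gene that is only detected in deeply sequenced datasets behaves like a
rare (leaky) transcript: its probability of detection rises with the
number of aligned reads.  That relationship is modelled here as a logistic
regression of the per-dataset detection indicator on the untransformed
aligned-read count, ``logit(p) = intercept + beta * reads``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from leakygene.classify import GeneCall
from leakygene.io import Compendium

__all__ = [
    "GeneSummary",
    "DetectionDepthModel",
    "summarize_gene",
    "fit_detection_depth_model",
    "predict_detection",
    "condition_tpm_summary",
]

_COUNT_FIELDS = [
    "n_datasets",
    "n_detected",
    "n_ge_1tpm",
    "n_lt_1_detected",
    "n_active_gmm",
    "n_leaky_gmm",
    "n_undetermined_gmm",
    "n_above_ztpm",
    "n_below_ztpm",
    "n_eligible_gmm",
    "n_eligible_ztpm",
]


@dataclass
class GeneSummary:
    """Per-subtype (and overall) call counts for one gene.

    ``per_subtype`` maps subtype -> dict of counts; the key ``"all"``
    aggregates every dataset.  Percentages are always reported next to the
    denominator they use, because "percent active" against all datasets and
    against eligible (bimodal, detected) datasets are different claims.
    """

    gene_id: str
    per_subtype: dict[str, dict[str, int]] = field(default_factory=dict)

    def percent(self, subtype: str, count_field: str, denominator_field: str) -> float:
        counts = self.per_subtype[subtype]
        denom = counts[denominator_field]
        return 100.0 * counts[count_field] / denom if denom else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": self.gene_id, "subtype": subtype, **counts}
            for subtype, counts in self.per_subtype.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class DetectionDepthModel:
    """Fitted logistic model of detection probability versus aligned reads."""

    intercept: float
    beta: float
    se_intercept: float
    se_beta: float
    n: int
    converged: bool

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("model requires n >= 2 observations")
        if self.converged and not (
            np.isfinite(self.intercept) and np.isfinite(self.beta)
        ):
            raise ValueError("converged model must have finite coefficients")


def summarize_gene(
    calls: list[GeneCall], grouping: dict[str, str] | None = None
) -> GeneSummary:
    """Aggregate one gene's per-dataset calls into per-subtype counts.

    ``grouping`` maps dataset_id to subtype; omitted datasets fall into the
    ``"unknown"`` bucket.  Duplicate (gene, dataset) pairs are rejected.
    """
    if not calls:
        raise ValueError("no calls supplied")
    gene_ids = {c.gene_id for c in calls}
    if len(gene_ids) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(gene_ids)}")
    seen = set()
    for call in calls:
        key = (call.gene_id, call.dataset_id)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)

    grouping = grouping or {}
    summary = GeneSummary(gene_id=calls[0].gene_id)

    def bucket(subtype: str) -> dict[str, int]:
        return summary.per_subtype.setdefault(
            subtype, {f: 0 for f in _COUNT_FIELDS}
        )

    for call in calls:
        for counts in (bucket(grouping.get(call.dataset_id, "unknown")), bucket("all")):
            counts["n_datasets"] += 1
            if call.tpm > 0:
                counts["n_detected"] += 1
            if call.call_1tpm == "ge_1":
                counts["n_ge_1tpm"] += 1
            elif call.call_1tpm == "lt_1_detected":
                counts["n_lt_1_detected"] += 1
            if call.call_gmm in {"active", "leaky", "undetermined"}:
                counts["n_eligible_gmm"] += 1
                counts[f"n_{call.call_gmm}_gmm"] += 1
            if call.call_ztpm in {"above", "below"}:
                counts["n_eligible_ztpm"] += 1
                counts[f"n_{call.call_ztpm}_ztpm"] += 1
    return summary


def fit_detection_depth_model(
    detected: np.ndarray, aligned_reads: np.ndarray
) -> DetectionDepthModel:
    """Maximum-likelihood logistic fit of detection on aligned reads.

    Fitted by iteratively reweighted least squares with a 1e-10 tolerance
    on the coefficient change.  Reads enter untransformed.  A single-class
    outcome or complete separation has no finite MLE and raises.
    """
    detected = np.asarray(detected, dtype=float)
    reads = np.asarray(aligned_reads, dtype=float)
    if detected.shape != reads.shape:
        raise ValueError("detected and aligned_reads must have equal length")
    classes = set(np.unique(detected))
    if not classes <= {0.0, 1.0}:
        raise ValueError("detected must be binary (0/1)")
    if len(classes) < 2:
        raise ValueError(
            "degenerate outcome: all datasets are "
            + ("detected" if classes == {1.0} else "not detected")
            + "; the logistic MLE does not exist"
        )
    # complete separation: a read-count threshold perfectly splits the classes
    if reads[detected == 1].min() > reads[detected == 0].max() or reads[
        detected == 1
    ].max() < reads[detected == 0].min():
        raise ValueError(
            "complete separation: detection is perfectly split by read depth, "
            "coefficients diverge"
        )

    X = sm.add_constant(reads)
    model = sm.GLM(detected, X, family=sm.families.Binomial())
    result = model.fit(tol=1e-10, maxiter=200)
    params = np.asarray(result.params)
    ses = np.asarray(result.bse)
    return DetectionDepthModel(
        intercept=float(params[0]),
        beta=float(params[1]),
        se_intercept=float(ses[0]),
        se_beta=float(ses[1]),
        n=int(detected.size),
        converged=bool(result.converged),
    )


def predict_detection(model: DetectionDepthModel, reads: float) -> float:
    """Detection probability at a given aligned-read count."""
    if not model.converged:
        raise ValueError("model did not converge")
    if reads < 0:
        raise ValueError("reads must be non-negative")
    eta = model.intercept + model.beta * reads
    return float(1.0 / (1.0 + np.exp(-eta)))


def condition_tpm_summary(
    compendium: Compendium, gene: str, condition_key: str | None = None
) -> pd.DataFrame:
    """Per-condition TPM range summary for one gene.

    Returns one row per condition with ``n``, ``min_tpm``, ``max_tpm`` and
    ``n_ge_1tpm``.  ``condition_key`` restricts the summary to a single
    condition (which must exist); by default all conditions are reported.
    """
    conditions: dict[str, list[float]] = {}
    for ds in compendium.datasets:
        conditions.setdefault(ds.condition, []).append(float(ds.tpm.get(gene, 0.0)))
    if condition_key is not None:
        if condition_key not in conditions:
            raise ValueError(
                f"condition {condition_key!r} not present; "
                f"known: {sorted(conditions)}"
            )
        conditions = {condition_key: conditions[condition_key]}
    rows = []
    for condition in sorted(conditions):
        values = np.array(conditions[condition])
        rows.append(
            {
                "condition": condition,
                "n": int(values.size),
                "min_tpm": float(values.min()) if values.size else 0.0,
                "max_tpm": float(values.max()) if values.size else 0.0,
                "n_ge_1tpm": int((values >= 1).sum()),
            }
        )
    return pd.DataFrame(rows)
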