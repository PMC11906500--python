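"""Per-dataset classification of gene expression: active, leaky, or absent.

The transcriptome of one bulk RNA-seq dataset, viewed on the log2-TPM
scale over detected genes, is typically bimodal: a high Gaussian component
of actively transcribed genes and a low component attributed to leaky
transcription.  Three independent classifiers are implemented:

* a two-component Gaussian mixture fitted by expectation-maximisation,
  yielding P(active)/P(leaky) posteriors per gene;
* the zTPM transform (z-score of log2-TPM over detected genes) compared
  against a fixed activity threshold (default -2.38, derived from HUVEC
  chromatin and expression data);
* a simple 1-TPM detection threshold.

Zero-TPM genes are excluded from all distributions rather than imputed: the
detection dichotomy is ``TPM > 0`` versus ``TPM = 0``, with no pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclasses_field

import numpy as np

from leakygene.io import ExpressionDataset

__all__ = [
    "GmmFit",
    "GeneCall",
    "log2_detected",
    "assess_modality",
    "fit_gmm",
    "classify_gene_gmm",
    "compute_ztpm",
    "classify_gene_ztpm",
    "classify_gene_1tpm",
    "call_gene_in_dataset",
    "ZTPM_THRESHOLD",
]

#: zTPM activity threshold determined for HUVEC; comparison is inclusive.
ZTPM_THRESHOLD = -2.38

_SIGMA_FLOOR = 1e-3


@dataclass
class GmmFit:
    """Parameters of a two-component Gaussian mixture on log2-TPM values.

    Components are labelled so that ``mu_low < mu_high``; the low component
    models leaky transcription and the high component active expression.
    """

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    w_low: float
    w_high: float
    loglik: float
    n_iter: int
    converged: bool
    n_values: int
    modality: str = "bimodal"
    loglik_trace: list[float] = dataclasses_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mu_low >= self.mu_high:
            raise ValueError("mu_low must be below mu_high")
        if abs(self.w_low + self.w_high - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.sigma_low, self.sigma_high) < _SIGMA_FLOOR:
            raise ValueError(f"sigmas must be >= {_SIGMA_FLOOR}")


@dataclass
class GeneCall:
    """Classification record for one gene in one dataset.

    ``log2tpm``, ``ztpm`` and the posteriors are None exactly when the gene
    is undetected (TPM = 0).  ``call_gmm``/``call_ztpm`` carry
    ``dataset_unimodal`` when the dataset's expression distribution did not
    qualify for the respective method.
    """

    gene_id: str
    dataset_id: str
    tpm: float
    log2tpm: float | None
    ztpm: float | None
    p_active: float | None
    p_leaky: float | None
    call_gmm: str
    call_ztpm: str
    call_1tpm: str


def log2_detected(dataset: ExpressionDataset) -> np.ndarray:
    """log2(TPM) over this dataset's detected (TPM > 0) genes.

    No pseudocount is applied; zero-TPM genes are simply excluded, so an
    all-zero dataset yields an empty vector.
    """
    values = np.array([v for v in dataset.tpm.values() if v > 0], dtype=float)
    return np.log2(values) if values.size else np.empty(0)


def _normal_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _em_two_component(
    values: np.ndarray, tol: float, max_iter: int
) -> tuple[float, float, float, float, float, float, int, bool]:
    """EM for a two-component 1-D Gaussian mixture, median-split initialised."""
    x = np.sort(values)
    n = x.size
    half = n // 2
    lo, hi = x[:half], x[half:]
    mu = np.array([lo.mean(), hi.mean()])
    sigma = np.array([max(lo.std(), _SIGMA_FLOOR), max(hi.std(), _SIGMA_FLOOR)])
    w = np.array([half / n, 1 - half / n])

    loglik = -np.inf
    converged = False
    n_iter = 0
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        # E step: responsibilities via log-sum-exp
        logp = np.stack(
            [np.log(w[k]) + _normal_logpdf(x, mu[k], sigma[k]) for k in range(2)]
        )
        logp_max = logp.max(axis=0)
        log_total = logp_max + np.log(np.exp(logp - logp_max).sum(axis=0))
        new_loglik = float(log_total.sum())
        trace.append(new_loglik)
        resp = np.exp(logp - log_total)

        # M step
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.maximum(np.sqrt(var), _SIGMA_FLOOR)

        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    return (
        float(mu[0]),
        float(mu[1]),
        float(sigma[0]),
        float(sigma[1]),
        float(w[0]),
        float(w[1]),
        n_iter,
        converged,
        loglik,
        trace,
    )


def assess_modality(
    values: np.ndarray, min_n: int = 500, bic_margin: float = 10.0
) -> str:
    """Decide whether a log2-TPM distribution is bimodal, unimodal, or too small.

    Returns ``"undetermined"`` when fewer than ``min_n`` values are supplied.
    Otherwise a two-component Gaussian mixture is compared against a single
    Gaussian by BIC; ``"bimodal"`` requires the two-component model to win
    by at least ``bic_margin`` (a decisive margin on the BIC scale).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < min_n:
        return "undetermined"

    mu1, sd1 = values.mean(), max(values.std(), _SIGMA_FLOOR)
    loglik1 = float(_normal_logpdf(values, mu1, sd1).sum())
    bic1 = 2 * math.log(n) - 2 * loglik1

    *_, loglik2, _trace = _em_two_component(values, tol=1e-8, max_iter=500)
    bic2 = 5 * math.log(n) - 2 * loglik2

    return "bimodal" if bic1 - bic2 >= bic_margin else "unimodal"


def fit_gmm(
    values: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmmFit:
    """Fit the two-component active/leaky mixture to log2-TPM values by EM.

    Initialisation splits the sorted values at the median (ties broken by
    value order, hence deterministic); ``seed`` is accepted for interface
    stability but the fit itself is deterministic.  A sigma floor of 1e-3
    prevents component collapse.
    """
    del seed  # deterministic initialisation; kept for a stable signature
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values to fit a mixture, got {values.size}")
    mu_low, mu_high, s_low, s_high, w_low, w_high, n_iter, converged, loglik, trace = (
        _em_two_component(values, tol=tol, max_iter=max_iter)
    )
    return GmmFit(
        mu_low=mu_low,
        mu_high=mu_high,
        sigma_low=s_low,
        sigma_high=s_high,
        w_low=w_low,
        w_high=w_high,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        n_values=int(values.size),
        loglik_trace=trace,
    )


def classify_gene_gmm(
    tpm: float, fit: GmmFit, margin: float = 0.0
) -> tuple[float | None, float | None, str]:
    """Posterior active/leaky classification of one TPM value under a fit.

    Returns ``(p_active, p_leaky, call)``.  The call is ``active`` when
    P(active) >= 0.5 + margin, ``leaky`` when P(leaky) >= 0.5 + margin and
    ``undetermined`` otherwise; with the default margin of 0 this is a pure
    argmax with ``undetermined`` only at an exact tie.  ``tpm = 0`` yields
    ``not_detected`` with undefined posteriors.
    """
    if not fit.converged:
        raise ValueError("GMM fit did not converge; refusing to classify")
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if tpm == 0:
        return None, None, "not_detected"
    x = math.log2(tpm)
    log_low = math.log(fit.w_low) + float(
        _normal_logpdf(np.array([x]), fit.mu_low, fit.sigma_low)[0]
    )
    log_high = math.log(fit.w_high) + float(
        _normal_logpdf(np.array([x]), fit.mu_high, fit.sigma_high)[0]
    )
    m = max(log_low, log_high)
    denom = math.exp(log_low - m) + math.exp(log_high - m)
    p_active = math.exp(log_high - m) / denom
    p_leaky = 1.0 - p_active
    if p_active >= 0.5 + margin and p_active > p_leaky:
        call = "active"
    elif p_leaky >= 0.5 + margin and p_leaky > p_active:
        call = "leaky"
    else:
        call = "undetermined"
    return p_active, p_leaky, call


def compute_ztpm(dataset: ExpressionDataset) -> dict[str, float]:
    """zTPM per detected gene: z-score of log2-TPM over the dataset's detected genes.

    Uses the sample (n-1) standard deviation.  Needs at least three detected
    genes; a zero-spread dataset is degenerate and rejected.  Multiplying
    every TPM by a positive constant shifts all log2 values equally and
    leaves zTPMs unchanged, which is what makes them comparable across
    datasets.
    """
    detected = {g: v for g, v in dataset.tpm.items() if v > 0}
    if len(detected) < 3:
        raise ValueError(
            f"need >= 3 detected genes to standardise, got {len(detected)}"
        )
    log2tpm = np.log2(np.array(list(detected.values())))
    mean = log2tpm.mean()
    sd = log2tpm.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate dataset: all detected genes share one TPM value")
    return {g: float((lv - mean) / sd) for g, lv in zip(detected, log2tpm)}


def classify_gene_ztpm(ztpm: float | None, threshold: float = ZTPM_THRESHOLD) -> str:
    """'above' iff zTPM >= threshold (inclusive); None (undetected) -> 'not_detected'."""
    if ztpm is None:
        return "not_detected"
    return "above" if ztpm >= threshold else "below"


def classify_gene_1tpm(tpm: float) -> str:
    """Three-way 1-TPM call: 'ge_1' (>= 1), 'lt_1_detected' (0 < TPM < 1), 'not_detected' (0)."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if tpm == 0:
        return "not_detected"
    return "ge_1" if tpm >= 1 else "lt_1_detected"


def call_gene_in_dataset(
    gene_id: str,
    dataset: ExpressionDataset,
    fit: GmmFit | None = None,
    ztpms: dict[str, float] | None = None,
    modality: str | None = None,
    ztpm_threshold: float = ZTPM_THRESHOLD,
    margin: float = 0.0,
) -> GeneCall:
    """Assemble the full GeneCall for one gene in one dataset.

    ``fit`` (only meaningful for bimodal datasets) and ``ztpms`` may be
    precomputed once per dataset and shared across genes.  ``modality``
    gates the GMM and zTPM calls: a unimodal dataset yields
    ``dataset_unimodal`` for both.
    """
    tpm = float(dataset.tpm.get(gene_id, 0.0))
    log2tpm = math.log2(tpm) if tpm > 0 else None
    call_1tpm = classify_gene_1tpm(tpm)

    if modality is None:
        modality = assess_modality(log2_detected(dataset))

    p_active = p_leaky = None
    if tpm == 0:
        call_gmm = call_ztpm = "not_detected"
        ztpm = None
    elif modality == "unimodal":
        call_gmm = call_ztpm = "dataset_unimodal"
        ztpm = None
    else:
        if fit is not None and modality == "bimodal":
            p_active, p_leaky, call_gmm = classify_gene_gmm(tpm, fit, margin=margin)
        else:
            call_gmm = "undetermined"
        if ztpms is None:
            ztpms = compute_ztpm(dataset)
        ztpm = ztpms.get(gene_id)
        call_ztpm = classify_gene_ztpm(ztpm, threshold=ztpm_threshold)

    return GeneCall(
        gene_id=gene_id,
        dataset_id=dataset.dataset_id,
        tpm=tpm,
        log2tpm=log2tpm,
        ztpm=ztpm,
        p_active=p_active,
        p_leaky=p_leaky,
        call_gmm=call_gmm,
        call_ztpm=call_ztpm,
        call_1tpm=call_1tpm,
    )
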