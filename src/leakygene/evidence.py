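"""End-to-end evidence dossier: run every configured tier on one gene.

The dossier aggregates, for a single target gene, the bulk-compendium
classification summary, the detection-versus-depth model, the genomic
neighbourhood correlations, single-cell detection statistics, proteome
presence/absence with signature flags and enrichment, and the promoter
accessibility call.  Each section is either populated or explicitly marked
skipped with a reason, and the whole run is deterministic given the seeds
in the config.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

from leakygene import __version__
from leakygene.classify import (
    ZTPM_THRESHOLD,
    assess_modality,
    call_gene_in_dataset,
    compute_ztpm,
    fit_gmm,
    log2_detected,
)
from leakygene.epigenome import build_meta_profile, call_promoter_accessibility
from leakygene.io import Compendium, read_mtx_counts, read_tpm_matrix
from leakygene.neighborhood import (
    classify_neighborhood,
    neighbor_correlations,
    regress_target_on_neighbor,
)
from leakygene.proteome import (
    DEFAULT_PANELS,
    ProteomeDataset,
    dataset_detection,
    exclusive_proteins,
    hypergeometric_enrichment,
    signature_flags,
)
from leakygene.sc import (
    cluster_gene_stats,
    log_normalize,
    qc_filter_cells,
    select_clusters_by_markers,
)
from leakygene.simulate import (
    BulkSimParams,
    simulate_bulk_compendium,
    simulate_dnase_tracks,
    simulate_proteome,
    simulate_sc_dataset,
)
from leakygene.summary import (
    condition_tpm_summary,
    fit_detection_depth_model,
    predict_detection,
    summarize_gene,
)

__all__ = ["run_evidence", "config_hash", "compendium_calls"]


def config_hash(config: dict) -> str:
    """Stable hash of the semantic content of a config mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def compendium_calls(
    compendium: Compendium,
    genes: list[str],
    ztpm_threshold: float = ZTPM_THRESHOLD,
    min_n_modality: int = 500,
):
    """Per-dataset GeneCalls for several genes, sharing fits across genes.

    Modality is assessed once per dataset; bimodal datasets get one GMM fit
    and one zTPM map reused by every queried gene.
    """
    calls: dict[str, list] = {g: [] for g in genes}
    for ds in compendium.datasets:
        values = log2_detected(ds)
        modality = assess_modality(values, min_n=min_n_modality)
        fit = None
        ztpms = None
        if modality == "bimodal":
            fit = fit_gmm(values)
            ztpms = compute_ztpm(ds)
        elif modality == "undetermined" and values.size >= 3:
            ztpms = compute_ztpm(ds)
        for gene in genes:
            calls[gene].append(
                call_gene_in_dataset(
                    gene,
                    ds,
                    fit=fit,
                    ztpms=ztpms,
                    modality=modality,
                    ztpm_threshold=ztpm_threshold,
                )
            )
    return calls


def _skipped(reason: str) -> dict:
    return {"status": "skipped", "reason": reason}


def _bulk_section(config: dict, gene: str, seed: int) -> tuple[dict, Compendium | None]:
    bulk_cfg = config.get("bulk")
    if not bulk_cfg:
        return _skipped("no bulk section in config"), None
    if "tpm_matrix" in bulk_cfg:
        compendium = read_tpm_matrix(bulk_cfg["tpm_matrix"], bulk_cfg["metadata"])
    else:
        sim_cfg = dict(bulk_cfg.get("simulate", {}))
        sim_cfg.setdefault("seed", seed)
        ripple = [tuple(p) for p in sim_cfg.pop("ripple_pairs", [])]
        params = BulkSimParams(ripple_pairs=ripple, **sim_cfg)
        compendium, _ = simulate_bulk_compendium(params)
        if gene not in compendium.gene_universe:
            # make the target a ripple-coupled leaky gene by default
            params = BulkSimParams(
                ripple_pairs=ripple or [(gene, "he_neighbor", 0.67)], **sim_cfg
            )
            compendium, _ = simulate_bulk_compendium(params)

    genes = [gene] + [g for g in bulk_cfg.get("extra_genes", []) if g != gene]
    calls = compendium_calls(compendium, genes)
    grouping = {ds.dataset_id: ds.subtype for ds in compendium.datasets}
    summary = summarize_gene(calls[gene], grouping)

    detected = np.array([1.0 if c.tpm > 0 else 0.0 for c in calls[gene]])
    reads = np.array(
        [float(compendium.dataset(c.dataset_id).aligned_reads) for c in calls[gene]]
    )
    try:
        model = fit_detection_depth_model(detected, reads)
        depth = {
            "intercept": model.intercept,
            "beta": model.beta,
            "se_intercept": model.se_intercept,
            "se_beta": model.se_beta,
            "n": model.n,
            "p_at_zero_reads": predict_detection(model, 0),
        }
    except ValueError as exc:
        depth = _skipped(f"depth model not estimable: {exc}")

    conditions = condition_tpm_summary(compendium, gene)
    section = {
        "status": "ok",
        "summary": summary.to_frame().to_dict(orient="records"),
        "depth_model": depth,
        "condition_summary": conditions.to_dict(orient="records"),
    }
    return section, compendium


def _neighborhood_section(
    config: dict, gene: str, compendium: Compendium | None
) -> dict:
    nb_cfg = config.get("neighborhood")
    if not nb_cfg:
        return _skipped("no neighborhood section in config")
    if compendium is None:
        return _skipped("neighborhood analysis needs the bulk compendium")
    neighbors = list(nb_cfg.get("neighbors", []))
    if not neighbors:
        return _skipped("no neighbours configured")
    correlations = neighbor_correlations(compendium, gene, neighbors)
    regression_neighbor = nb_cfg.get("regression_neighbor", neighbors[0])
    try:
        regression = regress_target_on_neighbor(compendium, gene, regression_neighbor)
    except ValueError as exc:
        regression = _skipped(str(exc))
    calls = compendium_calls(compendium, [gene, *neighbors])
    he_le_ne = classify_neighborhood(calls)
    return {
        "status": "ok",
        "correlations": correlations.to_dict(orient="records"),
        "regression": regression,
        "neighborhood_calls": he_le_ne,
    }


def _sc_section(config: dict, gene: str, seed: int) -> dict:
    sc_cfg = config.get("sc")
    if not sc_cfg:
        return _skipped("no sc section in config")
    if "mtx" in sc_cfg:
        ds = read_mtx_counts(
            sc_cfg["mtx"], sc_cfg["features"], sc_cfg["barcodes"], sc_cfg["labels"]
        )
    else:
        sim_cfg = dict(sc_cfg.get("simulate", {}))
        sim_cfg.setdefault("seed", seed)
        ds, _ = simulate_sc_dataset(
            n_cells_per_type=sim_cfg["n_cells_per_type"],
            programs=sim_cfg["programs"],
            leaky_rate=sim_cfg.get("leaky_rate", 0.01),
            seed=sim_cfg["seed"],
            leaky_gene=sim_cfg.get("leaky_gene"),
        )
    # cells detecting no gene at all cannot be normalised; drop them by default
    ds = qc_filter_cells(ds, int(sc_cfg.get("min_features", 1)))
    normalised = log_normalize(ds, float(sc_cfg.get("scale_factor", 10_000.0)))
    genes = list(dict.fromkeys([gene, *sc_cfg.get("genes", [])]))
    stats = cluster_gene_stats(ds, normalised, genes)
    markers = sc_cfg.get("markers", [])
    selected = (
        select_clusters_by_markers(
            cluster_gene_stats(ds, normalised, markers),
            markers,
            min_pct=float(sc_cfg.get("min_pct", 30.0)),
            min_mean=float(sc_cfg.get("min_mean", 0.25)),
        )
        if markers
        else []
    )
    return {
        "status": "ok",
        "n_cells": ds.n_cells,
        "stats": stats.table.to_dict(orient="records"),
        "selected_clusters": selected,
    }


def _proteome_section(config: dict, gene: str, seed: int) -> dict:
    prot_cfg = config.get("proteome")
    if not prot_cfg:
        return _skipped("no proteome section in config")
    panels = prot_cfg.get("panels", DEFAULT_PANELS)
    if "table" in prot_cfg:
        import pandas as pd

        table = pd.read_csv(prot_cfg["table"], sep="\t", index_col=0)
    else:
        sim_cfg = dict(prot_cfg.get("simulate", {}))
        sim_cfg.setdefault("seed", seed)
        table = simulate_proteome(
            n_samples=sim_cfg.get("n_samples", 6),
            depth_per_sample=sim_cfg.get("depth_per_sample", 50),
            truth_present=set(sim_cfg.get("truth_present", [f"P{i:03d}" for i in range(80)])),
            marker_panels=panels,
            contaminate=[tuple(c) for c in sim_cfg.get("contaminate", [])],
            seed=sim_cfg["seed"],
        )
    ds = ProteomeDataset.from_table(table, dataset_id=prot_cfg.get("dataset_id", "proteome"))
    calls, matrix, n_total = dataset_detection(ds)
    flags = {
        sample: signature_flags(set(matrix.index[matrix[sample]]), panels)
        for sample in matrix.columns
    }
    gene_samples = [s for s in matrix.columns if matrix.loc[gene, s]] if gene in matrix.index else []
    enrichment = []
    if gene_samples and len(gene_samples) < len(matrix.columns):
        interest = {s: set(matrix.index[matrix[s]]) for s in gene_samples}
        others = {
            s: set(matrix.index[matrix[s]])
            for s in matrix.columns
            if s not in gene_samples
        }
        exclusive = exclusive_proteins(interest, others)
        universe = {p for dets in interest.values() for p in dets} | {
            p for dets in others.values() for p in dets
        }
        gene_sets = {name: set(markers) for name, markers in panels.items()}
        if "gene_sets" in prot_cfg:
            from leakygene.io import read_gmt

            gene_sets.update(read_gmt(prot_cfg["gene_sets"]))
        enrichment = [
            {
                "set_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_hyper": r.p_hyper,
                "q_bh": r.q_bh,
            }
            for r in hypergeometric_enrichment(exclusive, gene_sets, universe)
        ]
    return {
        "status": "ok",
        "gene_dataset_call": "D" if calls.get(gene, False) else "ND",
        "n_proteins_detected": n_total,
        "signature_flags": {
            s: {"ec": f.ec, "ic": f.ic, "mc": f.mc} for s, f in flags.items()
        },
        "enrichment": enrichment,
    }


def _dnase_section(config: dict, seed: int) -> dict:
    dnase_cfg = config.get("dnase")
    if not dnase_cfg:
        return _skipped("no dnase section in config")
    region = tuple(dnase_cfg.get("region", ("chr1", 0, 20_000)))
    promoter = tuple(dnase_cfg.get("promoter", (9_000, 11_000)))
    if "tracks" in dnase_cfg:
        from leakygene.io import read_bedgraph

        tracks = [read_bedgraph(p) for p in dnase_cfg["tracks"]]
    else:
        sim_cfg = dict(dnase_cfg.get("simulate", {}))
        sim_cfg.setdefault("seed", seed)
        tracks = simulate_dnase_tracks(
            n_tracks=sim_cfg.get("n_tracks", 15),
            region=region,
            open_windows=[tuple(w) for w in sim_cfg.get("open_windows", [])],
            snr=sim_cfg.get("snr", 10.0),
            seed=sim_cfg["seed"],
        )
    profile = build_meta_profile(tracks, region, step=int(dnase_cfg.get("step", 20)))
    call = call_promoter_accessibility(
        profile, promoter, fold_threshold=float(dnase_cfg.get("fold_threshold", 3.0))
    )
    call["n_tracks"] = profile.n_tracks
    return {"status": "ok", **call}


def run_evidence(config: dict) -> dict[str, Any]:
    """Execute every configured evidence tier for one gene.

    Returns the dossier as a plain dict (JSON-serialisable).  Sections not
    configured are marked skipped with a reason; a stage failure raises
    with the stage name attached.
    """
    gene = config.get("gene")
    if not gene:
        raise ValueError("config must name a target 'gene'")
    seed = int(config.get("seed", 0))

    dossier: dict[str, Any] = {
        "gene": gene,
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "config_hash": config_hash(config),
        },
    }
    stages = [
        ("bulk", lambda: _bulk_section(config, gene, seed)),
        ("neighborhood", None),
        ("sc", lambda: _sc_section(config, gene, seed)),
        ("proteome", lambda: _proteome_section(config, gene, seed)),
        ("dnase", lambda: _dnase_section(config, seed)),
    ]
    compendium = None
    for name, runner in stages:
        try:
            if name == "bulk":
                dossier[name], compendium = runner()
            elif name == "neighborhood":
                dossier[name] = _neighborhood_section(config, gene, compendium)
            else:
                dossier[name] = runner()
        except Exception as exc:
            raise RuntimeError(f"evidence stage {name!r} failed: {exc}") from exc
    return dossier
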