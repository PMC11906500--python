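"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions
-----------
* Genomic coordinates are 0-based half-open internally, matching BED and
  bedGraph, the two interval formats handled here.
* Missing expression cells are 0 TPM, not NA: the detection dichotomy used
  throughout is ``TPM > 0`` versus ``TPM = 0``.
* Gene identifiers are opaque strings; an optional two-column alias table
  maps protein identifiers to gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "Compendium",
    "GeneInterval",
    "SignalTrack",
    "read_tpm_matrix",
    "write_tpm_matrix",
    "read_mtx_counts",
    "write_mtx_counts",
    "read_gmt",
    "read_alias_table",
    "read_bed",
    "read_bedgraph",
    "write_bedgraph",
]

_SPECIES = {"human", "mouse"}


@dataclass
class ExpressionDataset:
    """One bulk RNA-seq sample: a per-gene TPM vector plus metadata.

    ``aligned_reads`` is the number of aligned read pairs, the predictor of
    the detection-versus-depth logistic model.
    """

    dataset_id: str
    species: str
    subtype: str
    condition: str
    aligned_reads: int
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(
                f"species must be one of {sorted(_SPECIES)}, got {self.species!r}"
            )
        if self.aligned_reads < 0:
            raise ValueError("aligned_reads must be non-negative")
        for gene, value in self.tpm.items():
            if value < 0:
                raise ValueError(f"negative TPM {value} for gene {gene!r}")

    def detected_genes(self) -> list[str]:
        """Genes with TPM > 0 in this dataset."""
        return [g for g, v in self.tpm.items() if v > 0]


@dataclass
class Compendium:
    """Ordered collection of bulk expression datasets sharing a gene universe."""

    datasets: list[ExpressionDataset]
    gene_universe: set[str]

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_ids must be unique")
        for ds in self.datasets:
            missing = set(ds.tpm) - self.gene_universe
            if missing:
                raise ValueError(
                    f"dataset {ds.dataset_id!r} has genes outside the universe: "
                    f"{sorted(missing)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.datasets)

    def dataset(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)

    def tpm_frame(self) -> pd.DataFrame:
        """Dense genes x datasets TPM matrix; absent cells are 0."""
        genes = sorted(self.gene_universe)
        data = {
            ds.dataset_id: [ds.tpm.get(g, 0.0) for g in genes] for ds in self.datasets
        }
        return pd.DataFrame(data, index=genes)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": ds.dataset_id,
                "species": ds.species,
                "subtype": ds.subtype,
                "condition": ds.condition,
                "aligned_reads": ds.aligned_reads,
            }
            for ds in self.datasets
        ]
        return pd.DataFrame(rows).set_index("dataset_id")


@dataclass(frozen=True)
class GeneInterval:
    """Genomic interval of a gene, 0-based half-open, stranded."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be non-negative")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SignalTrack:
    """Non-overlapping, sorted signal intervals on one chromosome.

    Intervals are ``(start, end, value)`` with 0-based half-open
    coordinates and non-negative values, as in bedGraph.
    """

    chrom: str
    intervals: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, value in self.intervals:
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) is empty or inverted")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            if value < 0:
                raise ValueError(f"negative signal value {value}")
            prev_end = end


# ---------------------------------------------------------------------------
# bulk TPM matrix


def read_tpm_matrix(path: str | Path, metadata_path: str | Path) -> Compendium:
    """Read a genes x datasets TPM matrix (TSV) and its metadata table.

    The matrix's first column holds gene identifiers and the header row the
    dataset identifiers.  The metadata TSV must contain ``dataset_id``,
    ``species``, ``subtype``, ``condition`` and ``aligned_reads`` columns.
    Empty cells become 0 TPM.  Duplicated gene identifiers, negative values
    and datasets absent from the metadata are rejected.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene_id(s): {dupes[:5]}")
    matrix = matrix.fillna(0.0)
    if (matrix.values < 0).any():
        raise ValueError("TPM matrix contains negative values")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"dataset_id": str})
    required = {"dataset_id", "species", "subtype", "condition", "aligned_reads"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("dataset_id")

    datasets = []
    for dataset_id in matrix.columns:
        if dataset_id not in meta.index:
            raise ValueError(f"dataset {dataset_id!r} absent from metadata")
        row = meta.loc[dataset_id]
        col = matrix[dataset_id]
        datasets.append(
            ExpressionDataset(
                dataset_id=str(dataset_id),
                species=str(row["species"]),
                subtype=str(row["subtype"]),
                condition=str(row["condition"]),
                aligned_reads=int(row["aligned_reads"]),
                tpm={str(g): float(v) for g, v in col.items()},
            )
        )
    return Compendium(datasets=datasets, gene_universe={str(g) for g in matrix.index})


def write_tpm_matrix(
    compendium: Compendium, path: str | Path, metadata_path: str | Path
) -> None:
    """Write a Compendium as the TSV pair accepted by :func:`read_tpm_matrix`."""
    frame = compendium.tpm_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")
    compendium.metadata_frame().to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# sparse single-cell counts


def read_mtx_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
):
    """Read an MTX coordinate triplet with cluster labels into an ScDataset.

    ``features_path`` and ``barcodes_path`` are one-identifier-per-line text
    files; ``labels_path`` is a two-column TSV mapping barcode to cluster
    label.  Counts must be non-negative integers and every barcode must be
    labelled.
    """
    from leakygene.sc import ScDataset

    counts = scipy.io.mmread(str(mtx_path))
    counts = sp.csr_matrix(counts)
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise ValueError("MTX counts must be integers")
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("MTX counts must be non-negative")
    counts = counts.astype(np.int64)

    gene_ids = _read_lines(features_path)
    cell_ids = _read_lines(barcodes_path)
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(gene_ids)} features x {len(cell_ids)} barcodes"
        )

    labels_df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["barcode", "cluster"], dtype=str
    )
    label_map = dict(zip(labels_df["barcode"], labels_df["cluster"]))
    missing = [bc for bc in cell_ids if bc not in label_map]
    if missing:
        raise ValueError(f"barcode(s) missing from labels file: {missing[:5]}")
    labels = [label_map[bc] for bc in cell_ids]
    return ScDataset(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cluster_labels=labels
    )


def write_mtx_counts(
    ds,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(ds.counts))
    Path(features_path).write_text("\n".join(ds.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(ds.cell_ids) + "\n")
    with open(labels_path, "w") as fh:
        for bc, label in zip(ds.cell_ids, ds.cluster_labels):
            fh.write(f"{bc}\t{label}\n")


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# gene sets, aliases, intervals, signal


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into a name -> member-set map.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a set are collapsed.  Lines with fewer than three fields raise,
    naming the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            sets[name] = members
    return sets


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping a protein identifier to its gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "gene"], dtype=str)
    return dict(zip(df["alias"], df["gene"]))


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read 6-column BED into GeneIntervals (name column = gene_id)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED line {lineno} has fewer than 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            intervals.append(
                GeneInterval(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return intervals


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a single-chromosome bedGraph file into a SignalTrack."""
    rows: list[tuple[int, int, float]] = []
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            c, start, end, value = line.split("\t")[:4]
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(
                    f"bedGraph spans multiple chromosomes ({chrom!r}, {c!r}); "
                    "one track per chromosome is expected"
                )
            rows.append((int(start), int(end), float(value)))
    if chrom is None:
        raise ValueError("empty bedGraph file")
    rows.sort(key=lambda r: r[0])
    return SignalTrack(chrom=chrom, intervals=rows)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end, value in track.intervals:
            fh.write(f"{track.chrom}\t{start}\t{end}\t{value:.10g}\n")
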