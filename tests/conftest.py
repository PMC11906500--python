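import numpy as np
import pytest

from leakygene.io import Compendium, ExpressionDataset


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Four genes: one undetected, one sub-1-TPM, two robustly expressed."""
    return ExpressionDataset(
        dataset_id="ds0",
        species="human",
        subtype="HUVEC",
        condition="control",
        aligned_reads=30_000_000,
        tpm={"gA": 0.0, "gB": 0.5, "gC": 8.0, "gD": 64.0},
    )


@pytest.fixture
def toy_compendium() -> Compendium:
    tpms = [
        {"gA": 0.0, "gB": 0.3, "gC": 2.0, "gD": 10.0},
        {"gA": 0.0, "gB": 0.0, "gC": 4.0, "gD": 20.0},
        {"gA": 0.5, "gB": 1.5, "gC": 1.0, "gD": 5.0},
        {"gA": 0.0, "gB": 0.2, "gC": 3.0, "gD": 30.0},
    ]
    conditions = ["control", "control", "VEGF", "VEGF"]
    datasets = [
        ExpressionDataset(
            dataset_id=f"ds{i}",
            species="human",
            subtype="HUVEC" if i % 2 == 0 else "HDMEC",
            condition=conditions[i],
            aligned_reads=10_000_000 * (i + 1),
            tpm=tpm,
        )
        for i, tpm in enumerate(tpms)
    ]
    return Compendium(datasets=datasets, gene_universe={"gA", "gB", "gC", "gD"})


@pytest.fixture
def bimodal_values() -> np.ndarray:
    """10,000 log2-TPM draws: 40% leaky N(-2, 1.2) + 60% active N(4, 2)."""
    rng = np.random.default_rng(42)
    low = rng.normal(-2.0, 1.2, size=4000)
    high = rng.normal(4.0, 2.0, size=6000)
    values = np.concatenate([low, high])
    rng.shuffle(values)
    return values
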