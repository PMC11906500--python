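import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from leakygene.classify import GeneCall
from leakygene.io import Compendium, ExpressionDataset
from leakygene.neighborhood import (
    classify_neighborhood,
    holm_adjust,
    neighbor_correlations,
    regress_target_on_neighbor,
)
from leakygene.simulate import BulkSimParams, simulate_bulk_compendium


def _ripple_compendium(target_r=0.67, n_datasets=126, seed=13, extra_pairs=()):
    params = BulkSimParams(
        n_datasets=n_datasets,
        n_genes=600,
        dropout_intercept=10.0,  # leaky transcripts essentially always observed
        ripple_pairs=[("target", "nb", target_r), *extra_pairs],
        seed=seed,
    )
    comp, truth = simulate_bulk_compendium(params)
    return comp, truth


class TestNeighborCorrelations:
    def test_identical_profiles_give_r_one(self):
        rng = np.random.default_rng(0)
        datasets = []
        for i in range(10):
            base = {f"g{j}": float(v) for j, v in enumerate(rng.lognormal(1, 2, 50))}
            base["nb"] = base["target"] = float(rng.lognormal(1, 2))
            datasets.append(
                ExpressionDataset(f"d{i}", "human", "HUVEC", "control", 1, base)
            )
        comp = Compendium(datasets, set(datasets[0].tpm))
        frame = neighbor_correlations(comp, "target", ["nb"], exclude_unimodal=False)
        assert frame.iloc[0]["r"] == pytest.approx(1.0)
        assert frame.iloc[0]["p_raw"] < 1e-10

    def test_planted_ripple_r_recovered(self):
        comp, _ = _ripple_compendium(target_r=0.67)
        frame = neighbor_correlations(comp, "target", ["nb"], exclude_unimodal=False)
        assert frame.iloc[0]["n"] >= 120
        assert frame.iloc[0]["r"] == pytest.approx(0.67, abs=0.10)

    def test_unlinked_active_genes_uncorrelated(self):
        # a family of independently simulated active genes: Holm controls
        # the family-wise error, so at most ~1 of 10 may reach significance
        comp, truth = _ripple_compendium(seed=19)
        unlinked = [
            g for g, lbl in truth.gene_labels.items()
            if lbl == "active" and g not in {"target", "nb"}
        ][:10]
        frame = neighbor_correlations(comp, "target", unlinked,
                                      exclude_unimodal=False)
        assert (frame["r"].abs() < 0.25).all()
        assert (frame["p_holm"] <= 0.05).sum() <= 1
        assert frame["r"].mean() == pytest.approx(0.0, abs=0.1)

    def test_insufficient_pairs_flagged_not_raised(self, toy_compendium):
        frame = neighbor_correlations(toy_compendium, "gA", ["gB"],
                                      exclude_unimodal=False)
        assert bool(frame.iloc[0]["insufficient"])
        assert np.isnan(frame.iloc[0]["r"])

    def test_unknown_gene_rejected(self, toy_compendium):
        with pytest.raises(ValueError, match="nope"):
            neighbor_correlations(toy_compendium, "nope", ["gB"])

    def test_scale_invariance_per_dataset(self):
        comp, _ = _ripple_compendium(n_datasets=40, seed=23)
        before = neighbor_correlations(comp, "target", ["nb"],
                                       exclude_unimodal=False)
        for i, ds in enumerate(comp.datasets):
            factor = 10.0 ** (i % 3)
            ds.tpm = {g: v * factor for g, v in ds.tpm.items()}
        after = neighbor_correlations(comp, "target", ["nb"], exclude_unimodal=False)
        assert after.iloc[0]["r"] == pytest.approx(before.iloc[0]["r"], abs=1e-9)


class TestHolm:
    def test_hand_example(self):
        result = holm_adjust(np.array([0.01, 0.02, 0.04]))
        assert result == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust(np.array([0.2])) == pytest.approx([0.2])

    def test_ties_example(self):
        assert holm_adjust(np.array([0.5, 0.5])) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_bounded_by_raw_and_bonferroni_and_matches_statsmodels(self, ps):
        p = np.array(ps)
        adjusted = holm_adjust(p)
        assert (adjusted >= p - 1e-15).all()
        bonferroni = np.minimum(1.0, p * p.size)
        assert (adjusted <= bonferroni + 1e-12).all()
        _, reference, _, _ = multipletests(p, method="holm")
        assert adjusted == pytest.approx(reference)


class TestRegression:
    def test_linear_pair_recovers_slope_and_unit_r2(self):
        # target log2-TPM is exactly 2x the neighbour's on a large fixed
        # scaffold, so the zTPM pairs are linear with slope 2 up to the
        # (negligible) per-dataset variation the two genes themselves add
        rng = np.random.default_rng(41)
        scaffold = {f"s{j}": float(v) for j, v in enumerate(rng.lognormal(1, 2, 2000))}
        datasets = []
        for i, x in enumerate(np.linspace(-2.0, 2.0, 10)):
            tpm = dict(scaffold)
            tpm["nb"] = float(2.0**x)
            tpm["target"] = float(2.0 ** (2 * x))
            datasets.append(
                ExpressionDataset(f"d{i}", "human", "HUVEC", "control", 1, tpm)
            )
        comp = Compendium(datasets, set(datasets[0].tpm))
        result = regress_target_on_neighbor(comp, "target", "nb",
                                            exclude_unimodal=False)
        assert result["slope"] == pytest.approx(2.0, abs=0.01)
        assert result["r_squared"] == pytest.approx(1.0, abs=1e-4)

    def test_zero_variance_neighbor_rejected(self):
        rng = np.random.default_rng(43)
        scaffold = {f"s{j}": float(v) for j, v in enumerate(rng.lognormal(1, 2, 30))}
        tpm = dict(scaffold, nb=4.0, target=2.0)
        # identical datasets: the neighbour's zTPM carries no variance at all
        datasets = [
            ExpressionDataset(f"d{i}", "human", "HUVEC", "control", 1, dict(tpm))
            for i in range(6)
        ]
        comp = Compendium(datasets, set(datasets[0].tpm))
        with pytest.raises(ValueError, match="variance"):
            regress_target_on_neighbor(comp, "target", "nb", exclude_unimodal=False)

    def test_slope_and_r2_on_simulated_pair(self):
        comp, _ = _ripple_compendium(target_r=0.67, seed=29)
        result = regress_target_on_neighbor(comp, "target", "nb",
                                            exclude_unimodal=False)
        assert result["r_squared"] == pytest.approx(0.449, abs=0.1)

    def test_r_squared_equals_squared_pearson(self):
        comp, _ = _ripple_compendium(target_r=0.5, n_datasets=60, seed=31)
        frame = neighbor_correlations(comp, "target", ["nb"], exclude_unimodal=False)
        result = regress_target_on_neighbor(comp, "target", "nb",
                                            exclude_unimodal=False)
        assert result["r_squared"] == pytest.approx(frame.iloc[0]["r"] ** 2, abs=1e-9)
        assert result["n"] == frame.iloc[0]["n"]

    def test_independent_target_low_r2(self):
        comp, _ = _ripple_compendium(target_r=0.0, n_datasets=200, seed=37)
        result = regress_target_on_neighbor(comp, "target", "nb",
                                            exclude_unimodal=False)
        assert result["r_squared"] < 0.05

    def test_mean_r_estimate_unbiased_across_replicates(self):
        for target_r in (0.3, 0.67):
            estimates = []
            for rep in range(12):
                comp, _ = _ripple_compendium(
                    target_r=target_r, n_datasets=126, seed=1000 + rep
                )
                frame = neighbor_correlations(comp, "target", ["nb"],
                                              exclude_unimodal=False)
                estimates.append(frame.iloc[0]["r"])
            assert np.mean(estimates) == pytest.approx(target_r, abs=0.05)


class TestClassifyNeighborhood:
    def _calls(self, fracs):
        """fracs: (frac_ge1, frac_detected) -> 100 synthetic calls."""
        frac_ge1, frac_det = fracs
        calls = []
        for i in range(100):
            if i < frac_ge1 * 100:
                tpm, c1 = 5.0, "ge_1"
            elif i < frac_det * 100:
                tpm, c1 = 0.5, "lt_1_detected"
            else:
                tpm, c1 = 0.0, "not_detected"
            calls.append(
                GeneCall("g", f"d{i}", tpm, None, None, None, None,
                         "undetermined", "above", c1)
            )
        return calls

    def test_he_when_mostly_above_1tpm(self):
        calls = {"g": self._calls((0.99, 1.0))}
        assert classify_neighborhood(calls)["g"] == "HE"

    def test_ne_when_never_detected(self):
        calls = {"g": self._calls((0.0, 0.0))}
        assert classify_neighborhood(calls)["g"] == "NE"

    def test_le_between(self):
        calls = {"g": self._calls((0.05, 0.5))}
        assert classify_neighborhood(calls)["g"] == "LE"
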