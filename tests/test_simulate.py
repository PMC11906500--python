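import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from leakygene.classify import assess_modality, log2_detected
from leakygene.simulate import (
    BulkSimParams,
    simulate_bulk_compendium,
    simulate_dnase_tracks,
    simulate_proteome,
    simulate_sc_dataset,
)


class TestBulkCompendium:
    def test_same_seed_identical(self):
        params = BulkSimParams(n_datasets=5, n_genes=100, seed=11)
        c1, t1 = simulate_bulk_compendium(params)
        c2, t2 = simulate_bulk_compendium(params)
        assert t1.gene_labels == t2.gene_labels
        for d1, d2 in zip(c1.datasets, c2.datasets):
            assert d1.tpm == d2.tpm
            assert d1.aligned_reads == d2.aligned_reads

    def test_adding_dataset_preserves_earlier_ones(self):
        small = BulkSimParams(n_datasets=4, n_genes=100, seed=11)
        large = BulkSimParams(n_datasets=6, n_genes=100, seed=11)
        c_small, _ = simulate_bulk_compendium(small)
        c_large, _ = simulate_bulk_compendium(large)
        for d1, d2 in zip(c_small.datasets, c_large.datasets):
            assert d1.tpm == d2.tpm

    def test_no_leaky_class_when_frac_zero(self):
        params = BulkSimParams(
            n_datasets=3, n_genes=300, frac_leaky=0.0, frac_ne=0.3,
            frac_active=0.7, seed=2,
        )
        _, truth = simulate_bulk_compendium(params)
        assert "leaky" not in set(truth.gene_labels.values())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            BulkSimParams(frac_active=0.5, frac_leaky=0.2, frac_ne=0.2)

    def test_not_expressed_genes_always_zero(self):
        params = BulkSimParams(n_datasets=5, n_genes=200, seed=3)
        comp, truth = simulate_bulk_compendium(params)
        ne_genes = [g for g, lbl in truth.gene_labels.items() if lbl == "not_expressed"]
        for ds in comp.datasets:
            assert all(ds.tpm[g] == 0.0 for g in ne_genes)

    def test_leaky_detection_follows_logistic_curve(self):
        # empirical detection frequency at each depth must sit inside the
        # binomial CI around the closed-form logistic probability
        params = BulkSimParams(
            n_datasets=200, n_genes=400, frac_leaky=0.5, frac_ne=0.0,
            frac_active=0.5, dropout_intercept=-0.97, dropout_beta=3.96e-8,
            depth_range=(1e6, 1e8), seed=17,
        )
        comp, truth = simulate_bulk_compendium(params)
        leaky = [g for g, lbl in truth.gene_labels.items() if lbl == "leaky"]
        for ds in comp.datasets[::20]:
            p = expit(-0.97 + 3.96e-8 * ds.aligned_reads)
            k = sum(ds.tpm[g] > 0 for g in leaky)
            lo, hi = stats.binom.interval(0.9999, len(leaky), p)
            assert lo <= k <= hi

    def test_label_proportions_match_fractions(self):
        params = BulkSimParams(n_datasets=1, n_genes=5000, seed=5)
        _, truth = simulate_bulk_compendium(params)
        counts = {lbl: 0 for lbl in ("active", "leaky", "not_expressed")}
        for lbl in truth.gene_labels.values():
            counts[lbl] += 1
        for lbl, frac in [("active", 0.6), ("leaky", 0.15), ("not_expressed", 0.25)]:
            lo, hi = stats.binom.interval(0.9999, 5000, frac)
            assert lo <= counts[lbl] <= hi

    def test_marginal_distribution_is_bimodal(self):
        # well-separated defaults: mu_high - mu_low = 6 >= 4 * max(sigma)... use
        # tighter sigmas to satisfy the separation condition explicitly
        params = BulkSimParams(
            n_datasets=1, n_genes=2000, sigma_low=1.0, sigma_high=1.5,
            mu_low=-2, mu_high=4, seed=6,
        )
        comp, _ = simulate_bulk_compendium(params)
        assert assess_modality(log2_detected(comp.datasets[0])) == "bimodal"


class TestScDataset:
    PROGRAMS = {
        "EC": {"Pecam1": 5.0, "Kdr": 3.0, "Leak1": 0.0, "Cd3e": 0.0},
        "T": {"Pecam1": 0.0, "Kdr": 0.0, "Leak1": 2.0, "Cd3e": 4.0},
    }

    def test_leaky_rate_zero_means_no_counts(self):
        ds, truth = simulate_sc_dataset(
            {"EC": 200, "T": 50}, self.PROGRAMS, leaky_rate=0.0, seed=1,
            leaky_gene="Leak1",
        )
        gi = ds.gene_ids.index("Leak1")
        ec_cells = [i for i, lbl in enumerate(ds.cluster_labels) if lbl == "EC"]
        assert ds.counts[gi, ec_cells].sum() == 0

    def test_leaky_rate_recovered_at_scale(self):
        # mirrors the regime where ~1% of 4000+ non-expressing cells show
        # a single spurious count of the designated gene
        n = 4000
        rate = 0.01
        ds, truth = simulate_sc_dataset(
            {"EC": n, "T": 100}, self.PROGRAMS, leaky_rate=rate, seed=2,
            leaky_gene="Leak1",
        )
        gi = ds.gene_ids.index("Leak1")
        ec_cells = [i for i, lbl in enumerate(ds.cluster_labels) if lbl == "EC"]
        detected = int((ds.counts[gi, ec_cells].toarray() > 0).sum())
        lo, hi = stats.binom.interval(0.9999, n, rate)
        assert lo <= detected <= hi
        assert len(truth.extra["leaky_cells"]) == detected

    def test_same_seed_identical_matrix(self):
        args = ({"EC": 50, "T": 20}, self.PROGRAMS, 0.05)
        d1, _ = simulate_sc_dataset(*args, seed=9)
        d2, _ = simulate_sc_dataset(*args, seed=9)
        assert (d1.counts != d2.counts).nnz == 0

    def test_empty_programs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_sc_dataset({"EC": 10}, {}, leaky_rate=0.0, seed=0)

    def test_cluster_labels_are_true_types(self):
        ds, _ = simulate_sc_dataset(
            {"EC": 10, "T": 5}, self.PROGRAMS, leaky_rate=0.0, seed=3
        )
        assert sorted(set(ds.cluster_labels)) == ["EC", "T"]
        assert ds.cluster_labels.count("EC") == 10


class TestProteome:
    PANELS = {"IC": ["PTPRC", "CD3E"], "EC": ["KDR", "CDH5"], "MC": ["ELN"]}

    def test_no_contamination_no_ic_markers(self):
        table = simulate_proteome(
            n_samples=4, depth_per_sample=10,
            truth_present={f"P{i}" for i in range(20)},
            marker_panels=self.PANELS, contaminate=[], seed=4,
        )
        assert not set(table.index) & {"PTPRC", "CD3E"}

    def test_contaminated_samples_carry_panel(self):
        table = simulate_proteome(
            n_samples=4, depth_per_sample=10,
            truth_present={f"P{i}" for i in range(20)},
            marker_panels=self.PANELS, contaminate=[(0, "IC"), (2, "IC")], seed=4,
        )
        for marker in ("PTPRC", "CD3E"):
            for sample, expect in [("s000", True), ("s001", False), ("s002", True)]:
                value = table.loc[marker, sample]
                detected = not np.isnan(value) and value > 0.001
                assert detected == expect

    def test_depth_exceeding_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_proteome(2, 50, {"P1", "P2"}, seed=0)

    def test_same_seed_identical(self):
        kwargs = dict(
            n_samples=3, depth_per_sample=5,
            truth_present={f"P{i}" for i in range(10)}, seed=8,
        )
        t1 = simulate_proteome(**kwargs)
        t2 = simulate_proteome(**kwargs)
        assert t1.equals(t2)

    def test_absent_proteins_are_nan_or_sentinel(self):
        table = simulate_proteome(
            n_samples=10, depth_per_sample=3,
            truth_present={f"P{i}" for i in range(30)}, seed=5,
        )
        flat = table.to_numpy().ravel()
        absent = flat[np.isnan(flat) | (flat == 0.001)]
        assert absent.size > 0  # both not-detected conventions get exercised
        assert np.isnan(flat).any() and (flat == 0.001).any()


class TestDnaseTracks:
    REGION = ("chr1", 0, 10_000)

    def test_same_seed_identical(self):
        t1 = simulate_dnase_tracks(3, self.REGION, [(4000, 5000)], snr=5, seed=6)
        t2 = simulate_dnase_tracks(3, self.REGION, [(4000, 5000)], snr=5, seed=6)
        for a, b in zip(t1, t2):
            assert a.intervals == b.intervals

    def test_snr_one_indistinguishable(self):
        tracks = simulate_dnase_tracks(
            1, ("chr1", 0, 20_000), [(5000, 10_000)], snr=1.0, seed=7
        )
        values = np.array([v for _, _, v in tracks[0].intervals])
        starts = np.array([s for s, _, _ in tracks[0].intervals])
        inside = values[(starts >= 5000) & (starts < 10_000)]
        outside = values[(starts < 5000) | (starts >= 10_000)]
        assert stats.ks_2samp(inside, outside).pvalue > 0.01

    def test_no_open_windows_flat_background(self):
        tracks = simulate_dnase_tracks(2, self.REGION, [], snr=10, seed=8)
        values = np.array([v for _, _, v in tracks[0].intervals])
        # Exp(1) background: mean near 1
        assert values.mean() == pytest.approx(1.0, abs=0.15)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_dnase_tracks(1, self.REGION, [(0, 100), (50, 200)], snr=2, seed=0)

    def test_window_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_dnase_tracks(1, self.REGION, [(9000, 11_000)], snr=2, seed=0)
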