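import numpy as np
import pandas as pd
import pytest

import scontact as sc
from scontact.callers import (
    CNNDataset,
    ConvolutionalEcDNACaller,
    LogisticEcDNACaller,
    MarginError,
    aggregate_calls,
    assemble_training_dataset,
    binary_metrics,
    build_cnn_input,
    build_cnn_dataset,
    fit_lr,
    scan_cells,
)

from conftest import make_pairs

RES = 1_000_000


# ---------------------------------------------------------------------------
# logistic caller

def separable_features(n=400, seed=0):
    rng = np.random.default_rng(seed)
    neg = np.column_stack([rng.normal(2, 0.3, n), rng.normal(0.5, 0.05, n),
                           rng.normal(0.3, 0.05, n)])
    pos = np.column_stack([rng.normal(20, 2, n), rng.normal(0.15, 0.05, n),
                           rng.normal(2.5, 0.3, n)])
    X = pd.DataFrame(np.vstack([neg, pos]),
                     columns=["inferred_copy", "hub_index", "trans_cis_ratio"])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestLogisticCaller:
    def test_separable_features_high_heldout_accuracy(self):
        X, y = separable_features()
        _, metrics = fit_lr(X, y, seed=1)
        assert metrics["accuracy"] >= 0.95

    def test_permuted_labels_near_chance(self):
        X, y = separable_features()
        rng = np.random.default_rng(2)
        _, metrics = fit_lr(X, rng.permutation(y), seed=1)
        assert abs(metrics["accuracy"] - 0.5) <= 0.1

    def test_threshold_controls_call(self):
        X, y = separable_features()
        model = LogisticEcDNACaller().fit(X, y)
        row = pd.DataFrame([[6.0, 0.35, 1.0]], columns=X.columns)
        p = model.predict_proba(row)[0, 1]
        assume = 0.05 < p < 0.95
        if assume:
            assert model.predict(row, threshold=min(p - 0.01, 0.99))[0] == 1
            assert model.predict(row, threshold=min(p + 0.01, 1.0))[0] == 0

    def test_zero_weight_model_gives_half_probability(self):
        X, y = separable_features(50)
        model = LogisticEcDNACaller().fit(X, y)
        model._lr.coef_[:] = 0.0
        model._lr.intercept_[:] = 0.0
        p = model.predict_proba(X)[:, 1]
        np.testing.assert_allclose(p, 0.5)

    def test_single_class_labels_rejected(self):
        X, _ = separable_features(20)
        with pytest.raises(ValueError):
            LogisticEcDNACaller().fit(X, np.zeros(len(X), int))

    def test_no_signal_gives_small_coefficients(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(600, 3)),
                         columns=["inferred_copy", "hub_index", "trans_cis_ratio"])
        y = rng.integers(0, 2, 600)
        model = LogisticEcDNACaller().fit(X, y)
        # coefficient z-ish scale: |beta| small relative to separation scale
        assert np.all(np.abs(model.coef_) < 0.5)

    def test_nan_rows_dropped_in_fit_imputed_in_predict(self):
        X, y = separable_features(100)
        X.loc[3, "trans_cis_ratio"] = np.nan
        model = LogisticEcDNACaller().fit(X, y)
        p = model.predict_proba(X)
        assert np.isfinite(p).all()


# ---------------------------------------------------------------------------
# CNN input construction

class TestCnnInput:
    def test_neighborhood_shape_and_symmetry(self, genome):
        t = make_pairs([("chr1", 1, "chr1", 10_000_001, "A"),
                        ("chr1", 9_500_000, "chr1", 10_200_001, "A")], genome)
        cs = sc.bin_contacts(t, genome, RES)
        inp = build_cnn_input(cs.symmetric("A"), 10, genome, RES)
        assert inp.neighborhood.shape == (5, genome.n_bins(RES))
        assert np.array_equal(inp.local5x5, inp.local5x5.T)

    def test_binarization_is_idempotent(self, genome):
        t = make_pairs([("chr1", 1, "chr2", 1, "A")] * 7, genome)
        cs = sc.bin_contacts(t, genome, RES)
        inp = build_cnn_input(cs.symmetric("A"), 2, genome, RES)
        assert inp.neighborhood.max() == 1

    def test_empty_window_gives_zero_row_means(self, genome):
        t = make_pairs([("chr4", 1, "chr4", 5_000_001, "A")], genome)
        cs = sc.bin_contacts(t, genome, RES)
        inp = build_cnn_input(cs.symmetric("A"), 10, genome, RES)
        assert inp.neighborhood.sum() == 0
        assert np.all(inp.row_means == 0)
        assert inp.hub_index == 0.0

    def test_margin_bins_raise(self, genome):
        t = make_pairs([("chr1", 1, "chr2", 1, "A")], genome)
        cs = sc.bin_contacts(t, genome, RES)
        B = genome.n_bins(RES)
        for b in (0, 1, B - 2, B - 1):
            with pytest.raises(MarginError):
                build_cnn_input(cs.symmetric("A"), b, genome, RES)

    def test_row_means_l1_normalized(self, cellset_small, genome):
        bc = cellset_small.barcodes[0]
        inp = build_cnn_input(cellset_small.symmetric(bc), 10, genome, RES)
        assert inp.row_means.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# convolutional caller

def synthetic_cnn_dataset(n_per_class=40, B=40, seed=0):
    """Directly constructed, strongly separated three-class inputs."""
    rng = np.random.default_rng(seed)
    neighs, ys = [], []
    for cls in range(3):
        for _ in range(n_per_class):
            m = (rng.random((5, B)) < 0.02).astype(float)
            if cls == 1:      # ecDNA-like: dense dispersed trans row
                m[2] = (rng.random(B) < 0.6).astype(float)
            elif cls == 2:    # HSR-like: concentrated block
                m[2, 5:12] = 1.0
            neighs.append(m)
            ys.append(cls)
    neighs = np.stack(neighs)
    local = neighs[:, :, :5].reshape(len(neighs), 25)
    hub = np.array([0.1 if y == 1 else 0.8 if y == 2 else 0.4 for y in ys])
    rm = neighs.mean(axis=2)
    rm = rm / np.maximum(rm.sum(axis=1, keepdims=True), 1e-9)
    cells = np.array([f"c{i:03d}" for i in range(len(ys))], dtype=object)
    bins = np.full(len(ys), 10)
    return CNNDataset(neighs, local, hub, rm, cells, bins, np.array(ys))


class TestConvolutionalCaller:
    def test_learns_separated_classes(self):
        ds = synthetic_cnn_dataset()
        model = ConvolutionalEcDNACaller(epochs=10, seed=0).fit(ds)
        assert model.validation_report_["ternary_accuracy"] >= 0.9

    def test_same_seed_training_is_bit_identical(self):
        ds = synthetic_cnn_dataset(n_per_class=10)
        a = ConvolutionalEcDNACaller(epochs=3, seed=7).fit(ds)
        b = ConvolutionalEcDNACaller(epochs=3, seed=7).fit(ds)
        assert a.loss_history_ == b.loss_history_

    def test_missing_class_in_training_rejected(self):
        ds = synthetic_cnn_dataset(n_per_class=10)
        ds.y[ds.y == 2] = 1
        with pytest.raises(ValueError, match="classes absent"):
            ConvolutionalEcDNACaller(epochs=1, seed=0).fit(ds)

    def test_argmax_tie_breaks_to_lowest_class(self):
        probs = np.array([[1 / 3, 1 / 3, 1 / 3], [0.2, 0.7, 0.1]])
        assert ConvolutionalEcDNACaller._argmax(probs).tolist() == [0, 1]

    def test_forward_shape_audit_hg38(self):
        # B = 3044 (divisible by 4): conv widths B -> B/2 -> B/4 and the
        # first dense layer consumes 16*(B/4) + 25 + 1 + 5 features
        from scontact.callers import _ConvNet
        rng = np.random.default_rng(0)
        net = _ConvNet(3044, (8, 16), (45, 45), (223, 64), 31, 3, 0.5, rng)
        assert net.flat_dim == 16 * 761
        assert net.fc1.params["W"].shape == (223, 16 * 761 + 25 + 1 + 5)
        x = np.zeros((2, 5, 3044))
        logits = net.forward(x, np.zeros((2, 31)), False, rng)
        assert logits.shape == (2, 3)
        assert net._conv_out_shape == (2, 16, 761)

    def test_negative_class_weight_monotonically_suppresses_positives(self):
        ds = synthetic_cnn_dataset(n_per_class=20, seed=1)
        counts = []
        for neg_w in (1.0, 20.0):
            model = ConvolutionalEcDNACaller(
                epochs=4, seed=0, class_weights=[neg_w, 1.0, 1.0]).fit(ds)
            counts.append(int((model.predict(ds) > 0).sum()))
        assert counts[1] <= counts[0]

    def test_checkpoint_roundtrip(self, tmp_path):
        ds = synthetic_cnn_dataset(n_per_class=10)
        model = ConvolutionalEcDNACaller(epochs=2, seed=0).fit(ds)
        path = tmp_path / "model.npz"
        model.save(path)
        back = ConvolutionalEcDNACaller.load(path)
        np.testing.assert_allclose(model.predict_proba(ds), back.predict_proba(ds))


# ---------------------------------------------------------------------------
# scanning and aggregation

@pytest.fixture(scope="module")
def trained_small(cellset_small, sim_small, locus_bins):
    _, _, truth = sim_small
    ds = assemble_training_dataset(cellset_small, truth, locus_bins)
    return ConvolutionalEcDNACaller(epochs=10, seed=0).fit(ds)


class TestScanAndAggregate:
    def test_prediction_count_is_B_minus_4_per_cell(self, trained_small,
                                                    cellset_small):
        bcs = cellset_small.barcodes[:2]
        result = scan_cells(trained_small, cellset_small, barcodes=bcs)
        B = cellset_small.n_bins
        assert len(result.calls) == 2 * (B - 4)
        assert result.calls["bin"].min() == 2
        assert result.calls["bin"].max() == B - 3

    def test_genome_mismatch_rejected(self, trained_small):
        other = sc.Genome.from_dict({"chrA": 8_000_000})
        t = make_pairs([("chrA", 1, "chrA", 2_000_001, "X")], other)
        cs = sc.bin_contacts(t, other, RES)
        with pytest.raises(ValueError):
            scan_cells(trained_small, cs)

    def test_aggregate_fractions_partition(self, trained_small, cellset_small):
        bcs = cellset_small.barcodes[:6]
        result = scan_cells(trained_small, cellset_small, barcodes=bcs)
        per_bin, per_cell = aggregate_calls(result)
        sums = per_bin[["frac_none", "frac_ecDNA", "frac_HSR"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)
        assert len(per_cell) == 6
        assert (per_cell["any_positive"] ==
                (per_cell["any_ecdna"] | per_cell["any_hsr"])).all()


def test_binary_metrics_definitions():
    m = binary_metrics([1, 1, 0, 0, 0], [1, 0, 0, 0, 1])
    assert m["sensitivity"] == pytest.approx(0.5)
    assert m["specificity"] == pytest.approx(2 / 3)
    assert m["precision"] == pytest.approx(0.5)
    assert m["accuracy"] == pytest.approx(0.6)
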