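"""ecDNA/HSR callers over single-cell contact matrices.

Two classifiers predict, per (cell, 1 Mb bin), whether the bin carries a
focal amplification and of which kind:

* :class:`LogisticEcDNACaller` — multivariate logistic regression on
  the (inferred copy number, hub index, trans-to-cis contacting-bin
  ratio) triplet; binary ecDNA-vs-not with a configurable probability
  threshold.
* :class:`ConvolutionalEcDNACaller` — a small convolutional network
  over the binarized 5 Mb neighbourhood of a bin (a 5 x B matrix of
  cis + trans contacts), augmented with the local 5 x 5 contact block,
  the hub index and L1-normalised row means.  Ternary output:
  0 = none, 1 = ecDNA, 2 = HSR.

Both follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .features import FEATURE_COLUMNS, gini
from .genome import Genome
from .matrices import CellMatrixSet

__all__ = [
    "LogisticEcDNACaller",
    "ConvolutionalEcDNACaller",
    "CNNInput",
    "CNNDataset",
    "EcDNACallResult",
    "MarginError",
    "build_cnn_input",
    "build_cnn_dataset",
    "scan_cells",
    "aggregate_calls",
    "fit_lr",
    "binary_metrics",
    "CLASS_NAMES",
]

CLASS_NAMES = ("none", "ecDNA", "HSR")
MARGIN = 2  # bins skipped at each end of the global bin index


# ---------------------------------------------------------------------------
# metrics

def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Sensitivity, specificity, precision and accuracy of a binary call."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    div = lambda a, b: a / b if b else float("nan")
    return {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "precision": div(tp, tp + fp),
        "accuracy": div(tp + tn, tp + tn + fp + fn),
    }


# ---------------------------------------------------------------------------
# logistic-regression caller

class LogisticEcDNACaller(BaseEstimator, ClassifierMixin):
    """Multivariate logistic regression on the ecDNA feature triplet.

    Parameters
    ----------
    threshold
        Posterior-probability cutoff for a positive call (default 0.5;
        stricter screens may use e.g. 0.95).
    max_iter
        Solver iterations for the unpenalised fit.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients for
        (inferred_copy, hub_index, trans_cis_ratio).
    feature_medians_ : per-feature medians of the training rows, used to
        impute undefined features at prediction time when no per-bin
        population median is available.
    """

    def __init__(self, threshold: float = 0.5, max_iter: int = 1000) -> None:
        self.threshold = threshold
        self.max_iter = max_iter

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[FEATURE_COLUMNS].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y) -> "LogisticEcDNACaller":
        Xm = self._as_matrix(X)
        y = np.asarray(y).astype(int)
        if Xm.shape[1] != 3:
            raise ValueError("expected the 3-column feature triplet")
        keep = ~np.isnan(Xm).any(axis=1)
        Xm, y = Xm[keep], y[keep]
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class; cannot fit")
        self.feature_medians_ = np.median(Xm, axis=0)
        # C = inf: an unpenalised fit, matching a plain GLM
        self._lr = LogisticRegression(C=np.inf, max_iter=self.max_iter)
        self._lr.fit(Xm, y)
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        self.classes_ = self._lr.classes_
        return self

    def _impute(self, X) -> np.ndarray:
        Xm = self._as_matrix(X).copy()
        if isinstance(X, pd.DataFrame) and "bin" in X.columns:
            # per-bin population median over the prediction cohort
            bins = X["bin"].to_numpy()
            for j in range(Xm.shape[1]):
                col = pd.Series(Xm[:, j])
                med = col.groupby(bins).transform("median")
                col = col.fillna(med)
                Xm[:, j] = col.fillna(self.feature_medians_[j]).to_numpy()
        else:
            for j in range(Xm.shape[1]):
                m = np.isnan(Xm[:, j])
                Xm[m, j] = self.feature_medians_[j]
        return Xm

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._lr.predict_proba(self._impute(X))

    def predict(self, X, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        p = self.predict_proba(X)[:, 1]
        return (p >= thr).astype(int)

    def evaluate(self, X, y) -> dict[str, float]:
        return binary_metrics(np.asarray(y).astype(bool), self.predict(X).astype(bool))


def fit_lr(
    features: pd.DataFrame,
    labels: Sequence[int],
    threshold: float = 0.5,
    holdout: float = 0.2,
    seed: int = 0,
) -> tuple[LogisticEcDNACaller, dict[str, float]]:
    """Fit the logistic caller and report held-out performance."""
    y = np.asarray(labels).astype(int)
    idx_tr, idx_te = train_test_split(
        np.arange(len(y)), test_size=holdout, random_state=seed, stratify=y
    )
    model = LogisticEcDNACaller(threshold=threshold)
    Xdf = features.iloc[idx_tr] if isinstance(features, pd.DataFrame) else features[idx_tr]
    model.fit(Xdf, y[idx_tr])
    Xte = features.iloc[idx_te] if isinstance(features, pd.DataFrame) else features[idx_te]
    return model, model.evaluate(Xte, y[idx_te])


# ---------------------------------------------------------------------------
# CNN input construction

class MarginError(ValueError):
    """Raised for bins in the skipped genome margins (first/last two
    global bins), where the 5 Mb neighbourhood is incomplete."""


@dataclass
class CNNInput:
    """Features of one (cell, bin): binarized 5 x B neighbourhood, the
    5 x 5 local block among the five neighbourhood bins (diagonal =
    intra-bin contacts), the raw-count hub index of the centre bin and
    L1-normalised row means of the binarized neighbourhood."""

    neighborhood: np.ndarray  # (5, B) uint8
    local5x5: np.ndarray      # (5, 5) uint8
    hub_index: float
    row_means: np.ndarray     # (5,) sums to 1, or all-zero


@dataclass
class CNNDataset:
    """Stacked CNN inputs, optionally labelled (0 none / 1 ecDNA / 2 HSR)."""

    neighborhood: np.ndarray  # (N, 5, B)
    local5x5: np.ndarray      # (N, 25)
    hub: np.ndarray           # (N,)
    row_means: np.ndarray     # (N, 5)
    cells: np.ndarray         # (N,) barcode per row
    bins: np.ndarray          # (N,) global bin per row
    y: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.hub)

    @property
    def n_bins_genome(self) -> int:
        return self.neighborhood.shape[2]

    def extras(self) -> np.ndarray:
        return np.concatenate(
            [self.local5x5, self.hub[:, None], self.row_means], axis=1
        ).astype(float)


def _hub_from_row(row_counts: np.ndarray, bin_: int, genome: Genome, resolution: int) -> float:
    chrom_ids = genome.bin_chrom_ids(resolution)
    per_chrom = np.bincount(chrom_ids, weights=row_counts, minlength=genome.n_chroms)
    own = chrom_ids[bin_]
    keep = [
        ci for ci, name in enumerate(genome.chrom_names)
        if ci != own and name not in genome.excluded_chroms
    ]
    vec = per_chrom[keep]
    if vec.size == 0 or vec.sum() == 0:
        return 0.0  # all-zero neighbourhoods must not crash the scanner
    return gini(vec)


def build_cnn_input(
    cell_matrix: sp.spmatrix, bin_: int, genome: Genome, resolution: int
) -> CNNInput:
    """CNN features for one bin of one cell's symmetric contact matrix."""
    B = genome.n_bins(resolution)
    if bin_ < MARGIN or bin_ >= B - MARGIN:
        raise MarginError(f"bin {bin_} lies in the skipped margin of [0, {B})")
    rows = cell_matrix[bin_ - MARGIN : bin_ + MARGIN + 1]
    neigh = (np.asarray(rows.todense()) > 0).astype(np.uint8)
    local = neigh[:, bin_ - MARGIN : bin_ + MARGIN + 1]
    center = np.asarray(cell_matrix.getrow(bin_).todense()).ravel()
    hub = _hub_from_row(center, bin_, genome, resolution)
    rm = neigh.mean(axis=1)
    s = rm.sum()
    row_means = rm / s if s > 0 else rm
    return CNNInput(neigh, local, hub, row_means)


def build_cnn_dataset(
    cellset: CellMatrixSet,
    cell_bins: Iterable[tuple[str, int]],
    labels: Sequence[int] | None = None,
) -> CNNDataset:
    """Stack CNN inputs for the given (barcode, bin) pairs."""
    genome, res = cellset.genome, cellset.resolution
    cell_bins = list(cell_bins)
    neighs, locals_, hubs, rms, cells, bins_ = [], [], [], [], [], []
    cache: dict[str, sp.csr_matrix] = {}
    for bc, b in cell_bins:
        if bc not in cache:
            cache[bc] = cellset.symmetric(bc)
        inp = build_cnn_input(cache[bc], b, genome, res)
        neighs.append(inp.neighborhood)
        locals_.append(inp.local5x5.ravel())
        hubs.append(inp.hub_index)
        rms.append(inp.row_means)
        cells.append(bc)
        bins_.append(b)
    y = None if labels is None else np.asarray(labels, dtype=int)
    return CNNDataset(
        np.stack(neighs).astype(float),
        np.stack(locals_).astype(float),
        np.asarray(hubs, dtype=float),
        np.stack(rms).astype(float),
        np.asarray(cells, dtype=object),
        np.asarray(bins_, dtype=int),
        y=y,
    )


# ---------------------------------------------------------------------------
# convolutional caller

class _ConvNet:
    """The network graph: two conv modules -> flatten + side features ->
    two hidden dense layers -> 3-way softmax logits."""

    def __init__(self, B_padded: int, channels: tuple[int, int],
                 kernel_widths: tuple[int, int], fc_hidden: tuple[int, int],
                 n_extras: int, n_classes: int, dropout: float,
                 rng: np.random.Generator) -> None:
        c1, c2 = channels
        k1, k2 = kernel_widths
        p1, p2 = (k1 - 1) // 2, (k2 - 1) // 2  # "same" width
        self.conv1 = nn.ConvWidth(1, 5, c1, k1, p1, rng)
        self.bn1 = nn.BatchNorm(c1)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.MaxPoolWidth(2)
        self.drop_mid = nn.Dropout(dropout)
        self.conv2 = nn.ConvWidth(c1, 1, c2, k2, p2, rng)
        self.bn2 = nn.BatchNorm(c2)
        self.relu2 = nn.ReLU()
        self.pool2 = nn.MaxPoolWidth(2)
        self.flat_dim = c2 * (B_padded // 4)
        h1, h2 = fc_hidden
        self.fc1 = nn.Dense(self.flat_dim + n_extras, h1, rng)
        self.bn3 = nn.BatchNorm(h1, channel_axis=-1)
        self.gelu1 = nn.GELU()
        self.drop_fc = nn.Dropout(dropout)
        self.fc2 = nn.Dense(h1, h2, rng)
        self.gelu2 = nn.GELU()
        self.out = nn.Dense(h2, n_classes, rng)
        self.conv_stack = [self.conv1, self.bn1, self.relu1, self.pool1,
                           self.drop_mid, self.conv2, self.bn2, self.relu2, self.pool2]
        self.fc_stack = [self.fc1, self.bn3, self.gelu1, self.drop_fc,
                         self.fc2, self.gelu2, self.out]
        self.layers = self.conv_stack + self.fc_stack

    def forward(self, neigh: np.ndarray, extras: np.ndarray,
                train: bool, rng: np.random.Generator) -> np.ndarray:
        x = neigh[:, None, :, :]  # (N, 1, 5, B)
        for layer in self.conv_stack:
            x = layer.forward(x, train, rng)
        self._conv_out_shape = x.shape
        h = np.concatenate([x.reshape(x.shape[0], -1), extras], axis=1)
        for layer in self.fc_stack:
            h = layer.forward(h, train, rng)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.fc_stack):
            g = layer.backward(g)
        gconv = g[:, : self.flat_dim].reshape(self._conv_out_shape)
        for layer in reversed(self.conv_stack):
            gconv = layer.backward(gconv)


class ConvolutionalEcDNACaller(BaseEstimator, ClassifierMixin):
    """Convolutional ternary caller (none / ecDNA / HSR) on binarized
    5 Mb neighbourhood contact profiles.

    Two convolutional modules (conv -> batch norm -> ReLU -> max pool
    halving the width) with 8 and 16 channels and wide kernels (5 x 45,
    then 1 x 45) feed, together with the flattened 5 x 5 local block,
    the hub index and the row means, into dense layers of size 223 and
    64 and a 3-way softmax.  Training uses AdamW (lr 0.001, weight decay
    0.001), mini-batches of 32 over 40 epochs and the hard bootstrapped
    cross-entropy (beta = 0.99) with class weights biased toward the
    negative class.  The number of genome bins B is a free parameter;
    the neighbourhood is right-padded with zero columns to a multiple of
    four so both pooling stages divide evenly.

    All randomness (train/validation split at the cell level, weight
    initialisation, shuffling, dropout) derives from ``seed``.
    """

    def __init__(
        self,
        channels: tuple[int, int] = (8, 16),
        kernel_widths: tuple[int, int] = (45, 45),
        fc_hidden: tuple[int, int] = (223, 64),
        n_classes: int = 3,
        dropout: float = 0.5,
        epochs: int = 40,
        batch_size: int = 32,
        lr: float = 1e-3,
        weight_decay: float = 1e-3,
        beta: float = 0.99,
        class_weights: Sequence[float] | None = None,
        negative_bias: float = 2.0,
        train_fraction: float = 0.9,
        seed: int = 0,
    ) -> None:
        self.channels = channels
        self.kernel_widths = kernel_widths
        self.fc_hidden = fc_hidden
        self.n_classes = n_classes
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta = beta
        self.class_weights = class_weights
        self.negative_bias = negative_bias
        self.train_fraction = train_fraction
        self.seed = seed

    # -- helpers ---------------------------------------------------------

    def _pad(self, neigh: np.ndarray) -> np.ndarray:
        B = neigh.shape[2]
        target = self.B_padded_
        if B == target:
            return neigh
        return np.pad(neigh, ((0, 0), (0, 0), (0, target - B)))

    def _default_weights(self, y: np.ndarray) -> np.ndarray:
        counts = np.bincount(y, minlength=self.n_classes).astype(float)
        counts[counts == 0] = 1.0
        w = counts.sum() / (self.n_classes * counts)  # inverse class frequency
        w[0] *= self.negative_bias  # favour negative ('none') predictions
        return w

    # -- estimator API ---------------------------------------------------

    def fit(self, X: CNNDataset, y: Sequence[int] | None = None) -> "ConvolutionalEcDNACaller":
        ds = X
        y = ds.y if y is None else np.asarray(y, dtype=int)
        if y is None:
            raise ValueError("labels required: pass y or a labelled CNNDataset")
        rng = np.random.default_rng(self.seed)
        B = ds.n_bins_genome
        self.B_genome_ = B
        self.B_padded_ = int(4 * np.ceil(B / 4))

        # cell-level train/validation split
        cells = np.unique(ds.cells)
        rng.shuffle(cells)
        n_train = max(1, int(round(self.train_fraction * len(cells))))
        train_cells = set(cells[:n_train])
        tr = np.array([c in train_cells for c in ds.cells])
        va = ~tr
        missing = set(range(self.n_classes)) - set(np.unique(y[tr]))
        if missing:
            raise ValueError(f"classes absent from the training split: {sorted(missing)}")

        w = (np.asarray(self.class_weights, float) if self.class_weights is not None
             else self._default_weights(y[tr]))
        self.class_weights_ = w

        net = _ConvNet(self.B_padded_, tuple(self.channels), tuple(self.kernel_widths),
                       tuple(self.fc_hidden), 31, self.n_classes, self.dropout, rng)
        opt = nn.AdamW(net.layers, lr=self.lr, weight_decay=self.weight_decay)

        neigh = self._pad(ds.neighborhood)
        extras = ds.extras()
        idx_tr = np.flatnonzero(tr)
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(idx_tr)
            losses = []
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                logits = net.forward(neigh[sel], extras[sel], True, rng)
                loss, dlogits, _ = nn.bootstrapped_cross_entropy(
                    logits, y[sel], beta=self.beta, class_weights=w
                )
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))

        self.net_ = net
        self.classes_ = np.arange(self.n_classes)
        self.validation_report_ = (
            self._validate(neigh[va], extras[va], y[va], ds.cells[va]) if va.any() else None
        )
        return self

    def _forward_eval(self, neigh: np.ndarray, extras: np.ndarray,
                      chunk: int = 256) -> np.ndarray:
        probs = []
        dummy = np.random.default_rng(0)
        for start in range(0, len(neigh), chunk):
            logits = self.net_.forward(
                neigh[start : start + chunk], extras[start : start + chunk], False, dummy
            )
            probs.append(nn.softmax(logits))
        return np.concatenate(probs) if probs else np.zeros((0, self.n_classes))

    def _validate(self, neigh, extras, y, cells) -> dict:
        p = self._forward_eval(neigh, extras)
        pred = self._argmax(p)
        conf = np.zeros((self.n_classes, self.n_classes), dtype=int)
        for t, q in zip(y, pred):
            conf[t, q] += 1
        report = {
            "confusion": conf,
            "ternary_accuracy": float(np.mean(pred == y)),
            "binary": binary_metrics(y > 0, pred > 0),
        }
        # cell-level: a cell is positive if any of its rows is
        cell_truth = pd.Series(y > 0).groupby(np.asarray(cells)).any()
        cell_pred = pd.Series(pred > 0).groupby(np.asarray(cells)).any()
        report["cell_level_binary"] = binary_metrics(
            cell_truth.to_numpy(), cell_pred.reindex(cell_truth.index).to_numpy()
        )
        return report

    @staticmethod
    def _argmax(probs: np.ndarray) -> np.ndarray:
        # np.argmax already returns the lowest index on ties ('none' wins)
        return probs.argmax(axis=1)

    def predict_proba(self, X: CNNDataset) -> np.ndarray:
        check_is_fitted(self, "net_")
        if X.n_bins_genome != self.B_genome_:
            raise ValueError(
                f"genome bin count {X.n_bins_genome} != training bin count {self.B_genome_}"
            )
        return self._forward_eval(self._pad(X.neighborhood), X.extras())

    def predict(self, X: CNNDataset) -> np.ndarray:
        return self._argmax(self.predict_proba(X))

    # -- checkpointing ---------------------------------------------------

    def save(self, path: str) -> None:
        check_is_fitted(self, "net_")
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net_.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}.{k}"] = v
            if isinstance(layer, nn.BatchNorm):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        meta = {
            "params": self.get_params(),
            "B_genome": int(self.B_genome_),
            "class_weights": list(map(float, self.class_weights_)),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "ConvolutionalEcDNACaller":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = meta["params"]
        for key in ("channels", "kernel_widths", "fc_hidden"):
            params[key] = tuple(params[key])
        if params["class_weights"] is not None:
            params["class_weights"] = list(params["class_weights"])
        model = cls(**params)
        model.B_genome_ = meta["B_genome"]
        model.B_padded_ = int(4 * np.ceil(meta["B_genome"] / 4))
        model.class_weights_ = np.asarray(meta["class_weights"])
        model.classes_ = np.arange(model.n_classes)
        model.loss_history_ = []
        rng = np.random.default_rng(0)
        model.net_ = _ConvNet(model.B_padded_, tuple(model.channels),
                              tuple(model.kernel_widths), tuple(model.fc_hidden),
                              31, model.n_classes, model.dropout, rng)
        for i, layer in enumerate(model.net_.layers):
            for k in layer.params:
                layer.params[k] = data[f"layer{i}.{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"layer{i}.running_mean"]
                layer.running_var = data[f"layer{i}.running_var"]
        return model


# ---------------------------------------------------------------------------
# genome-wide scanning and aggregation

@dataclass
class EcDNACallResult:
    """Per-(cell, bin) calls with class probabilities."""

    calls: pd.DataFrame  # barcode, bin, class, p_none, p_ecdna, p_hsr
    n_classes: int = 3


def scan_cells(
    model: ConvolutionalEcDNACaller,
    cellset: CellMatrixSet,
    barcodes: Iterable[str] | None = None,
    chunk: int = 512,
) -> EcDNACallResult:
    """Scan every non-margin bin of every cell with a trained caller.

    Predictions cover global bins ``[2, B - 2)`` — i.e. B - 4 bins per
    cell, the first two and last two lacking a full 5 Mb neighbourhood.
    """
    check_is_fitted(model, "net_")
    genome, res = cellset.genome, cellset.resolution
    B = genome.n_bins(res)
    if B != model.B_genome_:
        raise ValueError(f"genome bin count {B} != model bin count {model.B_genome_}")
    chrom_ids = genome.bin_chrom_ids(res)
    excl = np.array([c in genome.excluded_chroms for c in genome.chrom_names])
    frames = []
    for bc in barcodes if barcodes is not None else cellset.barcodes:
        sym = cellset.symmetric(bc)
        dense = (np.asarray(sym.todense()) > 0).astype(float)
        windows = np.lib.stride_tricks.sliding_window_view(dense, 5, axis=0)
        neigh = np.transpose(windows, (0, 2, 1))  # (B-4, 5, B)
        bins_ = np.arange(MARGIN, B - MARGIN)
        # local 5x5 blocks
        local = np.stack([neigh[i, :, b - MARGIN : b + MARGIN + 1].ravel()
                          for i, b in enumerate(bins_)])
        # hub index per bin from raw counts aggregated per chromosome
        chrom_ind = np.zeros((B, genome.n_chroms))
        chrom_ind[np.arange(B), chrom_ids] = 1.0
        per_chrom = np.asarray(sym @ chrom_ind)[bins_]
        hubs = np.empty(len(bins_))
        for i, b in enumerate(bins_):
            vec = per_chrom[i].copy()
            keep = ~excl
            keep = keep.copy()
            keep[chrom_ids[b]] = False
            v = vec[keep]
            hubs[i] = 0.0 if v.sum() == 0 else gini(v)
        rm = neigh.mean(axis=2)
        sums = rm.sum(axis=1, keepdims=True)
        row_means = np.divide(rm, sums, out=np.zeros_like(rm), where=sums > 0)
        ds = CNNDataset(neigh, local, hubs, row_means,
                        np.full(len(bins_), bc, dtype=object), bins_)
        probs = model.predict_proba(ds)
        pred = model._argmax(probs)
        frames.append(pd.DataFrame({
            "barcode": bc, "bin": bins_, "class": pred,
            "p_none": probs[:, 0], "p_ecdna": probs[:, 1], "p_hsr": probs[:, 2],
        }))
    return EcDNACallResult(pd.concat(frames, ignore_index=True))


MODE_LABELS = {"none": 0, "ecDNA": 1, "HSR": 2}


def assemble_training_dataset(
    cellset: CellMatrixSet,
    truth: pd.DataFrame,
    locus_bins: Sequence[int],
) -> CNNDataset:
    """Labelled CNN dataset at a candidate locus.

    Every cell contributes one row per locus bin, labelled by the cell's
    amplicon mode there (``none`` / ``ecDNA`` / ``HSR``) from a truth
    table with columns ``barcode, mode``.
    """
    mode_by_cell = truth.drop_duplicates("barcode").set_index("barcode")["mode"]
    pairs_, labels = [], []
    for bc in cellset.barcodes:
        label = MODE_LABELS[mode_by_cell.get(bc, "none")]
        for b in locus_bins:
            pairs_.append((bc, int(b)))
            labels.append(label)
    return build_cnn_dataset(cellset, pairs_, labels)


def aggregate_calls(result: EcDNACallResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population aggregates of a scan.

    Returns ``(per_bin, per_cell)``: per bin, the fraction of cells
    whose call at that bin is each class; per cell, any-positive flags.
    """
    calls = result.calls
    per_bin = (
        calls.groupby("bin")["class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(result.n_classes), fill_value=0.0)
    )
    per_bin.columns = [f"frac_{CLASS_NAMES[c]}" for c in per_bin.columns]
    per_cell = calls.groupby("barcode")["class"].agg(
        any_ecdna=lambda s: bool((s == 1).any()),
        any_hsr=lambda s: bool((s == 2).any()),
    )
    per_cell["any_positive"] = per_cell["any_ecdna"] | per_cell["any_hsr"]
    return per_bin.reset_index(), per_cell.reset_index()
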