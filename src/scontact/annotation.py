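"""Chromatin-based cell annotation and malignant-state scoring.

* **scGAD scores** — per-cell raw contact counts over gene bodies; the
  chromatin analogue of an expression vector, used to co-embed Hi-C
  cells with RNA references.
* **k-NN label transfer** — Euclidean nearest reference neighbours with
  standardized inverse-distance scores that sum to one; the label with
  the highest aggregate score wins.
* **Overlap coefficients** — validation of annotations through
  co-embedding clusters.
* **Cellular-state scores** — signature mean minus expression-matched
  control mean (glioma OPC/NPC/AC/MES states), projected onto the
  differential-score / identity plane.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .matrices import CellMatrixSet

__all__ = [
    "gad_scores",
    "transfer_labels",
    "overlap_coefficients",
    "state_scores",
    "state_projection",
    "hic_state_scores",
    "STATES",
]

STATES = ("OPC", "NPC", "AC", "MES")
EPS = 1e-8


def gad_scores(
    cellset: CellMatrixSet, gene_bins: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Cells x genes matrix of raw contact counts over gene bodies.

    A contact contributes once to gene *g* when either anchor's bin
    overlaps the gene body (*gene_bins* maps gene -> global bins of its
    body at the set's resolution).
    """
    genes = list(gene_bins)
    out = np.zeros((len(cellset.barcodes), len(genes)), dtype=np.int64)
    for i, bc in enumerate(cellset.barcodes):
        u = cellset.upper(bc)
        for j, g in enumerate(genes):
            bins = np.asarray(list(gene_bins[g]), dtype=int)
            rows = u[bins].sum()
            cols = u[:, bins].sum()
            both = u[np.ix_(bins, bins)].sum()
            out[i, j] = int(rows + cols - both)
    return pd.DataFrame(out, index=pd.Index(cellset.barcodes, name="barcode"),
                        columns=genes)


def transfer_labels(
    query_embedding: np.ndarray,
    ref_embedding: np.ndarray,
    ref_labels: Sequence[str],
    k: int = 15,
    eps: float = EPS,
) -> pd.DataFrame:
    """k-NN label transfer with standardized neighbour scores.

    For each query cell the *k* Euclidean nearest reference neighbours
    get scores ``D_m = (1/(d_m + eps)) / sum(1/(d + eps))`` — summing to
    one, decreasing in distance — and the label whose neighbours
    accumulate the highest score is assigned.

    Returns a DataFrame with the assigned label, its aggregate score,
    and per-neighbour indices/distances/scores as object columns.
    """
    query = np.asarray(query_embedding, float)
    ref = np.asarray(ref_embedding, float)
    ref_labels = np.asarray(ref_labels)
    if k > len(ref):
        raise ValueError(f"k={k} exceeds reference size {len(ref)}")
    nbrs = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(ref)
    dist, idx = nbrs.kneighbors(query)
    inv = 1.0 / (dist + eps)
    scores = inv / inv.sum(axis=1, keepdims=True)
    labels = np.unique(ref_labels)
    agg = np.zeros((len(query), len(labels)))
    for li, lab in enumerate(labels):
        agg[:, li] = np.where(ref_labels[idx] == lab, scores, 0.0).sum(axis=1)
    best = agg.argmax(axis=1)
    return pd.DataFrame({
        "label": labels[best],
        "label_score": agg[np.arange(len(query)), best],
        "neighbor_idx": list(idx),
        "neighbor_dist": list(dist),
        "neighbor_score": list(scores),
    })


def overlap_coefficients(
    labels_a: Mapping[str, set],
    labels_b: Mapping[str, set],
    clusters: Mapping[str, set],
) -> pd.DataFrame:
    """Overlap coefficients between two annotations through co-embedding
    clusters: ``O_ij = max_k min(|A_i n C_k| / |A_i|, |B_j n C_k| / |B_j|)``."""
    out = pd.DataFrame(0.0, index=list(labels_a), columns=list(labels_b))
    for i, a in labels_a.items():
        for j, b in labels_b.items():
            if not a or not b:
                continue
            best = 0.0
            for c in clusters.values():
                best = max(best, min(len(a & c) / len(a), len(b & c) / len(b)))
            out.loc[i, j] = best
    return out


def _control_genes(
    mean_expr: pd.Series, gene_set: Sequence[str], n_bins: int, n_ctrl: int,
    rng: np.random.Generator,
) -> list[str]:
    # expression-matched control pool: genes from the same average-
    # expression bin as each signature gene, the signature itself
    # excluded so the score contrasts signal against background
    ranks = mean_expr.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    sig = set(gene_set)
    pool: list[str] = []
    for g in gene_set:
        same_bin = mean_expr.index[bins == bins[g]]
        candidates = same_bin.difference(sig)
        if len(candidates) == 0:
            candidates = same_bin
        take = min(n_ctrl, len(candidates))
        pool.extend(rng.choice(candidates, size=take, replace=False))
    return pool


def state_scores(
    expression: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Signature-minus-control state scores per cell.

    ``SC_j(i) = mean expression of G_j in cell i - mean expression of an
    expression-matched control set G_jcont`` (controls sampled per
    signature gene from its average-expression bin; *n_bins* bins,
    *n_ctrl* controls per gene, seeded).  Signature genes missing from
    the matrix are dropped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    mean_expr = expression.mean(axis=0)
    out = {}
    for state, genes in gene_sets.items():
        present = [g for g in genes if g in expression.columns]
        if len(present) < len(genes):
            warnings.warn(
                f"{state}: {len(genes) - len(present)} signature genes absent; dropped"
            )
        if not present:
            out[state] = np.full(len(expression), np.nan)
            continue
        ctrl = _control_genes(mean_expr, present, n_bins, n_ctrl, rng)
        sig_mean = expression[present].mean(axis=1)
        ctrl_mean = expression[ctrl].mean(axis=1)
        out[state] = (sig_mean - ctrl_mean).to_numpy()
    return pd.DataFrame(out, index=expression.index)


def state_projection(scores: pd.DataFrame) -> pd.DataFrame:
    """Two-dimensional state projection.

    ``D = max(SC_OPC, SC_NPC) - max(SC_AC, SC_MES)`` separates the
    progenitor pair from the differentiated pair; within the winning
    pair the identity value is ``log2(|SC_a - SC_b| + 1)``, signed
    positive toward OPC (progenitor pair) or AC (differentiated pair).
    The quadrant is the winning state.
    """
    sc = scores[list(STATES)]
    opc, npc, ac, mes = (sc[s].to_numpy() for s in STATES)
    d = np.maximum(opc, npc) - np.maximum(ac, mes)
    prog = d > 0
    pair_a = np.where(prog, opc, ac)
    pair_b = np.where(prog, npc, mes)
    identity = np.sign(pair_a - pair_b) * np.log2(np.abs(pair_a - pair_b) + 1.0)
    quadrant = np.where(
        prog,
        np.where(opc >= npc, "OPC", "NPC"),
        np.where(ac >= mes, "AC", "MES"),
    )
    return pd.DataFrame(
        {"D": d, "identity": identity, "quadrant": quadrant}, index=scores.index
    )


def hic_state_scores(
    neighbor_scores: np.ndarray, neighbor_sc: np.ndarray
) -> np.ndarray:
    """Neighbour-weighted state scores for Hi-C cells.

    ``HSC_j(i) = sum_g SC_j(g) * D_m(g)`` over the cell's reference
    neighbours: a convex combination of the neighbours' state scores.
    *neighbor_scores* is (cells, k) standardized scores; *neighbor_sc*
    is (cells, k, states).
    """
    d = np.asarray(neighbor_scores, float)
    sc = np.asarray(neighbor_sc, float)
    return np.einsum("nk,nks->ns", d, sc)
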