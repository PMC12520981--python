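"""Per-(cell, bin) interaction metrics used by the ecDNA callers.

Three metrics characterise how a 1 Mb genomic bin contacts the rest of
the genome in a single cell:

* **hub index** — the Gini coefficient of the bin's trans contacts
  aggregated per chromosome (own and excluded chromosomes dropped, zero
  chromosomes included).  Evenly dispersed trans contacts (ecDNA-like)
  give a low index; contacts concentrated on few chromosomes (HSR-like)
  give a high one.
* **trans-to-cis contacting-bin ratio** ``R = N_T / N_C`` — distinct
  trans partner bins over distinct cis partner bins; a copy-number
  robust measure of trans-interaction tendency.
* **inferred copy number** — from the coverage-based CNV profile.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import Genome
from .matrices import CellMatrixSet, CNVProfile

__all__ = [
    "gini",
    "hub_index",
    "trans_cis_bin_ratio",
    "cell_bin_features",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["inferred_copy", "hub_index", "trans_cis_ratio"]


def gini(x: np.ndarray) -> float:
    """Gini coefficient ``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))``.

    Computed via the sorted form; zero entries are legitimate members of
    the vector.  Returns NaN for an all-zero vector; raises on empty.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    if np.any(x < 0):
        raise ValueError("gini requires nonnegative values")
    total = x.sum()
    if total == 0:
        return float("nan")
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs)) / (n * total) - (n + 1.0) / n)


def _trans_counts_by_chrom(
    sym_row: sp.spmatrix, bin_: int, genome: Genome, resolution: int
) -> np.ndarray:
    """Trans contact counts of a query bin aggregated per eligible
    chromosome (own chromosome and excluded chromosomes dropped, zeros
    kept)."""
    chrom_ids = genome.bin_chrom_ids(resolution)
    own = chrom_ids[bin_]
    row = np.asarray(sym_row.todense()).ravel()
    per_chrom = np.bincount(chrom_ids, weights=row, minlength=genome.n_chroms)
    eligible = [
        ci
        for ci, name in enumerate(genome.chrom_names)
        if ci != own and name not in genome.excluded_chroms
    ]
    return per_chrom[eligible]


def hub_index(trans_counts_by_chrom: np.ndarray) -> float:
    """Gini coefficient of per-chromosome trans contact counts.

    The input vector must include zero entries for eligible chromosomes
    with no contacts.  NaN signals an all-zero (undefined) case.
    """
    return gini(trans_counts_by_chrom)


def trans_cis_bin_ratio(
    cell_matrix: sp.spmatrix, bin_: int, genome: Genome, resolution: int
) -> tuple[float, int, int]:
    """``(R, N_T, N_C)`` for a query bin of one cell's symmetric matrix.

    ``N_T`` counts distinct trans partner bins with nonzero count
    (excluded chromosomes dropped); ``N_C`` counts distinct cis partner
    bins including the bin itself when self-contacts exist.  ``R`` is NaN
    when ``N_C == 0``.
    """
    chrom_ids = genome.bin_chrom_ids(resolution)
    own = chrom_ids[bin_]
    row = cell_matrix.getrow(bin_)
    cols = row.indices[row.data > 0]
    partner_chroms = chrom_ids[cols]
    excluded = np.array(
        [genome.chrom_names[c] in genome.excluded_chroms for c in partner_chroms]
    ) if cols.size else np.zeros(0, dtype=bool)
    n_cis = int(np.sum(partner_chroms == own))
    n_trans = int(np.sum((partner_chroms != own) & ~excluded))
    r = n_trans / n_cis if n_cis > 0 else float("nan")
    return r, n_trans, n_cis


def trans_counts_matrix(
    cellset: CellMatrixSet, bin_: int, barcodes: Iterable[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Cells x eligible-chromosomes trans contact counts for one query
    bin (the hub-index input and the shuffle-null input)."""
    genome, res = cellset.genome, cellset.resolution
    barcodes = list(barcodes) if barcodes is not None else cellset.barcodes
    rows = [
        _trans_counts_by_chrom(cellset.symmetric(bc).getrow(bin_), bin_, genome, res)
        for bc in barcodes
    ]
    own = genome.bin_chrom_ids(res)[bin_]
    chroms = [
        name for ci, name in enumerate(genome.chrom_names)
        if ci != own and name not in genome.excluded_chroms
    ]
    return np.vstack(rows), chroms


def cell_bin_features(
    cellset: CellMatrixSet,
    bins: Iterable[int],
    barcodes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hub index and trans/cis partner-bin counts per (cell, bin)."""
    genome, res = cellset.genome, cellset.resolution
    bins = list(bins)
    rows = []
    for bc in barcodes if barcodes is not None else cellset.barcodes:
        sym = cellset.symmetric(bc)
        for b in bins:
            tc = _trans_counts_by_chrom(sym.getrow(b), b, genome, res)
            r, n_t, n_c = trans_cis_bin_ratio(sym, b, genome, res)
            rows.append(
                {
                    "barcode": bc,
                    "bin": b,
                    "hub_index": hub_index(tc) if tc.size else float("nan"),
                    "trans_cis_ratio": r,
                    "n_trans_contacts": int(tc.sum()),
                    "n_trans_bins": n_t,
                    "n_cis_bins": n_c,
                }
            )
    return pd.DataFrame(rows)


def build_feature_table(
    cellset: CellMatrixSet,
    cnv_per_cell: Mapping[str, CNVProfile],
    bins: Iterable[int] | None = None,
    barcodes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-(cell, bin) feature triplet for the ecDNA callers.

    One row per requested (cell, bin); undefined hub index / ratio
    propagate as NaN per their contracts.
    """
    barcodes = list(barcodes) if barcodes is not None else cellset.barcodes
    bins = list(bins) if bins is not None else list(range(cellset.n_bins))
    for bc in barcodes:
        prof = cnv_per_cell.get(bc)
        if prof is None:
            raise KeyError(f"no CNV profile for barcode {bc!r}")
        if prof.genome.chrom_names != cellset.genome.chrom_names or (
            prof.resolution != cellset.resolution
        ):
            raise ValueError("CNV profile genome/resolution mismatch with cell set")
    feats = cell_bin_features(cellset, bins, barcodes)
    copies = np.array(
        [cnv_per_cell[bc].inferred_copy[b] for bc, b in zip(feats["barcode"], feats["bin"])]
    )
    feats.insert(2, "inferred_copy", copies)
    return feats
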