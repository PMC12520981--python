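"""Multi-way chromatin contacts and frequency-Z-score hub calling.

A sequencing read (grouped by read ID across its pairwise contacts)
supports a multi-way contact when it touches >= 3 unique 10 kb bins
after per-contact filtering: only trans contacts and cis contacts with
genomic distance > 10 kb are retained, blacklist-overlapping pairs are
removed and only autosomes are considered.  Per cell type, a bin is a
hub when the fraction of cells whose multi-way reads touch it exceeds
the type's background by more than ``z_cutoff`` standard deviations,
with the top-1%-frequency and low-mappability bins excluded from both
background estimation and hub calls.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .genome import Genome
from .pairs import PairsTable

__all__ = ["extract_multiway", "call_hubs", "hub_enrichment"]

RESOLUTION = 10_000


def extract_multiway(
    pairs: PairsTable,
    genome: Genome,
    blacklist: Sequence[tuple[str, int, int]] | None = None,
    resolution: int = RESOLUTION,
    min_bins: int = 3,
    min_cis_distance: int = 10_000,
) -> tuple[sp.csr_matrix, list[str], pd.DataFrame]:
    """Extract multi-way reads and the per-cell bin indicator matrix.

    Returns ``(indicators, barcodes, reads)``: a cells x 10 kb-bins
    binary CSR matrix (1 iff the bin appears in >= 1 qualifying
    multi-way read of that cell), the row barcode order, and a table of
    qualifying reads (barcode, read_id, bins).

    Per-contact filters (trans or cis > *min_cis_distance*; blacklist;
    autosomes) apply before unique bins are counted, so a read whose
    anchors are filtered down to fewer than *min_bins* surviving bins
    does not qualify.
    """
    rec = pairs.records
    if pairs.readid_col not in rec.columns:
        raise ValueError(f"pairs lack the read-ID column {pairs.readid_col!r} "
                         "required for multi-way extraction")
    autosomes = set(genome.autosomes) - set(genome.excluded_chroms)
    keep = rec["chrom1"].isin(autosomes) & rec["chrom2"].isin(autosomes)
    cis = rec["chrom1"].to_numpy() == rec["chrom2"].to_numpy()
    dist = np.abs(rec["pos2"].to_numpy() - rec["pos1"].to_numpy())
    keep &= ~cis | (dist > min_cis_distance)
    if blacklist:
        bad = genome.interval_mask(blacklist, resolution)
        b1 = genome.bin_of(rec["chrom1"], rec["pos1"], resolution)
        b2 = genome.bin_of(rec["chrom2"], rec["pos2"], resolution)
        keep &= ~(bad[b1] | bad[b2])
    sub = rec.loc[keep]
    b1 = genome.bin_of(sub["chrom1"], sub["pos1"], resolution)
    b2 = genome.bin_of(sub["chrom2"], sub["pos2"], resolution)

    long = pd.DataFrame({
        "barcode": np.tile(sub[pairs.barcode_col].to_numpy(), 2),
        "read_id": np.tile(sub[pairs.readid_col].to_numpy(), 2),
        "bin": np.concatenate([b1, b2]),
    }).drop_duplicates()
    nuniq = long.groupby(["barcode", "read_id"], sort=False)["bin"].transform("nunique")
    mw = long.loc[nuniq >= min_bins]

    barcodes = sorted(pairs.barcodes.tolist())
    bc_index = {b: i for i, b in enumerate(barcodes)}
    cell_bins = mw[["barcode", "bin"]].drop_duplicates()
    rows = cell_bins["barcode"].map(bc_index).to_numpy()
    cols = cell_bins["bin"].to_numpy()
    n_bins = genome.n_bins(resolution)
    indicators = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(barcodes), n_bins),
    ).tocsr()
    reads = (
        mw.groupby(["barcode", "read_id"], sort=False)["bin"]
        .agg(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"bin": "bins"})
    )
    return indicators, barcodes, reads


def call_hubs(
    indicators: sp.spmatrix | np.ndarray,
    cell_types: Sequence[str],
    mappability: np.ndarray | None = None,
    z_cutoff: float = 1.96,
    top_freq_fraction: float = 0.01,
    min_mappability: float = 0.8,
) -> pd.DataFrame:
    """Per-(cell type, bin) multi-way hub calls by frequency Z-score.

    For each type, the per-bin frequency f is the fraction of the type's
    cells whose indicator is 1.  Mean and SD are estimated over bins
    excluding the top 1% by frequency (strictly above the nearest-rank
    99th percentile) and bins with mappability < 0.8, so outliers do not
    inflate the background; ``z = (f - mean) / SD`` is then computed for
    every bin.  A hub requires ``z > z_cutoff`` and adequate mappability
    — high frequency alone never disqualifies a bin, it is only held out
    of the background estimate.
    """
    ind = sp.csr_matrix(indicators)
    types = np.asarray(cell_types)
    if ind.shape[0] != len(types):
        raise ValueError("cell_types length != indicator rows")
    n_bins = ind.shape[1]
    mapp = np.ones(n_bins) if mappability is None else np.asarray(mappability, float)
    frames = []
    for t in np.unique(types):
        sel = np.flatnonzero(types == t)
        if len(sel) < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")
        f = np.asarray(ind[sel].mean(axis=0)).ravel()
        # nearest-rank (1 - top_freq_fraction) percentile; exclusion is strict >
        nz = np.sort(f)
        rank = int(np.ceil((1.0 - top_freq_fraction) * n_bins)) - 1
        top_cut = nz[min(max(rank, 0), n_bins - 1)]
        low_mapp = mapp < min_mappability
        excluded = (f > top_cut) | low_mapp  # held out of mean/SD estimation
        est = f[~excluded]
        sd = est.std()
        if sd == 0:
            warnings.warn(f"zero frequency SD for cell type {t!r}; no hubs called")
            z = np.full(n_bins, np.nan)
            hub = np.zeros(n_bins, dtype=bool)
        else:
            z = (f - est.mean()) / sd
            hub = (z > z_cutoff) & ~low_mapp
        frames.append(pd.DataFrame({
            "cell_type": t, "bin": np.arange(n_bins), "frequency": f,
            "z_score": z, "excluded": excluded, "hub": hub,
        }))
    return pd.concat(frames, ignore_index=True)


def hub_enrichment(
    hubs_by_type: Mapping[str, set[int]],
    annotations_by_type: Mapping[str, set[int]],
    universe: Sequence[int],
) -> pd.DataFrame:
    """Fisher's exact enrichment of annotation bins at multi-way hubs.

    For each (hub type A, annotation type B) a 2x2 table of hub/non-hub
    x annotated/not over the bin *universe*; reports the sample log2
    odds ratio (Haldane-Anscombe 0.5 correction when any cell is zero)
    and the Fisher p-value, flagging matched (A == B) comparisons.
    """
    universe = set(universe)
    rows = []
    for a, hubs in hubs_by_type.items():
        h = hubs & universe
        for b, annot in annotations_by_type.items():
            ann = annot & universe
            n11 = len(h & ann)
            n10 = len(h - ann)
            n01 = len(ann - h)
            n00 = len(universe) - n11 - n10 - n01
            table = np.array([[n11, n10], [n01, n00]])
            _, p = stats.fisher_exact(table, alternative="greater")
            t = table + 0.5 if (table == 0).any() else table.astype(float)
            oratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
            rows.append({
                "hub_type": a, "annotation_type": b, "matched": a == b,
                "n_hub_annotated": n11, "odds_ratio": oratio,
                "log2_odds_ratio": float(np.log2(oratio)), "p_value": float(p),
            })
    return pd.DataFrame(rows)
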