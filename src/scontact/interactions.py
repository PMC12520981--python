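"""Downstream analyses of ecDNA candidate loci.

* Copy-number-weighted binomial test for significant trans-interaction
  partners of an amplified locus: under the null, a 500 kb interval's
  share of its chromosome's contacts with the locus equals its share of
  the chromosome's copy number.
* Shuffle null for the hub index: chromosome identities of every trans
  contact are reassigned uniformly per cell, giving a background
  dispersion for evenly-spread contacts at matched depth.
* ecDNA boundary refinement at 10 kb from local interaction profiles.
* Gene classification against refined boundaries and per-gene
  copy-vs-expression Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .features import gini
from .genome import Genome
from .matrices import CNVProfile, symmetrize

__all__ = [
    "significant_trans_partners",
    "shuffle_hub_null",
    "refine_ecdna_boundary",
    "EcDNABoundary",
    "ecdna_genes",
    "copy_expression_correlation",
]


def significant_trans_partners(
    pseudobulk: sp.spmatrix,
    cnv: CNVProfile,
    ecdna_bins: Sequence[int],
    genome: Genome,
    resolution: int,
    alpha: float = 0.05,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Binomial test for intervals preferentially contacting an ecDNA locus.

    For each trans chromosome separately: ``N_i`` contacts between
    interval *i* and the locus, observed frequency ``P_i = N_i / sum_g
    N_g`` and expected frequency ``E_i = CN_i / sum_g CN_g`` from the
    inferred copy profile; the upper-tail p-value is ``P(X >= N_i)``
    with ``X ~ Binomial(sum_g N_g, E_i)``.  Bonferroni correction is
    applied across all tested intervals genome-wide; significance is
    ``p_adj < alpha``.

    Chromosomes with zero total contacts to the locus are skipped with a
    warning; intervals with zero copy but nonzero contacts have their
    expected frequency floored at *eps*.
    """
    ecdna_bins = np.asarray(list(ecdna_bins), dtype=int)
    sym = symmetrize(pseudobulk)
    contact_with_locus = np.asarray(sym[ecdna_bins].sum(axis=0)).ravel()
    chrom_ids = genome.bin_chrom_ids(resolution)
    ecdna_chroms = set(chrom_ids[ecdna_bins])
    copy = np.nan_to_num(cnv.inferred_copy, nan=0.0)

    rows = []
    for ci, chrom in enumerate(genome.chrom_names):
        if ci in ecdna_chroms or chrom in genome.excluded_chroms:
            continue
        sel = np.flatnonzero(chrom_ids == ci)
        n_i = contact_with_locus[sel]
        total = int(n_i.sum())
        if total == 0:
            warnings.warn(f"chromosome {chrom} has no contacts with the locus; skipped")
            continue
        cn = copy[sel]
        cn_sum = cn.sum()
        e_i = cn / cn_sum if cn_sum > 0 else np.full(len(sel), 1.0 / len(sel))
        e_i = np.where((e_i <= 0) & (n_i > 0), eps, e_i)
        # upper tail P(X >= N_i); survival function is P(X > N_i - 1)
        p = stats.binom.sf(n_i - 1, total, np.clip(e_i, 0.0, 1.0))
        p[n_i == 0] = 1.0
        chroms, starts, ends = genome.bin_to_coords(sel, resolution)
        rows.append(pd.DataFrame({
            "chrom": chroms, "start": starts, "end": ends, "bin": sel,
            "n_contacts": n_i.astype(int), "p_obs": n_i / total,
            "inferred_copy": cn, "e_expected": e_i, "p_value": p,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "bin", "n_contacts",
                                     "p_obs", "inferred_copy", "e_expected",
                                     "p_value", "p_adj", "significant"])
    out = pd.concat(rows, ignore_index=True)
    m = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_value"] * m)
    out["significant"] = out["p_adj"] < alpha
    return out


def shuffle_hub_null(
    trans_counts_by_chrom: pd.DataFrame | np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Hub-index shuffle null: chromosome identities of all trans
    contacts are reassigned uniformly per cell.

    *trans_counts_by_chrom* is cells x eligible-chromosomes counts of
    trans contacts from the query bin.  Each shuffle redistributes every
    cell's total uniformly over the eligible chromosomes (a multinomial
    draw, preserving per-cell totals) and recomputes the per-cell hub
    index.  The observed per-cell hub indices are compared with their
    per-cell null means by a one-sided Wilcoxon signed-rank test
    (observed greater).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    counts = np.asarray(trans_counts_by_chrom, dtype=int)
    rng = np.random.default_rng(seed)
    n_cells, n_chrom = counts.shape
    totals = counts.sum(axis=1)
    observed = np.array([gini(c) if c.sum() > 0 else np.nan for c in counts])

    null = np.full((n_shuffles, n_cells), np.nan)
    null_totals = np.empty((n_shuffles, n_cells), dtype=int)
    probs = np.full(n_chrom, 1.0 / n_chrom)
    for s in range(n_shuffles):
        shuffled = rng.multinomial(totals, probs)
        null_totals[s] = shuffled.sum(axis=1)
        for i in range(n_cells):
            if totals[i] > 0:
                null[s, i] = gini(shuffled[i])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_cell_mean = np.nanmean(null, axis=0)
    ok = ~np.isnan(observed) & ~np.isnan(null_cell_mean)
    if ok.sum() >= 10 and np.any(observed[ok] != null_cell_mean[ok]):
        p = stats.wilcoxon(observed[ok], null_cell_mean[ok], alternative="greater").pvalue
    else:
        p = float("nan")
    return {
        "observed": observed,
        "null": null,
        "totals": totals,
        "null_totals": null_totals,
        "observed_median": float(np.nanmedian(observed)) if ok.any() else float("nan"),
        "null_median": float(np.nanmedian(null)),
        "p_value": float(p),
    }


@dataclass
class EcDNABoundary:
    """Refined amplicon interval in 10 kb bin coordinates (half-open,
    relative to the candidate region's global bins)."""

    start_bin: int  # global 10 kb bin
    end_bin: int    # exclusive
    profile: np.ndarray
    smoothed: np.ndarray
    refined: bool   # False when no changepoint cleared the cutoff

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.start_bin, self.end_bin)


def refine_ecdna_boundary(
    pseudobulk_10kb: sp.spmatrix,
    candidate_bins: Sequence[int],
    smooth_window: int = 3,
) -> EcDNABoundary:
    """Refine a 1 Mb ecDNA candidate to 10 kb boundaries.

    The per-bin local interaction profile (contacts among bins of the
    candidate region) is rolling-mean smoothed, first-differenced, and
    thresholded at the mean absolute difference over the region; the
    outermost rising and falling changepoints become the boundaries.
    When no changepoint clears the cutoff the candidate region is
    returned unchanged with ``refined=False``.
    """
    bins = np.asarray(list(candidate_bins), dtype=int)
    sym = symmetrize(pseudobulk_10kb)
    local = np.asarray(sym[np.ix_(bins, bins)].todense())
    profile = local.sum(axis=1).astype(float)
    smoothed = (
        pd.Series(profile).rolling(smooth_window, center=True, min_periods=1)
        .mean().to_numpy()
    )
    diff = np.diff(smoothed)
    cutoff = np.mean(np.abs(diff))
    rising = np.flatnonzero(diff > cutoff)
    falling = np.flatnonzero(diff < -cutoff)
    if rising.size == 0 or falling.size == 0 or cutoff == 0:
        return EcDNABoundary(int(bins[0]), int(bins[-1]) + 1, profile, smoothed, False)

    def run_center(indices: np.ndarray, first: bool) -> int:
        # the centred smoothing window smears a sharp step over a run of
        # consecutive changepoints; the step sits at the run's centre
        breaks = np.flatnonzero(np.diff(indices) > 1)
        if first:
            run = indices[: breaks[0] + 1] if breaks.size else indices
        else:
            run = indices[breaks[-1] + 1 :] if breaks.size else indices
        return int(run[len(run) // 2])

    start = int(bins[run_center(rising, first=True) + 1])
    end = int(bins[run_center(falling, first=False) + 1])
    if end <= start:
        return EcDNABoundary(int(bins[0]), int(bins[-1]) + 1, profile, smoothed, False)
    return EcDNABoundary(start, end, profile, smoothed, True)


def ecdna_genes(
    boundary_a: tuple[str, int, int],
    genes: pd.DataFrame,
    boundary_b: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Classify genes against refined ecDNA intervals.

    *boundary_a* (and optionally *boundary_b*) are ``(chrom, start,
    end)`` genomic intervals; *genes* needs ``chrom, start, end, name``.
    A gene is an ecDNA gene iff its body is strictly contained in the
    interval.  With two intervals, genes in both are ``shared``; genes
    in exactly one are variable, sided 5'/3' by position relative to the
    shared core (the intersection).
    """
    def inside(iv):
        if iv is None:
            return np.zeros(len(genes), dtype=bool)
        c, s, e = iv
        return (
            (genes["chrom"] == c)
            & (genes["start"].to_numpy() >= s)
            & (genes["end"].to_numpy() <= e)
        )

    in_a = inside(boundary_a)
    out = genes.copy()
    if boundary_b is None:
        out["class"] = np.where(in_a, "ecDNA gene", "outside")
        return out
    in_b = inside(boundary_b)
    core_start = max(boundary_a[1], boundary_b[1])
    core_end = min(boundary_a[2], boundary_b[2])
    mid = genes[["start", "end"]].mean(axis=1).to_numpy()
    side = np.where(mid < core_start, "5' variable", "3' variable")
    cls = np.select(
        [in_a & in_b, in_a ^ in_b],
        ["shared", side],
        default="outside",
    )
    out["class"] = cls
    return out


def copy_expression_correlation(
    expression: pd.DataFrame,
    copy_per_cell: pd.DataFrame,
    gene_body_bins: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Per-gene Spearman correlation between expression and gene-body copy.

    *expression* is cells x genes; *copy_per_cell* is cells x 10 kb bins
    of inferred copy number; *gene_body_bins* maps gene name -> the 10 kb
    bins covering its body.  The copy of a gene in a cell is the mean
    inferred copy over its body bins.  Constant vectors give NaN with
    ``defined=False``.
    """
    shared = expression.index.intersection(copy_per_cell.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 matched cells across modalities")
    expr = expression.loc[shared]
    cnv = copy_per_cell.loc[shared]
    rows = []
    for gene, bins in gene_body_bins.items():
        if gene not in expr.columns:
            continue
        gc = cnv.iloc[:, list(bins)].mean(axis=1).to_numpy()
        ge = expr[gene].to_numpy(dtype=float)
        if np.all(gc == gc[0]) or np.all(ge == ge[0]):
            rows.append({"gene": gene, "scc": float("nan"), "p_value": float("nan"),
                         "defined": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(gc, ge)
        rows.append({"gene": gene, "scc": float(rho), "p_value": float(p), "defined": True})
    return pd.DataFrame(rows)
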