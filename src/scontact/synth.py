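"""Seeded synthetic barcoded contact data with planted truth.

The generator emulates droplet single-cell Hi-C libraries: per-cell
contact sets with power-law cis distance decay, a diploid background,
focal amplifications that are either ecDNA-like (amplified, trans
partners spread across chromosomes in proportion to their length,
strong intra-amplicon contacts irrespective of distance) or HSR-like
(amplified, trans contacts concentrated on a small target window,
extra local cis contacts), multi-way walks with planted hub bins, and a
matched negative-binomial expression matrix with copy-number dosage.

Every output is reproducible from the spec's single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Genome
from .pairs import PairsTable

__all__ = [
    "Amplicon",
    "Population",
    "SimSpec",
    "toy_genome",
    "ecdna_vs_hsr_spec",
    "simulate_cells",
    "simulate_multiway",
    "simulate_expression",
]

#: Default toy genome: four chromosomes of unequal length totalling
#: 80 Mb (B = 80 at 1 Mb), so convolutional training runs in seconds
#: while trans-contact mass still scales with chromosome size.
TOY_CHROM_MB = (28, 22, 18, 12)


def toy_genome(chrom_mb: Sequence[int] = TOY_CHROM_MB) -> Genome:
    sizes = {f"chr{i + 1}": mb * 1_000_000 for i, mb in enumerate(chrom_mb)}
    return Genome.from_dict(sizes)


@dataclass(frozen=True)
class Amplicon:
    """A focal amplification carried by every cell of a population."""

    chrom: str
    start: int
    end: int
    copy_number: int
    mode: str  # 'ecDNA' | 'HSR'
    #: HSR trans contacts concentrate on this window (defaults to the
    #: start of the next chromosome).
    target_chrom: str | None = None
    target_start: int = 0
    target_span: int = 5_000_000

    def __post_init__(self):
        if self.mode not in ("ecDNA", "HSR"):
            raise ValueError(f"unknown amplicon mode {self.mode!r}")


@dataclass(frozen=True)
class Population:
    name: str
    n_cells: int
    amplicons: tuple[Amplicon, ...] = ()


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the contact simulator.

    Rates are per-contact probabilities; ``depth`` is the expected
    number of contacts per cell (Poisson unless ``exact_depth``).
    """

    genome: Genome = field(default_factory=toy_genome)
    populations: tuple[Population, ...] = ()
    depth: int = 5000
    exact_depth: bool = False
    decay_exponent: float = 1.0      # cis contact density ~ d^-alpha
    min_cis_distance: int = 500
    trans_rate: float = 0.10         # diploid background
    ecdna_trans_rate: float = 0.35   # evenly dispersed trans partners
    hsr_trans_rate: float = 0.15     # fewer, concentrated trans partners
    hsr_concentration: float = 0.85  # mass on the HSR target window
    amplicon_intra_rate: float = 0.5 # cis contacts landing inside the amplicon
    copy_jitter: bool = True         # per-cell Poisson copy realisation
    seed: int = 0

    def with_seed(self, seed: int) -> "SimSpec":
        return replace(self, seed=seed)


def ecdna_vs_hsr_spec(
    n_cells: int = 500,
    copy_number: int = 20,
    depth: int = 5000,
    seed: int = 0,
    locus: tuple[str, int, int] = ("chr1", 10_000_000, 11_000_000),
) -> SimSpec:
    """Three matched populations — ecDNA, HSR (equal copies, same
    locus, contrasting trans dispersion) and a diploid background."""
    chrom, start, end = locus
    ec = Amplicon(chrom, start, end, copy_number, "ecDNA")
    hsr = Amplicon(chrom, start, end, copy_number, "HSR", target_chrom="chr3")
    return SimSpec(
        populations=(
            Population("ecDNA", n_cells, (ec,)),
            Population("HSR", n_cells, (hsr,)),
            Population("none", n_cells),
        ),
        depth=depth,
        seed=seed,
    )


# ---------------------------------------------------------------------------

def _sample_cis_distance(rng, n, alpha, dmin, dmax):
    dmax = np.maximum(dmax, dmin + 1)
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        return np.exp(np.log(dmin) + u * (np.log(dmax) - np.log(dmin))).astype(np.int64)
    a = 1.0 - alpha
    return ((dmin**a + u * (dmax**a - dmin**a)) ** (1.0 / a)).astype(np.int64)


def _resolve_target(amp: Amplicon, genome: Genome) -> tuple[str, int, int]:
    if amp.target_chrom is not None:
        tchrom = amp.target_chrom
    else:
        others = [c for c in genome.trans_chroms if c != amp.chrom]
        tchrom = others[0]
    tlen = genome.length_of(tchrom)
    start = min(amp.target_start, max(tlen - amp.target_span, 0))
    return tchrom, start, min(start + amp.target_span, tlen)


def simulate_cells(spec: SimSpec) -> tuple[PairsTable, pd.DataFrame]:
    """Simulate barcoded contacts for every population of *spec*.

    Returns the pairs table (upper-triangular normalised, unique read
    IDs, '+' strands) and a truth table with one row per (cell,
    amplicon) — cells without amplicons get a ``mode='none'`` row
    carrying their population and realised copy 2.
    """
    genome = spec.genome
    rng = np.random.default_rng(spec.seed)
    for pop in spec.populations:
        for amp in pop.amplicons:
            if amp.chrom not in genome or amp.end > genome.length_of(amp.chrom):
                raise ValueError(f"amplicon {amp} outside genome")

    chrom_arr = np.array(genome.chrom_names, dtype=object)
    lengths = np.array(genome.chrom_lengths, dtype=np.int64)
    trans_names = list(genome.trans_chroms)

    frames = []
    truth_rows = []
    read_counter = 0
    for pop in spec.populations:
        for ci in range(pop.n_cells):
            bc = f"{pop.name}_{ci:04d}"
            # realised per-cell amplicon copies
            amps = []
            for amp in pop.amplicons:
                copy = (
                    max(2, int(rng.poisson(amp.copy_number)))
                    if spec.copy_jitter
                    else amp.copy_number
                )
                amps.append((amp, copy))
                truth_rows.append({
                    "barcode": bc, "population": pop.name, "mode": amp.mode,
                    "chrom": amp.chrom, "start": amp.start, "end": amp.end,
                    "nominal_copy": amp.copy_number, "realized_copy": copy,
                })
            if not pop.amplicons:
                truth_rows.append({
                    "barcode": bc, "population": pop.name, "mode": "none",
                    "chrom": None, "start": -1, "end": -1,
                    "nominal_copy": 2, "realized_copy": 2,
                })

            n = spec.depth if spec.exact_depth else int(rng.poisson(spec.depth))
            if n == 0:
                continue
            # weighted anchor segments: diploid chromosomes + amplicons
            seg_chrom = list(chrom_arr)
            seg_start = [0] * len(chrom_arr)
            seg_end = list(lengths)
            seg_w = [2.0 * l for l in lengths]
            seg_amp: list[int] = [-1] * len(chrom_arr)
            for ai, (amp, copy) in enumerate(amps):
                seg_chrom.append(amp.chrom)
                seg_start.append(amp.start)
                seg_end.append(amp.end)
                # the amplicon's extra copies on top of the diploid background
                seg_w.append(float((copy - 2) * (amp.end - amp.start)))
                seg_amp.append(ai)
            w = np.array(seg_w)
            seg = rng.choice(len(w), size=n, p=w / w.sum())
            s_start = np.array(seg_start)[seg]
            s_end = np.array(seg_end)[seg]
            pos1 = (s_start + rng.random(n) * (s_end - s_start)).astype(np.int64) + 1
            chrom1 = np.array(seg_chrom, dtype=object)[seg]
            which_amp = np.array(seg_amp)[seg]

            chrom2 = np.empty(n, dtype=object)
            pos2 = np.empty(n, dtype=np.int64)
            u_type = rng.random(n)
            u_mode = rng.random(n)

            # abundance per chromosome (diploid plus amplicon excess), so
            # partner landings scale with local DNA amount
            chrom_weight = {c: 2.0 * genome.length_of(c) for c in genome.chrom_names}
            amp_by_chrom: dict[str, list[tuple[Amplicon, int]]] = {}
            for amp, copy in amps:
                chrom_weight[amp.chrom] += (copy - 2) * (amp.end - amp.start)
                amp_by_chrom.setdefault(amp.chrom, []).append((amp, copy))

            for mask, trans_p, amp_i in _contact_groups(which_amp, amps, spec, u_type):
                idx = np.flatnonzero(mask)
                if idx.size == 0:
                    continue
                is_trans = u_type[idx] < trans_p
                t_idx, c_idx = idx[is_trans], idx[~is_trans]
                amp = amps[amp_i][0] if amp_i >= 0 else None
                if t_idx.size:
                    _fill_trans(rng, t_idx, chrom1, chrom2, pos2, genome,
                                trans_names, chrom_weight, amp_by_chrom, amp, spec,
                                u_mode)
                if c_idx.size:
                    _fill_cis(rng, c_idx, chrom1, pos1, chrom2, pos2, genome,
                              amp, spec, u_mode)

            rid = np.array([f"r{read_counter + k:09d}" for k in range(n)], dtype=object)
            read_counter += n
            frames.append(pd.DataFrame({
                "readID": rid, "chrom1": chrom1, "pos1": pos1,
                "chrom2": chrom2, "pos2": pos2,
                "strand1": "+", "strand2": "+", "barcode": bc,
            }))

    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["readID", "chrom1", "pos1", "chrom2",
                                          "pos2", "strand1", "strand2", "barcode"]))
    chromsizes = dict(zip(genome.chrom_names, genome.chrom_lengths))
    table = PairsTable(records, chromsizes).normalize(genome)
    return table, pd.DataFrame(truth_rows)


def _contact_groups(which_amp, amps, spec, u_type):
    """Yield (mask, trans_rate, amplicon_index) per anchor group."""
    yield which_amp == -1, spec.trans_rate, -1
    for ai, (amp, _copy) in enumerate(amps):
        rate = spec.ecdna_trans_rate if amp.mode == "ecDNA" else spec.hsr_trans_rate
        yield which_amp == ai, rate, ai


def _sample_pos_in_chrom(rng, chrom, n, genome, chrom_weight, amp_by_chrom):
    """Positions within a chromosome, abundance-weighted: amplicon
    segments attract landings in proportion to their extra copies."""
    length = genome.length_of(chrom)
    pos = (rng.random(n) * length).astype(np.int64) + 1
    total_w = chrom_weight[chrom]
    u = rng.random(n)
    acc = 0.0
    for amp, copy in amp_by_chrom.get(chrom, ()):
        excess = (copy - 2) * (amp.end - amp.start) / total_w
        hit = (u >= acc) & (u < acc + excess)
        pos[hit] = (amp.start + rng.random(hit.sum()) * (amp.end - amp.start)).astype(np.int64) + 1
        acc += excess
    return pos


def _fill_trans(rng, idx, chrom1, chrom2, pos2, genome, trans_names,
                chrom_weight, amp_by_chrom, amp, spec, u_mode):
    if amp is not None and amp.mode == "HSR":
        tchrom, tstart, tend = _resolve_target(amp, genome)
        conc = u_mode[idx] < spec.hsr_concentration
        cidx = idx[conc]
        chrom2[cidx] = tchrom
        pos2[cidx] = (tstart + rng.random(cidx.size) * (tend - tstart)).astype(np.int64) + 1
        idx = idx[~conc]
    # abundance-weighted chromosome choice among chromosomes != anchor
    for c1 in np.unique(chrom1[idx]) if idx.size else []:
        sel = idx[chrom1[idx] == c1]
        others = [c for c in trans_names if c != c1]
        w = np.array([chrom_weight[c] for c in others], dtype=float)
        pick = rng.choice(len(others), size=sel.size, p=w / w.sum())
        oc = np.array(others, dtype=object)[pick]
        chrom2[sel] = oc
        for c in np.unique(oc):
            csel = sel[oc == c]
            pos2[csel] = _sample_pos_in_chrom(rng, c, csel.size, genome,
                                              chrom_weight, amp_by_chrom)


def _fill_cis(rng, idx, chrom1, pos1, chrom2, pos2, genome, amp, spec, u_mode):
    chrom2[idx] = chrom1[idx]
    if amp is not None:
        # intra-amplicon contacts irrespective of distance: a circular
        # ecDNA's cis-mapped contacts are ligations within the circle
        # itself, so all of them stay inside the amplicon; an HSR tandem
        # array keeps genuine flanking cis contacts as well
        intra_rate = 1.0 if amp.mode == "ecDNA" else spec.amplicon_intra_rate
        intra = u_mode[idx] < intra_rate
        aidx = idx[intra]
        pos2[aidx] = (amp.start + rng.random(aidx.size) * (amp.end - amp.start)).astype(np.int64) + 1
        idx = idx[~intra]
    if idx.size == 0:
        return
    clen = np.array([genome.length_of(c) for c in chrom1[idx]], dtype=np.int64)
    d = _sample_cis_distance(rng, idx.size, spec.decay_exponent,
                             spec.min_cis_distance, clen)
    sign = rng.choice([-1, 1], size=idx.size)
    p2 = pos1[idx] + sign * d
    # reflect at the ends so partners stay on-chromosome
    p2 = np.where(p2 < 1, pos1[idx] + d, p2)
    p2 = np.where(p2 > clen, pos1[idx] - d, p2)
    pos2[idx] = np.clip(p2, 1, clen)


# ---------------------------------------------------------------------------
# multi-way walks

def simulate_multiway(
    genome: Genome,
    cell_types: Mapping[str, int],
    hub_bins: Mapping[str, Sequence[int]],
    p_hub: float = 0.5,
    background_walks: int = 20,
    walk_anchors: int = 3,
    pair_reads: int = 50,
    resolution: int = 10_000,
    seed: int = 0,
) -> tuple[PairsTable, pd.DataFrame]:
    """Simulate walk-aware pairs with planted multi-way hub bins.

    Each cell of type *t* participates in a multi-way walk through each
    planted hub bin of *t* with probability *p_hub*; *background_walks*
    random walks and *pair_reads* plain two-anchor reads per cell form
    the background.  Returns the pairs table and a truth table of
    (cell_type, bin) planted hubs.
    """
    rng = np.random.default_rng(seed)
    n_bins = genome.n_bins(resolution)
    chroms_all, starts_all, _ = genome.bin_to_coords(np.arange(n_bins), resolution)
    eligible = np.flatnonzero(
        np.isin(chroms_all, list(set(genome.autosomes) - set(genome.excluded_chroms)))
    )

    def bin_pos(b):
        return chroms_all[b], int(starts_all[b]) + int(rng.integers(1, resolution // 2))

    rows = []
    rid = 0

    def emit_walk(bc, anchors):
        nonlocal rid
        rid += 1
        name = f"w{rid:08d}"
        for a, b in zip(anchors[:-1], anchors[1:]):
            c1, p1 = bin_pos(a)
            c2, p2 = bin_pos(b)
            rows.append((name, c1, p1, c2, p2, "+", "+", bc))

    truth = []
    for t, n_cells in cell_types.items():
        planted = np.asarray(list(hub_bins.get(t, ())), dtype=int)
        truth.extend({"cell_type": t, "bin": int(b)} for b in planted)
        for ci in range(n_cells):
            bc = f"{t}_{ci:04d}"
            for b in planted:
                if rng.random() < p_hub:
                    partners = rng.choice(eligible, size=walk_anchors - 1, replace=False)
                    emit_walk(bc, [b, *partners])
            for _ in range(background_walks):
                anchors = rng.choice(eligible, size=walk_anchors, replace=False)
                emit_walk(bc, list(anchors))
            for _ in range(pair_reads):
                a, b = rng.choice(eligible, size=2, replace=False)
                emit_walk(bc, [a, b])

    records = pd.DataFrame(
        rows, columns=["readID", "chrom1", "pos1", "chrom2", "pos2",
                       "strand1", "strand2", "barcode"],
    )
    chromsizes = dict(zip(genome.chrom_names, genome.chrom_lengths))
    return PairsTable(records, chromsizes).normalize(genome), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# matched expression

def simulate_expression(
    truth: pd.DataFrame,
    gene_names: Sequence[str],
    state_gene_sets: Mapping[str, Sequence[str]] | None = None,
    cell_states: Mapping[str, str] | None = None,
    state_effect: float = 1.0,
    dosage_genes: Sequence[str] | None = None,
    dosage_slope: float = 1.0,
    base_mean: float = 5.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial cells x genes counts matched to a contact truth
    table.

    State signature genes are shifted ``2**state_effect``-fold in cells
    of their state; *dosage_genes* scale linearly with the cell's
    realised amplicon copy (slope 1 = proportional dosage).
    """
    rng = np.random.default_rng(seed)
    cells = truth["barcode"].unique()
    copy_by_cell = truth.set_index("barcode")["realized_copy"].to_dict()
    genes = list(gene_names)
    base = base_mean * rng.lognormal(0.0, 0.5, size=len(genes))
    mean = np.tile(base, (len(cells), 1))

    if state_gene_sets and cell_states:
        gidx = {g: j for j, g in enumerate(genes)}
        for i, bc in enumerate(cells):
            st = cell_states.get(bc)
            if st and st in state_gene_sets:
                cols = [gidx[g] for g in state_gene_sets[st] if g in gidx]
                mean[i, cols] *= 2.0**state_effect
    if dosage_genes:
        cols = [j for j, g in enumerate(genes) if g in set(dosage_genes)]
        for i, bc in enumerate(cells):
            ratio = copy_by_cell.get(bc, 2) / 2.0
            mean[i, cols] *= 1.0 + dosage_slope * (ratio - 1.0)

    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    return pd.DataFrame(counts, index=pd.Index(cells, name="barcode"), columns=genes)
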