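"""Genome model: ordered chromosomes, binning schemes and interval masks.

A :class:`Genome` is an ordered collection of chromosomes with lengths.
Binning at a resolution ``r`` uses 0-based half-open bins of width ``r``;
the *global* bin index concatenates per-chromosome bins in chromosome
order, so a genome binned at 1 Mb has ``sum(ceil(L_c / r))`` global bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genome",
    "HG38_CHROM_SIZES",
    "read_chrom_sizes",
    "read_bed",
]

# GRCh38 primary assembly chromosome lengths (bp).
HG38_CHROM_SIZES: dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
    "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
    "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
    "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
    "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
    "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
    "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}

_SEX_CHROM_NAMES = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class Genome:
    """Ordered chromosomes with lengths and a global binning scheme.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers in genome order.
    chrom_lengths
        Length in bp per chromosome, same order as ``chrom_names``.
    excluded_chroms
        Chromosomes dropped from trans statistics (hub index, shuffle
        nulls).  Defaults to the Y chromosome when present.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    excluded_chroms: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.excluded_chroms is None:
            default = frozenset(c for c in self.chrom_names if c in {"chrY", "Y"})
            object.__setattr__(self, "excluded_chroms", default)
        else:
            object.__setattr__(self, "excluded_chroms", frozenset(self.excluded_chroms))

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int], **kwargs) -> "Genome":
        return cls(tuple(sizes), tuple(sizes.values()), **kwargs)

    @classmethod
    def hg38(cls, include_y: bool = False) -> "Genome":
        """hg38 with chr1..chr22, chrX (and optionally chrY)."""
        sizes = dict(HG38_CHROM_SIZES)
        if not include_y:
            sizes.pop("chrY")
        return cls.from_dict(sizes)

    # -- basic lookups ---------------------------------------------------

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_index

    @property
    def chrom_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chrom_names)}

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_index[chrom]]

    @property
    def trans_chroms(self) -> tuple[str, ...]:
        """Chromosomes participating in trans statistics."""
        return tuple(c for c in self.chrom_names if c not in self.excluded_chroms)

    @property
    def autosomes(self) -> tuple[str, ...]:
        auto = tuple(c for c in self.chrom_names if c not in _SEX_CHROM_NAMES)
        # Synthetic genomes may not follow chrX/chrY naming; treat every
        # chromosome as autosomal if none match the convention.
        return auto if auto else self.chrom_names

    # -- binning ---------------------------------------------------------

    def n_bins_per_chrom(self, resolution: int) -> np.ndarray:
        if resolution <= 0:
            raise ValueError("resolution must be > 0")
        return np.array(
            [math.ceil(l / resolution) for l in self.chrom_lengths], dtype=np.int64
        )

    def bin_offsets(self, resolution: int) -> np.ndarray:
        """Global index of the first bin of each chromosome (plus a final sentinel)."""
        return np.concatenate([[0], np.cumsum(self.n_bins_per_chrom(resolution))])

    def n_bins(self, resolution: int) -> int:
        return int(self.bin_offsets(resolution)[-1])

    def bin_chrom_ids(self, resolution: int) -> np.ndarray:
        """Per global bin, the integer chromosome index."""
        return np.repeat(
            np.arange(self.n_chroms), self.n_bins_per_chrom(resolution)
        )

    def bin_of(self, chrom: Iterable[str] | str, pos, resolution: int):
        """Global bin index of 1-based positions (pairs convention)."""
        offsets = self.bin_offsets(resolution)
        cidx = self.chrom_index
        if isinstance(chrom, str):
            return int(offsets[cidx[chrom]] + (int(pos) - 1) // resolution)
        ci = np.array([cidx[c] for c in chrom], dtype=np.int64)
        return offsets[ci] + (np.asarray(pos, dtype=np.int64) - 1) // resolution

    def bin_to_coords(self, bins, resolution: int):
        """(chrom, start, end) of global bins; 0-based half-open intervals."""
        bins = np.atleast_1d(np.asarray(bins, dtype=np.int64))
        offsets = self.bin_offsets(resolution)
        ci = np.searchsorted(offsets, bins, side="right") - 1
        start = (bins - offsets[ci]) * resolution
        chroms = np.array(self.chrom_names, dtype=object)[ci]
        lengths = np.array(self.chrom_lengths)[ci]
        end = np.minimum(start + resolution, lengths)
        return chroms, start, end

    def bins_in_region(self, chrom: str, start: int, end: int, resolution: int) -> np.ndarray:
        """Global bins overlapping a 0-based half-open region."""
        off = self.bin_offsets(resolution)[self.chrom_index[chrom]]
        first = start // resolution
        last = math.ceil(end / resolution)
        nmax = self.n_bins_per_chrom(resolution)[self.chrom_index[chrom]]
        return off + np.arange(max(first, 0), min(last, nmax), dtype=np.int64)

    def interval_mask(
        self, intervals: Sequence[tuple[str, int, int]], resolution: int
    ) -> np.ndarray:
        """Boolean mask over global bins: True where a bin overlaps any interval."""
        mask = np.zeros(self.n_bins(resolution), dtype=bool)
        for chrom, start, end in intervals:
            if chrom in self:
                mask[self.bins_in_region(chrom, start, end, resolution)] = True
        return mask

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, l in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{c}\t{l}\n")


def read_chrom_sizes(path: str | Path, **kwargs) -> Genome:
    """Read a two-column ``chrom<TAB>length`` table into a Genome."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"no chromosomes found in {path}")
    return Genome.from_dict(sizes, **kwargs)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3(+) intervals (0-based half-open), e.g. a blacklist."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
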