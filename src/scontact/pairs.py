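"""Barcoded pairs I/O, contact classification and per-cell QC.

Contacts are exchanged in the 4DN ``.pairs`` text dialect (optionally
gzipped) extended with a cell-barcode column and, for multi-way walks, a
read-ID column.  Positions are 1-based; records are normalised to the
upper triangle of the genome ordering, i.e. ``(chrom1, pos1) <=
(chrom2, pos2)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .genome import Genome

__all__ = [
    "PairsTable",
    "read_pairs",
    "write_pairs",
    "classify_contacts",
    "qc_cells",
    "CIS_SHORT",
    "CIS_LONG",
    "TRANS",
]

CIS_SHORT = "cis_short"
CIS_LONG = "cis_long"
TRANS = "trans"

#: Canonical column order for the extended pairs dialect.
CORE_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


@dataclass
class PairsTable:
    """Barcoded contact records plus the header chromosome sizes.

    ``records`` is a DataFrame with at least ``chrom1, pos1, chrom2,
    pos2`` and a barcode column; ``readID`` is optional and groups
    multi-way walks.
    """

    records: pd.DataFrame
    chromsizes: dict[str, int]
    barcode_col: str = "barcode"
    readid_col: str = "readID"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        missing = {c for c in ("chrom1", "pos1", "chrom2", "pos2", self.barcode_col)} - set(
            self.records.columns
        )
        if missing:
            raise ValueError(f"pairs records missing columns: {sorted(missing)}")
        unknown = (
            set(self.records["chrom1"].unique()) | set(self.records["chrom2"].unique())
        ) - set(self.chromsizes)
        if unknown:
            raise ValueError(f"records reference chromosomes absent from header: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barcodes(self) -> np.ndarray:
        return self.records[self.barcode_col].unique()

    def normalize(self, genome: Genome) -> "PairsTable":
        """Return a copy with records flipped to the upper triangle."""
        rec = self.records.copy()
        order = genome.chrom_index
        c1 = rec["chrom1"].map(order).to_numpy()
        c2 = rec["chrom2"].map(order).to_numpy()
        flip = (c1 > c2) | (
            (c1 == c2) & (rec["pos1"].to_numpy() > rec["pos2"].to_numpy())
        )
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            if a in rec.columns and b in rec.columns:
                va, vb = rec[a].to_numpy().copy(), rec[b].to_numpy().copy()
                rec.loc[flip, a] = vb[flip]
                rec.loc[flip, b] = va[flip]
        return PairsTable(rec, dict(self.chromsizes), self.barcode_col, self.readid_col)


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pairs(
    path: str | Path,
    genome: Genome | None = None,
    barcode_col: str = "barcode",
    readid_col: str = "readID",
    strict_chroms: bool = False,
) -> PairsTable:
    """Read an extended 4DN pairs file.

    Header lines start with ``#``; the ``#columns:`` line must declare
    ``chrom1 pos1 chrom2 pos2`` and the barcode column.  When *genome* is
    given, records on chromosomes outside it are skipped and counted
    (``n_skipped``), or rejected when ``strict_chroms`` is set.
    """
    chromsizes: dict[str, int] = {}
    columns: list[str] | None = None
    with _open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            if line.startswith("#chromsize:"):
                _, chrom, size = line.split()
                chromsizes[chrom] = int(size)
            elif line.startswith("#columns:"):
                columns = line.split()[1:]
    if columns is None:
        raise ValueError(f"{path}: missing #columns: declaration")
    if barcode_col not in columns:
        raise ValueError(
            f"{path}: pairs file lacks the required barcode column {barcode_col!r} "
            f"(declared columns: {columns})"
        )
    for c in ("chrom1", "pos1", "chrom2", "pos2"):
        if c not in columns:
            raise ValueError(f"{path}: pairs file lacks required column {c!r}")

    rec = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=columns,
        header=None,
        dtype={"chrom1": str, "chrom2": str, barcode_col: str},
    )
    n_skipped = 0
    if genome is not None:
        known = set(genome.chrom_names)
        keep = rec["chrom1"].isin(known) & rec["chrom2"].isin(known)
        n_skipped = int((~keep).sum())
        if n_skipped and strict_chroms:
            bad = sorted(
                (set(rec.loc[~keep, "chrom1"]) | set(rec.loc[~keep, "chrom2"])) - known
            )
            raise ValueError(f"{path}: records on chromosomes absent from genome: {bad}")
        rec = rec.loc[keep].reset_index(drop=True)
        chromsizes = {c: genome.length_of(c) for c in genome.chrom_names}
    return PairsTable(rec, chromsizes, barcode_col, readid_col, n_skipped=n_skipped)


def write_pairs(table: PairsTable, path: str | Path) -> None:
    """Write an extended 4DN pairs file (gzipped if *path* ends in .gz)."""
    cols = [c for c in CORE_COLUMNS if c in table.records.columns]
    extra = [c for c in table.records.columns if c not in cols]
    cols = cols + extra
    with _open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        for chrom, size in table.chromsizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: " + " ".join(cols) + "\n")
        table.records[cols].to_csv(fh, sep="\t", header=False, index=False)


def classify_contacts(
    records: pd.DataFrame | PairsTable, cis_long_bp: int = 1000
) -> pd.Series:
    """Classify each record as cis_short, cis_long (distance strictly
    greater than *cis_long_bp*) or trans."""
    rec = records.records if isinstance(records, PairsTable) else records
    cis = rec["chrom1"].to_numpy() == rec["chrom2"].to_numpy()
    dist = np.abs(rec["pos2"].to_numpy() - rec["pos1"].to_numpy())
    out = np.where(cis, np.where(dist > cis_long_bp, CIS_LONG, CIS_SHORT), TRANS)
    return pd.Series(pd.Categorical(out, categories=[CIS_SHORT, CIS_LONG, TRANS]),
                     index=rec.index, name="contact_class")


def qc_cells(
    table: PairsTable, min_pairs: int = 1000, cis_long_bp: int = 1000
) -> pd.DataFrame:
    """Per-barcode contact-class counts and a strict pass flag.

    A cell passes QC when its total number of contacts is strictly
    greater than *min_pairs*.
    """
    rec = table.records
    cols = ["barcode", "cis_short", "cis_long", "trans", "total_pairs", "pass_qc"]
    if rec.empty:
        return pd.DataFrame(columns=cols)
    cls = classify_contacts(rec, cis_long_bp=cis_long_bp)
    counts = (
        pd.crosstab(rec[table.barcode_col], cls)
        .reindex(columns=[CIS_SHORT, CIS_LONG, TRANS], fill_value=0)
        .rename_axis(index="barcode")
        .reset_index()
    )
    counts.columns.name = None
    counts["total_pairs"] = counts[[CIS_SHORT, CIS_LONG, TRANS]].sum(axis=1)
    counts["pass_qc"] = counts["total_pairs"] > min_pairs
    return counts[cols]
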