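"""Shared fixtures: a toy genome and a small simulated cohort reused
across the unit-test modules."""

import numpy as np
import pandas as pd
import pytest

import scontact as sc


@pytest.fixture(scope="session")
def genome():
    return sc.toy_genome()


@pytest.fixture(scope="session")
def sim_small():
    """30 cells per population (ecDNA / HSR / none) at modest depth."""
    spec = sc.ecdna_vs_hsr_spec(n_cells=30, depth=3000, seed=11)
    table, truth = sc.simulate_cells(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def cellset_small(sim_small):
    spec, table, _ = sim_small
    return sc.bin_contacts(table, spec.genome, 1_000_000)


@pytest.fixture(scope="session")
def cnv_small(cellset_small):
    g = cellset_small.genome
    return {
        bc: sc.infer_cnv(cellset_small.anchor_coverage(bc), g, 1_000_000)
        for bc in cellset_small.barcodes
    }


@pytest.fixture(scope="session")
def locus_bins(genome):
    """Global 1 Mb bins of the planted amplicon locus."""
    return genome.bins_in_region("chr1", 10_000_000, 11_000_000, 1_000_000)


def make_pairs(records, genome, **kwargs):
    """Build a PairsTable from (chrom1, pos1, chrom2, pos2, barcode[, readID])
    tuples."""
    rows = []
    for i, r in enumerate(records):
        rid = r[5] if len(r) > 5 else f"r{i:04d}"
        rows.append({
            "readID": rid, "chrom1": r[0], "pos1": r[1], "chrom2": r[2],
            "pos2": r[3], "strand1": "+", "strand2": "+", "barcode": r[4],
        })
    cols = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2",
            "barcode"]
    df = pd.DataFrame(rows, columns=cols) if not rows else pd.DataFrame(rows)
    chromsizes = dict(zip(genome.chrom_names, genome.chrom_lengths))
    return sc.PairsTable(df, chromsizes, **kwargs)
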