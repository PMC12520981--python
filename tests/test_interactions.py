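import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import scontact as sc
from scontact.interactions import EcDNABoundary, refine_ecdna_boundary
from scontact.matrices import CNVProfile


def binom_upper_tail(k, n, p):
    """Oracle: exact upper-tail P(X >= k) by direct enumeration."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


RES = 500_000


def build_pseudobulk(genome, locus_contacts, res=RES):
    """Upper-triangular pseudo-bulk with given contact counts between the
    locus bin (chr1 first bin) and every other global bin."""
    n = genome.n_bins(res)
    m = sp.lil_matrix((n, n), dtype=np.int64)
    for b, c in locus_contacts.items():
        lo, hi = min(0, b), max(0, b)
        m[lo, hi] = c
    return m.tocsr()


def uniform_cnv(genome, res=RES, copy=None):
    n = genome.n_bins(res)
    ratio = np.ones(n) if copy is None else np.asarray(copy, float) / 2.0
    return CNVProfile(genome, res, ratio, np.zeros(n, bool), "pseudobulk")


class TestSignificantTransPartners:
    def test_matches_enumeration_oracle(self, genome):
        # chr2 holds 20 locus contacts; each 500 kb interval has uniform
        # expected share, one interval gets 5 of them
        chr2_bins = genome.bins_in_region("chr2", 0, genome.length_of("chr2"), RES)
        contacts = {int(chr2_bins[0]): 5}
        for b in chr2_bins[1:16]:
            contacts[int(b)] = 1
        bulk = build_pseudobulk(genome, contacts)
        out = sc.significant_trans_partners(bulk, uniform_cnv(genome), [0],
                                            genome, RES)
        chr2 = out[out["chrom"] == "chr2"].set_index("bin")
        total = int(chr2["n_contacts"].sum())
        e = chr2.loc[chr2_bins[0], "e_expected"]
        expected_p = binom_upper_tail(5, total, e)
        assert chr2.loc[chr2_bins[0], "p_value"] == pytest.approx(
            expected_p, rel=1e-12)
        # spot-check the spec's magnitude: N=5 of 20 at E=0.05
        assert binom_upper_tail(5, 20, 0.05) == pytest.approx(2.57e-3, rel=0.01)

    def test_zero_contacts_gives_p_one(self, genome):
        chr2_bins = genome.bins_in_region("chr2", 0, genome.length_of("chr2"), RES)
        bulk = build_pseudobulk(genome, {int(chr2_bins[0]): 10})
        out = sc.significant_trans_partners(bulk, uniform_cnv(genome), [0],
                                            genome, RES)
        zero = out[(out["chrom"] == "chr2") & (out["n_contacts"] == 0)]
        assert (zero["p_value"] == 1.0).all()

    def test_copy_proportional_null_yields_no_significance(self, genome):
        # contacts distributed exactly proportional to copy number
        n = genome.n_bins(RES)
        copy = np.full(n, 2.0)
        chr2_bins = genome.bins_in_region("chr2", 0, genome.length_of("chr2"), RES)
        copy[chr2_bins[:5]] = 8.0
        weights = copy[chr2_bins] / copy[chr2_bins].sum()
        contacts = {int(b): int(round(w * 1000))
                    for b, w in zip(chr2_bins, weights)}
        bulk = build_pseudobulk(genome, contacts)
        out = sc.significant_trans_partners(
            bulk, uniform_cnv(genome, copy=copy), [0], genome, RES)
        assert not out["significant"].any()

    def test_bonferroni_uses_emitted_row_count(self, genome):
        chr2_bins = genome.bins_in_region("chr2", 0, genome.length_of("chr2"), RES)
        bulk = build_pseudobulk(genome, {int(b): 2 for b in chr2_bins[:10]})
        out = sc.significant_trans_partners(bulk, uniform_cnv(genome), [0],
                                            genome, RES)
        m = len(out)
        np.testing.assert_allclose(out["p_adj"],
                                   np.minimum(1.0, out["p_value"] * m))

    def test_own_chromosome_and_zero_chroms_skipped(self, genome):
        chr2_bins = genome.bins_in_region("chr2", 0, genome.length_of("chr2"), RES)
        bulk = build_pseudobulk(genome, {int(chr2_bins[0]): 4})
        with pytest.warns(UserWarning):
            out = sc.significant_trans_partners(bulk, uniform_cnv(genome), [0],
                                                genome, RES)
        assert set(out["chrom"]) == {"chr2"}  # chr3/chr4 have no contacts


class TestShuffleHubNull:
    def test_uniform_contacts_match_null(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(200, np.ones(23) / 23, size=40)
        out = sc.shuffle_hub_null(counts, n_shuffles=30, seed=1)
        assert out["p_value"] > 0.05

    def test_point_mass_exceeds_null(self):
        counts = np.zeros((40, 23), dtype=int)
        counts[:, 2] = 100  # all trans contacts on one of 23 chromosomes
        out = sc.shuffle_hub_null(counts, n_shuffles=30, seed=1)
        assert np.allclose(out["observed"], 22 / 23)
        assert out["observed_median"] > out["null_median"]
        assert out["p_value"] < 0.01

    def test_same_seed_identical_null(self):
        counts = np.random.default_rng(3).poisson(5, size=(20, 10))
        a = sc.shuffle_hub_null(counts, n_shuffles=20, seed=9)
        b = sc.shuffle_hub_null(counts, n_shuffles=20, seed=9)
        np.testing.assert_array_equal(a["null"], b["null"])

    def test_shuffles_preserve_per_cell_totals(self):
        counts = np.random.default_rng(4).poisson(8, size=(15, 6))
        out = sc.shuffle_hub_null(counts, n_shuffles=25, seed=2)
        np.testing.assert_array_equal(
            out["null_totals"], np.tile(out["totals"], (25, 1)))

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            sc.shuffle_hub_null(np.ones((5, 4), int), n_shuffles=0)


def step_matrix(n_bins, inside, rate_in, rate_out, rng=None):
    """Upper-triangular local matrix with an enriched diagonal block."""
    m = np.full((n_bins, n_bins), float(rate_out))
    lo, hi = inside
    m[lo:hi, lo:hi] = rate_in
    m = np.triu(m)
    if rng is not None:
        m = rng.poisson(m).astype(float)
    return sp.csr_matrix(m)


class TestBoundaryRefinement:
    def test_noise_free_step_recovered_exactly(self):
        m = step_matrix(100, (10, 60), 10.0, 1.0)
        b = refine_ecdna_boundary(m, range(100))
        assert b.refined
        assert (b.start_bin, b.end_bin) == (10, 60)

    def test_flat_profile_flagged_unchanged(self):
        m = step_matrix(100, (0, 100), 2.0, 2.0)
        b = refine_ecdna_boundary(m, range(100))
        assert not b.refined
        assert (b.start_bin, b.end_bin) == (0, 100)

    def test_poisson_noise_snr5_jaccard(self):
        # SNR 5: inside rate 5x the outside rate, 20 seeds
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = step_matrix(100, (10, 60), 25.0, 5.0, rng=rng)
            b = refine_ecdna_boundary(m, range(100))
            truth = set(range(10, 60))
            got = set(range(b.start_bin, b.end_bin))
            scores.append(len(truth & got) / len(truth | got))
        assert np.mean(scores) >= 0.8


class TestEcdnaGenes:
    genes = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "start": [100, 2000, 5200, 9000],
        "end": [900, 2900, 5900, 9900],
        "name": ["gA", "gB", "gC", "gD"],
    })

    def test_single_interval_strict_containment(self):
        out = sc.ecdna_genes(("chr1", 0, 3000), self.genes)
        assert out.set_index("name")["class"].to_dict() == {
            "gA": "ecDNA gene", "gB": "ecDNA gene",
            "gC": "outside", "gD": "outside"}

    def test_straddling_gene_excluded(self):
        out = sc.ecdna_genes(("chr1", 0, 2500), self.genes)
        assert out.set_index("name")["class"]["gB"] == "outside"

    def test_two_intervals_shared_and_sided_variable(self):
        # A = [1500, 6000), B = [0, 10000): core = [1500, 6000)
        out = sc.ecdna_genes(("chr1", 1500, 6000), self.genes,
                             boundary_b=("chr1", 0, 10_000))
        cls = out.set_index("name")["class"].to_dict()
        assert cls["gB"] == "shared" and cls["gC"] == "shared"
        assert cls["gA"] == "5' variable"
        assert cls["gD"] == "3' variable"


class TestCopyExpressionCorrelation:
    def _inputs(self, n=200, seed=0, coupled=True):
        rng = np.random.default_rng(seed)
        cells = [f"c{i}" for i in range(n)]
        copy = pd.DataFrame(rng.poisson(10, size=(n, 5)) + 1.0, index=cells)
        if coupled:
            expr = pd.DataFrame({"g1": 3.0 * copy.iloc[:, :3].mean(axis=1)},
                                index=cells)
        else:
            expr = pd.DataFrame({"g1": rng.normal(size=n)}, index=cells)
        return expr, copy

    def test_proportional_expression_gives_scc_one(self):
        expr, copy = self._inputs()
        out = sc.copy_expression_correlation(expr, copy, {"g1": [0, 1, 2]})
        assert out.iloc[0]["scc"] == pytest.approx(1.0)

    def test_independent_modalities_near_zero(self):
        hits = 0
        for seed in range(20):
            expr, copy = self._inputs(seed=seed, coupled=False)
            out = sc.copy_expression_correlation(expr, copy, {"g1": [0, 1]})
            hits += abs(out.iloc[0]["scc"]) < 0.2
        assert hits >= 19

    def test_constant_copy_undefined(self):
        expr, copy = self._inputs()
        copy.iloc[:, :] = 4.0
        out = sc.copy_expression_correlation(expr, copy, {"g1": [0]})
        assert not out.iloc[0]["defined"]
        assert np.isnan(out.iloc[0]["scc"])
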