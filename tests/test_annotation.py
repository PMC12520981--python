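import numpy as np
import pandas as pd
import pytest

import scontact as sc
from scontact.annotation import STATES

from conftest import make_pairs


class TestGadScores:
    def test_counts_contacts_anchored_in_gene_body(self, genome):
        # 7 contacts with >= 1 anchor in the gene body, 1 with none
        res = 10_000
        recs = [("chr1", 15_000, "chr2", 1, "A")] * 4
        recs += [("chr3", 1, "chr1", 12_000, "A")] * 3
        recs += [("chr4", 1, "chr4", 500_000, "A")]
        t = make_pairs(recs, genome)
        cs = sc.bin_contacts(t.normalize(genome), genome, res)
        body = genome.bins_in_region("chr1", 10_000, 20_000, res)
        out = sc.gad_scores(cs, {"geneX": body})
        assert out.loc["A", "geneX"] == 7

    def test_gene_without_contacts_scores_zero(self, genome):
        t = make_pairs([("chr1", 1, "chr2", 1, "A")], genome)
        cs = sc.bin_contacts(t, genome, 10_000)
        body = genome.bins_in_region("chr4", 0, 50_000, 10_000)
        out = sc.gad_scores(cs, {"g": body})
        assert out.loc["A", "g"] == 0

    def test_doubling_contacts_doubles_scores(self, genome):
        recs = [("chr1", 15_000, "chr2", 1, "A"), ("chr1", 1, "chr1", 11_000, "A")]
        single = sc.bin_contacts(make_pairs(recs, genome), genome, 10_000)
        double = sc.bin_contacts(
            make_pairs(recs + [(c1, p1, c2, p2, "B") for c1, p1, c2, p2, _ in recs],
                       genome), genome, 10_000)
        body = genome.bins_in_region("chr1", 10_000, 20_000, 10_000)
        s = sc.gad_scores(single, {"g": body})
        d = sc.gad_scores(double, {"g": body})
        assert d.loc["B", "g"] == s.loc["A", "g"]

    def test_intra_gene_contact_counts_once(self, genome):
        t = make_pairs([("chr1", 11_000, "chr1", 15_000, "A")], genome)
        cs = sc.bin_contacts(t, genome, 10_000)
        body = genome.bins_in_region("chr1", 10_000, 20_000, 10_000)
        assert sc.gad_scores(cs, {"g": body}).loc["A", "g"] == 1


class TestTransferLabels:
    def test_unanimous_neighbors_score_one(self):
        ref = np.array([[0.0], [0.1], [0.2]])
        out = sc.transfer_labels(np.array([[0.05]]), ref, ["T", "T", "T"], k=3)
        assert out.loc[0, "label"] == "T"
        assert out.loc[0, "label_score"] == pytest.approx(1.0)

    def test_equidistant_neighbors_share_equally(self):
        ref = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        out = sc.transfer_labels(np.zeros((1, 2)), ref, list("abcd"), k=4)
        np.testing.assert_allclose(out.loc[0, "neighbor_score"], 0.25)

    def test_scores_sum_to_one_and_decrease_with_distance(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(50, 3))
        out = sc.transfer_labels(rng.normal(size=(10, 3)), ref, ["x"] * 50, k=15)
        for _, row in out.iterrows():
            assert np.sum(row["neighbor_score"]) == pytest.approx(1.0)
            order = np.argsort(row["neighbor_dist"])
            assert np.all(np.diff(np.asarray(row["neighbor_score"])[order]) <= 1e-12)

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(1)
        ref = np.vstack([rng.normal(0, 1, (200, 4)), rng.normal(12, 1, (200, 4))])
        labels = ["a"] * 200 + ["b"] * 200
        query = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(12, 1, (100, 4))])
        truth = ["a"] * 100 + ["b"] * 100
        out = sc.transfer_labels(query, ref, labels, k=15)
        assert np.mean(out["label"] == truth) >= 0.99

    def test_k_exceeding_reference_rejected(self):
        with pytest.raises(ValueError):
            sc.transfer_labels(np.zeros((1, 2)), np.zeros((5, 2)), ["x"] * 5, k=10)


class TestOverlapCoefficients:
    def test_identical_partitions_have_unit_diagonal(self):
        part = {"x": set(range(10)), "y": set(range(10, 20))}
        out = sc.overlap_coefficients(part, part, part)
        assert out.loc["x", "x"] == 1.0 and out.loc["y", "y"] == 1.0
        assert out.loc["x", "y"] == 0.0

    def test_disjoint_clusters_zero(self):
        a = {"x": {1, 2}}
        b = {"y": {3, 4}}
        out = sc.overlap_coefficients(a, b, {"c": {1, 2}, "d": {3, 4}})
        assert out.loc["x", "y"] == 0.0

    def test_random_clusters_low_off_diagonal(self):
        rng = np.random.default_rng(2)
        cells = np.arange(1000)
        types = {f"t{i}": set(cells[i * 100:(i + 1) * 100]) for i in range(10)}
        shuffled = rng.permutation(cells)
        clusters = {f"c{i}": set(shuffled[i * 100:(i + 1) * 100]) for i in range(10)}
        out = sc.overlap_coefficients(types, types, clusters)
        off = out.to_numpy()[~np.eye(10, dtype=bool)]
        assert off.mean() < 0.3


def constant_expression(n_cells=60, n_genes=600, seed=0):
    """All genes share one per-cell profile: any control set matches."""
    rng = np.random.default_rng(seed)
    base = rng.normal(1.0, 0.2, size=n_cells)
    expr = pd.DataFrame(np.tile(base[:, None], (1, n_genes)),
                        index=[f"c{i}" for i in range(n_cells)],
                        columns=[f"g{i}" for i in range(n_genes)])
    return expr


class TestStateScores:
    def test_signature_identical_to_background_scores_zero(self):
        expr = constant_expression()
        out = sc.state_scores(expr, {"S": [f"g{i}" for i in range(10)]}, seed=1)
        np.testing.assert_allclose(out["S"], 0.0, atol=1e-12)

    def test_uniform_shift_of_signature_scores_one(self):
        expr = constant_expression()
        sig = [f"g{i}" for i in range(10)]
        expr[sig] += 1.0
        out = sc.state_scores(expr, {"S": sig}, seed=1)
        np.testing.assert_allclose(out["S"], 1.0, atol=1e-12)

    def test_missing_genes_warn_and_drop(self):
        expr = constant_expression()
        with pytest.warns(UserWarning, match="absent"):
            out = sc.state_scores(expr, {"S": ["g0", "nope"]}, seed=0)
        assert np.isfinite(out["S"]).all()

    def test_seeded_control_sampling_reproducible(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.lognormal(size=(40, 300)),
                            columns=[f"g{i}" for i in range(300)])
        sets = {"S": [f"g{i}" for i in range(0, 30, 3)]}
        a = sc.state_scores(expr, sets, seed=5)
        b = sc.state_scores(expr, sets, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_state_cells_score_highest(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(400)]
        sets = {s: genes[i * 25:(i + 1) * 25] for i, s in enumerate(STATES)}
        expr = pd.DataFrame(rng.lognormal(0, 0.3, size=(200, 400)), columns=genes)
        planted = np.repeat(list(STATES), 50)
        for i, s in enumerate(planted):
            expr.loc[expr.index[i], sets[s]] *= 4.0
        out = sc.state_scores(expr, sets, seed=6)
        best = out.idxmax(axis=1)
        assert np.mean(best.to_numpy() == planted) >= 0.95


class TestStateProjection:
    def _scores(self, opc, npc, ac, mes):
        return pd.DataFrame([[opc, npc, ac, mes]], columns=list(STATES))

    def test_progenitor_quadrant_and_differential(self):
        out = sc.state_projection(self._scores(1.0, 0.5, 0.2, 0.1))
        row = out.iloc[0]
        assert row["D"] == pytest.approx(0.8)
        assert row["quadrant"] == "OPC"
        assert row["identity"] == pytest.approx(np.log2(1.5))

    def test_tied_pair_identity_zero(self):
        out = sc.state_projection(self._scores(0.7, 0.7, 0.1, 0.0))
        assert out.iloc[0]["identity"] == 0.0

    def test_identity_magnitude_formula(self):
        out = sc.state_projection(self._scores(0.5, 0.3, 0.0, 0.0))
        assert abs(out.iloc[0]["identity"]) == pytest.approx(np.log2(1.2))

    def test_differentiated_pair_signed_toward_ac(self):
        out = sc.state_projection(self._scores(0.0, 0.0, 0.2, 0.9))
        row = out.iloc[0]
        assert row["D"] < 0 and row["quadrant"] == "MES"
        assert row["identity"] < 0  # MES side is negative


class TestHicStateScores:
    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(0)
        d = rng.dirichlet(np.ones(15), size=20)
        scs = rng.normal(size=(20, 15, 4))
        out = sc.hic_state_scores(d, scs)
        assert np.all(out <= scs.max(axis=1) + 1e-12)
        assert np.all(out >= scs.min(axis=1) - 1e-12)

    def test_constant_neighbors_give_their_value(self):
        d = np.full((3, 15), 1 / 15)
        scs = np.full((3, 15, 4), 0.7)
        np.testing.assert_allclose(sc.hic_state_scores(d, scs), 0.7)

    def test_degenerate_weight_selects_single_neighbor(self):
        d = np.zeros((1, 15))
        d[0, 4] = 1.0
        scs = np.arange(60, dtype=float).reshape(1, 15, 4)
        np.testing.assert_allclose(sc.hic_state_scores(d, scs)[0], scs[0, 4])
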