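"""Query preparation, WTCS/NCS/tau scoring, aggregation and touchstone search."""

import numpy as np
import pandas as pd
import pytest

import neurocmap as nc
from neurocmap.connectivity import (
    QuerySignature,
    enrichment_score,
    normalize_scores,
    prepare_query_from_degs,
    query_from_signature,
    summarize_median_tau,
    tau,
    touchstone_similarity,
    wtcs,
)
from oracles import tau_oracle, wtcs_oracle


def _degs(lfcs, sig=0.001):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(len(lfcs))],
            "log2_fold_change": lfcs,
            "significance": sig,
        }
    )


class TestQueryPreparation:
    def test_paper_scale_sizes(self, rng):
        degs = _degs(rng.normal(size=800))
        q = prepare_query_from_degs(degs, n_up=137, n_down=150)
        assert (len(q.up), len(q.down)) == (137, 150)
        assert not set(q.up) & set(q.down)

    def test_only_positive_lfc_errors(self):
        degs = _degs([0.5, 1.0, 2.0] * 10)
        with pytest.raises(ValueError, match="up|down|surviv"):
            prepare_query_from_degs(degs, n_up=5, n_down=5)

    def test_toy_sort_order(self):
        degs = _degs([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        q = prepare_query_from_degs(degs, n_up=2, n_down=2, min_genes=1)
        assert q.up == ("G0", "G1")
        assert q.down == ("G5", "G4")

    def test_significance_filter_applied(self):
        degs = _degs([3.0, 2.0, -3.0, -2.0])
        degs.loc[0, "significance"] = 0.5
        q = prepare_query_from_degs(
            degs, n_up=2, n_down=2, min_genes=1, significance_threshold=0.01
        )
        assert q.up == ("G1",)

    def test_panel_intersection_drops_absent_genes(self):
        degs = _degs([3.0, 2.0, -3.0, -2.0])
        q = prepare_query_from_degs(
            degs, n_up=2, n_down=2, min_genes=1, panel_genes=["G0", "G2"]
        )
        assert q.up == ("G0",) and q.down == ("G2",)

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            QuerySignature(up=("A", "B"), down=("B", "C"))


def _signature(zs, genes=None):
    genes = genes or [f"g{i}" for i in range(len(zs))]
    return pd.Series(np.asarray(zs, dtype=float), index=genes)


class TestWtcs:
    def test_extreme_query_is_positive_and_maximal(self, rng):
        sig = _signature(np.sort(rng.normal(size=50))[::-1])
        q = QuerySignature(up=tuple(sig.index[:5]), down=tuple(sig.index[-5:]))
        best = wtcs(q, sig)
        assert best > 0
        for _ in range(50):
            genes = rng.permutation(sig.index.to_numpy())
            rand_q = QuerySignature(up=tuple(genes[:5]), down=tuple(genes[5:10]))
            assert wtcs(rand_q, sig) <= best + 1e-12

    def test_swapping_lists_negates(self, rng):
        sig = _signature(rng.normal(size=40))
        genes = rng.permutation(sig.index.to_numpy())
        q = QuerySignature(up=tuple(genes[:6]), down=tuple(genes[6:12]))
        assert wtcs(q.swapped(), sig) == pytest.approx(-wtcs(q, sig))

    def test_running_sum_matches_hand_oracle(self):
        sig = _signature(np.arange(9, -1, -1.0))
        q = QuerySignature(up=("g0", "g1"), down=("g8", "g9"))
        expected = wtcs_oracle(q.up, q.down, dict(sig.items()))
        got = wtcs(q, sig)
        assert got == pytest.approx(expected)
        # by hand: ES_up = 1.0 (after both top hits), ES_down = -1.0
        assert got == pytest.approx(1.0)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(30):
            sig = _signature(rng.normal(size=25))
            genes = rng.permutation(sig.index.to_numpy())
            q = QuerySignature(up=tuple(genes[:4]), down=tuple(genes[4:8]))
            assert wtcs(q, sig) == pytest.approx(
                wtcs_oracle(q.up, q.down, dict(sig.items()))
            )

    def test_empty_intersection_is_nan(self, rng):
        sig = _signature(rng.normal(size=10))
        q = QuerySignature(up=("absent1",), down=("absent2",))
        assert np.isnan(wtcs(q, sig))


class TestNormalizeAndTau:
    def test_equal_scores_normalize_to_one(self):
        s = pd.Series([0.3, 0.3, 0.3], index=list("abc"))
        g = pd.Series(["x"] * 3, index=s.index)
        assert normalize_scores(s, g).tolist() == [1.0, 1.0, 1.0]

    def test_mean_normalization(self):
        s = pd.Series([0.2, 0.4], index=list("ab"))
        g = pd.Series(["x", "x"], index=s.index)
        out = normalize_scores(s, g)
        np.testing.assert_allclose(out.to_numpy(), [2 / 3, 4 / 3])

    def test_singleton_group_preserves_sign(self):
        s = pd.Series([-0.7], index=["a"])
        out = normalize_scores(s, pd.Series(["x"], index=["a"]))
        assert out["a"] == -1.0

    def test_tau_boundaries(self):
        ref = [0.1, 0.2, 0.3, 0.4]
        assert tau(0.5, ref) == 100.0
        assert tau(-0.5, ref) == -100.0
        assert tau(0.0, ref) == 0.0
        assert tau(0.25, ref) == 50.0
        assert tau_oracle(0.25, ref) == 50.0

    def test_tau_empty_touchstone_errors(self):
        with pytest.raises(ValueError, match="empty touchstone"):
            tau(0.5, [])

    def test_tau_invariant_under_monotone_rescaling(self, rng):
        ref = rng.normal(size=50)
        q = 0.37
        t1 = tau(q, ref)
        t2 = tau(np.sinh(q * 3), np.sinh(ref * 3))  # odd, monotone in |.|
        assert t1 == pytest.approx(t2)
        for _ in range(20):
            v = float(rng.normal())
            assert tau(v, ref) == pytest.approx(tau_oracle(v, list(ref)))


class TestSummaries:
    def _results(self, rows):
        df = pd.DataFrame(
            rows, columns=["pert_id", "pert_type", "cell_id", "ncs", "tau"]
        )
        df["query_id"] = "q"
        return df

    def test_single_cell_line_median_is_identity(self):
        r = self._results([("A", "CP", "c1", 1.0, 42.0)])
        out = summarize_median_tau(r).summary
        assert out.iloc[0]["median_tau"] == 42.0

    def test_odd_count_median(self):
        r = self._results(
            [("A", "CP", c, 1.0, t) for c, t in [("c1", -10), ("c2", 0), ("c3", 30)]]
        )
        assert summarize_median_tau(r).summary.iloc[0]["median_tau"] == 0.0

    def test_even_count_median_midpoint(self):
        r = self._results([("A", "CP", "c1", 1.0, -40.0), ("A", "CP", "c2", 1.0, 10.0)])
        assert summarize_median_tau(r).summary.iloc[0]["median_tau"] == -15.0

    def test_strongest_signature_represents_cell_line(self):
        r = self._results(
            [("A", "CP", "c1", 0.5, 20.0), ("A", "CP", "c1", 2.0, 80.0)]
        )
        assert summarize_median_tau(r).summary.iloc[0]["median_tau"] == 80.0


def _collection(rng, n_genes=60, n_perts=20, n_cells=2):
    genes = [f"g{i}" for i in range(n_genes)]
    cols, meta = {}, []
    for c in range(n_cells):
        for p in range(n_perts):
            sid = f"P{p:02d}:c{c}"
            cols[sid] = rng.normal(size=n_genes)
            meta.append((sid, f"P{p:02d}", "CP", f"c{c}", "1 uM", "24 h"))
    values = pd.DataFrame(cols, index=genes)
    col_meta = pd.DataFrame(
        meta,
        columns=["signature_id", "pert_id", "pert_type", "cell_id", "pert_dose", "pert_time"],
    ).set_index("signature_id")
    return nc.ExpressionMatrix(values=values, col_meta=col_meta, level=5)


class TestQueryEngine:
    def test_antisymmetry_end_to_end(self, rng):
        ref = _collection(rng)
        genes = ref.values.index.to_numpy()
        q = QuerySignature(up=tuple(genes[:10]), down=tuple(genes[10:20]))
        r1 = nc.run_query(q, ref)
        r2 = nc.run_query(q.swapped(), ref)
        np.testing.assert_allclose(r1["wtcs"], -r2["wtcs"], atol=1e-12)
        np.testing.assert_allclose(r1["ncs"], -r2["ncs"], atol=1e-12)
        np.testing.assert_allclose(r1["tau"], -r2["tau"], atol=1e-12)

    def test_self_recall_over_random_collections(self, rng):
        wins = 0
        for trial in range(20):
            ref = _collection(np.random.default_rng(1000 + trial), n_cells=1)
            target = ref.values.columns[int(rng.integers(0, ref.n_samples))]
            q = query_from_signature(ref.values[target], n_up=10, n_down=10)
            res = nc.run_query(q, ref)
            best = res["wtcs"].idxmax()
            wins += best == target
        assert wins == 20

    def test_null_median_tau_centered(self, rng):
        ref = _collection(np.random.default_rng(7), n_perts=25, n_cells=2)
        medians = []
        for _ in range(100):
            genes = rng.permutation(ref.values.index.to_numpy())
            q = QuerySignature(up=tuple(genes[:10]), down=tuple(genes[10:20]))
            res = nc.run_query(q, ref)
            medians.append(summarize_median_tau(res).summary["median_tau"].median())
        assert abs(np.mean(medians)) < 10


class TestTouchstoneSimilarity:
    def test_self_ranks_first(self, rng):
        ref = _collection(rng, n_cells=1)
        ranked = touchstone_similarity(ref, "P03", cell_id="c0")
        assert ranked.iloc[0]["pert_id"] == "P03"
        assert ranked.iloc[0]["score"] == ranked["score"].max()

    def test_identical_signatures_tie_broken_lexicographically(self, rng):
        ref = _collection(rng, n_cells=1, n_perts=12)
        v = ref.values
        v["PAA:c0"] = v["P05:c0"]  # exact duplicate under a new pert id
        meta = ref.col_meta.copy()
        meta.loc["PAA:c0"] = ["PAA", "CP", "c0", "1 uM", "24 h"]
        dup = nc.ExpressionMatrix(values=v, col_meta=meta, level=5)
        ranked = touchstone_similarity(dup, "P05", cell_id="c0")
        top2 = list(ranked.head(2)["pert_id"])
        assert set(top2) == {"P05", "PAA"}
        assert top2 == sorted(top2)

    def test_missing_selection_errors(self, rng):
        ref = _collection(rng)
        with pytest.raises(ValueError, match="no signature matches"):
            touchstone_similarity(ref, "NOPE")

    def test_planted_kd_in_top_decile(self):
        truth = nc.simulate_screen(
            nc.ScreenConfig(n_cell_lines=1, n_compounds=4, n_genes=80,
                            invariant_per_level=2, n_replicates=1,
                            vehicle_wells_per_plate=2),
            seed=3,
        ).truth
        cpd = truth.active_compounds()[0]
        sigs, meta = nc.simulate_touchstone(
            truth, n_reference_perts=40, planted_pert=cpd, seed=5
        )
        ref = nc.ExpressionMatrix(values=sigs, col_meta=meta, level=5)
        ranked = touchstone_similarity(ref, cpd, cell_id="TCL1")
        kd_rank = ranked.index.get_loc(
            ranked.index[ranked["pert_id"] == "KD_SHARED"][0]
        )
        pos = int(ranked[ranked["pert_id"] == "KD_SHARED"]["rank"].iloc[0])
        assert pos <= max(2, len(ranked) // 10)

    def test_correlation_method_self_first(self, rng):
        ref = _collection(rng, n_cells=1)
        ranked = touchstone_similarity(ref, "P07", method="correlation")
        assert ranked.iloc[0]["pert_id"] == "P07"
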