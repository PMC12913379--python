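"""Five-level plate processing: bead medians, ladder calibration, quantile
normalization, robust z-scores, weighted replicate collapse."""

import numpy as np
import pandas as pd
import pytest

import neurocmap as nc
from neurocmap.core import ExpressionMatrix
from neurocmap.levels import (
    default_invariant_reference,
    invariant_normalize,
    level1_to_level2,
    quantile_normalize,
    robust_zscore,
    collapse_replicates,
)
from oracles import median_oracle, quantile_normalize_oracle, robust_z_oracle


def _panel(n_ordinary=2, invariant_levels=0, per_level=1):
    rows = []
    for i in range(n_ordinary):
        rows.append(("G%d" % (i + 1), "G%d" % (i + 1), "B%03d" % (i + 1), 0, "t"))
    k = n_ordinary
    for lv in range(1, invariant_levels + 1):
        for j in range(per_level):
            k += 1
            rows.append((f"I{lv}_{j}", f"I{lv}_{j}", "B%03d" % k, lv, "t"))
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_symbol", "bead_barcode", "invariant_level", "panel"]
    )


def _beads(rows):
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "bead_barcode", "fluorescence_intensity"]
    )


class TestLevel2:
    @pytest.mark.parametrize(
        "fis, expected",
        [([500.0], 500.0), ([100.0, 300.0, 200.0], 200.0), ([10.0, 20.0, 30.0, 40.0], 25.0)],
    )
    def test_median_of_beads(self, fis, expected):
        beads = _beads([("P1", "A01", "B001", fi) for fi in fis])
        m = level1_to_level2(beads, _panel(1))
        assert m.values.loc["G1", "P1:A01"] == expected
        assert median_oracle(fis) == expected

    def test_missing_gene_gives_missing_value(self):
        beads = _beads([("P1", "A01", "B001", 5.0)])
        m = level1_to_level2(beads, _panel(2))
        assert np.isnan(m.values.loc["G2", "P1:A01"])

    def test_unknown_barcode_is_named_in_error(self):
        beads = _beads([("P1", "A01", "B999", 5.0)])
        with pytest.raises(ValueError, match="B999"):
            level1_to_level2(beads, _panel(1))

    def test_invariant_to_bead_order(self, rng):
        rows = [
            ("P1", "A01", f"B{(i % 2) + 1:03d}", float(v))
            for i, v in enumerate(rng.integers(1, 1000, size=40))
        ]
        beads = _beads(rows)
        shuffled = beads.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = level1_to_level2(beads, _panel(2)).values
        b = level1_to_level2(shuffled, _panel(2)).values
        pd.testing.assert_frame_equal(a, b)


def _ladder_matrix(distort=lambda x: x, gene_values=(100.0, 5000.0)):
    """One well holding the full 10-level ladder plus two ordinary genes."""
    panel = _panel(n_ordinary=len(gene_values), invariant_levels=10, per_level=3)
    ref = default_invariant_reference()
    vals = list(gene_values) + [ref[lv] for lv in panel["invariant_level"] if lv > 0]
    vals = [distort(v) for v in vals]
    values = pd.DataFrame({"P1:A01": vals}, index=panel["gene_id"])
    row_meta = panel.set_index("gene_id")
    return ExpressionMatrix(values=values, row_meta=row_meta, level=2), panel


class TestInvariantCalibration:
    def test_identity_when_ladder_already_canonical(self):
        m, _ = _ladder_matrix()
        out = invariant_normalize(m)
        np.testing.assert_allclose(
            np.log2(out.matrix.values.to_numpy() + 1),
            np.log2(m.values.to_numpy() + 1),
            atol=1e-9,
        )
        assert out.well_qc["passed"].all()

    def test_doubling_distortion_recovered_within_1pct(self):
        m, _ = _ladder_matrix(distort=lambda v: 2.0 * v)
        out = invariant_normalize(m)
        for g, truth in (("G1", 100.0), ("G2", 5000.0)):
            got = out.matrix.values.loc[g, "P1:A01"]
            assert abs(got - truth) / truth < 0.01

    def test_extrapolation_below_lowest_node_is_linear(self):
        # value below the lowest ladder median follows the two lowest
        # calibration nodes (4-level ladder: interpolation only, no smooth)
        ref = default_invariant_reference(n_levels=4)
        panel = _panel(n_ordinary=1, invariant_levels=4, per_level=3)
        vals = [10.0 * 2.0] + [2.0 * ref[lv] for lv in panel["invariant_level"] if lv > 0]
        values = pd.DataFrame({"P1:A01": vals}, index=panel["gene_id"])
        m = ExpressionMatrix(values=values, row_meta=panel.set_index("gene_id"), level=2)
        out = invariant_normalize(m, reference=ref)
        obs = np.log2(2.0 * ref.to_numpy() + 1)
        canon = np.log2(ref.to_numpy() + 1)
        slope = (canon[1] - canon[0]) / (obs[1] - obs[0])
        x = np.log2(10.0 * 2.0 + 1)
        expected = 2 ** (canon[0] + (x - obs[0]) * slope) - 1
        assert out.matrix.values.loc["G1", "P1:A01"] == pytest.approx(expected, rel=1e-9)

    def test_non_monotone_medians_isotonic_adjusted(self, caplog):
        ref = default_invariant_reference()

        def scramble(v):
            # swap levels 3 and 4 of the ladder
            if v == ref[3]:
                return ref[4]
            if v == ref[4]:
                return ref[3]
            return v

        m, _ = _ladder_matrix(distort=scramble)
        out = invariant_normalize(m)
        assert out.well_qc["isotonic_adjusted"].iloc[0]
        assert out.well_qc["passed"].iloc[0]

    def test_too_few_levels_flags_failed_well(self):
        panel = _panel(n_ordinary=1, invariant_levels=1, per_level=2)
        values = pd.DataFrame({"P1:A01": [50.0, 64.0, 64.0]}, index=panel["gene_id"])
        m = ExpressionMatrix(values=values, row_meta=panel.set_index("gene_id"), level=2)
        out = invariant_normalize(
            m, reference=pd.Series([64.0], index=pd.Index([1], name="level"))
        )
        assert not out.well_qc["passed"].iloc[0]
        # failed wells are left unchanged
        assert out.matrix.values.loc["G1", "P1:A01"] == 50.0


def _mk(values, plate="P1"):
    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"G{i}" for i in range(len(values))],
        columns=[f"S{j}" for j in range(len(values[0]))],
    )
    cm = pd.DataFrame({"plate_id": [plate] * values.shape[1]}, index=values.columns)
    return ExpressionMatrix(values=values, col_meta=cm, level=2)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = _mk([[1, 1], [3, 3], [2, 2]])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_two_columns_mean_of_sorted(self):
        # columns [1,3] and [2,4] -> both become [1.5, 3.5] in rank order
        m = _mk([[1, 2], [3, 4]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_sorted_values_identical_across_columns(self, rng):
        m = _mk(rng.normal(size=(30, 6)))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            block = rng.integers(0, 8, size=(12, 4)).astype(float)  # many ties
            m = _mk(block)
            out = quantile_normalize(m).values.to_numpy()
            np.testing.assert_allclose(out, quantile_normalize_oracle(block), atol=1e-12)

    def test_single_well_plate_warns_unchanged(self):
        m = _mk([[1.0], [5.0]])
        with pytest.warns(UserWarning, match="single well"):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestRobustZ:
    def test_constant_row_is_zero(self):
        z = robust_zscore(_mk([[5, 5, 5, 5]]))
        np.testing.assert_array_equal(z.values.to_numpy(), [[0, 0, 0, 0]])

    def test_outlier_value(self):
        z = robust_zscore(_mk([[1, 2, 3, 4, 100]]))
        # median 3, MAD 1 -> z(100) = 97 / 1.4826
        assert z.values.iloc[0, 4] == pytest.approx(97 / 1.4826)
        assert z.values.iloc[0, 4] == pytest.approx(65.4256, abs=1e-3)

    def test_median_sample_gets_zero(self, rng):
        row = rng.normal(size=(1, 7))
        z = robust_zscore(_mk(row)).values.to_numpy()[0]
        med_pos = np.argsort(row[0])[3]
        assert z[med_pos] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            block = rng.normal(size=(8, 5))
            z = robust_zscore(_mk(block)).values.to_numpy()
            np.testing.assert_allclose(z, robust_z_oracle(block), atol=1e-10)

    def test_scale_equivariance(self, rng):
        block = rng.normal(size=(6, 5))
        z1 = robust_zscore(_mk(block)).values.to_numpy()
        z2 = robust_zscore(_mk(3.0 * block + 7.0)).values.to_numpy()
        np.testing.assert_allclose(z1, z2, atol=1e-9)
        z3 = robust_zscore(_mk(-2.0 * block)).values.to_numpy()
        np.testing.assert_allclose(z3, -z1, atol=1e-9)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="robust reference"):
            robust_zscore(_mk([[1, 2]]))


class TestCollapse:
    def test_identical_replicates_pass_through(self, rng):
        col = rng.normal(size=20)
        z = pd.DataFrame({"r1": col, "r2": col, "r3": col})
        sig, w = collapse_replicates(z)
        np.testing.assert_allclose(sig.to_numpy(), col)
        np.testing.assert_allclose(w.to_numpy(), [1 / 3] * 3)

    def test_two_replicates_arithmetic_mean(self, rng):
        z = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        sig, w = collapse_replicates(z)
        np.testing.assert_allclose(sig.to_numpy(), z.mean(axis=1).to_numpy())
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5])

    def test_single_replicate_identity(self, rng):
        z = pd.DataFrame({"only": rng.normal(size=10)})
        sig, w = collapse_replicates(z)
        np.testing.assert_array_equal(sig.to_numpy(), z["only"].to_numpy())

    def test_anticorrelated_outlier_downweighted(self, rng):
        base = rng.normal(size=50)
        z = pd.DataFrame(
            {
                "r1": base + 0.1 * rng.normal(size=50),
                "r2": base + 0.1 * rng.normal(size=50),
                "bad": -0.3 * base + 0.5 * rng.normal(size=50),
            }
        )
        _, w = collapse_replicates(z)
        assert w["bad"] == w.min()
        assert w["bad"] < w["r1"] and w["bad"] < w["r2"]

    def test_convex_combination_bounds(self, rng):
        z = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        sig, w = collapse_replicates(z)
        assert (w > 0).all()
        lo = z.min(axis=1) - 1e-12
        hi = z.max(axis=1) + 1e-12
        assert ((sig >= lo) & (sig <= hi)).all()
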