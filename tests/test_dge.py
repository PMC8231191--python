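"""Single-replicate DE stage: filtering, normalization, robust z, p-values, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uranet import dge
from uranet.dge import (EmptyUniverseError, InsufficientBackgroundError,
                        MAD_SCALE, bh_adjust, call_degs, filter_by_cpm,
                        log_normalize_vs_panel_mean, p_values_from_z,
                        robust_z_scores)


def frame(rows, genes=None, conds=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    conds = conds or [f"c{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=conds)


class TestFilterByCpm:
    def test_mean_threshold_is_strict(self, small_matrix):
        out = filter_by_cpm(small_matrix, 1.0)
        assert list(out.index) == ["GA", "GC", "GD"]  # GB mean 0.5 dropped
        assert list(out.columns) == list(small_matrix.columns)

    def test_gene_at_exactly_threshold_is_removed(self):
        out = filter_by_cpm(frame([[1.0, 1.0], [2.0, 2.0]]), 1.0)
        assert list(out.index) == ["g1"]

    def test_threshold_zero_is_identity_on_positive_matrix(self, small_matrix):
        pd.testing.assert_frame_equal(filter_by_cpm(small_matrix, 0.0),
                                      small_matrix)

    def test_negative_threshold_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            filter_by_cpm(small_matrix, -1.0)


class TestLogNormalize:
    def test_hand_worked_row(self):
        # CPM [1,1,1,7] + pseudocount 1 -> log2 [1,1,1,3], mean 1.5
        out = log_normalize_vs_panel_mean(frame([[1, 1, 1, 7]]))
        np.testing.assert_allclose(out.to_numpy()[0],
                                   [-0.5, -0.5, -0.5, 1.5])

    def test_constant_row_maps_to_zero(self):
        out = log_normalize_vs_panel_mean(frame([[3, 3, 3, 3]]))
        np.testing.assert_array_equal(out.to_numpy(), 0.0)

    def test_row_means_are_zero_by_construction(self):
        rng = np.random.default_rng(0)
        out = log_normalize_vs_panel_mean(frame(rng.uniform(0, 50, (30, 8))))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)


class TestRobustZ:
    def test_outlier_row_hand_value(self):
        z = robust_z_scores(frame([[1, 2, 3, 4, 10]]))
        # median 3, MAD 1: the outlier condition scores 7 / 1.4826
        np.testing.assert_allclose(z.iloc[0, 4], 7.0 / MAD_SCALE, rtol=1e-12)
        np.testing.assert_allclose(z.iloc[0, :4] * MAD_SCALE, [-2, -1, 0, 1],
                                   rtol=1e-12)

    def test_symmetric_three_point_row(self):
        z = robust_z_scores(frame([[-1, 0, 1]]))
        np.testing.assert_allclose(z.to_numpy()[0],
                                   np.array([-1, 0, 1]) / MAD_SCALE, rtol=1e-12)

    def test_constant_row_scores_zero(self):
        z = robust_z_scores(frame([[5, 5, 5, 5]]))
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_mad_zero_falls_back_to_sd_scale(self):
        # majority ties make MAD 0 while the SD is finite
        row = [2.0, 2.0, 2.0, 2.0, 6.0]
        z = robust_z_scores(frame([row]))
        sd = np.std(row, ddof=1)
        np.testing.assert_allclose(z.iloc[0, 4], 4.0 / sd, rtol=1e-12)

    def test_requires_three_conditions(self):
        with pytest.raises(InsufficientBackgroundError):
            robust_z_scores(frame([[1, 2]]))

    # grid-valued rows keep median/MAD arithmetic exact in floating point
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-2000, 2000).map(lambda i: i / 100),
                    min_size=5, max_size=12),
           st.integers(-10000, 10000).map(lambda i: i / 100),
           st.integers(1, 5000).map(lambda i: i / 100))
    def test_shift_invariance_and_scale_equivariance(self, row, shift, scale):
        base = robust_z_scores(frame([row])).to_numpy()
        shifted = robust_z_scores(frame([np.asarray(row) + shift])).to_numpy()
        np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-9)
        scaled = robust_z_scores(frame([np.asarray(row) * scale])).to_numpy()
        np.testing.assert_allclose(scaled, base, rtol=1e-9, atol=1e-9)

    def test_outlier_resistance_vs_mean_sd_zscore(self):
        # one runaway value: the bulk keeps fixed scores while the outlier's
        # robust z grows without bound -- a mean/SD z saturates near sqrt(n)
        bulk = [1.0, 2.0] * 4  # MAD 0.5 regardless of the outlier
        previous = 0.0
        for outlier in (10.0, 1e3, 1e6):
            row = np.array(bulk + [outlier])
            z = robust_z_scores(frame([row])).to_numpy()[0]
            np.testing.assert_allclose(
                z[:8], robust_z_scores(frame([bulk + [20.0]])).to_numpy()[0][:8])
            assert z[8] > previous and z[8] > outlier / 10
            previous = z[8]
            classic = (row - row.mean()) / row.std(ddof=1)
            assert classic[8] < 3.1

    def test_identical_bulk_falls_back_to_bounded_sd_score(self):
        # with n-1 identical values the MAD is 0, so the SD fallback applies
        # and the outlier's score saturates instead of growing
        z3 = robust_z_scores(frame([[1.0] * 9 + [1e3]])).to_numpy()[0]
        z6 = robust_z_scores(frame([[1.0] * 9 + [1e6]])).to_numpy()[0]
        assert z3[9] == pytest.approx(z6[9], rel=1e-6)  # saturated
        assert np.all(z3[:9] == z3[0])


class TestPValues:
    def test_zero_z_gives_p_one_and_symmetry(self):
        assert p_values_from_z(np.array([0.0])) == pytest.approx(1.0)
        z = np.linspace(-4, 4, 17)
        np.testing.assert_allclose(p_values_from_z(z), p_values_from_z(-z))

    def test_normal_quantile_identity(self):
        assert p_values_from_z(np.array([1.959964]))[0] == pytest.approx(
            0.05, rel=1e-5)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            p_values_from_z(np.array([np.nan]))


class TestBHAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant_vectors_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_against_independent_step_up_oracle(self):
        def step_up(p):
            p = np.asarray(p)
            order = np.argsort(p, kind="mergesort")
            m = len(p)
            adj = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = adj
            return out

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), step_up(p), rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_bounded_between_raw_p_and_one(self, p):
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCallDegs:
    def test_one_record_per_drug_gene_pair(self, small_matrix):
        out = call_degs(small_matrix, cpm_threshold=0.0)
        assert len(out) == 16
        assert set(out["drug"]) == set(small_matrix.columns)
        assert (np.sign(out["robust_z"]) == out["direction"]).all()
        assert (out["p_adj"] >= out["p_value"] - 1e-12).all()

    def test_planted_outlier_is_called_up(self):
        rng = np.random.default_rng(1)
        cpm = pd.DataFrame(
            2.0 ** (8 + 0.1 * rng.standard_normal((50, 10))),
            index=[f"g{i}" for i in range(50)],
            columns=[f"d{j}" for j in range(10)])
        cpm.loc["g0", "d0"] *= 2 ** 4  # 4 log2-units above its background
        out = call_degs(cpm).set_index(["drug", "gene"])
        hit = out.loc[("d0", "g0")]
        assert hit["is_deg"] and hit["direction"] == 1
        assert hit["p_adj"] < 0.05

    def test_empty_universe_raises(self, small_matrix):
        with pytest.raises(EmptyUniverseError):
            call_degs(small_matrix, cpm_threshold=1e6)

    def test_duplicate_gene_ids_rejected(self):
        bad = frame([[1, 2, 3], [4, 5, 6]], genes=["g", "g"])
        with pytest.raises(ValueError, match="duplicate gene"):
            call_degs(bad)

    def test_global_bh_scope_pools_pairs(self, small_matrix):
        per = call_degs(small_matrix, cpm_threshold=0.0, bh_scope="per_drug")
        pooled = call_degs(small_matrix, cpm_threshold=0.0, bh_scope="global")
        assert (pooled["p_value"] == per["p_value"]).all()
        assert not (pooled["p_adj"] == per["p_adj"]).all()

    def test_roundtrip_tsv(self, small_matrix, tmp_path):
        out = call_degs(small_matrix, cpm_threshold=0.0)
        path = tmp_path / "degs.tsv"
        dge.write_deg_table(out, path)
        back = dge.read_deg_table(path)
        pd.testing.assert_frame_equal(out, back, check_dtype=False)
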