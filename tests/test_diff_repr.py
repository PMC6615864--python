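"""CPM filtering, TMM, NB dispersions/GLM/LRT and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import dropscreen as ds
from dropscreen import diff_repr
from dropscreen.errors import DesignError, DropscreenError


def _cm(array, samples=None):
    arr = np.asarray(array)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ds.CountMatrix(
        pd.DataFrame(arr, index=[f"h{i}" for i in range(arr.shape[0])], columns=samples)
    )


class TestCpmAndFilter:
    def test_cpm_values(self):
        out = ds.cpm(np.array([[5], [0]]), lib_sizes=[10_000_000])
        assert out[0, 0] == pytest.approx(0.5)
        assert out[1, 0] == 0.0

    def test_cpm_identity_scale(self):
        assert ds.cpm(np.array([[1_000_000]]), [1_000_000])[0, 0] == 1e6

    def test_zero_library_size_names_sample(self):
        cm = _cm([[0], [0]])
        with pytest.raises(DropscreenError, match="s0"):
            ds.cpm(cm.counts)

    def _sheet(self, samples, timepoints):
        return ds.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "pool": "1",
                    "timepoint": timepoints,
                    "treatment": ["none" if t == "t0" else "PDS" for t in timepoints],
                    "replicate": list(range(1, len(samples) + 1)),
                }
            )
        )

    def test_failing_any_t0_replicate_removes_hairpin(self):
        # CPM across three t0 reps = (0.6, 0.7, 0.4) -> fails the "all" rule
        counts = np.array(
            [[6, 7, 4], [9_999_994, 9_999_993, 9_999_996]], dtype=np.int64
        )
        ss = self._sheet(["a", "b", "c"], ["t0", "t0", "t0"])
        filt = ds.filter_low_counts(_cm(counts, ["a", "b", "c"]), ss)
        assert filt.hairpin_ids == ["h1"]

    def test_boundary_cpm_is_kept_inclusive(self):
        # exactly CPM 0.5 in every t0 replicate
        counts = np.array([[1, 1], [1_999_999, 1_999_999]], dtype=np.int64)
        ss = self._sheet(["a", "b"], ["t0", "t0"])
        filt = ds.filter_low_counts(_cm(counts, ["a", "b"]), ss)
        assert "h0" in filt.hairpin_ids

    def test_counts_of_ten_hairpins_three_failing(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(100, 200, size=(10, 2))
        counts[3] = [0, 150]
        counts[6] = [1, 1]
        counts[9] = [0, 0]
        # bulk up other rows so CPM of the failing rows is < 0.5
        counts[0] = [4_000_000, 4_000_000]
        ss = self._sheet(["a", "b"], ["t0", "t0"])
        filt = ds.filter_low_counts(_cm(counts, ["a", "b"]), ss)
        assert filt.shape[0] == 7

    def test_no_t0_samples_is_design_error(self):
        ss = self._sheet(["a", "b"], ["tF", "tF"])
        with pytest.raises(DesignError, match="t0"):
            ds.filter_low_counts(_cm([[1, 1]], ["a", "b"]), ss)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(50, 500, size=30)
        nf = ds.tmm_factors(_cm(np.column_stack([col, col])))
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(50, 500, size=30)
        nf = ds.tmm_factors(_cm(np.column_stack([col, 2 * col])))
        assert np.allclose(nf.factors, 1.0)

    def test_factors_have_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.01, size=(100, 4))
        nf = ds.tmm_factors(_cm(counts))
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_depth_scaling_leaves_factors_nearly_unchanged(self):
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 0.01, size=(200, 3))
        scaled = counts.copy()
        scaled[:, 1] *= 4
        f0 = ds.tmm_factors(_cm(counts)).factors.to_numpy()
        f1 = ds.tmm_factors(_cm(scaled)).factors.to_numpy()
        assert np.allclose(f0, f1, atol=0.01)


class TestNbGlm:
    def test_poisson_limit_matches_statsmodels_irls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        y = rng.poisson(30, size=6).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        off = np.log(rng.uniform(0.8, 1.2, size=6))
        beta, _, _ = ds.fit_nb_glm(y, X, off, phi=0.0)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        assert np.allclose(beta, ref.params, atol=1e-8)

    def test_one_group_closed_form(self):
        y = np.array([10.0, 20.0, 30.0])
        off = np.log(np.array([1.0, 2.0, 3.0]))
        beta, mu, _ = ds.fit_nb_glm(y, np.ones((3, 1)), off, phi=0.1)
        expected_mu = y.sum() / np.exp(off).sum() * np.exp(off)
        assert np.allclose(mu, expected_mu, rtol=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(DropscreenError, match="rank"):
            ds.fit_nb_glm(np.ones(4), X, 0.0, phi=0.1)

    def test_all_zero_counts_degenerate_but_finite(self):
        beta, mu, dev = ds.fit_nb_glm(np.zeros(4), np.ones((4, 1)), 0.0, phi=0.1)
        assert np.all(mu < 1e-6) and np.isfinite(dev)


class TestLRT:
    def _designs(self):
        X_full = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        X_red = np.ones((6, 1))
        return X_full, X_red

    def test_identical_groups_give_null_result(self):
        X_full, X_red = self._designs()
        lr, p, _ = ds.lrt_contrast(
            np.array([20, 20, 20, 20, 20, 20]), X_full, X_red, 0.0, phi=0.1
        )
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_doubled_counts_give_log2fc_about_one(self):
        X_full, X_red = self._designs()
        _, p, lfc = ds.lrt_contrast(
            np.array([100, 110, 90, 200, 220, 180]),
            X_full,
            X_red,
            0.0,
            phi=0.01,
            treat_col=1,
        )
        assert lfc == pytest.approx(1.0, abs=0.05)
        assert p < 0.01

    def test_non_nested_designs_rejected(self):
        X_full = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        X_other = np.column_stack([np.repeat([1.0, 0.0], 3), np.arange(6.0)])
        with pytest.raises(DropscreenError, match="nested"):
            ds.lrt_contrast(np.ones(6), X_full, X_other, 0.0, phi=0.1)


class TestDispersions:
    def _sim(self, phi, n=800, seed=6):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(200), 0.8, size=n)
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        if phi > 0:
            lam = rng.gamma(1 / phi, phi * mu[:, None], size=(n, 6))
        else:
            lam = np.broadcast_to(mu[:, None], (n, 6))
        Y = rng.poisson(lam).astype(float)
        return Y, X, np.zeros(6)

    def test_common_dispersion_recovers_truth(self):
        Y, X, off = self._sim(phi=0.1, n=2000)
        est = ds.estimate_common_dispersion(Y, X, off)
        assert 0.08 <= est <= 0.12

    def test_poisson_data_gives_tiny_dispersion(self):
        Y, X, off = self._sim(phi=0.0, n=1000)
        est = ds.estimate_common_dispersion(Y, X, off)
        assert est <= 0.01

    def test_single_hairpin_equals_grid_argmax(self):
        Y, X, off = self._sim(phi=0.2, n=1)
        est = ds.estimate_common_dispersion(Y, X, off)
        grid = np.logspace(-4, 1, 200)
        apls = [
            float(diff_repr.adjusted_profile_loglik(Y, X, off, g)[0]) for g in grid
        ]
        brute = grid[int(np.argmax(apls))]
        assert abs(np.log10(est) - np.log10(brute)) < 0.05

    def test_huge_prior_collapses_tagwise_to_common(self):
        Y, X, off = self._sim(phi=0.1, n=300)
        common = ds.estimate_common_dispersion(Y, X, off)
        disp = ds.estimate_tagwise_dispersion(
            Y, X, phi_common=common, prior_df=1e9, offsets=off
        )
        assert np.allclose(np.log10(disp.phi_tag), np.log10(common), atol=0.1)

    def test_zero_prior_matches_per_hairpin_grid_oracle(self):
        Y, X, off = self._sim(phi=0.2, n=40)
        disp = ds.estimate_tagwise_dispersion(
            Y, X, phi_common=0.2, prior_df=0.0, offsets=off
        )
        grid = diff_repr._PHI_GRID
        apl = np.column_stack(
            [diff_repr.adjusted_profile_loglik(Y, X, off, g) for g in grid]
        )
        brute = grid[np.argmax(apl, axis=1)]
        step = np.log10(grid[1]) - np.log10(grid[0])
        assert np.all(
            np.abs(np.log10(np.asarray(disp.phi_tag)) - np.log10(brute)) <= step
        )

    def test_tagwise_estimates_track_mixed_truth(self):
        rng = np.random.default_rng(7)
        n = 2000
        phis = np.where(rng.random(n) < 0.5, 0.05, 0.3)
        mu = rng.lognormal(np.log(300), 0.5, size=n)
        lam = rng.gamma(1 / phis[:, None], phis[:, None] * mu[:, None], size=(n, 6))
        Y = rng.poisson(lam).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        disp = ds.estimate_tagwise_dispersion(Y, X, prior_df=5, offsets=np.zeros(6))
        rho = sps.spearmanr(phis, np.asarray(disp.phi_tag)).statistic
        assert rho >= 0.5

    def test_zero_residual_df_is_error(self):
        Y = np.ones((5, 2))
        X = np.eye(2)
        with pytest.raises(DropscreenError, match="degrees of freedom"):
            ds.estimate_common_dispersion(Y, X, np.zeros(2))


class TestBH:
    def test_worked_example(self):
        out = ds.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_boundary(self):
        assert ds.bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(ds.bh_adjust([0.0, 1.0]), [0.0, 1.0])

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            out = ds.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank_pos, idx in enumerate(order):
            j = np.arange(rank_pos, m)
            brute[idx] = min(1.0, np.min(p[order[j]] * m / (j + 1)))
        assert np.allclose(ds.bh_adjust(p), brute)


class TestRunDifferential:
    def test_fdr_is_at_least_p(self, small_screen):
        dr = small_screen["dr"]
        assert (dr["fdr"] >= dr["p"] - 1e-12).all()
        assert dr["lr"].min() >= 0
        assert dr["p"].between(0, 1).all()

    def test_replicate_relabelling_changes_nothing(self, small_screen):
        """Statistics depend on group membership, not replicate order."""
        cm, ss, lib = small_screen["cm"], small_screen["ss"], small_screen["lib"]
        tab = ss.table.copy()
        pds = tab["treatment"] == "PDS"
        tab.loc[pds, "replicate"] = tab.loc[pds, "replicate"].to_numpy()[::-1]
        dr2 = ds.run_differential(cm, ds.SampleSheet(tab), lib=lib)
        pd.testing.assert_frame_equal(
            small_screen["dr"].sort_values(["contrast", "hairpin_id"]).reset_index(drop=True),
            dr2.sort_values(["contrast", "hairpin_id"]).reset_index(drop=True),
        )

    def test_unknown_contrast_rejected(self, small_screen):
        with pytest.raises(DesignError, match="not in pool"):
            ds.run_differential(
                small_screen["cm"],
                small_screen["ss"],
                contrasts=["Olaparib-t0"],
            )
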