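import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import acqstruct as aq
from acqstruct.factor import (
    align_to_blueprint,
    blueprint_target_mask,
    correlation_matrix,
    extract,
    fit_statistics,
    model_degrees_of_freedom,
    rotate_to_target,
    target_criterion,
)


class TestCorrelationMatrix:
    def test_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.cos(x)})
        R, n = correlation_matrix(df)
        assert n == 10
        assert R.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((10000, 4)),
                          columns=list("abcd"))
        R, _ = correlation_matrix(df)
        off = R.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)

    def test_listwise_uses_complete_rows_only(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [2.0, 1, 3, 9]})
        _, n = correlation_matrix(df, use="listwise")
        assert n == 3


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("k, m, expected", [
        (54, 5, 1171),
        (6, 1, 9),  # 21 - (6 + 6 - 0)
    ])
    def test_known_values(self, k, m, expected):
        assert model_degrees_of_freedom(k, m) == expected

    @given(st.integers(2, 40), st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_matches_enumerated_parameter_count(self, k, m):
        if m >= k:
            return
        moments = len([(i, j) for i in range(k) for j in range(i, k)])
        rot_constraints = len([(i, j) for i in range(m) for j in range(i + 1, m)])
        free = k * m + k - rot_constraints
        assert model_degrees_of_freedom(k, m) == moments - free


class TestExtract:
    def test_pca_identity_trace_conservation(self):
        R = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        sol = extract(R, 4, method="pca")
        lam = sol.loadings.to_numpy()
        np.testing.assert_allclose(lam.T @ lam, np.eye(4), atol=1e-10)
        assert (lam**2).sum() == pytest.approx(4.0)

    def test_minres_equicorrelation_closed_form(self):
        # one-factor equicorrelation 0.49 has the exact solution lambda=0.7
        k = 6
        R = np.full((k, k), 0.49)
        np.fill_diagonal(R, 1.0)
        sol = extract(pd.DataFrame(R), 1, method="minres")
        np.testing.assert_allclose(sol.loadings.to_numpy().ravel(), 0.7,
                                   atol=1e-6)
        np.testing.assert_allclose(sol.uniquenesses.to_numpy(), 0.51,
                                   atol=1e-6)

    def test_ml_population_subspace_recovery(self, population_solution):
        """On the exact population correlation matrix the ML loading space
        must contain the true pattern (rotation-invariant comparison)."""
        _, _, ind_load, sol = population_solution
        L = sol.loadings.to_numpy()
        M, *_ = np.linalg.lstsq(L, ind_load.to_numpy(), rcond=None)
        resid = L @ M - ind_load.to_numpy()
        assert np.abs(resid).max() < 0.02

    def test_indefinite_matrix_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="indefinite"):
            extract(pd.DataFrame(R), 1, method="ml")

    def test_ml_matches_factanal_oracle(self, tmp_path):
        """Canonical ML loadings agree with R's factanal on the same matrix."""
        rng = np.random.default_rng(4)
        lam = np.zeros((9, 2))
        lam[:5, 0] = [0.8, 0.7, 0.6, 0.5, 0.4]
        lam[4:, 1] = [0.3, 0.6, 0.7, 0.5, 0.6]
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        rcsv = tmp_path / "R.csv"
        pd.DataFrame(R).to_csv(rcsv, index=False)
        script = textwrap.dedent(f"""
            R <- as.matrix(read.csv("{rcsv}"))
            dimnames(R) <- NULL
            fit <- factanal(covmat = R, factors = 2, rotation = "none")
            L <- matrix(as.numeric(fit$loadings), ncol = 2)
            write.csv(L, "{tmp_path}/L.csv", row.names = FALSE)
        """)
        (tmp_path / "fa.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "fa.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "L.csv").to_numpy()
        sol = extract(pd.DataFrame(R), 2, method="ml")
        ours = sol.loadings.to_numpy()
        # canonical forms agree up to per-column sign
        np.testing.assert_allclose(np.abs(ours), np.abs(ref), atol=0.01)


class TestTargetRotation:
    @pytest.fixture()
    def toy(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = [0.7, 0.6, 0.8]
        lam[3:, 1] = [0.5, 0.7, 0.6]
        lam[2, 1] = 0.25
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        sol = extract(pd.DataFrame(R), 2, method="minres")
        mask = np.full((6, 2), np.nan)
        mask[3:, 0] = 0.0
        mask[:3, 1] = 0.0
        return sol, mask

    def test_satisfied_target_keeps_structure(self, toy):
        sol, mask = toy
        mask2 = mask.copy()
        mask2[2, 1] = np.nan  # free the true cross-loading: target attainable
        rot = rotate_to_target(sol, mask2, oblique=True)
        assert rot.criterion_value < 1e-8

    def test_orthogonal_matches_grid_search_oracle(self, toy):
        sol, mask = toy
        rot = rotate_to_target(sol, mask, oblique=False)
        A = sol.loadings.to_numpy()
        W = np.isfinite(mask).astype(float)
        theta = np.deg2rad(np.arange(0.0, 360.0, 0.05))
        c, s = np.cos(theta), np.sin(theta)
        best = np.inf
        for refl in (1.0, -1.0):
            # all planar rotations (and reflections) of the 2-factor solution
            T = np.stack([np.stack([c, -refl * s]), np.stack([s, refl * c])])
            L = np.einsum("kf,fgt->kgt", A, T)
            crit = ((L**2) * W[:, :, None]).sum(axis=(0, 1))
            best = min(best, crit.min())
        assert rot.criterion_value == pytest.approx(best, abs=1e-5)

    def test_orthogonal_criterion_dominates_oblique(self, toy):
        sol, mask = toy
        ortho = rotate_to_target(sol, mask, oblique=False)
        obli = rotate_to_target(sol, mask, oblique=True)
        assert ortho.criterion_value >= obli.criterion_value - 1e-10

    def test_rotation_preserves_implied_correlation(self, population_solution):
        bp = aq.build_default_blueprint()
        _, _, ind_load, sol = population_solution
        mask = blueprint_target_mask(bp, list(sol.loadings.index))
        rot = rotate_to_target(sol, mask, oblique=True)
        np.testing.assert_allclose(rot.implied_correlation(),
                                   sol.implied_correlation(), atol=1e-8)

    def test_full_target_recovers_population_pattern(self, population_solution):
        """Rotating toward the known population pattern reproduces it and
        the true factor correlations exactly on noise-free input."""
        cfg, _, ind_load, sol = population_solution
        rot = rotate_to_target(sol, ind_load, oblique=True)
        np.testing.assert_allclose(rot.loadings.to_numpy(),
                                   ind_load.to_numpy(), atol=0.02)
        np.testing.assert_allclose(rot.phi.to_numpy(),
                                   np.asarray(cfg.factor_correlations),
                                   atol=0.02)

    def test_zero_target_recovery_bounded(self, population_solution):
        """The theory zero-target conflicts with true secondary loadings,
        so recovery is approximate; the error stays within 0.1."""
        bp = aq.build_default_blueprint()
        _, _, ind_load, sol = population_solution
        mask = blueprint_target_mask(bp, list(sol.loadings.index))
        rot = align_to_blueprint(rotate_to_target(sol, mask, oblique=True), bp)
        assert np.abs(rot.loadings.to_numpy() - ind_load.to_numpy()).max() < 0.1


class TestFitStatistics:
    def test_reference_design_df(self, bp, analysis_acq):
        fit = analysis_acq.fits[("corrected", "triplet54")]
        assert fit.df == 1171

    def test_perfect_fit_limits(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.7
        lam[4:, 1] = 0.6
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        sol = extract(pd.DataFrame(R), 2, method="ml")
        fit = fit_statistics(pd.DataFrame(R), sol, n=1000)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)
        assert fit.cfi == pytest.approx(1.0, abs=1e-6)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-4)
        assert fit.srmr < 1e-3

    def test_saturated_model_reports_nulls(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 3))
        R, _ = correlation_matrix(pd.DataFrame(X, columns=list("abc")))
        sol = extract(R, 1, method="ml")
        fit = fit_statistics(R, sol, n=200)
        assert fit.df == 0
        assert fit.chi_square is None and fit.cfi is None

    def test_requires_ml_solution(self):
        R = pd.DataFrame(np.eye(3) + 0.3 - 0.3 * np.eye(3))
        sol = extract(R, 1, method="minres")
        with pytest.raises(ValueError, match="ml"):
            fit_statistics(R, sol, n=100)


class TestAlignment:
    def test_aligned_solution_unchanged(self, bp, population_solution):
        _, _, ind_load, sol = population_solution
        mask = blueprint_target_mask(bp, list(sol.loadings.index))
        rot = rotate_to_target(sol, mask, oblique=True)
        ali = align_to_blueprint(rot, bp)
        again = align_to_blueprint(ali, bp)
        pd.testing.assert_frame_equal(ali.loadings, again.loadings)

    def test_known_scramble_recovered(self, bp, population_solution):
        _, _, ind_load, sol = population_solution
        mask = blueprint_target_mask(bp, list(sol.loadings.index))
        ali = align_to_blueprint(rotate_to_target(sol, mask, oblique=True), bp)
        rng = np.random.default_rng(7)
        perm = rng.permutation(5)
        signs = np.array([1, -1, 1, -1, -1], float)
        scr_lam = ali.loadings.to_numpy()[:, perm] * signs
        scr_phi = ali.phi.to_numpy()[np.ix_(perm, perm)] * np.outer(signs, signs)
        scrambled = aq.FactorSolution(
            loadings=pd.DataFrame(scr_lam, index=ali.loadings.index,
                                  columns=[f"F{j}" for j in range(5)]),
            phi=pd.DataFrame(scr_phi, index=[f"F{j}" for j in range(5)],
                             columns=[f"F{j}" for j in range(5)]),
            uniquenesses=ali.uniquenesses,
            rotation=ali.rotation,
            criterion_value=ali.criterion_value,
            method=ali.method,
        )
        restored = align_to_blueprint(scrambled, bp)
        np.testing.assert_allclose(restored.loadings.to_numpy(),
                                   ali.loadings.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(restored.phi.to_numpy(),
                                   ali.phi.to_numpy(), atol=1e-10)

    def test_single_negated_column_undone(self, bp, population_solution):
        _, _, ind_load, sol = population_solution
        mask = blueprint_target_mask(bp, list(sol.loadings.index))
        ali = align_to_blueprint(rotate_to_target(sol, mask, oblique=True), bp)
        flipped = ali.loadings.copy()
        flipped["A"] = -flipped["A"]
        phi_f = ali.phi.copy()
        phi_f.loc["A"] = -phi_f.loc["A"]
        phi_f["A"] = -phi_f["A"]
        neg = aq.FactorSolution(
            loadings=flipped, phi=phi_f,
            uniquenesses=ali.uniquenesses, rotation=ali.rotation,
            criterion_value=ali.criterion_value, method=ali.method,
        )
        restored = align_to_blueprint(neg, bp)
        np.testing.assert_allclose(restored.loadings.to_numpy(),
                                   ali.loadings.to_numpy(), atol=1e-10)
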