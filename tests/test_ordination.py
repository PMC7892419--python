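"""Redundancy analysis: design builders, the fit, and the permutation test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from distinctfish.ordination import (
    RDADesign,
    build_spatial_design,
    build_spatiotemporal_design,
    build_temporal_design,
    fit_rda,
    permutation_test_rda,
)

ENV_COLS = ["sst_c", "sss_psu", "depth_m", "bstress", "pci", "effort_hours",
            "nao", "amo"]


def make_env(n_cells=5, n_years=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    depth = rng.uniform(20, 120, n_cells)
    nao = rng.normal(size=n_years)
    amo = rng.normal(size=n_years)
    for c in range(n_cells):
        for y in range(n_years):
            rows.append(
                {
                    "cell_id": f"c{c}",
                    "year": 1990 + y,
                    "sst_c": rng.uniform(8, 14),
                    "sss_psu": rng.uniform(33, 35),
                    "depth_m": depth[c],
                    "bstress": rng.uniform(0.2, 1.2),
                    "pci": rng.uniform(0.5, 3),
                    "effort_hours": rng.uniform(100, 4000),
                    "nao": nao[y],
                    "amo": amo[y],
                }
            )
    return pd.DataFrame(rows)


def make_series(n_cells=5, n_years=6, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("Q1", "Q4"):
        for c in range(n_cells):
            for y in range(n_years):
                rows.append(
                    {
                        "group": g,
                        "cell_id": f"c{c}",
                        "year": 1990 + y,
                        "richness": int(rng.integers(0, 8)),
                        "total_abundance": float(rng.uniform(0, 500)),
                    }
                )
    return pd.DataFrame(rows)


def oracle_rda(Y, X):
    """Normal-equations fit + eigendecomposition, kept deliberately naive."""
    n = Y.shape[0]
    Yc = Y - Y.mean(0)
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    B = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
    Yhat = Xc @ B
    lam_c = np.sort(np.linalg.eigvalsh(Yhat.T @ Yhat / (n - 1)))[::-1]
    lam_r = np.sort(np.linalg.eigvalsh((Yc - Yhat).T @ (Yc - Yhat) / (n - 1)))[::-1]
    total = np.trace(Yc.T @ Yc) / (n - 1)
    return lam_c, lam_r, lam_c.sum() / total


class TestDesignBuilders:
    def test_spatial_shape(self):
        d = build_spatial_design(make_series(), make_env())
        assert d.Y.shape == (5, 2)
        assert d.predictor_names == [
            "sst_c", "sss_psu", "depth_m", "bstress", "pci", "effort_hours"
        ]

    def test_spatial_drops_cell_without_env(self):
        env = make_env()
        d = build_spatial_design(make_series(), env[env["cell_id"] != "c3"])
        assert "c3" not in d.row_ids
        assert "c3" in d.dropped_rows

    def test_constant_predictor_dropped_with_warning(self):
        env = make_env()
        env["depth_m"] = 55.0
        with pytest.warns(UserWarning, match="depth_m"):
            d = build_spatial_design(make_series(), env)
        assert "depth_m" not in d.predictor_names
        assert "depth_m" in d.dropped_predictors

    def test_temporal_shape_includes_climate_indices(self):
        d = build_temporal_design(make_series(), make_env())
        assert d.Y.shape == (6, 2)
        assert "nao" in d.predictor_names and "amo" in d.predictor_names
        assert "depth_m" not in d.predictor_names

    def test_spatiotemporal_excludes_missing_trends(self):
        trends = pd.DataFrame(
            {
                "group": ["Q1"] * 5 + ["Q4"] * 5,
                "cell_id": [f"c{i}" for i in range(5)] * 2,
                "rho": [0.1, 0.5, -0.2, 0.8, 0.3, 0.2, np.nan, 0.1, -0.5, 0.9],
                "n_years": 6,
                "reason": "",
            }
        )
        d = build_spatiotemporal_design(trends, make_env())
        assert "c1" not in d.row_ids
        assert d.Y.shape == (4, 2)
        assert np.all(np.abs(d.Y) <= 1)

    def test_spatiotemporal_constant_trend_errors(self):
        trends = pd.DataFrame(
            {
                "group": ["Q1"] * 4 + ["Q4"] * 4,
                "cell_id": [f"c{i}" for i in range(4)] * 2,
                "rho": [0.5] * 4 + [0.1, 0.2, 0.3, 0.4],
                "n_years": 6,
                "reason": "",
            }
        )
        with pytest.raises(ValueError, match="degenerate response"):
            build_spatiotemporal_design(trends, make_env())


class TestFitRDA:
    def test_univariate_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        d = RDADesign(list(range(30)), y[:, None], x[:, None], ["y"], ["x"])
        res = fit_rda(d)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.proportion_constrained == pytest.approx(r2, abs=1e-10)

    def test_perfect_constraint(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(12, 2))
        X = Y - Y.mean(0)
        d = RDADesign(list(range(12)), Y, X, ["a", "b"], ["p", "q"])
        res = fit_rda(d)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            Y = rng.normal(size=(8, 2))
            X = rng.normal(size=(8, 3))
            d = RDADesign(list(range(8)), Y, X, ["a", "b"], ["p", "q", "r"])
            res = fit_rda(d)
            lam_c, lam_r, prop = oracle_rda(Y, X)
            assert np.allclose(res.eigenvalues, lam_c[: len(res.eigenvalues)],
                               atol=1e-10)
            assert res.proportion_constrained == pytest.approx(prop, abs=1e-10)

    def test_variance_conservation(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 2))
        X = rng.normal(size=(40, 5))
        d = RDADesign(list(range(40)), Y, X, ["a", "b"], list("pqrst"))
        res = fit_rda(d)
        total = res.eigenvalues.sum() + res.residual_eigenvalues.sum()
        assert total == pytest.approx(res.total_variance, rel=1e-9)

    def test_invariant_to_linear_reparameterization_of_X(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(25, 2))
        X = rng.normal(size=(25, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        d1 = RDADesign(list(range(25)), Y, X, ["a", "b"], ["p", "q", "r"])
        d2 = RDADesign(list(range(25)), Y, X @ A, ["a", "b"], ["p", "q", "r"])
        assert fit_rda(d1).proportion_constrained == pytest.approx(
            fit_rda(d2).proportion_constrained, abs=1e-10
        )

    def test_rank_deficient_X_uses_pseudoinverse(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(20, 2))
        X = rng.normal(size=(20, 2))
        Xdup = np.column_stack([X, X[:, 0]])  # rank 2, three columns
        d = RDADesign(list(range(20)), Y, Xdup, ["a", "b"], ["p", "q", "p2"])
        res = fit_rda(d)
        assert res.rank == 2
        d0 = RDADesign(list(range(20)), Y, X, ["a", "b"], ["p", "q"])
        assert res.proportion_constrained == pytest.approx(
            fit_rda(d0).proportion_constrained, abs=1e-10
        )

    def test_overfit_refused(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(4, 2))
        X = rng.normal(size=(4, 5))
        d = RDADesign(list(range(4)), Y, X, ["a", "b"], list("pqrst"))
        with pytest.raises(ValueError, match="trivially 1"):
            fit_rda(d)

    def test_constant_Y_refused(self):
        X = np.random.default_rng(7).normal(size=(10, 2))
        d = RDADesign(list(range(10)), np.ones((10, 2)), X, ["a", "b"], ["p", "q"])
        with pytest.raises(ValueError, match="constant response"):
            fit_rda(d)

    def test_matches_vegan_reference(self, tmp_path):
        """Cross-check eigenvalues against vegan::rda on one small instance."""
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(8, 2))
        X = rng.normal(size=(8, 3))
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("Y.csv", header=FALSE))
            X <- as.matrix(read.csv("X.csv", header=FALSE))
            m <- rda(Y ~ X)
            cat(m$CCA$eig, sep="\\n")
            cat(m$CCA$tot.chi / m$tot.chi, "\\n")
            """
        )
        (tmp_path / "check.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        vals = [float(v) for v in proc.stdout.split()]
        d = RDADesign(list(range(8)), Y, X, ["a", "b"], ["p", "q", "r"])
        res = fit_rda(d)
        assert np.allclose(res.eigenvalues, vals[:-1], atol=1e-6)
        assert res.proportion_constrained == pytest.approx(vals[-1], abs=1e-6)


class TestPermutationTest:
    def test_perfect_constraint_minimal_p(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(15, 2))
        d = RDADesign(list(range(15)), Y, Y - Y.mean(0), ["a", "b"], ["p", "q"])
        out = permutation_test_rda(d, n_perm=99, seed=1)
        assert out["p_value"] == pytest.approx(1 / 100)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(20, 2))
        X = rng.normal(size=(20, 3))
        d = RDADesign(list(range(20)), Y, X, ["a", "b"], ["p", "q", "r"])
        a = permutation_test_rda(d, n_perm=199, seed=5)
        b = permutation_test_rda(d, n_perm=199, seed=5)
        assert a == b

    def test_signal_detected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        Y = X @ np.array([[1.0, 0.3], [-0.5, 1.2]]) + 0.1 * rng.normal(size=(40, 2))
        d = RDADesign(list(range(40)), Y, X, ["a", "b"], ["p", "q"])
        out = permutation_test_rda(d, n_perm=199, seed=3)
        assert out["p_value"] <= 0.01

    def test_invalid_n_perm(self):
        d = RDADesign([0, 1, 2], np.eye(3, 2), np.arange(3)[:, None], ["a", "b"], ["p"])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_rda(d, n_perm=0)
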