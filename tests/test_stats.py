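import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fragsar.stats import (
    adjusted_r2,
    partial_spearman,
    spearman_matrix,
    varpart2,
)

# ---------------------------------------------------------------------------
# brute-force oracles, intentionally naive and independent of the package code
# ---------------------------------------------------------------------------


def naive_midranks(values):
    values = list(values)
    ranks = [0.0] * len(values)
    for i, v in enumerate(values):
        smaller = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        ranks[i] = smaller + (ties + 1) / 2.0
    return ranks


def naive_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def naive_spearman(x, y):
    return naive_pearson(naive_midranks(x), naive_midranks(y))


def naive_residuals(y, controls):
    """OLS residuals of y on [1, controls] via normal equations."""
    X = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in controls])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return np.asarray(y, float) - X @ beta


def naive_partial_spearman(x, y, controls):
    rx = naive_midranks(x)
    ry = naive_midranks(y)
    rcs = [naive_midranks(c) for c in controls]
    return naive_pearson(list(naive_residuals(rx, rcs)), list(naive_residuals(ry, rcs)))


def naive_adj_r2(y, X):
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    n, p = X.shape[0], X.shape[1] - 1
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(17)
    return pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))


class TestSpearmanMatrix:
    def test_monotone_relation_is_unity(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 4, 9, 16, 25]})
        (res,) = spearman_matrix(df)
        assert res.rho == pytest.approx(1.0)

    def test_perfect_inverse(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]})
        (res,) = spearman_matrix(df)
        assert res.rho == pytest.approx(-1.0)

    def test_matches_naive_oracle(self, random_table):
        results = spearman_matrix(random_table)
        for r in results:
            expected = naive_spearman(random_table[r.var_x], random_table[r.var_y])
            assert r.rho == pytest.approx(expected, abs=1e-12)

    def test_bonferroni_family_is_all_pairs(self, random_table):
        results = spearman_matrix(random_table)
        m = len(results)
        assert m == 10  # C(5,2)
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * m))

    def test_monotone_transform_invariance(self, random_table):
        base = spearman_matrix(random_table)
        warped = random_table.copy()
        warped["a"] = np.exp(warped["a"])
        for r0, r1 in zip(base, spearman_matrix(warped)):
            assert r1.rho == pytest.approx(r0.rho, abs=1e-12)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 2, 2, 2]})
        (res,) = spearman_matrix(df)
        assert np.isnan(res.rho)


class TestPartialSpearman:
    def test_matches_naive_oracle(self, random_table):
        for controls in [(), ("c",), ("c", "d"), ("c", "d", "e")]:
            r = partial_spearman(random_table, "a", "b", controls)
            expected = naive_partial_spearman(
                random_table["a"], random_table["b"],
                [random_table[c] for c in controls],
            )
            assert r.rho == pytest.approx(expected, abs=1e-10)

    def test_empty_controls_equal_plain_spearman(self, random_table):
        r = partial_spearman(random_table, "a", "b")
        plain = naive_spearman(random_table["a"], random_table["b"])
        assert r.rho == pytest.approx(plain, abs=1e-12)

    def test_recursion_formula_single_control(self, random_table):
        """Residual-based partial correlation equals the textbook recursion
        (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)) on rank-transformed data;
        with all three pairwise rank correlations at 0.5 it yields 1/3."""
        r_xy = naive_spearman(random_table["a"], random_table["b"])
        r_xz = naive_spearman(random_table["a"], random_table["c"])
        r_yz = naive_spearman(random_table["b"], random_table["c"])
        recursion = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r = partial_spearman(random_table, "a", "b", ("c",))
        assert r.rho == pytest.approx(recursion, abs=1e-10)
        assert (0.5 - 0.25) / (1 - 0.25) == pytest.approx(1 / 3)

    def test_irrelevant_control_keeps_association(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": x, "c": rng.normal(size=n)})
        r = partial_spearman(df, "x", "y", ("c",))
        assert r.rho >= 0.99

    def test_perfect_control_removes_association(self):
        rng = np.random.default_rng(2)
        n = 500
        c = rng.normal(size=n)
        df = pd.DataFrame({"x": rng.normal(size=n), "y": c, "c": c})
        r = partial_spearman(df, "x", "y", ("c",))
        assert abs(r.rho) < 0.1

    def test_pingouin_cross_check(self, random_table):
        pingouin = pytest.importorskip("pingouin")
        ours = partial_spearman(random_table, "a", "b", ("c", "d"))
        ref = pingouin.partial_corr(
            random_table, x="a", y="b", covar=["c", "d"], method="spearman"
        )
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_input_validation(self, random_table):
        with pytest.raises(ValueError, match="disjoint"):
            partial_spearman(random_table, "a", "b", ("a",))
        with pytest.raises(ValueError, match="singular"):
            df = random_table.copy()
            df["c2"] = df["c"]
            partial_spearman(df, "a", "b", ("c", "c2"))


class TestVarpart:
    def test_fractions_sum_to_one(self, random_table):
        y = random_table["a"].to_numpy()
        r = varpart2(y, random_table[["b"]].to_numpy(),
                     random_table[["c", "d", "e"]].to_numpy())
        assert r.frac_a + r.frac_b + r.frac_c + r.frac_d == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_adjusted_r2_algebra(self):
        rng = np.random.default_rng(23)
        n = 40
        X1 = rng.normal(size=(n, 1))
        X2 = rng.normal(size=(n, 3))
        y = X1[:, 0] + X2[:, 1] + rng.normal(size=n)
        r = varpart2(y, X1, X2)
        rf = naive_adj_r2(y, np.column_stack([X1, X2]))
        r1 = naive_adj_r2(y, X1)
        r2 = naive_adj_r2(y, X2)
        assert r.frac_a == pytest.approx(rf - r2, abs=1e-10)
        assert r.frac_c == pytest.approx(rf - r1, abs=1e-10)
        assert r.frac_b == pytest.approx(r1 + r2 - rf, abs=1e-10)
        assert r.frac_d == pytest.approx(1 - rf, abs=1e-10)

    def test_saturated_by_x1(self):
        rng = np.random.default_rng(3)
        n = 200
        X1 = rng.normal(size=(n, 1))
        X2 = rng.normal(size=(n, 2))
        y = 2.0 * X1[:, 0]
        r = varpart2(y, X1, X2)
        assert r.frac_a == pytest.approx(1.0, abs=0.02)
        assert abs(r.frac_c) < 0.02 and abs(r.frac_d) < 0.02

    def test_pure_noise_unexplained(self):
        rng = np.random.default_rng(4)
        n = 500
        r = varpart2(rng.normal(size=n), rng.normal(size=(n, 1)),
                     rng.normal(size=(n, 4)))
        assert abs(r.frac_a) < 0.05 and abs(r.frac_c) < 0.05
        assert r.frac_d == pytest.approx(1.0, abs=0.05)

    def test_orthogonal_known_variance_shares(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x1 = rng.normal(size=(n, 1))
        x2 = rng.normal(size=(n, 1))
        # variance shares: v1 = .36, v2 = .16, noise .48
        y = 0.6 * x1[:, 0] + 0.4 * x2[:, 0] + np.sqrt(0.48) * rng.normal(size=n)
        r = varpart2(y, x1, x2)
        assert r.frac_a == pytest.approx(0.36, abs=0.02)
        assert r.frac_c == pytest.approx(0.16, abs=0.02)
        assert abs(r.frac_b) < 0.02

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(6)
        n = 30
        X1 = rng.normal(size=(n, 1))
        with pytest.raises(ValueError, match="collinear"):
            varpart2(rng.normal(size=n), X1, np.column_stack([X1, X1]))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_vegan_cross_check(self, tmp_path):
        """vegan::varpart (the standard redundancy-analysis partitioning tool)
        must agree with the native implementation on a random table."""
        rng = np.random.default_rng(7)
        n = 30
        df = pd.DataFrame(rng.normal(size=(n, 6)),
                          columns=["y", "x1", "f1", "f2", "f3", "f4"])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "vp.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- read.csv("{csv}")
            vp <- varpart(d$y, ~ x1, ~ f1 + f2 + f3 + f4, data = d)
            f <- vp$part$indfract$Adj.R.square
            cat(sprintf("%.12f %.12f %.12f %.12f", f[1], f[2], f[3], f[4]))
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                              timeout=120)
        assert proc.returncode == 0, proc.stderr
        # vegan's indfract rows: [a]=unique X1, [b]=unique X2, [c]=shared, [d]=resid
        uniq1, uniq2, shared, resid = map(float, proc.stdout.split())
        ours = varpart2(df["y"].to_numpy(), df[["x1"]].to_numpy(),
                        df[["f1", "f2", "f3", "f4"]].to_numpy())
        assert ours.frac_a == pytest.approx(uniq1, abs=1e-6)
        assert ours.frac_c == pytest.approx(uniq2, abs=1e-6)
        assert ours.frac_b == pytest.approx(shared, abs=1e-6)
        assert ours.frac_d == pytest.approx(resid, abs=1e-6)
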