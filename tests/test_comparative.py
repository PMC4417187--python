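import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from drscan.comparative import (
    ContrastSet,
    SpeciesRecord,
    constraint_line,
    contrast_correlation,
    ensemble_z_test,
    group_pairwise_tests,
    independent_contrasts,
    load_tree,
    pic_partial_correlation,
    prepare_tree,
    residualize,
    subpopulation_tests,
)
from drscan.synthetic_data import _yule_tree, simulate_bm_traits


class TestResidualize:
    def test_exact_linear_relation_gives_zero_residuals(self):
        x = np.arange(10.0)
        assert np.allclose(residualize(2 * x, x), 0.0, atol=1e-10)

    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 6.0])
        res = residualize(y, np.zeros((3, 0)))
        assert np.allclose(res, y - y.mean())

    def test_two_covariates_match_normal_equations(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        design = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(residualize(y, X), y - design @ beta, atol=1e-10)
        res = residualize(y, X)
        assert abs(res.sum()) < 1e-8
        assert np.allclose(res @ X, 0.0, atol=1e-7)

    def test_collinear_covariates_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError, match="collinear"):
            residualize(x, np.column_stack([x, 2 * x]))


class TestIndependentContrasts:
    def test_two_taxon_case(self):
        cs = independent_contrasts(load_tree("(A:1,B:1);"), {"A": 4.0, "B": 2.0})
        assert cs.values == pytest.approx([np.sqrt(2)], abs=1e-5)

    def test_three_taxon_hand_execution(self):
        # ((A:1,B:1):1, C:2): contrast AB = (3-1)/sqrt(2); node AB value 2
        # with adjusted branch 1.5, so contrast (AB,C) = 0
        cs = independent_contrasts(load_tree("((A:1,B:1):1,C:2);"),
                                   {"A": 3.0, "B": 1.0, "C": 2.0})
        assert sorted(np.abs(cs.values)) == pytest.approx([0.0, np.sqrt(2)], abs=1e-9)

    def test_constant_trait_gives_zero_contrasts(self):
        tree = _yule_tree(16, 1.0, seed=3)
        cs = independent_contrasts(tree, {l.taxon.label: 5.0 for l in tree.leaf_node_iter()})
        assert len(cs) == 15
        assert np.allclose(cs.values, 0.0)

    def test_missing_leaf_value_is_error(self):
        with pytest.raises(ValueError, match="no trait value"):
            independent_contrasts(load_tree("(A:1,B:1);"), {"A": 1.0})

    def test_matches_r_ape_pic(self, rng, tmp_path):
        """Cross-check Felsenstein pruning against ape::pic (independent code)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        tree = prepare_tree(_yule_tree(8, 1.0, seed=9))
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        trait = {l: float(v) for l, v in zip(leaves, rng.normal(size=8))}
        newick = tree.as_string(schema="newick").strip().removeprefix("[&R] ")
        (tmp_path / "t.nwk").write_text(newick + "\n")
        (tmp_path / "x.tsv").write_text(
            "\n".join(f"{k}\t{v!r}" for k, v in trait.items()) + "\n")
        rcode = f"""
        library(ape)
        tr <- read.tree('{tmp_path}/t.nwk')
        x <- read.table('{tmp_path}/x.tsv', row.names=1)
        v <- setNames(x[[1]], rownames(x))
        cat(sprintf('%.12g', sort(abs(pic(v[tr$tip.label], tr)))), sep='\\n')
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        r_vals = np.array([float(v) for v in out.stdout.split()])
        ours = np.sort(np.abs(independent_contrasts(tree, trait, resolve=False).values))
        assert len(ours) == len(r_vals) == 7
        assert ours == pytest.approx(r_vals, rel=1e-6, abs=1e-8)


class TestContrastCorrelation:
    def test_proportional_contrasts_give_unit_correlation(self):
        cx = ContrastSet(values=np.array([1.0, -2.0, 0.5, 3.0]))
        cy = ContrastSet(values=2 * cx.values)
        rho, p = contrast_correlation(cx, cy)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_contrasts_give_zero(self):
        cx = ContrastSet(values=np.array([1.0, 1.0, -1.0, -1.0]))
        cy = ContrastSet(values=np.array([1.0, -1.0, 1.0, -1.0]))
        rho, p = contrast_correlation(cx, cy)
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_too_few_contrasts_rejected(self):
        c = ContrastSet(values=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            contrast_correlation(c, c)

    def test_star_phylogeny_reduces_to_ordinary_correlation(self, rng):
        # on a (resolved) star with unit branches, contrasts are scaled
        # pairwise differences; the PIC correlation approaches the ordinary
        # leaf correlation
        n = 64
        newick = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
        tree = load_tree(newick)
        x = rng.normal(size=n)
        y = 0.8 * x + 0.6 * rng.normal(size=n)
        tx = {f"s{i}": x[i] for i in range(n)}
        ty = {f"s{i}": y[i] for i in range(n)}
        tree = prepare_tree(tree)
        cx = independent_contrasts(tree, tx, resolve=False)
        cy = independent_contrasts(tree, ty, resolve=False)
        rho, _ = contrast_correlation(cx, cy)
        r_leaf = np.corrcoef(x, y)[0, 1]
        assert rho == pytest.approx(r_leaf, abs=0.1)


class TestPicPartialCorrelation:
    def test_confounder_removal(self, rng):
        """Lifespan driven purely by mass; an independent repeat trait must
        show a null partial correlation (the headline methodological point:
        mass and phylogeny control abolish naive correlations)."""
        tree = prepare_tree(_yule_tree(64, 1.0, seed=21))
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        rejected = 0
        n_rep = 100
        naive_sig = 0
        for _ in range(n_rep):
            tr = simulate_bm_traits(tree, np.diag([1.0, 1.0]), np.zeros(2), rng)
            mass = np.array([tr[s][0] for s in leaves])
            repeat = np.array([tr[s][1] for s in leaves])
            lifespan = 0.9 * mass + 0.1 * rng.normal(size=len(leaves))
            _, p_naive = stats.pearsonr(lifespan, repeat)
            naive_sig += p_naive < 0.05
            _, p, _ = pic_partial_correlation(
                tree, dict(zip(leaves, lifespan)), dict(zip(leaves, repeat)),
                controls=[dict(zip(leaves, mass))], resolve=False)
            rejected += p < 0.05
        # naive correlations are frequently spuriously significant ...
        assert naive_sig > 0.25 * n_rep
        # ... while the corrected chain stays near its nominal level
        assert rejected <= 0.12 * n_rep

    def test_leaf_ordering_flag_runs(self, rng):
        tree = prepare_tree(_yule_tree(16, 1.0, seed=2))
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        tr = simulate_bm_traits(tree, np.diag([1.0, 1.0, 1.0]), np.zeros(3), rng)
        args = (tree, {s: tr[s][0] for s in leaves}, {s: tr[s][1] for s in leaves})
        kw = dict(controls=[{s: tr[s][2] for s in leaves}], resolve=False)
        rho_c, _, _ = pic_partial_correlation(*args, order="contrast", **kw)
        rho_l, _, _ = pic_partial_correlation(*args, order="leaf", **kw)
        assert -1 <= rho_c <= 1 and -1 <= rho_l <= 1


class TestSubpopulationTests:
    def test_median_split_sizes(self):
        rep = subpopulation_tests(np.arange(1.0, 11.0), np.arange(10.0), percentile=50)
        assert (rep.n_short, rep.n_long) == (5, 5)
        assert rep.threshold == pytest.approx(5.5)

    def test_identical_distributions_ks_null(self):
        lifespans = np.arange(1.0, 21.0)
        values = np.tile([3.0, 7.0, 1.0, 9.0, 5.0], 4)  # same multiset in both halves
        rep = subpopulation_tests(lifespans, values, percentile=50)
        assert rep.ks_stat == pytest.approx(0.0)
        assert rep.ks_p == pytest.approx(1.0)

    def test_one_sided_power_on_shifted_normals(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            short = rng.normal(1.0, 1.0, size=100)  # short-lived: +1 sd shift
            long_ = rng.normal(0.0, 1.0, size=100)
            lifespans = np.concatenate([np.zeros(100), np.ones(100)])
            values = np.concatenate([short, long_])
            rep = subpopulation_tests(lifespans, values, percentile=50,
                                      alternative="greater")
            hits += rep.t_p < 0.05
        assert hits >= 0.95 * n_rep

    def test_empty_subpopulation_rejected(self):
        with pytest.raises(ValueError):
            subpopulation_tests(np.ones(5), np.arange(5.0), percentile=90)


class TestEnsembleZTest:
    def test_null_case(self):
        z, p = ensemble_z_test(10, (10.0, 2.0))
        assert (z, p) == (0.0, pytest.approx(1.0))

    def test_three_sigma(self):
        z, p = ensemble_z_test(16, (10.0, 2.0))
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(0.0026997, abs=1e-6)

    def test_zero_sd_is_error(self):
        with pytest.raises(ValueError):
            ensemble_z_test(10, (10.0, 0.0))


class TestConstraintLine:
    def test_collinear_support_recovered_exactly(self):
        ids = list("abcde")
        x = np.array([0.0, 1, 2, 3, 4])
        y = 2 * x + 1
        line = constraint_line(ids, x, y, support=["a", "c", "e"])
        assert (line.slope, line.intercept) == (pytest.approx(2.0), pytest.approx(1.0))
        assert line.above == ()

    def test_support_all_points_is_ordinary_regression(self, rng):
        ids = [f"s{i}" for i in range(20)]
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        line = constraint_line(ids, x, y, support=ids)
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert line.slope == pytest.approx(slope)

    def test_five_support_points_match_closed_form(self, rng):
        ids = [f"s{i}" for i in range(30)]
        x = rng.uniform(0, 100, 30)
        y = rng.uniform(0, 20, 30)
        support = ["s1", "s4", "s9", "s16", "s25"]
        line = constraint_line(ids, x, y, support=support, exclude=["s25"])
        idx = [1, 4, 9, 16]
        xs, ys = x[idx], y[idx]
        slope = ((xs - xs.mean()) @ (ys - ys.mean())) / ((xs - xs.mean()) @ (xs - xs.mean()))
        assert line.slope == pytest.approx(slope)
        assert line.support == ("s1", "s4", "s9", "s16")
        for sid in line.above:
            i = ids.index(sid)
            assert y[i] > line.slope * x[i] + line.intercept

    def test_too_few_support_points(self):
        with pytest.raises(ValueError):
            constraint_line(["a", "b"], np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                            support=["a"])


class TestGroupPairwise:
    def test_identical_groups_not_significant(self):
        g = np.arange(30.0)
        mat = group_pairwise_tests({"x": g, "y": g.copy()})
        assert mat.loc["x", "y"] > 0.9

    def test_matrix_symmetric_two_sided(self, rng):
        groups = {k: rng.normal(loc, 1.0, 25) for k, loc in
                  [("a", 0.0), ("b", 0.5), ("c", 1.0)]}
        mat = group_pairwise_tests(groups)
        for i in "abc":
            for j in "abc":
                if i != j:
                    assert mat.loc[i, j] == pytest.approx(mat.loc[j, i])

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)  # 2 sd shift
        mat = group_pairwise_tests({"a": a, "b": b})
        assert mat.loc["a", "b"] < 0.01

    def test_degenerate_group_skipped(self):
        mat = group_pairwise_tests({"a": np.arange(10.0), "b": np.array([1.0])})
        assert np.isnan(mat.loc["a", "b"])
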